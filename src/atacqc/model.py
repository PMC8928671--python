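"""Core data model: genome layout, fragment libraries, peak sets, TSS references.

Coordinates are 0-based half-open (BED convention) throughout.  A fragment
is one sequenced pair; its two mate read intervals are reconstructed from
the fragment ends with a fixed read length: ``[start, min(start+rl, end))``
and ``[max(end-rl, start), end)``.  Mates never extend past the opposite
fragment end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import intervals as iv

MAX_FRAGMENT_LENGTH = 2000  # maximum plausible insert for paired-end mapping
DEFAULT_READ_LENGTH = 75

__all__ = [
    "GenomeLayout",
    "FragmentLibrary",
    "PeakSet",
    "TssReference",
    "mark_duplicates",
    "merge_intervals",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus the nuclear vs mitochondrial partition."""

    lengths: dict[str, int]
    mito: str = "chrM"

    def __post_init__(self) -> None:
        if len(set(self.lengths)) != len(self.lengths):
            raise ValueError("chromosome names must be unique")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def nuclear(self) -> tuple[str, ...]:
        return tuple(c for c in self.lengths if c != self.mito)

    @property
    def nuclear_length(self) -> int:
        return sum(self.lengths[c] for c in self.nuclear)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


class PeakSet:
    """A named set of genomic intervals with optional condition labels.

    Backed by a DataFrame with columns ``chrom``, ``start``, ``end`` and
    optionally ``name`` and ``labels`` (frozensets of condition tokens).
    """

    def __init__(self, df: pd.DataFrame, merged: bool = False):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"PeakSet frame needs columns {sorted(required)}")
        if len(df) and not (df["start"].to_numpy() < df["end"].to_numpy()).all():
            raise ValueError("all intervals must satisfy start < end")
        self.df = df.reset_index(drop=True)
        self.is_merged = merged

    @classmethod
    def from_arrays(cls, chroms, starts, ends, labels=None, **kwargs):
        df = pd.DataFrame(
            {
                "chrom": np.asarray(chroms, dtype=object),
                "start": np.asarray(starts, dtype=np.int64),
                "end": np.asarray(ends, dtype=np.int64),
            }
        )
        if labels is not None:
            df["labels"] = [frozenset(x) for x in labels]
        return cls(df, **kwargs)

    @classmethod
    def empty(cls):
        return cls.from_arrays([], [], [], merged=True)

    def __len__(self) -> int:
        return len(self.df)

    def total_bases(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def merged(self, union_labels: bool = False) -> "PeakSet":
        return merge_intervals(self, union_labels=union_labels)

    def by_chrom(self):
        """Iterate ``(chrom, starts, ends, index)`` sorted by chromosome."""
        for chrom, sub in self.df.groupby("chrom", sort=True, observed=True):
            yield (
                chrom,
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub.index.to_numpy(),
            )

    def chrom_lookup(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Mapping chrom -> (sorted starts, ends); requires a merged set."""
        if not self.is_merged:
            raise ValueError("chrom_lookup requires a merged PeakSet")
        return {
            chrom: (starts, ends) for chrom, starts, ends, _ in self.by_chrom()
        }


def merge_intervals(peaks: PeakSet, union_labels: bool = False) -> PeakSet:
    """bedtools-merge semantics: fuse intervals overlapping by >=1 base.

    Abutting intervals stay separate under half-open coordinates.  With
    ``union_labels``, each merged interval carries the union of the
    condition labels of its members.
    """
    frames = []
    has_labels = union_labels and "labels" in peaks.df.columns
    for chrom, starts, ends, idx in peaks.by_chrom():
        ms, me, gid = iv.merge_arrays(starts, ends)
        frame = pd.DataFrame({"chrom": chrom, "start": ms, "end": me})
        if has_labels:
            labels = peaks.df.loc[idx, "labels"].to_numpy()
            out: list[set] = [set() for _ in range(len(ms))]
            for g, lab in zip(gid, labels):
                out[g] |= lab
            frame["labels"] = [frozenset(x) for x in out]
        frames.append(frame)
    if not frames:
        return PeakSet.empty()
    df = pd.concat(frames, ignore_index=True)
    return PeakSet(df, merged=True)


@dataclass
class FragmentLibrary:
    """Ordered paired-end fragment records plus bookkeeping counts.

    ``records`` columns: chrom (object), start, end (int64), duplicate (bool).
    ``total_reads`` and ``mito_reads`` are pre-deduplication counts (each
    fragment contributes two reads); they survive filtering so that %mito
    keeps its pre-dedup definition.
    """

    records: pd.DataFrame
    layout: GenomeLayout
    read_length: int = DEFAULT_READ_LENGTH
    total_reads: int | None = None
    mito_reads: int | None = None
    dedup_applied: bool = False

    def __post_init__(self) -> None:
        if "duplicate" not in self.records.columns:
            self.records = self.records.assign(
                duplicate=np.zeros(len(self.records), dtype=bool)
            )
        self.records = self.records.reset_index(drop=True)
        if self.total_reads is None:
            self.total_reads = 2 * len(self.records)
        if self.mito_reads is None:
            mito = self.records["chrom"].to_numpy() == self.layout.mito
            self.mito_reads = 2 * int(mito.sum())
        if self.read_length < 1:
            raise ValueError("read length must be >= 1")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_fragments(self) -> int:
        return len(self.records)

    def is_mito(self) -> np.ndarray:
        return self.records["chrom"].to_numpy() == self.layout.mito

    def nuclear(self) -> "FragmentLibrary":
        """View restricted to nuclear fragments; pre-dedup counts preserved."""
        sub = self.records[~self.is_mito()]
        return replace(self, records=sub.reset_index(drop=True))

    def dedup(self) -> "FragmentLibrary":
        """Drop duplicate-flagged records (run mark_duplicates first)."""
        lib = self if self.dedup_applied else mark_duplicates(self)
        sub = lib.records[~lib.records["duplicate"].to_numpy()]
        return replace(lib, records=sub.reset_index(drop=True))

    @property
    def unique_nuclear_fragments(self) -> int:
        lib = self if self.dedup_applied else mark_duplicates(self)
        keep = ~lib.records["duplicate"].to_numpy() & ~lib.is_mito()
        return int(keep.sum())

    def insert_sizes(self) -> np.ndarray:
        return (self.records["end"] - self.records["start"]).to_numpy()

    def mate_spans(self) -> tuple[np.ndarray, np.ndarray]:
        """Read intervals of both mates, concatenated: (starts, ends).

        Mate 1 spans ``[start, min(start+rl, end))`` and mate 2 spans
        ``[max(end-rl, start), end)``; the output has 2x n_fragments rows
        (mate-1 block then mate-2 block, preserving record order within
        each block).
        """
        s = self.records["start"].to_numpy()
        e = self.records["end"].to_numpy()
        rl = self.read_length
        m1s, m1e = s, np.minimum(s + rl, e)
        m2s, m2e = np.maximum(e - rl, s), e
        return np.concatenate([m1s, m2s]), np.concatenate([m1e, m2e])

    def read_5prime_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(chroms, positions) of the single 5' base of every read.

        The plus-strand mate starts at the fragment start; the minus-strand
        mate starts at ``end - 1`` (last covered base).
        """
        chroms = self.records["chrom"].to_numpy()
        s = self.records["start"].to_numpy()
        e = self.records["end"].to_numpy()
        return np.concatenate([chroms, chroms]), np.concatenate([s, e - 1])


def mark_duplicates(lib: FragmentLibrary) -> FragmentLibrary:
    """Flag all but the first record of each identical (chrom, start, end).

    Mirrors coordinate-based duplicate marking of proper pairs: both mates'
    5' positions coincide exactly when the fragment triple does.  Pre-dedup
    read counts are untouched.
    """
    if len(lib.records) == 0:
        raise ValueError("cannot mark duplicates on an empty library")
    dup = lib.records.duplicated(subset=["chrom", "start", "end"], keep="first")
    rec = lib.records.assign(duplicate=dup.to_numpy())
    return replace(lib, records=rec, dedup_applied=True)


@dataclass(frozen=True)
class TssReference:
    """Strand-aware single-base transcription start sites."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "pos", "strand"]
    ))

    def __post_init__(self) -> None:
        if len(self.df):
            bad = ~self.df["strand"].isin(["+", "-"])
            if bad.any():
                raise ValueError("strand must be '+' or '-'")
        dedup = self.df.drop_duplicates(subset=["chrom", "pos", "strand"])
        object.__setattr__(self, "df", dedup.reset_index(drop=True))

    @classmethod
    def from_arrays(cls, chroms, positions, strands):
        return cls(pd.DataFrame({
            "chrom": np.asarray(chroms, dtype=object),
            "pos": np.asarray(positions, dtype=np.int64),
            "strand": np.asarray(strands, dtype=object),
        }))

    def __len__(self) -> int:
        return len(self.df)
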