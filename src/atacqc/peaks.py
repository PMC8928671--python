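"""Desk-scale peak calling and cross-condition peak bookkeeping.

The caller is a deliberate stand-in for MACS2's ``--nomodel --extsize 200
--shift -100`` invocation: every read contributes a 200 bp smoothing window
centered on its 5' start; the per-base pileup is tested against a Poisson
null whose rate is the maximum of the genome-wide window rate and a 10 kb
local rate; per-base p-values are Benjamini-Hochberg adjusted over the
whole nuclear genome; significant bases closer than 30 bp are fused and
regions shorter than 200 bp are discarded.  It reproduces the procedure at
desk scale -- bit-exact MACS2 parity is a non-goal, and narrowPeak files
from real MACS2 runs are accepted wherever a PeakSet is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from . import intervals as iv
from .model import FragmentLibrary, PeakSet, merge_intervals

EXTSIZE = 200        # smoothing window width = minimum peak length
LOCAL_WINDOW = 10_000
MERGE_GAP = 30

__all__ = [
    "call_peaks",
    "subsample_library",
    "ConditionPeakTable",
    "build_condition_table",
    "compare_dedup_nodedup",
    "build_count_matrix",
]


def _pileup_and_starts(positions: np.ndarray, length: int):
    """Smoothing-window pileup and raw 5'-start counts for one chromosome."""
    half = EXTSIZE // 2
    win_s = np.clip(positions - half, 0, length)
    win_e = np.clip(positions + half, 0, length)
    diff = np.bincount(win_s, minlength=length + 1).astype(np.int64)
    np.subtract.at(diff, win_e, 1)
    pileup = np.cumsum(diff)[:length]
    start_counts = np.bincount(positions, minlength=length)
    return pileup, start_counts


def _local_lambda(start_counts: np.ndarray, length: int) -> np.ndarray:
    half = LOCAL_WINDOW // 2
    cumulative = np.concatenate([[0], np.cumsum(start_counts)])
    idx = np.arange(length)
    lo = np.clip(idx - half, 0, length)
    hi = np.clip(idx + half, 0, length)
    window_counts = cumulative[hi] - cumulative[lo]
    return window_counts * (EXTSIZE / LOCAL_WINDOW)


def call_peaks(
    lib: FragmentLibrary,
    qcut: float = 0.05,
    use_duplicates: bool = True,
) -> PeakSet:
    """Poisson pileup peak calling on nuclear reads.

    ``use_duplicates`` mirrors ``--keep-dup all`` (records used as given);
    when False the library is deduplicated first.
    """
    nuclear = lib.nuclear() if use_duplicates else lib.dedup().nuclear()
    if len(nuclear) == 0:
        return PeakSet.empty()

    chroms, positions = nuclear.read_5prime_positions()
    genome_length = lib.layout.nuclear_length
    lam_global = len(positions) * EXTSIZE / genome_length

    per_chrom: dict[str, dict] = {}
    all_pvals: list[np.ndarray] = []
    for chrom in sorted(set(chroms.tolist())):
        length = lib.layout.lengths[chrom]
        pos = positions[chroms == chrom]
        pileup, start_counts = _pileup_and_starts(pos, length)
        lam = np.maximum(lam_global, _local_lambda(start_counts, length))
        tested = np.flatnonzero(pileup > 0)
        pvals = poisson.sf(pileup[tested] - 1, lam[tested])
        per_chrom[chrom] = {
            "pileup": pileup, "tested": tested, "pvals": pvals,
        }
        all_pvals.append(pvals)

    # BH over every base of the nuclear genome: untested (zero-pileup)
    # bases carry p = 1 and sort after all tested bases, so adjusting the
    # tested vector with m = genome_length is exact.
    flat = np.concatenate(all_pvals) if all_pvals else np.empty(0)
    significant_flat = np.zeros(flat.size, dtype=bool)
    if flat.size:
        order = np.argsort(flat, kind="stable")
        ranks = np.arange(1, flat.size + 1)
        stepup = flat[order] * genome_length / ranks
        qvals_sorted = np.minimum.accumulate(stepup[::-1])[::-1]
        sig_sorted = qvals_sorted < qcut
        significant_flat[order] = sig_sorted
        qvals = np.empty(flat.size)
        qvals[order] = np.minimum(qvals_sorted, 1.0)

    rows = []
    offset = 0
    for chrom in sorted(per_chrom):
        info = per_chrom[chrom]
        k = info["pvals"].size
        sig_mask = significant_flat[offset:offset + k]
        sig_positions = info["tested"][sig_mask]
        sig_qvals = qvals[offset:offset + k][sig_mask] if k else np.empty(0)
        offset += k
        if sig_positions.size == 0:
            continue
        # fuse runs of significant bases separated by <= MERGE_GAP
        gaps = np.diff(sig_positions)
        breaks = np.flatnonzero(gaps > MERGE_GAP + 1)
        bounds = np.concatenate([[0], breaks + 1, [sig_positions.size]])
        region_qmin = np.minimum.reduceat(sig_qvals, bounds[:-1])
        pileup = info["pileup"]
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            start = int(sig_positions[a])
            end = int(sig_positions[b - 1]) + 1
            if end - start < EXTSIZE:
                continue
            summit = start + int(np.argmax(pileup[start:end]))
            rows.append(
                (chrom, start, end, int(pileup[summit]), summit,
                 float(region_qmin[i]))
            )

    if not rows:
        return PeakSet.empty()
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "signal", "summit", "qvalue"]
    )
    # regions are built per chromosome from disjoint significant runs, so
    # they are already non-overlapping (the post-hoc merge is a no-op here
    # but kept as an invariant check)
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    df["name"] = [f"peak_{i + 1}" for i in range(len(df))]
    df["score"] = np.minimum(
        1000, (-10 * np.log10(np.maximum(df["qvalue"], 1e-300))).astype(int)
    )
    return PeakSet(df, merged=True)


def subsample_library(
    lib: FragmentLibrary, n_reads: int, seed: int
) -> FragmentLibrary:
    """Uniform, seeded sample of n_reads/2 fragments without replacement.

    Pairs are kept intact and record order is stable (sorted original
    indices), so repeated calls with one seed reproduce bit-identically.
    """
    if n_reads % 2:
        raise ValueError("n_reads must be even (pairs are kept intact)")
    n_pairs = n_reads // 2
    if n_pairs > len(lib):
        raise ValueError(
            f"requested {n_pairs} pairs but only {len(lib)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(len(lib), size=n_pairs, replace=False))
    records = lib.records.iloc[chosen].reset_index(drop=True)
    from dataclasses import replace
    out = replace(lib, records=records)
    out.total_reads = 2 * len(records)
    out.mito_reads = 2 * int(
        (records["chrom"].to_numpy() == lib.layout.mito).sum()
    )
    return out


@dataclass
class ConditionPeakTable:
    """Merged master intervals labeled with contributing conditions."""

    peaks: PeakSet          # merged, with 'labels' column
    conditions: tuple[str, ...]

    def _label_counts(self) -> np.ndarray:
        return np.array([len(l) for l in self.peaks.df["labels"]])

    def reproducible(self, min_conditions: int = 3) -> PeakSet:
        """Master intervals detected in at least ``min_conditions``."""
        keep = self._label_counts() >= min_conditions
        return PeakSet(self.peaks.df[keep].reset_index(drop=True), merged=True)

    def missing(self, condition: str, min_conditions: int = 3) -> PeakSet:
        """Peaks reproducible in >= min_conditions others but absent here."""
        if condition not in self.conditions:
            raise KeyError(f"unknown condition label {condition!r}")
        labels = self.peaks.df["labels"]
        keep = np.array([
            condition not in l and len(l - {condition}) >= min_conditions
            for l in labels
        ])
        return PeakSet(self.peaks.df[keep].reset_index(drop=True), merged=True)


def build_condition_table(
    per_condition_peaks: list[tuple[str, PeakSet]],
) -> ConditionPeakTable:
    """Concatenate per-condition calls into a labeled master peak table.

    Peaks overlapping by >=1 base across conditions fuse into one master
    interval carrying the union of contributing condition labels.
    """
    labels = [label for label, _ in per_condition_peaks]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate condition labels")
    if len(labels) < 2:
        raise ValueError("need at least two conditions")
    frames = []
    for label, peaks in per_condition_peaks:
        df = peaks.df[["chrom", "start", "end"]].copy()
        df["labels"] = [frozenset([label])] * len(df)
        frames.append(df)
    combined = PeakSet(pd.concat(frames, ignore_index=True))
    merged = merge_intervals(combined, union_labels=True)
    return ConditionPeakTable(peaks=merged, conditions=tuple(labels))


def compare_dedup_nodedup(
    peaks_a: PeakSet, peaks_b: PeakSet
) -> dict[str, PeakSet]:
    """Partition two peak sets into shared / unique-to-a / unique-to-b.

    "Shared" intervals (>=1 bp overlap across the inputs) are counted on
    merged coordinates of the union, as in a collapse-style bedtools merge
    of both call sets.
    """
    table = build_condition_table([("a", peaks_a), ("b", peaks_b)])
    df = table.peaks.df
    n_labels = df["labels"].map(len)
    shared = PeakSet(df[n_labels == 2].reset_index(drop=True), merged=True)
    only_a = PeakSet(
        df[df["labels"].map(lambda l: l == frozenset(["a"]))].reset_index(drop=True),
        merged=True,
    )
    only_b = PeakSet(
        df[df["labels"].map(lambda l: l == frozenset(["b"]))].reset_index(drop=True),
        merged=True,
    )
    return {"shared": shared, "unique_a": only_a, "unique_b": only_b}


def build_count_matrix(
    libs: list[tuple[str, FragmentLibrary]],
    common_peaks: PeakSet,
) -> pd.DataFrame:
    """Reads-in-peak count matrix: peaks as rows, samples as columns.

    Entry (p, s) is the number of deduplicated nuclear reads (mates) of
    sample s overlapping peak p by >=1 base.
    """
    merged = common_peaks if common_peaks.is_merged else common_peaks.merged()
    if len(merged) == 0:
        return pd.DataFrame(index=pd.Index([], name="peak"))
    peak_index = [
        f"{c}:{s}-{e}"
        for c, s, e in zip(
            merged.df["chrom"], merged.df["start"], merged.df["end"]
        )
    ]
    matrix = pd.DataFrame(
        0, index=pd.Index(peak_index, name="peak"),
        columns=[name for name, _ in libs], dtype=np.int64,
    )
    for name, lib in libs:
        dedup = lib.dedup().nuclear()
        chroms = dedup.records["chrom"].to_numpy()
        starts, ends = dedup.mate_spans()
        span_chroms = np.concatenate([chroms, chroms])
        counts = np.zeros(len(merged), dtype=np.int64)
        for chrom, ps, pe, idx in merged.by_chrom():
            mask = span_chroms == chrom
            counts[idx] = iv.count_overlapping_spans(
                starts[mask], ends[mask], ps, pe
            )
        matrix[name] = counts
    return matrix
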