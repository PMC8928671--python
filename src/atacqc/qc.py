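"""The five ATAC-seq library-quality metrics.

* FRiP: fraction of deduplicated non-mitochondrial reads (mates counted
  independently) overlapping a merged reference peak set by >=1 base.
* TSS enrichment: aggregate per-base read coverage over a 4000 bp window
  centered on each TSS, normalized by the mean depth of the 100 outermost
  bases at each end; the score is the maximum normalized depth in the
  200 bp upstream of the TSS (strand-aware).
* Sub-nucleosomal score: histogram maximum below 150 bp over the maximum
  at >=150 bp.
* %mito: percent of all post-trim reads on the mitochondrial chromosome,
  counted before duplicate removal.
* Estimated complexity: Lander-Waterman saturation model, solving
  ``unique = X * (1 - exp(-total / X))`` for the latent pool size X.

Undefined metrics (zero denominators) raise :class:`UndefinedMetricError`;
:func:`qc_report` converts them into explicit missing values with reasons,
never silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import intervals as iv
from .model import FragmentLibrary, PeakSet, TssReference

TSS_WINDOW = 2000          # half-width of the profile window
TSS_FLANK = 100            # outermost bases per end used for normalization
SUBNUC_CUTOFF = 150        # insert sizes below this are "sub-nucleosomal"

__all__ = [
    "UndefinedMetricError",
    "InsertSizeHistogram",
    "QcReport",
    "frip",
    "tss_profile",
    "tss_enrichment",
    "insert_size_histogram",
    "subnucleosomal_score",
    "pct_mito",
    "estimate_complexity",
    "qc_report",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is degenerate; the value does not exist."""


@dataclass
class InsertSizeHistogram:
    """Deduplicated fragment counts in 1 bp insert-size bins."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        for size, count in self.counts.items():
            if size < 1 or count < 0:
                raise ValueError("sizes must be >=1 and counts >=0")


def insert_size_histogram(lib: FragmentLibrary) -> InsertSizeHistogram:
    sizes = lib.dedup().insert_sizes()
    values, counts = np.unique(sizes, return_counts=True)
    return InsertSizeHistogram(dict(zip(values.tolist(), counts.tolist())))


def frip(
    lib: FragmentLibrary,
    ref_peaks: PeakSet,
    fragment_level: bool = False,
) -> float:
    """Fraction of dedup nuclear reads overlapping the reference peaks.

    Each mate counts independently as a read interval (bedtools
    ``intersect -u`` on reads); set ``fragment_level`` to count whole
    fragments instead.
    """
    dedup = lib.dedup().nuclear()
    if len(dedup) == 0:
        raise UndefinedMetricError("no deduplicated nuclear reads")
    merged = ref_peaks if ref_peaks.is_merged else ref_peaks.merged()
    lookup = merged.chrom_lookup()
    if fragment_level:
        chroms = dedup.records["chrom"].to_numpy()
        starts = dedup.records["start"].to_numpy()
        ends = dedup.records["end"].to_numpy()
    else:
        chroms, _ = dedup.read_5prime_positions()
        starts, ends = dedup.mate_spans()
    hits = 0
    for chrom in np.unique(chroms):
        if chrom not in lookup:
            continue
        mask = chroms == chrom
        ms, me = lookup[chrom]
        hits += int(iv.spans_overlap_any(starts[mask], ends[mask], ms, me).sum())
    return hits / len(starts)


def tss_profile(lib: FragmentLibrary, tss: TssReference) -> np.ndarray:
    """Aggregate read-span coverage over TSS-centered windows.

    Returns a length-4000 array whose index i corresponds to offset
    i - 2000 from the TSS in the upstream-to-downstream orientation
    (minus-strand windows are flipped before aggregation).
    """
    if len(tss) == 0:
        raise UndefinedMetricError("empty TSS reference")
    dedup = lib.dedup().nuclear()
    width = 2 * TSS_WINDOW
    profile = np.zeros(width, dtype=np.float64)
    chroms = dedup.records["chrom"].to_numpy()
    starts, ends = dedup.mate_spans()
    span_chroms = np.concatenate([chroms, chroms])
    for chrom, sub in tss.df.groupby("chrom", sort=True):
        length = lib.layout.lengths.get(chrom)
        if length is None:
            continue
        mask = span_chroms == chrom
        s = np.clip(starts[mask], 0, length)
        e = np.clip(ends[mask], 0, length)
        diff = np.bincount(s, minlength=length + 1).astype(np.int64)
        np.subtract.at(diff, e, 1)
        coverage = np.cumsum(diff)[:length]
        for pos, strand in zip(sub["pos"].to_numpy(), sub["strand"]):
            # profile index i holds offset i - TSS_WINDOW; offset 0 is the
            # TSS base on either strand (minus-strand windows are mirrored
            # around the TSS base, so "upstream" means higher coordinates)
            if strand == "-":
                lo, hi = pos - TSS_WINDOW + 1, pos + TSS_WINDOW + 1
            else:
                lo, hi = pos - TSS_WINDOW, pos + TSS_WINDOW
            window = np.zeros(width, dtype=np.float64)
            src_lo, src_hi = max(lo, 0), min(hi, length)
            if src_hi > src_lo:
                window[src_lo - lo:src_hi - lo] = coverage[src_lo:src_hi]
            if strand == "-":
                window = window[::-1]
            profile += window
    return profile


def tss_enrichment(
    lib: FragmentLibrary,
    tss: TssReference,
    window: str = "upstream200",
) -> float:
    """Fold enrichment of TSS-proximal coverage over outer-flank coverage.

    ``window`` selects where the maximum of the normalized profile is
    taken: ``upstream200`` uses offsets [-200, -1] relative to the TSS;
    ``centered200`` uses the symmetric [-200, +199] window.
    """
    profile = tss_profile(lib, tss)
    flank = np.concatenate([profile[:TSS_FLANK], profile[-TSS_FLANK:]])
    flank_mean = flank.mean()
    if flank_mean == 0:
        raise UndefinedMetricError("zero coverage in the TSS window flanks")
    normalized = profile / flank_mean
    center = TSS_WINDOW
    if window == "upstream200":
        region = normalized[center - 200:center]
    elif window == "centered200":
        region = normalized[center - 200:center + 200]
    else:
        raise ValueError(f"unknown TSS window mode {window!r}")
    return float(region.max())


def subnucleosomal_score(hist: InsertSizeHistogram) -> float:
    """max counts at sizes < 150 bp over max counts at sizes >= 150 bp."""
    if not hist.counts:
        raise UndefinedMetricError("empty insert-size histogram")
    sub = [c for s, c in hist.counts.items() if s < SUBNUC_CUTOFF]
    nuc = [c for s, c in hist.counts.items() if s >= SUBNUC_CUTOFF]
    if not sub or not nuc:
        raise UndefinedMetricError(
            "insert-size histogram lacks one side of the 150 bp boundary"
        )
    return max(sub) / max(nuc)


def pct_mito(lib: FragmentLibrary) -> float:
    """Percent mitochondrial reads, computed BEFORE duplicate removal."""
    if not lib.total_reads:
        raise UndefinedMetricError("zero total reads")
    return 100.0 * lib.mito_reads / lib.total_reads


def estimate_complexity(total_fragments: int, unique_fragments: int) -> float:
    """Latent library size under the Lander-Waterman saturation model.

    Solves ``unique = X * (1 - exp(-total/X))`` for X to 1e-9 relative
    tolerance.  ``unique == total`` (no duplicates observed) returns
    ``math.inf``.
    """
    if unique_fragments > total_fragments:
        raise ValueError("unique fragments cannot exceed total fragments")
    if unique_fragments <= 0 or total_fragments <= 0:
        raise UndefinedMetricError("need positive fragment counts")
    if unique_fragments == total_fragments:
        return math.inf

    def saturation_gap(x: float) -> float:
        return x * (1.0 - math.exp(-total_fragments / x)) - unique_fragments

    hi = float(unique_fragments)
    while saturation_gap(hi) <= 0:
        hi *= 2.0
    return float(brentq(saturation_gap, unique_fragments / 2.0, hi, rtol=1e-9))


@dataclass
class QcReport:
    """The five metrics plus supporting counts for one library.

    Metrics that are undefined for this library are ``None``, with the
    reason recorded in ``missing_reasons``.
    """

    frip: float | None
    tss_enrichment: float | None
    subnucleosomal_score: float | None
    pct_mito: float | None
    estimated_complexity: float | None
    total_reads: int = 0
    mito_reads: int = 0
    dedup_nuclear_reads: int = 0
    reads_in_peaks: int = 0
    total_fragments: int = 0
    unique_fragments: int = 0
    missing_reasons: dict[str, str] = field(default_factory=dict)

    METRICS = (
        "frip", "tss_enrichment", "subnucleosomal_score",
        "pct_mito", "estimated_complexity",
    )

    def as_row(self) -> dict:
        row = {m: getattr(self, m) for m in self.METRICS}
        row.update(
            total_reads=self.total_reads,
            mito_reads=self.mito_reads,
            dedup_nuclear_reads=self.dedup_nuclear_reads,
            total_fragments=self.total_fragments,
            unique_fragments=self.unique_fragments,
        )
        return row


def qc_report(
    lib: FragmentLibrary,
    ref_peaks: PeakSet | None = None,
    tss: TssReference | None = None,
    tss_window: str = "upstream200",
) -> QcReport:
    """Compute all five metrics, carrying undefined ones as missing values."""
    missing: dict[str, str] = {}
    values: dict[str, float | None] = {}

    if len(lib) == 0:
        reasons = {m: "empty library" for m in QcReport.METRICS}
        return QcReport(None, None, None, None, None, missing_reasons=reasons)

    from .model import mark_duplicates

    marked = lib if lib.dedup_applied else mark_duplicates(lib)

    def attempt(name: str, fn):
        try:
            values[name] = fn()
        except UndefinedMetricError as exc:
            values[name] = None
            missing[name] = str(exc)

    attempt(
        "frip",
        (lambda: frip(marked, ref_peaks))
        if ref_peaks is not None
        else (lambda: (_ for _ in ()).throw(
            UndefinedMetricError("no reference peak set supplied"))),
    )
    attempt(
        "tss_enrichment",
        (lambda: tss_enrichment(marked, tss, window=tss_window))
        if tss is not None
        else (lambda: (_ for _ in ()).throw(
            UndefinedMetricError("no TSS reference supplied"))),
    )
    attempt(
        "subnucleosomal_score",
        lambda: subnucleosomal_score(insert_size_histogram(marked)),
    )
    attempt("pct_mito", lambda: pct_mito(marked))

    nuclear = marked.nuclear()
    total_frags = len(nuclear)
    unique_frags = marked.unique_nuclear_fragments
    attempt(
        "estimated_complexity",
        lambda: estimate_complexity(total_frags, unique_frags),
    )

    dedup_nuclear = marked.dedup().nuclear()
    reads_in_peaks = 0
    if values.get("frip") is not None:
        reads_in_peaks = round(values["frip"] * 2 * len(dedup_nuclear))

    return QcReport(
        frip=values.get("frip"),
        tss_enrichment=values.get("tss_enrichment"),
        subnucleosomal_score=values.get("subnucleosomal_score"),
        pct_mito=values.get("pct_mito"),
        estimated_complexity=values.get("estimated_complexity"),
        total_reads=marked.total_reads,
        mito_reads=marked.mito_reads,
        dedup_nuclear_reads=2 * len(dedup_nuclear),
        reads_in_peaks=reads_in_peaks,
        total_fragments=len(marked),
        unique_fragments=unique_frags,
        missing_reasons=missing,
    )
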