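"""Functional-bias statistics against ChIP-seq peaks and genome segments.

The central test asks whether the accessibility peaks a condition *fails*
to recover (its "missing" peaks: reproducibly detected in at least three
other conditions but absent here) overlap a factor's ChIP-seq peaks more
often than the reproducible background does.  With B background peaks of
which K overlap the ChIP set, and n missing peaks of which k overlap, the
p-value is the hypergeometric upper tail P(X >= k) -- the
``phyper(k-1, K, B-K, n, lower.tail=FALSE)`` convention -- and the fold
enrichment is (k/n)/(K/B).

Coverage matrices follow the FRiP-ChIP / FRiP-TF definitions: FRiP-ChIP is
the fraction of deduplicated nuclear reads in the merged union of all ChIP
peaks; FRiP-TF for factor f is the fraction of those ChIP-overlapping
reads that fall in f's peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from . import intervals as iv
from .model import FragmentLibrary, PeakSet, merge_intervals
from .peaks import ConditionPeakTable

__all__ = [
    "EnrichmentResult",
    "CoverageMatrix",
    "missing_peak_enrichment",
    "adjust_bh",
    "frip_chip_tf",
    "summarize_matrix",
    "annotate_segments",
]


@dataclass
class EnrichmentResult:
    """One condition x factor hypergeometric enrichment outcome."""

    factor: str
    condition: str
    p_value: float
    fold: float
    k: int              # missing peaks overlapping the ChIP set
    n: int              # missing peaks
    K: int              # background peaks overlapping the ChIP set
    B: int              # background peaks
    chip_peaks: int
    adjusted_p: float | None = None
    testable: bool = True

    def as_row(self) -> dict:
        return {
            "factor": self.factor, "condition": self.condition,
            "p_value": self.p_value, "adjusted_p": self.adjusted_p,
            "fold": self.fold, "k": self.k, "n": self.n,
            "K": self.K, "B": self.B, "chip_peaks": self.chip_peaks,
            "testable": self.testable,
        }


def _count_overlapping(query: PeakSet, reference: PeakSet) -> int:
    """Number of query intervals overlapping the reference by >=1 base."""
    merged = reference if reference.is_merged else reference.merged()
    lookup = merged.chrom_lookup()
    hits = 0
    for chrom, starts, ends, _ in query.by_chrom():
        if chrom not in lookup:
            continue
        ms, me = lookup[chrom]
        hits += int(iv.spans_overlap_any(starts, ends, ms, me).sum())
    return hits


def missing_peak_enrichment(
    table: ConditionPeakTable,
    condition: str,
    chip: PeakSet,
    factor: str = "",
    min_conditions: int = 3,
) -> EnrichmentResult:
    """Hypergeometric enrichment of a condition's missing peaks in ChIP peaks.

    Background = master peaks detected in >= ``min_conditions`` conditions;
    missing = peaks detected in >= ``min_conditions`` conditions other than
    ``condition`` and not in ``condition`` itself.  Results with n == 0 or
    K == 0 are flagged untestable (p = 1, fold = nan).
    """
    background = table.reproducible(min_conditions)
    missing = table.missing(condition, min_conditions)
    B, n = len(background), len(missing)
    K = _count_overlapping(background, chip) if B else 0
    k = _count_overlapping(missing, chip) if n else 0
    if n == 0 or K == 0:
        return EnrichmentResult(
            factor=factor, condition=condition, p_value=1.0,
            fold=float("nan"), k=k, n=n, K=K, B=B,
            chip_peaks=len(chip), testable=False,
        )
    p_value = float(hypergeom.sf(k - 1, B, K, n))
    fold = (k / n) / (K / B)
    return EnrichmentResult(
        factor=factor, condition=condition, p_value=p_value, fold=fold,
        k=k, n=n, K=K, B=B, chip_peaks=len(chip),
    )


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvalues, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)) or np.any(np.isnan(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def enrichment_table(
    table: ConditionPeakTable,
    chip_sets: list[tuple[str, PeakSet]],
    conditions: list[str] | None = None,
    min_conditions: int = 3,
) -> pd.DataFrame:
    """All condition x factor enrichments, BH-adjusted within condition."""
    conditions = list(conditions or table.conditions)
    rows: list[EnrichmentResult] = []
    for condition in conditions:
        batch = [
            missing_peak_enrichment(
                table, condition, chip, factor=factor,
                min_conditions=min_conditions,
            )
            for factor, chip in chip_sets
        ]
        testable = [r for r in batch if r.testable]
        if testable:
            adjusted = adjust_bh([r.p_value for r in testable])
            for r, adj in zip(testable, adjusted):
                r.adjusted_p = float(adj)
        rows.extend(batch)
    return pd.DataFrame([r.as_row() for r in rows])


@dataclass
class CoverageMatrix:
    """Factors (or segment classes) x samples coverage-fraction matrix."""

    values: pd.DataFrame
    kind: str = "frip_tf"

    def zscores(self, cap: float | None = None) -> pd.DataFrame:
        """Row-wise z-scores (sample sd, ddof=1); zero-sd rows become 0.

        ``cap`` clips for display export only -- stored values are never
        capped.
        """
        mean = self.values.mean(axis=1)
        sd = self.values.std(axis=1, ddof=1)
        z = self.values.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
        z = z.fillna(0.0)
        if cap is not None:
            z = z.clip(-cap, cap)
        return z

    def mad(self) -> pd.Series:
        """Per-row median absolute deviation (unscaled)."""
        med = self.values.median(axis=1)
        return (self.values.sub(med, axis=0)).abs().median(axis=1)


def frip_chip_tf(
    lib: FragmentLibrary,
    chip_sets: list[tuple[str, PeakSet]],
) -> tuple[float, pd.Series]:
    """FRiP-ChIP plus the per-factor FRiP-TF column for one library.

    Returns ``(frip_chip, frip_tf)`` where ``frip_tf[f]`` is the fraction
    of ChIP-overlapping reads that overlap factor f's peaks.  When no read
    overlaps any ChIP peak, FRiP-ChIP is 0 and the FRiP-TF column is all
    missing (NaN).
    """
    dedup = lib.dedup().nuclear()
    if len(dedup) == 0:
        raise ValueError("library has no deduplicated nuclear reads")
    chroms = dedup.records["chrom"].to_numpy()
    starts, ends = dedup.mate_spans()
    span_chroms = np.concatenate([chroms, chroms])

    def hit_mask(peaks: PeakSet) -> np.ndarray:
        merged = peaks if peaks.is_merged else peaks.merged()
        mask = np.zeros(starts.size, dtype=bool)
        for chrom, (ms, me) in merged.chrom_lookup().items():
            sel = span_chroms == chrom
            mask[sel] = iv.spans_overlap_any(starts[sel], ends[sel], ms, me)
        return mask

    union = merge_intervals(PeakSet(pd.concat(
        [p.df[["chrom", "start", "end"]] for _, p in chip_sets],
        ignore_index=True,
    )))
    any_hit = hit_mask(union)
    n_any = int(any_hit.sum())
    frip_chip = n_any / starts.size
    if n_any == 0:
        tf = pd.Series(
            np.nan, index=[f for f, _ in chip_sets], name="frip_tf"
        )
        return frip_chip, tf
    tf_values = {
        factor: int(hit_mask(peaks).sum()) / n_any
        for factor, peaks in chip_sets
    }
    return frip_chip, pd.Series(tf_values, name="frip_tf")


def summarize_matrix(matrix: CoverageMatrix, cap: float = 1.5):
    """Row-wise z-scores (capped copy for display) and per-row MAD."""
    if matrix.values.shape[1] < 2:
        raise ValueError("need at least two sample columns")
    return {
        "z": matrix.zscores(),
        "z_display": matrix.zscores(cap=cap),
        "mad": matrix.mad(),
    }


def annotate_segments(
    lib: FragmentLibrary, segments: PeakSet
) -> pd.Series:
    """Per-class fraction of dedup reads, assigned by each read's 5' base.

    ``segments`` must carry a ``name`` column with class labels and must
    partition the genome (overlapping intervals of different classes are a
    hard error).  Reads whose 5' base falls in an unannotated gap count in
    no class, so fractions may sum to < 1.
    """
    if "name" not in segments.df.columns:
        raise ValueError("segments need a 'name' column with class labels")
    dedup = lib.dedup().nuclear()
    if len(dedup) == 0:
        raise ValueError("library has no deduplicated nuclear reads")
    chroms, positions = dedup.read_5prime_positions()
    classes = sorted(set(segments.df["name"]))
    counts = {c: 0 for c in classes}
    for chrom, starts, ends, idx in segments.by_chrom():
        order = np.argsort(starts, kind="stable")
        s, e = starts[order], ends[order]
        if np.any(s[1:] < e[:-1]):
            raise ValueError(
                f"segmentation intervals overlap on {chrom}; "
                "classes must partition the genome"
            )
        labels = segments.df.loc[idx, "name"].to_numpy()[order]
        sel = chroms == chrom
        which = iv.points_in_intervals(positions[sel], s, e)
        hit = which[which >= 0]
        for j, c in zip(*np.unique(hit, return_counts=True)):
            counts[labels[j]] += int(c)
    total = positions.size
    return pd.Series(
        {c: counts[c] / total for c in classes}, name="fraction"
    )
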