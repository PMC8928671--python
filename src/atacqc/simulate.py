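"""Defined-FRiP library simulation.

Deduplicated read pairs are partitioned into a "signal" pool (at least one
mate overlapping a master peak set) and a "background" pool (neither mate
overlapping).  Libraries with a prescribed fraction of signal pairs and a
prescribed read depth are then reconstituted by seeded sampling without
replacement, pairs kept intact, and the grid of (defined FRiP x depth x
replicate) cells is swept while recording peak counts and all reference
variants of FRiP plus TSS enrichment and the sub-nucleosomal score.

Depth is counted in reads (mates): a depth of 1,000,000 reads means
500,000 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import intervals as iv
from . import qc
from .model import FragmentLibrary, PeakSet, TssReference
from .peaks import call_peaks

__all__ = [
    "SignalBackgroundPartition",
    "SimulationGrid",
    "partition_by_peaks",
    "construct_defined_frip",
    "run_grid",
]

DESK_DEPTHS = (200_000, 500_000, 1_000_000)
PAPER_DEPTHS = tuple(range(10_000_000, 50_000_001, 5_000_000))
DEFAULT_FRIPS = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass
class SignalBackgroundPartition:
    """Disjoint signal/background fragment pools from one library."""

    signal: FragmentLibrary
    background: FragmentLibrary

    @property
    def n_signal(self) -> int:
        return len(self.signal)

    @property
    def n_background(self) -> int:
        return len(self.background)


def partition_by_peaks(
    lib: FragmentLibrary, master: PeakSet
) -> SignalBackgroundPartition:
    """Classify deduplicated nuclear pairs by mate-level peak overlap.

    A pair goes to the signal pool when at least one of its two mate read
    intervals overlaps the master peak set by >=1 base.
    """
    dedup = lib.dedup().nuclear()
    merged = master if master.is_merged else master.merged()
    lookup = merged.chrom_lookup()
    n = len(dedup)
    chroms = dedup.records["chrom"].to_numpy()
    starts, ends = dedup.mate_spans()
    mate_hit = np.zeros(2 * n, dtype=bool)
    for chrom, (ms, me) in lookup.items():
        mask = np.concatenate([chroms, chroms]) == chrom
        mate_hit[mask] = iv.spans_overlap_any(starts[mask], ends[mask], ms, me)
    pair_hit = mate_hit[:n] | mate_hit[n:]
    signal = replace(dedup, records=dedup.records[pair_hit].reset_index(drop=True))
    background = replace(
        dedup, records=dedup.records[~pair_hit].reset_index(drop=True)
    )
    for pool in (signal, background):
        pool.total_reads = 2 * len(pool)
        pool.mito_reads = 0
    return SignalBackgroundPartition(signal=signal, background=background)


def construct_defined_frip(
    part: SignalBackgroundPartition,
    target_frip: float,
    depth_reads: int,
    seed: int,
) -> FragmentLibrary:
    """Reconstitute a library at a defined signal fraction and read depth."""
    if not 0 < target_frip <= 1:
        raise ValueError("target FRiP must be in (0, 1]")
    if depth_reads % 2:
        raise ValueError("depth must be an even number of reads")
    n_pairs = depth_reads // 2
    n_signal = round(target_frip * n_pairs)
    n_background = n_pairs - n_signal
    if n_signal > part.n_signal:
        raise ValueError(
            f"need {n_signal} signal pairs, pool has {part.n_signal} "
            f"(short by {n_signal - part.n_signal})"
        )
    if n_background > part.n_background:
        raise ValueError(
            f"need {n_background} background pairs, pool has "
            f"{part.n_background} (short by {n_background - part.n_background})"
        )
    rng = np.random.default_rng(seed)
    sig_idx = np.sort(rng.choice(part.n_signal, size=n_signal, replace=False))
    bg_idx = np.sort(
        rng.choice(part.n_background, size=n_background, replace=False)
    )
    records = pd.concat(
        [part.signal.records.iloc[sig_idx], part.background.records.iloc[bg_idx]],
        ignore_index=True,
    )
    out = replace(part.signal, records=records)
    out.total_reads = 2 * len(records)
    out.mito_reads = 0
    out.dedup_applied = True  # pools were deduplicated; sampling w/o replacement
    return out


def _cell_seed(master_seed: int, frip_level: float, depth: int, rep: int) -> int:
    """Deterministic per-cell seed below 2**31."""
    mix = np.random.SeedSequence(
        [int(master_seed), int(round(frip_level * 1000)), int(depth), int(rep)]
    )
    return int(mix.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


@dataclass
class SimulationGrid:
    """Defined-FRiP x depth x replicate design with per-cell outcomes."""

    frip_levels: tuple[float, ...] = DEFAULT_FRIPS
    depths: tuple[int, ...] = DESK_DEPTHS
    replicates: int = 3
    seed: int = 0
    outcomes: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not all(0 < f < 1 for f in self.frip_levels):
            raise ValueError("FRiP levels must lie in (0, 1)")
        if any(d % 2 for d in self.depths):
            raise ValueError("depths must be even read counts")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def summary(self) -> pd.DataFrame:
        """Mean and min-max per grid cell (the error-bar convention)."""
        if self.outcomes is None:
            raise ValueError("run the grid first")
        return (
            self.outcomes
            .groupby(["frip_level", "depth", "metric"])["value"]
            .agg(["mean", "min", "max"])
            .reset_index()
        )


def run_grid(
    part: SignalBackgroundPartition,
    grid: SimulationGrid,
    master: PeakSet,
    external: PeakSet | None = None,
    tss: TssReference | None = None,
    call_subsample_peaks: bool = True,
    qcut: float = 0.05,
) -> SimulationGrid:
    """Sweep the grid, recording per-cell metric outcomes in long format.

    Per-cell failures (e.g. infeasible pool sizes) are recorded as
    ``error`` rows and the sweep continues.
    """
    master_merged = master if master.is_merged else master.merged()
    external_merged = (
        external.merged() if external is not None and not external.is_merged
        else external
    )
    rows: list[dict] = []

    def record(level, depth, rep, metric, value):
        rows.append({
            "frip_level": level, "depth": depth, "replicate": rep,
            "metric": metric, "value": value,
        })

    for level in grid.frip_levels:
        for depth in grid.depths:
            for rep in range(grid.replicates):
                cell_seed = _cell_seed(grid.seed, level, depth, rep)
                try:
                    lib = construct_defined_frip(part, level, depth, cell_seed)
                except ValueError as exc:
                    record(level, depth, rep, "error", float("nan"))
                    continue
                record(
                    level, depth, rep, "aggregate_frip",
                    qc.frip(lib, master_merged),
                )
                if external_merged is not None:
                    record(
                        level, depth, rep, "external_frip",
                        qc.frip(lib, external_merged),
                    )
                if tss is not None and len(tss):
                    try:
                        record(
                            level, depth, rep, "tss_enrichment",
                            qc.tss_enrichment(lib, tss),
                        )
                    except qc.UndefinedMetricError:
                        pass
                try:
                    record(
                        level, depth, rep, "subnucleosomal_score",
                        qc.subnucleosomal_score(qc.insert_size_histogram(lib)),
                    )
                except qc.UndefinedMetricError:
                    pass
                if call_subsample_peaks:
                    own_peaks = call_peaks(lib, qcut=qcut)
                    record(level, depth, rep, "peak_count", float(len(own_peaks)))
                    if len(own_peaks):
                        record(
                            level, depth, rep, "subsample_frip",
                            qc.frip(lib, own_peaks),
                        )
    out = replace(grid)
    out.outcomes = pd.DataFrame(rows)
    return out
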