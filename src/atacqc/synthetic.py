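"""Seeded generator of genomes, annotations and fragment libraries.

The generator emulates the statistical structure the analysis assumes so
every stage runs without downloads:

* a small diploid-agnostic genome (two 5 Mb nuclear chromosomes plus a
  16.5 kb mitochondrial chromosome);
* a planted landscape of disjoint accessibility peaks with heavy-tailed
  (lognormal) strengths, a configurable fraction of which contain a TSS;
* fragment libraries drawn *with replacement* from a finite latent pool of
  distinct molecules, so duplicates arise exactly as the Lander-Waterman
  saturation model assumes;
* signal fragments placed wholly inside their source peak (mate-level
  peak classification is therefore exact), background fragments placed
  uniformly in the inter-peak gaps, insert sizes drawn from a tri-modal
  sub-nucleosomal / mono-nucleosome / di-nucleosome mixture, and a
  configurable fraction of molecules on the mitochondrial chromosome;
* per-factor-class coverage multipliers emulating condition-specific
  biases, plus ChIP peak sets (class peaks + decoys) and a 7-class genome
  segmentation that tiles the genome exactly.

All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    FragmentLibrary,
    GenomeLayout,
    PeakSet,
    TssReference,
)

__all__ = [
    "GeneratorConfig",
    "Annotation",
    "generate_annotation",
    "generate_library",
    "generate_condition_panel",
    "write_gtf_lite",
]

SEGMENT_CLASSES = ("TSS", "E", "WE", "CTCF", "R", "T", "PF")
# substream indices off the master seed
_STREAMS = {"annotation": 0, "library": 1, "panel": 2}
MIN_INSERT = 20


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic data generator.

    Library defaults follow the median profile of a good native
    preparation: FRiP 0.34, 24% mitochondrial reads, sub-nucleosomal
    mixture weights giving a score near 1.9, and a latent complexity well
    above the default depth so duplication stays light.
    """

    seed: int = 0
    # genome
    n_nuclear_chroms: int = 2
    nuclear_chrom_length: int = 5_000_000
    mito_length: int = 16_500
    mito_name: str = "chrM"
    # peak landscape
    n_peaks: int = 300
    peak_width_min: int = 400
    peak_width_max: int = 1000
    tss_peak_fraction: float = 0.3
    peak_weight_sigma: float = 0.6     # lognormal strength spread
    # library
    n_fragments: int = 200_000
    frip: float = 0.34
    tss_enrichment_strength: float = 4.0
    tss_jitter: float = 100.0
    size_weights: tuple[float, float, float] = (0.50, 0.37, 0.13)
    size_means: tuple[float, float, float] = (75.0, 200.0, 380.0)
    size_sds: tuple[float, float, float] = (25.0, 35.0, 60.0)
    mito_fraction: float = 0.24
    complexity: int = 1_500_000
    read_length: int = 75
    # condition effects / ChIP landscape
    factor_names: tuple[str, ...] = ("CTCF", "POLR2A", "EP300", "RAD21", "TBP")
    factor_assigned_fraction: float = 0.8
    chip_decoys_per_factor: int = 40
    chip_decoy_width: tuple[int, int] = (300, 800)
    # segmentation
    segment_block_min: int = 2_000
    segment_block_max: int = 20_000

    def __post_init__(self) -> None:
        for name, value in (
            ("frip", self.frip),
            ("tss_peak_fraction", self.tss_peak_fraction),
            ("mito_fraction", self.mito_fraction),
            ("factor_assigned_fraction", self.factor_assigned_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.size_weights) - 1.0) > 1e-9:
            raise ValueError("size mixture weights must sum to 1")
        if self.peak_width_min < MIN_INSERT:
            raise ValueError(
                f"peaks narrower than the minimum insert ({MIN_INSERT} bp) "
                "cannot host fragments"
            )

    def stream(self, name: str, extra: tuple[int, ...] = ()) -> np.random.Generator:
        key = (_STREAMS[name],) + extra
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=key)
        )


@dataclass
class Annotation:
    """Generated genome layout, peak landscape and functional annotation."""

    layout: GenomeLayout
    peaks: PeakSet                  # columns: + name, factor_class, tss_proximal, weight, tss_pos
    tss: TssReference
    chip: dict[str, PeakSet]
    segments: PeakSet               # 'name' column holds the 7-class labels


def _sample_disjoint(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    n: int,
    width_lo: int,
    width_hi: int,
    forbidden: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    max_rounds: int = 200,
):
    """Disjoint intervals by rejection sampling, optionally avoiding a set."""
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    out: list[tuple[str, int, int]] = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    if forbidden:
        for c, (fs, fe) in forbidden.items():
            taken.setdefault(c, []).extend(zip(fs.tolist(), fe.tolist()))
    for _ in range(max_rounds):
        if len(out) >= n:
            break
        need = n - len(out)
        pick = rng.choice(len(chroms), size=need, p=lengths / lengths.sum())
        widths = rng.integers(width_lo, width_hi + 1, size=need)
        for ci, w in zip(pick, widths):
            chrom = chroms[ci]
            limit = chrom_lengths[chrom] - int(w)
            if limit <= 0:
                continue
            s = int(rng.integers(0, limit))
            e = s + int(w)
            if all(e <= ts or s >= te for ts, te in taken[chrom]):
                taken[chrom].append((s, e))
                out.append((chrom, s, e))
    if len(out) < n:
        raise ValueError(
            f"could not place {n} disjoint intervals of width "
            f"{width_lo}-{width_hi}; genome capacity exceeded"
        )
    out = out[:n]
    out.sort()
    return out


def generate_annotation(cfg: GeneratorConfig) -> Annotation:
    """Planted peaks, TSSs, ChIP sets and an exact 7-class segmentation."""
    rng = cfg.stream("annotation")
    lengths = {
        f"chr{i + 1}": cfg.nuclear_chrom_length
        for i in range(cfg.n_nuclear_chroms)
    }
    lengths[cfg.mito_name] = cfg.mito_length
    layout = GenomeLayout(lengths=lengths, mito=cfg.mito_name)
    nuclear_lengths = {c: layout.lengths[c] for c in layout.nuclear}

    placed = _sample_disjoint(
        rng, nuclear_lengths, cfg.n_peaks,
        cfg.peak_width_min, cfg.peak_width_max,
    )
    df = pd.DataFrame(placed, columns=["chrom", "start", "end"])
    df["name"] = [f"acc_{i + 1}" for i in range(len(df))]
    df["weight"] = rng.lognormal(0.0, cfg.peak_weight_sigma, size=len(df))

    n_tss = int(round(cfg.tss_peak_fraction * len(df)))
    tss_idx = rng.choice(len(df), size=n_tss, replace=False) if n_tss else []
    tss_proximal = np.zeros(len(df), dtype=bool)
    tss_proximal[list(tss_idx)] = True
    df["tss_proximal"] = tss_proximal
    tss_pos = np.full(len(df), -1, dtype=np.int64)
    strands = np.full(len(df), ".", dtype=object)
    mids = ((df["start"] + df["end"]) // 2).to_numpy()
    tss_pos[tss_proximal] = mids[tss_proximal]
    strands[tss_proximal] = rng.choice(["+", "-"], size=int(tss_proximal.sum()))
    df["tss_pos"] = tss_pos

    assigned = rng.random(len(df)) < cfg.factor_assigned_fraction
    classes = np.full(len(df), "", dtype=object)
    if cfg.factor_names:
        classes[assigned] = rng.choice(
            list(cfg.factor_names), size=int(assigned.sum())
        )
    df["factor_class"] = classes

    peaks = PeakSet(df, merged=True)
    tss = TssReference.from_arrays(
        df.loc[tss_proximal, "chrom"].to_numpy(),
        tss_pos[tss_proximal],
        strands[tss_proximal],
    )

    forbidden = {
        chrom: (starts, ends) for chrom, starts, ends, _ in peaks.by_chrom()
    }
    chip: dict[str, PeakSet] = {}
    for factor in cfg.factor_names:
        own = df[df["factor_class"] == factor]
        decoys = _sample_disjoint(
            rng, nuclear_lengths, cfg.chip_decoys_per_factor,
            cfg.chip_decoy_width[0], cfg.chip_decoy_width[1],
            forbidden=forbidden,
        )
        decoy_df = pd.DataFrame(decoys, columns=["chrom", "start", "end"])
        chip_df = pd.concat(
            [own[["chrom", "start", "end"]], decoy_df], ignore_index=True
        ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        chip_df["name"] = [f"{factor}_{i + 1}" for i in range(len(chip_df))]
        chip[factor] = PeakSet(chip_df, merged=True)

    seg_rows = []
    for chrom, length in nuclear_lengths.items():
        pos = 0
        while pos < length:
            block = int(rng.integers(cfg.segment_block_min, cfg.segment_block_max + 1))
            end = min(pos + block, length)
            seg_rows.append(
                (chrom, pos, end, str(rng.choice(list(SEGMENT_CLASSES))))
            )
            pos = end
    segments = PeakSet(
        pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "name"]),
        merged=True,
    )
    return Annotation(layout=layout, peaks=peaks, tss=tss, chip=chip,
                      segments=segments)


def _complement_gaps(ann: Annotation) -> pd.DataFrame:
    """Inter-peak gaps of the nuclear genome as a DataFrame."""
    rows = []
    lookup = {
        chrom: (starts, ends) for chrom, starts, ends, _ in ann.peaks.by_chrom()
    }
    for chrom in ann.layout.nuclear:
        length = ann.layout.lengths[chrom]
        starts, ends = lookup.get(chrom, (np.empty(0, int), np.empty(0, int)))
        edges = np.concatenate([[0], ends])
        stops = np.concatenate([starts, [length]])
        for gs, ge in zip(edges, stops):
            if ge - gs >= MIN_INSERT:
                rows.append((chrom, int(gs), int(ge)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _draw_insert_sizes(rng, cfg: GeneratorConfig, n: int) -> np.ndarray:
    comp = rng.choice(3, size=n, p=np.asarray(cfg.size_weights))
    means = np.asarray(cfg.size_means)[comp]
    sds = np.asarray(cfg.size_sds)[comp]
    sizes = np.rint(rng.normal(means, sds)).astype(np.int64)
    return np.clip(sizes, MIN_INSERT, 2000)


def generate_library(
    cfg: GeneratorConfig,
    ann: Annotation,
    n_fragments: int | None = None,
    class_multipliers: dict[str, float] | None = None,
    seed: int | None = None,
) -> FragmentLibrary:
    """Draw a fragment library from a finite latent molecule pool.

    The nuclear pool holds ``cfg.complexity`` distinct molecules; the
    mitochondrial pool is sized so a uniform draw lands on chrM with
    probability ``cfg.mito_fraction``.  Depth draws are uniform with
    replacement over the combined pool, which makes the Lander-Waterman
    model exactly the right complexity-recovery model.
    ``class_multipliers`` rescales the selection weight of peaks whose
    ``factor_class`` matches, emulating condition-specific coverage biases.
    """
    n_fragments = n_fragments if n_fragments is not None else cfg.n_fragments
    rng = (
        cfg.stream("library")
        if seed is None
        else np.random.default_rng(seed)
    )
    pdf = ann.peaks.df
    if len(pdf) == 0 and cfg.frip > 0:
        raise ValueError("cannot place signal fragments without peaks")

    n_nuclear = int(cfg.complexity)
    f = cfg.mito_fraction
    n_mito = int(round(n_nuclear * f / (1.0 - f))) if f < 1.0 else 0

    # --- nuclear pool ---
    sizes = _draw_insert_sizes(rng, cfg, n_nuclear)
    is_signal = rng.random(n_nuclear) < cfg.frip
    n_sig = int(is_signal.sum())
    chrom_pool = np.empty(n_nuclear, dtype=object)
    start_pool = np.zeros(n_nuclear, dtype=np.int64)
    end_pool = np.zeros(n_nuclear, dtype=np.int64)

    if n_sig:
        weights = pdf["weight"].to_numpy().astype(float).copy()
        tssp = pdf["tss_proximal"].to_numpy()
        weights[tssp] *= cfg.tss_enrichment_strength
        if class_multipliers:
            for klass, mult in class_multipliers.items():
                weights[pdf["factor_class"].to_numpy() == klass] *= mult
        weights /= weights.sum()
        peak_idx = rng.choice(len(pdf), size=n_sig, p=weights)
        ps = pdf["start"].to_numpy()[peak_idx]
        pe = pdf["end"].to_numpy()[peak_idx]
        widths = pe - ps
        length = np.minimum(sizes[is_signal], widths)
        hi = pe - length  # inclusive upper bound for start
        tss_here = pdf["tss_proximal"].to_numpy()[peak_idx]
        tpos = pdf["tss_pos"].to_numpy()[peak_idx]
        start = ps + np.floor(
            rng.random(n_sig) * (hi - ps + 1)
        ).astype(np.int64)
        if tss_here.any():
            jitter = np.rint(
                rng.normal(0.0, cfg.tss_jitter, size=int(tss_here.sum()))
            ).astype(np.int64)
            centered = tpos[tss_here] + jitter - length[tss_here] // 2
            start[tss_here] = np.clip(centered, ps[tss_here], hi[tss_here])
        chrom_pool[is_signal] = pdf["chrom"].to_numpy()[peak_idx]
        start_pool[is_signal] = start
        end_pool[is_signal] = start + length

    n_bg = n_nuclear - n_sig
    if n_bg:
        gaps = _complement_gaps(ann)
        glen = (gaps["end"] - gaps["start"]).to_numpy().astype(float)
        gi = rng.choice(len(gaps), size=n_bg, p=glen / glen.sum())
        gs = gaps["start"].to_numpy()[gi]
        ge = gaps["end"].to_numpy()[gi]
        length = np.minimum(sizes[~is_signal], ge - gs)
        start = gs + np.floor(
            rng.random(n_bg) * (ge - length - gs + 1)
        ).astype(np.int64)
        chrom_pool[~is_signal] = gaps["chrom"].to_numpy()[gi]
        start_pool[~is_signal] = start
        end_pool[~is_signal] = start + length

    # --- mitochondrial pool ---
    if n_mito:
        msizes = np.clip(
            _draw_insert_sizes(rng, cfg, n_mito), MIN_INSERT,
            cfg.mito_length - 1,
        )
        mstart = np.floor(
            rng.random(n_mito) * (cfg.mito_length - msizes + 1)
        ).astype(np.int64)
        chrom_pool = np.concatenate(
            [chrom_pool, np.full(n_mito, cfg.mito_name, dtype=object)]
        )
        start_pool = np.concatenate([start_pool, mstart])
        end_pool = np.concatenate([end_pool, mstart + msizes])

    draws = rng.integers(0, n_nuclear + n_mito, size=n_fragments)
    records = pd.DataFrame({
        "chrom": chrom_pool[draws],
        "start": start_pool[draws],
        "end": end_pool[draws],
    })
    return FragmentLibrary(
        records=records, layout=ann.layout, read_length=cfg.read_length
    )


def generate_condition_panel(
    cfg: GeneratorConfig,
    ann: Annotation,
    conditions: list[tuple[str, dict[str, float]]],
    n_fragments: int | None = None,
) -> list[tuple[str, FragmentLibrary]]:
    """One library per condition, sharing the annotation.

    Each condition supplies per-factor-class coverage multipliers; its
    library seed is derived deterministically from the master seed and the
    condition index, so regeneration is byte-identical.
    """
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    panel = []
    for i, (label, multipliers) in enumerate(conditions):
        rng_seed = int(
            cfg.stream("panel", (i,)).integers(0, 2**31 - 1)
        )
        lib = generate_library(
            cfg, ann, n_fragments=n_fragments,
            class_multipliers=multipliers, seed=rng_seed,
        )
        panel.append((label, lib))
    return panel


def write_gtf_lite(tss: TssReference, path, transcript_length: int = 500) -> None:
    """Emit a minimal GTF with one protein-coding transcript per TSS.

    Useful for exercising the GTF-based TSS-reference builder on generated
    annotations: reading the file back reproduces ``tss``.
    """
    with open(path, "w") as fh:
        fh.write("#!atacqc synthetic GTF-lite\n")
        for i, row in tss.df.iterrows():
            pos, strand = int(row["pos"]), row["strand"]
            if strand == "+":
                start1, end1 = pos + 1, pos + transcript_length
            else:
                start1, end1 = max(1, pos + 1 - transcript_length + 1), pos + 1
            attrs = (
                f'gene_id "G{i}"; transcript_id "T{i}"; '
                f'gene_type "protein_coding"; transcript_type "protein_coding";'
            )
            fh.write(
                f"{row['chrom']}\tsynthetic\ttranscript\t{start1}\t{end1}\t.\t"
                f"{strand}\t.\t{attrs}\n"
            )
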