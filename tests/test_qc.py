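"""The five library-quality metrics against constructed cases and oracles."""

import math
from collections import defaultdict

import numpy as np
import pytest

from atacqc import qc
from atacqc.model import PeakSet, TssReference
from atacqc.synthetic import GeneratorConfig, generate_annotation, generate_library


def naive_read_spans(lib):
    """Per-mate read intervals by direct per-record arithmetic."""
    out = []
    rl = lib.read_length
    for chrom, s, e in lib.records[["chrom", "start", "end"]].itertuples(
        index=False
    ):
        out.append((chrom, s, min(s + rl, e)))
        out.append((chrom, max(e - rl, s), e))
    return out


class TestFrip:
    def test_all_reads_inside_peak_gives_one(self, tiny_layout, lib_builder):
        lib = lib_builder(tiny_layout, [("chr1", 1000, 1200)] )
        peaks = PeakSet.from_arrays(["chr1"], [900], [1500]).merged()
        assert qc.frip(lib, peaks) == 1.0

    def test_empty_reference_gives_zero(self, tiny_layout, lib_builder):
        lib = lib_builder(tiny_layout, [("chr1", 1000, 1200)])
        assert qc.frip(lib, PeakSet.empty()) == 0.0

    def test_single_base_overlap_counts_one_mate_of_four(
        self, tiny_layout, lib_builder
    ):
        # peak [1000, 2000); mate [1999, 2049) shares exactly base 1999
        lib = lib_builder(
            tiny_layout,
            [("chr1", 1999, 2150), ("chr1", 5000, 5100)],
            read_length=50,
        )
        peaks = PeakSet.from_arrays(["chr1"], [1000], [2000]).merged()
        assert qc.frip(lib, peaks) == 0.25

    def test_matches_all_pairs_overlap_oracle(self, tiny_layout, lib_builder):
        rng = np.random.default_rng(10)
        frags = [
            ("chr1", int(s), int(s + l))
            for s, l in zip(
                rng.integers(0, 90_000, 60), rng.integers(30, 400, 60)
            )
        ]
        lib = lib_builder(tiny_layout, frags)
        ps = np.sort(rng.choice(9_000, 10, replace=False)) * 10
        peaks = PeakSet.from_arrays(["chr1"] * 10, ps, ps + 80).merged()
        mset = list(zip(peaks.df["start"], peaks.df["end"]))
        spans = naive_read_spans(lib.dedup().nuclear())
        want = sum(
            1 for _, a, b in spans
            if any(a < e and s < b for s, e in mset)
        ) / len(spans)
        assert qc.frip(lib, peaks) == pytest.approx(want, abs=1e-12)

    def test_mito_reads_excluded(self, tiny_layout, lib_builder):
        lib = lib_builder(
            tiny_layout, [("chr1", 1000, 1100), ("chrM", 10, 110)]
        )
        peaks = PeakSet.from_arrays(["chr1"], [900], [1500]).merged()
        assert qc.frip(lib, peaks) == 1.0

    def test_no_nuclear_reads_is_undefined(self, tiny_layout, lib_builder):
        lib = lib_builder(tiny_layout, [("chrM", 10, 110)])
        with pytest.raises(qc.UndefinedMetricError):
            qc.frip(lib, PeakSet.empty())


def tss_oracle(lib, tss, mode="upstream200"):
    """Direct per-base evaluation of the TSS enrichment definition."""
    cov = defaultdict(lambda: defaultdict(float))
    for chrom, a, b in naive_read_spans(lib.dedup().nuclear()):
        for p in range(a, b):
            cov[chrom][p] += 1
    profile = [0.0] * 4000
    for _, row in tss.df.iterrows():
        for i in range(4000):
            offset = i - 2000
            if row["strand"] == "+":
                p = row["pos"] + offset
            else:
                p = row["pos"] - offset
            profile[i] += cov[row["chrom"]].get(p, 0.0)
    flank = profile[:100] + profile[-100:]
    norm = sum(flank) / 200
    lo, hi = (1800, 2000) if mode == "upstream200" else (1800, 2200)
    return max(profile[lo:hi]) / norm


class TestTssEnrichment:
    def test_uniform_coverage_normalizes_to_one(self, tiny_layout, lib_builder):
        frags = [("chr1", i * 100, (i + 1) * 100) for i in range(80, 120)]
        lib = lib_builder(tiny_layout, frags, read_length=100)
        tss = TssReference.from_arrays(["chr1"], [10_000], ["+"])
        assert qc.tss_enrichment(lib, tss) == 1.0

    @pytest.mark.parametrize("mode", ["upstream200", "centered200"])
    def test_matches_per_base_oracle(self, tiny_layout, lib_builder, mode):
        rng = np.random.default_rng(11)
        frags = [
            ("chr1", int(10_000 + d), int(10_000 + d + l))
            for d, l in zip(
                rng.integers(-2300, 2300, 150), rng.integers(40, 350, 150)
            )
        ]
        lib = lib_builder(tiny_layout, frags)
        tss = TssReference.from_arrays(
            ["chr1", "chr1"], [10_000, 10_400], ["+", "-"]
        )
        got = qc.tss_enrichment(lib, tss, window=mode)
        assert got == pytest.approx(tss_oracle(lib, tss, mode), rel=1e-12)

    def test_strand_flip_symmetry(self, tiny_layout, lib_builder):
        rng = np.random.default_rng(12)
        L = tiny_layout.lengths["chr1"]
        frags = [
            ("chr1", int(s), int(s + l))
            for s, l in zip(
                rng.integers(7000, 13_000, 100), rng.integers(40, 300, 100)
            )
        ]
        lib = lib_builder(tiny_layout, frags)
        tss = TssReference.from_arrays(["chr1"], [10_000], ["+"])
        flipped = lib_builder(
            tiny_layout, [(c, L - e, L - s) for c, s, e in frags]
        )
        tss_flipped = TssReference.from_arrays(["chr1"], [L - 10_000 - 1], ["-"])
        assert qc.tss_enrichment(lib, tss) == pytest.approx(
            qc.tss_enrichment(flipped, tss_flipped), rel=1e-12
        )

    def test_no_coverage_near_tss_is_undefined(self, tiny_layout, lib_builder):
        lib = lib_builder(tiny_layout, [("chr1", 50_000, 50_200)])
        tss = TssReference.from_arrays(["chr1"], [10_000], ["+"])
        with pytest.raises(qc.UndefinedMetricError):
            qc.tss_enrichment(lib, tss)


class TestSubnucleosomalScore:
    def test_two_bin_case(self):
        hist = qc.InsertSizeHistogram({100: 50, 200: 25})
        assert qc.subnucleosomal_score(hist) == 2.0

    def test_149_is_sub_and_150_is_not(self):
        hist = qc.InsertSizeHistogram({149: 7, 150: 7})
        assert qc.subnucleosomal_score(hist) == 1.0

    def test_tri_modal_matches_full_scan_oracle(self):
        rng = np.random.default_rng(13)
        sizes = np.concatenate([
            rng.normal(75, 25, 4000), rng.normal(200, 35, 3000),
            rng.normal(380, 60, 1000),
        ]).round().astype(int)
        sizes = sizes[sizes >= 1]
        vals, counts = np.unique(sizes, return_counts=True)
        hist = qc.InsertSizeHistogram(dict(zip(vals.tolist(), counts.tolist())))
        want = max(
            c for s, c in hist.counts.items() if s < 150
        ) / max(c for s, c in hist.counts.items() if s >= 150)
        assert qc.subnucleosomal_score(hist) == want

    def test_one_sided_histogram_is_undefined(self):
        with pytest.raises(qc.UndefinedMetricError):
            qc.subnucleosomal_score(qc.InsertSizeHistogram({80: 10}))


class TestPctMito:
    def test_all_mitochondrial(self, tiny_layout, lib_builder):
        lib = lib_builder(tiny_layout, [("chrM", 0, 100), ("chrM", 5, 105)])
        assert qc.pct_mito(lib) == 100.0

    def test_one_in_four_fragments(self, tiny_layout, lib_builder):
        frags = [("chr1", i * 1000, i * 1000 + 100) for i in range(3)]
        lib = lib_builder(tiny_layout, frags + [("chrM", 0, 100)])
        assert qc.pct_mito(lib) == 25.0

    def test_duplicates_counted_pre_dedup(self, tiny_layout, lib_builder):
        from atacqc.model import mark_duplicates

        lib = lib_builder(
            tiny_layout,
            [("chrM", 0, 100), ("chrM", 0, 100),
             ("chr1", 10, 110), ("chr1", 500, 600)],
        )
        assert qc.pct_mito(mark_duplicates(lib)) == 50.0


def complexity_bisection_oracle(total, unique, iters=200):
    lo, hi = float(unique), float(unique)
    while hi * (1 - math.exp(-total / hi)) - unique <= 0:
        hi *= 2
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid * (1 - math.exp(-total / mid)) - unique <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestEstimateComplexity:
    def test_no_duplicates_means_unbounded(self):
        assert qc.estimate_complexity(1000, 1000) == math.inf

    @pytest.mark.parametrize(
        "total,unique,expected",
        [(100, 50, 62.75), (2, 1, 1.255)],
    )
    def test_known_roots(self, total, unique, expected):
        assert qc.estimate_complexity(total, unique) == pytest.approx(
            expected, abs=0.005
        )

    def test_matches_bisection_oracle_on_random_pairs(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            total = int(rng.integers(2, 10_000_000))
            unique = int(rng.integers(1, total))
            got = qc.estimate_complexity(total, unique)
            want = complexity_bisection_oracle(total, unique)
            assert got == pytest.approx(want, rel=1e-6)

    def test_monotone_in_unique(self):
        values = [qc.estimate_complexity(1000, u) for u in (400, 600, 800)]
        assert values[0] < values[1] < values[2]

    def test_unique_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            qc.estimate_complexity(10, 11)


class TestQcReport:
    def test_empty_library_reports_all_missing(self, tiny_layout, lib_builder):
        rep = qc.qc_report(lib_builder(tiny_layout, []))
        assert all(getattr(rep, m) is None for m in rep.METRICS)
        assert rep.total_reads == 0
        assert set(rep.missing_reasons) == set(rep.METRICS)

    def test_generator_library_recovers_defined_frip(self):
        cfg = GeneratorConfig(
            seed=21, frip=0.5, n_fragments=60_000, complexity=600_000
        )
        ann = generate_annotation(cfg)
        lib = generate_library(cfg, ann)
        rep = qc.qc_report(lib, ann.peaks, ann.tss)
        assert rep.frip == pytest.approx(0.5, abs=0.02)
        assert rep.missing_reasons == {}
        assert rep.dedup_nuclear_reads > 0

    def test_generator_mito_fraction_recovered(self):
        cfg = GeneratorConfig(
            seed=22, mito_fraction=0.25, n_fragments=40_000,
            complexity=400_000,
        )
        ann = generate_annotation(cfg)
        lib = generate_library(cfg, ann)
        rep = qc.qc_report(lib, ann.peaks, ann.tss)
        # binomial 3 sd at n = 80k reads is ~0.5 percentage points
        assert rep.pct_mito == pytest.approx(25.0, abs=1.0)

    def test_undefined_metrics_are_missing_not_zero(
        self, tiny_layout, lib_builder
    ):
        lib = lib_builder(tiny_layout, [("chrM", 0, 100)])
        rep = qc.qc_report(lib, PeakSet.empty())
        assert rep.frip is None
        assert "frip" in rep.missing_reasons
        assert rep.pct_mito == 100.0
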