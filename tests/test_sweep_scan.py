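import numpy as np
import pandas as pd
import pytest

from caprapop.io_formats import GeneInterval
from caprapop.sweep_scan import (
    DegenerateScoresError,
    XpclrConfig,
    assemble_scan,
    call_regions,
    equalize_samples,
    estimate_omega,
    make_segments,
    map_genes,
    physical_to_map,
    scan_chromosome,
    select_window_snps,
    xpclr_score,
)
from caprapop.synthetic_data import (
    SimConfig,
    SweepSpec,
    inject_sweep,
    population_map,
    simulate_genotypes,
)


class TestMapAndSegments:
    @pytest.mark.parametrize(
        "bp,cm", [(1_000_000, 1.0), (0, 0.0), (2500, 0.0025)]
    )
    def test_physical_to_map_default_rate(self, bp, cm):
        assert physical_to_map(bp) == pytest.approx(cm)

    def test_fifty_cm_chromosome_two_segments_with_stated_kept_spans(self):
        segs = make_segments(50.0)
        assert [(s.start_cm, s.end_cm) for s in segs] == [(0.0, 27.0), (25.0, 50.0)]
        assert [(s.keep_start_cm, s.keep_end_cm) for s in segs] == [
            (0.0, 26.0),
            (26.0, 50.0),
        ]

    def test_short_chromosome_single_untrimmed_segment(self):
        (seg,) = make_segments(20.0)
        assert (seg.start_cm, seg.end_cm) == (0.0, 20.0)
        assert (seg.keep_start_cm, seg.keep_end_cm) == (0.0, 20.0)

    def test_fiftytwo_cm_chromosome_three_segments_middle_trimmed_both_sides(self):
        segs = make_segments(52.0)
        assert len(segs) == 3
        mid = segs[1]
        assert mid.keep_start_cm > mid.start_cm
        assert mid.keep_end_cm < mid.end_cm

    @pytest.mark.parametrize("length", [20.0, 50.0, 52.0, 100.0])
    def test_kept_spans_tile_chromosome_exactly(self, length):
        segs = make_segments(length)
        assert segs[0].keep_start_cm == 0.0
        assert segs[-1].keep_end_cm == length
        for a, b in zip(segs, segs[1:]):
            assert a.keep_end_cm == pytest.approx(b.keep_start_cm, abs=1e-12)
            assert a.keep_end_cm <= a.end_cm
            assert b.keep_start_cm >= b.start_cm


class TestWindowSelection:
    def test_mutually_correlated_snps_share_weight(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, size=(30, 1)).astype(np.int8)
        ref = np.concatenate([base, base, base], axis=1)  # three identical
        cm = np.array([0.0, 0.01, 0.02])
        idx, w = select_window_snps(cm, 0.0, ref, XpclrConfig())
        assert idx.tolist() == [0, 1, 2]
        assert np.allclose(w, 1.0 / 3.0)

    def test_independent_snps_weight_one(self):
        rng = np.random.default_rng(2)
        ref = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
        cm = np.linspace(0, 0.04, 5)
        _, w = select_window_snps(cm, 0.0, ref, XpclrConfig())
        assert np.allclose(w, 1.0)

    def test_window_capped_at_250_snps(self):
        rng = np.random.default_rng(3)
        ref = rng.integers(0, 3, size=(10, 500)).astype(np.int8)
        cm = np.linspace(-0.2, 0.2, 500)
        idx, w = select_window_snps(cm, 0.0, ref, XpclrConfig())
        assert idx.size == 250 and w.size == 250


class TestXpclrScore:
    def test_no_differentiation_scores_near_zero(self):
        rng = np.random.default_rng(5)
        scores = []
        for _ in range(100):
            p2 = rng.uniform(0.1, 0.9, 30)
            p1 = np.clip(p2 + rng.normal(0, 0.02, 30), 0, 1)
            d = rng.uniform(0.001, 0.25, 30)
            s, _ = xpclr_score(p1, p2, d, np.ones(30), omega=0.02, n1_chr=28)
            scores.append(s)
        assert np.median(scores) < 0.5

    def test_fixed_test_population_scores_high(self):
        p2 = np.full(20, 0.5)
        p1 = np.ones(20)
        d = np.linspace(0.001, 0.1, 20)
        s, s_hat = xpclr_score(p1, p2, d, np.ones(20), omega=0.005, n1_chr=28)
        assert s > 50

    def test_doubling_weights_doubles_a_positive_score(self):
        rng = np.random.default_rng(7)
        p2 = rng.uniform(0.2, 0.8, 25)
        p1 = np.clip(p2 + rng.normal(0.3, 0.1, 25), 0, 1)
        d = rng.uniform(0.001, 0.2, 25)
        w = rng.uniform(0.5, 1.0, 25)
        s1, shat1 = xpclr_score(p1, p2, d, w, omega=0.01, n1_chr=28)
        s2, shat2 = xpclr_score(p1, p2, d, 2 * w, omega=0.01, n1_chr=28)
        assert s1 > 0
        assert s2 == pytest.approx(2 * s1, rel=1e-12)
        assert shat1 == shat2

    def test_empty_window_flagged_undefined(self):
        s, s_hat = xpclr_score(
            np.array([]), np.array([]), np.array([]), np.array([]),
            omega=0.01, n1_chr=28,
        )
        assert np.isnan(s)


@pytest.fixture(scope="module")
def sweep_scan_result():
    cfg = SimConfig(
        pop_sizes={"Black": 14, "Draa": 14, "Northern": 8},
        chrom_lengths={"chr1": 4_000_000},
        n_sites=6000,
        seed=51,
    )
    m, _ = simulate_genotypes(cfg)
    pm = population_map(cfg)
    m2, truth = inject_sweep(
        m, SweepSpec("chr1", 2_000_000, "Black", 80_000.0, 1.0), pm, seed=52
    )
    track = scan_chromosome(m2, pm, "Black", "chr1", chrom_length_bp=4_000_000)
    return m2, pm, truth, track


class TestScanAssembly:
    def test_track_covers_every_grid_point_exactly_once(self, sweep_scan_result):
        _, _, _, track = sweep_scan_result
        spacing = XpclrConfig().grid_spacing_bp
        expected = np.arange(spacing, 4_000_001, spacing)
        assert np.array_equal(np.sort(track["bp"].to_numpy()), expected)

    def test_scores_nonnegative_and_localize_injected_sweep(self, sweep_scan_result):
        _, _, truth, track = sweep_scan_result
        scores = track["score"].to_numpy()
        assert np.nanmin(scores) >= 0
        peak_bp = track["bp"].iloc[int(np.nanargmax(scores))]
        assert abs(peak_bp - truth["sweep_pos"]) <= 500_000  # 0.5 cM

    def test_assemble_rejects_duplicate_grid_points(self, sweep_scan_result):
        _, _, _, track = sweep_scan_result
        with pytest.raises(ValueError, match="more than one"):
            assemble_scan([track, track.iloc[:5]])

    def test_single_chromosome_assembly_is_identity(self, sweep_scan_result):
        _, _, _, track = sweep_scan_result
        out = assemble_scan([track])
        assert out.equals(track.sort_values(["chrom", "bp"]).reset_index(drop=True))


class TestRegionsAndGenes:
    def _track(self, scores, chrom="chr1", spacing=2500):
        n = len(scores)
        return pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "bp": np.arange(spacing, spacing * (n + 1), spacing),
                "cm": np.arange(spacing, spacing * (n + 1), spacing) / 1e6,
                "score": scores,
                "s_hat": [0.01] * n,
                "n_snps": [10] * n,
                "segment": [0] * n,
            }
        )

    def test_top_fraction_threshold_counts(self):
        rng = np.random.default_rng(9)
        scores = rng.random(10_000)
        track = self._track(scores)
        regions, threshold = call_regions(track, top_fraction=0.001)
        assert (scores >= threshold).sum() == 10

    def test_two_separated_peaks_make_two_regions(self):
        scores = [0.0] * 100
        scores[10], scores[11] = 5.0, 6.0
        scores[60] = 7.0
        track = self._track(scores)
        regions, _ = call_regions(track, top_fraction=0.03)
        assert len(regions) == 2
        assert regions[0].peak_score == 6.0 and regions[1].peak_score == 7.0

    def test_single_gap_does_not_split_a_region(self):
        scores = [0.0] * 100
        scores[20], scores[22] = 5.0, 5.5  # gap of one grid step at 21
        track = self._track(scores)
        regions, _ = call_regions(track, top_fraction=0.02)
        assert len(regions) == 1
        # the region spans the bridged gap: grid points 20..22 inclusive
        assert regions[0].n_grid_points == 3

    def test_all_tied_scores_degenerate(self):
        track = self._track([1.0] * 50)
        with pytest.raises(DegenerateScoresError):
            call_regions(track)

    def test_gene_flank_intersection_arithmetic(self):
        from caprapop.sweep_scan import SweepRegion

        region = SweepRegion(0, "chr1", 7400, 9000, 5.0, 8000, 3)
        genes = [
            GeneInterval("hit_by_flank", "chr1", 5000, 6000),  # flank end 7500
            GeneInterval("far_gene", "chr1", 20_000, 21_000),
            GeneInterval("inside", "chr1", 7500, 8500),
            GeneInterval("other_chrom", "chr2", 7400, 9000),
        ]
        hits = map_genes([region], genes, flank_bp=1500)
        by_id = {h.gene_id: h for h in hits}
        assert set(by_id) == {"hit_by_flank", "inside"}
        assert by_id["hit_by_flank"].overlap_bp == 101  # 7400..7500
        # flanked 6000..10000 clipped to region 7400..9000 -> 1601 bp
        assert by_id["inside"].overlap_bp == 1601


class TestEqualize:
    def test_oversized_population_subsampled_to_target(self):
        pops = {f"b{i}": "Black" for i in range(22)}
        pops.update({f"d{i}": "Draa" for i in range(14)})
        out = equalize_samples(pops, 14, seed=7)
        assert sum(1 for p in out.values() if p == "Black") == 14
        assert sum(1 for p in out.values() if p == "Draa") == 14

    def test_target_at_population_size_is_identity(self):
        pops = {f"s{i}": "A" for i in range(5)}
        assert equalize_samples(pops, 5, seed=1) == pops

    def test_fixed_seed_reproducible(self):
        pops = {f"s{i}": "A" for i in range(30)}
        assert equalize_samples(pops, 10, seed=3) == equalize_samples(
            pops, 10, seed=3
        )


def test_omega_estimate_scales_with_divergence():
    rng = np.random.default_rng(13)
    p2 = rng.uniform(0.1, 0.9, 5000)
    lo = np.clip(p2 + rng.normal(0, np.sqrt(0.005 * p2 * (1 - p2))), 0, 1)
    hi = np.clip(p2 + rng.normal(0, np.sqrt(0.05 * p2 * (1 - p2))), 0, 1)
    w_lo = estimate_omega(lo, p2, 10**6, 10**6, thin=1)
    w_hi = estimate_omega(hi, p2, 10**6, 10**6, thin=1)
    assert w_lo == pytest.approx(0.005, rel=0.3)
    assert w_hi == pytest.approx(0.05, rel=0.3)
    assert w_hi > w_lo
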