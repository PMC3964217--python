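"""Signal module: normalization, strand offset, binding calls, peaks."""

import numpy as np
import pytest

from conftest import make_reads, uniform_reads
from etsgeo.annotation import PromoterRegion
from etsgeo.signal import (
    BindingCall,
    PromoterSignal,
    call_bound_promoters,
    collect_signals,
    control_threshold,
    estimate_strand_offset,
    find_top_peak,
    normalize_coverage,
    promoter_signal,
    select_top_signal,
    shift_reads,
)

CHR = {"chr1": 1_000_000}


class TestNormalizeCoverage:
    def test_uniform_reads_give_unit_kb_windows(self):
        rng = np.random.default_rng(0)
        track = normalize_coverage(uniform_reads(rng, 100_000, 1_000_000), CHR)
        total = track.fwd["chr1"] + track.rev["chr1"]
        # genome-wide mean normalized reads per kb is exactly 1
        assert total.sum() / (1_000_000 / 1000) == pytest.approx(1.0, abs=1e-9)
        kb_sums = total[: 999_000].reshape(-1, 1000).sum(axis=1)
        assert np.all(np.abs(kb_sums - 1.0) < 0.5)

    def test_depth_invariance(self):
        reads = make_reads([("chr1", 100, 150, "+"), ("chr1", 400, 450, "-")])
        doubled = make_reads(
            [("chr1", 100, 150, "+"), ("chr1", 400, 450, "-")] * 2
        )
        t1 = normalize_coverage(reads, CHR)
        t2 = normalize_coverage(doubled, CHR)
        assert np.allclose(t1.fwd["chr1"], t2.fwd["chr1"])
        assert np.allclose(t1.rev["chr1"], t2.rev["chr1"])

    def test_replicates_with_10x_depth_give_identical_promoter_signals(self):
        rng = np.random.default_rng(1)
        base = uniform_reads(rng, 2000, 1_000_000)
        deep = make_reads(
            [(r.chrom, r.start, r.end, r.strand) for r in base.itertuples()] * 10
        )
        prom = PromoterRegion("g", "chr1", 5000, 6000, "+")
        s1 = promoter_signal(normalize_coverage(base, CHR), [prom])["g"]
        s2 = promoter_signal(normalize_coverage(deep, CHR), [prom])["g"]
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            normalize_coverage(make_reads([]), CHR)


class TestStrandOffset:
    def _paired_reads(self, centers, shift, read_len=50):
        rows = []
        for c in centers:
            rows.append(("chr1", c, c + read_len, "+"))
            rows.append(("chr1", c + shift, c + shift + read_len, "-"))
        return make_reads(rows)

    def test_exact_translation_recovered(self):
        reads = self._paired_reads(range(1000, 50_000, 500), shift=120)
        track = normalize_coverage(reads, {"chr1": 60_000})
        assert estimate_strand_offset(track, 200) == 120

    def test_zero_shift(self):
        reads = self._paired_reads(range(1000, 50_000, 500), shift=0)
        track = normalize_coverage(reads, {"chr1": 60_000})
        assert estimate_strand_offset(track, 200) == 0

    def test_flat_strand_returns_zero_with_warning(self, caplog):
        reads = make_reads([("chr1", 100, 150, "+")] * 5)
        track = normalize_coverage(reads, {"chr1": 10_000})
        with caplog.at_level("WARNING"):
            assert estimate_strand_offset(track) == 0

    def test_noisy_peaks_match_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        rows = []
        for peak in (10_000, 30_000):
            for _ in range(300):
                c = int(rng.normal(peak, 30))
                rows.append(("chr1", c, c + 50, "+"))
                c2 = c + 150 + int(rng.normal(0, 2))  # additive placement noise
                rows.append(("chr1", c2, c2 + 50, "-"))
        track = normalize_coverage(make_reads(rows), {"chr1": 50_000})
        got = estimate_strand_offset(track, 300)

        f, r = track.fwd["chr1"], track.rev["chr1"]
        oracle = max(
            range(301),
            key=lambda k: np.corrcoef(f[: len(f) - k], r[k:])[0, 1] if k else np.corrcoef(f, r)[0, 1],
        )
        assert got == oracle
        assert abs(got - 150) <= 5


class TestPromoterSignal:
    def test_fully_contained_reads_sum_to_count_times_factor(self):
        reads = make_reads([("chr1", 5000 + 10 * i, 5050 + 10 * i, "+") for i in range(10)])
        track = normalize_coverage(reads, CHR)
        prom = PromoterRegion("g", "chr1", 4800, 5800, "+")
        sig = promoter_signal(track, [prom])["g"]
        assert sig == pytest.approx(10 * track.normalization_factor)

    def test_straddling_read_counts_overlap_only(self):
        reads = make_reads([("chr1", 980, 1030, "+")])
        track = normalize_coverage(reads, CHR)
        prom = PromoterRegion("g", "chr1", 1000, 2000, "+")
        sig = promoter_signal(track, [prom])["g"]
        assert sig == pytest.approx(track.normalization_factor * 30 / 50)

    def test_empty_promoter_scores_zero(self):
        reads = make_reads([("chr1", 100, 150, "+")])
        track = normalize_coverage(reads, CHR)
        prom = PromoterRegion("g", "chr1", 500_000, 501_000, "+")
        assert promoter_signal(track, [prom])["g"] == 0.0


def _sig(gene, vals, factor="f"):
    return PromoterSignal(gene, factor, tuple(vals))


class TestCallBound:
    def _controls(self):
        # 200 control promoters, signals 0..199 per replicate
        return [_sig(f"g{i:03d}", (float(i), float(i)), "control") for i in range(200)]

    def test_bound_requires_every_replicate(self):
        controls = self._controls()
        s_star = control_threshold(
            np.concatenate([c.replicate_signals for c in controls]), 0.005
        )
        hi, lo = s_star + 10, s_star - 10
        treatment = [
            _sig("g000", (hi, hi, hi)),
            _sig("g001", (hi, hi, lo)),
        ]
        calls = {c.gene_id: c for c in call_bound_promoters(treatment, controls, 0.005)}
        assert calls["g000"].bound
        assert not calls["g001"].bound  # replicate intersection rule

    def test_bias_promoters_flagged_and_removed(self):
        controls = self._controls() + [_sig("hot", (1e6, 1e6), "control")]
        treatment = [_sig("hot", (1e6, 1e6, 1e6)), _sig("g000", (1e6, 1e6, 1e6))]
        calls = {c.gene_id: c for c in call_bound_promoters(treatment, controls, 0.005)}
        assert calls["hot"].bias_flag and not calls["hot"].bound
        assert calls["g000"].bound and not calls["g000"].bias_flag

    def test_lowering_fdr_shrinks_bound_set(self):
        rng = np.random.default_rng(3)
        controls = [
            _sig(f"g{i:03d}", rng.exponential(10, size=2), "control") for i in range(500)
        ]
        treatment = [
            _sig(f"g{i:03d}", rng.exponential(15, size=3)) for i in range(500)
        ]
        prev = None
        for fdr in (0.05, 0.02, 0.01, 0.005, 0.001):
            bound = {
                c.gene_id for c in call_bound_promoters(treatment, controls, fdr) if c.bound
            }
            if prev is not None:
                assert bound <= prev
            prev = bound

    def test_all_zero_controls_use_smallest_positive_treatment(self, caplog):
        controls = [_sig("a", (0.0, 0.0), "control"), _sig("b", (0.0, 0.0), "control")]
        treatment = [_sig("a", (5.0, 7.0)), _sig("b", (0.0, 2.0))]
        with caplog.at_level("WARNING"):
            calls = {c.gene_id: c for c in call_bound_promoters(treatment, controls)}
        assert calls["a"].bound
        assert not calls["b"].bound


class TestFindTopPeak:
    def _track(self, rows, length=10_000):
        return normalize_coverage(make_reads(rows), {"chr1": length})

    def test_rectangular_pileup_centered(self):
        rows = [("chr1", 2475, 2525, "+")] * 20
        track = self._track(rows)
        prom = PromoterRegion("g", "chr1", 2000, 3000, "+")
        peak = find_top_peak(track, prom)
        assert peak.width == 145
        assert abs(peak.center - 2500) <= 1
        assert peak.end - peak.start == 145

    def test_largest_of_two_pileups_wins(self):
        rows = [("chr1", 2100, 2150, "+")] * 5 + [("chr1", 2700, 2750, "+")] * 9
        peak = find_top_peak(self._track(rows), PromoterRegion("g", "chr1", 2000, 3000, "+"))
        assert abs(peak.center - 2725) <= 73

    def test_tie_breaks_leftmost(self):
        rows = [("chr1", 2100, 2150, "+")] * 5 + [("chr1", 2700, 2750, "+")] * 5
        peak = find_top_peak(self._track(rows), PromoterRegion("g", "chr1", 2000, 3000, "+"))
        assert peak.center < 2400

    def test_all_zero_promoter_has_no_peak(self):
        track = self._track([("chr1", 9000, 9050, "+")])
        assert find_top_peak(track, PromoterRegion("g", "chr1", 2000, 3000, "+")) is None

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(9)
        rows = [
            ("chr1", int(s), int(s) + 50, "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(2000, 2950, size=200)
        ]
        track = self._track(rows)
        prom = PromoterRegion("g", "chr1", 2000, 3000, "+")
        peak = find_top_peak(track, prom)
        sig = track.both("chr1")[2000:3000]
        sums = np.array([sig[i : i + 145].sum() for i in range(1000 - 145 + 1)])
        ties = np.flatnonzero(sums >= sums.max() - 1e-9 * max(1.0, sums.max()))
        run = [ties[0]]
        for t in ties[1:]:
            if t == run[-1] + 1:
                run.append(t)
            else:
                break
        best = int((run[0] + run[-1]) // 2)
        assert peak.center == 2000 + best + 72
        assert peak.height == pytest.approx(sums[best])


class TestSelectTopSignal:
    def test_top_half(self):
        sigs = [_sig(f"g{i}", (float(i + 1),)) for i in range(4)]
        top = select_top_signal(sigs, {s.gene_id for s in sigs}, 0.5)
        assert {s.gene_id for s in top} == {"g2", "g3"}

    def test_fraction_one_is_identity(self):
        sigs = [_sig(f"g{i}", (float(i),)) for i in range(5)]
        assert len(select_top_signal(sigs, {s.gene_id for s in sigs}, 1.0)) == 5

    def test_850_bound_yield_425(self):
        sigs = [_sig(f"g{i:04d}", (float(i),)) for i in range(850)]
        assert len(select_top_signal(sigs, {s.gene_id for s in sigs}, 0.5)) == 425

    def test_empty_input(self):
        assert select_top_signal([], set(), 0.5) == []


def test_shift_moves_reads_toward_midpoint():
    reads = make_reads([("chr1", 100, 150, "+"), ("chr1", 300, 350, "-")])
    shifted = shift_reads(reads, 120)
    assert shifted.loc[0, "start"] == 160
    assert shifted.loc[1, "start"] == 240
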