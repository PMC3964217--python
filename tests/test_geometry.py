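"""Pair geometry, spacing density, resampling null, helical phase."""

import numpy as np
import pytest
from scipy.stats import kstest, norm

from etsgeo.geometry import (
    BACK_TO_BACK,
    DIRECT,
    FACE_TO_FACE,
    DensityTrack,
    MotifPair,
    helical_phase,
    pair_geometry,
    phase_profile,
    resample_pvalues,
    select_two_motif_promoters,
    spacing_density,
)
from etsgeo.motifs import MotifHit


def hit(offset, strand, region="p"):
    return MotifHit(region, offset, strand, "CCGGAAG")


class TestPairGeometry:
    def test_plus_left_minus_right_is_face_to_face(self):
        pair = pair_geometry(hit(100, "+"), hit(300, "-"))
        assert pair.signed_distance == -200
        assert pair.orientation == FACE_TO_FACE

    def test_minus_left_plus_right_is_back_to_back(self):
        pair = pair_geometry(hit(100, "-"), hit(300, "+"))
        assert pair.signed_distance == 200
        assert pair.orientation == BACK_TO_BACK

    def test_argument_order_irrelevant(self):
        a, b = hit(100, "+"), hit(300, "-")
        assert pair_geometry(a, b) == pair_geometry(b, a)

    def test_coincident_centers_tie_break(self):
        pair = pair_geometry(hit(100, "-"), hit(100, "+"))
        assert pair.signed_distance == 0
        assert pair.orientation == FACE_TO_FACE

    def test_same_strand_is_direct(self):
        pair = pair_geometry(hit(100, "+"), hit(300, "+"))
        assert pair.orientation == DIRECT


class TestSelectTwoMotifPromoters:
    def test_exactly_two_opposite_strand_hits_kept(self):
        hits = {
            "a": [hit(10, "+", "a"), hit(400, "-", "a")],
            "b": [hit(10, "+", "b"), hit(200, "-", "b"), hit(700, "+", "b")],
            "c": [hit(10, "+", "c"), hit(400, "+", "c")],
        }
        pairs = select_two_motif_promoters(hits)
        assert [p.promoter_id for p in pairs] == ["a"]


def brute_density(distances):
    """O(pairs x positions) oracle for the 100-bp sliding window counts."""
    positions = np.arange(-1000, 1001)
    return np.array(
        [sum(1 for d in distances if p - 50 <= d < p + 50) for p in positions]
    )


class TestSpacingDensity:
    def test_single_pair_window_arithmetic(self):
        track = spacing_density([MotifPair("p", -200, FACE_TO_FACE)])
        nz = np.flatnonzero(track.counts)
        assert track.positions[nz[0]] == -249
        assert track.positions[nz[-1]] == -150
        assert track.counts.sum() == 100
        assert set(track.counts[nz]) == {1}

    def test_empty_subset_gives_zero_track(self):
        track = spacing_density([MotifPair("p", -200, FACE_TO_FACE)], subset=[])
        assert track.counts.sum() == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        dists = rng.integers(-993, 994, size=400)
        pairs = [
            MotifPair(f"p{i}", int(d), FACE_TO_FACE if d <= 0 else BACK_TO_BACK)
            for i, d in enumerate(dists)
        ]
        track = spacing_density(pairs)
        assert np.array_equal(track.counts, brute_density(dists))

    def test_mirror_symmetry(self):
        """Negating all distances reverses the track."""
        rng = np.random.default_rng(29)
        dists = rng.integers(-900, 901, size=200)
        fwd = spacing_density(
            [MotifPair(f"p{i}", int(d), FACE_TO_FACE) for i, d in enumerate(dists)]
        )
        rev = spacing_density(
            [MotifPair(f"p{i}", int(-d), FACE_TO_FACE) for i, d in enumerate(dists)]
        )
        # window [p-50, p+50) is half-open: mirror aligns to position -p shifted by 1
        assert np.array_equal(fwd.counts[1:], rev.counts[1:][::-1])


def _population(rng, n=1500):
    close = rng.integers(-49, 50, size=int(n * 0.6))
    far = rng.integers(50, 994, size=n - close.size) * rng.choice([-1, 1], size=n - close.size)
    return np.concatenate([close, far])


def _pairs(dists):
    return [
        MotifPair(f"p{i}", int(d), FACE_TO_FACE if d <= 0 else BACK_TO_BACK)
        for i, d in enumerate(dists)
    ]


class TestResamplePvalues:
    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(3)
        pop = _pairs(_population(rng))
        obs = spacing_density(pop, subset=[f"p{i}" for i in range(300)])
        a = resample_pvalues(pop, obs, 300, runs=200, seed=11)
        b = resample_pvalues(pop, obs, 300, runs=200, seed=11)
        assert np.array_equal(a.p_values, b.p_values)
        assert a.alpha_corrected == pytest.approx(0.05 / 2001)

    def test_observation_at_null_mean_gives_half(self):
        rng = np.random.default_rng(5)
        pop = _pairs(_population(rng))
        probe = spacing_density(pop, subset=[f"p{i}" for i in range(300)])
        fit = resample_pvalues(pop, probe, 300, runs=400, seed=2)
        # an observation sitting exactly on the null mean has p ~ 0.5
        at_mean = DensityTrack(probe.positions, np.round(fit.null_mean).astype(int))
        res = resample_pvalues(pop, at_mean, 300, runs=400, seed=2,
                               continuity_correction=False)
        mid = np.flatnonzero(fit.null_sd > 2)
        assert mid.size > 100
        assert np.allclose(res.p_values[mid], 0.5, atol=0.1)
        well = mid[np.abs(at_mean.counts[mid] - res.null_mean[mid]) < 0.01 * res.null_sd[mid]]
        assert np.allclose(res.p_values[well], 0.5, atol=0.005)

    def test_three_sigma_tail(self):
        """An observation at mu + 3 sigma maps to the normal tail ~1.35e-3."""
        rng = np.random.default_rng(6)
        pop = _pairs(_population(rng))
        obs = spacing_density(pop, subset=[f"p{i}" for i in range(300)])
        res = resample_pvalues(pop, obs, 300, runs=400, seed=3)
        i = 1000  # position 0, well-populated
        synthetic = DensityTrack(
            obs.positions,
            np.round(res.null_mean + 3 * res.null_sd).astype(int),
        )
        res2 = resample_pvalues(pop, synthetic, 300, runs=400, seed=3,
                                continuity_correction=False)
        z = (synthetic.counts[i] - res2.null_mean[i]) / res2.null_sd[i]
        assert res2.p_values[i] == pytest.approx(norm.sf(z))
        assert res2.p_values[i] == pytest.approx(1.35e-3, rel=0.35)

    def test_null_pvalues_uniform_at_probe_positions(self):
        """Under the null, p-values are approximately uniform (KS at 20 probes)."""
        rng = np.random.default_rng(8)
        pop_d = _population(rng, 2000)
        pop = _pairs(pop_d)
        probes = np.linspace(-800, 800, 20).astype(int) + 1000
        pvals = []
        for t in range(40):
            draw = rng.choice(pop_d, size=300, replace=True)
            obs = spacing_density(_pairs(draw))
            res = resample_pvalues(pop, obs, 300, runs=150, seed=100 + t,
                                   continuity_correction=False)
            pvals.extend(res.p_values[probes])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_zero_variance_position(self):
        pop = _pairs([0] * 50)  # every resample identical
        obs = spacing_density(pop)
        res = resample_pvalues(pop, obs, 50, runs=50, seed=1)
        assert res.flagged is not None and res.flagged.all()
        assert res.p_values[1000] == 1.0  # obs equals null mean
        hot = DensityTrack(obs.positions, obs.counts + 10)
        res2 = resample_pvalues(pop, hot, 50, runs=50, seed=1)
        assert res2.p_values[1000] == np.finfo(float).tiny


class TestHelicalPhase:
    @pytest.mark.parametrize(
        "distance,expected",
        [(26, 180.0), (104, 0.0), (100, -138.46153846)],
    )
    def test_reference_distances(self, distance, expected):
        assert helical_phase(distance) == pytest.approx(expected, abs=1e-6)

    def test_negative_distance_uses_magnitude(self):
        assert helical_phase(-26) == helical_phase(26)

    def test_range_is_half_open(self):
        for d in range(0, 500):
            phi = helical_phase(d)
            assert -180.0 < phi <= 180.0


class TestPhaseProfile:
    def test_bound_equals_all_gives_flat_profile(self):
        rng = np.random.default_rng(9)
        phases = rng.uniform(-180, 180, size=500)
        prof = phase_profile(phases, phases)
        assert np.allclose(prof.relative_binding, 1.0)
        assert np.nanmean(prof.relative_binding) == pytest.approx(1.0, abs=1e-6)

    def test_windows_wrap_at_180(self):
        all_phases = [175.0, -175.0] * 50
        prof = phase_profile(all_phases, [175.0] * 50, window=40, step=10)
        i = int(np.argmin(np.abs(prof.grid - 180)))
        assert prof.n_all[i] == 100  # both clusters fall in the +/-180 window

    def test_planted_preference_recovered(self):
        """Bound pairs concentrated near 90 degrees peak within +/-20."""
        rng = np.random.default_rng(12)
        n = 8000
        all_phases = rng.uniform(-180, 180, size=n)
        weight = np.exp(2 * (np.cos(np.deg2rad(all_phases - 90)) - 1))
        bound_mask = rng.random(n) < 0.3 * weight
        prof = phase_profile(all_phases, all_phases[bound_mask])
        peak = prof.grid[int(np.nanargmax(prof.relative_binding))]
        assert abs((peak - 90 + 180) % 360 - 180) <= 20
        # harmonic smooth curve peaks nearby too
        fine = np.linspace(-180, 180, 721)
        fit_peak = fine[int(np.argmax(prof.fitted(fine)))]
        assert abs((fit_peak - 90 + 180) % 360 - 180) <= 20
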