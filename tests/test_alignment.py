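"""DIST/NORM alignment scores, error propagation oracle, two-way ANOVA."""

import numpy as np
import pytest

from dielstarch import (
    AlignedProfile,
    LightRegime,
    TranscriptModel,
    alignment_anova,
    alignment_scores,
    alignment_table,
    pairwise_dist,
    scale_scores,
    simulate_transcript,
)
from dielstarch.core import ValidationError


def profile(offsets, means, sems, anchor="dawn"):
    return AlignedProfile(anchor=anchor, offsets=offsets, means=means, sems=sems)


def photoperiod_series(peak_zt, photoperiods=(6, 12, 18), noise_sd=0.2, n_reps=3,
                       seed=0, track="dawn", amplitude=3.0):
    """One transcript across photoperiods; peak fixed to dawn or to dusk."""
    out = []
    for i, p in enumerate(photoperiods):
        regime = LightRegime(24, p)
        peak = peak_zt if track == "dawn" else (p + peak_zt) % 24
        m = TranscriptModel(
            baseline=10, amplitude=amplitude, peak_zt=peak, peak_width=6,
            noise_sd=noise_sd, n_reps=n_reps, seed=seed * 100 + i,
        )
        out.append(simulate_transcript(m, regime, gene="G"))
    return out


class TestPairwiseDist:
    def test_identical_profiles_distance_zero(self):
        a = profile([0, 2, 4, 6], [1, 2, 3, 4], [0.1] * 4)
        d, n = pairwise_dist(a, a)
        assert d == 0.0 and n == 0.0

    def test_constant_offset_closed_form(self):
        a = profile([0, 2, 4, 6], [3, 3, 3, 3], [0.0] * 4)
        b = profile([0, 2, 4, 6], [5, 5, 5, 5], [0.0] * 4)
        with pytest.warns(UserWarning):
            d, n = pairwise_dist(a, b)
        assert d == pytest.approx(4.0)  # δ=2 at k=4 points
        assert np.isinf(n)

    def test_matches_numeric_jacobian_oracle(self):
        rng = np.random.default_rng(3)
        offs = np.arange(0, 12.1, 2.0)
        a = profile(offs, rng.uniform(1, 5, offs.size), rng.uniform(0.1, 0.5, offs.size))
        b = profile(offs, rng.uniform(1, 5, offs.size), rng.uniform(0.1, 0.5, offs.size))
        d, n = pairwise_dist(a, b)
        prop_err = d / n

        def dist_fn(am, bm):
            return np.sqrt(np.sum((am - bm) ** 2))

        # finite-difference gradient of the distance wrt every mean
        eps = 1e-7
        var = 0.0
        for vec, sems in ((a.means, a.sems), (b.means, b.sems)):
            for j in range(vec.size):
                orig = vec[j]
                vec[j] = orig + eps
                up = dist_fn(a.means, b.means)
                vec[j] = orig - eps
                down = dist_fn(a.means, b.means)
                vec[j] = orig
                grad = (up - down) / (2 * eps)
                var += grad**2 * sems[j] ** 2
        assert prop_err == pytest.approx(np.sqrt(var), abs=1e-8)
        assert d == pytest.approx(dist_fn(a.means, b.means), abs=1e-12)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(11)
        offs = np.arange(0, 8.1, 2.0)
        ps = [
            profile(offs, rng.uniform(0, 5, offs.size), rng.uniform(0.1, 0.3, offs.size))
            for _ in range(3)
        ]
        d01, _ = pairwise_dist(ps[0], ps[1])
        d10, _ = pairwise_dist(ps[1], ps[0])
        d02, _ = pairwise_dist(ps[0], ps[2])
        d12, _ = pairwise_dist(ps[1], ps[2])
        assert d01 == pytest.approx(d10)
        assert d02 <= d01 + d12 + 1e-12

    def test_too_few_shared_offsets_rejected(self):
        a = profile([0, 2, 4], [1, 2, 3], [0.1] * 3)
        b = profile([4, 6, 8], [1, 2, 3], [0.1] * 3)
        with pytest.raises(ValidationError):
            pairwise_dist(a, b)


class TestAlignmentScores:
    def test_dawn_locked_transcript_prefers_dawn_anchor(self):
        series = photoperiod_series(peak_zt=4.0, track="dawn", seed=1)
        dawn = alignment_scores(series, "dawn")
        dusk = alignment_scores(series, "dusk")
        assert dawn.dist_raw < dusk.dist_raw

    def test_dusk_locked_transcript_reverses_ordering(self):
        series = photoperiod_series(peak_zt=2.0, track="dusk", seed=2)
        dawn = alignment_scores(series, "dawn")
        dusk = alignment_scores(series, "dusk")
        assert dusk.dist_raw < dawn.dist_raw

    def test_identical_treatments_score_zero(self, t24_12h):
        m = TranscriptModel(10, 3, 6, 6, noise_sd=0.0, n_reps=2)
        s = simulate_transcript(m, t24_12h)
        res = alignment_scores([s, s], "dawn")
        assert res.dist_raw == 0.0

    def test_min_max_scaling_bounds_and_order(self):
        series_a = photoperiod_series(4.0, track="dawn", seed=3)
        series_b = photoperiod_series(2.0, track="dusk", seed=4)
        scores = [
            alignment_scores(series_a, "dawn"),
            alignment_scores(series_a, "dusk"),
            alignment_scores(series_b, "dawn"),
            alignment_scores(series_b, "dusk"),
        ]
        df = scale_scores(scores)
        assert df["dist_scaled"].min() == 0.0
        assert df["dist_scaled"].max() == 1.0
        order_raw = df["dist_raw"].rank().to_list()
        order_scaled = df["dist_scaled"].rank().to_list()
        assert order_raw == order_scaled

    def test_single_treatment_rejected(self, t24_12h):
        s = simulate_transcript(TranscriptModel(10, 3, 6, 6), t24_12h)
        with pytest.raises(ValidationError):
            alignment_scores([s], "dawn")


class TestAlignmentAnova:
    def test_identical_series_relabelled_nonsignificant(self, t24_12h):
        m = TranscriptModel(10, 3, 6, 6, noise_sd=0.2, n_reps=4, seed=6)
        s = simulate_transcript(m, t24_12h)
        res = alignment_anova(s, s, "dawn")
        assert res.p_photoperiod > 0.99
        assert res.aligned

    def test_dawn_locked_discriminates_anchors(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            series = photoperiod_series(
                peak_zt=4.0, photoperiods=(6, 18), track="dawn",
                noise_sd=0.2, n_reps=4, seed=seed,
            )
            dawn = alignment_anova(series[0], series[1], "dawn")
            dusk = alignment_anova(series[0], series[1], "dusk")
            # a dawn-tracking transcript is synchronized under dawn
            # anchoring only; desynchronization appears in the
            # photoperiod x time interaction under dusk anchoring
            if dawn.aligned and not dusk.aligned:
                hits += 1
        assert hits / n_seeds >= 0.9

    def test_type1_rate_near_nominal_under_null(self, t24_12h):
        rejections = 0
        n_sims = 300
        for seed in range(n_sims):
            a = simulate_transcript(
                TranscriptModel(10, 3, 6, 6, noise_sd=0.3, n_reps=3, seed=seed * 2),
                t24_12h,
            )
            b = simulate_transcript(
                TranscriptModel(10, 3, 6, 6, noise_sd=0.3, n_reps=3, seed=seed * 2 + 1),
                t24_12h,
            )
            if alignment_anova(a, b, "dawn").p_photoperiod < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_permuting_treatments_leaves_scores_unchanged(self):
        series = photoperiod_series(4.0, track="dawn", seed=9)
        fwd = alignment_scores(series, "dusk")
        rev = alignment_scores(series[::-1], "dusk")
        assert fwd.dist_raw == pytest.approx(rev.dist_raw)
        assert fwd.norm_raw == pytest.approx(rev.norm_raw)


class TestAlignmentTable:
    def test_full_table_flags_dawn_tracking(self):
        table = alignment_table(
            {
                "DAWN_G": photoperiod_series(4.0, track="dawn", seed=12, noise_sd=0.15, n_reps=4),
                "DUSK_G": photoperiod_series(2.0, track="dusk", seed=13, noise_sd=0.15, n_reps=4),
            }
        )
        assert set(table["anchor"]) == {"dawn", "dusk"}
        dawn_g = table[table["transcript"] == "DAWN_G"].set_index("anchor")
        assert (
            dawn_g.loc["dawn", "dist_scaled"] < dawn_g.loc["dusk", "dist_scaled"]
        )
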