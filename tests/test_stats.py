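"""Descriptive FI statistics: sample SD, summaries, histograms, concordance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fvquant import (
    generate_animal_field,
    group_concordance,
    sample_sd,
    scatter_distribution,
    summarize_group,
    summarize_sample,
)
from fvquant.presets import RAT_STAGE_PARAMS
from tests.conftest import midline_profile, profile_from_values


class TestSampleSd:
    def test_constant_values_zero(self):
        assert sample_sd([7, 7, 7]) == 0.0

    def test_two_values_hand_formula(self):
        # S = sqrt(((2-3)^2 + (4-3)^2) / 1) = sqrt(2)
        assert sample_sd([2, 4]) == pytest.approx(np.sqrt(2.0))

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            sample_sd([5.0])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 255), min_size=2, max_size=60))
    def test_matches_brute_force_formula(self, values):
        v = np.array(values)
        brute = np.sqrt(np.sum((v - np.mean(v)) ** 2) / (len(v) - 1))
        assert sample_sd(v) == pytest.approx(brute, abs=1e-12)


class TestSampleSummary:
    def test_constant_profile(self):
        s = summarize_sample(profile_from_values([5, 5, 5, 5]))
        assert (s.mean, s.sd, s.median, s.range) == (5, 0, 5, 0)

    def test_brute_force_order_statistics(self):
        s = summarize_sample(profile_from_values([1, 2, 3, 4]))
        assert s.mean == pytest.approx(2.5)
        assert s.sd == pytest.approx(np.sqrt(5.0 / 3.0))  # 1.2909...
        assert s.median == pytest.approx(2.5)  # midpoint of central pair
        assert (s.min, s.max, s.range) == (1, 4, 3)

    def test_sd_field_equals_sample_sd(self, control_params):
        img, _ = generate_animal_field(control_params, 0, seed=6)
        prof = midline_profile(img)
        s = summarize_sample(prof)
        assert s.sd == sample_sd(prof.finite_values())

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            summarize_sample(profile_from_values([1, np.nan]))


class TestGroupSummary:
    def test_single_sample_identity(self):
        prof = profile_from_values([1, 2, 3, 4, 8])
        s = summarize_sample(prof)
        g = summarize_group([prof])
        assert (g.mean, g.sd, g.median, g.min, g.max, g.range) == (
            s.mean, s.sd, s.median, s.min, s.max, s.range)

    def test_pooled_two_samples_brute_force(self):
        a = profile_from_values([1, 2, 3, 4])
        b = profile_from_values([10, 11, 12, 13])
        g = summarize_group([a, b])
        pooled = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        assert g.mean == pytest.approx(pooled.mean())
        assert g.min == 1 and g.max == 13 and g.range == 12
        assert g.median == pytest.approx(np.median(pooled))
        assert g.n_pixels == 8 and g.n_samples == 2

    def test_group_range_bounds_member_ranges(self, control_params):
        profs = [
            midline_profile(generate_animal_field(control_params, i, seed=13)[0])
            for i in range(5)
        ]
        g = summarize_group(profs)
        for p in profs:
            assert g.range >= summarize_sample(p).range

    def test_calibrated_lgd_group_mean(self):
        # LGD preset, n=11: pooled mean within 3 SE of 54.6
        p = RAT_STAGE_PARAMS["LGD"]
        profs = [
            midline_profile(generate_animal_field(p, i, seed=21)[0])
            for i in range(p.n_animals)
        ]
        g = summarize_group(profs)
        se = p.between_sd / np.sqrt(p.n_animals)
        assert abs(g.mean - 54.6) < 3 * se + 1.0  # +1 G slack for spot depletion


class TestScatterDistribution:
    def test_constant_profiles_one_bin(self):
        d = scatter_distribution({"A": [profile_from_values([50] * 9)]})
        assert (d.counts["A"] > 0).sum() == 1
        assert d.total("A") == 9

    def test_counts_conserved(self, control_params):
        profs = [
            midline_profile(generate_animal_field(control_params, i, seed=2)[0])
            for i in range(4)
        ]
        d = scatter_distribution({"Control": profs}, bin_width=5.0)
        assert d.total("Control") == sum(p.finite_values().size for p in profs)

    def test_control_mass_concentrated_25_35(self):
        # Control pixels concentrate in a narrow band around 32.5, unlike
        # any lesion stage.  With 10 animals the in-band fraction is
        # dominated by the between-animal draw, so compare the observed
        # fraction against its analytic expectation under the calibrated
        # parameters with a clustered (per-animal) standard error.
        from scipy import stats as sps

        frac = {}
        per_animal = {}
        for stage in ("Control", "Cancer"):
            p = RAT_STAGE_PARAMS[stage]
            profs = [
                midline_profile(generate_animal_field(p, i, seed=31)[0])
                for i in range(p.n_animals)
            ]
            d = scatter_distribution({stage: profs})
            edges = d.bin_edges[:-1]
            band = (edges >= 25) & (edges < 35)
            frac[stage] = d.counts[stage][band].sum() / d.counts[stage].sum()
            per_animal[stage] = np.array([
                ((v := pr.finite_values()) >= 25).mean() - (v >= 35).mean()
                for pr in profs
            ])
        p = RAT_STAGE_PARAMS["Control"]
        x = np.arange(p.line_px) - (p.line_px - 1) / 2
        pixel_sd = np.hypot(p.within_sd, p.axial_slope * x.std())
        m = np.linspace(p.mean_g - 5 * p.between_sd, p.mean_g + 5 * p.between_sd, 2001)
        w = sps.norm.pdf(m, p.mean_g, p.between_sd)
        band_prob = sps.norm.cdf(35, m, pixel_sd) - sps.norm.cdf(25, m, pixel_sd)
        expected = np.trapezoid(band_prob * w, m) / np.trapezoid(w, m)
        se = per_animal["Control"].std(ddof=1) / np.sqrt(10)
        assert abs(frac["Control"] - expected) < 3 * se
        assert frac["Control"] > frac["Cancer"]

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            scatter_distribution({}, bin_width=0.0)


class TestConcordance:
    def test_identical_profiles_r_one(self):
        p = profile_from_values([1, 5, 2, 8, 3])
        c = group_concordance([p, profile_from_values([1, 5, 2, 8, 3])])
        assert c.mean_r == pytest.approx(1.0)

    def test_anticorrelated_profiles_r_minus_one(self):
        v = np.array([1.0, 5.0, 2.0, 8.0, 3.0])
        c = group_concordance([profile_from_values(v), profile_from_values(10 - v)])
        assert c.mean_r == pytest.approx(-1.0)

    def test_shared_slope_high_r_vs_direct_formula(self, rng):
        x = np.arange(200.0)
        a = 0.03 * x + rng.normal(0, 0.5, 200)
        b = 0.03 * x + rng.normal(0, 0.5, 200)
        c = group_concordance([profile_from_values(a), profile_from_values(b)])
        direct = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert c.mean_r == pytest.approx(direct, abs=1e-12)
        assert c.mean_r > 0.7

    def test_unequal_lengths_resampled(self):
        long = profile_from_values(np.sin(np.linspace(0, 3, 200)))
        short = profile_from_values(np.sin(np.linspace(0, 3, 50)))
        c = group_concordance([long, short])
        assert c.mean_r > 0.95

    def test_short_profiles_rejected(self):
        with pytest.raises(ValueError):
            group_concordance([profile_from_values([1, 2]), profile_from_values([3, 4])])
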