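"""Decline rates, rate contrasts, mediation, and the two-level growth model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voxelight.containers import BrainMask, CohortVolumes, default_affine
from voxelight.longitudinal import (
    annual_decline_rate,
    cognitive_change,
    fit_growth_model,
    fit_null_model,
    mediate,
    rate_cognition_correlation,
    rate_group_diff,
    region_rates,
)
from voxelight.synthetic import (
    EffectRegion,
    SynthConfig,
    generate_cohort,
    generate_followup,
    simulate_growth,
    simulate_mediation,
)
from voxelight.voxelwise import build_mask


def _mask(dims=(4, 4, 4)):
    return BrainMask(np.ones(dims, bool), default_affine(1.0))


class TestAnnualRate:
    def test_arithmetic_of_the_rate_definition(self):
        """V1=1.0, V2=0.98 over 2 years: -0.01 per year."""
        mask = _mask()
        v1 = CohortVolumes(np.ones((1, 4, 4, 4)), mask.affine, ["s"])
        v2 = CohortVolumes(np.full((1, 4, 4, 4), 0.98), mask.affine, ["s"])
        rm = annual_decline_rate(v1, v2, np.array([2.0]), mask)
        assert np.allclose(rm.rates, -0.01)

    def test_no_change_is_zero_everywhere(self, rng):
        mask = _mask()
        data = rng.uniform(0.5, 1.0, size=(3, 4, 4, 4))
        v = CohortVolumes(data, mask.affine, ["a", "b", "c"])
        rm = annual_decline_rate(v, v, np.array([1.0, 2.0, 3.0]), mask)
        assert np.allclose(rm.rates, 0.0)

    def test_absolute_mode(self):
        mask = _mask()
        v1 = CohortVolumes(np.full((1, 4, 4, 4), 2.0), mask.affine, ["s"])
        v2 = CohortVolumes(np.full((1, 4, 4, 4), 1.5), mask.affine, ["s"])
        rm = annual_decline_rate(v1, v2, np.array([2.0]), mask, mode="absolute")
        assert np.allclose(rm.rates, -0.25)

    def test_zero_baseline_masked_and_counted(self):
        mask = _mask()
        d1 = np.ones((1, 4, 4, 4)); d1[0, 0, 0, 0] = 0.0
        v1 = CohortVolumes(d1, mask.affine, ["s"])
        v2 = CohortVolumes(np.ones((1, 4, 4, 4)), mask.affine, ["s"])
        rm = annual_decline_rate(v1, v2, np.array([1.0]), mask)
        assert rm.n_undefined == 1
        assert np.isnan(rm.rates).sum() == 1

    def test_nonpositive_interval_rejected(self):
        mask = _mask()
        v = CohortVolumes(np.ones((1, 4, 4, 4)), mask.affine, ["s"])
        with pytest.raises(ValueError, match="positive"):
            annual_decline_rate(v, v, np.array([0.0]), mask)

    def test_roundtrip_recovers_planted_rates_exactly(self):
        """With jitter and follow-up noise off, recovered voxel-wise rates
        equal the planted generator rates to machine precision."""
        cfg = SynthConfig(
            n_per_group=10, effect_regions=[], cognitive_weights={},
            interval_jitter_sd=0.0, followup_noise_sd=0.0, seed=3,
        )
        phen, vols, _, truth = generate_cohort(cfg)
        follow, phen2, _, report = generate_followup(vols, phen, truth, cfg)
        mask = build_mask(vols)
        rm = annual_decline_rate(vols, follow, phen2["interval_years"], mask)
        region = truth.decline_masks["frontal"][mask.data]
        exposed = (phen2["group"] == "DD").to_numpy()
        expected = np.full(rm.rates.shape, cfg.decline_rate_base)
        expected[np.ix_(exposed, region)] += cfg.decline_rate_delta
        ok = np.isfinite(rm.rates)
        assert ok.all()
        assert np.abs(rm.rates - expected).max() < 1e-12


class TestRegionRates:
    def test_two_region_hand_average(self):
        mask = BrainMask(np.ones((2, 2, 2), bool), np.eye(4))
        atlas = np.array([1, 1, 1, 1, 2, 2, 2, 2]).reshape(2, 2, 2)
        rates = np.arange(8.0)[None, :]
        from voxelight.longitudinal import DeclineRateMap

        rm = DeclineRateMap(rates, mask, ["s"], np.ones(1))
        table = region_rates(rm, atlas)
        assert table.loc[0, "region_1"] == pytest.approx(np.mean([0, 1, 2, 3]))
        assert table.loc[0, "region_2"] == pytest.approx(np.mean([4, 5, 6, 7]))

    def test_one_region_atlas_is_global_mean(self, rng):
        mask = _mask()
        rates = rng.normal(size=(2, mask.n_voxels))
        from voxelight.longitudinal import DeclineRateMap

        rm = DeclineRateMap(rates, mask, ["a", "b"], np.ones(2))
        table = region_rates(rm, np.ones((4, 4, 4), int))
        assert np.allclose(table["region_1"], rates.mean(axis=1))


class TestRateGroupDiff:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted_rate_cohort():
        cfg = SynthConfig(
            n_per_group=40, effect_regions=[], cognitive_weights={},
            decline_rate_delta=-0.02, age_shift_years=0.0, seed=17,
        )
        phen, vols, _, truth = generate_cohort(cfg)
        follow, phen2, _, _ = generate_followup(vols, phen, truth, cfg)
        mask = build_mask(vols)
        rm = annual_decline_rate(vols, follow, phen2["interval_years"], mask)
        return cfg, phen2, truth, mask, rm

    def test_planted_cluster_peak_inside_truth_mask(self, planted_rate_cohort):
        cfg, phen2, truth, mask, rm = planted_rate_cohort
        stat, clusters = rate_group_diff(
            rm, phen2["group"].to_numpy(),
            phen2[["age", "gender", "education", "tiv"]],
        )
        assert len(clusters) >= 1
        peak = clusters.iloc[0]
        assert truth.decline_masks["frontal"][
            int(peak["peak_i"]), int(peak["peak_j"]), int(peak["peak_k"])
        ]

    def test_antisymmetry_under_label_swap(self, planted_rate_cohort):
        cfg, phen2, truth, mask, rm = planted_rate_cohort
        g = phen2["group"].to_numpy()
        s1, _ = rate_group_diff(rm, g, None)
        s2, _ = rate_group_diff(rm, np.where(g == "DD", "ODD", "DD"), None)
        assert np.allclose(s1.t, -s2.t, atol=1e-10)

    def test_null_delta_nothing_survives_fdr(self):
        cfg = SynthConfig(
            n_per_group=40, effect_regions=[], cognitive_weights={},
            decline_rate_delta=0.0, age_shift_years=0.0, seed=19,
        )
        phen, vols, _, truth = generate_cohort(cfg)
        follow, phen2, _, _ = generate_followup(vols, phen, truth, cfg)
        mask = build_mask(vols)
        rm = annual_decline_rate(vols, follow, phen2["interval_years"], mask)
        stat, clusters = rate_group_diff(rm, phen2["group"].to_numpy(), None)
        assert (stat.q <= 0.05).mean() < 0.01
        assert clusters.empty


class TestRateCognitionCorrelation:
    def test_identity_gives_r_one(self):
        table = pd.DataFrame({"subject_id": list("abcdef"),
                              "region_1": np.arange(6.0)})
        change = pd.DataFrame({"subject_id": list("abcdef"),
                               "memory": np.arange(6.0)})
        out = rate_cognition_correlation(table, change)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_matches_textbook_formula_on_six_pairs(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0, 7.0])
        table = pd.DataFrame({"subject_id": list("abcdef"), "region_1": x})
        change = pd.DataFrame({"subject_id": list("abcdef"), "memory": y})
        out = rate_cognition_correlation(table, change)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert out.loc[0, "r"] == pytest.approx(num / den)
        assert out.loc[0, "p"] == pytest.approx(stats.pearsonr(x, y).pvalue)

    def test_independent_noise_centered_at_zero(self, rng):
        rs = []
        for _ in range(50):
            table = pd.DataFrame({"subject_id": range(40),
                                  "region_1": rng.normal(size=40)})
            change = pd.DataFrame({"subject_id": range(40),
                                   "memory": rng.normal(size=40)})
            rs.append(rate_cognition_correlation(table, change).loc[0, "r"])
        assert abs(np.mean(rs)) < 0.08

    def test_too_few_pairs_rejected(self):
        table = pd.DataFrame({"subject_id": list("abc"), "region_1": [1.0, 2, 3]})
        change = pd.DataFrame({"subject_id": list("abc"), "memory": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="fewer than 5"):
            rate_cognition_correlation(table, change)


class TestMediation:
    def test_zero_b_path_gives_zero_proportion(self):
        df, truth = simulate_mediation(n=400, a=-0.02, b=0.0, c_direct=-0.1, seed=1)
        res = mediate(df["group"], df["rate"], df["change"],
                      df[["age"]], n_boot=500, seed=1)
        assert abs(res.indirect) < 0.02
        assert res.indirect_ci[0] <= 0.0 <= res.indirect_ci[1]

    def test_full_mediation_proportion_near_one(self):
        df, truth = simulate_mediation(n=300, a=-0.03, b=6.0, c_direct=0.0,
                                       sd_change=0.05, seed=2)
        res = mediate(df["group"], df["rate"], df["change"],
                      df[["age"]], n_boot=1000, seed=2)
        assert res.proportion_mediated is not None
        assert res.proportion_ci[0] <= 1.0 <= res.proportion_ci[1]
        assert res.proportion_mediated == pytest.approx(1.0, abs=0.25)

    def test_indirect_effect_recovered_over_seeds(self):
        """a*b estimates track the generating product within 10% on average
        at n=500 over 20 seeds."""
        truth_ab = -0.02 * 5.0
        ests = []
        for seed in range(20):
            df, _ = simulate_mediation(n=500, seed=seed)
            res = mediate(df["group"], df["rate"], df["change"],
                          df[["age"]], n_boot=50, seed=seed)
            ests.append(res.indirect)
        assert abs(np.mean(ests) - truth_ab) < 0.1 * abs(truth_ab)

    def test_proportion_invariant_to_outcome_rescaling(self):
        df, _ = simulate_mediation(n=300, seed=5)
        res1 = mediate(df["group"], df["rate"], df["change"], None,
                       n_boot=200, seed=5)
        res2 = mediate(df["group"], df["rate"], 10.0 * df["change"] + 3.0, None,
                       n_boot=200, seed=5)
        assert res1.proportion_mediated == pytest.approx(
            res2.proportion_mediated, abs=1e-10
        )

    def test_summary_prints_paths(self):
        df, _ = simulate_mediation(n=200, seed=7)
        res = mediate(df["group"], df["rate"], df["change"], None,
                      n_boot=100, seed=7)
        text = res.summary()
        assert "proportion mediated" in text
        assert "indirect" in text


class TestNullModel:
    def test_pure_between_subject_variance_icc_near_one(self):
        scores = np.repeat(np.arange(30.0), 3)
        df = pd.DataFrame({"subject_id": np.repeat(range(30), 3), "score": scores})
        res = fit_null_model(df)
        assert res.icc > 0.95

    def test_pure_noise_icc_near_zero(self, rng):
        df = pd.DataFrame({"subject_id": np.repeat(range(80), 3),
                           "score": rng.normal(size=240)})
        res = fit_null_model(df)
        assert res.icc < 0.1

    def test_variance_components_recovered(self):
        """200 subjects x 3 visits: both components within 10% of truth."""
        rng = np.random.default_rng(8)
        between, within = 1.0, 0.25
        subj = rng.normal(0, np.sqrt(between), 200)
        scores = subj[np.repeat(np.arange(200), 3)] + rng.normal(
            0, np.sqrt(within), 600
        )
        df = pd.DataFrame({"subject_id": np.repeat(range(200), 3), "score": scores})
        res = fit_null_model(df)
        assert res.var_between == pytest.approx(between, rel=0.15)
        assert res.var_within == pytest.approx(within, rel=0.1)

    def test_no_repeats_rejected(self):
        df = pd.DataFrame({"subject_id": range(10), "score": np.arange(10.0)})
        with pytest.raises(ValueError, match="repeated"):
            fit_null_model(df)


class TestGrowthModel:
    def test_recovers_known_group_slope_effect(self):
        long_df, truth = simulate_growth(n_subjects=300, seed=1)
        res = fit_growth_model(long_df)
        assert res.converged
        assert abs(res.fixed_effects["b14"] - truth["b14"]) < 2 * res.standard_errors["b14"]

    def test_gender_recoding_shifts_only_intercept_terms(self):
        long_df, _ = simulate_growth(n_subjects=150, seed=2)
        res1 = fit_growth_model(long_df)
        recoded = long_df.assign(gender=long_df["gender"] + 1.0)
        res2 = fit_growth_model(recoded)
        for k in ("b01", "b02", "b03", "b04", "b11", "b12", "b13", "b14"):
            assert res1.fixed_effects[k] == pytest.approx(
                res2.fixed_effects[k], abs=5e-3
            )
        shift = res2.fixed_effects["b00"] - res1.fixed_effects["b00"]
        assert shift == pytest.approx(-res1.fixed_effects["b02"], abs=5e-3)

    def test_zero_slope_variance_flagged_at_boundary(self):
        long_df, _ = simulate_growth(n_subjects=120, sd_slope=0.0, seed=3)
        res = fit_growth_model(long_df)
        assert res.var_slope < 0.005
        assert res.boundary or res.var_slope < 1e-4

    def test_missing_columns_rejected(self):
        df = pd.DataFrame({"subject_id": [1], "time": [0.0], "score": [1.0]})
        with pytest.raises(KeyError, match="missing"):
            fit_growth_model(df)

    def test_summary_lists_all_fixed_effects(self):
        long_df, _ = simulate_growth(n_subjects=80, seed=4)
        text = fit_growth_model(long_df).summary()
        for k in ("b00", "b04", "b10", "b14", "var(r0)"):
            assert k in text


def test_cognitive_change_arithmetic():
    base = pd.DataFrame({"subject_id": ["a", "b"], "memory": [1.0, 2.0]})
    follow = pd.DataFrame({"subject_id": ["a", "b"], "memory": [0.5, 2.0]})
    dt = pd.Series([2.0, 4.0], index=["a", "b"])
    out = cognitive_change(base, follow, dt)
    assert out.loc[out["subject_id"] == "a", "memory"].iloc[0] == pytest.approx(-0.25)
    assert out.loc[out["subject_id"] == "b", "memory"].iloc[0] == pytest.approx(0.0)
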