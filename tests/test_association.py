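"""OLS/GLM engine: coding, fitting, lsmeans, pairwise tests, covariate scan."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from binflux import association as assoc
from binflux.abundance import BinAbundanceMatrix


def _obs(n_per_cell=2, seed=0, with_abundance=False):
    """Balanced 2-set x 3-period x 2-dose grid of observations."""
    rng = np.random.default_rng(seed)
    rows = []
    for eset in ("non_acclimatized", "acclimatized"):
        for period in ("I", "II", "III"):
            for dose in (2.0, 3.0):
                for r in range(n_per_cell):
                    rows.append(
                        {
                            "sample_id": f"{eset[:1]}{period}{int(dose)}r{r}",
                            "experimental_set": eset,
                            "period": period,
                            "lcfa_dose": dose,
                            "abundance": rng.random() * 5,
                        }
                    )
    df = pd.DataFrame(rows)
    if not with_abundance:
        df = df.drop(columns="abundance")
    return df


class TestDesignMatrix:
    def test_treatment_coding_reference_is_first_sorted_level(self):
        obs = _obs()
        spec = assoc.GLMSpec(trait="methane_yield", fixed_effects=("period",))
        obs["methane_yield"] = 1.0
        X, labels, effect_cols, levels = assoc.build_design_matrix(obs, spec)
        assert labels == ["Intercept", "period[T.II]", "period[T.III]"]
        assert levels["period"] == ["I", "II", "III"]

    def test_two_level_factor_yields_one_dummy(self):
        obs = _obs()
        spec = assoc.GLMSpec(trait="acetate", fixed_effects=("inoculum",))
        obs["acetate"] = 1.0
        X, labels, _, _ = assoc.build_design_matrix(obs, spec)
        assert X.shape[1] == 2

    def test_collinear_columns_are_named(self):
        obs = _obs()
        # dose identical to the inoculum dummy -> aliased
        obs["lcfa_dose"] = (obs["experimental_set"] == "non_acclimatized").astype(float)
        obs["acetate"] = 1.0
        spec = assoc.GLMSpec(
            trait="acetate", fixed_effects=("inoculum", "lcfa_dose")
        )
        with pytest.raises(assoc.RankDeficiencyError) as err:
            assoc.build_design_matrix(obs, spec)
        assert err.value.aliased  # at least one named column


class TestFit:
    def test_exact_fit_recovers_slope(self):
        obs = _obs(with_abundance=True)
        obs["methane_yield"] = 3.0 + 2.5 * obs["abundance"]
        spec = assoc.GLMSpec(
            trait="methane_yield", fixed_effects=(), covariate_bin="b1"
        )
        fit = assoc.fit_glm(obs, spec)
        assert fit.params["abundance"] == pytest.approx(2.5, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_balanced_two_group_closed_form(self):
        obs = pd.DataFrame(
            {
                "experimental_set": ["non_acclimatized"] * 2 + ["acclimatized"] * 2,
                "acetate": [10.0, 10.0, 20.0, 20.0],
            }
        )
        spec = assoc.GLMSpec(trait="acetate", fixed_effects=("inoculum",))
        fit = assoc.fit_glm(obs, spec)
        # reference level is 'acclimatized' (first sorted), dummy is non_acclimatized
        assert fit.params["Intercept"] == pytest.approx(20.0, abs=1e-12)
        assert fit.params["inoculum[T.non_acclimatized]"] == pytest.approx(
            -10.0, abs=1e-12
        )
        lsm = assoc.lsmeans(fit, "inoculum")
        assert dict(zip(lsm["level"], lsm["lsmean"])) == pytest.approx(
            {"acclimatized": 20.0, "non_acclimatized": 10.0}
        )

    def test_matches_statsmodels_on_noisy_data(self):
        rng = np.random.default_rng(42)
        obs = _obs(with_abundance=True, seed=1)
        obs["acetate"] = (
            1.0
            + 0.5 * (obs["experimental_set"] == "non_acclimatized")
            + 0.3 * (obs["period"] == "II")
            - 0.2 * (obs["period"] == "III")
            + 0.1 * obs["lcfa_dose"]
            + 0.7 * obs["abundance"]
            + rng.normal(0, 0.3, len(obs))
        )
        spec = assoc.GLMSpec(
            trait="acetate",
            fixed_effects=("inoculum", "period", "lcfa_dose"),
            covariate_bin="b1",
        )
        fit = assoc.fit_glm(obs, spec)
        ref = smf.ols(
            "acetate ~ C(experimental_set) + C(period) + lcfa_dose + abundance",
            data=obs,
        ).fit()
        assert fit.params["abundance"] == pytest.approx(ref.params["abundance"], rel=1e-9)
        assert fit.bse["abundance"] == pytest.approx(ref.bse["abundance"], rel=1e-9)
        assert fit.pvalues["abundance"] == pytest.approx(
            ref.pvalues["abundance"], rel=1e-8
        )
        assert fit.df_resid == int(ref.df_resid)
        assert fit.params["Intercept"] == pytest.approx(ref.params["Intercept"], rel=1e-9)

    def test_sum_of_squares_decomposition(self):
        rng = np.random.default_rng(3)
        obs = _obs(seed=2)
        obs["butyrate"] = rng.random(len(obs))
        fit = assoc.fit_glm(
            obs, assoc.GLMSpec(trait="butyrate", fixed_effects=("inoculum", "period"))
        )
        assert fit.ss_model + fit.ss_resid == pytest.approx(fit.ss_total, rel=1e-8)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(8)
        obs = _obs(with_abundance=True, seed=5)
        obs["propionate"] = rng.random(len(obs)) * 4
        spec = assoc.GLMSpec(
            trait="propionate",
            fixed_effects=("inoculum", "period", "lcfa_dose"),
            covariate_bin="b1",
        )
        X, labels, _, _ = assoc.build_design_matrix(obs, spec)
        fit = assoc.fit_glm(obs, spec)
        resid = obs["propionate"].to_numpy() - X @ fit.params.to_numpy()
        Xs = X / np.linalg.norm(X, axis=0)
        assert np.max(np.abs(Xs.T @ resid)) < 1e-8

    def test_two_level_f_equals_t_squared(self):
        rng = np.random.default_rng(13)
        obs = _obs(seed=7)
        obs["total_vfa"] = rng.random(len(obs))
        fit = assoc.fit_glm(
            obs,
            assoc.GLMSpec(trait="total_vfa", fixed_effects=("inoculum", "period")),
        )
        F = fit.effect_tests.set_index("effect").loc["inoculum", "F"]
        t = fit.tvalues["inoculum[T.non_acclimatized]"]
        assert F == pytest.approx(t**2, rel=1e-10)

    def test_insufficient_df_is_an_error(self):
        obs = _obs(with_abundance=True).iloc[:3]
        obs = obs.assign(acetate=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="insufficient"):
            assoc.fit_glm(
                obs,
                assoc.GLMSpec(
                    trait="acetate",
                    fixed_effects=("lcfa_dose",),
                    covariate_bin="b1",
                ),
            )


class TestLsmeans:
    def test_balanced_design_lsmeans_equal_raw_means(self):
        rng = np.random.default_rng(21)
        obs = _obs(seed=10)
        obs["methane_yield"] = rng.normal(260, 10, len(obs))
        fit = assoc.fit_glm(
            obs,
            assoc.GLMSpec(trait="methane_yield", fixed_effects=("inoculum", "period")),
        )
        lsm = assoc.lsmeans(fit, "period")
        raw = obs.groupby("period")["methane_yield"].mean()
        for _, row in lsm.iterrows():
            assert row["lsmean"] == pytest.approx(raw[row["level"]], rel=1e-9)

    def test_unbalanced_lsmeans_match_hand_computed_prediction(self):
        """6-row unbalanced two-factor layout, hand-checked contrast.

        lsmean(level) = Intercept + beta_level + 0.5 * beta_other_dummy
        (equal weight over the other factor's two levels), which differs
        from the raw group mean here.
        """
        obs = pd.DataFrame(
            {
                "experimental_set": [
                    "acclimatized", "acclimatized", "acclimatized",
                    "non_acclimatized", "non_acclimatized", "non_acclimatized",
                ],
                "period": ["I", "I", "II", "I", "II", "II"],
                "acetate": [1.0, 1.2, 2.0, 1.6, 2.9, 3.1],
            }
        )
        fit = assoc.fit_glm(
            obs, assoc.GLMSpec(trait="acetate", fixed_effects=("inoculum", "period"))
        )
        b = fit.params
        lsm = assoc.lsmeans(fit, "inoculum").set_index("level")["lsmean"]
        expect_acc = b["Intercept"] + 0.5 * b["period[T.II]"]
        expect_non = (
            b["Intercept"]
            + b["inoculum[T.non_acclimatized]"]
            + 0.5 * b["period[T.II]"]
        )
        assert lsm["acclimatized"] == pytest.approx(expect_acc, rel=1e-12)
        assert lsm["non_acclimatized"] == pytest.approx(expect_non, rel=1e-12)
        raw = obs.groupby("experimental_set")["acetate"].mean()
        assert abs(lsm["acclimatized"] - raw["acclimatized"]) > 1e-3

    def test_identical_group_means_give_p_one(self):
        obs = pd.DataFrame(
            {
                "experimental_set": ["acclimatized"] * 3 + ["non_acclimatized"] * 3,
                "acetate": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            }
        )
        fit = assoc.fit_glm(
            obs, assoc.GLMSpec(trait="acetate", fixed_effects=("inoculum",))
        )
        tt = assoc.lsmeans_ttest(fit, "inoculum")
        assert tt["p_value"].iloc[0] == pytest.approx(1.0)

    def test_unknown_effect_is_an_error(self):
        obs = _obs().assign(acetate=1.0)
        fit = assoc.fit_glm(
            obs, assoc.GLMSpec(trait="acetate", fixed_effects=("inoculum",))
        )
        with pytest.raises(KeyError, match="period"):
            assoc.lsmeans(fit, "period")


class TestCovariateScan:
    def _abund_matrix(self, obs, values: dict[str, np.ndarray]):
        mat = pd.DataFrame(values, index=obs["sample_id"]).T
        mat.index.name = "bin_id"
        samples = obs[["sample_id", "experimental_set", "period", "lcfa_dose"]].copy()
        samples["reactor_id"] = "R"
        samples["replicate"] = 1
        samples["day"] = range(len(obs))
        samples["aligned_reads"] = 100
        return BinAbundanceMatrix(abundance=mat, samples=samples)

    def test_planted_slope_flagged_with_direction(self):
        rng = np.random.default_rng(17)
        obs = _obs(n_per_cell=3, seed=4)
        up = rng.random(len(obs)) * 5
        down = rng.random(len(obs)) * 5
        null = rng.random(len(obs)) * 5
        obs["acetate"] = 2.0 + 1.5 * up - 1.1 * down + rng.normal(0, 0.05, len(obs))
        abund = self._abund_matrix(obs, {"b_up": up, "b_down": down, "b_null": null})
        scan = assoc.covariate_scan(obs, abund, "acetate").set_index("bin_id")
        assert scan.loc["b_up", "sign"] == "increasing"
        assert scan.loc["b_up", "significant"]
        assert scan.loc["b_down", "sign"] == "decreasing"
        assert scan.loc["b_down", "significant"]
        assert not scan.loc["b_null", "significant"]

    def test_constant_abundance_surfaces_rank_error_and_continues(self):
        rng = np.random.default_rng(19)
        obs = _obs(seed=6)
        obs["acetate"] = rng.random(len(obs))
        good = rng.random(len(obs))
        abund = self._abund_matrix(
            obs, {"b_const": np.ones(len(obs)), "b_good": good}
        )
        scan = assoc.covariate_scan(obs, abund, "acetate").set_index("bin_id")
        assert scan.loc["b_const", "note"].startswith("rank_deficient")
        assert scan.loc["b_good", "note"] == ""

    def test_null_false_positive_rate_bounded(self):
        """Trait independent of all bins: flagged fraction near alpha."""
        rng = np.random.default_rng(29)
        obs = _obs(n_per_cell=3, seed=9)
        obs["butyrate"] = rng.normal(0.2, 0.05, len(obs))
        n_bins = 120
        vals = {f"b{i:03d}": rng.random(len(obs)) for i in range(n_bins)}
        abund = self._abund_matrix(obs, vals)
        scan = assoc.covariate_scan(obs, abund, "butyrate", alpha=0.05)
        frac = scan["significant"].mean()
        se = np.sqrt(0.05 * 0.95 / n_bins)
        assert frac <= 0.05 + 3 * se


def test_ac_pr_ratio_drops_zero_propionate_rows():
    proc = pd.DataFrame(
        {
            "reactor_id": ["R1"] * 3,
            "day": [1, 2, 3],
            "methane_yield": [260.0] * 3,
            "total_vfa": [2.5] * 3,
            "acetate": [1.2, 1.0, 0.9],
            "propionate": [0.4, 0.0, 0.3],
            "butyrate": [0.2] * 3,
            "ph": [7.8] * 3,
        }
    )
    out = assoc.compute_trait(proc, "ac_pr_ratio")
    assert len(out) == 2
    assert out.attrs["dropped_zero_propionate"] == 1
    assert out["ac_pr_ratio"].iloc[0] == pytest.approx(3.0)


def test_join_failure_lists_unmatched_records():
    design = pd.DataFrame(
        {
            "sample_id": ["s1"],
            "experimental_set": ["acclimatized"],
            "reactor_id": ["R9"],
            "replicate": [1],
            "lcfa_dose": [2.0],
            "period": ["I"],
            "day": [3],
            "aligned_reads": [100],
        }
    )
    proc = pd.DataFrame(
        {
            "reactor_id": ["R1"],
            "day": [3],
            "methane_yield": [260.0],
            "total_vfa": [2.5],
            "acetate": [1.0],
            "propionate": [0.5],
            "butyrate": [0.2],
            "ph": [7.8],
        }
    )
    with pytest.raises(KeyError, match="R9, day 3"):
        assoc.prepare_observations(design, proc, "acetate")
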