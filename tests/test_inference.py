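"""Mixed-model engine, ANOVA, EMMs and the contrast layer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stroopdelta as sd
from stroopdelta.inference import ModelSpec, cohens_d_westfall, emm, partial_eta_sq


def _oneway(means, n_per, resid_sd=30.0, part_sd=0.0, reps=1, seed=0):
    """Balanced (or unbalanced) one-factor layout with a nuisance 'batch'
    random grouping."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi, (mu, n) in enumerate(zip(means, n_per)):
        for i in range(n):
            poff = rng.normal(0, part_sd) if part_sd else 0.0
            for r in range(reps):
                rows.append(
                    dict(
                        cond=f"g{gi}",
                        batch=f"b{i % 4}",
                        unit=f"g{gi}u{i}",
                        y=mu + poff + rng.normal(0, resid_sd),
                    )
                )
    return pd.DataFrame(rows)


SPEC_BATCH = ModelSpec(response="y", fixed=(("cond",),), random=(("batch",),))


class TestFitLmm:
    def test_zero_variance_reduces_to_ols(self):
        data = _oneway([500, 520, 540], [20, 20, 20], seed=3)
        fit = sd.fit_lmm(data, SPEC_BATCH)
        # batch has no true effect: variance component collapses
        assert fit.result.varcomps[0] <= 1e-4 * fit.result.sigma2 + 1e-8
        X = np.column_stack(
            [
                np.ones(len(data)),
                (data.cond == "g0") * 1.0 - (data.cond == "g2") * 1.0,
                (data.cond == "g1") * 1.0 - (data.cond == "g2") * 1.0,
            ]
        )
        beta_ols = np.linalg.lstsq(X, data["y"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)

    def test_balanced_cell_means_recovered(self):
        data = _oneway([480, 500, 560], [12, 12, 12], seed=4)
        fit = sd.fit_lmm(data, SPEC_BATCH)
        g = emm(fit, ("cond",))
        cell = data.groupby("cond")["y"].mean()
        np.testing.assert_allclose(
            g.table["estimate"].to_numpy(), cell.to_numpy(), atol=1e-8
        )

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        rows = []
        for s in range(6):
            soff = rng.normal(0, 20)
            for p in range(8):
                poff = rng.normal(0, 30)
                for c, eff in (("a", 0), ("b", 15), ("c", -10)):
                    for _ in range(4):
                        rows.append(
                            dict(study=f"s{s}", pid=f"s{s}p{p}", cond=c,
                                 y=500 + eff + soff + poff + rng.normal(0, 40))
                        )
        df = pd.DataFrame(rows)
        spec = ModelSpec(
            response="y", fixed=(("cond",),), random=(("study", "pid"), ("study",))
        )
        ours = sd.fit_lmm(df, spec)
        sm_fit = smf.mixedlm(
            "y ~ C(cond, Sum)", df, groups="study",
            re_formula="1", vc_formula={"pid": "0 + C(pid)"},
        ).fit(reml=True, method="lbfgs")
        np.testing.assert_allclose(ours.beta, sm_fit.fe_params.values, atol=1e-5)
        assert ours.result.varcomps[0] == pytest.approx(float(sm_fit.vcomp[0]), rel=1e-2)
        assert ours.result.varcomps[1] == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-2
        )
        assert ours.result.sigma2 == pytest.approx(float(sm_fit.scale), rel=1e-2)

    def test_too_few_random_levels_rejected(self):
        data = _oneway([500], [6])
        data["batch"] = "b0"
        with pytest.raises(ValueError, match="levels"):
            sd.fit_lmm(data, SPEC_BATCH)


class TestAnova:
    def test_balanced_oneway_equals_classical_f(self):
        # nuisance batch variance collapses to the boundary for this draw,
        # so the GLS F must coincide with the classical one-way ANOVA F
        data = _oneway([490, 505, 520], [16, 16, 16], seed=12)
        fit = sd.fit_lmm(data, SPEC_BATCH)
        assert fit.result.varcomps[0] < 1e-2
        row = sd.anova_table(fit).iloc[0]
        groups = [g["y"].to_numpy() for _, g in data.groupby("cond")]
        f_classic = stats.f_oneway(*groups).statistic
        assert row["F"] == pytest.approx(f_classic, rel=1e-6)

    def test_eta_sq_internally_consistent(self, clean_single_target_cohort):
        retained, _, _ = sd.preprocess(clean_single_target_cohort)
        cdf = sd.build_cdf_dataset(retained)
        fit = sd.fit_lmm(cdf, sd.rt_model_spec())
        tab = sd.anova_table(fit)
        for _, r in tab.iterrows():
            if np.isfinite(r["df2"]):
                assert r["eta_sq_partial"] == pytest.approx(
                    partial_eta_sq(r["F"], r["df1"], r["df2"])
                )

    @pytest.mark.parametrize(
        "F, df1, df2, expected",
        [(0.0, 1, 10, 0.0), (5.0, 2, 20.0, 10.0 / 30.0)],
    )
    def test_partial_eta_sq_formula(self, F, df1, df2, expected):
        assert partial_eta_sq(F, df1, df2) == pytest.approx(expected)

    def test_partial_eta_sq_validates(self):
        with pytest.raises(ValueError):
            partial_eta_sq(-1, 1, 10)


class TestStepwise:
    def test_all_significant_spec_unchanged(self):
        data = _oneway([450, 520, 600], [15, 15, 15], seed=2)
        reduced, log = sd.stepwise_reduce(SPEC_BATCH, data, alpha=0.05)
        assert reduced == SPEC_BATCH and log == []

    def test_null_interaction_removed_first(self):
        rng = np.random.default_rng(11)
        rows = []
        for a in ("a0", "a1"):
            for b in ("b0", "b1"):
                for i in range(25):
                    y = 500 + (30 if a == "a1" else 0) + (20 if b == "b1" else 0)
                    rows.append(
                        dict(fa=a, fb=b, batch=f"b{i % 4}", y=y + rng.normal(0, 25))
                    )
        data = pd.DataFrame(rows)
        spec = ModelSpec(
            response="y",
            fixed=(("fa",), ("fb",), ("fa", "fb")),
            random=(("batch",),),
        )
        # oracle: the interaction's own p must be >= alpha before removal
        full = sd.fit_lmm(data, spec)
        p_int = sd.anova_table(full).set_index("term").loc["fa:fb", "p"]
        assert p_int >= 0.05
        reduced, log = sd.stepwise_reduce(spec, data, alpha=0.05)
        assert log[0]["removed"] == "fa:fb"
        assert ("fa",) in reduced.fixed and ("fb",) in reduced.fixed

    def test_marginality_protects_main_effects(self):
        rng = np.random.default_rng(13)
        rows = []
        for a in ("a0", "a1"):
            for b in ("b0", "b1"):
                # pure crossover: no main effects, strong interaction
                eff = 30 if (a == "a1") == (b == "b1") else -30
                for i in range(25):
                    rows.append(
                        dict(fa=a, fb=b, batch=f"b{i % 4}", y=500 + eff + rng.normal(0, 20))
                    )
        data = pd.DataFrame(rows)
        spec = ModelSpec(
            response="y",
            fixed=(("fa",), ("fb",), ("fa", "fb")),
            random=(("batch",),),
        )
        reduced, _ = sd.stepwise_reduce(spec, data, alpha=0.05)
        # interaction significant => its mains stay despite p ~ 1
        assert reduced.fixed == spec.fixed


class TestEmmAndContrasts:
    def test_unbalanced_equal_weight_contract(self):
        data = _oneway([10, 20], [10, 90], resid_sd=1e-6, seed=1)
        fit = sd.fit_lmm(data, SPEC_BATCH)
        g = emm(fit, ("cond",))
        np.testing.assert_allclose(
            g.table["estimate"].to_numpy(), [10.0, 20.0], atol=1e-4
        )
        grand = emm(fit, ())
        assert grand.table["estimate"].iloc[0] == pytest.approx(15.0, abs=1e-4)

    def test_tukey_two_levels_equals_unadjusted_t(self):
        data = _oneway([500, 520], [15, 15], seed=6)
        fit = sd.fit_lmm(data, SPEC_BATCH)
        g = emm(fit, ("cond",))
        tk = sd.pairwise_tukey(g, "cond")
        assert len(tk) == 1
        assert tk["p_adj"].iloc[0] == pytest.approx(tk["p_raw"].iloc[0], abs=1e-9)

    def test_tukey_identical_group_values_p_one(self):
        # the same response values in every group: contrasts are exactly 0
        rng = np.random.default_rng(9)
        base = rng.normal(500, 30, 20)
        data = pd.concat(
            [
                pd.DataFrame(
                    {"cond": g, "batch": [f"b{i % 4}" for i in range(20)], "y": base}
                )
                for g in ("g0", "g1", "g2")
            ],
            ignore_index=True,
        )
        fit = sd.fit_lmm(data, SPEC_BATCH)
        tk = sd.pairwise_tukey(emm(fit, ("cond",)), "cond")
        np.testing.assert_allclose(tk["estimate"], 0.0, atol=1e-10)
        assert (tk["p_adj"] > 0.999).all()

    def test_adjusted_p_not_below_raw(self, clean_single_target_cohort):
        retained, _, _ = sd.preprocess(clean_single_target_cohort)
        delta = sd.build_delta_dataset(sd.build_cdf_dataset(retained))
        fit = sd.fit_lmm(delta, sd.delta_model_spec())
        g = emm(fit, ("prob",))
        tk = sd.pairwise_tukey(g, "prob")
        assert (tk["p_adj"] >= tk["p_raw"] - 1e-12).all()
        vs0 = sd.contrasts_vs_zero(g)
        assert (vs0["p_adj"] >= vs0["p_raw"] - 1e-12).all()

    def test_bonferroni_multiplies_raw_p(self, clean_single_target_cohort):
        retained, _, _ = sd.preprocess(clean_single_target_cohort)
        delta = sd.build_delta_dataset(sd.build_cdf_dataset(retained))
        fit = sd.fit_lmm(delta, sd.delta_model_spec())
        vs0 = sd.contrasts_vs_zero(emm(fit, ("prob",)))
        m = len(vs0)
        np.testing.assert_allclose(
            vs0["p_adj"], np.minimum(1.0, m * vs0["p_raw"]), atol=1e-12
        )
        assert (vs0["ci_low"] <= vs0["estimate"]).all()
        assert (vs0["estimate"] <= vs0["ci_high"]).all()


class TestWestfallD:
    def test_arithmetic_example(self):
        assert cohens_d_westfall(12.0, [4, 5, 7]) == pytest.approx(3.0)

    def test_zero_estimate(self):
        assert cohens_d_westfall(0.0, [10.0]) == 0.0

    def test_sign_follows_estimate(self, rng):
        for _ in range(20):
            est = float(rng.normal(0, 50))
            vc = rng.uniform(1, 100, 3)
            assert np.sign(cohens_d_westfall(est, vc)) == np.sign(est)

    def test_all_zero_variance_errors(self):
        with pytest.raises(ValueError):
            cohens_d_westfall(1.0, [0.0, 0.0])
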