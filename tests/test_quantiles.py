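"""Type-8 quantile estimator, CDF/delta datasets and vincentization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stroopdelta as sd
from stroopdelta.quantiles import build_cdf_dataset, build_delta_dataset, vincentize


class TestHfQuantile8:
    @pytest.mark.parametrize(
        "sample, p, expected",
        [
            ([1, 2, 3, 4], 0.5, 2.5),
            ([5, 5, 5], 0.2, 5.0),
            ([5, 5, 5], 0.8, 5.0),
            ([10, 20, 30, 40, 50], 0.3, 19.333333333333332),
            ([10, 20, 30, 40, 50], 0.9, 50.0),  # h clamps to n
        ],
    )
    def test_worked_examples(self, sample, p, expected):
        assert sd.hf_quantile8(sample, p) == pytest.approx(expected, abs=1e-12)

    def test_matches_numpy_median_unbiased(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 60))
            x = rng.normal(500, 100, n)
            p = float(rng.uniform(0.01, 0.99))
            assert sd.hf_quantile8(x, p) == pytest.approx(
                np.quantile(x, p, method="median_unbiased"), abs=1e-9
            )

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            sd.hf_quantile8([], 0.5)

    def test_out_of_range_p_errors(self):
        with pytest.raises(ValueError):
            sd.hf_quantile8([1, 2], 1.0)

    @given(
        x=st.lists(st.floats(100, 1500), min_size=1, max_size=50),
        p1=st.floats(0.01, 0.99),
        p2=st.floats(0.01, 0.99),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_p_and_bounded(self, x, p1, p2):
        lo, hi = sorted((p1, p2))
        qlo, qhi = sd.hf_quantile8(x, lo), sd.hf_quantile8(x, hi)
        assert qlo <= qhi + 1e-12
        assert min(x) - 1e-9 <= qlo and qhi <= max(x) + 1e-9


def _toy_trials(pid="p1", n=30, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for cong, extra in (("congruent", 0.0), ("incongruent", 25.0)):
        rts = rng.normal(500 + shift + extra, 60, n)
        rows.append(
            pd.DataFrame(
                {
                    "study_id": "s1",
                    "participant_id": pid,
                    "target_type": "face",
                    "congruency": cong,
                    "rt_ms": rts,
                    "accuracy": True,
                    "responded": True,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestCdfDataset:
    def test_row_count_default_probs(self):
        cdf = build_cdf_dataset(_toy_trials())
        assert len(cdf) == 2 * 5  # congruencies x probs

    def test_quartile_style_grid(self):
        cdf = build_cdf_dataset(_toy_trials(), probs=(0.25, 0.5, 0.75))
        assert sorted(cdf["prob"].unique()) == [0.25, 0.5, 0.75]
        assert len(cdf) == 6

    def test_monotone_in_prob_per_cell(self, small_cohort):
        retained, _, _ = sd.preprocess(small_cohort)
        cdf = build_cdf_dataset(retained)
        for _, grp in cdf.groupby(
            ["study_id", "participant_id", "target_type", "congruency"], observed=True
        ):
            q = grp.sort_values("prob")["q_rt"].to_numpy()
            assert (np.diff(q) >= -1e-12).all()

    def test_small_cells_skipped_with_warning(self):
        t = _toy_trials(n=5)
        with pytest.warns(UserWarning, match="fewer than"):
            with pytest.raises(ValueError, match="minimum-trial"):
                build_cdf_dataset(t)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            build_cdf_dataset(_toy_trials().iloc[:0])

    def test_bad_probs_rejected(self):
        with pytest.raises(ValueError):
            build_cdf_dataset(_toy_trials(), probs=(0.5, 0.3))


class TestDeltaDataset:
    def _cdf(self, q_cong, q_inc):
        rows = []
        probs = np.linspace(0.25, 0.75, len(q_cong))
        for cong, qs in (("congruent", q_cong), ("incongruent", q_inc)):
            for p, q in zip(probs, qs):
                rows.append(("s1", "p1", "face", cong, p, q))
        return pd.DataFrame(
            rows,
            columns=[
                "study_id", "participant_id", "target_type", "congruency",
                "prob", "q_rt",
            ],
        )

    def test_delta_and_mean_rt_arithmetic(self):
        out = build_delta_dataset(self._cdf([400, 450, 500], [430, 470, 510]))
        assert list(out["delta"]) == [30, 20, 10]
        assert list(out["mean_rt"]) == [415, 460, 505]

    def test_identical_conditions_give_zero(self):
        out = build_delta_dataset(self._cdf([400, 500], [400, 500]))
        assert (out["delta"] == 0).all()

    def test_reversed_effect_sign_convention(self):
        out = build_delta_dataset(self._cdf([620], [590]))
        assert out["delta"].iloc[0] == -30  # faster incongruent => negative

    def test_reconstruction_identity_exact(self, small_cohort):
        retained, _, _ = sd.preprocess(small_cohort)
        cdf = build_cdf_dataset(retained)
        delta = build_delta_dataset(cdf)
        wide = cdf.pivot_table(
            index=["study_id", "participant_id", "target_type", "prob"],
            columns="congruency",
            values="q_rt",
            observed=True,
        ).dropna()
        merged = delta.merge(
            wide.reset_index(), on=["study_id", "participant_id", "target_type", "prob"]
        )
        np.testing.assert_array_equal(
            merged["congruent"].to_numpy() + merged["delta"].to_numpy(),
            merged["incongruent"].to_numpy(),
        )

    def test_missing_congruency_dropped_with_warning(self):
        cdf = self._cdf([400, 500], [430, 520])
        cdf = cdf[~((cdf.congruency == "incongruent") & (cdf.prob > 0.5))]
        with pytest.warns(UserWarning, match="lacking one congruency"):
            out = build_delta_dataset(cdf)
        assert len(out) == 1


class TestVincentize:
    def test_single_participant_identity(self):
        cdf = build_cdf_dataset(_toy_trials())
        v = vincentize(cdf, by=("target_type", "congruency"))
        merged = cdf.merge(v, on=["target_type", "congruency", "prob"], suffixes=("", "_v"))
        np.testing.assert_allclose(merged["q_rt"], merged["q_rt_v"])

    def test_two_participant_average(self):
        t = pd.concat(
            [_toy_trials(pid="p1", seed=1), _toy_trials(pid="p2", shift=100, seed=2)],
            ignore_index=True,
        )
        cdf = build_cdf_dataset(t)
        v = vincentize(cdf, by=("target_type", "congruency"))
        byhand = cdf.groupby(["target_type", "congruency", "prob"], observed=True)[
            "q_rt"
        ].mean()
        for _, row in v.iterrows():
            assert row["q_rt"] == pytest.approx(
                byhand.loc[(row["target_type"], row["congruency"], row["prob"])]
            )

    def test_brute_force_oracle_on_cohort(self, small_cohort):
        retained, _, _ = sd.preprocess(small_cohort)
        delta = build_delta_dataset(build_cdf_dataset(retained))
        v = vincentize(delta, by=("target_type",))
        oracle = delta.groupby(["target_type", "prob"], observed=True)["delta"].mean()
        for _, row in v.iterrows():
            assert row["delta"] == pytest.approx(
                oracle.loc[(row["target_type"], row["prob"])], abs=1e-12
            )
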