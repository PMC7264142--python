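"""AICc machinery, model averaging, mixed-model contract, repeatability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shoalsight.inference import (
    CandidateSet,
    FittedModel,
    ModelSpec,
    aicc,
    all_subsets,
    cooks_filter,
    fit_model,
    full_model_average,
    repeatability,
    spearman,
    standardize,
    weights_and_ri,
)


class TestStandardize:
    def test_basic_example(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, params = standardize(df, ["x"])
        np.testing.assert_allclose(out["x"], [-np.sqrt(1.5), 0, np.sqrt(1.5)])
        assert params["x"] == (2.0, pytest.approx(np.std([1, 2, 3.0])))

    def test_moments_after_scaling(self, rng):
        df = pd.DataFrame({"x": rng.normal(5, 3, 200)})
        out, _ = standardize(df, ["x"])
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, rng):
        df = pd.DataFrame({"x": rng.normal(5, 3, 50)})
        once, _ = standardize(df, ["x"])
        twice, _ = standardize(once, ["x"])
        np.testing.assert_allclose(once["x"], twice["x"], atol=1e-12)

    def test_zero_sd_named_in_error(self):
        with pytest.raises(ValueError, match="flat"):
            standardize(pd.DataFrame({"flat": [1.0, 1.0]}), ["flat"])


class TestAicc:
    def test_hand_evaluated_example(self):
        assert aicc(-100.0, 3, 100) == pytest.approx(206.25)

    def test_asymptotic_limit_is_aic(self):
        assert aicc(-50.0, 4, 10**9) == pytest.approx(-2 * -50.0 + 8, abs=1e-4)

    @given(st.floats(-1e4, 0), st.integers(1, 10), st.integers(13, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_correction_always_positive(self, ll, k, n):
        assert aicc(ll, k, n) > -2 * ll + 2 * k

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


def _stub(terms, ll, n=100):
    spec = ModelSpec(response="y", fixed=tuple(terms))
    params = pd.Series({"Intercept": 0.0, **{t: 1.0 for t in terms}})
    bse = pd.Series({"Intercept": 0.1, **{t: 0.1 for t in terms}})
    return FittedModel(spec, ll, len(terms) + 2, n, params, bse, True, True)


class TestWeightsAndRI:
    def test_equal_aicc_gives_equal_weights(self):
        cs = CandidateSet([_stub(["a"], -50.0), _stub(["b"], -50.0)])
        np.testing.assert_allclose(cs.weights, [0.5, 0.5])

    def test_term_in_every_model_has_ri_one(self):
        cs = CandidateSet([_stub(["a"], -50.0), _stub(["a", "b"], -49.0)])
        _, ri = weights_and_ri(cs)
        assert ri["a"] == pytest.approx(1.0)
        assert 0 < ri["b"] < 1

    def test_weights_match_bruteforce_on_eight_models(self):
        """Direct normalization of exp(-delta/2) for eight stated AICc values."""
        lls = [-52.0, -50.5, -51.0, -53.5, -50.0, -54.0, -55.0, -52.5]
        models = [_stub([f"x{i}"], ll) for i, ll in enumerate(lls)]
        cs = CandidateSet(models)
        a = np.array(sorted(aicc(ll, 3, 100) for ll in lls))
        brute = np.exp(-(a - a.min()) / 2)
        brute /= brute.sum()
        np.testing.assert_allclose(cs.weights, brute, rtol=1e-12)
        assert cs.weights.sum() == pytest.approx(1.0)


class TestFullAverage:
    def test_identical_beta_everywhere_is_unchanged(self):
        cs = CandidateSet([_stub(["a"], -50.0), _stub(["a", "b"], -50.0)])
        avg = full_model_average(cs)
        row = avg.estimates.set_index("term").loc["a"]
        assert row["estimate"] == pytest.approx(1.0)

    def test_zero_substitution_halves_partial_terms(self):
        """Term present in half the weight with beta = 2 averages to 1."""
        m1 = _stub(["a"], -50.0)
        m1.params["a"] = 2.0
        m2 = _stub(["c"], -50.0)  # same k -> same AICc -> equal weights
        avg = full_model_average(CandidateSet([m1, m2]))
        row = avg.estimates.set_index("term").loc["a"]
        assert row["estimate"] == pytest.approx(1.0)

    def test_shrinkage_towards_zero(self):
        """|full average| <= |conditional average| for partially present terms."""
        m1, m2 = _stub(["a"], -50.0), _stub([], -50.5)
        m1.params["a"] = 1.6
        cs = CandidateSet([m1, m2])
        avg = full_model_average(cs)
        full = abs(float(avg.estimates.set_index("term").loc["a", "estimate"]))
        w = cs.weights
        conditional = abs(1.6 * w[0] / w[0])
        assert full <= conditional

    def test_sign_recovery_on_sparse_regression(self, rng):
        """Nonzero coefficients keep their sign under full averaging."""
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(900 + rep)
            X = r.normal(size=(400, 4))
            y = 1.0 + 0.6 * X[:, 0] - 0.4 * X[:, 1] + r.normal(size=400)
            d = pd.DataFrame(X, columns=list("abcd"))
            d["y"] = y
            cs = all_subsets(ModelSpec(response="y", fixed=("a", "b", "c", "d")), d)
            est = full_model_average(cs).estimates.set_index("term")["estimate"]
            hits += (est["a"] > 0) and (est["b"] < 0)
        assert hits >= 19


class TestFitModel:
    def test_intercept_only_gaussian_returns_mean(self, rng):
        df = pd.DataFrame({"y": rng.normal(3.0, 1.0, 50)})
        fm = fit_model(ModelSpec(response="y"), df)
        assert fm.params["Intercept"] == pytest.approx(df["y"].mean())

    def test_binomial_intercept_on_balanced_data(self):
        df = pd.DataFrame({"y": [0, 1] * 40})
        fm = fit_model(ModelSpec(response="y", family="binomial"), df)
        assert fm.params["Intercept"] == pytest.approx(0.0, abs=1e-8)

    def test_lmm_fixed_effect_recovery_with_ci_coverage(self):
        """beta = 0.5 with fish-in-group intercepts recovered within its CI
        in nearly all replicates (12 groups x 8 fish x 20 obs)."""
        cover = 0
        n_rep = 30
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            rows = []
            for g in range(12):
                bg = rng.normal(0, 0.3)
                for f in range(8):
                    bf = rng.normal(0, 1.0)
                    x = rng.normal(size=20)
                    y = 0.5 * x + bg + bf + rng.normal(size=20)
                    for k in range(20):
                        rows.append({"g": f"g{g}", "f": f"g{g}f{f}", "x": x[k], "y": y[k]})
            df = pd.DataFrame(rows)
            fm = fit_model(
                ModelSpec(response="y", fixed=("x",),
                          random={"group": "g", "individual": "f"}),
                df,
            )
            b, se = float(fm.params["x"]), float(fm.bse["x"])
            cover += (b - 1.96 * se) <= 0.5 <= (b + 1.96 * se)
        assert cover >= int(0.87 * n_rep)

    def test_binomial_random_request_flagged_not_honoured(self):
        df = pd.DataFrame({"y": [0, 1] * 30, "g": ["a", "b"] * 30})
        fm = fit_model(ModelSpec(response="y", family="binomial",
                                 random={"group": "g"}), df)
        assert not fm.random_effects_honoured

    def test_log10_transform_applied(self, rng):
        df = pd.DataFrame({"y": 10 ** rng.normal(2, 0.1, 40)})
        fm = fit_model(ModelSpec(response="y", transform="log10"), df)
        assert fm.params["Intercept"] == pytest.approx(2.0, abs=0.1)


class TestCooksFilter:
    def test_homogeneous_data_nearly_untouched(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=300)})
        df["y"] = 2 * df["x"] + rng.normal(size=300)
        kept, removed = cooks_filter(ModelSpec(response="y", fixed=("x",)), df)
        assert len(removed) <= 6  # <= 2% incidental removals

    def test_gross_outlier_removed(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=100)})
        df["y"] = 2 * df["x"] + rng.normal(size=100)
        df.loc[50, ["x", "y"]] = [8.0, -40.0]
        kept, removed = cooks_filter(ModelSpec(response="y", fixed=("x",)), df)
        assert 50 in removed.index
        assert len(kept) + len(removed) == 100


class TestRepeatability:
    @staticmethod
    def _nested(rng, s_id, s_grp=0.05, s_res=0.6, n_groups=12, n_fish=8, n_obs=20):
        rows = []
        for g in range(n_groups):
            bg = rng.normal(0, np.sqrt(s_grp))
            for f in range(n_fish):
                bf = rng.normal(0, np.sqrt(s_id)) if s_id > 0 else 0.0
                for _ in range(n_obs):
                    rows.append({"g": f"g{g}", "f": f"g{g}f{f}",
                                 "y": bg + bf + rng.normal(0, np.sqrt(s_res))})
        return pd.DataFrame(rows)

    def test_zero_individual_variance_gives_near_zero_r(self, rng):
        df = self._nested(rng, s_id=0.0)
        res = repeatability(df, "y", individual="f", group="g", n_boot=0)
        assert res.R == pytest.approx(0.0, abs=0.03)
        assert res.p_lrt > 0.01

    def test_location_invariance(self, rng):
        df = self._nested(rng, s_id=0.4)
        r1 = repeatability(df, "y", individual="f", group="g", n_boot=0).R
        df2 = df.assign(y=df["y"] + 100.0)
        r2 = repeatability(df2, "y", individual="f", group="g", n_boot=0).R
        assert r2 == pytest.approx(r1, abs=1e-6)

    def test_ci_brackets_r_and_seeded(self, rng):
        df = self._nested(rng, s_id=0.4)
        a = repeatability(df, "y", individual="f", group="g", n_boot=15, seed=7)
        b = repeatability(df, "y", individual="f", group="g", n_boot=15, seed=7)
        assert a.ci == b.ci
        assert a.ci[0] <= a.R <= a.ci[1]


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -np.sqrt(x + 1))[0] == pytest.approx(-1.0)

    def test_matches_bruteforce_rank_formula(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 0.5])
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(10), np.arange(10.0))
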