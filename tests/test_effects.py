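import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from poolshift import effects as E
from poolshift.filters import build_panel

from conftest import factorial_counts

# printed 5x5 category cross-tabulation used as a fixture input
# (rows: first group None/Stage/Trt/Stage+Trt/Stage*Trt; columns: second group)
PUBLISHED_MATRIX = [
    [855, 131, 46, 40, 26],
    [60, 4, 9, 15, 19],
    [13, 4, 3, 3, 0],
    [4, 0, 0, 1, 2],
    [26, 6, 6, 6, 9],
]


def _design_20():
    stage = np.repeat([-1.0, -1.0, 1.0, 1.0], 5)
    trt = np.tile(np.repeat([-1.0, 1.0], 5), 2)
    return np.column_stack([np.ones(20), stage, trt, stage * trt])


def _fixture_counts(rng, n_loci=12, depth_lo=80, depth_hi=400):
    N = rng.integers(depth_lo, depth_hi, size=(n_loci, 20)).astype(float)
    p = rng.uniform(0.05, 0.6, size=(n_loci, 1))
    Y = rng.binomial(N.astype(int), p).astype(float)
    return Y, N


class TestIrls:
    def test_matches_statsmodels_full_model(self, rng):
        X = _design_20()
        Y, N = _fixture_counts(rng)
        beta, dev, conv = E.irls_binomial(Y, N, X)
        assert conv.all()
        for i in range(len(Y)):
            fit = sm.GLM(
                np.column_stack([Y[i], N[i] - Y[i]]), X, family=sm.families.Binomial()
            ).fit()
            assert np.allclose(beta[i], fit.params, atol=1e-7)
            assert dev[i] == pytest.approx(fit.deviance, abs=1e-7)

    def test_type3_lr_matches_statsmodels(self, rng):
        X = _design_20()
        Y, N = _fixture_counts(rng)
        _, dev_full, _ = E.irls_binomial(Y, N, X)
        for col in (1, 2, 3):
            Xr = np.delete(X, col, axis=1)
            _, dev_red, _ = E.irls_binomial(Y, N, Xr)
            for i in range(len(Y)):
                full = sm.GLM(
                    np.column_stack([Y[i], N[i] - Y[i]]), X, family=sm.families.Binomial()
                ).fit()
                red = sm.GLM(
                    np.column_stack([Y[i], N[i] - Y[i]]), Xr, family=sm.families.Binomial()
                ).fit()
                lr_oracle = red.deviance - full.deviance
                lr_ours = dev_red[i] - dev_full[i]
                assert lr_ours == pytest.approx(lr_oracle, abs=1e-6)

    def test_zero_weight_cells_ignored(self, rng):
        X = _design_20()
        Y, N = _fixture_counts(rng, n_loci=3)
        N[:, 0] = 0
        Y[:, 0] = 0
        beta, dev, conv = E.irls_binomial(Y, N, X)
        fit = sm.GLM(
            np.column_stack([Y[0, 1:], N[0, 1:] - Y[0, 1:]]),
            X[1:],
            family=sm.families.Binomial(),
        ).fit()
        assert np.allclose(beta[0], fit.params, atol=1e-7)


class TestFitGroup:
    def _panel(self, fn):
        return build_panel(factorial_counts({"L1": ("scaf1", 5, fn)}))

    def test_identical_cells_give_null_fit(self):
        panel = self._panel(lambda g, s, t, r: {"A": 30, "G": 10})
        res = E.fit_group_glms(panel, "MBP")
        row = res.iloc[0]
        assert abs(row["beta_stage"]) < 1e-6
        assert abs(row["beta_trt"]) < 1e-6
        assert abs(row["beta_int"]) < 1e-6
        for term in E.TERMS:
            assert row[f"p_{term}"] == pytest.approx(1.0, abs=1e-6)

    def test_strong_stage_effect_detected(self):
        def fn(g, s, t, r):
            return {"A": 180, "G": 20} if s == "day2" else {"A": 100, "G": 100}

        res = E.fit_group_glms(self._panel(fn), "MBP")
        assert res.iloc[0]["p_stage"] < 1e-10
        assert res.iloc[0]["p_int"] > 0.9

    def test_degenerate_locus_flagged(self):
        panel = self._panel(lambda g, s, t, r: {"A": 100})
        res = E.fit_group_glms(panel, "MBP")
        assert not res.iloc[0]["converged"]
        assert np.isnan(res.iloc[0]["p_stage"])

    def test_unknown_group_rejected(self, panel_small):
        with pytest.raises(ValueError):
            E.fit_group_glms(panel_small, "nope")

    def test_interaction_sign_recovered(self):
        def fn(g, s, t, r):
            # frequency rises only in the day22/high cell -> positive beta_int
            base = {"A": 150, "G": 50}
            if s == "day22" and t == "high":
                return {"A": 50, "G": 150}
            return base

        res = E.fit_group_glms(self._panel(fn), "MBP")
        assert res.iloc[0]["beta_int"] > 0
        assert res.iloc[0]["p_int"] < 1e-6


class TestBH:
    def test_qvalues_match_manual_stepup(self, rng):
        p = rng.uniform(size=40)
        q = E.bh_adjust(p)
        # independent BH implementation
        order = np.argsort(p)
        m = len(p)
        manual = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            manual[i] = running
        assert np.allclose(q, manual, atol=1e-12)

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(size=100)
        q = E.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_nan_excluded(self):
        q = E.bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_discovery_count_equals_stepup(self, rng):
        p = np.concatenate([rng.uniform(0, 1e-4, size=10), rng.uniform(size=90)])
        alpha = 0.05
        q = E.bh_adjust(p)
        ps = np.sort(p)
        crit = alpha * np.arange(1, 101) / 100
        passing = np.flatnonzero(ps <= crit)
        k = 0 if passing.size == 0 else passing.max() + 1
        assert int((q < alpha).sum()) == k


class TestClassification:
    def _results(self, p_stage, p_trt, p_int):
        n = len(p_stage)
        return pd.DataFrame(
            {
                "p_stage": p_stage,
                "p_trt": p_trt,
                "p_int": p_int,
                "beta_stage": np.zeros(n),
                "beta_trt": np.zeros(n),
                "beta_int": np.full(n, -0.5),
                "converged": [True] * n,
            },
            index=[f"L{i}" for i in range(n)],
        )

    def test_rules(self):
        ones = [1.0] * 7
        res = self._results(
            p_stage=[1e-9, 1.0, 1e-9, 1.0, 1e-9, 1.0, 1.0],
            p_trt=[1.0, 1e-9, 1e-9, 1.0, 1.0, 1e-9, 1.0],
            p_int=[1.0, 1.0, 1.0, 1e-9, 1e-9, 1e-9, 1.0],
        )
        out = E.classify_effects(res)
        assert list(out["category"]) == [
            "Stage",
            "Trt",
            "Stage+Trt",
            "Stage*Trt",
            "Stage*Trt",
            "Stage*Trt",
            "None",
        ]

    def test_all_insignificant_none(self):
        out = E.classify_effects(self._results([0.9] * 3, [0.8] * 3, [0.7] * 3))
        assert (out["category"] == "None").all()

    def test_interaction_sign_only_for_interactions(self):
        out = E.classify_effects(self._results([1.0, 1.0], [1.0, 1.0], [1e-9, 1.0]))
        assert list(out["interaction_sign"]) == ["-", "n/a"]

    def test_order_invariance(self, rng):
        res = self._results(
            rng.uniform(size=50).tolist(),
            rng.uniform(size=50).tolist(),
            rng.uniform(size=50).tolist(),
        )
        a = E.classify_effects(res)
        b = E.classify_effects(res.sample(frac=1, random_state=1))
        joined = a["category"].to_frame("a").join(b["category"].to_frame("b"))
        assert (joined["a"] == joined["b"]).all()

    def test_pooled_family_flag(self):
        res = self._results([0.01] * 4, [0.5] * 4, [0.5] * 4)
        per_term = E.classify_effects(res, family="per_term")
        pooled = E.classify_effects(res, family="pooled")
        # pooled family is larger, so q-values can only be >=
        assert (pooled["q_stage"] >= per_term["q_stage"] - 1e-12).all()

    def test_unconverged_excluded(self):
        res = self._results([0.001, 0.001], [1.0, 1.0], [1.0, 1.0])
        res.loc["L1", ["p_stage", "p_trt", "p_int"]] = np.nan
        res.loc["L1", "converged"] = False
        out = E.classify_effects(res)
        assert out.loc["L1", "category"] == "None"
        assert np.isnan(out.loc["L1", "q_stage"])


class TestCrosstab:
    def test_published_matrix_margins(self):
        ct = E.CategoryCrosstab.from_matrix(PUBLISHED_MATRIX, "MBP", "wild")
        assert ct.total == 1288
        assert ct.margins("MBP").tolist() == [1098, 107, 23, 7, 53]
        assert ct.margins("wild").tolist() == [958, 145, 64, 65, 56]

    def test_from_effects_diagonal(self):
        idx = [f"L{i}" for i in range(5)]
        cats = pd.Categorical(
            ["None", "Stage", "Trt", "Stage+Trt", "Stage*Trt"],
            categories=list(E.CATEGORY_LEVELS),
        )
        eff = pd.DataFrame({"category": cats}, index=idx)
        ct = E.CategoryCrosstab.from_effects(eff, eff, "MBP", "wild")
        assert np.trace(ct.matrix.to_numpy()) == 5
        assert ct.total == 5

    def test_all_none_single_cell(self):
        idx = [f"L{i}" for i in range(10)]
        cats = pd.Categorical(["None"] * 10, categories=list(E.CATEGORY_LEVELS))
        eff = pd.DataFrame({"category": cats}, index=idx)
        ct = E.CategoryCrosstab.from_effects(eff, eff, "MBP", "wild")
        assert ct.matrix.loc["None", "None"] == 10
        assert ct.total == 10

    def test_chi_square_against_scipy(self):
        from scipy.stats import chi2_contingency

        ct = E.CategoryCrosstab.from_matrix(PUBLISHED_MATRIX, "MBP", "wild")
        res = ct.chi_square()
        table = np.array([[190, 1098], [330, 958]])
        stat, p, dof, _ = chi2_contingency(table, correction=False)
        assert res["statistic"] == pytest.approx(stat)
        assert res["df"] == 1

    def test_chi_square_full_collapsing(self):
        ct = E.CategoryCrosstab.from_matrix(PUBLISHED_MATRIX, "MBP", "wild")
        res = ct.chi_square(collapsing="full")
        assert res["df"] == 4


class TestInteractionSign:
    def _eff(self, betas, cats):
        return pd.DataFrame(
            {
                "beta_int": betas,
                "category": pd.Categorical(cats, categories=list(E.CATEGORY_LEVELS)),
            }
        )

    def test_all_negative(self):
        eff = self._eff([-1.0, -0.2], ["Stage*Trt", "Stage*Trt"])
        assert E.interaction_sign_summary(eff) == 1.0

    def test_no_interaction_loci_nan(self):
        eff = self._eff([-1.0], ["Stage"])
        assert np.isnan(E.interaction_sign_summary(eff))

    def test_known_mixture_recovered(self):
        # 70/30 negative/positive
        betas = [-1.0] * 7 + [1.0] * 3
        eff = self._eff(betas, ["Stage*Trt"] * 10)
        assert E.interaction_sign_summary(eff) == pytest.approx(0.7)
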