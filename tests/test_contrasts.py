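import numpy as np
import pandas as pd
import pytest
from scipy import stats

from platefit import contrasts as cst
from platefit.exceptions import DesignError, InferenceError, ReportError


def make_obs(values, conditions, blocks, strain="S", metric="od_max"):
    rows = [(v, c, b, i + 1) for i, (v, c, b) in
            enumerate(zip(values, conditions, blocks))]
    return cst.MetricObservations.from_rows(strain, metric, rows)


def balanced_obs(rng=None, k=3, b=3, n=3, effects=None, noise=0.1):
    """k conditions x b blocks x n replicates, Gaussian noise."""
    rng = rng or np.random.default_rng(0)
    conds = [f"c{i}" for i in range(k)]
    effects = effects or {c: 0.0 for c in conds}
    vals, cc, bb = [], [], []
    for c in conds:
        for j in range(b):
            for _ in range(n):
                vals.append(1.0 + effects[c] + 0.2 * j + rng.normal(0, noise))
                cc.append(c)
                bb.append(f"E{j}")
    return make_obs(vals, cc, bb)


class TestBlockedAnova:
    def test_constant_data_gives_zero_variance(self):
        obs = balanced_obs(noise=0.0, effects=None)
        obs.data["value"] = 5.0
        fit = cst.fit_blocked_anova(obs)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)
        mm = cst.marginal_means(fit)
        np.testing.assert_allclose(mm["mean"], 5.0, rtol=1e-12)

    def test_residual_df_is_n_minus_k_minus_b_plus_1(self):
        fit = cst.fit_blocked_anova(balanced_obs(k=3, b=3, n=3))
        assert fit.df_resid == 27 - 3 - 3 + 1

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        obs = balanced_obs(rng, effects={"c0": 0.0, "c1": 0.3, "c2": -0.2})
        fit = cst.fit_blocked_anova(obs)
        # independent solve on an explicitly built dummy design
        df = obs.data
        X = pd.get_dummies(df[["condition", "block"]], drop_first=True, dtype=float)
        X.insert(0, "intercept", 1.0)
        Xm = X.to_numpy()
        beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ df["value"].to_numpy())
        np.testing.assert_allclose(fit.params, beta, atol=1e-10)
        resid = df["value"].to_numpy() - Xm @ beta
        sigma2 = resid @ resid / (len(df) - Xm.shape[1])
        assert fit.sigma2 == pytest.approx(sigma2, rel=1e-10)

    def test_singular_design_raises(self):
        # one condition per block: condition and block are confounded
        obs = make_obs([1.0, 1.1, 2.0, 2.1], ["a", "a", "b", "b"],
                       ["E1", "E1", "E2", "E2"])
        with pytest.raises(DesignError):
            cst.fit_blocked_anova(obs)


class TestMarginalMeans:
    def test_balanced_equals_raw_condition_means(self):
        rng = np.random.default_rng(3)
        obs = balanced_obs(rng, effects={"c0": 0.0, "c1": 0.5, "c2": 0.1})
        fit = cst.fit_blocked_anova(obs)
        mm = cst.marginal_means(fit).set_index("condition")["mean"]
        raw = obs.data.groupby("condition")["value"].mean()
        for c in raw.index:
            assert mm[c] == pytest.approx(raw[c], rel=1e-12)

    def test_all_equal_data_gives_grand_mean(self):
        obs = balanced_obs(noise=0.0)
        obs.data["value"] = 2.5
        mm = cst.marginal_means(cst.fit_blocked_anova(obs))
        np.testing.assert_allclose(mm["mean"], 2.5, rtol=1e-12)

    def test_unbalanced_matches_explicit_prediction(self):
        rng = np.random.default_rng(11)
        obs = balanced_obs(rng, effects={"c0": 0.0, "c1": 0.4, "c2": 0.0})
        # drop condition c2 from block E2 entirely
        df = obs.data[~((obs.data["condition"] == "c2")
                        & (obs.data["block"] == "E2"))].reset_index(drop=True)
        obs2 = cst.MetricObservations(strain="S", metric="od_max", data=df)
        fit = cst.fit_blocked_anova(obs2)
        mm = cst.marginal_means(fit).set_index("condition")["mean"]
        raw = df.groupby("condition")["value"].mean()
        # marginal mean for c2 differs from the raw mean...
        assert abs(mm["c2"] - raw["c2"]) > 1e-6
        # ...and matches an explicit design-matrix prediction averaged over blocks
        X = pd.get_dummies(df[["condition", "block"]], drop_first=True, dtype=float)
        X.insert(0, "intercept", 1.0)
        Xm = X.to_numpy()
        beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ df["value"].to_numpy())
        # prediction rows for c2 in each block, averaged
        rows = []
        for blk in sorted(df["block"].unique()):
            row = {"intercept": 1.0}
            for col in X.columns[1:]:
                row[col] = 1.0 if col in (f"condition_c2", f"block_{blk}") else 0.0
            rows.append([row.get(c, 0.0) for c in X.columns])
        pred = (np.asarray(rows) @ beta).mean()
        assert mm["c2"] == pytest.approx(pred, rel=1e-10)

    def test_invariant_to_factor_coding(self):
        rng = np.random.default_rng(5)
        obs = balanced_obs(rng, effects={"c0": 0.0, "c1": 0.2, "c2": -0.1})
        df = obs.data[~((obs.data["condition"] == "c1")
                        & (obs.data["block"] == "E0"))].reset_index(drop=True)
        obs = cst.MetricObservations(strain="S", metric="od_max", data=df)
        mm_ref = cst.marginal_means(cst.fit_blocked_anova(obs, coding="reference"))
        mm_sum = cst.marginal_means(cst.fit_blocked_anova(obs, coding="sum"))
        np.testing.assert_allclose(mm_ref["mean"], mm_sum["mean"], atol=1e-10)
        np.testing.assert_allclose(mm_ref["se"], mm_sum["se"], atol=1e-10)


class TestTukey:
    def test_k2_equals_unadjusted_t_interval(self):
        rng = np.random.default_rng(9)
        obs = balanced_obs(rng, k=2, effects={"c0": 0.0, "c1": 0.3})
        fit = cst.fit_blocked_anova(obs)
        (res,) = cst.tukey_pairwise(fit, alpha=0.05)
        tcrit = stats.t.ppf(0.975, fit.df_resid)
        half_t = tcrit * res.se
        assert (res.ci_high - res.ci_low) / 2 == pytest.approx(half_t, abs=1e-8)
        # p-value reduces to the ordinary two-sided t test
        p_t = 2 * stats.t.sf(abs(res.estimate / res.se), fit.df_resid)
        assert res.p_adj == pytest.approx(p_t, abs=1e-8)

    def test_all_pairs_returned(self):
        fit = cst.fit_blocked_anova(balanced_obs(k=4))
        assert len(cst.tukey_pairwise(fit)) == 6

    def test_null_data_nothing_significant(self):
        rng = np.random.default_rng(21)
        fit = cst.fit_blocked_anova(balanced_obs(rng))
        results = cst.tukey_pairwise(fit)
        # equal population means: estimates near 0, CIs symmetric-ish about 0
        assert all(r.ci_low < 0 < r.ci_high for r in results)
        assert not any(r.significant for r in results)

    def test_ci_p_duality(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            effects = {"c0": 0.0, "c1": rng.normal(0, 0.2), "c2": rng.normal(0, 0.2)}
            fit = cst.fit_blocked_anova(balanced_obs(rng, effects=effects))
            for r in cst.tukey_pairwise(fit):
                excludes_zero = r.ci_low > 0 or r.ci_high < 0
                assert excludes_zero == r.significant == (r.p_adj < r.alpha)

    def test_contrasts_invariant_to_coding(self):
        rng = np.random.default_rng(13)
        obs = balanced_obs(rng, effects={"c0": 0.0, "c1": 0.25, "c2": -0.15})
        by_pair = {}
        for coding in ("reference", "sum"):
            fit = cst.fit_blocked_anova(obs, coding=coding)
            for r in cst.tukey_pairwise(fit):
                by_pair.setdefault(r.pair, []).append(r)
        for pair, (a, b) in by_pair.items():
            assert a.estimate == pytest.approx(b.estimate, abs=1e-10)
            assert a.ci_low == pytest.approx(b.ci_low, abs=1e-10)
            assert a.p_adj == pytest.approx(b.p_adj, abs=1e-8)

    def test_label_permutation_consistency(self):
        rng = np.random.default_rng(17)
        obs = balanced_obs(rng, effects={"c0": 0.0, "c1": 0.3, "c2": -0.2})
        fit = cst.fit_blocked_anova(obs)
        base = {r.pair: r for r in cst.tukey_pairwise(fit)}
        relabel = {"c0": "z0", "c1": "a1", "c2": "m2"}
        df2 = obs.data.assign(condition=obs.data["condition"].map(relabel))
        obs2 = cst.MetricObservations(strain="S", metric="od_max", data=df2)
        renamed = {r.pair: r for r in cst.tukey_pairwise(cst.fit_blocked_anova(obs2))}
        inverse = {v: k for k, v in relabel.items()}
        for pair, r in renamed.items():
            orig_pair = (inverse[pair[0]], inverse[pair[1]])
            if orig_pair in base:
                o = base[orig_pair]
            else:
                o = base[(orig_pair[1], orig_pair[0])].reversed()
            assert r.estimate == pytest.approx(o.estimate, abs=1e-10)
            assert r.p_adj == pytest.approx(o.p_adj, abs=1e-8)

    def test_df_below_one_raises(self):
        obs = make_obs([1.0, 2.0, 1.5, 2.5], ["a", "b", "a", "b"],
                       ["E1", "E1", "E2", "E2"])
        fit = cst.fit_blocked_anova(obs)
        assert fit.df_resid == 1  # boundary: allowed
        obs_small = make_obs([1.0, 2.0, 1.1, 2.1], ["a", "b", "b", "a"],
                             ["E1", "E1", "E2", "E2"])
        fit2 = cst.fit_blocked_anova(obs_small)
        assert fit2.df_resid == 1
        df = obs.data.iloc[:3]
        obs3 = cst.MetricObservations(strain="S", metric="od_max", data=df)
        with pytest.raises(InferenceError):
            cst.tukey_pairwise(cst.fit_blocked_anova(obs3))


class TestDeltaTables:
    @staticmethod
    def _contrasts():
        rng = np.random.default_rng(31)
        vals, cc, bb = [], [], []
        truth = {"control": 0.3, "inulin": 0.9, "XOS": 0.7}
        for c, mu in truth.items():
            for j in range(3):
                for _ in range(3):
                    vals.append(mu + 0.05 * j + rng.normal(0, 0.02))
                    cc.append(c)
                    bb.append(f"E{j}")
        obs = make_obs(vals, cc, bb)
        return cst.tukey_pairwise(cst.fit_blocked_anova(obs))

    def test_orientation_and_signs(self):
        tables = cst.delta_tables(self._contrasts(), "control", "inulin", "XOS")
        assert tables.delta_ix.pair == ("inulin", "XOS")
        assert tables.delta_ix.estimate > 0  # inulin above XOS by construction
        for lab, r in tables.delta_c.items():
            assert r.pair == (lab, "control")
            assert r.estimate > 0

    def test_reorientation_negates_estimate_and_swaps_bounds(self):
        results = self._contrasts()
        r = results[0]
        f = r.reversed()
        assert f.estimate == -r.estimate
        assert f.ci_low == -r.ci_high and f.ci_high == -r.ci_low
        assert f.p_adj == r.p_adj and f.significant == r.significant

    def test_identical_populations_give_null_delta_ix(self):
        rng = np.random.default_rng(8)
        vals, cc, bb = [], [], []
        for c in ("control", "inulin", "XOS"):
            mu = 0.8 if c != "control" else 0.3
            for j in range(3):
                for _ in range(3):
                    vals.append(mu + rng.normal(0, 0.05))
                    cc.append(c)
                    bb.append(f"E{j}")
        tables = cst.delta_tables(
            cst.tukey_pairwise(cst.fit_blocked_anova(make_obs(vals, cc, bb))),
            "control", "inulin", "XOS",
        )
        assert abs(tables.delta_ix.estimate) < 0.1
        assert not tables.delta_ix.significant

    def test_missing_label_raises(self):
        with pytest.raises(ReportError):
            cst.delta_tables(self._contrasts(), "control", "inulin", "fructan")

    def test_glucose_comparisons_included_when_present(self):
        rng = np.random.default_rng(19)
        vals, cc, bb = [], [], []
        for c, mu in {"control": 0.3, "inulin": 0.9, "XOS": 0.7, "glucose": 0.8}.items():
            for j in range(3):
                for _ in range(3):
                    vals.append(mu + rng.normal(0, 0.02))
                    cc.append(c)
                    bb.append(f"E{j}")
        pairs = cst.tukey_pairwise(cst.fit_blocked_anova(make_obs(vals, cc, bb)))
        tables = cst.delta_tables(pairs, "control", "inulin", "XOS",
                                  glucose_label="glucose")
        assert set(tables.delta_glucose) == {"control", "inulin", "XOS"}
        assert all(r.pair[1] == "glucose" for r in tables.delta_glucose.values())


class TestDiagnostics:
    def test_gaussian_residuals_pass_shapiro(self):
        rng = np.random.default_rng(4)
        fit = cst.fit_blocked_anova(balanced_obs(rng, noise=0.1))
        d = cst.residual_diagnostics(fit)
        assert d["shapiro_p"] > 0.05
        assert "degenerate-residuals" not in d["flags"]

    def test_heavy_tailed_residuals_fail_shapiro(self):
        rng = np.random.default_rng(6)
        rejected = 0
        for trial in range(10):
            vals, cc, bb = [], [], []
            for c in ("c0", "c1", "c2"):
                for j in range(3):
                    for _ in range(3):
                        vals.append(1.0 + 0.1 * rng.standard_t(2))
                        cc.append(c)
                        bb.append(f"E{j}")
            fit = cst.fit_blocked_anova(make_obs(vals, cc, bb))
            if cst.residual_diagnostics(fit)["shapiro_p"] < 0.05:
                rejected += 1
        assert rejected >= 5  # heavy tails detected in most replicates

    def test_constant_residuals_flagged_not_crashing(self):
        obs = balanced_obs(noise=0.0)
        obs.data["value"] = 1.0
        d = cst.residual_diagnostics(cst.fit_blocked_anova(obs))
        assert "degenerate-residuals" in d["flags"]


class TestPreAverage:
    def test_collapses_to_one_row_per_cell(self):
        obs = balanced_obs()
        avg = cst.pre_average_blocks(obs)
        assert len(avg.data) == 9
        cell = obs.data[(obs.data["condition"] == "c0") & (obs.data["block"] == "E0")]
        got = avg.data[(avg.data["condition"] == "c0") & (avg.data["block"] == "E0")]
        assert got["value"].iloc[0] == pytest.approx(cell["value"].mean())
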