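"""Wealth index, conditional logistic regression and meta-analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from housemap.assoc import (
    binarize_covariates,
    build_wealth_index,
    conditional_logit,
    forest_data,
    meta_analysis,
    survey_associations,
)
from housemap.synth import ASSET_NAMES


def _asset_frame(n=400, seed=0):
    rng = np.random.default_rng(seed)
    data = {a: rng.integers(0, 2, n) for a in ASSET_NAMES}
    return pd.DataFrame(data)


class TestWealthIndex:
    def test_high_frequency_asset_excluded(self):
        hh = _asset_frame()
        hh["radio"] = 1
        hh.loc[hh.index[:5], "radio"] = 0  # 98.75% ownership
        widx = build_wealth_index(hh)
        assert "radio" not in widx.assets

    def test_high_missingness_excluded(self):
        hh = _asset_frame()
        hh.loc[hh.index[:80], "car"] = np.nan  # 20% missing
        widx = build_wealth_index(hh)
        assert "car" not in widx.assets

    def test_too_few_assets_rejected(self):
        hh = _asset_frame()[["car", "bicycle"]].copy()
        hh["car"] = 1
        with pytest.raises(ValueError):
            build_wealth_index(hh, asset_list=("car", "bicycle"))

    def test_perfectly_correlated_pair_is_rank_one(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 300)
        hh = pd.DataFrame({"car": a, "bicycle": a})
        widx = build_wealth_index(hh, asset_list=("car", "bicycle"))
        assert widx.explained_variance_ratio == pytest.approx(1.0)

    def test_binary_marks_top_quartile(self):
        widx = build_wealth_index(_asset_frame(seed=2))
        rate = widx.binary.mean()
        assert 0.15 <= rate <= 0.30  # ties can move it off exactly 25%

    def test_electrification_anchors_sign(self):
        widx = build_wealth_index(_asset_frame(seed=3))
        if "electrification" in widx.assets:
            assert widx.loadings[widx.assets.index("electrification")] > 0


class TestBinarize:
    def test_level_names(self):
        hh = pd.DataFrame({
            "education": ["secondary", "primary", "none", "higher"],
            "head_age": [30, 55, 56, 70],
        })
        out, n_exc = binarize_covariates(hh)
        assert n_exc == 0
        assert out["education_bin"].tolist() == [1, 0, 0, 1]
        # age 55 is not "over 55"; 56 is
        assert out["age_over_55"].tolist() == [0, 0, 1, 1]

    def test_missing_excluded_with_tally(self):
        hh = pd.DataFrame({
            "education": [1, np.nan, 0, 1],
            "head_age": [40, 50, np.nan, 60],
        })
        out, n_exc = binarize_covariates(hh)
        assert n_exc == 2 and len(out) == 2

    def test_all_missing_rejected(self):
        hh = pd.DataFrame({"education": [np.nan, np.nan], "head_age": [40, 50]})
        with pytest.raises(ValueError):
            binarize_covariates(hh)

    def test_implausible_age_rejected(self):
        hh = pd.DataFrame({"education": [1], "head_age": [150]})
        with pytest.raises(ValueError):
            binarize_covariates(hh)


def _paired_data(n_case_exposed=10, n_control_exposed=5):
    rows, cid = [], 0
    for _ in range(n_case_exposed):
        rows += [(cid, 1, 1), (cid, 0, 0)]
        cid += 1
    for _ in range(n_control_exposed):
        rows += [(cid, 1, 0), (cid, 0, 1)]
        cid += 1
    df = pd.DataFrame(rows, columns=["cluster", "improved", "exposure"])
    df["survey"] = "S"
    return df


def _enumerated_conditional_loglik(df, beta):
    """Brute-force conditional log-likelihood over within-cluster case sets."""
    ll = 0.0
    for _, grp in df.groupby("cluster"):
        x = grp["exposure"].to_numpy(float)
        y = grp["improved"].to_numpy(int)
        k = y.sum()
        num = np.exp(beta * (x * y).sum())
        den = sum(
            np.exp(beta * x[list(s)].sum())
            for s in itertools.combinations(range(len(x)), k)
        )
        ll += np.log(num / den)
    return ll


class TestConditionalLogit:
    def test_paired_closed_form(self):
        """10 vs 5 discordant pairs: conditional MLE OR is exactly their ratio."""
        res = conditional_logit(_paired_data(), exposures=("exposure",))
        assert np.exp(res.log_or[0]) == pytest.approx(2.0, abs=1e-4)

    def test_matches_enumeration_oracle(self):
        """Estimate maximises the brute-force conditional likelihood on
        strata of size <= 6."""
        rng = np.random.default_rng(0)
        rows = []
        for cid in range(30):
            size = rng.integers(2, 7)
            x = rng.integers(0, 2, size)
            p = 1 / (1 + np.exp(-(rng.normal() + 0.8 * x)))
            y = (rng.random(size) < p).astype(int)
            for xi, yi in zip(x, y):
                rows.append((cid, yi, xi))
        df = pd.DataFrame(rows, columns=["cluster", "improved", "exposure"])
        df["survey"] = "S"
        res = conditional_logit(df, exposures=("exposure",))
        bhat = res.log_or[0]
        ll_hat = _enumerated_conditional_loglik(df, bhat)
        for delta in (-0.05, 0.05):
            assert ll_hat >= _enumerated_conditional_loglik(df, bhat + delta)
        # and the gradient is ~0: parabola vertex within 1e-3
        grid = np.linspace(bhat - 0.01, bhat + 0.01, 11)
        lls = [_enumerated_conditional_loglik(df, b) for b in grid]
        assert abs(grid[int(np.argmax(lls))] - bhat) <= 2e-3

    def test_null_exposure_ci_covers_one(self):
        rng = np.random.default_rng(1)
        rows = []
        for cid in range(80):
            x = rng.integers(0, 2, 15)
            y = (rng.random(15) < 0.4).astype(int)
            rows += [(cid, yi, xi) for xi, yi in zip(x, y)]
        df = pd.DataFrame(rows, columns=["cluster", "improved", "exposure"])
        df["survey"] = "S"
        res = conditional_logit(df, exposures=("exposure",))
        assert res.ci_lower[0] <= 0.0 <= res.ci_upper[0]

    def test_no_informative_strata_rejected(self):
        df = pd.DataFrame({
            "cluster": [0, 0, 1, 1], "improved": [1, 1, 0, 0],
            "exposure": [0, 1, 0, 1], "survey": "S",
        })
        with pytest.raises(ValueError):
            conditional_logit(df, exposures=("exposure",))


class TestMetaAnalysis:
    def test_homogeneous_two_study_case(self):
        pooled = meta_analysis(np.log([2.0, 2.0]), np.array([0.2, 0.2]))
        assert pooled.tau2 == pytest.approx(0.0, abs=1e-12)
        o, lo, hi = pooled.odds_ratio()
        assert o == pytest.approx(2.0)

    def test_weights_sum_to_one(self):
        pooled = meta_analysis(np.array([0.1, 0.5, 0.9]),
                               np.array([0.1, 0.2, 0.3]))
        assert pooled.weights.sum() == pytest.approx(1.0)

    def test_three_study_hand_computation(self):
        eff = np.array([0.2, 0.5, 0.8])
        se = np.array([0.2, 0.3, 0.4])
        var = se**2
        w = 1 / var
        ybar = np.sum(w * eff) / np.sum(w)
        Q = np.sum(w * (eff - ybar) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - 2) / c)
        wr = 1 / (var + tau2)
        hand_pooled = np.sum(wr * eff) / np.sum(wr)
        hand_se = np.sqrt(1 / np.sum(wr))
        pooled = meta_analysis(eff, se)
        assert pooled.tau2 == pytest.approx(tau2, abs=1e-10)
        assert pooled.log_or == pytest.approx(hand_pooled, abs=1e-10)
        assert pooled.se == pytest.approx(hand_se, abs=1e-10)
        assert pooled.q_statistic == pytest.approx(Q, abs=1e-10)

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            meta_analysis(np.array([0.5]), np.array([0.1]))


class TestForest:
    def _results(self):
        hh1 = _paired_data(12, 5)
        hh2 = _paired_data(9, 6)
        hh2["cluster"] += 100
        hh1["survey"], hh2["survey"] = "A", "B"
        both = pd.concat([hh1, hh2])
        return survey_associations(both, exposures=("exposure",))

    def test_row_count_and_ordering(self):
        results, pooled = self._results()
        table = forest_data(results, pooled["exposure"], "exposure")
        assert len(table) == len(results) + 1
        assert (table["lower"] <= table["or"]).all()
        assert (table["or"] <= table["upper"]).all()

    def test_or_exponentiates_log_or(self):
        results, pooled = self._results()
        table = forest_data(results, pooled["exposure"], "exposure")
        for r in results:
            row = table[table["label"] == r.survey].iloc[0]
            assert row["or"] == pytest.approx(float(np.exp(r.log_or[0])))


class TestPlots:
    def test_forest_plot_renders(self, tmp_path):
        import matplotlib.pyplot as plt
        from housemap.plots import forest_plot
        results, pooled = TestForest()._results()
        table = forest_data(results, pooled["exposure"], "exposure")
        ax = forest_plot(table, title="exposure")
        ax.figure.savefig(tmp_path / "forest.png")
        plt.close("all")
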