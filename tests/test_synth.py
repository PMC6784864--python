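"""Synthetic-data generator: determinism, distributional and round-trip checks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from housemap.classify import classify_households
from housemap.featuremap import apply_feature_map
from housemap.synth import (
    ASSET_NAMES,
    SyntheticSpec,
    conditional_bernoulli,
    gen_covariate_grid,
    gen_cluster_survey,
    gen_household_attributes,
    gen_true_surface,
    simulate_survey,
)
from conftest import COVARIATES


class TestSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(nx=0)
        with pytest.raises(ValueError):
            SyntheticSpec(phi_true=1.0)
        with pytest.raises(ValueError):
            SyntheticSpec(years=())


class TestCovariateGrid:
    def test_seeded_determinism(self, small_spec):
        a = gen_covariate_grid(small_spec)
        b = gen_covariate_grid(small_spec)
        for name in a.data.data_vars:
            assert np.array_equal(a.layer(name), b.layer(name))

    def test_layer_counts(self, small_spec):
        grid = gen_covariate_grid(small_spec)
        assert len(grid.covariate_names) == small_spec.n_covariates
        assert set(grid.data.data_vars) >= {"population", "urban", "country"}
        assert len(grid.data.data_vars) == small_spec.n_covariates + 3

    def test_covariates_standardized(self, small_spec):
        grid = gen_covariate_grid(small_spec)
        for name in grid.covariate_names:
            layer = grid.layer(name)
            assert abs(layer.mean()) < 1e-6
            assert abs(layer.var() - 1.0) < 1e-6

    def test_auxiliary_layers(self, small_spec):
        grid = gen_covariate_grid(small_spec)
        assert np.all(grid.layer("population") > 0)
        assert set(np.unique(grid.layer("urban"))) <= {0.0, 1.0}
        countries = np.unique(grid.layer("country"))
        assert len(countries) == small_spec.n_countries


class TestTrueSurface:
    def test_bounded(self, small_world):
        values = small_world["surface"].values
        assert values.min() >= 0.0 and values.max() <= 1.0

    def test_zero_weights_give_half(self, small_spec):
        grid = gen_covariate_grid(small_spec)
        surface = gen_true_surface(grid, small_spec)
        surface.beta = np.zeros_like(surface.beta)
        surface.intercept = 0.0
        mu = expit(surface.linear_predictor(np.zeros((1, 9))))
        assert mu[0] == pytest.approx(0.5)

    def test_probed_cell_matches_direct_formula(self, small_spec, small_world):
        """Surface value equals a hand evaluation of logistic(b0 + a*beta.z)."""
        surf = small_world["surface"]
        grid = small_world["grid"]
        row, col = 3, 11
        year = small_spec.years[0]
        cov = np.array([grid.layer(n)[row, col] for n in grid.covariate_names])
        x = np.concatenate([cov, [grid.data.x.values[col]],
                            [grid.data.y.values[row]], [year]])
        xs = (x - surf.x_mean) / surf.x_sd
        z = apply_feature_map(xs, surf.spectral)
        a = np.sqrt(surf.spectral.sigma2 / surf.spectral.n_features)
        by_hand = expit(surf.intercept + a * float(z @ surf.beta))
        assert surf.values[0, row, col] == pytest.approx(by_hand, abs=1e-12)

    def test_covariate_count_mismatch(self, small_spec):
        grid = gen_covariate_grid(small_spec)
        bad = SyntheticSpec(**{**small_spec.__dict__, "n_covariates": 4})
        with pytest.raises(ValueError):
            gen_true_surface(grid, bad)


class TestClusterSurvey:
    def test_round_trip_classification(self, small_world):
        """Classifying generated attribute codes reproduces every stored flag."""
        hh = small_world["households"]
        classified, n_excluded = classify_households(hh)
        assert n_excluded == 0
        assert (classified["improved"].to_numpy() == hh["improved"].to_numpy()).all()

    def test_counts_match_flags(self, small_world):
        cl, hh = small_world["clusters"], small_world["households"]
        per_cluster = hh.groupby("cluster")["improved"].sum()
        assert (cl.set_index("cluster")["y_plus"] == per_cluster).all()

    def test_zero_clusters_rejected(self, small_spec):
        with pytest.raises(ValueError):
            SyntheticSpec(**{**small_spec.__dict__, "n_clusters": 0})

    def test_binomial_limit_of_cluster_variance(self):
        """With phi ~ 0 the improved-count variance approaches n*p*(1-p)."""
        spec = SyntheticSpec(nx=10, ny=10, n_clusters=40,
                             households_per_cluster=60, years=(2010,),
                             phi_true=0.0, seed=11)
        grid = gen_covariate_grid(spec)
        surface = gen_true_surface(grid, spec)
        # flatten the surface so every cluster shares one p: variance is then
        # comparable across clusters
        surface.values = np.full_like(surface.values, 0.3)
        clusters, _ = gen_cluster_survey(surface, spec)
        y = clusters["y_plus"].to_numpy()
        n = spec.households_per_cluster
        expected_var = n * 0.3 * 0.7
        assert np.var(y) == pytest.approx(expected_var, rel=0.5)

    def test_overdispersion_visible_at_large_phi(self):
        spec = SyntheticSpec(nx=10, ny=10, n_clusters=40,
                             households_per_cluster=60, years=(2010,),
                             phi_true=0.3, seed=11)
        grid = gen_covariate_grid(spec)
        surface = gen_true_surface(grid, spec)
        surface.values = np.full_like(surface.values, 0.3)
        clusters, _ = gen_cluster_survey(surface, spec)
        y = clusters["y_plus"].to_numpy()
        n = spec.households_per_cluster
        binom_var = n * 0.3 * 0.7
        # beta-binomial variance = n p q (1 + (n-1) phi): ~18x binomial here
        assert np.var(y) > 3 * binom_var

    def test_cluster_prevalences_track_surface(self, small_world):
        cl = small_world["clusters"]
        obs = cl["y_plus"] / cl["y_total"]
        assert obs.mean() == pytest.approx(cl["true_prevalence"].mean(), abs=0.05)


class TestConditionalBernoulli:
    def test_matches_enumeration(self):
        """Empirical subset frequencies match the product-weight law."""
        w = np.array([0.5, 1.0, 2.0, 1.5, 0.8])
        k = 2
        subsets = list(itertools.combinations(range(5), k))
        probs = np.array([np.prod(w[list(s)]) for s in subsets])
        probs /= probs.sum()
        rng = np.random.default_rng(0)
        counts = {s: 0 for s in subsets}
        n_draws = 20000
        for _ in range(n_draws):
            sel = conditional_bernoulli(w, k, rng)
            counts[tuple(np.flatnonzero(sel))] += 1
        emp = np.array([counts[s] / n_draws for s in subsets])
        assert np.max(np.abs(emp - probs)) < 0.01

    def test_fixed_size(self):
        rng = np.random.default_rng(1)
        for k in range(6):
            assert conditional_bernoulli(np.ones(5) * 2.0, k, rng).sum() == k

    def test_out_of_range_k(self):
        with pytest.raises(ValueError):
            conditional_bernoulli(np.ones(3), 4, np.random.default_rng(0))


class TestHouseholdAttributes:
    def test_asset_matrix_has_twelve_columns(self, small_world):
        hh = small_world["households"]
        assert all(a in hh.columns for a in ASSET_NAMES)
        assert len(ASSET_NAMES) == 12

    def test_cluster_totals_preserved(self, small_spec, small_world):
        """Reassigning labels within cluster keeps every cluster's count."""
        cl, hh = small_world["clusters"], small_world["households"]
        per_cluster = hh.groupby("cluster")["improved"].sum()
        assert (cl.set_index("cluster")["y_plus"] == per_cluster).all()

    def test_null_odds_ratios_give_independence(self):
        spec = SyntheticSpec(nx=10, ny=10, n_clusters=80,
                             households_per_cluster=40, years=(2010,),
                             log_or_education=0.0, log_or_wealth=0.0,
                             log_or_age=0.0, seed=3)
        world = simulate_survey(spec)
        hh = world["households"]
        from scipy.stats import chi2_contingency
        tab = pd.crosstab(hh["education"], hh["improved"])
        _, p, _, _ = chi2_contingency(tab)
        assert p > 0.001

    def test_missing_flag_rejected(self, small_spec):
        with pytest.raises(ValueError):
            gen_household_attributes(pd.DataFrame({"cluster": [0]}), small_spec)

    def test_seeded_determinism(self, small_spec):
        a = simulate_survey(small_spec)["households"]
        b = simulate_survey(small_spec)["households"]
        pd.testing.assert_frame_equal(a, b)
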