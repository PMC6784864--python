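"""Synthetic survey worlds with known ground truth.

Generates, from a single root seed, the full input stack the analysis
expects: smooth covariate rasters plus population / urban-mask / country-id
grids on the unit square, a true prevalence surface produced by the same
random-Fourier-feature model family the estimator fits, clustered two-stage
survey samples with beta-binomial overdispersion at cluster level, raw
household attribute codes consistent with the housing classifier, and
household socioeconomic covariates with configurable true within-cluster
odds ratios.  Every downstream stage is therefore testable by recovery.

Randomness is split deterministically from the root seed with
``numpy.random.SeedSequence.spawn``: child 0 drives the covariate grid,
child 1 the true surface, child 2 the cluster survey and child 3 the
household attributes, so regenerating any stage with the same spec is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .classify import load_jmp_lookup, load_material_lookup
from .featuremap import SpectralMeasure, apply_feature_map
from .raster import RasterStack

__all__ = [
    "SyntheticSpec",
    "TrueSurface",
    "gen_covariate_grid",
    "gen_true_surface",
    "gen_cluster_survey",
    "gen_household_attributes",
    "simulate_survey",
    "ASSET_NAMES",
]

#: the twelve durable-asset indicators used for the wealth index
ASSET_NAMES = (
    "car", "motorboat", "scooter", "cart", "bicycle", "television",
    "refrigerator", "radio", "watch", "mobile_telephone",
    "landline_telephone", "electrification",
)

COVARIATE_NAMES = (
    "aridity", "urbanicity", "accessibility", "friction", "nightlights",
    "irrigation",
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic world.

    Defaults emulate the study conditions: six spatial covariates (mirroring
    aridity, urbanicity, accessibility, travel friction, night-time lights
    and irrigation), surveys across the 2000-2015 window, 300 clusters of 50
    households (a desk-scale national survey), cluster-level overdispersion
    phi of 0.1 (a typical intra-cluster correlation for household outcomes),
    and true within-cluster odds ratios 1.80 / 2.53 / 1.31 for education,
    wealth and household-head age.
    """

    nx: int = 40
    ny: int = 40
    n_covariates: int = 6
    n_countries: int = 4
    n_true_frequencies: int = 20
    sigma2_true: float = 1.0
    base_prevalence: float = 0.25     # grand-mean improved-housing prevalence
    signal_sd: float = 1.2            # sd of true beta weights
    phi_true: float = 0.1
    n_clusters: int = 300
    households_per_cluster: int = 50
    years: tuple = (2000, 2005, 2010, 2015)
    log_or_education: float = float(np.log(1.80))
    log_or_wealth: float = float(np.log(2.53))
    log_or_age: float = float(np.log(1.31))
    prev_education: float = 0.40      # marginal P(more than primary)
    prev_wealth: float = 0.25         # top wealth quartile
    prev_age: float = 0.25            # head aged over 55
    # per-criterion propensity that an unimproved household violates each
    # of water / sanitation / crowding / materials (equal by default)
    deprivation_propensities: tuple = (0.5, 0.5, 0.5, 0.5)
    seed: int = 0

    def __post_init__(self):
        for name in ("nx", "ny", "n_covariates", "n_countries",
                     "n_true_frequencies", "n_clusters", "households_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.phi_true < 1.0:
            raise ValueError("phi_true must lie in [0, 1)")
        if len(self.years) == 0:
            raise ValueError("years must be non-empty")

    def streams(self, n: int = 4) -> list[np.random.Generator]:
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


# ---------------------------------------------------------------------------
# rasters


def _smooth_field(rng: np.random.Generator, xx: np.ndarray, yy: np.ndarray,
                  max_order: int = 3) -> np.ndarray:
    """Smooth random field from a fixed low-order trigonometric basis."""
    f = np.zeros_like(xx)
    for j in range(max_order + 1):
        for k in range(max_order + 1):
            amp = 1.0 / (1.0 + j + k)
            a, b, c, d = rng.standard_normal(4) * amp
            f += (a * np.cos(np.pi * j * xx) * np.cos(np.pi * k * yy)
                  + b * np.sin(np.pi * (j + 1) * xx) * np.cos(np.pi * k * yy)
                  + c * np.cos(np.pi * j * xx) * np.sin(np.pi * (k + 1) * yy)
                  + d * np.sin(np.pi * (j + 1) * xx) * np.sin(np.pi * (k + 1) * yy))
    return f


def gen_covariate_grid(spec: SyntheticSpec) -> RasterStack:
    """Covariate rasters plus population, urban-mask and country-id layers.

    Covariate layers are standardised cell-wise to mean 0 / variance 1;
    population is strictly positive with smooth spatial structure; the urban
    mask flags the densest quintile of cells; country ids partition the grid
    into vertical strips.
    """
    rng = spec.streams()[0]
    x = (np.arange(spec.nx) + 0.5) / spec.nx
    y = (np.arange(spec.ny) + 0.5) / spec.ny
    xx, yy = np.meshgrid(x, y)
    layers: dict[str, np.ndarray] = {}
    for i in range(spec.n_covariates):
        name = COVARIATE_NAMES[i] if i < len(COVARIATE_NAMES) else f"cov{i}"
        f = _smooth_field(rng, xx, yy)
        layers[name] = (f - f.mean()) / f.std()
    pop_field = _smooth_field(rng, xx, yy)
    pop = np.exp(1.5 * (pop_field - pop_field.mean()) / pop_field.std()) * 1000.0
    layers["population"] = pop
    layers["urban"] = (pop >= np.quantile(pop, 0.8)).astype(float)
    layers["country"] = np.floor(xx * spec.n_countries).clip(0, spec.n_countries - 1)
    return RasterStack.from_arrays(layers, x=x, y=y)


# ---------------------------------------------------------------------------
# true surface


@dataclass
class TrueSurface:
    """Known prevalence surface: logistic of a true feature-map predictor."""

    grid: RasterStack
    years: tuple
    values: np.ndarray                 # (n_years, ny, nx) in [0, 1]
    spectral: SpectralMeasure          # frozen generating measure
    beta: np.ndarray
    intercept: float
    x_mean: np.ndarray
    x_sd: np.ndarray

    def at(self, cell_rows: np.ndarray, cell_cols: np.ndarray, year) -> np.ndarray:
        yi = list(self.years).index(year)
        return self.values[yi, cell_rows, cell_cols]

    def linear_predictor(self, exog_raw: np.ndarray) -> np.ndarray:
        Xs = (np.atleast_2d(exog_raw) - self.x_mean) / self.x_sd
        Z = apply_feature_map(Xs, self.spectral)
        a = np.sqrt(self.spectral.sigma2 / self.spectral.n_features)
        return self.intercept + a * (Z @ self.beta)


def gen_true_surface(grid: RasterStack, spec: SyntheticSpec) -> TrueSurface:
    """Prevalence = logistic(true feature-map predictor) per cell and year."""
    if len(grid.covariate_names) != spec.n_covariates:
        raise ValueError(
            f"grid has {len(grid.covariate_names)} covariates, spec declares "
            f"{spec.n_covariates}"
        )
    rng = spec.streams()[1]
    cov = grid.covariate_matrix()
    xs, ys = grid.cell_coords()
    years = np.asarray(spec.years, dtype=float)
    blocks = [
        np.column_stack([cov, xs, ys, np.full(xs.shape, yr)]) for yr in years
    ]
    Xall = np.vstack(blocks)
    x_mean = Xall.mean(axis=0)
    sd = Xall.std(axis=0)
    x_sd = np.where(sd > 0, sd, 1.0)
    d = Xall.shape[1]
    M = spec.n_true_frequencies
    sm = SpectralMeasure(
        omega=rng.standard_normal((M, d)),
        theta=np.ones(d),
        sigma2=spec.sigma2_true,
    )
    beta = rng.standard_normal(2 * M) * spec.signal_sd
    intercept = float(logit(spec.base_prevalence))
    surf = TrueSurface(
        grid=grid, years=tuple(spec.years), values=np.empty(0),
        spectral=sm, beta=beta, intercept=intercept,
        x_mean=x_mean, x_sd=x_sd,
    )
    mu = expit(surf.linear_predictor(Xall))
    surf.values = mu.reshape(len(years), *grid.shape)
    return surf


# ---------------------------------------------------------------------------
# clustered survey


def _code_pools(material_lookup, jmp_lookup):
    pools = {"water": {"improved": [], "unimproved": []},
             "sanitation": {"improved": [], "unimproved": []}}
    for (domain, code), cat in jmp_lookup.items():
        pools[domain][cat].append(code)
    mats = {comp: {"finished": [], "unfinished": []} for comp in ("roof", "wall", "floor")}
    for (comp, code), cls in material_lookup.items():
        mats[comp]["finished" if cls == "finished" else "unfinished"].append(code)
    for d in (*pools.values(), *mats.values()):
        for v in d.values():
            v.sort()
    return pools, mats


def _draw_household_codes(rng, improved: bool, violations, pools, mats):
    """Raw attribute codes consistent with the intended improved flag.

    ``violations`` is a 4-bool array (water, sanitation, crowded, materials);
    all False for an improved household.
    """
    water_ok, san_ok, crowd_bad, mat_bad = violations
    rec = {}
    rec["water"] = rng.choice(pools["water"]["unimproved" if water_ok else "improved"])
    rec["sanitation"] = rng.choice(pools["sanitation"]["unimproved" if san_ok else "improved"])
    bedrooms = 1 + rng.poisson(1.0)
    if crowd_bad:
        members = 3 * bedrooms + 1 + rng.poisson(2.0)
    else:
        members = 1 + rng.integers(0, 3 * bedrooms)
    rec["bedrooms"], rec["members"] = int(bedrooms), int(members)
    n_finished = int(rng.integers(0, 2)) if mat_bad else int(rng.integers(2, 4))
    comps = ["roof", "wall", "floor"]
    finished_comps = rng.choice(3, size=n_finished, replace=False)
    for ci, comp in enumerate(comps):
        kind = "finished" if ci in finished_comps else "unfinished"
        rec[comp] = rng.choice(mats[comp][kind])
    return rec


def gen_cluster_survey(surface: TrueSurface, spec: SyntheticSpec):
    """Clustered two-stage sample from the true surface.

    Clusters are placed at grid cells with probability proportional to
    population (emulating PPS selection from a census frame) and assigned a
    survey year; the cluster's improved-count is beta-binomial around the
    surface value with dispersion ``phi_true``; household attribute codes
    are generated so the housing classifier reproduces each intended flag.

    Returns ``(clusters, households)`` data frames.
    """
    if spec.n_clusters < 1:
        raise ValueError("empty survey: n_clusters must be >= 1")
    rng = spec.streams()[2]
    grid = surface.grid
    ny, nx = grid.shape
    pop = grid.layer("population").ravel()
    p_sel = pop / pop.sum()
    cells = rng.choice(ny * nx, size=spec.n_clusters, replace=False, p=p_sel)
    rows, cols = np.divmod(cells, nx)
    years = np.asarray(spec.years)
    cl_year = years[rng.integers(0, len(years), size=spec.n_clusters)]
    material_lookup = load_material_lookup()
    jmp_lookup = load_jmp_lookup()
    pools, mats = _code_pools(material_lookup, jmp_lookup)
    props = np.asarray(spec.deprivation_propensities, dtype=float)

    xcoord = grid.data.x.values[cols]
    ycoord = grid.data.y.values[rows]
    country = grid.layer("country")[rows, cols].astype(int)
    cov = grid.covariate_matrix()[cells]
    h = spec.households_per_cluster

    cl_records, hh_records = [], []
    for c in range(spec.n_clusters):
        mu = float(surface.at(rows[c], cols[c], cl_year[c]))
        if spec.phi_true > 0:
            a = mu * (1 - spec.phi_true) / spec.phi_true
            b = (1 - mu) * (1 - spec.phi_true) / spec.phi_true
            p_c = rng.beta(a, b)
        else:
            p_c = mu
        improved = rng.random(h) < p_c
        for i in range(h):
            if improved[i]:
                viol = np.zeros(4, dtype=bool)
            else:
                viol = rng.random(4) < props
                if not viol.any():
                    viol[rng.choice(4, p=props / props.sum())] = True
            rec = _draw_household_codes(rng, improved[i], viol, pools, mats)
            rec.update(cluster=c, year=int(cl_year[c]),
                       survey=f"SVY{cl_year[c]}", improved=bool(improved[i]))
            hh_records.append(rec)
        cl_records.append({
            "cluster": c, "x": float(xcoord[c]), "y": float(ycoord[c]),
            "year": int(cl_year[c]), "survey": f"SVY{cl_year[c]}",
            "country": int(country[c]), "cell_row": int(rows[c]),
            "cell_col": int(cols[c]),
            **{name: float(cov[c, j]) for j, name in enumerate(grid.covariate_names)},
            "true_prevalence": mu, "realized_prevalence": float(p_c),
            "y_plus": int(improved.sum()), "y_total": h,
        })
    clusters = pd.DataFrame(cl_records)
    households = pd.DataFrame(hh_records)
    col_order = ["cluster", "year", "survey", "water", "sanitation",
                 "members", "bedrooms", "roof", "wall", "floor", "improved"]
    return clusters, households[col_order]


# ---------------------------------------------------------------------------
# household socioeconomic attributes


def conditional_bernoulli(weights: np.ndarray, k: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Sample a size-k subset with probability proportional to the product
    of the selected items' weights (the conditional Bernoulli model).

    Exact sequential sampling via elementary symmetric polynomials.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if not 0 <= k <= n:
        raise ValueError("k out of range")
    w = w / np.exp(np.mean(np.log(w)))  # geometric-mean normalisation
    E = np.zeros((n + 1, k + 1))
    E[n, 0] = 1.0
    for i in range(n - 1, -1, -1):
        E[i, 0] = 1.0
        jmax = min(k, n - i)
        for j in range(1, jmax + 1):
            E[i, j] = E[i + 1, j] + w[i] * E[i + 1, j - 1]
    sel = np.zeros(n, dtype=bool)
    remaining = k
    for i in range(n):
        if remaining == 0:
            break
        if n - i == remaining:
            sel[i:] = True
            break
        p = w[i] * E[i + 1, remaining - 1] / E[i, remaining]
        if rng.random() < p:
            sel[i] = True
            remaining -= 1
    return sel


def gen_household_attributes(households: pd.DataFrame,
                             spec: SyntheticSpec) -> pd.DataFrame:
    """Attach education/wealth/age binaries and 12 asset indicators.

    The three binaries are drawn iid at their marginal prevalences; within
    each cluster the improved labels are then reassigned by exact
    conditional-Bernoulli sampling with weights exp(sum of true log-odds
    ratios), holding the cluster's improved count fixed.  This makes the
    within-cluster conditional logistic model with the spec's log-ORs hold
    exactly, so association estimates are consistent for the true values.
    Attribute code columns are permuted with the labels so the housing
    classifier still reproduces every flag.  Asset indicators are generated
    from a latent wealth score so their first principal component aligns
    with the wealth binary (electrification loading positively).
    """
    if "improved" not in households.columns:
        raise ValueError("household table lacks the improved flag")
    if "cluster" not in households.columns:
        raise ValueError("household table lacks cluster ids")
    rng = spec.streams()[3]
    hh = households.reset_index(drop=True).copy()
    n = len(hh)
    edu = rng.random(n) < spec.prev_education
    wealth = rng.random(n) < spec.prev_wealth
    age = rng.random(n) < spec.prev_age
    gammas = np.array([spec.log_or_education, spec.log_or_wealth, spec.log_or_age])
    scores = np.column_stack([edu, wealth, age]).astype(float) @ gammas
    weights = np.exp(scores)

    code_cols = [c for c in ("water", "sanitation", "members", "bedrooms",
                             "roof", "wall", "floor") if c in hh.columns]
    new_improved = np.zeros(n, dtype=bool)
    for _, idx in hh.groupby("cluster").groups.items():
        idx = np.asarray(idx)
        k = int(hh.loc[idx, "improved"].sum())
        sel = conditional_bernoulli(weights[idx], k, rng)
        new_improved[idx] = sel
        # re-align raw codes: improved-coded rows go to newly-improved slots
        old_order = np.concatenate([
            idx[hh.loc[idx, "improved"].to_numpy(bool)],
            idx[~hh.loc[idx, "improved"].to_numpy(bool)],
        ])
        new_order = np.concatenate([idx[sel], idx[~sel]])
        hh.loc[new_order, code_cols] = hh.loc[old_order, code_cols].to_numpy()
    hh["improved"] = new_improved
    hh["education"] = edu.astype(int)
    hh["wealth"] = wealth.astype(int)
    hh["age_over_55"] = age.astype(int)
    hh["head_age"] = np.where(age, 56 + rng.integers(0, 30, n), 18 + rng.integers(0, 38, n))

    latent = wealth.astype(float) + 0.5 * rng.standard_normal(n)
    loadings = 0.8 + 1.2 * rng.random(len(ASSET_NAMES))
    loadings[ASSET_NAMES.index("electrification")] = 2.0
    intercepts = rng.uniform(-1.5, 0.5, len(ASSET_NAMES)) - loadings * spec.prev_wealth
    for j, name in enumerate(ASSET_NAMES):
        p = expit(intercepts[j] + loadings[j] * latent)
        hh[name] = (rng.random(n) < p).astype(int)
    return hh


def simulate_survey(spec: SyntheticSpec) -> dict:
    """Run the full generator: grid, surface, clusters and households."""
    grid = gen_covariate_grid(spec)
    surface = gen_true_surface(grid, spec)
    clusters, households = gen_cluster_survey(surface, spec)
    households = gen_household_attributes(households, spec)
    return {"grid": grid, "surface": surface, "clusters": clusters,
            "households": households}
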