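"""Household-level socioeconomic association analysis.

Per survey: an asset-based wealth index (linear PCA on filtered durable
assets, excluding house-construction variables), binary education / wealth /
household-head-age covariates, and within-cluster conditional logistic
regression of the improved-housing flag on the three binaries.  Survey
log-odds-ratios are pooled with DerSimonian-Laird random-effects
meta-analysis and laid out as forest-plot tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.discrete.conditional_models import ConditionalLogit
from statsmodels.stats.meta_analysis import combine_effects

from .synth import ASSET_NAMES

__all__ = [
    "WealthIndex",
    "SurveyAssociation",
    "PooledAssociation",
    "build_wealth_index",
    "binarize_covariates",
    "conditional_logit",
    "meta_analysis",
    "forest_data",
    "survey_associations",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile
SEPARATION_THRESHOLD = 15.0  # |log-OR| beyond this flags separation


@dataclass
class WealthIndex:
    """First-principal-component wealth score over filtered asset indicators."""

    assets: list[str]
    loadings: np.ndarray
    scores: np.ndarray
    binary: np.ndarray           # score strictly above the 75th percentile
    explained_variance_ratio: float


def build_wealth_index(
    households: pd.DataFrame,
    asset_list: tuple = ASSET_NAMES,
    standardize: bool = False,
) -> WealthIndex:
    """Asset-based wealth index excluding house-construction variables.

    Assets must pass both inclusion filters: fewer than 10% missing values
    and ownership frequency strictly between 5% and 95%.  The retained
    binaries are centred (optionally standardised) and projected on their
    first principal component, oriented so electrification (or, failing
    that, the dominant asset) loads positively; the binary indicator marks
    scores strictly above the 75th percentile.
    """
    cols = []
    for a in asset_list:
        if a not in households.columns:
            continue
        col = households[a]
        if col.isna().mean() >= 0.10:
            continue
        freq = col.dropna().mean()
        if not (0.05 < freq < 0.95):
            continue
        cols.append(a)
    if len(cols) < 2:
        raise ValueError(
            f"only {len(cols)} assets survive the inclusion filters; "
            "wealth index undefined"
        )
    X = households[cols].to_numpy(dtype=float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    if standardize:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=1)
    scores = pca.fit_transform(X - X.mean(axis=0)).ravel()
    loadings = pca.components_[0]
    anchor = cols.index("electrification") if "electrification" in cols else int(np.argmax(np.abs(loadings)))
    if loadings[anchor] < 0:
        loadings, scores = -loadings, -scores
    cutoff = np.percentile(scores, 75)
    return WealthIndex(
        assets=cols,
        loadings=loadings,
        scores=scores,
        binary=(scores > cutoff).astype(int),
        explained_variance_ratio=float(pca.explained_variance_ratio_[0]),
    )


EDUCATION_ABOVE_PRIMARY = {"secondary", "higher", "more than primary"}
EDUCATION_PRIMARY_OR_LESS = {"none", "no education", "primary", "primary or less"}


def binarize_covariates(
    households: pd.DataFrame,
    education_col: str = "education",
    age_col: str = "head_age",
) -> tuple[pd.DataFrame, int]:
    """Binary education (> primary) and age (head over 55) covariates.

    Education may already be 0/1 or a level name; household-head age is in
    years.  Households with missing values in either field are excluded
    fail-closed and tallied: returns (table, n_excluded).
    """
    for col in (education_col, age_col):
        if households[col].isna().all():
            raise ValueError(f"column {col!r} is entirely missing")
    out = households.copy()
    edu_raw = out[education_col]
    if edu_raw.dtype == object:
        known = EDUCATION_ABOVE_PRIMARY | EDUCATION_PRIMARY_OR_LESS
        bad = set(edu_raw.dropna().unique()) - known
        if bad:
            raise ValueError(f"unknown education levels: {sorted(bad)}")
        edu = edu_raw.map(lambda v: np.nan if pd.isna(v) else int(v in EDUCATION_ABOVE_PRIMARY))
    else:
        edu = edu_raw.astype(float)
    age = out[age_col].astype(float)
    if ((age < 0) | (age > 120)).any():
        raise ValueError("implausible household-head ages (outside 0-120)")
    out["education_bin"] = edu
    out["age_over_55"] = np.where(age.isna(), np.nan, (age > 55).astype(float))
    keep = out["education_bin"].notna() & out["age_over_55"].notna()
    n_excluded = int((~keep).sum())
    out = out[keep].copy()
    out["education_bin"] = out["education_bin"].astype(int)
    out["age_over_55"] = out["age_over_55"].astype(int)
    return out, n_excluded


@dataclass
class SurveyAssociation:
    """Adjusted within-cluster log-odds-ratios for one survey."""

    survey: str
    exposures: list[str]
    log_or: np.ndarray
    se: np.ndarray
    n_clusters: int
    n_informative: int
    separated: bool = False

    @property
    def ci_lower(self) -> np.ndarray:
        return self.log_or - Z95 * self.se

    @property
    def ci_upper(self) -> np.ndarray:
        return self.log_or + Z95 * self.se

    def odds_ratios(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure": self.exposures,
            "or": np.exp(self.log_or),
            "or_lower": np.exp(self.ci_lower),
            "or_upper": np.exp(self.ci_upper),
        })


def conditional_logit(
    households: pd.DataFrame,
    outcome: str = "improved",
    exposures: tuple = ("education_bin", "wealth_bin", "age_over_55"),
    cluster_col: str = "cluster",
    survey: str = "survey",
) -> SurveyAssociation:
    """Within-cluster conditional logistic regression for one survey.

    Maximises the conditional likelihood over within-cluster outcome
    permutations, eliminating cluster-level confounding.  Clusters without
    outcome variation carry no information and are dropped (counted in
    ``n_informative``).  Estimates beyond |log-OR| = 15 are flagged as
    separated so pooling can exclude them.
    """
    y = households[outcome].astype(int).to_numpy()
    X = households[list(exposures)].astype(float).to_numpy()
    groups = households[cluster_col].to_numpy()
    grp = pd.Series(y).groupby(groups)
    informative = grp.nunique() > 1
    n_informative = int(informative.sum())
    if n_informative == 0:
        raise ValueError("no informative clusters (no within-cluster outcome variation)")
    import warnings
    with warnings.catch_warnings():
        # non-informative groups are dropped by design; we tally them
        warnings.filterwarnings("ignore", message="Dropped .* groups")
        model = ConditionalLogit(y, X, groups=groups)
        res = model.fit(disp=False, method="newton", tol=1e-10)
    log_or = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    separated = bool(np.any(np.abs(log_or) > SEPARATION_THRESHOLD) or not np.all(np.isfinite(se)))
    name = households[survey].iloc[0] if survey in households.columns else ""
    return SurveyAssociation(
        survey=str(name), exposures=list(exposures), log_or=log_or, se=se,
        n_clusters=int(len(informative)), n_informative=n_informative,
        separated=separated,
    )


@dataclass
class PooledAssociation:
    """DerSimonian-Laird random-effects pooled log-odds-ratio."""

    exposure: str
    log_or: float
    se: float
    tau2: float
    weights: np.ndarray          # normalised per-survey RE weights
    surveys: list[str]
    q_statistic: float

    @property
    def ci_lower(self) -> float:
        return self.log_or - Z95 * self.se

    @property
    def ci_upper(self) -> float:
        return self.log_or + Z95 * self.se

    def odds_ratio(self) -> tuple[float, float, float]:
        return (float(np.exp(self.log_or)), float(np.exp(self.ci_lower)),
                float(np.exp(self.ci_upper)))


def meta_analysis(
    log_ors: np.ndarray,
    ses: np.ndarray,
    surveys: list[str] | None = None,
    exposure: str = "",
) -> PooledAssociation:
    """DerSimonian-Laird random-effects pooling of per-survey log-ORs.

    tau^2 comes from the Q statistic (floored at zero); weights are
    1 / (SE_i^2 + tau^2), normalised.  With tau^2 = 0 this reduces to
    fixed-effect inverse-variance pooling.
    """
    eff = np.asarray(log_ors, dtype=float)
    var = np.asarray(ses, dtype=float) ** 2
    if eff.shape[0] < 2:
        raise ValueError("need at least 2 surveys with finite estimates to pool")
    if not (np.all(np.isfinite(eff)) and np.all(np.isfinite(var))):
        raise ValueError("non-finite estimates passed to pooling")
    import warnings
    with warnings.catch_warnings():
        # statsmodels computes auxiliary HKSJ variances that can go negative
        # when the raw moment estimate of tau^2 is negative; we use only the
        # DL tau^2, floored below
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        res = combine_effects(eff, var, method_re="dl")
    tau2 = max(0.0, float(res.tau2))  # moment estimate floored at zero
    w = 1.0 / (var + tau2)
    pooled = float(np.sum(w * eff) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    w_fe = 1.0 / var
    q = float(np.sum(w_fe * (eff - np.sum(w_fe * eff) / np.sum(w_fe)) ** 2))
    return PooledAssociation(
        exposure=exposure, log_or=pooled, se=se, tau2=tau2,
        weights=w / w.sum(),
        surveys=list(surveys) if surveys is not None else [str(i) for i in range(len(eff))],
        q_statistic=q,
    )


def survey_associations(
    households: pd.DataFrame,
    survey_col: str = "survey",
    **kwargs,
) -> tuple[list[SurveyAssociation], dict[str, PooledAssociation]]:
    """Conditional-logit per survey, then pooled per exposure.

    Surveys flagged for separation are excluded from pooling.
    """
    results = [
        conditional_logit(grp, survey=survey_col, **kwargs)
        for _, grp in households.groupby(survey_col)
    ]
    usable = [r for r in results if not r.separated]
    pooled = {}
    if len(usable) >= 2:
        for j, exp_name in enumerate(usable[0].exposures):
            pooled[exp_name] = meta_analysis(
                np.array([r.log_or[j] for r in usable]),
                np.array([r.se[j] for r in usable]),
                surveys=[r.survey for r in usable],
                exposure=exp_name,
            )
    return results, pooled


def forest_data(
    results: list[SurveyAssociation],
    pooled: PooledAssociation,
    exposure: str,
) -> pd.DataFrame:
    """Plot-ready forest table: one row per survey plus the pooled diamond.

    Odds ratios exponentiate the stored log-ORs; the null line sits at
    OR = 1.
    """
    j = results[0].exposures.index(exposure) if results else 0
    wmap = dict(zip(pooled.surveys, pooled.weights))
    rows = [
        {
            "label": r.survey, "kind": "survey",
            "or": float(np.exp(r.log_or[j])),
            "lower": float(np.exp(r.ci_lower[j])),
            "upper": float(np.exp(r.ci_upper[j])),
            "weight": float(wmap.get(r.survey, np.nan)),
        }
        for r in results
    ]
    o, lo, hi = pooled.odds_ratio()
    rows.append({"label": "Pooled", "kind": "pooled", "or": o, "lower": lo,
                 "upper": hi, "weight": 1.0})
    return pd.DataFrame(rows)
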