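"""Out-of-sample validation and probabilistic scoring.

Two cross-validation designs mirror the model-performance checks used for
survey-based prevalence mapping: repeated 75/25 random splits averaged over
ten repeats, and leave-one-administrative-unit-out holdouts that respect
spatial blocks (random splits are optimistic under spatial autocorrelation).
Point accuracy is scored by mean squared error and Pearson correlation at
both the observation (cluster) level and the aggregate survey level;
ensemble forecasts are scored by the continuous ranked probability score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FitConfig, HousingPrevalenceModel

__all__ = ["ValidationReport", "random_split_cv", "admin_holdout_cv", "crps"]


def crps(ensemble_values, observation: float) -> float:
    """Empirical continuous ranked probability score of an ensemble forecast.

    CRPS = mean|X - y| - 0.5 * mean|X - X'| with the double mean taken over
    all ordered member pairs.  Non-negative, and for a single member it
    degenerates to the absolute error |m - y|.
    """
    X = np.asarray(ensemble_values, dtype=float).ravel()
    if X.size == 0:
        raise ValueError("empty ensemble")
    term1 = np.mean(np.abs(X - float(observation)))
    term2 = 0.5 * np.mean(np.abs(X[:, None] - X[None, :]))
    return float(term1 - term2)


@dataclass
class ValidationReport:
    """Cross-validation scores.

    ``per_rep`` has one row per repeat (or per held-out unit) with MSE and
    Pearson correlation at observation and survey level; ``summary`` holds
    the averages.  ``crps_mean`` is filled when an ensemble was scored.
    """

    per_rep: pd.DataFrame
    summary: dict
    scheme: str
    crps_mean: float | None = None

    def to_csv(self, path: str) -> None:
        self.per_rep.to_csv(path, index=False)


def _metrics(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    mse = float(np.mean((obs - pred) ** 2))
    if np.std(obs) == 0 or np.std(pred) == 0:
        corr = 1.0 if mse == 0 else 0.0
    else:
        corr = float(np.corrcoef(obs, pred)[0, 1])
    return mse, corr


def _score_split(test: pd.DataFrame, pred: np.ndarray) -> dict:
    obs = (test["y_plus"] / test["y_total"]).to_numpy()
    mse, corr = _metrics(obs, pred)
    out = {"mse": mse, "corr": corr}
    if "survey" in test.columns and test["survey"].nunique() > 1:
        df = pd.DataFrame({"survey": test["survey"].values, "obs": obs, "pred": pred})
        agg = df.groupby("survey").mean()
        out["survey_mse"], out["survey_corr"] = _metrics(
            agg["obs"].to_numpy(), agg["pred"].to_numpy()
        )
    else:
        out["survey_mse"] = out["survey_corr"] = np.nan
    return out


def _default_fit_fn(covariates, config: FitConfig):
    def fit_fn(train: pd.DataFrame):
        model = HousingPrevalenceModel.from_clusters(train, covariates)
        res = model.fit(config=config)

        def predict_fn(test: pd.DataFrame) -> np.ndarray:
            cols = model.exog_names
            return res.predict(test[cols].to_numpy(dtype=float))

        return predict_fn

    return fit_fn


def random_split_cv(
    clusters: pd.DataFrame,
    covariates: list[str] | None = None,
    config: FitConfig | None = None,
    train_frac: float = 0.75,
    reps: int = 10,
    seed: int = 0,
    fit_fn=None,
) -> ValidationReport:
    """Repeated random-split validation (default 75/25 x 10, scores averaged).

    ``fit_fn(train) -> predict_fn(test)`` may replace the default model fit
    (e.g. an oracle predictor for calibration checks).  Standardisation and
    all other training statistics are computed inside the fold, so no
    information leaks from test clusters.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    n = len(clusters)
    if n < 8:
        raise ValueError("need at least 8 clusters for split validation")
    if fit_fn is None:
        fit_fn = _default_fit_fn(covariates, config or FitConfig())
    rng = np.random.default_rng(seed)
    # stratify on survey when available so every split represents each survey
    if "survey" in clusters.columns and clusters["survey"].nunique() > 1:
        strata = [np.asarray(ix) for _, ix in
                  clusters.groupby("survey").indices.items()]
    else:
        strata = [np.arange(n)]
    rows = []
    for rep in range(reps):
        tr_parts, te_parts = [], []
        for s in strata:
            perm = rng.permutation(s)
            cut = min(int(round(train_frac * len(s))), len(s))
            tr_parts.append(perm[:cut])
            te_parts.append(perm[cut:])
        tr = np.concatenate(tr_parts)
        te = np.concatenate(te_parts)
        if te.size == 0:  # degenerate strata rounding: keep one test cluster
            tr, te = tr[:-1], tr[-1:]
        train, test = clusters.iloc[tr], clusters.iloc[te]
        pred = np.asarray(fit_fn(train)(test), dtype=float)
        rows.append({"rep": rep, **_score_split(test, pred)})
    per_rep = pd.DataFrame(rows)
    summary = per_rep.drop(columns="rep").mean().to_dict()
    return ValidationReport(per_rep=per_rep, summary=summary, scheme="random_split")


def admin_holdout_cv(
    clusters: pd.DataFrame,
    admin_col: str = "country",
    covariates: list[str] | None = None,
    config: FitConfig | None = None,
    fit_fn=None,
) -> ValidationReport:
    """Leave-one-administrative-unit-out spatial block validation."""
    units = clusters[admin_col].unique()
    if len(units) < 2:
        raise ValueError("need at least 2 administrative units")
    if fit_fn is None:
        fit_fn = _default_fit_fn(covariates, config or FitConfig())
    rows = []
    pooled_obs, pooled_pred = [], []
    for unit in sorted(units):
        mask = clusters[admin_col] == unit
        train, test = clusters[~mask], clusters[mask]
        pred = np.asarray(fit_fn(train)(test), dtype=float)
        rows.append({"unit": unit, "n_test": len(test), **_score_split(test, pred)})
        pooled_obs.append((test["y_plus"] / test["y_total"]).to_numpy())
        pooled_pred.append(pred)
    per_rep = pd.DataFrame(rows)
    mse, corr = _metrics(np.concatenate(pooled_obs), np.concatenate(pooled_pred))
    summary = {
        "mse": mse, "corr": corr,
        "mean_unit_mse": float(per_rep["mse"].mean()),
        "mean_unit_corr": float(per_rep["corr"].mean()),
    }
    return ValidationReport(per_rep=per_rep, summary=summary, scheme="admin_holdout")
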