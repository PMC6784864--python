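"""Beta-binomial random-Fourier-feature geostatistical prevalence model.

The model regresses per-cluster counts ``(y_plus, y_total)`` of households
with an improved outcome on covariates, planar coordinates and time through
a random-Fourier-feature map with a learned spectral measure:

    mu_i   = logistic( b0 + sqrt(sigma^2 / M) * beta^T z(x_i | omega) )
    y_i^+  ~ BetaBinomial(y_i^total, mu_i, phi)

where ``z`` holds M cosine and M sine features, the frequencies ``omega``
are scaled per input dimension by rectified ARD parameters (exact zeros
drop a covariate), and ``phi`` is cluster-level overdispersion.  Fitting
maximises the (optionally Dirichlet-weighted, dropout-regularised)
log-likelihood with ADAM; uncertainty comes from the weighted likelihood
bootstrap.

Usage follows the statsmodels convention: build a
:class:`HousingPrevalenceModel` (e.g. via :meth:`from_clusters`), call
``fit()`` for an :class:`RFFResults`, and ``results.bootstrap()`` for a
:class:`BootstrapResults` ensemble.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .betabinom import _grad_core, _loglik_core, betabinom_loglik
from .featuremap import SpectralMeasure, apply_feature_map
from .raster import RasterStack

__all__ = ["HousingPrevalenceModel", "RFFResults", "BootstrapResults", "FitConfig"]

_MU_EPS = 1e-10


@dataclass
class FitConfig:
    """Optimiser settings for the ADAM fit.

    Full-batch gradients are used throughout: at survey scale (hundreds to a
    few thousand clusters) a full gradient costs microseconds, so minibatch
    machinery would only add noise.
    """

    n_features: int = 100          # M frequencies -> 2M trig features
    learning_rate: float = 0.01
    max_iter: int = 6000
    dropout: float = 0.35          # feature-activation dropout probability
    learn_frequencies: bool = False  # adapt omega beyond the ARD rescaling
    learn_scales: bool = True       # adapt ARD scales theta
    tol: float = 1e-7              # objective-change convergence threshold
    tol_window: int = 100          # ... measured over this many steps
    snapshot_every: int = 25       # trajectory-averaging stride under dropout
    snapshot_burn: float = 0.5     # fraction of iterations before snapshots
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_features < 1:
            raise ValueError("need at least one frequency")


class _Adam:
    """Plain ADAM ascent on a flat parameter vector."""

    def __init__(self, n, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, params, grad):
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return params + self.lr * mhat / (np.sqrt(vhat) + self.eps)


class HousingPrevalenceModel:
    """Beta-binomial RFF regression of cluster prevalence on space-time inputs.

    Parameters
    ----------
    y_plus, y_total : (n,) int arrays
        Improved-household count and classified-household count per cluster.
    exog : (n, d) array
        Raw (unstandardised) inputs: covariates, then x, y, year.  The model
        standardises each column with training means/sds and keeps the
        constants so prediction uses the training transform.
    exog_names : sequence of str, optional
    """

    def __init__(self, y_plus, y_total, exog, exog_names=None):
        self.y_plus = np.asarray(y_plus, dtype=float).ravel()
        self.y_total = np.asarray(y_total, dtype=float).ravel()
        self.exog_raw = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog_raw.shape[0] != self.y_plus.shape[0]:
            raise ValueError("exog and response lengths differ")
        if self.y_plus.shape[0] == 0:
            raise ValueError("no observations")
        if np.any(self.y_plus > self.y_total) or np.any(self.y_plus < 0):
            raise ValueError("need 0 <= y_plus <= y_total")
        d = self.exog_raw.shape[1]
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(d)
        ]
        if len(self.exog_names) != d:
            raise ValueError("exog_names length mismatch")
        self.x_mean = self.exog_raw.mean(axis=0)
        sd = self.exog_raw.std(axis=0)
        self.x_sd = np.where(sd > 0, sd, 1.0)
        self.exog = (self.exog_raw - self.x_mean) / self.x_sd

    # ------------------------------------------------------------------
    @classmethod
    def from_clusters(
        cls,
        clusters: pd.DataFrame,
        covariates: list[str],
        coords: tuple[str, str] = ("x", "y"),
        year: str = "year",
    ) -> "HousingPrevalenceModel":
        """Build from an aggregated cluster table with y_plus/y_total columns."""
        cols = [*covariates, *coords, year]
        exog = clusters[cols].to_numpy(dtype=float)
        return cls(
            clusters["y_plus"].to_numpy(),
            clusters["y_total"].to_numpy(),
            exog,
            exog_names=cols,
        )

    @property
    def nobs(self) -> int:
        return self.y_plus.shape[0]

    def standardize(self, exog_raw: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(exog_raw, dtype=float)) - self.x_mean) / self.x_sd

    # -- parameter packing ---------------------------------------------
    def _init_params(self, config: FitConfig, rng: np.random.Generator):
        d = self.exog.shape[1]
        M = config.n_features
        omega = rng.standard_normal((M, d))
        p0 = self.y_plus.sum() / max(self.y_total.sum(), 1.0)
        p0 = float(np.clip(p0, 0.01, 0.99))
        parts = [
            np.array([logit(p0)]),        # b0
            np.zeros(2 * M),              # beta (cos, sin)
            np.ones(d),                   # theta
            np.array([0.0]),              # log sigma^2
            np.array([logit(0.1)]),       # zeta = logit(phi)
            omega.ravel(),                # frequencies
        ]
        return np.concatenate(parts)

    @staticmethod
    def _unpack(params, M, d):
        i = 0
        b0 = params[i]; i += 1
        beta = params[i:i + 2 * M]; i += 2 * M
        theta = params[i:i + d]; i += d
        log_s2 = params[i]; i += 1
        zeta = params[i]; i += 1
        omega = params[i:].reshape(M, d)
        return b0, beta, theta, log_s2, zeta, omega

    # -- objective ------------------------------------------------------
    def _obj_grad(self, params, M, weights, mask=None, keep_prob=1.0,
                  learn_frequencies=True, learn_scales=True):
        """Weighted log-likelihood and its gradient at ``params``.

        ``mask`` is an optional (2M,) 0/1 dropout mask on feature
        activations; kept activations are rescaled by 1/keep_prob.
        """
        X = self.exog
        n, d = X.shape
        b0, beta, theta, log_s2, zeta, omega = self._unpack(params, M, d)
        s = np.maximum(theta, 0.0)
        U = X @ (omega * s).T                     # (n, M)
        C, S = np.cos(U), np.sin(U)
        if mask is not None:
            mc = mask[:M] / keep_prob
            ms = mask[M:] / keep_prob
        else:
            mc = ms = np.ones(M)
        a = np.exp(0.5 * log_s2) / np.sqrt(M)
        bc, bs = beta[:M], beta[M:]
        lin = C @ (bc * mc) + S @ (bs * ms)
        eta = b0 + a * lin
        mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
        phi = float(np.clip(expit(zeta), 1e-8, 1 - 1e-8))
        ll = _loglik_core(self.y_plus, self.y_total, mu, phi)
        obj = float(np.sum(weights * ll))

        d_mu, d_phi = _grad_core(self.y_plus, self.y_total, mu, phi)
        g = weights * d_mu * mu * (1 - mu)        # d obj / d eta, per obs
        grad_b0 = g.sum()
        grad_bc = a * (C * mc) .T @ g
        grad_bs = a * (S * ms).T @ g
        grad_logs2 = 0.5 * float(g @ (a * lin))
        grad_zeta = float(np.sum(weights * d_phi)) * phi * (1 - phi)
        # through the angles U
        V = -S * (bc * mc) + C * (bs * ms)        # d lin / d U, (n, M)
        B = g[:, None] * V                        # (n, M)
        if learn_scales:
            grad_theta = a * ((X.T @ B) * omega.T).sum(axis=1) * (theta > 0)
        else:
            grad_theta = np.zeros(d)
        if learn_frequencies:
            grad_omega = a * (B.T @ X) * s[None, :]
        else:
            grad_omega = np.zeros((M, d))
        grad = np.concatenate([
            [grad_b0], grad_bc, grad_bs, grad_theta,
            [grad_logs2], [grad_zeta], grad_omega.ravel(),
        ])
        return obj, grad

    # -- fitting --------------------------------------------------------
    def fit(self, config: FitConfig | None = None, weights=None,
            start_params=None, snapshots: bool = True, **overrides) -> "RFFResults":
        """Maximise the (weighted) beta-binomial log-likelihood with ADAM.

        ``weights`` multiply per-observation log-likelihood terms (all ones
        for the plain fit; n * Dirichlet draws for the weighted likelihood
        bootstrap).  With ``dropout > 0`` the gradient is stochastic: the
        optimiser runs all ``max_iter`` steps and, unless ``snapshots`` is
        False, parameter snapshots from the post-burn-in trajectory are kept
        so that predictions average over the stationary dropout ensemble
        (a Monte-Carlo-dropout posterior mean) instead of using one noisy
        final iterate.  With dropout off the fit is deterministic and early
        stopping triggers when the objective moves less than ``tol`` over
        ``tol_window`` steps.
        """
        config = config or FitConfig()
        if overrides:
            config = FitConfig(**{**config.__dict__, **overrides})
        M, d = config.n_features, self.exog.shape[1]
        rng = np.random.default_rng(config.seed)
        w = np.ones(self.nobs) if weights is None else np.asarray(weights, dtype=float)
        if w.shape[0] != self.nobs:
            raise ValueError("weights length mismatch")
        params = (np.array(start_params, dtype=float, copy=True)
                  if start_params is not None else self._init_params(config, rng))
        opt = _Adam(params.shape[0], config.learning_rate)
        p_drop = config.dropout
        keep = 1.0 - p_drop
        burn = int(config.snapshot_burn * config.max_iter)
        history: list[float] = []
        snaps: list[np.ndarray] = []
        n_iter = 0
        converged = False
        for it in range(config.max_iter):
            mask = (rng.random(2 * M) >= p_drop).astype(float) if p_drop > 0 else None
            obj, grad = self._obj_grad(
                params, M, w, mask=mask, keep_prob=keep,
                learn_frequencies=config.learn_frequencies,
                learn_scales=config.learn_scales,
            )
            if not np.isfinite(obj):
                raise RuntimeError(
                    f"objective diverged at iteration {it}: obj={obj}; "
                    "try a smaller learning rate"
                )
            history.append(obj)
            params = opt.step(params, grad)
            n_iter = it + 1
            if (snapshots and p_drop > 0 and it >= burn
                    and it % config.snapshot_every == 0):
                snaps.append(params.copy())
            if (p_drop == 0 and it >= config.tol_window
                    and abs(history[-1] - history[-1 - config.tol_window]) < config.tol):
                converged = True
                break
        # final objective without dropout noise
        final_obj, _ = self._obj_grad(params, M, w,
                                      learn_frequencies=config.learn_frequencies,
                                      learn_scales=config.learn_scales)
        b0, beta, theta, log_s2, zeta, omega = self._unpack(params, M, d)
        sm = SpectralMeasure(omega=omega, theta=theta, sigma2=float(np.exp(log_s2)))
        if snaps:
            phi = float(np.mean([expit(self._unpack(p, M, d)[4]) for p in snaps]))
        else:
            phi = float(expit(zeta))
        return RFFResults(
            model=self, config=config, spectral=sm,
            intercept=float(b0), beta=beta.copy(),
            phi=phi, params=params.copy(), snapshots=snaps,
            loglik=final_obj, n_iter=n_iter, converged=converged,
        )


@dataclass
class RFFResults:
    """Point fit of the beta-binomial RFF model.

    Carries the fitted spectral measure, regression weights, overdispersion
    and the training standardisation (through ``model``); ``bootstrap()``
    produces the weighted-likelihood-bootstrap ensemble.
    """

    model: HousingPrevalenceModel
    config: FitConfig
    spectral: SpectralMeasure
    intercept: float
    beta: np.ndarray
    phi: float
    params: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    snapshots: list = field(default_factory=list)

    # -- prediction ----------------------------------------------------
    def _mu_at(self, params: np.ndarray, Xs: np.ndarray) -> np.ndarray:
        M = self.config.n_features
        b0, beta, theta, log_s2, zeta, omega = self.model._unpack(
            params, M, Xs.shape[1])
        sm = SpectralMeasure(omega=omega, theta=theta, sigma2=float(np.exp(log_s2)))
        Z = apply_feature_map(Xs, sm)
        a = np.sqrt(sm.sigma2 / M)
        return expit(b0 + a * (Z @ beta))

    def linear_predictor(self, exog_raw: np.ndarray) -> np.ndarray:
        Xs = self.model.standardize(exog_raw)
        Z = apply_feature_map(Xs, self.spectral)
        a = np.sqrt(self.spectral.sigma2 / self.spectral.n_features)
        return self.intercept + a * (Z @ self.beta)

    def predict(self, exog_raw: np.ndarray | None = None) -> np.ndarray:
        """Prevalence mu at raw input rows (training rows when omitted).

        Under dropout the prediction averages mu over the stored
        post-burn-in trajectory snapshots; without dropout it is the plug-in
        logistic at the converged parameters.
        """
        if exog_raw is None:
            exog_raw = self.model.exog_raw
        Xs = self.model.standardize(exog_raw)
        if self.snapshots:
            return np.mean([self._mu_at(p, Xs) for p in self.snapshots], axis=0)
        return self._mu_at(self.params, Xs)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    def cluster_posterior_mean(self) -> np.ndarray:
        """Fitted cluster-level prevalence: empirical-Bayes posterior mean.

        Each cluster's own prevalence is a beta draw around the surface, so
        its fitted value combines the surface prediction with the cluster's
        observed count under the fitted overdispersion:
        E[p_c | y_c] = (y_c + alpha_c) / (n_c + alpha_c + beta_c) with
        alpha_c = mu_c (1-phi)/phi, beta_c = (1-mu_c)(1-phi)/phi.
        """
        mu = self.predict()
        a = mu * (1 - self.phi) / self.phi
        b = (1 - mu) * (1 - self.phi) / self.phi
        return (self.model.y_plus + a) / (self.model.y_total + a + b)

    def predict_surface(self, grid: RasterStack, year: float) -> np.ndarray:
        """Prevalence raster for one year; NaN-covariate cells stay missing."""
        exog, valid, shape = _grid_exog(grid, year, self.model)
        out = np.full(shape[0] * shape[1], np.nan)
        if valid.any():
            out[valid] = self.predict(exog[valid])
        return out.reshape(shape)

    @property
    def ard_scales(self) -> pd.Series:
        """Rectified per-dimension length-scale multipliers; zeros mark
        covariates the model has switched off."""
        return pd.Series(self.spectral.effective_scales, index=self.model.exog_names)

    def summary(self) -> str:
        lines = [
            "Beta-binomial random-Fourier-feature geostatistical model",
            "=" * 60,
            f"No. clusters:        {self.model.nobs}",
            f"No. frequencies (M): {self.config.n_features}",
            f"Log-likelihood:      {self.loglik:.4f}",
            f"Iterations:          {self.n_iter} (converged: {self.converged})",
            f"Intercept:           {self.intercept:.4f}",
            f"Amplitude sigma^2:   {self.spectral.sigma2:.4f}",
            f"Overdispersion phi:  {self.phi:.4f}",
            f"Dropout rate:        {self.config.dropout}",
            "-" * 60,
            "ARD effective scales (0 = covariate switched off):",
        ]
        for name, val in self.ard_scales.items():
            lines.append(f"  {name:<18s} {val:8.4f}")
        return "\n".join(lines)

    # -- bootstrap -----------------------------------------------------
    def bootstrap(self, B: int = 100, seed: int = 0,
                  max_iter: int | None = None) -> "BootstrapResults":
        """Weighted likelihood bootstrap: ``B`` refits under uniform
        Dirichlet(1, ..., 1) likelihood weights (scaled by n), warm-started
        at the point fit.  The refits approximate a posterior sample.
        """
        if B < 2:
            raise ValueError("need B >= 2 for interval estimation")
        rng = np.random.default_rng(seed)
        n = self.model.nobs
        if max_iter is None:
            # members warm-start at the point fit; a fraction of the point
            # fit's iterations reaches the reweighted optimum
            max_iter = max(750, self.config.max_iter // 4)
        cfg = FitConfig(**{**self.config.__dict__, "max_iter": max_iter,
                           "seed": int(rng.integers(2**31))})
        members = []
        for b in range(B):
            w = rng.dirichlet(np.ones(n)) * n
            res = self.model.fit(
                config=cfg, weights=w, start_params=self.params,
                snapshots=False, seed=int(rng.integers(2**31)),
            )
            members.append(res)
        return BootstrapResults(point=self, members=members, seed=seed)

    # -- serialization -------------------------------------------------
    def to_json(self, path: str) -> None:
        payload = {
            "exog_names": self.model.exog_names,
            "x_mean": self.model.x_mean.tolist(),
            "x_sd": self.model.x_sd.tolist(),
            "omega": self.spectral.omega.tolist(),
            "theta": self.spectral.theta.tolist(),
            "sigma2": self.spectral.sigma2,
            "intercept": self.intercept,
            "beta": self.beta.tolist(),
            "phi": self.phi,
            "config": {k: v for k, v in self.config.__dict__.items()},
            "loglik": self.loglik,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _grid_exog(grid: RasterStack, year: float, model: HousingPrevalenceModel):
    """Assemble raw model inputs for every grid cell at one year."""
    cov = grid.covariate_matrix()
    xs, ys = grid.cell_coords()
    exog = np.column_stack([cov, xs, ys, np.full(xs.shape, float(year))])
    if exog.shape[1] != model.exog_raw.shape[1]:
        raise ValueError(
            f"grid supplies {exog.shape[1]} input dims, model expects "
            f"{model.exog_raw.shape[1]}"
        )
    valid = ~np.isnan(exog).any(axis=1)
    return exog, valid, grid.shape


@dataclass
class BootstrapResults:
    """Weighted-likelihood-bootstrap ensemble around a point fit."""

    point: RFFResults
    members: list[RFFResults]
    seed: int
    ci_level: float = 0.95

    @property
    def B(self) -> int:
        return len(self.members)

    def _q(self):
        alpha = 1 - self.ci_level
        return 100 * alpha / 2, 100 * (1 - alpha / 2)

    def predict(self, exog_raw: np.ndarray | None = None) -> np.ndarray:
        """(B, n) matrix of member predictions."""
        return np.vstack([m.predict(exog_raw) for m in self.members])

    def predict_interval(self, exog_raw: np.ndarray | None = None):
        """(mean, lower, upper) across the ensemble at the given inputs."""
        P = self.predict(exog_raw)
        lo, hi = self._q()
        return P.mean(axis=0), np.percentile(P, lo, axis=0), np.percentile(P, hi, axis=0)

    def cluster_prevalence_interval(
        self,
        exog_raw: np.ndarray | None = None,
        n_draws: int = 20,
        seed: int = 0,
    ):
        """Predictive 95% intervals for cluster-level prevalence.

        A cluster's own prevalence is a beta draw around the surface value
        (overdispersion phi), so the predictive distribution mixes, over
        ensemble members, Beta(mu(1-phi)/phi, (1-mu)(1-phi)/phi) at the
        member's fitted mu and phi.  Quantiles are taken over ``n_draws``
        beta draws per member.  Returns (median, lower, upper).
        """
        P = self.predict(exog_raw)                    # (B, n)
        rng = np.random.default_rng(seed)
        draws = []
        for b, member in enumerate(self.members):
            phi = member.phi
            a = np.maximum(P[b] * (1 - phi) / phi, 1e-6)
            c = np.maximum((1 - P[b]) * (1 - phi) / phi, 1e-6)
            draws.append(rng.beta(a, c, size=(n_draws, P.shape[1])))
        D = np.vstack(draws)
        lo, hi = self._q()
        return (np.percentile(D, 50, axis=0), np.percentile(D, lo, axis=0),
                np.percentile(D, hi, axis=0))

    def predict_surface(self, grid: RasterStack, year: float):
        """(mean, lower, upper) prevalence rasters for one year."""
        exog, valid, shape = _grid_exog(grid, year, self.point.model)
        ncell = shape[0] * shape[1]
        P = np.full((self.B, ncell), np.nan)
        if valid.any():
            sub = exog[valid]
            for b, m in enumerate(self.members):
                P[b, valid] = m.predict(sub)
        lo, hi = self._q()
        mean = P.mean(axis=0).reshape(shape)
        lower = np.nanpercentile(np.where(valid, P, np.nan), lo, axis=0).reshape(shape)
        upper = np.nanpercentile(np.where(valid, P, np.nan), hi, axis=0).reshape(shape)
        lower[~valid.reshape(shape)] = np.nan
        upper[~valid.reshape(shape)] = np.nan
        return mean, lower, upper


def select_dropout(
    model: HousingPrevalenceModel,
    config: FitConfig | None = None,
    grid=(0.0, 0.1, 0.2, 0.5),
    val_frac: float = 0.25,
    seed: int = 0,
) -> float:
    """Choose the dropout rate by random search over a validation split.

    Fits on a (1 - val_frac) subsample at each candidate rate and scores the
    held-out clusters' beta-binomial log-likelihood; returns the best rate.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    n = model.nobs
    idx = rng.permutation(n)
    n_val = max(1, int(round(val_frac * n)))
    val, train = idx[:n_val], idx[n_val:]
    sub = HousingPrevalenceModel(
        model.y_plus[train], model.y_total[train],
        model.exog_raw[train], exog_names=model.exog_names,
    )
    best_p, best_score = grid[0], -np.inf
    for p in grid:
        res = sub.fit(config=config, dropout=float(p))
        mu = np.clip(res.predict(model.exog_raw[val]), _MU_EPS, 1 - _MU_EPS)
        score = float(np.sum(betabinom_loglik(
            model.y_plus[val], model.y_total[val], mu, res.phi)))
        if score > best_score:
            best_p, best_score = float(p), score
    return best_p
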