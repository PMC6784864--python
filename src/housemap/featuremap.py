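"""Random Fourier feature map with learnable spectral measure and ARD scales.

The trigonometric feature map

    z(x | omega) = [cos(x^T omega_r), sin(x^T omega_r)]_{r=1..M}

approximates, via Bochner's theorem, a shift-invariant kernel

    k(x_i, x_j) ~ (sigma^2 / M) * z(x_i)^T z(x_j)

whose spectral measure is the distribution of the frequencies omega_r.
Frequencies are initialised from a standard normal (the Gaussian-kernel
spectral measure) and may be adapted during fitting, giving a spectral
measure learned from the data rather than fixed a priori.

Automatic relevance determination (ARD) enters through per-dimension
unconstrained scale parameters theta: the effective frequencies are
omega_r * relu(theta), so a dimension whose rectified scale reaches exactly
zero drops out of the kernel entirely — sparse covariate selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralMeasure", "build_feature_map", "apply_feature_map", "kernel_approx"]


def relu(t: np.ndarray) -> np.ndarray:
    return np.maximum(t, 0.0)


@dataclass
class SpectralMeasure:
    """Frequencies, ARD scales and amplitude defining an approximate kernel.

    Attributes
    ----------
    omega : (M, d) ndarray
        Spectral frequencies, one row per feature pair.
    theta : (d,) ndarray
        Unconstrained ARD pre-scales; the effective per-dimension scale is
        ``relu(theta)`` and exact zeros switch a dimension off.
    sigma2 : float
        Kernel amplitude (variance at zero lag), > 0.
    """

    omega: np.ndarray
    theta: np.ndarray
    sigma2: float = 1.0

    def __post_init__(self):
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        if self.omega.shape[1] != self.theta.shape[0]:
            raise ValueError(
                f"omega has {self.omega.shape[1]} columns but theta has "
                f"{self.theta.shape[0]} entries"
            )
        if self.omega.shape[0] < 1:
            raise ValueError("need at least one frequency")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    @property
    def n_features(self) -> int:
        return self.omega.shape[0]

    @property
    def n_dims(self) -> int:
        return self.omega.shape[1]

    @property
    def effective_scales(self) -> np.ndarray:
        return relu(self.theta)

    def scaled_frequencies(self) -> np.ndarray:
        return self.omega * self.effective_scales[np.newaxis, :]


def build_feature_map(X: np.ndarray, M: int, seed: int | np.random.Generator = 0) -> SpectralMeasure:
    """Initialise a spectral measure for inputs ``X`` with ``M`` frequencies.

    Frequencies start standard normal, ARD scales at unit effective scale
    and amplitude at 1; all three are typically adapted during fitting.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise ValueError("empty input matrix")
    if M < 1:
        raise ValueError(f"need M >= 1 frequencies, got {M}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = X.shape[1]
    omega = rng.standard_normal((M, d))
    return SpectralMeasure(omega=omega, theta=np.ones(d), sigma2=1.0)


def apply_feature_map(x: np.ndarray, sm: SpectralMeasure) -> np.ndarray:
    """Evaluate z(x | omega) = [cos, sin] features; rows of x map to rows out.

    Returns an array of shape ``(n, 2M)`` (or ``(2M,)`` for a single vector):
    the first M columns are cosines, the last M sines.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != sm.n_dims:
        raise ValueError(f"input has {X.shape[1]} dims, spectral measure {sm.n_dims}")
    U = X @ sm.scaled_frequencies().T
    Z = np.concatenate([np.cos(U), np.sin(U)], axis=1)
    return Z[0] if single else Z


def kernel_approx(xi: np.ndarray, xj: np.ndarray, sm: SpectralMeasure) -> float:
    """Monte-Carlo kernel value (sigma^2 / M) z(xi)^T z(xj).

    Symmetric in its arguments and exactly sigma^2 at zero lag.  With fixed
    standard-normal frequencies and unit scales this converges to the
    Gaussian kernel exp(-|xi-xj|^2 / 2) at the O(M^{-1/2}) Monte-Carlo rate.
    """
    zi = apply_feature_map(xi, sm)
    zj = apply_feature_map(xj, sm)
    return float(sm.sigma2 / sm.n_features * zi @ zj)
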