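"""Target densities for scattering-model inference.

Ties a forward model and a measured 1-D curve to the potential energy
``U(z) = -log p(z)`` sampled by the HMC engine.  The likelihood is a
Gaussian residual model with a single unknown variance ``sigma2`` that is
appended to the model's parameter vector and sampled along with it; for
SAXS and reflectivity the residuals are taken on the logarithm of the
intensity.  Parameters are mapped to an unconstrained sampling scale by
per-parameter transforms (identity / log / logit), with the Jacobian of
the inverse map folded into the potential so the transformed density
integrates correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Dataset",
    "ForwardModel",
    "ParameterTransform",
    "log_likelihood",
    "numerical_gradient",
    "TargetDensity",
    "CallableTarget",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class Dataset:
    """A 1-D scattering curve.

    Parameters
    ----------
    abscissa
        Strictly increasing grid: q in 1/Angstrom, exit angle in degrees,
        or a detector pixel index.
    y
        Observed intensities, same length as ``abscissa``.
    scale
        ``"log"`` if residuals are formed on ln(intensity) (SAXS,
        reflectivity), ``"linear"`` otherwise.
    errors
        Optional per-point standard deviations used as relative weights.
    """

    abscissa: np.ndarray
    y: np.ndarray
    scale: str = "log"
    errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.abscissa.ndim != 1 or self.abscissa.shape != self.y.shape:
            raise ValueError("abscissa and y must be 1-D arrays of equal length")
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"unknown observation scale {self.scale!r}")
        if self.scale == "log" and np.any(self.y <= 0):
            raise ValueError("log observation scale requires positive observations")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.y.shape:
                raise ValueError("errors must match y in shape")

    @property
    def n(self) -> int:
        return self.y.size


class ForwardModel:
    """Contract for a forward scattering model.

    Subclasses define ``param_names`` (physical model parameters, not
    including the residual variance) and ``predict(theta, x)`` which must
    accept a parameter vector of shape ``(P,)`` or a batch ``(B, P)`` and
    return intensities of shape ``(n,)`` or ``(B, n)``.
    """

    param_names: Sequence[str] = ()

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def predict(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError


_TRANSFORM_KINDS = ("identity", "log", "logit")


@dataclass
class ParameterTransform:
    """Per-parameter map between physical scale and unconstrained sampling scale.

    ``kinds[i]`` is one of ``identity`` (unbounded), ``log`` (positive) or
    ``logit`` (bounded interval, requires ``bounds[i]``).
    """

    kinds: Sequence[str]
    bounds: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k in self.kinds:
            if k not in _TRANSFORM_KINDS:
                raise ValueError(f"unknown transform kind {k!r}")
        for i, k in enumerate(self.kinds):
            if k == "logit" and i not in self.bounds:
                raise ValueError(f"logit transform for parameter {i} needs bounds")

    @property
    def n(self) -> int:
        return len(self.kinds)

    def to_sampling(self, x: np.ndarray) -> np.ndarray:
        """Physical -> sampling scale."""
        x = np.asarray(x, dtype=float)
        z = np.array(x, copy=True)
        for i, k in enumerate(self.kinds):
            if k == "log":
                z[..., i] = np.log(x[..., i])
            elif k == "logit":
                lo, hi = self.bounds[i]
                u = (x[..., i] - lo) / (hi - lo)
                z[..., i] = np.log(u) - np.log1p(-u)
        return z

    def to_physical(self, z: np.ndarray) -> np.ndarray:
        """Sampling -> physical scale."""
        z = np.asarray(z, dtype=float)
        x = np.array(z, copy=True)
        for i, k in enumerate(self.kinds):
            if k == "log":
                x[..., i] = np.exp(z[..., i])
            elif k == "logit":
                lo, hi = self.bounds[i]
                s = 1.0 / (1.0 + np.exp(-z[..., i]))
                x[..., i] = lo + (hi - lo) * s
        return x

    def dx_dz(self, z: np.ndarray) -> np.ndarray:
        """Elementwise derivative of the inverse map, d physical / d sampling."""
        z = np.asarray(z, dtype=float)
        d = np.ones_like(z)
        for i, k in enumerate(self.kinds):
            if k == "log":
                d[..., i] = np.exp(z[..., i])
            elif k == "logit":
                lo, hi = self.bounds[i]
                s = 1.0 / (1.0 + np.exp(-z[..., i]))
                d[..., i] = (hi - lo) * s * (1.0 - s)
        return d

    def dlogjac_dz(self, z: np.ndarray) -> np.ndarray:
        """Gradient of log |d physical / d sampling| w.r.t. z."""
        z = np.asarray(z, dtype=float)
        g = np.zeros_like(z)
        for i, k in enumerate(self.kinds):
            if k == "log":
                g[..., i] = 1.0
            elif k == "logit":
                s = 1.0 / (1.0 + np.exp(-z[..., i]))
                g[..., i] = 1.0 - 2.0 * s
        return g

    def log_jacobian(self, z: np.ndarray) -> np.ndarray:
        """log |d physical / d sampling| summed over coordinates.

        Works on a single vector ``(N,)`` or batch ``(B, N)``; returns a
        scalar or ``(B,)``.
        """
        z = np.asarray(z, dtype=float)
        lj = np.zeros(z.shape[:-1], dtype=float)
        for i, k in enumerate(self.kinds):
            if k == "log":
                lj = lj + z[..., i]
            elif k == "logit":
                lo, hi = self.bounds[i]
                zi = z[..., i]
                # log[(hi-lo) s (1-s)] computed stably
                lj = lj + np.log(hi - lo) - zi - 2.0 * np.log1p(np.exp(-zi))
        return lj


def log_likelihood(params: np.ndarray, model: ForwardModel, data: Dataset) -> float:
    """Gaussian log-likelihood on the dataset's observation scale.

    ``params`` is the physical-scale vector ``(model params..., sigma2)``;
    the residual variance is the last entry.  Non-finite or non-positive
    model predictions on a log scale map to ``-inf`` (certain rejection).
    """
    params = np.asarray(params, dtype=float)
    theta, sigma2 = params[:-1], params[-1]
    if not np.isfinite(sigma2) or sigma2 <= 0:
        return -np.inf
    f = model.predict(theta, data.abscissa)
    return _gaussian_loglik(data, np.atleast_2d(f), np.array([sigma2]))[0]


def _gaussian_loglik(data: Dataset, f: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """Vectorized Gaussian log-likelihood for batches of predictions.

    f: (B, n) physical-scale predictions; sigma2: (B,).  Returns (B,).
    """
    out = np.full(f.shape[0], -np.inf)
    if data.scale == "log":
        ok = np.all(np.isfinite(f) & (f > 0), axis=1) & (sigma2 > 0)
        resid = np.where(f > 0, np.log(np.where(f > 0, f, 1.0)) - np.log(data.y), np.inf)
    else:
        ok = np.all(np.isfinite(f), axis=1) & (sigma2 > 0)
        resid = f - data.y
    if data.errors is not None:
        resid = resid / data.errors
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        ssr = np.sum(resid**2, axis=1)
        ll = -ssr / (2.0 * sigma2) - 0.5 * data.n * (np.log(sigma2) + _LOG_2PI)
    out[ok] = ll[ok]
    return out


def numerical_gradient(
    U: Callable[[np.ndarray], float],
    z: np.ndarray,
    h: float | np.ndarray = 1e-5,
) -> np.ndarray:
    """Central-difference gradient of a scalar potential.

    Falls back to a one-sided difference when a probe point returns a
    non-finite value; raises if both sides are non-finite.
    """
    z = np.asarray(z, dtype=float)
    hvec = np.broadcast_to(np.asarray(h, dtype=float), z.shape).copy()
    g = np.empty_like(z)
    u0 = None
    for i in range(z.size):
        e = np.zeros_like(z)
        e[i] = hvec[i]
        up, um = U(z + e), U(z - e)
        if np.isfinite(up) and np.isfinite(um):
            g[i] = (up - um) / (2.0 * hvec[i])
        else:
            if u0 is None:
                u0 = U(z)
            if np.isfinite(up):
                g[i] = (up - u0) / hvec[i]
            elif np.isfinite(um):
                g[i] = (u0 - um) / hvec[i]
            else:
                raise FloatingPointError(
                    f"potential non-finite on both sides of coordinate {i}"
                )
    return g


class TargetDensity:
    """Potential energy ``U(z)`` and gradient for a model + dataset.

    ``U(z) = -log L(untransform(z)) - log|J|`` where the parameter vector on
    the physical scale is ``(model params..., sigma2)``.  Gradients are
    central finite differences evaluated through a single batched call to
    ``model.predict`` (2N+1 parameter vectors per gradient), with step
    ``h_i = max(h, h |z_i|)`` per coordinate.
    """

    def __init__(
        self,
        model: ForwardModel,
        data: Dataset,
        transform: ParameterTransform,
        fd_step: float = 1e-5,
    ) -> None:
        if transform.n != model.n_params + 1:
            raise ValueError(
                "transform must cover model parameters plus the residual variance"
            )
        self.model = model
        self.data = data
        self.transform = transform
        self.fd_step = float(fd_step)

    @property
    def n_dim(self) -> int:
        return self.transform.n

    def _potential_batch(self, z: np.ndarray) -> np.ndarray:
        """U for a batch (B, N) of sampling-scale vectors; returns (B,)."""
        x = self.transform.to_physical(z)
        theta, sigma2 = x[:, :-1], x[:, -1]
        f = np.atleast_2d(self.model.predict(theta, self.data.abscissa))
        ll = _gaussian_loglik(self.data, f, sigma2)
        lj = self.transform.log_jacobian(z)
        U = -(ll + lj)
        return np.where(np.isfinite(U), U, np.inf)

    def potential(self, z: np.ndarray) -> float:
        return float(self._potential_batch(np.atleast_2d(np.asarray(z, float)))[0])

    __call__ = potential

    def gradient(self, z: np.ndarray) -> np.ndarray:
        return self.value_and_grad(z)[1]

    def value_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        if hasattr(self.model, "predict_and_jacobian"):
            return self._value_and_grad_jacobian(np.asarray(z, float))
        return self._value_and_grad_fd(np.asarray(z, float))

    def _value_and_grad_jacobian(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        """Exact gradient through a model-supplied prediction Jacobian."""
        x = self.transform.to_physical(z)
        theta, sigma2 = x[:-1], x[-1]
        f, J = self.model.predict_and_jacobian(theta, self.data.abscissa)
        n = self.data.n
        bad = sigma2 <= 0 or not np.all(np.isfinite(f))
        if not bad and self.data.scale == "log":
            bad = np.any(f <= 0)
        if bad:
            return np.inf, np.full(z.size, np.nan)
        if self.data.scale == "log":
            r = np.log(f) - np.log(self.data.y)
            dr = J / f[:, None]
        else:
            r = f - self.data.y
            dr = J
        if self.data.errors is not None:
            r = r / self.data.errors
            dr = dr / self.data.errors[:, None]
        ssr = float(r @ r)
        U = ssr / (2.0 * sigma2) + 0.5 * n * (np.log(sigma2) + _LOG_2PI)
        dU_x = np.empty(z.size)
        dU_x[:-1] = (r @ dr) / sigma2
        dU_x[-1] = -ssr / (2.0 * sigma2**2) + 0.5 * n / sigma2
        g = dU_x * self.transform.dx_dz(z) - self.transform.dlogjac_dz(z)
        U = U - float(self.transform.log_jacobian(z))
        return U, g

    def gauss_newton_hessian(self, z: np.ndarray,
                             floor: float = 1e-6) -> np.ndarray:
        """Gauss-Newton curvature of U on the sampling scale.

        ``J_z' J_z / sigma2`` for the residual block (model Jacobian
        required) plus the analytic n/2 curvature of the log-variance
        coordinate.  Used as a full preconditioning mass matrix for
        strongly correlated posteriors — the full-covariance analogue of
        restarting with the inverse sample covariance.
        """
        if not hasattr(self.model, "predict_and_jacobian"):
            raise ValueError("model does not expose a prediction Jacobian")
        z = np.asarray(z, dtype=float)
        x = self.transform.to_physical(z)
        theta, sigma2 = x[:-1], x[-1]
        f, J = self.model.predict_and_jacobian(theta, self.data.abscissa)
        if self.data.scale == "log":
            J = J / f[:, None]
        if self.data.errors is not None:
            J = J / self.data.errors[:, None]
        Jz = J * self.transform.dx_dz(z)[None, :-1]
        n = z.size
        H = np.zeros((n, n))
        H[:-1, :-1] = Jz.T @ Jz / sigma2
        H[-1, -1] = 0.5 * self.data.n * self.transform.dx_dz(z)[-1] ** 2 \
            / sigma2**2
        H = 0.5 * (H + H.T)
        return H + floor * np.trace(H) / n * np.eye(n)

    def _value_and_grad_fd(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        n = z.size
        h = np.maximum(self.fd_step, self.fd_step * np.abs(z))
        batch = np.empty((2 * n + 1, n))
        batch[0] = z
        for i in range(n):
            batch[1 + 2 * i] = z
            batch[1 + 2 * i, i] += h[i]
            batch[2 + 2 * i] = z
            batch[2 + 2 * i, i] -= h[i]
        u = self._potential_batch(batch)
        u0 = u[0]
        up, um = u[1::2], u[2::2]
        with np.errstate(invalid="ignore"):
            g = (up - um) / (2.0 * h)
        onesided = ~np.isfinite(g)
        if np.any(onesided):
            with np.errstate(invalid="ignore"):
                g = np.where(np.isfinite(up) & onesided, (up - u0) / h, g)
                g = np.where(
                    np.isfinite(um) & ~np.isfinite(up) & onesided,
                    (u0 - um) / h, g,
                )
        return float(u0), g


class CallableTarget:
    """Wrap plain callables as a target density (for analytic targets).

    ``grad`` defaults to a central finite difference of ``U``.
    """

    def __init__(
        self,
        U: Callable[[np.ndarray], float],
        grad: Callable[[np.ndarray], np.ndarray] | None = None,
        fd_step: float = 1e-6,
    ) -> None:
        self._U = U
        self._grad = grad
        self.fd_step = fd_step

    def potential(self, z: np.ndarray) -> float:
        return float(self._U(np.asarray(z, dtype=float)))

    __call__ = potential

    def gradient(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self._grad is not None:
            return np.asarray(self._grad(z), dtype=float)
        return numerical_gradient(self._U, z, self.fd_step)

    def value_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        return self.potential(z), self.gradient(z)
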