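"""SAXS forward model: dilute polydisperse spheres.

Scattering intensity of a dilute dispersion of spheres whose radii
follow a normal distribution (mean R, s.d. sigma_R), convolved with a
Gaussian instrumental resolution of width sigma_q, with scattering-volume
normalization, an intensity scale I0 and a flat background Ib:

    I(q) = I0 * [ \\iint r(q', q) P(R') F^2(q', R') dR' dq'
                  / \\int P(R') V^2(R') dR' ] + Ib

where F(q, R) = 3 V(R) [sin(qR) - qR cos(qR)] / (qR)^3 is the sphere
form amplitude, V(R) = 4 pi R^3 / 3.  The denominator makes the fraction
approach 1 as q -> 0, so I(0) = I0 + Ib.

Both integrals are evaluated by fixed quadrature: Gauss-Legendre over
R in [R - 5 sigma_R, R + 5 sigma_R] truncated at R > 0 with renormalized
normal weights (61 nodes), and a 21-node Gaussian kernel over
q +- 4 sigma_q for the resolution smearing.  sigma_q = 0 degenerates to
no smearing exactly; the model uses |sigma_q| so that the resolution
width may be sampled unconstrained (its posterior can cross zero when
the data carry no resolution information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss

from .likelihood import ForwardModel

__all__ = ["QuadratureSpec", "sphere_form_amplitude", "saxs_intensity",
           "PolydisperseSphereModel", "SAXS_PARAM_NAMES"]

SAXS_PARAM_NAMES = ("I0", "Ib", "R", "sigma_R", "sigma_q")


@dataclass(frozen=True)
class QuadratureSpec:
    """Discretization of the size and resolution integrals."""

    n_nodes_R: int = 61
    n_nodes_q: int = 21
    trunc_R: float = 5.0  # +- multiples of sigma_R
    trunc_q: float = 4.0  # +- multiples of sigma_q

    def __post_init__(self) -> None:
        if self.n_nodes_R < 3 or self.n_nodes_q < 3:
            raise ValueError("quadrature needs at least 3 nodes per axis")


def sphere_form_amplitude(q: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Form amplitude F(q, R) of a homogeneous sphere, in volume units.

    F(0, R) = V(R) = 4 pi R^3 / 3; small |qR| handled by the series
    expansion F = V (1 - (qR)^2/10 + (qR)^4/280 - ...).
    """
    q = np.asarray(q, dtype=float)
    R = np.asarray(R, dtype=float)
    x = q * R
    V = 4.0 * np.pi * R**3 / 3.0
    ax = np.abs(x)
    small = ax < 1e-3
    xs = np.where(small, 1.0, x)  # avoid 0/0 in the generic branch
    with np.errstate(invalid="ignore", divide="ignore"):
        generic = 3.0 * V * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    series = V * (1.0 - x**2 / 10.0 + x**4 / 280.0)
    return np.where(small, series, generic)


from functools import lru_cache


@lru_cache(maxsize=8)
def _leggauss_cached(n: int):
    return leggauss(n)


def _r_quadrature(R, sigma_R, quad):
    """Truncated-normal size nodes and weights.

    R, sigma_R: (B,) arrays.  Returns nodes (B, nR) and probability
    weights (B, nR) normalized to sum to 1 (renormalized truncation).
    """
    t, w = _leggauss_cached(quad.n_nodes_R)  # on [-1, 1]
    lo = np.maximum(R - quad.trunc_R * sigma_R, 1e-12)
    hi = R + quad.trunc_R * sigma_R
    mid = 0.5 * (hi + lo)
    half = 0.5 * (hi - lo)
    nodes = mid[:, None] + half[:, None] * t[None, :]
    dens = np.exp(-0.5 * ((nodes - R[:, None]) / sigma_R[:, None]) ** 2)
    wts = w[None, :] * half[:, None] * dens
    return nodes, wts / wts.sum(axis=1, keepdims=True)


def _q_kernel(quad):
    """Resolution kernel nodes (units of sigma_q) and normalized weights."""
    u = np.linspace(-quad.trunc_q, quad.trunc_q, quad.n_nodes_q)
    w = np.exp(-0.5 * u**2)
    return u, w / w.sum()


def _shape_kernel(x: np.ndarray) -> np.ndarray:
    """g(x) = [(sin x - x cos x) / x^3]^2 so that F^2 = 9 V^2 g(qR).

    Lean in-place evaluation (this is the hot loop of SAXS inference);
    |x| < 1e-3 is patched with the series g = [1/3 (1 - x^2/10)]^2.
    """
    c = np.cos(x)
    s = np.sin(x)
    s -= x * c  # sin x - x cos x
    small = np.abs(x) < 1e-3
    any_small = bool(np.any(small))
    if any_small:
        x_small = x[small]
        x = np.where(small, 1.0, x)
    x3 = x * x * x
    g = s / x3
    g *= g
    if any_small:
        g[small] = (1.0 / 9.0) * (1.0 - x_small**2 / 10.0) ** 2
    return g


def _normalized_fraction(q, R, sR, sq, quad):
    """The volume-normalized, size-averaged, resolution-smeared fraction.

    Scalar shape parameters (R, sigma_R, sigma_q); returns (nq,).  The
    fraction is <= 1 everywhere and -> 1 as q -> 0.

    The size average S(q') is evaluated on a dense linear q' grid whose
    spacing resolves the fastest qR oscillation (dq * R_max <= 1/6 rad)
    and interpolated onto the resolution-smearing nodes by a cubic
    spline; S is even in q', so negative smeared nodes fold back.
    """
    from scipy.interpolate import CubicSpline

    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        Rn, Rw = _r_quadrature(np.array([R]), np.array([sR]), quad)
        Rn, Rw = Rn[0], Rw[0]
        u, uw = _q_kernel(quad)
        wV2 = Rw * (4.0 * np.pi / 3.0) ** 2 * Rn**6
        wV2_sum = wV2.sum()
    if not (np.isfinite(wV2_sum) and wV2_sum > 0):
        return np.full(q.size, np.nan)
    q_hi = q[-1] + quad.trunc_q * abs(sq) + 1e-12
    r_max = Rn[-1]
    if not (np.isfinite(q_hi) and np.isfinite(r_max)):
        return np.full(q.size, np.nan)
    n_dense = int(np.ceil(6.0 * q_hi * r_max)) + 8
    if n_dense > 100_000:
        # absurd shape parameters (warm-up excursions): flag as invalid
        # rather than allocating an enormous quadrature grid
        return np.full(q.size, np.nan)
    n_dense = max(n_dense, 64)
    qd = np.linspace(0.0, q_hi, n_dense)
    g = _shape_kernel(qd[:, None] * Rn[None, :])  # (n_dense, nR)
    S = 9.0 * (g @ wV2) / wV2_sum
    spline = CubicSpline(qd, S)
    qs = np.abs(q[None, :] + sq * u[:, None])  # fold: S is even
    return uw @ spline(qs)


def saxs_intensity(
    params: np.ndarray,
    q: np.ndarray,
    quad: QuadratureSpec = QuadratureSpec(),
) -> np.ndarray:
    """Model intensity for parameters (I0, Ib, R, sigma_R, sigma_q).

    ``params`` may be a single vector (5,) or a batch (B, 5); returns
    (nq,) or (B, nq) accordingly.  Batch rows sharing the same shape
    triple (R, sigma_R, sigma_q) reuse one quadrature evaluation, so a
    finite-difference batch costs little more than the distinct shapes
    it probes.
    """
    p = np.atleast_2d(np.asarray(params, dtype=float))
    single = np.asarray(params).ndim == 1
    q = np.asarray(q, dtype=float)
    if np.any(p[:, 2] <= 0) or np.any(p[:, 3] <= 0):
        raise ValueError("R and sigma_R must be positive")
    out = np.empty((p.shape[0], q.size))
    cache: dict[tuple, np.ndarray] = {}
    for b, (I0, Ib, R, sR, sq) in enumerate(p):
        key = (R, sR, sq)
        frac = cache.get(key)
        if frac is None:
            frac = _normalized_fraction(q, R, sR, sq, quad)
            cache[key] = frac
        out[b] = I0 * frac + Ib
    return out[0] if single else out


def _shape_kernel_pair(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """g(x) and g'(x) sharing one sin/cos evaluation.

    g = [(sin x - x cos x)/x^3]^2;  g' = (2 sw x sin x - 6 sw^2 / x) / x^6
    with sw = sin x - x cos x.  Small |x| via the series.
    """
    c = np.cos(x)
    s = np.sin(x)
    sw = s - x * c
    small = np.abs(x) < 1e-3
    xs = np.where(small, 1.0, x)
    x3 = xs * xs * xs
    g = (sw / x3) ** 2
    gp = (2.0 * sw * xs * s - 6.0 * sw**2 / xs) / (x3 * x3)
    if np.any(small):
        x_s = x[small]
        g[small] = (1.0 / 9.0) * (1.0 - x_s**2 / 10.0) ** 2
        gp[small] = -(2.0 / 45.0) * x_s
    return g, gp


class PolydisperseSphereModel(ForwardModel):
    """Forward-model wrapper exposing the SAXS intensity to the likelihood.

    Provides the exact parameter Jacobian alongside the prediction: the
    size and resolution integrals are explicit quadratures, so their
    derivatives w.r.t. (I0, Ib, R, sigma_R, sigma_q) follow analytically
    from the same dense-grid kernel pass (including quadrature-node
    motion with R and sigma_R).
    """

    param_names = SAXS_PARAM_NAMES

    def __init__(self, quad: QuadratureSpec = QuadratureSpec()):
        self.quad = quad

    def predict(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        return saxs_intensity(theta, x, self.quad)

    def predict_and_jacobian(self, theta: np.ndarray, x: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
        from scipy.interpolate import CubicSpline

        quad = self.quad
        q = np.asarray(x, float)
        I0, Ib, R, sR, sq = (float(v) for v in np.asarray(theta, float))
        if not np.all(np.isfinite(np.asarray(theta, float))):
            return np.full(q.size, np.nan), np.full((q.size, 5), np.nan)
        if R <= 0 or sR <= 0:
            raise ValueError("R and sigma_R must be positive")
        t, glw = _leggauss_cached(quad.n_nodes_R)
        lo_raw = R - quad.trunc_R * sR
        clipped = lo_raw < 1e-12
        lo = max(lo_raw, 1e-12)
        hi = R + quad.trunc_R * sR
        Rn = 0.5 * (hi + lo) + 0.5 * (hi - lo) * t
        # node motion: dRn/dR and dRn/dsigma_R (window edges move)
        dlo_dR, dhi_dR = (0.0 if clipped else 1.0), 1.0
        dlo_ds = 0.0 if clipped else -quad.trunc_R
        dhi_ds = quad.trunc_R
        dRn_dR = 0.5 * (dhi_dR + dlo_dR) + 0.5 * (dhi_dR - dlo_dR) * t
        dRn_ds = 0.5 * (dhi_ds + dlo_ds) + 0.5 * (dhi_ds - dlo_ds) * t
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            tt = (Rn - R) / sR
            Nn = np.exp(-0.5 * tt**2)
            # unnormalized weight incl. V^2 (normalization cancels)
            omega = glw * Nn * Rn**6
            dt_dR = (dRn_dR - 1.0) / sR
            dt_ds = dRn_ds / sR - tt / sR
            dN_dR = -Nn * tt * dt_dR
            dN_ds = -Nn * tt * dt_ds
            dom_dR = glw * (dN_dR * Rn**6 + Nn * 6.0 * Rn**5 * dRn_dR)
            dom_ds = glw * (dN_ds * Rn**6 + Nn * 6.0 * Rn**5 * dRn_ds)
            W = omega.sum()
            W_R, W_s = dom_dR.sum(), dom_ds.sum()
        if not (np.isfinite(W) and W > 0):
            # degenerate quadrature (underflowed weights at extreme
            # sigma_R): invalid-parameter signal
            return np.full(q.size, np.nan), np.full((q.size, 5), np.nan)

        q_hi = q[-1] + quad.trunc_q * abs(sq) + 1e-12
        n_dense = int(np.ceil(6.0 * q_hi * Rn[-1])) + 8
        if n_dense > 100_000:
            nan = np.full(q.size, np.nan)
            return nan, np.full((q.size, 5), np.nan)
        n_dense = max(n_dense, 64)
        qd = np.linspace(0.0, q_hi, n_dense)
        g, gp = _shape_kernel_pair(qd[:, None] * Rn[None, :])
        A = g @ omega
        A_R = g @ dom_dR + (gp * qd[:, None]) @ (omega * dRn_dR)
        A_s = g @ dom_ds + (gp * qd[:, None]) @ (omega * dRn_ds)
        S = 9.0 * A / W
        S_R = 9.0 * (A_R * W - A * W_R) / W**2
        S_s = 9.0 * (A_s * W - A * W_s) / W**2
        sp = CubicSpline(qd, np.column_stack([S, S_R, S_s]))
        u, uw = _q_kernel(quad)
        qraw = q[None, :] + sq * u[:, None]
        qs = np.abs(qraw)
        vals = sp(qs)  # (nu, nq, 3)
        F = uw @ vals[:, :, 0]
        dF_dR = uw @ vals[:, :, 1]
        dF_ds = uw @ vals[:, :, 2]
        Sprime = sp.derivative()(qs)[:, :, 0] * np.sign(qraw)
        dF_dsq = (uw[:, None] * Sprime * u[:, None]).sum(axis=0)
        f = I0 * F + Ib
        J = np.empty((q.size, 5))
        J[:, 0] = F
        J[:, 1] = 1.0
        J[:, 2] = I0 * dF_dR
        J[:, 3] = I0 * dF_ds
        J[:, 4] = I0 * dF_dsq
        return f, J


def default_q_grid(n: int = 100, q_min: float = 0.002, q_max: float = 0.05
                   ) -> np.ndarray:
    """Log-spaced q grid covering the sphere-oscillation regime for R ~ 760 A."""
    return np.geomspace(q_min, q_max, n)
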