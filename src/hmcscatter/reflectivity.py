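"""Specular X-ray reflectivity of a smeared multilayer (effective-density
model) computed by dynamical (Parratt) recursion.

In the conventional box model interfacial roughness enters as a
Debye-Waller-like damping of each Fresnel coefficient, which is valid
only while layer thicknesses greatly exceed the roughnesses.  The
effective-density model instead builds a continuous dispersion-depth
profile delta(z) from error-function-smeared interfaces,

    delta(z) = sum_j delta_j w_j(z),
    w_j(z) = 1/2 [erf((z - Z_{j-1}) / (sqrt(2) s_{j-1}))
                  - erf((z - Z_j) / (sqrt(2) s_j))],

(with the ambient and substrate taking the open-ended weights), so that
layer material may penetrate deeply into its neighbours; the weights sum
to 1 at every depth.  The profile is sliced into thin uniform slabs and
the reflectivity is obtained from the exact recursive Fresnel solution,
valid for arbitrarily rough, thin stacks.

Geometry: ambient (water) on top, layers ordered top -> bottom, then the
substrate (Si).  Depth z increases into the film, z = 0 at the
ambient/first-layer interface.  q = 4 pi sin(theta) / lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .likelihood import ForwardModel

__all__ = [
    "Layer",
    "LayerStack",
    "DispersionProfile",
    "effective_density_profile",
    "slice_profile",
    "parratt_reflectivity",
    "reflectivity_curve",
    "BilayerReflectivityModel",
    "delta_from_electron_density",
    "WATER_DELTA_20KEV",
    "SI_DELTA_20KEV",
    "LAMBDA_20KEV",
]

R_E = 2.8179403262e-5  # classical electron radius, Angstrom
LAMBDA_20KEV = 0.6199  # Angstrom


def delta_from_electron_density(rho_e: float, lam: float) -> float:
    """Dispersion delta = r_e lambda^2 rho_e / (2 pi) (rho_e in e/A^3)."""
    return R_E * lam**2 * rho_e / (2.0 * np.pi)


WATER_DELTA_20KEV = delta_from_electron_density(0.3344, LAMBDA_20KEV)
SI_DELTA_20KEV = delta_from_electron_density(0.6993, LAMBDA_20KEV)


@dataclass
class Layer:
    """One box layer: thickness, dispersion, upper-interface roughness."""

    thickness: float  # Angstrom
    delta: float
    roughness: float  # sigma of the interface above this layer, Angstrom
    beta: float = 0.0  # absorption index, optional

    def __post_init__(self) -> None:
        if self.thickness < 0 or self.roughness < 0:
            raise ValueError("thickness and roughness must be non-negative")


@dataclass
class LayerStack:
    """Ambient / layers / substrate with an intensity scale.

    ``substrate_roughness`` is the interface between the last layer and
    the substrate.  Three-layer (outer head, tail, inner head) and
    four-layer (+ water cushion) lipid-bilayer presets are provided by
    :func:`bilayer_stack`.
    """

    layers: list[Layer]
    ambient_delta: float = WATER_DELTA_20KEV
    substrate_delta: float = SI_DELTA_20KEV
    substrate_roughness: float = 3.0
    ambient_beta: float = 0.0
    substrate_beta: float = 0.0
    I0: float = 1.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")

    @property
    def interface_positions(self) -> np.ndarray:
        """Depths of the K+1 interfaces (z=0 at ambient/layer 1)."""
        th = np.array([ly.thickness for ly in self.layers])
        return np.concatenate([[0.0], np.cumsum(th)])

    @property
    def interface_roughnesses(self) -> np.ndarray:
        return np.array([ly.roughness for ly in self.layers]
                        + [self.substrate_roughness])


@dataclass
class DispersionProfile:
    """delta(z) (and beta(z)) on a depth grid increasing into the film."""

    z: np.ndarray
    delta: np.ndarray
    beta: np.ndarray | None = None


def _interface_erfs(z: np.ndarray, positions: np.ndarray,
                    sigmas: np.ndarray) -> np.ndarray:
    """erf((z - Z_j)/(sqrt(2) s_j)) for each interface; sharp if s_j = 0."""
    out = np.empty((positions.size, z.size))
    for j, (Z, s) in enumerate(zip(positions, sigmas)):
        if s > 0:
            out[j] = erf((z - Z) / (np.sqrt(2.0) * s))
        else:
            out[j] = np.where(z > Z, 1.0, np.where(z < Z, -1.0, 0.0))
    return out


def layer_weights(stack: LayerStack, z: np.ndarray) -> np.ndarray:
    """Smeared occupation weights, rows = (ambient, layers..., substrate).

    The telescoping erf construction sums to 1 identically at every z;
    an explicit renormalization guards against roundoff.
    """
    z = np.asarray(z, dtype=float)
    E = _interface_erfs(z, stack.interface_positions,
                        stack.interface_roughnesses)
    K = len(stack.layers)
    w = np.empty((K + 2, z.size))
    w[0] = 0.5 * (1.0 - E[0])
    for j in range(K):
        w[j + 1] = 0.5 * (E[j] - E[j + 1])
    w[K + 1] = 0.5 * (1.0 + E[K])
    return w / w.sum(axis=0, keepdims=True)


def effective_density_profile(stack: LayerStack, z: np.ndarray
                              ) -> DispersionProfile:
    """Continuous smeared dispersion profile induced by the box parameters."""
    z = np.asarray(z, dtype=float)
    w = layer_weights(stack, z)
    deltas = np.array([stack.ambient_delta]
                      + [ly.delta for ly in stack.layers]
                      + [stack.substrate_delta])
    betas = np.array([stack.ambient_beta]
                     + [ly.beta for ly in stack.layers]
                     + [stack.substrate_beta])
    return DispersionProfile(z, deltas @ w, betas @ w)


def default_z_grid(stack: LayerStack, dz: float = 0.5,
                   pad_sigmas: float = 4.0) -> np.ndarray:
    """Slicing window extending pad_sigmas x max roughness past the
    outermost interfaces."""
    pos = stack.interface_positions
    smax = float(np.max(stack.interface_roughnesses))
    lo = pos[0] - pad_sigmas * max(smax, 1.0)
    hi = pos[-1] + pad_sigmas * max(smax, 1.0)
    n = max(int(np.ceil((hi - lo) / dz)), 2)
    return np.linspace(lo, hi, n + 1)


def slice_profile(profile: DispersionProfile) -> tuple[np.ndarray, np.ndarray,
                                                       np.ndarray]:
    """Uniform thin slabs from a profile: (delta_mid, beta_mid, dz)."""
    z = profile.z
    dmid = 0.5 * (profile.delta[:-1] + profile.delta[1:])
    if profile.beta is None:
        bmid = np.zeros_like(dmid)
    else:
        bmid = 0.5 * (profile.beta[:-1] + profile.beta[1:])
    return dmid, bmid, np.diff(z)


def parratt_reflectivity(
    slab_delta: np.ndarray,
    slab_thickness: np.ndarray,
    q: np.ndarray,
    lam: float,
    ambient_delta: float = 0.0,
    substrate_delta: float = 0.0,
    slab_beta: np.ndarray | None = None,
    ambient_beta: float = 0.0,
    substrate_beta: float = 0.0,
) -> np.ndarray:
    """|r|^2 of a slab stack by the recursive Fresnel (Parratt) solution.

    ``slab_delta`` may be (M,) or a batch (B, M) sharing one thickness
    vector; returns (nq,) or (B, nq).  Interfaces between slabs are
    sharp — roughness is carried by the sliced effective-density profile.
    Below the critical angle of a non-absorbing substrate the result is
    exactly 1 (total external reflection).
    """
    q = np.asarray(q, dtype=float)
    d = np.atleast_2d(np.asarray(slab_delta, dtype=float))
    single = np.asarray(slab_delta).ndim == 1
    B, M = d.shape
    th = np.asarray(slab_thickness, dtype=float)
    k0 = 2.0 * np.pi / lam
    s2 = (q * lam / (4.0 * np.pi)) ** 2  # sin^2(theta), (nq,)

    # media 0..M+1 = ambient, slabs, substrate
    deltas = np.empty((B, M + 2))
    deltas[:, 0] = ambient_delta
    deltas[:, 1:M + 1] = d
    deltas[:, M + 1] = substrate_delta
    absorbing = (slab_beta is not None and np.any(slab_beta)) or ambient_beta \
        or substrate_beta
    arg = s2[None, None, :] - 2.0 * deltas[:, :, None]
    if absorbing:
        betas = np.zeros((B, M + 2))
        if slab_beta is not None:
            betas[:, 1:M + 1] = np.atleast_2d(slab_beta)
        betas[:, 0] = ambient_beta
        betas[:, M + 1] = substrate_beta
        kz = k0 * np.sqrt(arg + 2j * betas[:, :, None])
    else:
        # principal branch with Im >= 0, via two cheap real square roots
        kz = k0 * (np.sqrt(np.maximum(arg, 0.0))
                   + 1j * np.sqrt(np.maximum(-arg, 0.0)))
    rf = (kz[:, :-1] - kz[:, 1:]) / (kz[:, :-1] + kz[:, 1:])  # (B, M+1, nq)
    r = rf[:, M].copy()
    if M:
        phase = np.exp((2j * th[None, :, None]) * kz[:, 1:M + 1])
        for j in range(M - 1, -1, -1):
            rp = r * phase[:, j]
            r = (rf[:, j] + rp) / (1.0 + rf[:, j] * rp)
    R = np.abs(r) ** 2
    return R[0] if single else R


def parratt_with_gradient(
    slab_delta: np.ndarray,
    slab_thickness: np.ndarray,
    q: np.ndarray,
    lam: float,
    ambient_delta: float = 0.0,
    substrate_delta: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Reflectivity and its exact gradient w.r.t. every slab dispersion.

    Adjoint (reverse-mode) differentiation of the Parratt recursion: the
    recursion is holomorphic in the slab dispersions, so one forward and
    one backward sweep yield dR/d delta_m for all M slabs at the cost of
    a few forward evaluations — the numerical-gradient route would need
    2M forward solves.  Non-absorbing media only.  Returns
    (R (nq,), dR (M, nq)).
    """
    q = np.asarray(q, dtype=float)
    d = np.asarray(slab_delta, dtype=float)
    th = np.asarray(slab_thickness, dtype=float)
    M = d.size
    k0 = 2.0 * np.pi / lam
    s2 = (q * lam / (4.0 * np.pi)) ** 2
    deltas = np.concatenate([[ambient_delta], d, [substrate_delta]])
    arg = s2[None, :] - 2.0 * deltas[:, None]
    kz = k0 * (np.sqrt(np.maximum(arg, 0.0))
               + 1j * np.sqrt(np.maximum(-arg, 0.0)))  # (M+2, nq)
    S = kz[:-1] + kz[1:]
    rf = (kz[:-1] - kz[1:]) / S  # (M+1, nq)
    p = np.exp((2j * th[:, None]) * kz[1:M + 1])  # (M, nq)
    # forward sweep, storing r^(j) at every interface
    r_all = np.empty((M + 1, q.size), dtype=complex)
    r_all[M] = rf[M]
    c_all = np.empty((M, q.size), dtype=complex)
    D_all = np.empty((M, q.size), dtype=complex)
    for j in range(M - 1, -1, -1):
        c = r_all[j + 1] * p[j]
        D = 1.0 + rf[j] * c
        c_all[j], D_all[j] = c, D
        r_all[j] = (rf[j] + c) / D
    r0 = r_all[0]
    R = np.abs(r0) ** 2
    if M == 0:
        return R, np.empty((0, q.size))
    # backward sweep: lam_j = d r0 / d r^(j)
    grad_rf = np.empty((M + 1, q.size), dtype=complex)
    grad_p = np.empty((M, q.size), dtype=complex)
    lam_j = np.ones(q.size, dtype=complex)
    for j in range(M):
        inv_D2 = 1.0 / (D_all[j] * D_all[j])
        a = lam_j * (1.0 - rf[j] * rf[j]) * inv_D2  # d r0 / d c_j
        grad_rf[j] = lam_j * (1.0 - c_all[j] * c_all[j]) * inv_D2
        grad_p[j] = a * r_all[j + 1]
        lam_j = a * p[j]
    grad_rf[M] = lam_j
    # assemble d r0 / d kz_m for the slab media m = 1..M
    kz_s = kz[1:M + 1]
    g_kz = (grad_rf[:M] * (-2.0 * kz[:M] / (S[:M] * S[:M]))
            + grad_rf[1:M + 1] * (2.0 * kz[2:M + 2] / (S[1:M + 1] * S[1:M + 1]))
            + grad_p * (2j * th[:, None]) * p)
    dr0_ddelta = g_kz * (-(k0**2) / kz_s)
    dR = 2.0 * np.real(np.conj(r0)[None, :] * dr0_ddelta)
    return R, dR


def merge_slabs(delta: np.ndarray, thickness: np.ndarray,
                tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge consecutive thin slabs whose dispersion varies by < tol.

    Exact for plateau regions (constant-delta stretches collapse to one
    slab); returns (segment starts, merged delta, merged thickness) for
    a single reference profile.  Used to compress the fine uniform
    slicing before the recursive reflectivity computation.
    """
    n = delta.size
    starts = [0]
    lo = hi = delta[0]
    for k in range(1, n):
        v = delta[k]
        lo, hi = min(lo, v), max(hi, v)
        if hi - lo > tol:
            starts.append(k)
            lo = hi = v
    starts = np.asarray(starts)
    counts = np.diff(np.append(starts, n))
    dm = np.add.reduceat(delta * thickness, starts) \
        / np.add.reduceat(thickness, starts)
    tm = np.add.reduceat(thickness, starts)
    return starts, dm, tm


def reflectivity_curve(
    stack: LayerStack,
    q: np.ndarray,
    lam: float = LAMBDA_20KEV,
    dz: float = 0.5,
) -> np.ndarray:
    """I(q) = I0 * Parratt(slice(effective_density_profile(stack)))."""
    z = default_z_grid(stack, dz)
    prof = effective_density_profile(stack, z)
    dmid, bmid, thick = slice_profile(prof)
    R = parratt_reflectivity(
        dmid, thick, q, lam,
        ambient_delta=stack.ambient_delta, substrate_delta=stack.substrate_delta,
        slab_beta=bmid, ambient_beta=stack.ambient_beta,
        substrate_beta=stack.substrate_beta,
    )
    return stack.I0 * R


# --- lipid-bilayer fitting model -------------------------------------------

BILAYER3_PARAM_NAMES = (
    "I0", "sigma_Si", "h_o", "h_t", "h_i",
    "delta_o", "delta_t", "delta_i", "sigma_o", "sigma_t", "sigma_i",
)
BILAYER4_PARAM_NAMES = (
    "I0", "sigma_Si", "h_o", "h_t", "h_i", "h_w",
    "delta_o", "delta_t", "delta_i", "delta_w",
    "sigma_o", "sigma_t", "sigma_i", "sigma_w",
)


def bilayer_stack(params: dict[str, float], n_layers: int = 3,
                  lam: float = LAMBDA_20KEV) -> LayerStack:
    """Supported-bilayer stack in water on Si.

    Three layers: outer head, hydrocarbon tail, inner head; the
    four-layer variant adds a water-cushion layer between the inner head
    and the substrate.
    """
    layers = [
        Layer(params["h_o"], params["delta_o"], params["sigma_o"]),
        Layer(params["h_t"], params["delta_t"], params["sigma_t"]),
        Layer(params["h_i"], params["delta_i"], params["sigma_i"]),
    ]
    if n_layers == 4:
        layers.append(Layer(params["h_w"], params["delta_w"],
                            params["sigma_w"]))
    elif n_layers != 3:
        raise ValueError("bilayer preset supports 3 or 4 layers")
    return LayerStack(
        layers,
        ambient_delta=delta_from_electron_density(0.3344, lam),
        substrate_delta=delta_from_electron_density(0.6993, lam),
        substrate_roughness=params["sigma_Si"],
        I0=params.get("I0", 1.0),
    )


class BilayerReflectivityModel(ForwardModel):
    """Reflectivity of the supported lipid bilayer as a fit model.

    Parameter order follows ``param_names``; the residual variance is
    appended by the likelihood layer, not here.
    """

    def __init__(self, n_layers: int = 3, lam: float = LAMBDA_20KEV,
                 dz: float = 0.5):
        if n_layers not in (3, 4):
            raise ValueError("n_layers must be 3 or 4")
        self.n_layers = n_layers
        self.lam = lam
        self.dz = dz
        self.param_names = (BILAYER3_PARAM_NAMES if n_layers == 3
                            else BILAYER4_PARAM_NAMES)

    def _stack(self, theta: np.ndarray) -> LayerStack:
        params = dict(zip(self.param_names, theta))
        return bilayer_stack(params, self.n_layers, self.lam)

    def predict(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        th = np.atleast_2d(np.asarray(theta, dtype=float))
        single = np.asarray(theta).ndim == 1
        q = np.asarray(x, float)
        # batch rows sharing identical stack parameters (columns past I0)
        # reuse one reflectivity computation
        out = np.empty((th.shape[0], q.size))
        keys = [tuple(row[1:]) for row in th]
        uniq: dict[tuple, int] = {}
        rows = []
        for k, row in zip(keys, th):
            if k not in uniq:
                uniq[k] = len(rows)
                rows.append(row)
        R = self._reflectivity_batch(np.array(rows), q)
        for b, k in enumerate(keys):
            out[b] = th[b, 0] * R[uniq[k]]
        return out[0] if single else out

    def _reflectivity_batch(self, th: np.ndarray, q: np.ndarray) -> np.ndarray:
        stacks = [self._stack(row) for row in th]
        # shared z window so the whole batch runs one Parratt recursion
        smax = max(float(np.max(s.interface_roughnesses)) for s in stacks)
        depth = max(float(s.interface_positions[-1]) for s in stacks)
        z = self._z_edges(smax, depth)
        if z is None:
            return np.full((th.shape[0], q.size), np.nan)
        dmid = np.empty((th.shape[0], z.size - 1))
        for b, s in enumerate(stacks):
            prof = effective_density_profile(s, z)
            dmid[b] = 0.5 * (prof.delta[:-1] + prof.delta[1:])
        return parratt_reflectivity(
            dmid, np.diff(z), q, self.lam,
            ambient_delta=stacks[0].ambient_delta,
            substrate_delta=stacks[0].substrate_delta,
        )

    def _z_edges(self, smax: float, depth: float) -> np.ndarray:
        """Slicing window on a fixed dz lattice.

        Anchoring every slab boundary to multiples of dz keeps the
        discretization error a smooth function of the stack parameters:
        window growth only adds padding slabs of ambient/substrate
        material, which have no optical effect.
        """
        if not (np.isfinite(smax) and np.isfinite(depth)):
            return None
        pad = 4.0 * max(smax, 1.0)
        lo = -np.ceil(pad / self.dz) * self.dz
        hi = np.ceil((depth + pad) / self.dz) * self.dz
        n = max(int(round((hi - lo) / self.dz)), 2)
        if n > 100_000:
            # absurd stack parameters (warm-up excursions): flag invalid
            return None
        return lo + self.dz * np.arange(n + 1)

    def predict_and_jacobian(self, theta: np.ndarray, x: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
        """Curve and its exact parameter Jacobian (nq, P).

        Chains the adjoint Parratt gradient (dR per slab dispersion)
        through the analytic derivatives of the smeared effective-density
        profile w.r.t. thicknesses, dispersions and roughnesses.  The
        slab thicknesses and the slicing window are treated as fixed for
        the evaluation; the padding slabs carry ambient/substrate
        dispersion, so the window choice itself has no effect on R.
        """
        theta = np.asarray(theta, dtype=float)
        q = np.asarray(x, float)
        names = self.param_names
        K = self.n_layers
        stack = self._stack(theta)
        Z = stack.interface_positions            # (K+1,)
        sig = stack.interface_roughnesses        # (K+1,)
        med_delta = np.array([stack.ambient_delta]
                             + [ly.delta for ly in stack.layers]
                             + [stack.substrate_delta])  # (K+2,)
        z = self._z_edges(float(sig.max()), float(Z[-1]))
        if z is None:
            return (np.full(q.size, np.nan),
                    np.full((q.size, len(names)), np.nan))
        w = layer_weights(stack, z)              # (K+2, nz)
        profile = med_delta @ w
        # d profile / d E_j and the erf kernels per interface
        pE = 0.5 * (med_delta[1:] - med_delta[:-1])  # (K+1,)
        safe = np.where(sig > 0, sig, 1.0)[:, None]
        t = (z[None, :] - Z[:, None]) / (np.sqrt(2.0) * safe)
        gauss = np.exp(-t**2) * (sig > 0)[:, None]  # (K+1, nz)
        dE_dZ = -np.sqrt(2.0 / np.pi) / safe * gauss
        dE_ds = (2.0 / np.sqrt(np.pi)) * gauss * (-t) / safe
        P = len(names)
        dprof = np.zeros((P, z.size))
        ih = {f"h_{s}": k for k, s in zip(range(1, K + 1),
                                          ("o", "t", "i", "w"))}
        isig = {"sigma_o": 0, "sigma_t": 1, "sigma_i": 2, "sigma_w": 3,
                "sigma_Si": K}
        for pidx, name in enumerate(names):
            if name == "I0":
                continue
            if name.startswith("delta_"):
                layer = 1 + ("o", "t", "i", "w").index(name[6:])
                dprof[pidx] = w[layer]
            elif name.startswith("h_"):
                k = ih[name]
                dprof[pidx] = np.sum(pE[k:, None] * dE_dZ[k:], axis=0)
            else:  # roughness
                j = isig[name]
                dprof[pidx] = pE[j] * dE_ds[j]
        dmid = 0.5 * (profile[:-1] + profile[1:])
        dprof_mid = 0.5 * (dprof[:, :-1] + dprof[:, 1:])  # (P, M)
        R, dR = parratt_with_gradient(
            dmid, np.diff(z), q, self.lam,
            ambient_delta=stack.ambient_delta,
            substrate_delta=stack.substrate_delta)
        I0 = theta[0]
        f = I0 * R
        J = I0 * (dprof_mid @ dR).T               # (nq, P)
        J[:, 0] = R
        return f, J
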