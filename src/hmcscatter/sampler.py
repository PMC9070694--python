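"""Gradient-based MCMC engine.

Hamiltonian Monte Carlo with leapfrog integration and Metropolis
correction, a No-U-Turn sampler (slice variant) that automates the
trajectory length, Nesterov dual-averaging step-size adaptation,
diagonal mass-matrix preconditioning, constraint reflection, and a
random-walk Metropolis baseline.

The sampler augments the parameter vector x with an auxiliary momentum p
drawn from N(0, M) and evolves the Hamiltonian H(x, p) = U(x) + K(p),
K(p) = p' M^{-1} p / 2, by the time-reversible, volume-preserving
leapfrog integrator.  A Metropolis test with probability
min{1, exp(H_old - H_new)} corrects the discretization error; the
momentum-distribution normalization constant is dropped throughout as it
cancels in the acceptance ratio for a fixed mass matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "MassMatrix",
    "PhaseState",
    "SamplerConfig",
    "Chain",
    "DualAveraging",
    "sample_momentum",
    "kinetic_energy",
    "leapfrog_step",
    "hmc_draw",
    "nuts_draw",
    "dual_averaging_update",
    "adapt_mass_matrix",
    "run_chain",
    "reflect_at_constraint",
    "rw_proposal_scale",
]


class MassMatrix:
    """Momentum covariance M (diagonal vector or full SPD matrix).

    Momenta are proposed as p ~ N(0, M); the kinetic energy uses M^{-1}.
    Diagonal form stores the diagonal; full form keeps a Cholesky factor.
    """

    def __init__(self, value: np.ndarray | float | None = None, n: int | None = None):
        if value is None:
            if n is None:
                raise ValueError("identity mass needs the dimension n")
            value = np.ones(n)
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            if n is None:
                raise ValueError("scalar mass needs the dimension n")
            arr = np.full(n, float(arr))
        if arr.ndim == 1:
            if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
                raise ValueError("diagonal mass entries must be positive finite")
            self.diag: np.ndarray | None = arr
            self._chol: np.ndarray | None = None
            self._inv: np.ndarray | None = None
            self.n = arr.size
        elif arr.ndim == 2:
            if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
                raise ValueError("full mass matrix must be square symmetric")
            try:
                self._chol = np.linalg.cholesky(arr)
            except np.linalg.LinAlgError as err:
                raise ValueError("mass matrix must be positive definite") from err
            self.diag = None
            self._inv = np.linalg.inv(arr)
            self.n = arr.shape[0]
        else:
            raise ValueError("mass must be a vector (diagonal) or matrix")

    @classmethod
    def identity(cls, n: int) -> "MassMatrix":
        return cls(np.ones(n))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Draw p ~ N(0, M)."""
        if self.n == 0:
            return np.empty(0)
        zn = rng.standard_normal(self.n)
        if self.diag is not None:
            return np.sqrt(self.diag) * zn
        return self._chol @ zn

    def solve(self, p: np.ndarray) -> np.ndarray:
        """M^{-1} p (the velocity)."""
        if self.diag is not None:
            return p / self.diag
        return self._inv @ p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.solve(p))


def sample_momentum(mass: MassMatrix, rng: np.random.Generator) -> np.ndarray:
    """Momentum refresh: a zero-mean multivariate normal with covariance M."""
    return mass.sample(rng)


def kinetic_energy(p: np.ndarray, mass: MassMatrix) -> float:
    """K(p) = p' M^{-1} p / 2 (normalization constant dropped)."""
    p = np.asarray(p, dtype=float)
    if p.size != mass.n:
        raise ValueError("momentum and mass dimensions disagree")
    return mass.kinetic(p)


@dataclass
class PhaseState:
    """A point in the augmented state space with cached energies/gradient."""

    position: np.ndarray
    momentum: np.ndarray
    potential: float
    kinetic: float
    grad: np.ndarray | None = None

    @property
    def hamiltonian(self) -> float:
        return self.potential + self.kinetic


@dataclass
class SamplerConfig:
    """Sampler settings shared by all kernels.

    ``n_leapfrog`` is the fixed trajectory length for plain HMC;
    ``max_depth`` bounds the NUTS binary-tree doubling.  Adaptation (dual
    averaging of the step size, mass estimation) runs only during the
    first ``n_burn_in`` iterations.
    """

    step_size: float = 0.1
    n_leapfrog: int = 10
    n_iterations: int = 1000
    n_burn_in: int = 200
    seed: int = 0
    adaptation: Literal["none", "dual_averaging"] = "dual_averaging"
    target_accept: float = 0.8
    mass_strategy: Literal[
        "identity", "inverse_variance_diag", "gradient_scaled_diag"
    ] = "identity"
    max_depth: int = 10
    divergence_threshold: float = 1000.0

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.n_burn_in >= self.n_iterations:
            raise ValueError("n_burn_in must be smaller than n_iterations")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class Chain:
    """Ordered draws with acceptance flags and adaptation history."""

    draws: np.ndarray  # (n_iterations, N) sampling-scale positions
    accepted: np.ndarray  # bool per draw
    energy_before: np.ndarray  # H at trajectory start
    energy_after: np.ndarray  # H at proposed/selected state
    step_size_trace: np.ndarray
    divergent: np.ndarray  # bool per draw
    burn_in_index: int
    mass: MassMatrix | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.draws.shape[0]
        for name in ("accepted", "energy_before", "energy_after",
                     "step_size_trace", "divergent"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length inconsistent with draws")

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[0]

    @property
    def n_dim(self) -> int:
        return self.draws.shape[1]

    def posterior(self) -> np.ndarray:
        """Post-burn-in draws (sampling scale)."""
        return self.draws[self.burn_in_index:]

    @property
    def acceptance_rate(self) -> float:
        post = self.accepted[self.burn_in_index:]
        return float(np.mean(post)) if post.size else float("nan")

    @property
    def n_divergent(self) -> int:
        return int(np.sum(self.divergent))


class DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman–Gelman constants).

    Drives the mean acceptance statistic toward ``target_accept``;
    ``adapted_step`` holds the running averaged value at which the step
    size is frozen after burn-in.
    """

    def __init__(
        self,
        eps0: float,
        target_accept: float = 0.8,
        gamma: float = 0.05,
        t0: float = 10.0,
        kappa: float = 0.75,
    ) -> None:
        self.mu = math.log(10.0 * eps0)
        self.target_accept = target_accept
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0

    def update(self, accept_stat: float) -> float:
        """One adaptation step; returns the new step size."""
        accept_stat = min(1.0, max(0.0, accept_stat))
        self.t += 1
        eta = 1.0 / (self.t + self.t0)
        self.h_bar = (1.0 - eta) * self.h_bar + eta * (self.target_accept - accept_stat)
        self.log_eps = self.mu - math.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1.0 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    @property
    def step_size(self) -> float:
        return math.exp(self.log_eps)

    @property
    def adapted_step(self) -> float:
        return math.exp(self.log_eps_bar)


def dual_averaging_update(
    adapt_state: DualAveraging, accept_stat: float, iteration: int | None = None
) -> tuple[DualAveraging, float]:
    """Functional wrapper around :meth:`DualAveraging.update`."""
    eps = adapt_state.update(accept_stat)
    return adapt_state, eps


def leapfrog_step(
    state: PhaseState,
    eps: float,
    target,
    mass: MassMatrix,
) -> PhaseState:
    """One leapfrog step: half-kick, drift, half-kick.

    ``target`` must provide ``value_and_grad``.  The gradient at the
    current position is cached on the state so consecutive steps cost one
    gradient evaluation each.  A non-finite gradient or potential yields
    a state with infinite potential (divergent-trajectory signal).
    """
    if state.grad is None:
        u, g = target.value_and_grad(state.position)
        state = PhaseState(state.position, state.momentum, u, state.kinetic, g)
    g = state.grad
    if not np.all(np.isfinite(g)):
        return PhaseState(state.position, state.momentum, np.inf, state.kinetic, g)
    p_half = state.momentum - 0.5 * eps * g
    x_new = state.position + eps * mass.solve(p_half)
    u_new, g_new = target.value_and_grad(x_new)
    if not (np.isfinite(u_new) and np.all(np.isfinite(g_new))):
        return PhaseState(x_new, p_half, np.inf, mass.kinetic(p_half), None)
    p_new = p_half - 0.5 * eps * g_new
    return PhaseState(x_new, p_new, u_new, mass.kinetic(p_new), g_new)


def _fresh_state(x, p, target, mass) -> PhaseState:
    u, g = target.value_and_grad(x)
    return PhaseState(np.asarray(x, float), p, u, mass.kinetic(p), g)


def hmc_draw(
    x: np.ndarray,
    cfg: SamplerConfig,
    target,
    mass: MassMatrix,
    rng: np.random.Generator,
    eps: float | None = None,
) -> tuple[np.ndarray, bool, float, bool]:
    """One fixed-length HMC iteration.

    Returns (new position, accepted, Delta H, divergent).  A divergent
    trajectory (non-finite energy or |Delta H| above threshold) is
    rejected and flagged; the previous position is retained.
    """
    x_new, acc, dh, div, _, _ = _hmc_draw_full(x, cfg, target, mass, rng, eps)
    return x_new, acc, dh, div


def _hmc_draw_full(x, cfg, target, mass, rng, eps=None):
    """hmc_draw returning also (H_before, H_after)."""
    eps = cfg.step_size if eps is None else eps
    p0 = sample_momentum(mass, rng)
    state = _fresh_state(x, p0, target, mass)
    h0 = state.hamiltonian
    if not np.isfinite(h0):
        raise ValueError("potential energy not finite at the current position")
    s = state
    for _ in range(cfg.n_leapfrog):
        s = leapfrog_step(s, eps, target, mass)
        if not np.isfinite(s.hamiltonian):
            return np.asarray(x, float), False, np.inf, True, h0, np.inf
    dh = s.hamiltonian - h0
    if abs(dh) > cfg.divergence_threshold:
        return np.asarray(x, float), False, dh, True, h0, s.hamiltonian
    if math.log(rng.uniform()) < -dh:
        return s.position, True, dh, False, h0, s.hamiltonian
    return np.asarray(x, float), False, dh, False, h0, s.hamiltonian


# --- NUTS (slice variant of Hoffman & Gelman, 2014, Algorithm 3/6) ---------


class _TreeInfo:
    __slots__ = ("minus", "plus", "proposal", "n", "stop", "divergent",
                 "alpha", "n_alpha")


def _uturn(minus: PhaseState, plus: PhaseState, mass: MassMatrix) -> bool:
    dx = plus.position - minus.position
    return (dx @ mass.solve(minus.momentum)) < 0 or (dx @ mass.solve(plus.momentum)) < 0


def _build_tree(state, logu, v, depth, eps, h0, target, mass, rng, dmax):
    info = _TreeInfo()
    if depth == 0:
        s = leapfrog_step(state, v * eps, target, mass)
        h = s.hamiltonian
        info.minus = info.plus = s
        info.proposal = s
        info.n = 1 if (np.isfinite(h) and logu <= -h) else 0
        info.divergent = (not np.isfinite(h)) or (-h < logu - dmax)
        info.stop = info.divergent
        if np.isfinite(h):
            info.alpha = min(1.0, math.exp(min(0.0, h0 - h)))
        else:
            info.alpha = 0.0
        info.n_alpha = 1
        return info
    left = _build_tree(state, logu, v, depth - 1, eps, h0, target, mass, rng, dmax)
    if left.stop:
        return left
    inner = left.plus if v == 1 else left.minus
    right = _build_tree(inner, logu, v, depth - 1, eps, h0, target, mass, rng, dmax)
    info.minus = left.minus if v == 1 else right.minus
    info.plus = right.plus if v == 1 else left.plus
    ntot = left.n + right.n
    if right.n > 0 and rng.uniform() < right.n / max(ntot, 1):
        info.proposal = right.proposal
    else:
        info.proposal = left.proposal
    info.n = ntot
    info.alpha = left.alpha * left.n_alpha / (left.n_alpha + right.n_alpha) + \
        right.alpha * right.n_alpha / (left.n_alpha + right.n_alpha)
    info.n_alpha = left.n_alpha + right.n_alpha
    info.divergent = left.divergent or right.divergent
    info.stop = right.stop or _uturn(info.minus, info.plus, mass)
    return info


def nuts_draw(
    x: np.ndarray,
    eps: float,
    target,
    mass: MassMatrix,
    max_depth: int,
    rng: np.random.Generator,
    divergence_threshold: float = 1000.0,
) -> tuple[np.ndarray, dict]:
    """One No-U-Turn draw (slice-sampling tree).

    Doubles a leapfrog trajectory in random directions until the path
    starts to retrace (U-turn criterion), a divergence occurs, or
    ``max_depth`` is reached, then returns a uniform draw from the slice
    candidate set.  Info dict carries the mean acceptance statistic used
    by dual averaging, tree depth, divergence flag and energies.
    """
    p0 = sample_momentum(mass, rng)
    init = _fresh_state(x, p0, target, mass)
    h0 = init.hamiltonian
    if not np.isfinite(h0):
        raise ValueError("potential energy not finite at the current position")
    logu = -h0 + math.log(rng.uniform())
    minus = plus = init
    proposal = init
    n = 1
    depth = 0
    divergent = False
    alpha, n_alpha = 1.0, 1
    while depth < max_depth:
        v = 1 if rng.uniform() < 0.5 else -1
        edge = plus if v == 1 else minus
        sub = _build_tree(edge, logu, v, depth, eps, h0, target, mass, rng,
                          divergence_threshold)
        if v == 1:
            plus = sub.plus
        else:
            minus = sub.minus
        divergent = divergent or sub.divergent
        alpha, n_alpha = sub.alpha, sub.n_alpha
        if not sub.stop and sub.n > 0 and rng.uniform() < sub.n / n:
            proposal = sub.proposal
        n += sub.n
        depth += 1
        if sub.stop or _uturn(minus, plus, mass):
            break
    accepted = proposal is not init
    info = {
        "accept_stat": alpha,
        "depth": depth,
        "divergent": divergent,
        "energy_before": h0,
        "energy_after": proposal.hamiltonian if accepted else h0,
        "accepted": accepted,
    }
    return proposal.position, info


def reflect_at_constraint(state: PhaseState, constraint_normal: np.ndarray) -> PhaseState:
    """Mirror the momentum about a constraint surface, kinetic energy kept.

    Householder reflection p' = p - 2 (n.p) n / (n.n) about the surface
    with outward normal n; used to bounce trajectories off a hard
    constraint without energy loss.
    """
    nvec = np.asarray(constraint_normal, dtype=float)
    norm2 = float(nvec @ nvec)
    if norm2 == 0.0:
        raise ValueError("constraint normal must be non-zero")
    p = state.momentum - 2.0 * (state.momentum @ nvec) / norm2 * nvec
    return PhaseState(state.position, p, state.potential, state.kinetic, state.grad)


def adapt_mass_matrix(
    warmup: "Chain | np.ndarray",
    strategy: str = "inverse_variance_diag",
    grad_probe: Callable[[np.ndarray], np.ndarray] | None = None,
    floor: float = 1e-12,
    n_probe: int = 20,
) -> MassMatrix:
    """Diagonal mass matrix from warm-up draws.

    ``inverse_variance_diag``: diag(1 / var_i) of the draws — the inverse
    diagonal covariance preconditioner.  ``gradient_scaled_diag``: diagonal
    proportional to the mean |dU/dx_i| over probe points, snapped to a
    small set of magnitude levels (coarse preconditioning).  Zero-variance
    coordinates are floored.
    """
    draws = warmup.posterior() if isinstance(warmup, Chain) else np.asarray(warmup, float)
    if draws.ndim != 2:
        raise ValueError("warmup draws must be a (n, N) array")
    n, N = draws.shape
    if strategy == "identity":
        return MassMatrix.identity(N)
    if strategy == "inverse_variance_diag":
        if n < 10:
            raise ValueError("need at least 10 warm-up draws for the variance strategy")
        var = np.var(draws, axis=0)
        return MassMatrix(1.0 / np.maximum(var, floor))
    if strategy == "gradient_scaled_diag":
        if grad_probe is None:
            raise ValueError("gradient strategy needs a gradient callback")
        idx = np.linspace(0, n - 1, min(n, n_probe)).astype(int)
        gmean = np.mean([np.abs(grad_probe(draws[i])) for i in idx], axis=0)
        gmean = np.maximum(gmean, floor)
        return MassMatrix(_bin_magnitudes(gmean))
    raise ValueError(f"unknown mass strategy {strategy!r}")


def _bin_magnitudes(g: np.ndarray, decade_width: float = 1.0) -> np.ndarray:
    """Snap positive values to a few representative magnitude levels.

    Values are grouped on the log10 axis into clusters separated by gaps
    wider than ``decade_width``; each cluster is replaced by its geometric
    mean rounded to one significant figure, and the smallest level is
    scaled to 1.
    """
    logs = np.log10(g)
    order = np.argsort(logs)
    labels = np.empty(g.size, dtype=int)
    lab = 0
    labels[order[0]] = 0
    for prev, cur in zip(order[:-1], order[1:]):
        if logs[cur] - logs[prev] > decade_width:
            lab += 1
        labels[cur] = lab
    out = np.empty_like(g)
    for k in range(lab + 1):
        sel = labels == k
        gm = 10.0 ** np.mean(logs[sel])
        exp10 = math.floor(math.log10(gm))
        out[sel] = round(gm / 10.0**exp10) * 10.0**exp10
    return out / out.min()


def rw_proposal_scale(draws: np.ndarray) -> np.ndarray:
    """Random-walk proposal s.d. per coordinate from reference draws.

    Diagonal of the sample covariance scaled by the classic 2.4^2/N
    optimal-scaling factor.
    """
    draws = np.asarray(draws, float)
    var = np.var(draws, axis=0)
    return np.sqrt(var * 2.4**2 / draws.shape[1])


def _rw_draw(x, scale, target, u_cur, rng):
    prop = x + scale * rng.standard_normal(x.size)
    u_prop = target.potential(prop)
    if np.isfinite(u_prop) and math.log(rng.uniform()) < u_cur - u_prop:
        return prop, True, u_prop
    return x, False, u_cur


def run_chain(
    x0: np.ndarray,
    cfg: SamplerConfig,
    target,
    kernel: Literal["hmc", "nuts", "random_walk"] = "nuts",
    rng: np.random.Generator | None = None,
    mass: MassMatrix | None = None,
    rw_scale: np.ndarray | float | None = None,
) -> Chain:
    """Run a full Markov chain with burn-in-only adaptation.

    Adaptation schedule (burn-in only): dual averaging of the step size
    throughout burn-in; when ``cfg.mass_strategy`` is non-identity and no
    mass matrix is supplied, the sampler runs the first half of burn-in
    with the identity mass, estimates the preconditioner from those
    draws (inverse diagonal variance, or gradient-magnitude scaling),
    then restarts adaptation with the new mass.  After burn-in the step
    size is frozen at the dual-averaged value and the mass is fixed.
    """
    x0 = np.asarray(x0, dtype=float)
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    N = x0.size
    if mass is None:
        mass = MassMatrix.identity(N)
        adapt_mass = cfg.mass_strategy != "identity" and cfg.n_burn_in >= 20
    else:
        adapt_mass = False

    if not np.isfinite(target.potential(x0)):
        raise ValueError("potential energy not finite at the initial position")

    n_it = cfg.n_iterations
    draws = np.empty((n_it, N))
    accepted = np.zeros(n_it, dtype=bool)
    divergent = np.zeros(n_it, dtype=bool)
    e_before = np.full(n_it, np.nan)
    e_after = np.full(n_it, np.nan)
    eps_trace = np.empty(n_it)

    if kernel == "random_walk":
        if rw_scale is None:
            rw_scale = 0.1
        scale = np.broadcast_to(np.asarray(rw_scale, float), (N,)).copy()
        x = x0.copy()
        u_cur = target.potential(x)
        for t in range(n_it):
            x, acc, u_cur = _rw_draw(x, scale, target, u_cur, rng)
            draws[t] = x
            accepted[t] = acc
            e_before[t] = u_cur
            e_after[t] = u_cur
            eps_trace[t] = 0.0
        return Chain(draws, accepted, e_before, e_after, eps_trace, divergent,
                     cfg.n_burn_in, mass=None, meta={"kernel": kernel})

    use_da = cfg.adaptation == "dual_averaging" and cfg.n_burn_in > 0
    da = DualAveraging(cfg.step_size, cfg.target_accept) if use_da else None
    eps = cfg.step_size
    mass_switch = cfg.n_burn_in // 2 if adapt_mass else -1

    x = x0.copy()
    for t in range(n_it):
        if t == mass_switch:
            window = draws[mass_switch // 2: mass_switch]
            try:
                if cfg.mass_strategy == "gradient_scaled_diag":
                    mass = adapt_mass_matrix(window, cfg.mass_strategy,
                                             grad_probe=target.gradient)
                else:
                    mass = adapt_mass_matrix(window, cfg.mass_strategy)
            except ValueError:
                mass = MassMatrix.identity(N)
            if use_da:
                da = DualAveraging(eps, cfg.target_accept)  # restart adaptation
        if kernel == "hmc":
            x_new, acc, dh, div, h0, h1 = _hmc_draw_full(x, cfg, target, mass, rng,
                                                         eps=eps)
            accept_stat = min(1.0, math.exp(min(0.0, -dh))) if np.isfinite(dh) else 0.0
            e_before[t] = h0
            e_after[t] = h1
        elif kernel == "nuts":
            x_new, info = nuts_draw(x, eps, target, mass, cfg.max_depth, rng,
                                    cfg.divergence_threshold)
            acc = info["accepted"]
            div = info["divergent"]
            accept_stat = info["accept_stat"]
            e_before[t] = info["energy_before"]
            e_after[t] = info["energy_after"]
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
        x = x_new
        draws[t] = x
        accepted[t] = acc
        divergent[t] = div
        eps_trace[t] = eps
        if t < cfg.n_burn_in:
            if use_da:
                eps = da.update(accept_stat)
            if t == cfg.n_burn_in - 1:
                if use_da:
                    eps = da.adapted_step
                if np.all(divergent[: cfg.n_burn_in]):
                    raise RuntimeError(
                        "all burn-in iterations divergent; reduce the step size "
                        "or check the gradients"
                    )
    return Chain(draws, accepted, e_before, e_after, eps_trace, divergent,
                 cfg.n_burn_in, mass=mass,
                 meta={"kernel": kernel, "final_step_size": eps})


def run_multistart(
    x0_list: Sequence[np.ndarray],
    cfg: SamplerConfig,
    target,
    kernel: str = "nuts",
    **kwargs,
) -> list[Chain]:
    """Multi-start chains: one chain per initial value, seeds offset from cfg.seed."""
    chains = []
    for i, x0 in enumerate(x0_list):
        rng = np.random.default_rng(cfg.seed + i)
        chains.append(run_chain(np.asarray(x0, float), cfg, target, kernel,
                                rng=rng, **kwargs))
    return chains
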