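"""Seeded synthetic datasets emulating the three measurement regimes.

Each preset carries the published posterior-mean parameter values as
ground truth and the corresponding instrument grid, so every stage of
the pipeline is testable without downloads.  Noise is multiplicative
log-normal for log-scale models, ``y = f(truth) * exp(eps)`` with
``eps ~ N(0, sigma2)``, matching the Gaussian residual model on the
logarithmic intensity; linear-scale models receive additive Gaussian
noise.  The truth record travels with the dataset so recovery scoring is
self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .likelihood import Dataset, ForwardModel
from .saxs import PolydisperseSphereModel, default_q_grid
from .reflectivity import BilayerReflectivityModel
from .xwfh import WaveguideGeometry, XWFHModel

__all__ = ["SyntheticSpec", "simulate_dataset",
           "saxs_table1", "refl_table2", "refl_cushion4", "xwfh_table3"]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    model: ForwardModel
    truth: dict[str, float]  # includes the residual variance "sigma2"
    abscissa: np.ndarray
    scale: str = "log"
    seed: int = 0
    name: str = "synthetic"

    @property
    def truth_vector(self) -> np.ndarray:
        """(model params..., sigma2) in the model's declared order."""
        vals = [self.truth[k] for k in self.model.param_names]
        return np.array(vals + [self.truth["sigma2"]], dtype=float)


def simulate_dataset(spec: SyntheticSpec) -> tuple[Dataset, dict[str, float]]:
    """Noisy curve plus the truth record that generated it."""
    theta = spec.truth_vector[:-1]
    sigma2 = spec.truth["sigma2"]
    f = spec.model.predict(theta, spec.abscissa)
    rng = np.random.default_rng(spec.seed)
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    eps = rng.normal(0.0, np.sqrt(sigma2), size=f.shape) if sigma2 > 0 else 0.0
    if spec.scale == "log":
        y = f * np.exp(eps)
    else:
        y = f + eps
    data = Dataset(spec.abscissa, y, scale=spec.scale)
    return data, dict(spec.truth)


# --- presets: published mean values as ground truth ------------------------

SAXS_TRUTH = {
    "I0": 1.34, "Ib": 2.00e-5, "R": 757.7, "sigma_R": 59.5,
    "sigma_q": 1.44e-5, "sigma2": 1.78e-3,
}

REFL_TRUTH = {
    "I0": 1.06, "sigma_Si": 2.6,
    "h_o": 12.2, "h_t": 22.7, "h_i": 11.2,
    "delta_o": 6.59e-7, "delta_t": 4.19e-7, "delta_i": 9.30e-7,
    "sigma_o": 4.9, "sigma_t": 4.2, "sigma_i": 8.5,
    "sigma2": 5.7e-4,
}

# four-layer variant with a thin, rough water cushion between the inner
# head group and the substrate (the model-selection study)
REFL4_TRUTH = {
    **{k: v for k, v in REFL_TRUTH.items()},
    "h_i": 4.6, "h_w": 3.2, "delta_w": 5.8e-7, "sigma_w": 19.3,
}

XWFH_TRUTH = {
    "I0": 0.122, "z_offset": 15.71, "sigma_air_ps": 39.8, "d_ps": 222.2,
    "sigma_ps_ptba": 25.0, "d_ptba": 609.4, "d_au": 7.01,
    "f_elastic": 1.46e-9, "sigma2": 0.623e-3,
}


def saxs_table1(seed: int = 0, n_q: int = 100) -> SyntheticSpec:
    """Polydisperse-sphere SAXS regime: R = 757.7 A silica spheres,
    100 log-spaced q in [0.002, 0.05] 1/A, log-normal noise."""
    return SyntheticSpec(
        model=PolydisperseSphereModel(),
        truth=dict(SAXS_TRUTH),
        abscissa=default_q_grid(n_q),
        scale="log",
        seed=seed,
        name="saxs_table1",
    )


def refl_table2(seed: int = 0, n_q: int = 200, dz: float = 0.5
                ) -> SyntheticSpec:
    """Three-layer supported-bilayer reflectivity at 20 keV,
    200 linear q in [0.02, 0.6] 1/A."""
    return SyntheticSpec(
        model=BilayerReflectivityModel(n_layers=3, dz=dz),
        truth=dict(REFL_TRUTH),
        abscissa=np.linspace(0.02, 0.60, n_q),
        scale="log",
        seed=seed,
        name="refl_table2",
    )


def refl_cushion4(seed: int = 0, n_q: int = 200, dz: float = 0.5
                  ) -> SyntheticSpec:
    """Four-layer stack with a thin, rough water cushion (model-selection
    study: the cushion and inner-head thicknesses are barely resolvable
    and strongly anti-correlated)."""
    return SyntheticSpec(
        model=BilayerReflectivityModel(n_layers=4, dz=dz),
        truth=dict(REFL4_TRUTH),
        abscissa=np.linspace(0.02, 0.60, n_q),
        scale="log",
        seed=seed,
        name="refl_cushion4",
    )


def xwfh_table3(seed: int = 0, n_pixels: int = 150, n_basis: int = 30,
                monolayer_index: int | None = None,
                geometry: WaveguideGeometry | None = None) -> SyntheticSpec:
    """Buried gold monolayer hologram: ~7 A of gold between a 222 A PS
    cap and a 609 A PtBA layer, detected over a pixel grid.

    The true spline coefficient vector is a single nonzero coefficient
    (a monolayer); its index defaults to the basis function peaking
    nearest the PS/PtBA interface where the gold sits.
    """
    geometry = geometry or WaveguideGeometry()
    model = XWFHModel(geometry, n_basis=n_basis)
    basis_depth = XWFH_TRUTH["d_ps"] + XWFH_TRUTH["d_ptba"]
    if monolayer_index is None:
        from .xwfh import CBSBasis
        grev = CBSBasis(n_basis, basis_depth).greville()
        monolayer_index = int(np.argmin(np.abs(grev - XWFH_TRUTH["d_ps"])))
    truth = dict(XWFH_TRUTH)
    for k in range(n_basis):
        truth[f"a{k + 1}"] = 0.0
    truth[f"a{monolayer_index + 1}"] = 9.99e-3 * 30 / n_basis
    pixels = np.arange(n_pixels, dtype=float) + 20.0
    return SyntheticSpec(
        model=model,
        truth=truth,
        abscissa=pixels,
        scale="log",
        seed=seed,
        name="xwfh_table3",
    )
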