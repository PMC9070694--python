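"""Readers and writers: 1-D curves, run configuration, chain output.

Curves are whitespace- or comma-delimited text with '#' comments and
columns (abscissa, intensity[, error]).  Chains serialize to a columnar
text file (one row per iteration) and to an ``.npz`` container with a
JSON metadata entry.  Run configuration is YAML.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .likelihood import Dataset
from .sampler import Chain, MassMatrix, SamplerConfig

__all__ = ["read_curve", "write_curve", "RunConfig", "load_config",
           "save_chain_text", "save_chain_npz", "load_chain_npz"]


def read_curve(path: str | Path, scale: str = "log") -> Dataset:
    """Parse a two- or three-column text curve into a Dataset.

    '#'-comment lines are skipped; commas are treated as whitespace.
    Out-of-order rows are sorted (with a warning); duplicate abscissa
    values are averaged (with a warning).
    """
    path = Path(path)
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        s = line.split("#", 1)[0].strip().replace(",", " ")
        if not s:
            continue
        parts = s.split()
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}:{ln}: expected 2 or 3 columns")
        try:
            rows.append([float(v) for v in parts])
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: non-numeric value") from err
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError(f"{path}: inconsistent column count")
    arr = np.array(rows)
    x = arr[:, 0]
    if np.any(np.diff(x) < 0):
        warnings.warn(f"{path}: abscissa not sorted; sorting", stacklevel=2)
        arr = arr[np.argsort(x, kind="stable")]
        x = arr[:, 0]
    if np.any(np.diff(x) == 0):
        warnings.warn(f"{path}: duplicate abscissa averaged", stacklevel=2)
        uniq, inv = np.unique(x, return_inverse=True)
        merged = np.zeros((uniq.size, ncol))
        counts = np.bincount(inv)
        for c in range(ncol):
            merged[:, c] = np.bincount(inv, weights=arr[:, c]) / counts
        merged[:, 0] = uniq
        arr = merged
    err = arr[:, 2] if ncol == 3 else None
    return Dataset(arr[:, 0], arr[:, 1], scale=scale, errors=err)


def write_curve(path: str | Path, data: Dataset,
                header: str | None = None) -> None:
    cols = [data.abscissa, data.y]
    if data.errors is not None:
        cols.append(data.errors)
    hdr = header or "abscissa intensity" + (" error" if data.errors is not None
                                            else "")
    np.savetxt(path, np.column_stack(cols), header=hdr)


@dataclass
class RunConfig:
    """Schema-validated fit configuration.

    ``model``: one of ``saxs_spheres`` / ``bilayer_refl`` / ``xwfh``;
    ``parameters`` maps each free parameter name to
    {init, transform, [bounds]} (multi-start via a list of inits);
    ``fixed`` pins parameters; ``sampler`` fills a SamplerConfig.
    """

    model: str
    parameters: dict[str, dict[str, Any]]
    sampler: dict[str, Any] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    data: str | None = None
    output_dir: str = "."
    kernel: str = "nuts"
    seed: int = 0

    _MODELS = ("saxs_spheres", "bilayer_refl", "xwfh")

    def __post_init__(self) -> None:
        if self.model not in self._MODELS:
            raise ValueError(f"unknown model {self.model!r}; "
                             f"choose from {self._MODELS}")
        for name, spec in self.parameters.items():
            if "init" not in spec:
                raise ValueError(f"parameter {name!r} needs an initial value")
            kind = spec.get("transform", "identity")
            if kind not in ("identity", "log", "logit"):
                raise ValueError(f"parameter {name!r}: bad transform {kind!r}")
            if kind == "logit" and "bounds" not in spec:
                raise ValueError(f"parameter {name!r}: logit needs bounds")

    def sampler_config(self) -> SamplerConfig:
        return SamplerConfig(seed=self.seed, **self.sampler)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return RunConfig(**raw)


def save_chain_text(path: str | Path, chain: Chain,
                    names: list[str] | None = None) -> None:
    """Columnar text: parameters, acceptance flag, step size, Delta H."""
    n, N = chain.draws.shape
    names = names or [f"x{i}" for i in range(N)]
    dh = chain.energy_after - chain.energy_before
    table = np.column_stack([chain.draws, chain.accepted.astype(float),
                             chain.step_size_trace, dh])
    hdr = " ".join(names + ["accepted", "step_size", "delta_H"])
    np.savetxt(path, table, header=hdr)


def save_chain_npz(path: str | Path, chain: Chain,
                   extra_meta: dict | None = None) -> None:
    """Binary container with draws, flags and JSON metadata."""
    meta = dict(chain.meta)
    if extra_meta:
        meta.update(extra_meta)
    meta["burn_in_index"] = chain.burn_in_index
    mass_diag = (chain.mass.diag if chain.mass is not None
                 and chain.mass.diag is not None else np.array([]))
    np.savez_compressed(
        path,
        draws=chain.draws,
        accepted=chain.accepted,
        energy_before=chain.energy_before,
        energy_after=chain.energy_after,
        step_size_trace=chain.step_size_trace,
        divergent=chain.divergent,
        mass_diag=mass_diag,
        meta=np.frombuffer(json.dumps(meta, default=str).encode(),
                           dtype=np.uint8),
    )


def load_chain_npz(path: str | Path) -> Chain:
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        mass = (MassMatrix(f["mass_diag"]) if f["mass_diag"].size
                else None)
        burn = int(meta.pop("burn_in_index", 0))
        return Chain(f["draws"], f["accepted"], f["energy_before"],
                     f["energy_after"], f["step_size_trace"],
                     f["divergent"], burn, mass=mass, meta=meta)
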