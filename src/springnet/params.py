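"""Shared model parameters for the cross-linked particle-network system.

A single parameter set drives all three tiers of the model stack: the
stochastic particle simulator, the macroscopic aggregation-diffusion
equation, and the spectral stability analysis.  All quantities are in the
scaled (non-dimensional) units in which the mobility is 1 and the spring
constant defaults to 2, so that the pair potential is exactly
``(r - ell)^2 - (R - ell)^2`` inside its support.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union


@dataclass(frozen=True)
class ModelParams:
    """Physical/scaled parameters shared by every tier of the model.

    Parameters
    ----------
    D : float
        Noise intensity (diffusion coefficient), ``D >= 0``.
    ell : float
        Spring equilibrium length, ``0 <= ell < R``.
    R : float
        Detection radius of the pair potential (compact support radius).
    L : float
        Domain half-size; the periodic domain is ``[-L, L)`` per dimension.
    kappa : float
        Spring constant; the scaled model fixes ``kappa = 2``.
    nu_f, nu_d : float
        Linking / unlinking frequencies of the stochastic link process.
    mu : float
        Mobility of the overdamped particle dynamics (fixed to 1 in the
        scaled model; retained for completeness).
    dim : int
        Spatial dimension, 1 or 2.
    """

    D: float
    ell: float
    R: float = 0.75
    L: float = 3.0
    kappa: float = 2.0
    nu_f: float = 1.0
    nu_d: float = 1.0
    mu: float = 1.0
    dim: int = 1

    def __post_init__(self) -> None:
        if self.dim not in (1, 2):
            raise ValueError(f"dim must be 1 or 2, got {self.dim}")
        if not 0 < self.R <= self.L:
            raise ValueError("detection radius must satisfy 0 < R <= L")
        if self.dim == 1 and not self.R < self.L:
            raise ValueError("1D analysis requires R < L")
        if not 0 <= self.ell < self.R:
            raise ValueError("spring length must satisfy 0 <= ell < R")
        if self.D < 0:
            raise ValueError("noise intensity D must be non-negative")
        if self.kappa <= 0:
            raise ValueError("spring constant kappa must be positive")
        if self.nu_f <= 0 or self.nu_d <= 0:
            raise ValueError("link frequencies nu_f, nu_d must be positive")
        if self.mu <= 0:
            raise ValueError("mobility mu must be positive")

    @property
    def alpha(self) -> float:
        """Ratio ``ell / R`` in [0, 1); the natural bifurcation parameter."""
        return self.ell / self.R

    @property
    def ratio_RL(self) -> float:
        """Range-to-domain ratio ``R / L``."""
        return self.R / self.L

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_config(params_or_dict, path: Union[str, Path]) -> None:
    """Write a flat ``key = value`` config file (one key per line)."""
    d = params_or_dict.to_dict() if hasattr(params_or_dict, "to_dict") else dict(params_or_dict)
    lines = [f"{k} = {v}" for k, v in d.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: Union[str, Path]) -> dict:
    """Read a flat ``key = value`` config file into a dict.

    Values are parsed as int when possible, else float, else kept as str.
    Blank lines and ``#`` comments are ignored.
    """
    out: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        for cast in (int, float):
            try:
                out[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            out[key] = val
    return out


def params_from_config(path: Union[str, Path], **overrides) -> ModelParams:
    d = read_config(path)
    d.update(overrides)
    fields = {f.name for f in dataclasses.fields(ModelParams)}
    return ModelParams(**{k: v for k, v in d.items() if k in fields})
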