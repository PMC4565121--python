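"""Model configuration.

All lengths are micrometres (um).  The reference configuration describes a
spherically symmetric animal cell of radius 16 um whose microtubules (MTs) are
grafted at the centrosome, carrying a chondriome of total length 1 mm split
into 0.2 um graph edges.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError

#: Dimensionless scale constants of the position-dependent fusion/fission
#: rate fields (see graph_dynamics).  The radial *shapes* of the rates follow
#: from the cytoskeleton densities; these two amplitudes set where on the
#: gamma axis the fusion-dominated regime sits.  They are calibrated once
#: against the model's published operating regime -- mean segment length
#: s(gamma) peaking at gamma ~ 0.1 at mid-cell (r = L/2) with a peak of a
#: few micrometres -- and are not meant to be varied in normal use.
#: docs/methods.md discusses the calibration.
RATE_SCALE_TIP_TIP = 8000.0
RATE_SCALE_TIP_SIDE = 155.0


@dataclass
class SimulationConfig:
    """Scalar parameters of the cell model.

    Attributes
    ----------
    n_f:
        Number of microtubules grafted at the centrosome.
    L:
        MT contour length (um); also the cell radius.
    L_p:
        MT persistence length (um).
    a:
        Bond (monomer) length of the discrete chain representation (um).
    sigma:
        Proximity threshold (um): two fiber axes closer than ``sigma`` form a
        potential crossing; equals a typical mitochondrion diameter.
    edge_length:
        Length of one mitochondrial graph edge (um).
    M:
        Total mitochondrial (chondriome) length in the cell (um).
    l1, l2:
        Contour interval [l1, l2] of the MTs accessible to mitochondria (um).
    gamma:
        Global fusion-to-fission propensity ratio of the enzymatic machinery.
    psi:
        Drift-to-diffusion ratio of motor-driven transport along MTs (1/um).
        Positive values bias mitochondria towards the MT plus ends (cell
        periphery), negative towards the centrosome.
    dr:
        Radial shell width (um); defaults to 0.01 * L.
    seed:
        Master seed for all stochastic components.
    n_runs:
        Default ensemble size for stochastic per-shell simulations.
    rate_scale_tip_tip, rate_scale_tip_side:
        Dimensionless amplitudes of the alpha_1 / alpha_2 rate fields.
    """

    n_f: int = 200
    L: float = 16.0
    L_p: float = 32.0
    a: float = 0.02
    sigma: float = 0.2
    edge_length: float = 0.2
    M: float = 1000.0
    l1: float | None = None  # defaults to L/32 (0.5 um at the reference L)
    l2: float | None = None  # defaults to 0.9375 L (15 um at the reference L)
    gamma: float = 0.1
    psi: float = 0.0
    dr: float | None = None
    seed: int = 0
    n_runs: int = 1000
    rate_scale_tip_tip: float = RATE_SCALE_TIP_TIP
    rate_scale_tip_side: float = RATE_SCALE_TIP_SIDE

    def __post_init__(self) -> None:
        if self.dr is None:
            self.dr = 0.01 * self.L
        if self.l1 is None:
            self.l1 = self.L / 32.0
        if self.l2 is None:
            self.l2 = 0.9375 * self.L
        self.validate()

    def validate(self) -> None:
        if self.n_f < 1:
            raise ConfigError(f"n_f must be >= 1, got {self.n_f}")
        for name in ("L", "L_p", "a", "sigma", "edge_length", "M", "dr"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.a > self.L:
            raise ConfigError(f"bond length a={self.a} exceeds contour L={self.L}")
        if not 0 <= self.l1 < self.l2:
            raise ConfigError(f"need 0 <= l1 < l2, got l1={self.l1}, l2={self.l2}")
        if self.l2 > self.L:
            raise ConfigError(f"l2={self.l2} exceeds the MT length L={self.L}")
        if self.gamma < 0:
            raise ConfigError(f"gamma must be >= 0, got {self.gamma}")
        if self.n_runs < 1:
            raise ConfigError(f"n_runs must be >= 1, got {self.n_runs}")

    @property
    def n_edges_total(self) -> int:
        """Total number of mitochondrial graph edges, M / edge_length."""
        return int(round(self.M / self.edge_length))

    @property
    def r_grid(self):
        """Shell midpoints covering (0, L]."""
        import numpy as np

        n = int(round(self.L / self.dr))
        return (np.arange(n) + 0.5) * self.dr

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise ConfigError(f"cannot parse {path}: {e}") from e
        return cls.from_dict(d)


def load_config(path: str | Path | None = None, **overrides) -> SimulationConfig:
    """Load a configuration from a JSON file, applying keyword overrides.

    With no arguments returns the reference cell configuration.
    """
    if path is None:
        base = {}
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"configuration file not found: {p}")
        base = json.loads(p.read_text())
        if not isinstance(base, dict):
            raise ConfigError(f"{p} must contain a JSON object")
    base.update(overrides)
    return SimulationConfig.from_dict(base)


def reference_config(**overrides) -> SimulationConfig:
    """The reference cell: 200 MTs of 16 um (L_p = 32 um) around the
    centrosome, sigma = edge length = 0.2 um, M = 1 mm of mitochondria spread
    uniformly (psi = 0) over contour positions [0.5, 15] um."""
    return SimulationConfig(**overrides)
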