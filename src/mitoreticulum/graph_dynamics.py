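"""Position-dependent rate fields and the deterministic steady state.

The chondriome at radius r is a graph of fixed-length edges whose nodes have
degree 1 (free ends, density u1), 2 (bulk, u2) or 3 (branching, u3).  Two
reaction pairs drive it:

* tip-to-tip:  U1 + U1 <-> U2, relative rate alpha_1(r) -- sequential fusion
  of two free ends, enabled by two mitochondria superimposed on one fiber
  (Q2) or on two sigma-proximal fibers (S11);
* tip-to-side: U1 + U2 <-> U3, relative rate alpha_2(r) -- branching, gated
  by occupied fiber crossings alone (S11).

With mass-action kinetics the steady state per shell is

    u2 = (alpha_1 / 2) u1^2,    u3 = alpha_2 u1 u2,
    u1 + 2 u2 + 3 u3 = 2 Q1          (edge conservation),

a cubic in u1 with a unique non-negative root.  Node densities are measured
in graph edges per um of radius; alpha_1, alpha_2 carry units of um so that
the products are intensive.

The rate fields take the form

    alpha_1 = c1 * gamma * (Q2 + S11) / qbar^2,
    alpha_2 = c2 * gamma * S11 / qbar^2,

(all densities in edge units) where gamma is the global fusion/fission
propensity ratio of the enzymatic machinery, qbar = M/(edge_length * L) is
the cell-mean edge density and c1, c2 are fixed dimensionless amplitudes
calibrated once against the published operating regime of the model; see
docs/methods.md.  The fixed normalisation preserves the occupancy
amplification carried by S11 ~ Q1^2: biasing mitochondria along the fibers
(psi != 0) feeds back quadratically into the branching rate, which is what
lets a moderate drift revert the clustering pattern.  Normalising by the
local Q1(r)^2 instead (``normalization="local"``) cancels that
amplification and leaves only the geometric 1/r^2 decay of the crossings.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .errors import SolverError
from .wlc_theory import CellDensities

__all__ = [
    "RateField",
    "NodeDensities",
    "rate_field",
    "steady_state_nodes",
    "solve_radial_steady_state",
    "mean_segment_length",
    "partition_border",
]

#: shells with fewer edge densities than this are treated as empty
_Q1_FLOOR = 1e-9


@dataclass
class RateField:
    """alpha_1(r), alpha_2(r) and the shell edge density q1(r) (edge units)."""

    r: np.ndarray
    q1: np.ndarray  # edges per um of radius
    q2: np.ndarray  # same-fiber pair density, edges per um
    s11: np.ndarray  # occupied-crossing pair density, edge pairs per um
    alpha1: np.ndarray  # um
    alpha2: np.ndarray  # um
    gamma: float
    psi: float


def rate_field(
    config: SimulationConfig,
    densities: CellDensities | None = None,
    r=None,
    gamma: float | None = None,
    normalization: str = "global",
) -> RateField:
    """Evaluate the position-dependent fusion/fission rate ratios.

    Both rates scale linearly in gamma; shells without substrate (q1 = 0)
    get zero rates.  ``normalization`` selects the intensive divisor of the
    pair densities: the cell-mean edge density squared ("global", default)
    or the local Q1(r)^2 ("local"); see the module docstring.
    """
    if normalization not in ("global", "local"):
        raise SolverError(f"unknown normalization {normalization!r}")
    if densities is None:
        densities = CellDensities(config)
    if r is None:
        r = config.r_grid
    if gamma is None:
        gamma = config.gamma
    r = np.asarray(r, dtype=float)
    ell = config.edge_length
    q1 = densities.Q1(r) / ell
    q2 = densities.Q2(r) / ell
    s11 = densities.S11(r) / ell**2
    alpha1 = np.zeros_like(q1)
    alpha2 = np.zeros_like(q1)
    # shells carrying less than 0.05 edge are empty for all practical
    # purposes (distribution tails below l1); rates there are meaningless
    floor = max(_Q1_FLOOR, 0.05 / config.dr)
    ok = q1 > floor
    q1 = np.where(ok, q1, 0.0)
    q2 = np.where(ok, q2, 0.0)
    s11 = np.where(ok, s11, 0.0)
    if normalization == "global":
        denom = np.full_like(q1, (config.M / (ell * config.L)) ** 2)
    else:
        denom = q1**2
    alpha1[ok] = config.rate_scale_tip_tip * gamma * (q2[ok] + s11[ok]) / denom[ok]
    alpha2[ok] = config.rate_scale_tip_side * gamma * s11[ok] / denom[ok]
    return RateField(
        r=r, q1=q1, q2=q2, s11=s11, alpha1=alpha1, alpha2=alpha2,
        gamma=gamma, psi=config.psi,
    )


@dataclass
class NodeDensities:
    """Steady-state node densities per shell (edges per um of radius)."""

    r: np.ndarray
    q1: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    u3: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray

    @property
    def fractions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Node abundances as fractions of the total system size 2 Q1."""
        with np.errstate(divide="ignore", invalid="ignore"):
            tot = 2.0 * self.q1
            return tuple(
                np.where(tot > 0, w * u / np.where(tot > 0, tot, 1.0), 0.0)
                for u, w in ((self.u1, 1.0), (self.u2, 2.0), (self.u3, 3.0))
            )

    def to_dataframe(self, edge_length: float = 0.2):
        import pandas as pd

        f1, f2, f3 = self.fractions
        return pd.DataFrame(
            {
                "r": self.r,
                "q1": self.q1,
                "u1": self.u1,
                "u2": self.u2,
                "u3": self.u3,
                "frac1": f1,
                "frac2": f2,
                "frac3": f3,
                "s_um": mean_segment_length(self, edge_length),
                "alpha1": self.alpha1,
                "alpha2": self.alpha2,
            }
        )


def steady_state_nodes(q1: float, alpha1: float, alpha2: float) -> tuple[float, float, float]:
    """Solve one shell's mass-action balance for (u1, u2, u3).

    Substituting u2 and u3 into the edge-conservation condition gives

        u1 + alpha1 u1^2 + (3/2) alpha1 alpha2 u1^3 = 2 q1,

    whose left side is strictly increasing in u1 >= 0, so the non-negative
    root is unique and bracketed by [0, 2 q1].
    """
    if q1 < 0 or alpha1 < 0 or alpha2 < 0:
        raise SolverError(f"negative inputs: q1={q1}, alpha1={alpha1}, alpha2={alpha2}")
    if q1 <= _Q1_FLOOR:
        return 0.0, 0.0, 0.0
    target = 2.0 * q1
    c3 = 1.5 * alpha1 * alpha2

    def F(u):
        return u * (1.0 + u * (alpha1 + u * c3)) - target

    lo, hi = 0.0, target
    if F(hi) < 0:  # cannot happen for alpha >= 0; guard against fp trouble
        raise SolverError(f"root not bracketed for q1={q1}")
    from scipy.optimize import brentq

    u1 = brentq(F, lo, hi, xtol=1e-15, rtol=1e-14)
    u2 = 0.5 * alpha1 * u1 * u1
    u3 = alpha2 * u1 * u2
    resid = abs(u1 + 2 * u2 + 3 * u3 - target)
    if resid > 1e-8 * max(target, 1.0):
        raise SolverError(f"steady-state residual {resid} too large at q1={q1}")
    return u1, u2, u3


def solve_radial_steady_state(
    config: SimulationConfig,
    densities: CellDensities | None = None,
    r=None,
    gamma: float | None = None,
) -> NodeDensities:
    """Per-shell deterministic steady state on the radial grid.

    Shells are independent (no radial transport at steady state); empty
    shells return all-zero densities.
    """
    rf = rate_field(config, densities=densities, r=r, gamma=gamma)
    n = len(rf.r)
    u1 = np.zeros(n)
    u2 = np.zeros(n)
    u3 = np.zeros(n)
    for i in range(n):
        try:
            u1[i], u2[i], u3[i] = steady_state_nodes(rf.q1[i], rf.alpha1[i], rf.alpha2[i])
        except SolverError as e:
            raise SolverError(f"shell {i} (r={rf.r[i]:.3f} um): {e}") from e
    return NodeDensities(
        r=rf.r, q1=rf.q1, u1=u1, u2=u2, u3=u3, alpha1=rf.alpha1, alpha2=rf.alpha2
    )


def mean_segment_length(nodes: NodeDensities, edge_length: float | None = None) -> np.ndarray:
    """Mean segment length s(r) = 2 Q1 / (u1 + 3 u3).

    A segment is a linear stretch between nodes of degree 1 or 3; the shell
    carries (u1 + 3 u3)/2 segment ends.  Returned in um when ``edge_length``
    is given, otherwise in edges; empty shells are masked with NaN.
    """
    denom = nodes.u1 + 3.0 * nodes.u3
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0, 2.0 * nodes.q1 / np.where(denom > 0, denom, 1.0), np.nan)
    if edge_length is not None:
        s = s * edge_length
    return s


def partition_border(nodes: NodeDensities) -> float | None:
    """Radius separating the branching-dominated (u3 > u2) perinuclear zone
    from the bulk-dominated periphery.

    Returns the smallest r at which u2(r) > u3(r) while u3 dominates at
    smaller radii; None when branching never dominates (border at or inside
    the innermost shell) or never yields (border beyond the cell)."""
    occupied = nodes.q1 > _Q1_FLOOR
    if not occupied.any():
        return None
    idx = np.nonzero(occupied)[0]
    inner = idx[0]
    if nodes.u3[inner] <= nodes.u2[inner]:
        return None  # no branching-dominated core
    for i in idx:
        if nodes.u2[i] > nodes.u3[i]:
            return float(nodes.r[i])
    return None  # branching dominates everywhere: border beyond the cell
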