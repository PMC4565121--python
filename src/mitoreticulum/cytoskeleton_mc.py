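"""Explicit Monte Carlo representation of the microtubule cytoskeleton.

Each microtubule (MT) is a freely rotating chain (FRC): ``N = floor(L/a)``
bonds of fixed length ``a``, each at a fixed polar angle ``theta`` to its
predecessor with a torsion angle uniform on [0, 2pi).  One end is grafted at
the centrosome (origin) with a direction uniform on the unit sphere.  In the
limit a -> 0 at fixed ``2a/theta**2`` the FRC converges to the worm-like
chain with persistence length ``L_p = 2a/theta**2``.

The module also provides empirical estimators used to validate the analytic
densities of :mod:`mitoreticulum.wlc_theory`: radial contour histograms
(``Q_0``), the sigma-proximal contour-pair mass (``S_00``), discrete merged
crossing detection, and a tangent-correlation persistence-length fit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import SimulationConfig
from .errors import ParameterError

__all__ = [
    "PolymerChain",
    "CytoskeletonArray",
    "CrossingSet",
    "PersistenceFit",
    "persistence_from_bond",
    "bond_angle_for_persistence",
    "generate_frc_chain",
    "generate_cytoskeleton",
    "detect_crossings",
    "radial_histogram",
    "proximity_pair_density",
    "estimate_persistence",
]


# ---------------------------------------------------------------------------
# stiffness <-> bond angle


def persistence_from_bond(a: float, theta: float) -> float:
    """Persistence length of an FRC with bond length ``a`` and bond angle
    ``theta``: ``L_p = 2a / theta**2`` (small-angle/WLC correspondence)."""
    if not a > 0:
        raise ParameterError(f"bond length must be positive, got {a}")
    if not 0 < theta < math.pi:
        raise ParameterError(f"bond angle must lie in (0, pi), got {theta}")
    return 2.0 * a / theta**2


def bond_angle_for_persistence(a: float, L_p: float) -> float:
    """Bond angle giving persistence length ``L_p``: ``theta = sqrt(2a/L_p)``."""
    if not a > 0:
        raise ParameterError(f"bond length must be positive, got {a}")
    if not L_p > 0:
        raise ParameterError(f"persistence length must be positive, got {L_p}")
    theta = math.sqrt(2.0 * a / L_p)
    if theta >= math.pi:
        raise ParameterError(
            f"persistence length {L_p} below the FRC resolution limit 2a/pi^2"
        )
    return theta


# ---------------------------------------------------------------------------
# chain containers


@dataclass
class PolymerChain:
    """One MT as an ordered polyline grafted at the origin.

    ``vertices`` has shape (n_bonds + 1, 3) in um with ``vertices[0] = 0``.
    """

    vertices: np.ndarray
    bond_length: float
    bond_angle: float

    @property
    def n_bonds(self) -> int:
        return len(self.vertices) - 1

    @property
    def contour_length(self) -> float:
        return self.n_bonds * self.bond_length

    def tangents(self) -> np.ndarray:
        """Unit bond vectors, shape (n_bonds, 3)."""
        b = np.diff(self.vertices, axis=0)
        return b / np.linalg.norm(b, axis=1, keepdims=True)

    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.vertices[-1]))


@dataclass
class CytoskeletonArray:
    """A set of ``n_f`` FRC chains sharing (L, a, theta), grafted at the
    origin with independent uniform-sphere directions."""

    chains: list[PolymerChain]
    seed: int
    sigma: float = 0.2

    @property
    def n_f(self) -> int:
        return len(self.chains)

    def vertex_array(self) -> np.ndarray:
        """Stacked vertices, shape (n_f, n_bonds + 1, 3)."""
        return np.stack([c.vertices for c in self.chains])


@dataclass
class CrossingSet:
    """Discrete two-fiber crossing spots.

    One entry per contiguous sub-``sigma`` proximity region of a chain pair,
    located at the minimum-distance segment pair.  Columns: chain indices
    ``i < j``, contour positions ``rho_i``, ``rho_j`` (um), midpoint radius
    ``r`` (um) and the minimum axis distance ``d`` (um).
    """

    chain_i: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    chain_j: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    rho_i: np.ndarray = field(default_factory=lambda: np.empty(0))
    rho_j: np.ndarray = field(default_factory=lambda: np.empty(0))
    r: np.ndarray = field(default_factory=lambda: np.empty(0))
    d: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.r)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chain_i": self.chain_i,
                "chain_j": self.chain_j,
                "rho_i": self.rho_i,
                "rho_j": self.rho_j,
                "r": self.r,
                "d": self.d,
            }
        )


# ---------------------------------------------------------------------------
# chain generation


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _frc_walk(u0: np.ndarray, torsions: np.ndarray, theta: float) -> np.ndarray:
    """Directions of an FRC bundle.

    u0 : (n_chains, 3) first-bond directions; torsions : (n_chains, n_bonds-1)
    uniform angles.  Returns unit bond directions (n_chains, n_bonds, 3).
    """
    n_chains, nm1 = torsions.shape
    n_bonds = nm1 + 1
    dirs = np.empty((n_chains, n_bonds, 3))
    dirs[:, 0] = u0
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    d = u0
    for k in range(1, n_bonds):
        # orthonormal frame transverse to the current direction; the seam of
        # the reference axis is irrelevant because the torsion is uniform
        ref = np.where(np.abs(d[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
        e1 = np.cross(d, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(d, e1)
        phi = torsions[:, k - 1][:, None]
        d = cos_t * d + sin_t * (np.cos(phi) * e1 + np.sin(phi) * e2)
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        dirs[:, k] = d
    return dirs


def generate_frc_chain(
    L: float,
    a: float,
    theta: float,
    graft_direction,
    seed: int | np.random.Generator = 0,
) -> PolymerChain:
    """Generate one FRC chain of ``floor(L/a)`` bonds.

    The first bond points along ``graft_direction``; each subsequent bond sits
    at polar angle ``theta`` from its predecessor with uniform torsion.
    ``theta = 0`` yields a straight chain (rigid-rod limit).
    """
    if not L >= a > 0:
        raise ParameterError(f"need L >= a > 0, got L={L}, a={a}")
    if not 0 <= theta < math.pi:
        raise ParameterError(f"bond angle must lie in [0, pi), got {theta}")
    u0 = np.asarray(graft_direction, dtype=float)
    norm = np.linalg.norm(u0)
    if not norm > 0:
        raise ParameterError("graft direction must be a non-zero vector")
    u0 = u0 / norm
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_bonds = int(L / a)
    if theta == 0.0:
        dirs = np.tile(u0, (n_bonds, 1))
    else:
        torsions = rng.uniform(0.0, 2.0 * math.pi, (1, n_bonds - 1))
        dirs = _frc_walk(u0[None, :], torsions, theta)[0]
    vertices = np.vstack([np.zeros(3), np.cumsum(a * dirs, axis=0)])
    return PolymerChain(vertices=vertices, bond_length=a, bond_angle=theta)


def generate_cytoskeleton(config: SimulationConfig) -> CytoskeletonArray:
    """Generate the ``n_f``-chain MT array of ``config``.

    One master seed spawns an independent substream per chain (graft direction
    and torsions), so increasing ``n_f`` extends the array without reshuffling
    existing chains.  Deterministic given ``config.seed``.
    """
    theta = bond_angle_for_persistence(config.a, config.L_p)
    n_bonds = int(config.L / config.a)
    children = np.random.SeedSequence(config.seed).spawn(config.n_f)
    u0 = np.empty((config.n_f, 3))
    torsions = np.empty((config.n_f, n_bonds - 1))
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        u0[i] = _random_unit_vectors(rng, 1)[0]
        torsions[i] = rng.uniform(0.0, 2.0 * math.pi, n_bonds - 1)
    dirs = _frc_walk(u0, torsions, theta)
    verts = np.concatenate(
        [np.zeros((config.n_f, 1, 3)), np.cumsum(config.a * dirs, axis=1)], axis=1
    )
    chains = [
        PolymerChain(vertices=verts[i], bond_length=config.a, bond_angle=theta)
        for i in range(config.n_f)
    ]
    return CytoskeletonArray(chains=chains, seed=config.seed, sigma=config.sigma)


# ---------------------------------------------------------------------------
# geometry


def _segment_pair_distance(p1, d1, p2, d2) -> np.ndarray:
    """Exact minimum distances between segment pairs.

    Segments are ``p + t*d`` with t in [0, 1]; all arrays (n, 3).  Standard
    clamped closest-point computation, vectorised.
    """
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)
    denom = a * e - b * b
    s = np.where(denom > 1e-14, (b * f - c * e) / np.where(denom > 1e-14, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    # recompute t for clamped s, then re-clamp s for clamped t
    t = np.where(e > 1e-14, (b * s + f) / np.where(e > 1e-14, e, 1.0), 0.0)
    t_cl = np.clip(t, 0.0, 1.0)
    s = np.where(a > 1e-14, (b * t_cl - c) / np.where(a > 1e-14, a, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    diff = (p1 + s[:, None] * d1) - (p2 + t_cl[:, None] * d2)
    return np.linalg.norm(diff, axis=1), s, t_cl


def _candidate_pairs(array: CytoskeletonArray, radius: float):
    """Cross-chain bond pairs whose midpoints lie within ``radius``.

    Returns flat bond indices (chain major) and the supporting arrays.
    """
    verts = array.vertex_array()  # (n_f, n+1, 3)
    n_f, n_v, _ = verts.shape
    n_b = n_v - 1
    p = verts[:, :-1, :].reshape(-1, 3)
    d = (verts[:, 1:, :] - verts[:, :-1, :]).reshape(-1, 3)
    mid = p + 0.5 * d
    tree = cKDTree(mid)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs):
        ci = pairs[:, 0] // n_b
        cj = pairs[:, 1] // n_b
        keep = ci != cj
        pairs = pairs[keep]
    return pairs, p, d, mid, n_b


def detect_crossings(array: CytoskeletonArray, sigma: float | None = None) -> CrossingSet:
    """Find discrete crossing spots between chain pairs.

    All unordered chain pairs are scanned (through a KD-tree prune whose
    output is identical to the all-pairs scan); segment pairs with exact
    minimum distance < sigma are grouped into contiguous proximity regions,
    and each region contributes exactly one crossing at its minimum-distance
    point.
    """
    if sigma is None:
        sigma = array.sigma
    if not sigma > 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    a = array.chains[0].bond_length
    pairs, p, d, mid, n_b = _candidate_pairs(array, sigma + a)
    empty = CrossingSet()
    if len(pairs) == 0:
        return empty
    dist, s, t = _segment_pair_distance(p[pairs[:, 0]], d[pairs[:, 0]], p[pairs[:, 1]], d[pairs[:, 1]])
    below = dist < sigma
    if not below.any():
        return empty
    pairs, dist, s, t = pairs[below], dist[below], s[below], t[below]
    ci, bi = pairs[:, 0] // n_b, pairs[:, 0] % n_b
    cj, bj = pairs[:, 1] // n_b, pairs[:, 1] % n_b
    # enforce i < j ordering of the chain indices
    flip = ci > cj
    ci, cj = np.where(flip, cj, ci), np.where(flip, ci, cj)
    bi, bj = np.where(flip, bj, bi), np.where(flip, bi, bj)
    s, t = np.where(flip, t, s), np.where(flip, s, t)

    # group sub-threshold segment pairs of each chain pair into contiguous
    # regions: union-find with adjacency in both bond indices
    order = np.lexsort((bj, bi, cj, ci))
    ci, cj, bi, bj, dist, s, t = (x[order] for x in (ci, cj, bi, bj, dist, s, t))
    n = len(ci)
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # bucket by chain pair, then link pairs adjacent in (bi, bj)
    key = ci.astype(np.int64) * (cj.max() + 1) + cj
    start = 0
    gap = 2  # segments this close along both contours belong to one region
    for g in range(1, n + 1):
        if g == n or key[g] != key[start]:
            blk = slice(start, g)
            ib, jb = bi[blk], bj[blk]
            m = g - start
            for x in range(m):
                close = (np.abs(ib - ib[x]) <= gap) & (np.abs(jb - jb[x]) <= gap)
                for y in np.nonzero(close)[0]:
                    rx, ry = find(start + x), find(start + y)
                    if rx != ry:
                        parent[rx] = ry
            start = g
    roots = np.array([find(x) for x in range(n)])
    out_i, out_j, out_ri, out_rj, out_r, out_d = [], [], [], [], [], []
    verts = array.vertex_array()
    for root in np.unique(roots):
        members = np.nonzero(roots == root)[0]
        best = members[np.argmin(dist[members])]
        c1, c2, b1, b2 = ci[best], cj[best], bi[best], bj[best]
        rho1 = (b1 + s[best]) * a
        rho2 = (b2 + t[best]) * a
        pt1 = verts[c1, b1] + s[best] * (verts[c1, b1 + 1] - verts[c1, b1])
        pt2 = verts[c2, b2] + t[best] * (verts[c2, b2 + 1] - verts[c2, b2])
        out_i.append(c1)
        out_j.append(c2)
        out_ri.append(rho1)
        out_rj.append(rho2)
        out_r.append(float(np.linalg.norm(0.5 * (pt1 + pt2))))
        out_d.append(dist[best])
    return CrossingSet(
        chain_i=np.array(out_i, int),
        chain_j=np.array(out_j, int),
        rho_i=np.array(out_ri),
        rho_j=np.array(out_rj),
        r=np.array(out_r),
        d=np.array(out_d),
    )


# ---------------------------------------------------------------------------
# empirical radial estimators


def radial_histogram(obj, dr: float, L: float | None = None):
    """Radial density histogram.

    For a :class:`CytoskeletonArray`: per-shell MT contour length / dr
    (empirical Q_0 before the 1/n_f normalisation); bond midpoints carry the
    bond length.  For a :class:`CrossingSet`: crossing count / dr.

    Returns ``(r_mid, density)``.
    """
    if not dr > 0:
        raise ParameterError(f"dr must be positive, got {dr}")
    if isinstance(obj, CytoskeletonArray):
        verts = obj.vertex_array()
        mids = 0.5 * (verts[:, 1:, :] + verts[:, :-1, :])
        radii = np.linalg.norm(mids, axis=-1).ravel()
        weight = obj.chains[0].bond_length
    elif isinstance(obj, CrossingSet):
        radii = obj.r
        weight = 1.0
    else:
        raise ParameterError(f"cannot histogram object of type {type(obj)!r}")
    if L is None:
        L = float(radii.max()) + dr if len(radii) else dr
    edges = np.arange(0.0, L + dr, dr)
    counts, _ = np.histogram(radii, bins=edges)
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    return r_mid, counts * weight / dr


def proximity_pair_density(
    array: CytoskeletonArray, sigma: float, dr: float, L: float | None = None
):
    """Empirical estimator of the crossing-mass density S_00(r).

    S_00(r) dr is the contour-pair mass: the double contour integral, over
    ordered pairs of *distinct* fibers, of the indicator that the two axis
    points lie within sigma, with the first point in the shell at r.  The
    discrete estimator weights every sub-sigma bond-midpoint pair by a**2
    and bins it at the radius of each member in turn (ordered pairs).

    Returns ``(r_mid, density)`` with density in um^2 per um of radius.
    """
    if not sigma > 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    a = array.chains[0].bond_length
    pairs, p, d, mid, n_b = _candidate_pairs(array, sigma)
    if L is None:
        L = array.chains[0].contour_length
    edges = np.arange(0.0, L + dr, dr)
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    if len(pairs) == 0:
        return r_mid, np.zeros(len(r_mid))
    radii = np.linalg.norm(mid[pairs.ravel()], axis=1)
    counts, _ = np.histogram(radii, bins=edges)
    return r_mid, counts * a * a / dr


# ---------------------------------------------------------------------------
# persistence estimation


@dataclass
class PersistenceFit:
    """Tangent-correlation persistence-length estimate.

    ``reliable`` is False when the correlation barely decays over the
    available contour (near-rigid chains): the estimate then only bounds L_p
    from below.
    """

    L_p: float
    n_points: int
    reliable: bool


def estimate_persistence(obj, max_fraction: float = 0.5) -> PersistenceFit:
    """Fit exp(-s / L_p) to the mean tangent-tangent correlation.

    ``obj`` is a chain, a list of chains, or a :class:`CytoskeletonArray`.
    The correlation is averaged over all bond pairs at contour separation
    ``s = k a`` for k up to ``max_fraction`` of the chain, and the decay
    length is obtained from a weighted linear fit of log C(s).
    """
    if isinstance(obj, CytoskeletonArray):
        chains = obj.chains
    elif isinstance(obj, PolymerChain):
        chains = [obj]
    else:
        chains = list(obj)
    if any(c.n_bonds < 2 for c in chains):
        raise ParameterError("persistence estimation needs >= 2 bonds per chain")
    a = chains[0].bond_length
    n_bonds = min(c.n_bonds for c in chains)
    k_max = max(2, int(n_bonds * max_fraction))
    tang = np.stack([c.tangents()[:n_bonds] for c in chains])  # (n_c, n_b, 3)
    corr = np.empty(k_max + 1)
    corr[0] = 1.0
    for k in range(1, k_max + 1):
        corr[k] = float(np.mean(np.einsum("cij,cij->ci", tang[:, :-k], tang[:, k:])))
    # fit over the informative window where the correlation is well above
    # noise but has decayed appreciably
    pos = corr > 0.05
    upto = int(np.argmin(pos)) if not pos.all() else len(corr)
    k = np.arange(1, upto)
    if len(k) < 2:
        return PersistenceFit(L_p=math.inf, n_points=0, reliable=False)
    y = np.log(corr[1:upto])
    slope = float(np.sum(k * y) / np.sum(k * k))
    if slope >= 0:
        return PersistenceFit(L_p=math.inf, n_points=len(k), reliable=False)
    L_p = -a / slope
    contour_span = k_max * a
    # if the correlation decayed by < 10% over the span, the fit only bounds
    reliable = corr[min(k_max, upto - 1)] < 0.9
    return PersistenceFit(L_p=L_p, n_points=len(k), reliable=reliable)
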