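"""Analytic densities of the centrosome-organized cytoskeleton model.

Four layers, each building on the previous one:

* ``occupancy``      -- eps(rho, psi): fraction of MT contour covered by
  mitochondria, the steady state of drift-diffusion transport along a fiber.
* ``end_to_end_pdf`` -- P(r, rho): probability density of the distance r
  between the centrosome and the point at contour position rho of a
  semiflexible fiber (Wilhelm--Frey-type radial distribution, two-branch
  evaluation).
* ``radial_density`` -- Q_j(r) = n_f * int_r^L P(r, rho) eps(rho)^j drho:
  radial density of MT contour occupied by j superimposed mitochondria
  (j = 0: bare cytoskeleton).
* ``crossing_density`` -- S_jj(r) = Q_j(r) * int Q_j(xi) A(xi, r)/(4 pi xi^2)
  dxi: density of occupied two-fiber crossings; ``A`` is the spherical-cap
  area of the shell xi inside a sigma-ball at radius r.  In the bulk
  S_jj ~ sigma^3 Q_j^2 / (3 r^2).

All quantities are per um of radius; contour is measured in um (divide by the
edge length for graph-edge units).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .config import SimulationConfig
from .errors import EvaluationError, OverloadedCytoskeletonError, ParameterError

__all__ = [
    "occupancy",
    "OccupancyProfile",
    "end_to_end_pdf",
    "radial_density",
    "cap_area",
    "crossing_density",
    "crossing_density_asymptotic",
    "CellDensities",
    "RadialProfile",
]

_SERIES_CAP = 50
_SERIES_TOL = 1e-12


# ---------------------------------------------------------------------------
# occupancy


@dataclass
class OccupancyProfile:
    """Steady-state occupancy eps(rho) on [l1, l2].

    For psi != 0 the unconstrained solution is C * exp(psi * rho).  When the
    normalisation would push eps above 1 the profile saturates: eps = 1 on a
    contiguous interval at the crowded end and decays exponentially away from
    it, with the break point rho_star fixed by mass conservation.  This is
    the capacity-limited steady state; a configuration whose mass cannot fit
    at all (M > n_f (l2 - l1)) raises ``OverloadedCytoskeletonError``.
    """

    psi: float
    l1: float
    l2: float
    M: float
    n_f: int
    C: float
    rho_star: float | None  # saturation break point, None if eps < 1 throughout

    def __call__(self, rho) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        eps = np.zeros_like(rho)
        inside = (rho >= self.l1) & (rho <= self.l2)
        if self.psi == 0.0:
            eps[inside] = self.C
        elif self.rho_star is None:
            eps[inside] = self.C * np.exp(self.psi * rho[inside])
        else:
            if self.psi < 0:
                sat = inside & (rho <= self.rho_star)
            else:
                sat = inside & (rho >= self.rho_star)
            tail = inside & ~sat
            eps[sat] = 1.0
            eps[tail] = np.exp(self.psi * (rho[tail] - self.rho_star))
        return eps

    @property
    def saturated(self) -> bool:
        return self.rho_star is not None


def occupancy(config: SimulationConfig | None = None, **kw) -> OccupancyProfile:
    """Solve the steady-state occupancy profile for ``config``.

    Keyword overrides (psi, l1, l2, M, n_f) are applied on top of the config
    (or of the reference values when no config is given).
    """
    if config is None:
        config = SimulationConfig()
    psi = kw.get("psi", config.psi)
    l1 = kw.get("l1", config.l1)
    l2 = kw.get("l2", config.l2)
    M = kw.get("M", config.M)
    n_f = kw.get("n_f", config.n_f)
    if not (0 <= l1 < l2):
        raise ParameterError(f"need 0 <= l1 < l2, got {l1}, {l2}")
    if not M > 0:
        raise ParameterError(f"M must be positive, got {M}")
    capacity = n_f * (l2 - l1)
    if M > capacity * (1 + 1e-12):
        raise OverloadedCytoskeletonError(
            f"M = {M} um exceeds the cytoskeleton capacity n_f*(l2-l1) = {capacity} um"
        )
    if psi == 0.0:
        return OccupancyProfile(psi, l1, l2, M, n_f, C=M / capacity, rho_star=None)
    C = M * psi / (n_f * (math.exp(psi * l2) - math.exp(psi * l1)))
    eps_max = C * math.exp(psi * (l1 if psi < 0 else l2))
    if eps_max <= 1.0:
        return OccupancyProfile(psi, l1, l2, M, n_f, C=C, rho_star=None)

    # capacity-limited branch: eps = 1 on the crowded side of rho_star
    def mass_defect(rho_star: float) -> float:
        if psi < 0:
            sat = rho_star - l1
            tail = (math.exp(psi * (l2 - rho_star)) - 1.0) / psi
        else:
            sat = l2 - rho_star
            tail = (1.0 - math.exp(psi * (l1 - rho_star))) / psi
        return n_f * (sat + tail) - M

    rho_star = brentq(mass_defect, l1, l2, xtol=1e-12)
    return OccupancyProfile(psi, l1, l2, M, n_f, C=math.nan, rho_star=rho_star)


# ---------------------------------------------------------------------------
# end-to-end distance distribution


def _g_theta(kappa: np.ndarray) -> np.ndarray:
    """g(y) = sum_{l>=1} (-1)^(l+1) exp(-pi^2 l^2 y), with the Poisson-dual
    form for small y.  Used for the closed-form normalisation of the radial
    distribution: int_0^Y f(y) dy = 1/2 - g(Y)."""
    kappa = np.asarray(kappa, dtype=float)
    out = np.empty_like(kappa)
    small = kappa < 0.15
    ks = kappa[small]
    if ks.size:
        acc = np.zeros_like(ks)
        for m in range(_SERIES_CAP):
            h = m + 0.5
            acc += np.exp(-h * h / ks)
        out[small] = 0.5 - 0.5 / np.sqrt(math.pi * ks) * acc
    kl = kappa[~small]
    if kl.size:
        acc = np.zeros_like(kl)
        for l in range(1, _SERIES_CAP + 1):
            term = (-1.0) ** (l + 1) * np.exp(-math.pi**2 * l * l * kl)
            acc += term
            if np.max(np.abs(term)) < _SERIES_TOL:
                break
        out[~small] = acc
    return out


def _radial_shape(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Unnormalised radial end-to-end density f(y), y = kappa (1 - x).

    Two equivalent series (Jacobi-theta duals of one another): the
    oscillating series converges fast for large y, the Hermite-type dual for
    small y (near full extension).  The split at y = 0.3 coincides with the
    classic near-extension rule r > 0.9 rho at the reference stiffness
    kappa ~ 2-3 and stays convergent for all kappa.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(y)
    valid = y > 0
    stiff = valid & (y < 0.3)
    series = valid & ~stiff
    ys = y[series]
    if ys.size:
        acc = np.zeros_like(ys)
        converged = np.zeros_like(ys, dtype=bool)
        for l in range(1, _SERIES_CAP + 1):
            pl = math.pi**2 * l * l
            term = (-1.0) ** (l + 1) * pl * np.exp(-pl * ys)
            acc += term
            converged |= np.abs(term) < _SERIES_TOL * np.maximum(np.abs(acc), 1.0)
        if not converged.all():
            raise EvaluationError(
                "end-to-end series did not converge within "
                f"{_SERIES_CAP} terms (min y = {ys.min():.3g})"
            )
        out[series] = acc
    yh = y[stiff]
    if yh.size:
        acc = np.zeros_like(yh)
        for m in range(_SERIES_CAP):
            h = m + 0.5
            term = np.exp(-h * h / yh) / np.sqrt(math.pi * yh) * (h * h / yh**2 - 0.5 / yh)
            acc += term
            if np.max(np.abs(term)) < _SERIES_TOL:
                break
        out[stiff] = acc
    return np.maximum(out, 0.0)


class _SpectralTable:
    """Exact WLC radial end-to-end density on a universal (kappa, x) grid.

    The characteristic function of the end-to-end vector is propagated in
    the Legendre basis of the tangent direction,

        d a_l / ds = -[l(l+1)/(2 kappa)] a_l
                     + i q (c_l a_{l+1} + c_{l-1} a_{l-1}),

    with isotropic ends (phi(q) = a_0(1), a_l(0) = delta_l0), and inverted
    by p(x) = (2x/pi) int q sin(qx) phi(q) dq.  A cosine taper over the top
    quarter of the q range suppresses the truncation ringing of the
    rod-like 1/q tail.  Built lazily, once per process; accuracy is a few
    0.1% of the peak across the tabulated range kappa <= 3, where the
    theta-series approximation is no longer reliable.
    """

    KAPPA_MAX = 8.0

    def __init__(self, n_kappa: int = 36, n_x: int = 1601):
        self.kappas = np.geomspace(0.15, self.KAPPA_MAX, n_kappa)
        self.x = np.linspace(0.0, 1.0, n_x)
        self.table = np.empty((n_kappa, n_x))
        for i, kappa in enumerate(self.kappas):
            self.table[i] = self._build_row(kappa)

    def _build_row(self, kappa: float) -> np.ndarray:
        from scipy.linalg import expm

        # q phi(q) is the sine transform of p(x)/x, which is supported on
        # [0, 1]; sampling at q_k = k pi therefore yields the exact sine
        # series  p(x) = 2 x sum_k q_k phi(q_k) sin(q_k x).
        l_max = int(30 + 17 * kappa)
        k_max = max(40, int((120.0 + 170.0 * kappa) / math.pi))
        l = np.arange(l_max + 1)
        diag = -l * (l + 1) / (2.0 * kappa)
        c = (l[:-1] + 1) / np.sqrt((2 * l[:-1] + 1) * (2 * l[:-1] + 3))
        base = np.diag(diag.astype(complex))
        off = np.diag(c, 1) + np.diag(c, -1)
        qk = math.pi * np.arange(1, k_max + 1)
        phi = np.empty(k_max)
        for i, qi in enumerate(qk):
            phi[i] = expm(base + 1j * qi * off)[0, 0].real
        p = 2.0 * self.x * (np.sin(np.outer(self.x, qk)) @ (qk * phi))
        p = np.clip(p, 0.0, None)
        return p / np.trapezoid(p, self.x)

    def pdf(self, x: np.ndarray, kappa: np.ndarray) -> np.ndarray:
        """Bilinear interpolation (linear in log kappa and in x)."""
        lk = np.log(np.clip(kappa, self.kappas[0], self.kappas[-1]))
        grid = np.log(self.kappas)
        j = np.clip(np.searchsorted(grid, lk) - 1, 0, len(grid) - 2)
        t = (lk - grid[j]) / (grid[j + 1] - grid[j])
        t = np.clip(t, 0.0, 1.0)
        xi = np.clip(x, 0.0, 1.0) * (len(self.x) - 1)
        i0 = np.clip(xi.astype(int), 0, len(self.x) - 2)
        u = xi - i0
        lo = self.table[j, i0] * (1 - u) + self.table[j, i0 + 1] * u
        hi = self.table[j + 1, i0] * (1 - u) + self.table[j + 1, i0 + 1] * u
        return lo * (1 - t) + hi * t


_spectral_table: _SpectralTable | None = None


def _get_spectral_table() -> _SpectralTable:
    global _spectral_table
    if _spectral_table is None:
        _spectral_table = _SpectralTable()
    return _spectral_table


def end_to_end_pdf(r, rho, L_p: float, method: str = "auto") -> np.ndarray:
    """Density P(r, rho) of the distance r between the grafted end and the
    contour point rho of a semiflexible fiber with persistence length L_p.

    Normalised so that int_0^rho P(r, rho) dr = 1; P = 0 for r > rho.
    Broadcasts over ``r`` and ``rho``.

    ``method``: "auto" (default) uses the two-branch theta series for stiff
    segments (kappa = L_p/rho > 3, where its error is below a few 0.1%) and
    the exact spectral table otherwise; "series" and "spectral" force one
    evaluation path.
    """
    if not L_p > 0:
        raise ParameterError(f"L_p must be positive, got {L_p}")
    if method not in ("auto", "series", "spectral"):
        raise ParameterError(f"unknown method {method!r}")
    r = np.asarray(r, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ParameterError("contour position rho must be positive")
    r, rho = np.broadcast_arrays(r, rho)
    r = np.atleast_1d(r)
    rho = np.atleast_1d(rho)
    kappa = L_p / rho
    x = r / rho
    inside = (x >= 0) & (x <= 1)
    out = np.zeros_like(x)
    if method == "series":
        use_series = inside
    elif method == "spectral":
        if np.any(kappa[inside] > _SpectralTable.KAPPA_MAX):
            raise ParameterError(
                f"spectral table covers kappa <= {_SpectralTable.KAPPA_MAX}"
            )
        use_series = np.zeros_like(inside)
    else:
        use_series = inside & (kappa > _SpectralTable.KAPPA_MAX)
    use_spec = inside & ~use_series
    if use_series.any():
        k = kappa[use_series]
        y = k * (1.0 - x[use_series])
        norm = rho[use_series] / k * (0.5 - _g_theta(k))
        out[use_series] = _radial_shape(y, x[use_series]) / norm
    if use_spec.any():
        tab = _get_spectral_table()
        out[use_spec] = tab.pdf(x[use_spec], kappa[use_spec]) / rho[use_spec]
    return out


# ---------------------------------------------------------------------------
# radial densities


def _gauss_nodes(a: float, b: float, n: int = 64):
    xg, wg = np.polynomial.legendre.leggauss(n)
    mid, half = 0.5 * (a + b), 0.5 * (b - a)
    return mid + half * xg, half * wg


def _clustered_nodes(a: float, b: float, n: int = 96, power: int = 4):
    """Gauss-Legendre nodes mapped by rho = a + (b-a) t**power, which packs
    nodes towards ``a``.  Resolves the near-diagonal ridge of P(r, rho):
    for stiff fibers the density at fixed r is peaked at rho barely above r
    with width ~ r^2 / (2 L_p)."""
    t, wt = _gauss_nodes(0.0, 1.0, n)
    nodes = a + (b - a) * t**power
    weights = wt * (b - a) * power * t ** (power - 1)
    return nodes, weights


def radial_density(
    r,
    j: int,
    config: SimulationConfig,
    eps: OccupancyProfile | None = None,
    n_nodes: int = 64,
) -> np.ndarray:
    """Q_j(r) = n_f int_r^L P(r, rho) eps(rho)^j drho, in um of contour per
    um of radius.  Steric constraints limit j < 3.

    The integration runs over [r, L] only (contour closer to the graft than r
    cannot reach the shell); it is split at l1, l2 where eps has kinks, and
    the segment starting at rho = r uses node clustering towards r.
    """
    if j not in (0, 1, 2):
        raise ParameterError(f"occupancy power j must be 0, 1 or 2, got {j}")
    if eps is None:
        eps = occupancy(config)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    L = config.L
    out = np.zeros_like(r)
    breakpoints = [config.l1, config.l2] if j > 0 else []
    for i, ri in enumerate(r):
        if ri >= L or ri < 0:
            continue
        lo = max(ri, 1e-9)
        pts = [lo] + [b for b in breakpoints if lo < b < L] + [L]
        total = 0.0
        for k, (aa, bb) in enumerate(zip(pts[:-1], pts[1:])):
            if k == 0:
                nodes, weights = _clustered_nodes(aa, bb, max(n_nodes, 96))
            else:
                nodes, weights = _gauss_nodes(aa, bb, n_nodes)
            pv = end_to_end_pdf(ri, nodes, config.L_p)
            w = pv if j == 0 else pv * eps(nodes) ** j
            total += float(np.sum(weights * w))
        out[i] = config.n_f * total
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# crossings


def cap_area(xi, r: float, sigma: float):
    """Area of the sphere of radius xi inside a ball of radius sigma centred
    at distance r from the origin:
    A(xi, r) = 2 pi xi [xi - (xi^2 - sigma^2 + r^2)/(2 r)].

    Defined for |xi - r| <= sigma (the sphere intersects the ball); outside
    that domain a ``ParameterError`` is raised.  At xi = r the cap area is
    pi sigma^2; it vanishes at xi = r + sigma; for xi <= sigma - r the whole
    sphere lies inside the ball (A = 4 pi xi^2, the formula's value at the
    lower contact point).
    """
    if not r > 0:
        raise ParameterError(f"r must be positive, got {r}")
    if not sigma > 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    xi = np.asarray(xi, dtype=float)
    tol = 1e-12
    outside = (xi > r + sigma + tol) | ((xi < r - sigma - tol) & (xi > sigma - r + tol))
    if np.any(outside):
        raise ParameterError(
            f"cap_area domain |xi - r| <= sigma violated (r={r}, sigma={sigma})"
        )
    return _cap_area_clamped(xi, r, sigma)


def _cap_area_clamped(xi, r, sigma):
    """cap_area with A clamped to [0, 4 pi xi^2]; valid for any xi >= 0."""
    xi = np.asarray(xi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = xi - (xi * xi - sigma * sigma + r * r) / (2.0 * r)
    A = 2.0 * math.pi * xi * np.nan_to_num(h)
    return np.clip(A, 0.0, 4.0 * math.pi * xi * xi)


def crossing_density(
    r,
    j: int,
    config: SimulationConfig,
    Q_func=None,
    n_nodes: int = 48,
) -> np.ndarray:
    """S_jj(r): density of two-fiber crossings occupied by j mitochondria on
    both fibers, in um^2 of contour pairs per um of radius.

    S_jj(r) = Q_j(r) * int_{max(r-sigma,0)}^{min(r+sigma,L)}
              Q_j(xi) A(xi, r) / (4 pi xi^2) dxi.

    ``Q_func`` maps an array of radii to Q_j values; by default it is built
    from :func:`radial_density` on a dense grid (expensive -- reuse a
    :class:`CellDensities` instance for repeated evaluations).
    """
    if j not in (0, 1):
        raise ParameterError(f"crossing order j must be 0 or 1, got {j}")
    sigma = config.sigma
    if Q_func is None:
        dens = CellDensities(config)
        Q_func = dens.Q0 if j == 0 else dens.Q1
    r = np.atleast_1d(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    for i, ri in enumerate(r):
        if not ri > 0:
            continue
        lo = max(ri - sigma, 1e-9)
        hi = min(ri + sigma, config.L)
        if hi <= lo:
            continue
        nodes, weights = _gauss_nodes(lo, hi, n_nodes)
        ball_mass = float(
            np.sum(
                weights
                * Q_func(nodes)
                * _cap_area_clamped(nodes, ri, sigma)
                / (4.0 * math.pi * nodes**2)
            )
        )
        out[i] = Q_func(np.array([ri]))[0] * ball_mass
    return out if out.shape else float(out)


def crossing_density_asymptotic(r, Q0, sigma: float):
    """Bulk approximation S_jj ~ sigma^3 Q_j(r)^2 / (3 r^2), valid where Q_j
    varies little over a sigma-neighbourhood of r."""
    r = np.asarray(r, dtype=float)
    Q0 = np.asarray(Q0, dtype=float)
    return sigma**3 * Q0**2 / (3.0 * r**2)


# ---------------------------------------------------------------------------
# bundled profiles


@dataclass
class RadialProfile:
    """A quantity tabulated on shells of width dr."""

    r: np.ndarray
    values: np.ndarray
    name: str
    units: str

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"r": self.r, self.name: self.values})


class CellDensities:
    """Precomputed eps, Q_j and S_jj for one configuration.

    Profiles are evaluated on a dense internal grid once and interpolated
    thereafter, which makes the downstream rate fields cheap.  Callables
    ``Q0``, ``Q1``, ``Q2``, ``S00``, ``S11`` accept radius arrays (um) and
    return densities in um (contour) or um^2 (contour pairs) per um of
    radius.
    """

    def __init__(self, config: SimulationConfig, n_grid: int = 400, n_nodes: int = 64):
        self.config = config
        self.eps = occupancy(config)
        L = config.L
        self._grid = np.linspace(L / n_grid * 0.5, L * (1 - 1e-9), n_grid)
        self._q = {
            j: radial_density(self._grid, j, config, eps=self.eps, n_nodes=n_nodes)
            for j in (0, 1, 2)
        }
        self._s = {}

    def _interp(self, table: np.ndarray):
        grid = self._grid

        def f(r):
            r = np.asarray(r, dtype=float)
            return np.interp(r, grid, table, left=table[0], right=0.0)

        return f

    @property
    def Q0(self):
        return self._interp(self._q[0])

    @property
    def Q1(self):
        return self._interp(self._q[1])

    @property
    def Q2(self):
        return self._interp(self._q[2])

    def _S(self, j: int):
        if j not in self._s:
            Q_func = self._interp(self._q[j])
            self._s[j] = crossing_density(self._grid, j, self.config, Q_func=Q_func)
        return self._interp(self._s[j])

    @property
    def S00(self):
        return self._S(0)

    @property
    def S11(self):
        return self._S(1)

    def profile(self, name: str, r=None) -> RadialProfile:
        """Tabulate one of Q0/Q1/Q2/S00/S11 on the config's shell grid."""
        if r is None:
            r = self.config.r_grid
        func = getattr(self, name)
        units = "um/um" if name.startswith("Q") else "um^2/um"
        return RadialProfile(r=np.asarray(r), values=func(r), name=name, units=units)
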