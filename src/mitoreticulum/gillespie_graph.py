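"""Exact stochastic (agent-based) simulation of the fission/fusion graph.

The chondriome slice at one radial shell is a set of ``n_edges`` unit-length
edges whose endpoints are grouped into nodes of degree 1-3.  Four reaction
channels evolve it (Gillespie's direct method, two uniform random numbers per
event):

* tip-to-tip fusion   U1 + U1 -> U2   propensity (k+/Omega) u1(u1-1)/2
* bulk fission        U2 -> U1 + U1   propensity k-  u2
* tip-to-side fusion  U1 + U2 -> U3   propensity (l+/Omega) u1 u2
* branch fission      U3 -> U1 + U2   propensity l-  u3

with k+/k- = alpha_1, l+/l- = alpha_2 and the volume factor Omega equal to
the shell width dr, which makes the intensive rates match the deterministic
shell equations of :mod:`mitoreticulum.graph_dynamics`.  Fission and fusion
conserve the edge count exactly; node degrees never exceed 3 by
construction.

Fusing the two ends of a single edge onto each other (a one-edge loop,
directly or through a bulk node) is excluded; cycles spanning two or more
edges are allowed.  Excluded picks are realised as exact null events: time
advances, the state does not, which reproduces the process with per-pair
rates on the allowed transitions only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .errors import ParameterError
from .graph_dynamics import rate_field
from .wlc_theory import CellDensities

__all__ = [
    "MitoGraph",
    "Rates",
    "EventChannel",
    "RunSummary",
    "ClusterSizeDistribution",
    "init_fragmented",
    "init_chain",
    "propensities",
    "run",
    "equilibrate",
    "cluster_sizes",
    "largest_cluster_fraction",
    "stationary_ensemble",
    "allocate_shell_edges",
    "radial_ensemble",
]


# ---------------------------------------------------------------------------
# graph state


class MitoGraph:
    """Dynamic graph of fixed-length mitochondrial edges.

    Edge ``e`` owns endpoints ``2e`` and ``2e+1``; a node is a set of 1-3
    endpoints fused together.  Nodes are indexed per degree for O(1) uniform
    sampling.
    """

    __slots__ = ("n_edges", "node_of", "members", "_by_deg", "_pos", "_next")

    def __init__(self, n_edges: int):
        if n_edges < 1:
            raise ParameterError(f"n_edges must be >= 1, got {n_edges}")
        self.n_edges = n_edges
        self.node_of = [0] * (2 * n_edges)
        self.members: dict[int, list[int]] = {}
        self._by_deg: tuple[list[int], ...] = ([], [], [], [])  # index by degree-1
        self._pos: dict[int, int] = {}
        self._next = 0

    # -- bookkeeping -------------------------------------------------------

    def _new_node(self, endpoints: list[int]) -> int:
        nid = self._next
        self._next += 1
        self.members[nid] = endpoints
        for ep in endpoints:
            self.node_of[ep] = nid
        lst = self._by_deg[len(endpoints) - 1]
        self._pos[nid] = len(lst)
        lst.append(nid)
        return nid

    def _drop_node(self, nid: int) -> list[int]:
        eps = self.members.pop(nid)
        lst = self._by_deg[len(eps) - 1]
        i = self._pos.pop(nid)
        last = lst.pop()
        if last != nid:
            lst[i] = last
            self._pos[last] = i
        return eps

    # -- queries -----------------------------------------------------------

    def degree_counts(self) -> tuple[int, int, int]:
        d = self._by_deg
        return len(d[0]), len(d[1]), len(d[2])

    def degree_of(self, nid: int) -> int:
        return len(self.members[nid])

    def sample_node(self, degree: int, rng) -> int:
        lst = self._by_deg[degree - 1]
        return lst[int(rng.random() * len(lst))]

    def max_degree(self) -> int:
        for d in (3, 2, 1):
            if self._by_deg[d - 1]:
                return d
        return 0

    # -- transformations ---------------------------------------------------

    def fuse(self, na: int, nb: int) -> int:
        """Merge two nodes (tip-to-tip or tip-to-side)."""
        eps = self._drop_node(na) + self._drop_node(nb)
        return self._new_node(eps)

    def split_bulk(self, nid: int) -> tuple[int, int]:
        """Degree-2 fission: one bulk node into two free ends."""
        e1, e2 = self._drop_node(nid)
        return self._new_node([e1]), self._new_node([e2])

    def split_branch(self, nid: int, which: int) -> tuple[int, int]:
        """Degree-3 fission: detach endpoint ``which`` (0..2) as a free end,
        the exact reverse of tip-to-side fusion."""
        eps = self._drop_node(nid)
        detached = eps.pop(which)
        return self._new_node([detached]), self._new_node(eps)

    # -- structure ---------------------------------------------------------

    def cluster_edge_sizes(self) -> np.ndarray:
        """Sizes (in edges) of the connected components."""
        parent = list(range(self.n_edges))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for eps in self.members.values():
            if len(eps) > 1:
                r0 = find(eps[0] >> 1)
                for ep in eps[1:]:
                    r = find(ep >> 1)
                    if r != r0:
                        parent[r] = r0
        counts: dict[int, int] = {}
        for e in range(self.n_edges):
            r = find(e)
            counts[r] = counts.get(r, 0) + 1
        return np.array(sorted(counts.values(), reverse=True))

    def to_networkx(self):
        """Multigraph with one vertex per node and one link per edge."""
        import networkx as nx

        g = nx.MultiGraph()
        g.add_nodes_from(self.members)
        for e in range(self.n_edges):
            g.add_edge(self.node_of[2 * e], self.node_of[2 * e + 1], edge_id=e)
        return g

    def check_invariants(self) -> None:
        degs = [len(v) for v in self.members.values()]
        assert sum(degs) == 2 * self.n_edges, "endpoint count mismatch"
        assert all(1 <= d <= 3 for d in degs), "degree outside 1..3"
        for e in range(self.n_edges):
            assert self.node_of[2 * e] != self.node_of[2 * e + 1], "single-edge loop"


def init_fragmented(n_edges: int) -> MitoGraph:
    """Fully fragmented chondriome: every edge isolated, u1 = 2 n."""
    g = MitoGraph(n_edges)
    for ep in range(2 * n_edges):
        g._new_node([ep])
    return g


def init_chain(n_edges: int) -> MitoGraph:
    """Fully fused linear chain: u1 = 2, u2 = n - 1."""
    g = MitoGraph(n_edges)
    g._new_node([0])
    for e in range(n_edges - 1):
        g._new_node([2 * e + 1, 2 * e + 2])
    g._new_node([2 * n_edges - 1])
    return g


# ---------------------------------------------------------------------------
# rates and propensities


@dataclass
class Rates:
    """Absolute channel rates.

    ``k_minus`` and ``l_minus`` set the timescale (default 1; only the
    ratios alpha shape the stationary structure); ``omega`` is the volume
    factor (shell width dr in um)."""

    alpha1: float
    alpha2: float
    k_minus: float = 1.0
    l_minus: float = 1.0
    omega: float = 1.0

    @property
    def k_plus_pair(self) -> float:
        return self.alpha1 * self.k_minus / self.omega

    @property
    def l_plus_pair(self) -> float:
        return self.alpha2 * self.l_minus / self.omega


@dataclass
class EventChannel:
    kind: str
    propensity: float


def _n_isolated_edges(g: MitoGraph) -> int:
    node_of, members = g.node_of, g.members
    return sum(
        1
        for e in range(g.n_edges)
        if len(members[node_of[2 * e]]) == 1 and len(members[node_of[2 * e + 1]]) == 1
    )


def _n_forbidden_tip_side(g: MitoGraph) -> int:
    """(tip, bulk-node) picks that would loop a single edge: edges with one
    free end whose other endpoint sits in a degree-2 node."""
    node_of, members = g.node_of, g.members
    n = 0
    for e in range(g.n_edges):
        da = len(members[node_of[2 * e]])
        db = len(members[node_of[2 * e + 1]])
        if (da == 1 and db == 2) or (da == 2 and db == 1):
            n += 1
    return n


def propensities(graph: MitoGraph, rates: Rates) -> list[EventChannel]:
    """Exact channel propensities for the current state (self-loop-excluded
    pair counts)."""
    u1, u2, u3 = graph.degree_counts()
    pairs_tt = u1 * (u1 - 1) // 2 - _n_isolated_edges(graph)
    pairs_ts = u1 * u2 - _n_forbidden_tip_side(graph)
    return [
        EventChannel("tip_tip_fuse", rates.k_plus_pair * max(pairs_tt, 0)),
        EventChannel("deg2_fission", rates.k_minus * u2),
        EventChannel("tip_side_fuse", rates.l_plus_pair * max(pairs_ts, 0)),
        EventChannel("deg3_fission", rates.l_minus * u3),
    ]


# ---------------------------------------------------------------------------
# the event loop


@dataclass
class RunSummary:
    """Trajectory summary of one Gillespie run."""

    t_end: float
    n_events: int
    n_null: int
    u_mean: np.ndarray  # time-averaged (u1, u2, u3) counts
    max_degree: int
    absorbed: bool = False
    cluster_sizes: np.ndarray | None = None


def run(
    graph: MitoGraph,
    rates: Rates,
    n_events: int | None = None,
    rng: np.random.Generator | None = None,
    record: bool = True,
    t_end: float | None = None,
) -> RunSummary:
    """Advance ``graph`` by ``n_events`` Gillespie events (or until the
    simulated time exceeds ``t_end``) in place.

    Event selection is the standard two-random-number scheme (exponential
    waiting time, propensity-proportional channel); concrete nodes are chosen
    uniformly within the channel.  Excluded picks (single-edge loops) are
    exact null events.  Returns time-averaged node counts when ``record``.

    Sampling note: the state at a fixed simulated *time* is distributed by
    the stationary law; the state right after the N-th event is biased by
    the jump chain.  Use ``t_end`` (or the time-averaged ``u_mean``) for
    stationary statistics.
    """
    if n_events is None and t_end is None:
        raise ParameterError("specify n_events and/or t_end")
    if n_events is None:
        n_events = 2**63 - 1
    if rng is None:
        rng = np.random.default_rng()
    kp = rates.k_plus_pair
    lp = rates.l_plus_pair
    km = rates.k_minus
    lm = rates.l_minus
    node_of = graph.node_of
    members = graph.members
    t = 0.0
    n_null = 0
    max_deg = graph.max_degree()
    u_acc = np.zeros(3)
    u1, u2, u3 = graph.degree_counts()
    rand = rng.random
    log = math.log
    for step in range(n_events):
        a_tt = kp * u1 * (u1 - 1) * 0.5
        a_2 = km * u2
        a_ts = lp * u1 * u2
        a_3 = lm * u3
        total = a_tt + a_2 + a_ts + a_3
        if total <= 0.0:
            return RunSummary(
                t_end=t,
                n_events=step,
                n_null=n_null,
                u_mean=(u_acc / t if (record and t > 0) else np.array([u1, u2, u3], float)),
                max_degree=max_deg,
                absorbed=True,
                cluster_sizes=graph.cluster_edge_sizes() if record else None,
            )
        dt = -log(1.0 - rand()) / total
        if t_end is not None and t + dt > t_end:
            if record:
                u_acc += np.array([u1, u2, u3]) * (t_end - t)
            t = t_end
            return RunSummary(
                t_end=t,
                n_events=step,
                n_null=n_null,
                u_mean=(u_acc / t if (record and t > 0) else np.array([u1, u2, u3], float)),
                max_degree=max_deg,
                cluster_sizes=graph.cluster_edge_sizes() if record else None,
            )
        if record:
            u_acc += np.array([u1, u2, u3]) * dt
        t += dt
        x = rand() * total
        if x < a_tt:
            lst = graph._by_deg[0]
            i1 = int(rand() * u1)
            i2 = int(rand() * (u1 - 1))
            if i2 >= i1:
                i2 += 1
            na, nb = lst[i1], lst[i2]
            ea = members[na][0]
            eb = members[nb][0]
            if eb == (ea ^ 1):
                n_null += 1  # the two ends of one isolated edge
                continue
            graph.fuse(na, nb)
            u1 -= 2
            u2 += 1
        elif x < a_tt + a_2:
            nid = graph.sample_node(2, rng)
            graph.split_bulk(nid)
            u1 += 2
            u2 -= 1
        elif x < a_tt + a_2 + a_ts:
            na = graph.sample_node(1, rng)
            nb = graph.sample_node(2, rng)
            ea = members[na][0]
            if (ea ^ 1) in members[nb]:
                n_null += 1  # would loop a single edge through a bulk node
                continue
            graph.fuse(na, nb)
            u1 -= 1
            u2 -= 1
            u3 += 1
            if max_deg < 3:
                max_deg = 3
        else:
            nid = graph.sample_node(3, rng)
            graph.split_branch(nid, int(rand() * 3))
            u1 += 1
            u2 += 1
            u3 -= 1
        if u2 > 0 and max_deg < 2:
            max_deg = 2
    return RunSummary(
        t_end=t,
        n_events=n_events,
        n_null=n_null,
        u_mean=(u_acc / t if (record and t > 0) else np.array([u1, u2, u3], float)),
        max_degree=max_deg,
        cluster_sizes=graph.cluster_edge_sizes() if record else None,
    )


def equilibrate(
    graph: MitoGraph,
    rates: Rates,
    rng: np.random.Generator,
    burnin_per_edge: int = 20,
    window_per_edge: int = 10,
    max_windows: int = 8,
    z: float = 1.96,
) -> int:
    """Drive ``graph`` to stationarity in place; returns events consumed.

    Burn-in of ``burnin_per_edge`` events per edge, then windows of
    ``window_per_edge`` events per edge until the u1 means of two consecutive
    windows agree within ``z`` combined standard errors (batch means of 4
    sub-windows), or ``max_windows`` is hit.
    """
    n = graph.n_edges
    consumed = run(graph, rates, burnin_per_edge * n, rng, record=False).n_events
    w = max(window_per_edge * n, 40)
    prev = None
    for _ in range(max_windows):
        batches = []
        for _ in range(4):
            s = run(graph, rates, w // 4, rng, record=True)
            consumed += s.n_events
            batches.append(s.u_mean[0])
            if s.absorbed:
                return consumed
        mean = float(np.mean(batches))
        se = float(np.std(batches, ddof=1) / 2.0)
        if prev is not None:
            pm, pse = prev
            if abs(mean - pm) <= z * math.hypot(se, pse) + 1e-9:
                return consumed
        prev = (mean, se)
    return consumed


# ---------------------------------------------------------------------------
# cluster statistics


@dataclass
class ClusterSizeDistribution:
    """Histogram of connected-component sizes (in edges) over an ensemble."""

    sizes: np.ndarray  # all cluster sizes pooled over runs
    n_runs: int
    n_edges: int
    largest_fractions: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def probabilities(self):
        """(size, probability) over distinct sizes; probabilities sum to 1."""
        vals, counts = np.unique(self.sizes, return_counts=True)
        return vals, counts / counts.sum()

    @property
    def mean_size(self) -> float:
        return float(np.mean(self.sizes))

    @property
    def largest_fraction(self) -> float:
        """Ensemble mean of (largest component)/(total edges)."""
        return float(np.mean(self.largest_fractions))

    def to_dataframe(self):
        import pandas as pd

        vals, probs = self.probabilities
        counts = np.round(probs * len(self.sizes)).astype(int)
        return pd.DataFrame({"size": vals, "count": counts, "probability": probs})


def cluster_sizes(graph: MitoGraph) -> ClusterSizeDistribution:
    sizes = graph.cluster_edge_sizes()
    return ClusterSizeDistribution(
        sizes=sizes,
        n_runs=1,
        n_edges=graph.n_edges,
        largest_fractions=np.array([sizes.max() / graph.n_edges]),
    )


def largest_cluster_fraction(distributions) -> np.ndarray:
    """Ensemble-mean largest-cluster fraction per shell/distribution."""
    return np.array([d.largest_fraction for d in distributions])


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class EnsembleResult:
    """Stationary statistics of independent runs at fixed parameters."""

    n_edges: int
    n_runs: int
    clusters: ClusterSizeDistribution
    u_mean: np.ndarray  # ensemble mean of time-averaged (u1, u2, u3)
    u_se: np.ndarray  # standard error of the ensemble mean
    max_degree: int


def stationary_ensemble(
    n_edges: int,
    rates: Rates,
    n_runs: int,
    seed: int | np.random.SeedSequence = 0,
    sample_per_edge: int = 10,
    init: str = "fragmented",
) -> EnsembleResult:
    """Equilibrate ``n_runs`` independently seeded systems and pool their
    stationary statistics (counter-based per-run substreams)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n_runs)
    all_sizes = []
    fractions = np.empty(n_runs)
    u = np.empty((n_runs, 3))
    max_deg = 0
    for i in range(n_runs):
        rng = np.random.default_rng(streams[i])
        g = init_chain(n_edges) if init == "chain" else init_fragmented(n_edges)
        equilibrate(g, rates, rng)
        s = run(g, rates, max(sample_per_edge * n_edges, 40), rng, record=True)
        sizes = s.cluster_sizes if s.cluster_sizes is not None else g.cluster_edge_sizes()
        all_sizes.append(sizes)
        fractions[i] = sizes.max() / n_edges
        u[i] = s.u_mean
        max_deg = max(max_deg, s.max_degree)
    pooled = np.concatenate(all_sizes)
    dist = ClusterSizeDistribution(
        sizes=pooled, n_runs=n_runs, n_edges=n_edges, largest_fractions=fractions
    )
    return EnsembleResult(
        n_edges=n_edges,
        n_runs=n_runs,
        clusters=dist,
        u_mean=u.mean(axis=0),
        u_se=u.std(axis=0, ddof=1) / math.sqrt(n_runs) if n_runs > 1 else np.zeros(3),
        max_degree=max_deg,
    )


def allocate_shell_edges(q1, dr: float, total_edges: int) -> np.ndarray:
    """Integer edges per shell from the density q1 (edges/um), largest-
    remainder rounding so the counts sum exactly to ``total_edges``."""
    q1 = np.asarray(q1, dtype=float)
    weight = np.clip(q1, 0.0, None) * dr
    if weight.sum() <= 0:
        raise ParameterError("cannot allocate edges: empty density profile")
    ideal = weight / weight.sum() * total_edges
    base = np.floor(ideal).astype(int)
    short = total_edges - int(base.sum())
    if short > 0:
        order = np.argsort(ideal - base)[::-1]
        base[order[:short]] += 1
    return base


def radial_ensemble(
    config: SimulationConfig,
    densities: CellDensities | None = None,
    gamma: float | None = None,
    probe_radii=None,
    n_runs: int | None = None,
    seed: int | None = None,
    sample_per_edge: int = 10,
) -> dict[float, EnsembleResult]:
    """Independent per-shell stationary ensembles.

    ``probe_radii`` selects shells (nearest grid shell per radius; default:
    the whole grid); shells allocated fewer than 2 edges are skipped.  Edge
    counts per shell follow Q1(r) dr with exact-total rounding, so the
    summed edge length over all shells equals M.
    """
    if densities is None:
        densities = CellDensities(config)
    rf = rate_field(config, densities=densities, gamma=gamma)
    counts = allocate_shell_edges(rf.q1, config.dr, config.n_edges_total)
    r_grid = rf.r
    if probe_radii is None:
        idx = range(len(r_grid))
    else:
        idx = [int(np.argmin(np.abs(r_grid - r))) for r in probe_radii]
    if n_runs is None:
        n_runs = config.n_runs
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    shells = master.spawn(len(r_grid))
    out: dict[float, EnsembleResult] = {}
    for i in idx:
        if counts[i] < 2:
            continue
        rates = Rates(alpha1=rf.alpha1[i], alpha2=rf.alpha2[i], omega=config.dr)
        out[float(r_grid[i])] = stationary_ensemble(
            int(counts[i]), rates, n_runs, seed=shells[i], sample_per_edge=sample_per_edge
        )
    return out
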