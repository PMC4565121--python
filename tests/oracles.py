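"""Independent oracles used by the test suite.

These deliberately avoid the package's own event loop and solvers:

* :func:`enumerate_ctmc` builds the full continuous-time Markov chain of the
  fission/fusion graph on a tiny edge set by brute-force state enumeration
  and solves its stationary distribution with a dense linear solve.
* :func:`ode_steady_state` integrates the mass-action rate equations to
  equilibrium with an off-the-shelf stiff integrator.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive CTMC on labelled endpoint partitions


def _canon(state: frozenset) -> frozenset:
    return state


def _blocks(state):
    return [tuple(sorted(b)) for b in state]


def state_key(state: frozenset, n_edges: int):
    """Observable class of a labelled state: node degree counts plus the
    sorted cluster-size multiset (the statistics the simulation reports)."""
    blocks = _blocks(state)
    degs = [len(b) for b in blocks]
    u = (degs.count(1), degs.count(2), degs.count(3))
    parent = list(range(n_edges))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b in blocks:
        for ep in b[1:]:
            r1, r2 = find(b[0] // 2), find(ep // 2)
            if r1 != r2:
                parent[r1] = r2
    sizes = {}
    for e in range(n_edges):
        r = find(e)
        sizes[r] = sizes.get(r, 0) + 1
    return u + (tuple(sorted(sizes.values())),)


def _forbidden_merge(b1, b2) -> bool:
    """True when merging two blocks would fuse both ends of one edge."""
    for ep in b1:
        if (ep ^ 1) in b2:
            return True
    return False


def enumerate_ctmc(n_edges: int, k_plus: float, k_minus: float, l_plus: float, l_minus: float):
    """All reachable graph states and the stationary distribution.

    States are partitions of the 2*n_edges endpoints into blocks of size
    <= 3 with no block containing both ends of one edge.  Transitions follow
    the four reaction channels with per-pair rates ``k_plus``/``l_plus`` and
    per-node rates ``k_minus``/``l_minus`` (branch fission splits off each
    of the three endpoints at l_minus/3).

    Returns (states, index, Q) with Q the generator matrix.
    """
    start = frozenset(frozenset([ep]) for ep in range(2 * n_edges))
    states = [start]
    index = {start: 0}
    transitions = []  # (i, j, rate)
    frontier = [start]
    while frontier:
        nxt = []
        for state in frontier:
            i = index[state]
            blocks = sorted(_blocks(state))
            singles = [b for b in blocks if len(b) == 1]
            doubles = [b for b in blocks if len(b) == 2]
            triples = [b for b in blocks if len(b) == 3]

            def push(new_state, rate):
                if new_state not in index:
                    index[new_state] = len(states)
                    states.append(new_state)
                    nxt.append(new_state)
                transitions.append((i, index[new_state], rate))

            for b1, b2 in combinations(singles, 2):
                if _forbidden_merge(b1, b2):
                    continue
                new = frozenset(
                    fb
                    for fb in state
                    if fb != frozenset(b1) and fb != frozenset(b2)
                ) | {frozenset(b1 + b2)}
                push(new, k_plus)
            for b in doubles:
                new = (state - {frozenset(b)}) | {frozenset([b[0]]), frozenset([b[1]])}
                push(new, k_minus)
            for b1 in singles:
                for b2 in doubles:
                    if _forbidden_merge(b1, b2):
                        continue
                    new = (state - {frozenset(b1), frozenset(b2)}) | {frozenset(b1 + b2)}
                    push(new, l_plus)
            for b in triples:
                for ep in b:
                    rest = tuple(x for x in b if x != ep)
                    new = (state - {frozenset(b)}) | {frozenset([ep]), frozenset(rest)}
                    push(new, l_minus / 3.0)
        frontier = nxt
    n = len(states)
    Q = np.zeros((n, n))
    for i, j, rate in transitions:
        Q[i, j] += rate
    np.fill_diagonal(Q, -Q.sum(axis=1) + np.diag(Q))
    return states, index, Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Solve pi Q = 0, sum(pi) = 1 by a dense least-squares solve."""
    n = len(Q)
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def class_distribution(n_edges, k_plus, k_minus, l_plus, l_minus):
    """Stationary probability of each observable state class."""
    states, _, Q = enumerate_ctmc(n_edges, k_plus, k_minus, l_plus, l_minus)
    pi = stationary_distribution(Q)
    out: dict[tuple, float] = {}
    for s, p in zip(states, pi):
        key = state_key(s, n_edges)
        out[key] = out.get(key, 0.0) + p
    return out


# ---------------------------------------------------------------------------
# mass-action ODE oracle


def ode_steady_state(q1: float, alpha1: float, alpha2: float, t_end: float = 1e4):
    """Equilibrium of the mass-action fission/fusion system by long-time
    integration, starting fully fragmented (u1 = 2 q1).

    Reactions (k- = l- = 1): tip-to-tip at rate (alpha1/2) u1^2 forward and
    u2 backward; tip-to-side at rate alpha2 u1 u2 forward and u3 backward.
    """
    from scipy.integrate import solve_ivp

    def rhs(_, u):
        u1, u2, u3 = u
        r1 = 0.5 * alpha1 * u1 * u1 - u2
        r2 = alpha2 * u1 * u2 - u3
        return [-2.0 * r1 - r2, r1 - r2, r2]

    sol = solve_ivp(
        rhs, (0.0, t_end), [2.0 * q1, 0.0, 0.0], method="LSODA", rtol=1e-12, atol=1e-12
    )
    return sol.y[:, -1]
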