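"""Harmonic transition-state-theory kinetics on a KTN.

Provides microscopic TST rates between adjacent minima, assembly of the full
rate matrix, effective two-state rates between arbitrary sets of minima via
mean first-passage times, Eyring conversions between rates and free-energy
barriers, the two-state exchange decomposition used for NMR chemical
exchange, and extraction of the fastest (highest-probability) path.

Rate convention: the harmonic TST rate out of minimum ``a`` through
transition state ``ts`` is

    k(a ->) = (o_a / o_ts) * exp(log_prod_a - log_prod_ts)
              * exp(-(V_ts - V_a) / k_B T)

where the log-product difference (kappa minimum modes vs kappa-1 saddle
modes) carries the s^-1 attempt frequency.  These rates satisfy detailed
balance with the harmonic-superposition weights exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .constants import KB_KCAL, T_DEFAULT, beta, eyring_prefactor
from .harmonic_thermo import equilibrium_occupations
from .ktn_io import KTN, Minimum, TransitionState

__all__ = [
    "RateMatrix",
    "TwoStateResult",
    "tst_rate",
    "exchange_to_microrates",
    "eyring_barrier",
    "barrier_to_rate",
    "build_rate_matrix",
    "two_state_rates",
    "fastest_path",
    "path_annotation",
]


def tst_rate(minimum: Minimum, ts: TransitionState, T: float = T_DEFAULT) -> float:
    """Harmonic TST escape rate (s^-1) from ``minimum`` over ``ts``."""
    if ts.min1 != minimum.id and ts.min2 != minimum.id:
        raise ValueError(
            f"transition state {ts.id} does not connect minimum {minimum.id}"
        )
    b = beta(T)
    return (
        (minimum.pg_order / ts.pg_order)
        * np.exp(minimum.log_prod - ts.log_prod)
        * np.exp(-(ts.V - minimum.V) * b)
    )


def exchange_to_microrates(k_ex: float, p_minor: float) -> tuple[float, float]:
    """Split a two-state exchange rate into forward and reverse rates.

    In two-state chemical exchange ``k_ex = k_f + k_r`` and the minor-state
    population fixes the split: ``k_f = p_minor * k_ex`` (major -> minor),
    ``k_r = (1 - p_minor) * k_ex``.
    """
    if not 0.0 < p_minor < 1.0:
        raise ValueError("minor-state population must lie in (0, 1)")
    if k_ex <= 0:
        raise ValueError("exchange rate must be positive")
    return p_minor * k_ex, (1.0 - p_minor) * k_ex


def eyring_barrier(k: float, T: float = T_DEFAULT) -> float:
    """Effective free-energy barrier (kcal/mol) of a rate via the Eyring relation.

    ``dG = k_B T ln(k_B T / (h k))`` with unit transmission coefficient.
    """
    if k <= 0:
        raise ValueError("rate must be positive")
    return KB_KCAL * T * np.log(eyring_prefactor(T) / k)


def barrier_to_rate(dG: float, T: float = T_DEFAULT) -> float:
    """Inverse of :func:`eyring_barrier`: ``k = (k_B T / h) exp(-dG / k_B T)``."""
    return eyring_prefactor(T) * np.exp(-dG / (KB_KCAL * T))


@dataclass
class RateMatrix:
    """Inter-minimum rate-constant matrix at one temperature.

    ``K[i, j]`` is the rate (s^-1) from the minimum at storage index ``j``
    to the one at index ``i``, summed over all connecting transition states;
    diagonal entries are minus the column escape sums so that the master
    equation reads ``dp/dt = K p``.
    """

    T: float
    ids: np.ndarray
    K: np.ndarray

    def index_of(self, mid: int) -> int:
        where = np.flatnonzero(self.ids == mid)
        if where.size == 0:
            raise KeyError(f"minimum id {mid} not in rate matrix")
        return int(where[0])

    def rate(self, a: int, b: int) -> float:
        """Rate constant from minimum id ``a`` to minimum id ``b``."""
        return float(self.K[self.index_of(b), self.index_of(a)])


def build_rate_matrix(ktn: KTN, T: float = T_DEFAULT) -> RateMatrix:
    """Assemble the full TST rate matrix; parallel transition states sum.

    Degenerate-rearrangement saddles (min1 == min2) contribute nothing.
    Disconnected minima are allowed and simply have zero rates.
    """
    idx = {m.id: i for i, m in enumerate(ktn.minima)}
    n = ktn.n_minima
    K = np.zeros((n, n))
    by_id = {m.id: m for m in ktn.minima}
    for ts in ktn.edges():
        a, b = ts.min1, ts.min2
        K[idx[b], idx[a]] += tst_rate(by_id[a], ts, T)
        K[idx[a], idx[b]] += tst_rate(by_id[b], ts, T)
    np.fill_diagonal(K, 0.0)
    K[np.diag_indices(n)] = -K.sum(axis=0)
    return RateMatrix(T=T, ids=np.array([m.id for m in ktn.minima]), K=K)


@dataclass
class TwoStateResult:
    """Effective two-state kinetics between two sets of minima."""

    k_f: float
    k_r: float
    dG_f: float
    dG_r: float
    T: float

    @property
    def k_ex(self) -> float:
        return self.k_f + self.k_r


def _mfpt_to(rm: RateMatrix, targets: np.ndarray) -> np.ndarray:
    """Mean first-passage time to the target set from every non-target state.

    Solves the linear system of the generator restricted to non-target
    states; raises ``np.linalg.LinAlgError`` via a singular-matrix check when
    the target set is unreachable from some source.
    """
    n = rm.K.shape[0]
    keep = np.setdiff1d(np.arange(n), targets)
    # Generator with rows as sources: Q[i, j] = k(i -> j), Q[i, i] = -escape
    Q = rm.K.T
    Qsub = Q[np.ix_(keep, keep)]
    tau = np.full(n, 0.0)
    try:
        tau[keep] = np.linalg.solve(Qsub, -np.ones(keep.size))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "target set unreachable from part of the network "
            f"(singular restricted generator): {err}"
        ) from None
    if np.any(tau[keep] < 0):
        raise np.linalg.LinAlgError(
            "negative mean first-passage time: target set unreachable "
            "from some source states"
        )
    return tau


def two_state_rates(
    ktn: KTN,
    set_a,
    set_b,
    T: float = T_DEFAULT,
) -> TwoStateResult:
    """Effective A<->B rates as inverse equilibrium-averaged MFPTs.

    ``k_(A->B) = 1 / <tau_B>_A`` where the mean first-passage time to the
    absorbing B set is averaged over starting minima in A with equilibrium
    weights conditioned on A.  Barriers follow from :func:`eyring_barrier`.
    The two-state detailed-balance relation ``k_f / k_r = P_B / P_A`` holds
    exactly in the metastable (two-state) limit.
    """
    set_a, set_b = set(set_a), set(set_b)
    if not set_a or not set_b:
        raise ValueError("both minimum sets must be nonempty")
    if set_a & set_b:
        raise ValueError("the two sets must be disjoint")
    rm = build_rate_matrix(ktn, T)
    occ = equilibrium_occupations(ktn, T)
    p = occ.p
    ia = np.array(sorted(rm.index_of(m) for m in set_a))
    ib = np.array(sorted(rm.index_of(m) for m in set_b))

    tau_to_b = _mfpt_to(rm, ib)
    tau_to_a = _mfpt_to(rm, ia)
    mfpt_ab = float(p[ia] @ tau_to_b[ia] / p[ia].sum())
    mfpt_ba = float(p[ib] @ tau_to_a[ib] / p[ib].sum())
    k_f, k_r = 1.0 / mfpt_ab, 1.0 / mfpt_ba
    return TwoStateResult(
        k_f=k_f, k_r=k_r,
        dG_f=eyring_barrier(k_f, T), dG_r=eyring_barrier(k_r, T),
        T=T,
    )


def _branching_graph(ktn: KTN, T: float) -> nx.DiGraph:
    """Directed graph weighted by -ln of branching probabilities.

    ``P(a -> b) = k(a -> b) / sum_c k(a -> c)`` with rates summed over
    parallel transition states; each directed edge stores the lowest-energy
    connecting transition state (ties broken by smallest ts id).
    """
    rm = build_rate_matrix(ktn, T)
    g = nx.DiGraph()
    g.add_nodes_from(rm.ids.tolist())
    best_ts: dict[tuple[int, int], TransitionState] = {}
    for ts in ktn.edges():
        for pair in [(ts.min1, ts.min2), (ts.min2, ts.min1)]:
            cur = best_ts.get(pair)
            if cur is None or (ts.V, ts.id) < (cur.V, cur.id):
                best_ts[pair] = ts
    escape = -np.diag(rm.K)
    for (a, b), ts in best_ts.items():
        k_ab = rm.rate(a, b)
        out = escape[rm.index_of(a)]
        if k_ab <= 0 or out <= 0:
            continue
        g.add_edge(a, b, weight=-float(np.log(k_ab / out)), ts=ts)
    return g


def fastest_path(ktn: KTN, a: int, b: int, T: float = T_DEFAULT) -> list:
    """Highest-probability path from minimum ``a`` to ``b``.

    Minimises the sum of ``-ln P(edge)`` over directed branching
    probabilities (waiting times are ignored, as in the best-path notion of
    discrete path sampling).  Returns an alternating sequence
    ``[Minimum, TransitionState, Minimum, ...]``; ties between equal-weight
    paths are broken deterministically towards smaller transition-state ids.
    """
    by_id = {m.id: m for m in ktn.minima}
    if a not in by_id or b not in by_id:
        raise KeyError("path endpoints must be minima of the network")
    if a == b:
        return [by_id[a]]
    g = _branching_graph(ktn, T)
    nodes = _dijkstra_lex(g, a, b)
    if nodes is None:
        raise nx.NetworkXNoPath(f"no path between minima {a} and {b}")
    out: list = [by_id[nodes[0]]]
    for u, v in zip(nodes[:-1], nodes[1:]):
        out.append(g.edges[u, v]["ts"])
        out.append(by_id[v])
    return out


def _dijkstra_lex(g: nx.DiGraph, a: int, b: int) -> list[int] | None:
    """Dijkstra with lexicographic (total weight, ts-id sequence) ordering.

    The secondary key resolves exact weight ties towards the path whose
    transition-state id sequence is smallest.
    """
    import heapq

    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    heap = [(0.0, (), a, [a])]
    while heap:
        dist, tie, node, path = heapq.heappop(heap)
        if node in best and (dist, tie) >= best[node]:
            continue
        best[node] = (dist, tie)
        if node == b:
            return path
        for _, v, data in g.edges(node, data=True):
            cand = (dist + data["weight"], tie + (data["ts"].id,))
            if v not in best or cand < best[v]:
                heapq.heappush(heap, (*cand, v, path + [v]))
    return None


def path_annotation(path, structures) -> "pandas.DataFrame":
    """Base-pair table for each minimum along a path.

    ``structures`` maps minimum id to a PDB path or parsed model accepted by
    :func:`ktnkit.rna_descriptors.annotate_base_pairs`.  Returns a tidy
    DataFrame with columns (step, minimum, i, j, category).
    """
    import pandas as pd

    from .ktn_io import Minimum as _Min
    from .rna_descriptors import annotate_base_pairs

    rows = []
    step = 0
    for item in path:
        if not isinstance(item, _Min):
            continue
        if item.id not in structures:
            raise KeyError(f"no structure supplied for minimum {item.id}")
        for bp in annotate_base_pairs(structures[item.id]):
            rows.append(
                {"step": step, "minimum": item.id, "i": bp.i, "j": bp.j,
                 "category": bp.category}
            )
        step += 1
    return pd.DataFrame(rows, columns=["step", "minimum", "i", "j", "category"])
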