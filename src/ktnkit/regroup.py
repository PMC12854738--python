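"""Free-energy regrouping of minima into kinetic groups.

At a chosen temperature, minima separated by free-energy barriers below a
threshold interconvert quickly compared to everything else and are lumped
into a single group.  The procedure iterates to a fixed point:

1. compute each group's free energy ``F_I = -k_B T ln sum_{i in I} w_i``
   (harmonic-superposition weights) and, for every adjacent group pair, the
   transition-ensemble free energy ``F_IJ = -k_B T ln sum_ts w_ts`` over all
   connecting transition states (parallel paths add entropy);
2. mark every pair with BOTH ``F_IJ - F_I < dG_thresh`` and
   ``F_IJ - F_J < dG_thresh``;
3. merge all marked pairs simultaneously (connected components of the
   marked graph) and repeat until nothing merges.

The simultaneous-closure sweep makes the result independent of any merge
ordering by construction.  Transition-state weights include the Eyring
prefactor (``ln w_ts = -beta V - log_prod - ln o - ln(k_B T / h)``) so that
for a single transition state between two lone minima, ``F_ts - F_min``
equals the Eyring barrier of the harmonic TST rate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .constants import KB_KCAL, T_DEFAULT, beta, eyring_prefactor
from .harmonic_thermo import log_weights
from .ktn_io import KTN

__all__ = ["GroupedNetwork", "regroup_free_energy", "effective_barriers",
           "barrier_scan"]


@dataclass
class GroupedNetwork:
    """Partition of minima into free-energy groups at one temperature.

    ``F_group`` maps group label -> free energy (kcal/mol, common constant
    dropped, same gauge as minimum free energies); ``F_ts`` maps unordered
    group-label pairs -> transition-ensemble free energy (Eyring gauge, see
    module docstring).
    """

    T: float
    dG_thresh: float
    groups: dict[int, frozenset[int]]
    F_group: dict[int, float]
    F_ts: dict[frozenset[int], float] = field(default_factory=dict)

    def group_of(self, minimum_id: int) -> int:
        for label, members in self.groups.items():
            if minimum_id in members:
                return label
        raise KeyError(f"minimum {minimum_id} not in any group")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def occupations(self) -> dict[int, float]:
        """Equilibrium group probabilities from the group free energies."""
        labels = sorted(self.groups)
        lw = np.array([-self.F_group[l] / (KB_KCAL * self.T) for l in labels])
        p = np.exp(lw - logsumexp(lw))
        p /= p.sum()
        return dict(zip(labels, p.tolist()))


def _ts_log_weights(ktn: KTN, T: float) -> np.ndarray:
    """Log-weights of transition states in the Eyring gauge (see module doc)."""
    b = beta(T)
    V = np.array([t.V for t in ktn.transition_states])
    lp = np.array([t.log_prod for t in ktn.transition_states])
    pg = np.array([t.pg_order for t in ktn.transition_states])
    return -V * b - lp - np.log(pg) - np.log(eyring_prefactor(T))


def regroup_free_energy(
    ktn: KTN, T: float = T_DEFAULT, dG_thresh: float = 0.0
) -> GroupedNetwork:
    """Lump minima whose mutual barriers fall below ``dG_thresh`` (kcal/mol)."""
    if dG_thresh < 0:
        raise ValueError("regrouping threshold must be >= 0")
    ktn.check()
    kBT = KB_KCAL * T
    min_lw = dict(zip((m.id for m in ktn.minima), log_weights(ktn, T)))
    ts_lw = _ts_log_weights(ktn, T)

    # current partition: label -> member ids; start from singletons
    part: dict[int, frozenset[int]] = {
        m.id: frozenset([m.id]) for m in ktn.minima
    }

    def group_F(members: frozenset[int]) -> float:
        return float(-kBT * logsumexp([min_lw[i] for i in members]))

    def inter_ts_F(label_of: dict[int, int]) -> dict[frozenset[int], float]:
        pools: dict[frozenset[int], list[float]] = {}
        for ts, lw in zip(ktn.transition_states, ts_lw):
            if ts.degenerate:
                continue
            la, lb = label_of[ts.min1], label_of[ts.min2]
            if la == lb:
                continue
            pools.setdefault(frozenset((la, lb)), []).append(lw)
        return {k: float(-kBT * logsumexp(v)) for k, v in pools.items()}

    while True:
        F = {label: group_F(members) for label, members in part.items()}
        label_of = {i: label for label, members in part.items() for i in members}
        Fts = inter_ts_F(label_of)
        merge_graph = nx.Graph()
        merge_graph.add_nodes_from(part)
        for pair, f in Fts.items():
            la, lb = tuple(pair)
            if f - F[la] < dG_thresh and f - F[lb] < dG_thresh:
                merge_graph.add_edge(la, lb)
        if merge_graph.number_of_edges() == 0:
            return GroupedNetwork(
                T=T, dG_thresh=dG_thresh, groups=part, F_group=F, F_ts=Fts
            )
        new_part: dict[int, frozenset[int]] = {}
        for comp in nx.connected_components(merge_graph):
            members = frozenset().union(*(part[l] for l in comp))
            new_part[min(members)] = members  # label = smallest member id
        part = new_part


def effective_barriers(
    gn: GroupedNetwork, group_a: int, group_b: int
) -> tuple[float, float]:
    """Forward and reverse free-energy barriers between two adjacent groups.

    ``dG(A->B) = F_ts(A,B) - F_A`` and conversely; in the Eyring gauge these
    convert to effective rates via ``barrier_to_rate``.
    """
    key = frozenset((group_a, group_b))
    if key not in gn.F_ts:
        raise KeyError(
            f"groups {group_a} and {group_b} share no transition-state "
            "ensemble; use kinetics.two_state_rates for path-mediated rates"
        )
    f = gn.F_ts[key]
    return f - gn.F_group[group_a], f - gn.F_group[group_b]


def barrier_scan(
    ktn: KTN,
    anchor_a: int,
    anchor_b: int,
    thresholds,
    T: float = T_DEFAULT,
) -> "pandas.DataFrame":
    """Effective barriers between the groups of two anchor minima, vs threshold.

    The regrouped barriers depend on the lumping threshold; rather than fix a
    magic constant, this scan reports (threshold, n_groups, dG_ab, dG_ba)
    rows so the dependence is explicit.  Rows where the two anchors fall in
    the same group, or in non-adjacent groups, carry NaN barriers.
    """
    import pandas as pd

    rows = []
    for thr in thresholds:
        gn = regroup_free_energy(ktn, T=T, dG_thresh=float(thr))
        la, lb = gn.group_of(anchor_a), gn.group_of(anchor_b)
        if la == lb or frozenset((la, lb)) not in gn.F_ts:
            ab = ba = float("nan")
        else:
            ab, ba = effective_barriers(gn, la, lb)
        rows.append(
            {"threshold": float(thr), "n_groups": gn.n_groups,
             "dG_ab": ab, "dG_ba": ba}
        )
    return pd.DataFrame(rows)
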