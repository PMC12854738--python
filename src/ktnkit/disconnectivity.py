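"""Superbasin analysis and disconnectivity trees.

A disconnectivity graph summarises landscape topography: each minimum is a
leaf hanging at its own energy, and two branches merge at the lowest energy
threshold at which a path exists between them whose transition states all
lie below that threshold.  The same construction applies to potential
energies of a raw KTN or to the free energies of a regrouped network (pass
the quotient network through :func:`quotient_ktn`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .ktn_io import KTN, Minimum, TransitionState
from .regroup import GroupedNetwork

__all__ = [
    "DisconnectivityTree",
    "superbasin_partition",
    "build_tree",
    "color_tree",
    "select_funnel",
    "quotient_ktn",
    "layout_tree",
]


@dataclass
class TreeNode:
    """A superbasin at one threshold level (or a leaf minimum)."""

    id: int
    level: int | None          # level index, None for leaves
    energy: float              # threshold energy (node) or minimum energy (leaf)
    members: frozenset[int]    # minimum ids contained
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    color: float | None = None
    funnel: str | None = None


@dataclass
class DisconnectivityTree:
    """Threshold-level superbasin tree.

    ``levels`` lists the descending energy thresholds; ``nodes`` maps node id
    to :class:`TreeNode`; leaves are the nodes with ``level is None``.
    """

    levels: np.ndarray
    nodes: dict[int, TreeNode]
    leaf_of: dict[int, int]    # minimum id -> leaf node id
    source: KTN | None = None          # network the tree was built from
    energy_of: object = None           # energy accessor used at build time

    @property
    def leaves(self) -> list[TreeNode]:
        return [self.nodes[i] for i in sorted(self.leaf_of.values())]

    def root_ids(self) -> list[int]:
        return [n.id for n in self.nodes.values() if n.parent is None
                and n.level is not None]

    def merge_level(self, a: int, b: int) -> float:
        """Lowest threshold energy at which minima ``a`` and ``b`` share a basin."""
        ancestors_a = self._ancestor_chain(self.leaf_of[a])
        node = self.nodes[self.leaf_of[b]].parent
        while node is not None:
            if node in ancestors_a and a in self.nodes[node].members:
                return self.nodes[node].energy
            node = self.nodes[node].parent
        raise KeyError(f"minima {a} and {b} never merge within the tree")

    def _ancestor_chain(self, nid: int) -> set[int]:
        out = set()
        cur = self.nodes[nid].parent
        while cur is not None:
            out.add(cur)
            cur = self.nodes[cur].parent
        return out

    def to_dict(self) -> dict:
        """JSON-serialisable representation."""
        return {
            "levels": self.levels.tolist(),
            "nodes": [
                {
                    "id": n.id, "level": n.level, "energy": n.energy,
                    "members": sorted(n.members), "parent": n.parent,
                    "children": n.children, "color": n.color,
                    "funnel": n.funnel,
                }
                for n in self.nodes.values()
            ],
        }


def superbasin_partition(ktn: KTN, E: float, energy_of=None) -> list[frozenset[int]]:
    """Partition minima into superbasins at threshold ``E``.

    Two minima share a basin iff they are connected by a path whose
    transition states all have energy <= E.  Minima lying above E are
    excluded.  ``energy_of`` optionally remaps stationary-point energies
    (default: potential energy ``V``).
    """
    if energy_of is None:
        energy_of = lambda sp: sp.V
    g = nx.Graph()
    for m in ktn.minima:
        if energy_of(m) <= E:
            g.add_node(m.id)
    for ts in ktn.edges():
        if energy_of(ts) <= E and ts.min1 in g and ts.min2 in g:
            g.add_edge(ts.min1, ts.min2)
    return [frozenset(c) for c in nx.connected_components(g)]


def build_tree(
    ktn: KTN,
    dE: float,
    E_max: float | None = None,
    energy_of=None,
) -> DisconnectivityTree:
    """Build the disconnectivity tree with level spacing ``dE`` from ``E_max`` down.

    Levels run ``E_max, E_max - dE, ...`` until below the lowest minimum.
    The node containing a set of minima at each level is their superbasin;
    parents point one level up.  Leaves attach to the lowest level whose
    basin still contains them.
    """
    if dE <= 0:
        raise ValueError("level spacing dE must be positive")
    if energy_of is None:
        energy_of = lambda sp: sp.V
    if ktn.n_minima == 0:
        raise ValueError("cannot build a tree for an empty network")
    vmin = min(energy_of(m) for m in ktn.minima)
    if E_max is None:
        tops = [energy_of(t) for t in ktn.edges()] or [vmin]
        E_max = max(max(tops), vmin) + dE
    if E_max < vmin:
        raise ValueError("E_max lies below the global minimum: empty tree")
    levels = []
    e = E_max
    while e >= vmin:
        levels.append(e)
        e -= dE
    levels = np.array(levels)

    nodes: dict[int, TreeNode] = {}
    leaf_of: dict[int, int] = {}
    next_id = 0
    # leaves
    for m in ktn.minima:
        nodes[next_id] = TreeNode(
            id=next_id, level=None, energy=energy_of(m),
            members=frozenset([m.id]),
        )
        leaf_of[m.id] = next_id
        next_id += 1

    prev_cells: dict[frozenset[int], int] = {}
    for li, E in enumerate(levels):  # top level first
        cells = superbasin_partition(ktn, E, energy_of=energy_of)
        cur: dict[frozenset[int], int] = {}
        for cell in cells:
            node = TreeNode(id=next_id, level=li, energy=float(E), members=cell)
            nodes[next_id] = node
            cur[cell] = next_id
            next_id += 1
            # parent: the cell one level up containing this one
            for up_cell, up_id in prev_cells.items():
                if cell <= up_cell:
                    node.parent = up_id
                    nodes[up_id].children.append(node.id)
                    break
        prev_cells = cur

    # attach each leaf to the lowest-level node containing it
    lowest: dict[int, int] = {}
    for nid, node in nodes.items():
        if node.level is None:
            continue
        for mid in node.members:
            best = lowest.get(mid)
            if best is None or node.level > nodes[best].level:
                lowest[mid] = nid
    for mid, leaf_id in leaf_of.items():
        parent = lowest.get(mid)
        if parent is not None:
            nodes[leaf_id].parent = parent
            nodes[parent].children.append(leaf_id)
    return DisconnectivityTree(levels=levels, nodes=nodes, leaf_of=leaf_of,
                               source=ktn, energy_of=energy_of)


def color_tree(
    tree: DisconnectivityTree,
    values: dict[int, float],
    weights: dict[int, float] | None = None,
) -> DisconnectivityTree:
    """Attach a per-minimum scalar (e.g. an order parameter) to the tree.

    Leaves carry their own value; internal nodes carry the weighted mean of
    their member minima (uniform weights unless occupation probabilities are
    supplied).  Modifies the tree in place and returns it.
    """
    missing = [m for m in tree.leaf_of if m not in values]
    if missing:
        raise KeyError(f"missing order-parameter values for minima {sorted(missing)}")
    if weights is None:
        weights = {m: 1.0 for m in tree.leaf_of}
    for node in tree.nodes.values():
        vs = np.array([values[m] for m in node.members])
        ws = np.array([weights[m] for m in node.members])
        node.color = float(vs @ ws / ws.sum())
    return tree


def select_funnel(
    tree: DisconnectivityTree, anchor: int, level: float
) -> frozenset[int]:
    """Minima belonging to the anchor's superbasin at threshold ``level``.

    The programmatic equivalent of cutting a funnel out of the graph by hand
    at a chosen branch point.  When the tree remembers its source network the
    cut is exact; otherwise it snaps to the nearest tree level at or above
    the requested energy.
    """
    if anchor not in tree.leaf_of:
        raise KeyError(f"anchor minimum {anchor} not in tree")
    if level > tree.levels.max() + 1e-12:
        raise ValueError("cut level lies above the top of the tree")
    if tree.source is not None:
        # exact cut, not snapped to the presentation grid
        for cell in superbasin_partition(tree.source, level,
                                         energy_of=tree.energy_of):
            if anchor in cell:
                return cell
        raise ValueError(f"minimum {anchor} lies above the cut level {level}")
    candidates = [n for n in tree.nodes.values()
                  if n.level is not None and n.energy >= level - 1e-12
                  and anchor in n.members]
    if not candidates:
        raise ValueError(f"no superbasin containing minimum {anchor} at {level}")
    best = max(candidates, key=lambda n: n.level)
    return best.members


def quotient_ktn(gn: GroupedNetwork, ktn: KTN) -> KTN:
    """Collapse a grouped network into a free-energy KTN.

    Each group becomes one 'minimum' at its group free energy; each adjacent
    group pair becomes one 'transition state' at the transition-ensemble free
    energy.  The result feeds :func:`build_tree` to draw free-energy
    disconnectivity graphs.  Log-products and point-group orders are set
    neutral (0 and 1): all thermodynamic content already lives in F.
    """
    label_to_new = {label: i + 1 for i, label in enumerate(sorted(gn.groups))}
    minima = [
        Minimum(id=label_to_new[label], V=gn.F_group[label], log_prod=0.0)
        for label in sorted(gn.groups)
    ]
    ts_list = []
    for k, (pair, f) in enumerate(sorted(gn.F_ts.items(),
                                         key=lambda kv: sorted(kv[0])), start=1):
        la, lb = sorted(pair)
        ts_list.append(TransitionState(
            id=k, V=f, log_prod=0.0, pg_order=1.0,
            min1=label_to_new[la], min2=label_to_new[lb],
        ))
    return KTN(minima=minima, transition_states=ts_list)


def layout_tree(tree: DisconnectivityTree) -> dict[int, float]:
    """Deterministic recursive-midpoint x positions for plotting.

    Leaves are placed left-to-right in ascending minimum-id order within
    each subtree; every internal node sits at the midpoint of its children.
    Rendering itself is left to the host plotting environment.
    """
    x: dict[int, float] = {}
    counter = [0.0]

    def place(nid: int) -> float:
        node = tree.nodes[nid]
        kids = [c for c in node.children]
        if not kids:
            x[nid] = counter[0]
            counter[0] += 1.0
            return x[nid]
        kids.sort(key=lambda c: min(tree.nodes[c].members))
        xs = [place(c) for c in kids]
        x[nid] = float(np.mean(xs))
        return x[nid]

    for rid in sorted(tree.root_ids(),
                      key=lambda r: min(tree.nodes[r].members)):
        place(rid)
    return x
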