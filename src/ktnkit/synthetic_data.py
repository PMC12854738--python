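"""Generators for every input the pipeline consumes.

Three families of synthetic inputs, all deterministic under a fixed seed:

* funneled toy KTNs with exactly known funnel membership and minimax merge
  energies (emulating multi-funnel stemloop topography);
* two-state networks constructed so that their harmonic TST rates equal the
  Eyring rates of prescribed forward/reverse barriers exactly;
* idealised A-form RNA duplex/bulge coordinates whose base pairing is known
  by construction, for exercising the structural annotation stack.

The RNA fixtures use idealised nucleotide geometry generated in code
(regular-polygon rings, standard bond lengths, a puckered ribose) arranged
with A-form helical parameters (rise 2.81 A, twist 32.7 deg).  They are
geometric test doubles, not thermodynamically realistic RNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KCAL, T_DEFAULT, eyring_prefactor
from .ktn_io import KTN, Minimum, TransitionState
from .rna_descriptors import BasePair

__all__ = [
    "FunnelSpec",
    "FunnelGroundTruth",
    "generate_funnel_ktn",
    "generate_two_state",
    "generate_random_ktn",
    "build_helix_fixture",
    "A_FORM_RISE",
    "A_FORM_TWIST",
]

A_FORM_RISE = 2.81       # A per base-pair step
A_FORM_TWIST = 32.7      # degrees per base-pair step

_LOGPROD_LO, _LOGPROD_HI = math.log(1e12), math.log(1e13)


# ---------------------------------------------------------------------------
# funneled KTNs

@dataclass
class FunnelSpec:
    """Recipe for a multi-funnel toy landscape."""

    n_funnels: int = 2
    minima_per_funnel: int = 5
    intra_barrier: float = 2.0    # kcal/mol above the higher of each pair
    inter_barrier: float = 8.0    # kcal/mol above the global minimum
    energy_spread: float = 1.5    # kcal/mol of intra-funnel roughness
    funnel_offset: float = 1.0    # kcal/mol between successive funnel floors
    seed: int = 0

    def validate(self) -> None:
        if self.n_funnels < 1 or self.minima_per_funnel < 1:
            raise ValueError("need at least one funnel with one minimum")
        if not self.inter_barrier > self.intra_barrier > 0:
            raise ValueError("require inter_barrier > intra_barrier > 0")
        if self.energy_spread < 0:
            raise ValueError("energy_spread must be >= 0")


@dataclass
class FunnelGroundTruth:
    """Exact funnel membership and merge energies of a generated landscape."""

    membership: list[frozenset[int]]
    hub: list[int]                       # lowest minimum of each funnel
    intra_ts: dict[tuple[int, int], float]
    inter_ts: dict[tuple[int, int], float]   # (funnel_a, funnel_b) -> TS energy
    energies: dict[int, float]

    def funnel_of(self, mid: int) -> int:
        for f, members in enumerate(self.membership):
            if mid in members:
                return f
        raise KeyError(mid)

    def minimax(self, a: int, b: int) -> float:
        """Exact minimax (lowest maximum-TS) path energy between two minima."""
        if a == b:
            return self.energies[a]
        fa, fb = self.funnel_of(a), self.funnel_of(b)

        def to_hub(m: int, f: int) -> float:
            if m == self.hub[f]:
                return -np.inf
            key = (min(m, self.hub[f]), max(m, self.hub[f]))
            return self.intra_ts[key]

        if fa == fb:
            return max(to_hub(a, fa), to_hub(b, fa))
        lo, hi = min(fa, fb), max(fa, fb)
        inter = max(self.inter_ts[(f, f + 1)] for f in range(lo, hi))
        return max(to_hub(a, fa), to_hub(b, fb), inter)


def generate_funnel_ktn(spec: FunnelSpec) -> tuple[KTN, FunnelGroundTruth]:
    """Star-per-funnel KTN: every funnel member connects to its hub.

    Minimum energies are ``funnel floor + U(0, energy_spread)``; each
    intra-funnel transition state sits ``intra_barrier`` above the higher of
    its pair, and successive funnel hubs are joined by one transition state
    ``inter_barrier`` above the global minimum.  The star topology makes
    every pairwise minimax path energy exactly computable.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    minima: list[Minimum] = []
    membership: list[frozenset[int]] = []
    energies: dict[int, float] = {}
    mid = 0
    for f in range(spec.n_funnels):
        ids = []
        for _ in range(spec.minima_per_funnel):
            mid += 1
            V = f * spec.funnel_offset + rng.uniform(0, spec.energy_spread)
            minima.append(Minimum(
                id=mid, V=V, log_prod=rng.uniform(_LOGPROD_LO, _LOGPROD_HI),
                pg_order=1.0,
            ))
            energies[mid] = V
            ids.append(mid)
        membership.append(frozenset(ids))

    by_id = {m.id: m for m in minima}
    hub = [min(members, key=lambda i: by_id[i].V) for members in membership]
    vmin_global = min(energies.values())

    ts_list: list[TransitionState] = []
    intra_ts: dict[tuple[int, int], float] = {}
    tid = 0
    for f, members in enumerate(membership):
        for m in sorted(members):
            if m == hub[f]:
                continue
            tid += 1
            V = max(by_id[m].V, by_id[hub[f]].V) + spec.intra_barrier
            ts_list.append(TransitionState(
                id=tid, V=V, log_prod=rng.uniform(_LOGPROD_LO, _LOGPROD_HI),
                pg_order=1.0, min1=hub[f], min2=m,
            ))
            key = (min(m, hub[f]), max(m, hub[f]))
            intra_ts[key] = V
    inter_ts: dict[tuple[int, int], float] = {}
    for f in range(spec.n_funnels - 1):
        tid += 1
        V = vmin_global + spec.inter_barrier
        ts_list.append(TransitionState(
            id=tid, V=V, log_prod=rng.uniform(_LOGPROD_LO, _LOGPROD_HI),
            pg_order=1.0, min1=hub[f], min2=hub[f + 1],
        ))
        inter_ts[(f, f + 1)] = V
    ktn = KTN(minima=minima, transition_states=ts_list, kappa=1)
    truth = FunnelGroundTruth(
        membership=membership, hub=hub, intra_ts=intra_ts,
        inter_ts=inter_ts, energies=energies,
    )
    return ktn, truth


# ---------------------------------------------------------------------------
# two-state networks

def generate_two_state(
    dG_f: float, dG_r: float, T: float = T_DEFAULT
) -> KTN:
    """Two minima and one transition state realising prescribed Eyring barriers.

    Log-products are chosen so that the harmonic TST rates equal
    ``barrier_to_rate(dG)`` at temperature T exactly; composing with
    :func:`ktnkit.kinetics.two_state_rates` therefore recovers the input
    barriers to rounding error.
    """
    if dG_f <= 0 or dG_r <= 0:
        raise ValueError("barriers must be positive")
    lp_ts = math.log(1e12)
    lp_min = lp_ts + math.log(eyring_prefactor(T))
    V_ts = dG_f
    minima = [
        Minimum(id=1, V=0.0, log_prod=lp_min),
        Minimum(id=2, V=dG_f - dG_r, log_prod=lp_min),
    ]
    ts = TransitionState(id=1, V=V_ts, log_prod=lp_ts, pg_order=1.0,
                         min1=1, min2=2)
    return KTN(minima=minima, transition_states=[ts], kappa=1)


# ---------------------------------------------------------------------------
# random KTNs for property and oracle tests

def generate_random_ktn(
    n: int,
    seed: int,
    spread: float = 2.0,
    barrier: float = 3.0,
    extra_edge_frac: float = 0.4,
    deep_wells: tuple[int, int] | None = None,
    well_depth: float = 6.0,
    kappa: int = 1,
) -> KTN:
    """Random connected KTN: spanning tree plus extra transition states.

    ``deep_wells=(a, b)`` lowers two minima by ``well_depth`` so the rest of
    the network is sparsely populated — the metastable two-state regime.
    """
    if n < 1:
        raise ValueError("need at least one minimum")
    rng = np.random.default_rng(seed)
    V = rng.uniform(0, spread, size=n)
    if deep_wells is not None:
        a, b = deep_wells
        V[a - 1] -= well_depth
        V[b - 1] -= well_depth + rng.uniform(0, 0.5)
    minima = [
        Minimum(id=i + 1, V=float(V[i]),
                log_prod=float(rng.uniform(_LOGPROD_LO, _LOGPROD_HI)))
        for i in range(n)
    ]
    edges: set[tuple[int, int]] = set()
    order = rng.permutation(n) + 1
    for k in range(1, n):
        a = int(order[k])
        b = int(order[rng.integers(0, k)])
        edges.add((min(a, b), max(a, b)))
    n_extra = int(extra_edge_frac * n)
    while len(edges) < (n - 1) + n_extra and n > 2:
        a, b = rng.choice(n, size=2, replace=False) + 1
        edges.add((min(int(a), int(b)), max(int(a), int(b))))
    ts_list = []
    for k, (a, b) in enumerate(sorted(edges), start=1):
        vts = max(V[a - 1], V[b - 1]) + rng.uniform(0.5, barrier)
        ts_list.append(TransitionState(
            id=k, V=float(vts),
            log_prod=float(rng.uniform(_LOGPROD_LO, _LOGPROD_HI)),
            pg_order=1.0, min1=a, min2=b,
        ))
    return KTN(minima=minima, transition_states=ts_list, kappa=kappa)


# ---------------------------------------------------------------------------
# idealised RNA coordinates

_COMPLEMENT = {"A": {"U"}, "U": {"A", "G"}, "G": {"C", "U"}, "C": {"G"}}

_RING6 = ("N1", "C2", "N3", "C4", "C5", "C6")
_BOND = 1.38          # aromatic ring bond length, A
_NN_DISTANCE = 2.9    # WC-edge N...N hydrogen-bond distance, A
_GLYCOSIDIC = 1.48    # N-C1' bond, A
_SUGAR_R = 1.29       # ribose ring circumradius for 1.52 A bonds
_PUCKER_Q = 0.38      # Cremer-Pople-like puckering amplitude, A


def _rotation_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _base_template(base: str) -> dict[str, np.ndarray]:
    """Idealised nucleotide in its own base frame.

    Six-ring centroid at the origin, ring in the xy-plane, Watson-Crick-edge
    nitrogen on +x, glycosidic C1' and a puckered five-atom ribose attached
    beyond the glycosidic nitrogen.
    """
    purine = base in ("A", "G")
    atoms: dict[str, np.ndarray] = {}
    # WC nitrogen (N1 purine, N3 pyrimidine) sits at polar angle 0
    start = 0.0 if purine else -120.0
    for k, name in enumerate(_RING6):
        ang = math.radians(start + 60.0 * k)
        atoms[name] = _BOND * np.array([math.cos(ang), math.sin(ang), 0.0])
    if purine:
        # fuse a regular pentagon [C4, C5, N7, C8, N9] on the C4-C5 edge
        c4, c5 = atoms["C4"], atoms["C5"]
        mid = 0.5 * (c4 + c5)
        out = mid / np.linalg.norm(mid)
        side = np.linalg.norm(c5 - c4)
        apothem = side / (2 * math.tan(math.pi / 5))
        radius = side / (2 * math.sin(math.pi / 5))
        center = mid + apothem * out
        phi4 = math.atan2(*(c4 - center)[[1, 0]])
        phi5 = math.atan2(*(c5 - center)[[1, 0]])
        # step direction from C4 towards N9 (away from C5)
        step = -2 * math.pi / 5 if ((phi4 - phi5) % (2 * math.pi)) < math.pi \
            else 2 * math.pi / 5
        for j, name in enumerate(("N9", "C8", "N7"), start=1):
            ang = phi4 + step * j
            atoms[name] = center + radius * np.array(
                [math.cos(ang), math.sin(ang), 0.0]
            )
    gly = "N9" if purine else "N1"
    g = atoms[gly]
    e1 = g / np.linalg.norm(g)
    atoms["C1'"] = g + _GLYCOSIDIC * e1
    # puckered ribose in the plane spanned by e1 and the base normal,
    # displaced out of that plane by the pucker amplitude
    e3 = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(e3, e1)
    center = atoms["C1'"] + _SUGAR_R * e1
    names = ("C1'", "C2'", "C3'", "C4'", "O4'")
    for k, name in enumerate(names):
        ang = math.pi + 2 * math.pi * k / 5
        # generic pseudorotation phase offset so no endocyclic torsion is
        # accidentally zero by symmetry
        z = math.sqrt(2.0 / 5.0) * _PUCKER_Q * math.cos(0.3 + 4 * math.pi * k / 5)
        atoms[name] = (center
                       + _SUGAR_R * math.cos(ang) * e1
                       + _SUGAR_R * math.sin(ang) * e3
                       + z * e2)
    return atoms


def _wc_radius(base: str) -> float:
    tpl = _base_template(base)
    n = tpl["N1" if base in ("A", "G") else "N3"]
    return float(np.linalg.norm(n[:2]))


def build_helix_fixture(
    sequence: str,
    pairing: list[tuple[int, int]],
    bend_angle: float = 0.0,
    bend_after_pair: int | None = None,
    slippage: int = 0,
    allow_noncanonical: bool = False,
    path=None,
):
    """Idealised A-form duplex/bulge coordinates with known base pairing.

    ``sequence`` is the full 1-based nucleotide string; ``pairing`` lists
    (i, j) with i on strand 1 and j its partner.  Pairs are stacked with
    A-form rise/twist; unpaired residues are flipped out radially (a crude
    bulge).  ``bend_angle`` rigidly bends the stem after pair index
    ``bend_after_pair`` (default: the midpoint).  ``slippage`` shifts every
    partner index by that many residues (pairs sliding off the strand are
    dropped), emulating a base-pair register shift.

    Returns ``(structure, ground_truth)`` where ``structure`` is a Bio.PDB
    Structure and ``ground_truth`` the exact list of constructed
    :class:`~ktnkit.rna_descriptors.BasePair` (all cWW).  If ``path`` is
    given the structure is also written there in PDB format.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if slippage:
        pairing = [(i, j + slippage) for (i, j) in pairing
                   if 1 <= j + slippage <= n and (j + slippage) != i]
    seen: set[int] = set()
    for (i, j) in pairing:
        if not (1 <= i <= n and 1 <= j <= n) or i >= j:
            raise ValueError(f"invalid pair ({i}, {j})")
        if i in seen or j in seen:
            raise ValueError(f"residue used in two pairs: ({i}, {j})")
        seen |= {i, j}
        if not allow_noncanonical and \
                sequence[j - 1] not in _COMPLEMENT[sequence[i - 1]]:
            raise ValueError(
                f"non-complementary pair {sequence[i-1]}{i}-{sequence[j-1]}{j}"
            )
    pairing = sorted(pairing)

    placements: dict[int, np.ndarray] = {}   # residue -> 4x4-ish (R, t)
    transforms: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    flip = np.diag([-1.0, 1.0, -1.0])        # 180 deg about y
    for step, (i, j) in enumerate(pairing):
        s = 0.5 * (_NN_DISTANCE + _wc_radius(sequence[i - 1])
                   + _wc_radius(sequence[j - 1]))
        Rz = _rotation_z(step * A_FORM_TWIST)
        tz = np.array([0.0, 0.0, step * A_FORM_RISE])
        transforms[i] = (Rz, Rz @ np.array([-s, 0.0, 0.0]) + tz)
        transforms[j] = (Rz @ flip, Rz @ np.array([s, 0.0, 0.0]) + tz)
    # flipped-out placement for unpaired residues, radially off-axis at the
    # height of the preceding pair step
    paired_set = {r for p in pairing for r in p}
    step_of = {r: k for k, (i, j) in enumerate(pairing) for r in (i, j)}
    n_out = 0
    for r in range(1, n + 1):
        if r in paired_set:
            continue
        below = [step_of[q] for q in paired_set if q < r]
        step = max(below) if below else 0
        # successive flipped-out residues are staggered in angle and height
        # so they never clash with each other
        Rz = _rotation_z(step * A_FORM_TWIST + 60.0 * n_out)
        t = Rz @ np.array([-11.0, 0.0, 0.0]) + np.array(
            [0.0, 0.0, (step + 0.5) * A_FORM_RISE + 0.7 * n_out]
        )
        transforms[r] = (Rz, t)
        n_out += 1

    if bend_angle and pairing:
        split = bend_after_pair if bend_after_pair is not None \
            else len(pairing) // 2
        zj = (split - 0.5) * A_FORM_RISE
        th = math.radians(bend_angle)
        c, s_ = math.cos(th), math.sin(th)
        Rb = np.array([[1.0, 0.0, 0.0], [0.0, c, -s_], [0.0, s_, c]])
        pivot = np.array([0.0, 0.0, zj])
        for step, (i, j) in enumerate(pairing):
            if step < split:
                continue
            for r in (i, j):
                R, t = transforms[r]
                transforms[r] = (Rb @ R, Rb @ (t - pivot) + pivot)

    structure = _build_structure(sequence, transforms)
    truth = [
        BasePair(i=i, j=j, edge_i="WC", edge_j="WC",
                 orientation="cis", category="cWW")
        for (i, j) in pairing
    ]
    if path is not None:
        from Bio.PDB import PDBIO

        io = PDBIO()
        io.set_structure(structure)
        io.save(str(path))
    return structure, truth


def _build_structure(sequence: str, transforms):
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("fixture")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    serial = 1
    for r in range(1, len(sequence) + 1):
        base = sequence[r - 1]
        sb.init_residue(f"  {base}", " ", r, " ")
        R, t = transforms[r]
        for name, local in _base_template(base).items():
            coord = R @ local + t
            element = name[0]
            sb.init_atom(name, coord.astype(np.float32), 0.0, 1.0, " ",
                         name, serial, element=element)
            serial += 1
    return sb.get_structure()
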