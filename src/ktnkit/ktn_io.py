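"""Data model and plain-text I/O for stationary-point databases.

A kinetic transition network (KTN) is a graph whose nodes are local minima of
a potential energy surface and whose edges are transition states (Hessian
index-1 saddle points).  Each stationary point carries the quantities needed
for harmonic-superposition thermodynamics: its potential energy ``V``
(kcal/mol), the natural log of the product of its normal-mode frequencies
``log_prod`` (frequencies in s^-1; kappa modes for a minimum, kappa-1 for a
transition state), and its point-group order.

File dialect
------------
Minima and transition states are stored as whitespace-separated numeric
tables, one stationary point per line, ids given by 1-based line number:

* minima file: ``V  log_prod  pg_order  [ignored trailing columns]``
* transition-state file: ``V  log_prod  pg_order  min1  min2  [ignored]``

Trailing columns beyond those listed are read and ignored, so databases that
append extra per-point fields (e.g. moments of inertia) load unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "Minimum",
    "TransitionState",
    "KTN",
    "ValidationReport",
    "read_stationary_points",
    "write_stationary_points",
    "validate_ktn",
]


@dataclass
class Minimum:
    """A local minimum of the landscape."""

    id: int
    V: float
    log_prod: float
    pg_order: float = 1.0
    coords_ref: str | None = None

    def __post_init__(self) -> None:
        if self.pg_order < 1:
            raise ValueError(f"minimum {self.id}: point-group order must be >= 1")


@dataclass
class TransitionState:
    """An index-1 saddle point connecting two minima.

    ``min1 == min2`` marks a degenerate rearrangement; such saddles are kept
    in the database but never contribute graph edges or rates.
    """

    id: int
    V: float
    log_prod: float
    pg_order: float
    min1: int
    min2: int

    def __post_init__(self) -> None:
        if self.pg_order < 1:
            raise ValueError(f"transition state {self.id}: point-group order must be >= 1")

    @property
    def degenerate(self) -> bool:
        return self.min1 == self.min2


@dataclass
class KTN:
    """A kinetic transition network: minima plus connecting transition states.

    ``kappa`` is the number of vibrational degrees of freedom, identical for
    every minimum of one network (each transition state has kappa-1 real
    modes).  It is required for heat-capacity curves but optional otherwise.
    """

    minima: list[Minimum] = field(default_factory=list)
    transition_states: list[TransitionState] = field(default_factory=list)
    kappa: int | None = None

    @property
    def n_minima(self) -> int:
        return len(self.minima)

    @property
    def n_ts(self) -> int:
        return len(self.transition_states)

    def minimum(self, mid: int) -> Minimum:
        return self._min_index()[mid]

    def _min_index(self) -> dict[int, Minimum]:
        return {m.id: m for m in self.minima}

    def edges(self) -> Iterable[TransitionState]:
        """Transition states that contribute graph edges (non-degenerate)."""
        return (ts for ts in self.transition_states if not ts.degenerate)

    def graph(self):
        """The network as an undirected :class:`networkx.MultiGraph`.

        Nodes are minimum ids; each non-degenerate transition state is one
        edge keyed by its id with attribute ``ts``.
        """
        import networkx as nx

        g = nx.MultiGraph()
        for m in self.minima:
            g.add_node(m.id, minimum=m)
        for ts in self.edges():
            g.add_edge(ts.min1, ts.min2, key=ts.id, ts=ts)
        return g

    def check(self) -> None:
        """Raise ``ValueError`` on referential or uniqueness violations."""
        ids = [m.id for m in self.minima]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate minimum ids")
        ts_ids = [t.id for t in self.transition_states]
        if len(set(ts_ids)) != len(ts_ids):
            raise ValueError("duplicate transition-state ids")
        known = set(ids)
        bad = [t.id for t in self.transition_states
               if t.min1 not in known or t.min2 not in known]
        if bad:
            raise ValueError(
                "transition states referencing unknown minima: "
                + ", ".join(str(i) for i in bad)
            )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_ktn`."""

    n_below_minimum: int = 0
    action: str = "none"
    offending_ts: list[int] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return self.n_below_minimum == 0


def _parse_table(path: Path, n_required: int, label: str) -> list[list[float]]:
    rows: list[list[float]] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            try:
                values = [float(x) for x in fields[:n_required]]
            except ValueError:
                errors.append(f"{label} line {lineno}: non-numeric field")
                continue
            if len(values) < n_required:
                errors.append(
                    f"{label} line {lineno}: expected >= {n_required} columns, "
                    f"got {len(fields)}"
                )
                continue
            rows.append(values)
    if errors:
        raise ValueError("malformed stationary-point file:\n" + "\n".join(errors))
    return rows


def read_stationary_points(
    min_file: str | Path,
    ts_file: str | Path,
    kappa: int | None = None,
) -> KTN:
    """Read a stationary-point database into a :class:`KTN`.

    Ids are assigned as 1-based line numbers (blank and ``#`` comment lines
    do not advance the counter).  Raises ``FileNotFoundError`` for missing
    files and ``ValueError`` listing offending line numbers for malformed
    rows or transition states that reference nonexistent minima.
    """
    min_file, ts_file = Path(min_file), Path(ts_file)
    minima = [
        Minimum(id=i, V=r[0], log_prod=r[1], pg_order=r[2])
        for i, r in enumerate(_parse_table(min_file, 3, "minima"), start=1)
    ]
    known = {m.id for m in minima}
    ts_list = []
    bad: list[str] = []
    for i, r in enumerate(_parse_table(ts_file, 5, "ts"), start=1):
        ts = TransitionState(
            id=i, V=r[0], log_prod=r[1], pg_order=r[2],
            min1=int(r[3]), min2=int(r[4]),
        )
        if ts.min1 not in known or ts.min2 not in known:
            bad.append(f"ts line {i}: references minima ({ts.min1}, {ts.min2})")
        ts_list.append(ts)
    if bad:
        raise ValueError(
            "transition states reference nonexistent minima:\n" + "\n".join(bad)
        )
    return KTN(minima=minima, transition_states=ts_list, kappa=kappa)


def write_stationary_points(
    ktn: KTN, min_file: str | Path, ts_file: str | Path
) -> None:
    """Write a KTN back to the plain-text dialect.

    Numbers use the shortest decimal representation that round-trips the
    double exactly, so read(write(ktn)) reproduces the network bit for bit.
    """
    ktn.check()
    with open(min_file, "w") as fh:
        for m in ktn.minima:
            fh.write(f"{m.V!r} {m.log_prod!r} {m.pg_order!r}\n")
    with open(ts_file, "w") as fh:
        for t in ktn.transition_states:
            fh.write(
                f"{t.V!r} {t.log_prod!r} {t.pg_order!r} "
                f"{t.min1:d} {t.min2:d}\n"
            )


def validate_ktn(
    ktn: KTN,
    policy: Literal["discard", "clamp", "error"] = "discard",
) -> tuple[KTN, ValidationReport]:
    """Enforce the saddle-point invariant V_ts >= max(V_min1, V_min2).

    A transition state lying below either connected minimum cannot be an
    index-1 saddle between them.  Policy:

    * ``discard`` — drop the offending transition states;
    * ``clamp`` — raise their energy to the higher connected minimum;
    * ``error`` — raise ``ValueError`` naming the offenders.

    Returns the (possibly new) KTN and a :class:`ValidationReport`.
    """
    ktn.check()
    idx = ktn._min_index()
    offenders = [
        ts for ts in ktn.transition_states
        if ts.V < max(idx[ts.min1].V, idx[ts.min2].V)
    ]
    report = ValidationReport(
        n_below_minimum=len(offenders),
        action=policy if offenders else "none",
        offending_ts=[t.id for t in offenders],
    )
    if not offenders:
        return ktn, report
    if policy == "error":
        raise ValueError(
            "transition states below a connected minimum: "
            + ", ".join(str(t.id) for t in offenders)
        )
    if policy == "discard":
        bad = {t.id for t in offenders}
        kept = [t for t in ktn.transition_states if t.id not in bad]
        return KTN(minima=list(ktn.minima), transition_states=kept,
                   kappa=ktn.kappa), report
    if policy == "clamp":
        new_ts = []
        for t in ktn.transition_states:
            floor = max(idx[t.min1].V, idx[t.min2].V)
            if t.V < floor:
                t = TransitionState(t.id, floor, t.log_prod, t.pg_order,
                                    t.min1, t.min2)
            new_ts.append(t)
        return KTN(minima=list(ktn.minima), transition_states=new_ts,
                   kappa=ktn.kappa), report
    raise ValueError(f"unknown policy {policy!r}")
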