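"""Structure-level RNA analysis: base pairs, order parameters, descriptors, PCA.

Base-pair detection follows the r-vector idea: each nucleobase carries a
local reference frame (origin at the six-membered-ring centroid, x towards
the Watson-Crick edge, z along the ring normal), and two bases are paired
when each base's centre, expressed in the other's frame, falls inside a flat
ellipsoid around the base plane.  Interacting edges are read off the azimuth
of the partner direction, and cis/trans from the alignment of the two ring
normals.  Geometric pairs that resist edge/orientation assignment are
reported in the catch-all ``XXX`` category.

Residue numbering is 1-based throughout (position 1 = the first residue of
the construct); callers working in conventional full-length numbering can
shift with an offset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BasePair",
    "PairingGeometry",
    "PCAModel",
    "load_model",
    "base_frame",
    "annotate_base_pairs",
    "wc_edge_distance",
    "pucker_phase",
    "interhelical_angles",
    "sasa",
    "compute_descriptors",
    "fit_pca",
    "project",
    "DEFAULT_PAIR_DISTANCES",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}
RNA_RESNAMES = PURINES | PYRIMIDINES
#: six-membered-ring atoms shared by all nucleobases, in ring order
RING6 = ("N1", "C2", "N3", "C4", "C5", "C6")

#: Watson-Crick-edge nitrogen per base type (N1 for purines, N3 for pyrimidines)
WC_NITROGEN = {"A": "N1", "G": "N1", "C": "N3", "U": "N3"}

#: base-pair distance features of the stemloop descriptor set
DEFAULT_PAIR_DISTANCES = [(8, 23), (9, 23), (10, 21), (10, 22), (10, 23),
                          (11, 22), (12, 21)]


@dataclass(frozen=True)
class BasePair:
    """One annotated base pair (i < j, 1-based residue indices)."""

    i: int
    j: int
    edge_i: str | None
    edge_j: str | None
    orientation: str | None
    category: str  # e.g. 'cWW', 'tWH', or 'XXX'


@dataclass
class PairingGeometry:
    """Geometric thresholds of the pair-detection ellipsoid.

    ``a`` is the in-plane semi-axis and ``b`` the out-of-plane semi-axis of
    the acceptance ellipsoid around each base, applied mutually; ``z_max``
    additionally caps the out-of-plane offset so that stacked neighbours
    (offset by the helical rise, ~2.8 A) are never mistaken for pairs;
    ``min_inplane`` is the in-plane radius below which the azimuth, hence
    the edge assignment, is considered unreliable; ``min_normal_alignment``
    is the minimum |cos| between ring normals for a cis/trans call.
    """

    a: float = 6.5
    b: float = 3.0
    z_max: float = 2.0
    min_inplane: float = 1.5
    min_normal_alignment: float = 0.5


def load_model(obj):
    """Return a Bio.PDB ``Model`` from a path or any Bio.PDB entity."""
    from Bio.PDB import PDBParser
    from Bio.PDB.Entity import Entity

    if isinstance(obj, (str, Path)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = PDBParser(QUIET=True).get_structure("m", str(obj))
        return next(structure.get_models())
    if isinstance(obj, Entity):
        if obj.level == "S":
            return next(obj.get_models())
        while obj.level not in ("M",):
            obj = obj.parent
        return obj
    raise TypeError(f"cannot interpret {type(obj)} as a structure")


def _rna_residues(model) -> dict[int, object]:
    """Map 1-based residue number -> Bio.PDB residue, skipping non-RNA."""
    out = {}
    for chain in model:
        for res in chain:
            name = res.get_resname().strip()
            if name not in RNA_RESNAMES:
                warnings.warn(f"skipping non-RNA residue {name} {res.id[1]}")
                continue
            out[res.id[1]] = res
    return out


def _coord(res, atom: str) -> np.ndarray:
    if atom not in res:
        raise KeyError(
            f"residue {res.get_resname().strip()} {res.id[1]}: missing atom {atom}"
        )
    return np.asarray(res[atom].get_coord(), dtype=float)


def base_frame(res) -> tuple[np.ndarray, np.ndarray]:
    """Local reference frame of a nucleobase.

    Returns ``(origin, axes)`` with ``axes`` a 3x3 matrix whose rows are the
    unit x, y, z axes in global coordinates: origin at the centroid of the
    available six-ring atoms (C2, C4, C6 at minimum), x towards the
    Watson-Crick-edge nitrogen projected into the ring plane, z the ring
    normal by Newell's method over the ordered ring atoms (right-handed).
    """
    name = res.get_resname().strip()
    ring = [a for a in RING6 if a in res]
    if not {"C2", "C4", "C6"} <= set(ring):
        raise KeyError(
            f"residue {name} {res.id[1]}: ring atoms C2/C4/C6 required for a frame"
        )
    pts = np.array([_coord(res, a) for a in ring])
    origin = pts.mean(axis=0)
    centered = pts - origin
    # Newell normal: sum of successive cross products, deterministic in ring order
    z = np.zeros(3)
    for k in range(len(centered)):
        z += np.cross(centered[k], centered[(k + 1) % len(centered)])
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError(f"residue {name} {res.id[1]}: degenerate ring geometry")
    z /= nz
    wc = _coord(res, WC_NITROGEN[name])
    x = wc - origin
    x -= (x @ z) * z
    nx_ = np.linalg.norm(x)
    if nx_ < 1e-9:
        raise ValueError(f"residue {name} {res.id[1]}: WC edge direction undefined")
    x /= nx_
    y = np.cross(z, x)
    return origin, np.vstack([x, y, z])


def _edge_from_azimuth(theta_deg: float) -> str:
    """Interacting edge from the partner azimuth in a base's own frame."""
    if -60.0 <= theta_deg <= 60.0:
        return "WC"
    if 60.0 < theta_deg <= 180.0:
        return "Hoogsteen"
    return "Sugar"


_EDGE_LETTER = {"WC": "W", "Hoogsteen": "H", "Sugar": "S"}


def annotate_base_pairs(model, geometry: PairingGeometry | None = None) -> list[BasePair]:
    """Detect and classify base pairs in a structure.

    Residues i and j are paired when the mutual r-vectors (centre of one
    base in the frame of the other) both fall inside the acceptance
    ellipsoid ``(x/a)^2 + (y/a)^2 + (z/b)^2 <= 1`` with ``|z| <= z_max``.
    Edges come from azimuth sectors, orientation from the sign of the
    ring-normal dot product (antiparallel normals = cis).  Pairs whose
    geometry defeats edge or orientation assignment are classed ``XXX``.
    """
    geom = geometry or PairingGeometry()
    model = load_model(model)
    residues = _rna_residues(model)
    frames = {}
    for num, res in residues.items():
        frames[num] = base_frame(res)
    pairs: list[BasePair] = []
    nums = sorted(residues)
    for ai in range(len(nums)):
        for bi in range(ai + 1, len(nums)):
            i, j = nums[ai], nums[bi]
            oi, Ri = frames[i]
            oj, Rj = frames[j]
            rij = Ri @ (oj - oi)  # centre of j in frame of i
            rji = Rj @ (oi - oj)
            ok = True
            for r in (rij, rji):
                rho = (r[0] / geom.a) ** 2 + (r[1] / geom.a) ** 2 \
                    + (r[2] / geom.b) ** 2
                if rho > 1.0 or abs(r[2]) > geom.z_max:
                    ok = False
                    break
            if not ok:
                continue
            pairs.append(_classify(i, j, rij, rji, Ri, Rj, geom))
    return pairs


def _classify(i, j, rij, rji, Ri, Rj, geom: PairingGeometry) -> BasePair:
    inplane_ij = math.hypot(rij[0], rij[1])
    inplane_ji = math.hypot(rji[0], rji[1])
    normal_dot = float(Ri[2] @ Rj[2])
    if (inplane_ij < geom.min_inplane or inplane_ji < geom.min_inplane
            or abs(normal_dot) < geom.min_normal_alignment):
        return BasePair(i, j, None, None, None, "XXX")
    edge_i = _edge_from_azimuth(math.degrees(math.atan2(rij[1], rij[0])))
    edge_j = _edge_from_azimuth(math.degrees(math.atan2(rji[1], rji[0])))
    orientation = "cis" if normal_dot < 0 else "trans"
    letters = sorted((_EDGE_LETTER[edge_i], _EDGE_LETTER[edge_j]),
                     key="WHS".index)
    category = orientation[0] + "".join(letters)
    return BasePair(i, j, edge_i, edge_j, orientation, category)


def wc_edge_distance(model, i: int, j: int) -> float:
    """Distance (A) between the Watson-Crick-edge nitrogens of residues i, j.

    Uses N1 for purines and N3 for pyrimidines; paired bases sit around 3 A.
    """
    residues = _rna_residues(load_model(model))
    coords = []
    for num in (i, j):
        if num not in residues:
            raise KeyError(f"residue {num} not found")
        res = residues[num]
        coords.append(_coord(res, WC_NITROGEN[res.get_resname().strip()]))
    return float(np.linalg.norm(coords[0] - coords[1]))


_NU_ATOMS = [
    ("C4'", "O4'", "C1'", "C2'"),   # nu0
    ("O4'", "C1'", "C2'", "C3'"),   # nu1
    ("C1'", "C2'", "C3'", "C4'"),   # nu2
    ("C2'", "C3'", "C4'", "O4'"),   # nu3
    ("C3'", "C4'", "O4'", "C1'"),   # nu4
]


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees (IUPAC convention)."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.cross(n1, n2) @ (b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(y, n1 @ n2))


def sugar_torsions(res) -> np.ndarray:
    """The five endocyclic ribose torsions nu0..nu4 in degrees."""
    return np.array([
        _dihedral(*(np.asarray(_coord(res, a)) for a in quad))
        for quad in _NU_ATOMS
    ])


def pucker_phase(res, min_amplitude: float = 1.0) -> float:
    """Pseudorotation phase P (degrees, [0, 360)) of a ribose ring.

    Altona-Sundaralingam: ``tan P = ((nu4 + nu1) - (nu3 + nu0)) /
    (2 nu2 (sin 36 + sin 72))``, quadrant-resolved via atan2 so the sign of
    nu2 is honoured.  A near-planar ring (pucker amplitude below
    ``min_amplitude`` degrees) has no defined phase and raises ValueError.
    """
    nu = sugar_torsions(res)
    num = (nu[4] + nu[1]) - (nu[3] + nu[0])
    den = 2.0 * nu[2] * (math.sin(math.radians(36)) + math.sin(math.radians(72)))
    P = math.degrees(math.atan2(num, den)) % 360.0
    tau_m = nu[2] / math.cos(math.radians(P)) if abs(math.cos(math.radians(P))) > 1e-9 \
        else num / (2 * (math.sin(math.radians(36)) + math.sin(math.radians(72))))
    if abs(tau_m) < min_amplitude:
        raise ValueError(
            f"residue {res.id[1]}: ring nearly planar "
            f"(amplitude {abs(tau_m):.2f} deg), pucker phase undefined"
        )
    return P


def _stem_frame(residues: dict[int, object], stem_pairs) -> np.ndarray:
    """Orthonormal frame (rows x,y,z) of a helical stem from its C1' atoms.

    z is the least-squares axis through the per-pair C1' midpoints, oriented
    from the first to the last pair; x is the perpendicular component of the
    first pair's strand-1 C1' offset.
    """
    if len(stem_pairs) < 3:
        raise ValueError("need at least 3 base pairs to fit a helical axis")
    mids, firsts = [], []
    for (i, j) in stem_pairs:
        ci = _coord(residues[i], "C1'")
        cj = _coord(residues[j], "C1'")
        mids.append(0.5 * (ci + cj))
        firsts.append(ci)
    mids = np.array(mids)
    center = mids.mean(axis=0)
    _, s, vt = np.linalg.svd(mids - center)
    if s[0] < 1e-6:
        raise ValueError("degenerate stem geometry: coincident pair midpoints")
    z = vt[0]
    if z @ (mids[-1] - mids[0]) < 0:
        z = -z
    x = firsts[0] - mids[0]
    x = x - (x @ z) * z
    nx_ = np.linalg.norm(x)
    if nx_ < 1e-9:
        raise ValueError("degenerate stem geometry: reference direction undefined")
    x /= nx_
    return np.vstack([x, np.cross(z, x), z])


def interhelical_angles(model, stem1_pairs, stem2_pairs) -> tuple[float, float, float]:
    """Euler angles (alpha, beta, gamma; z-y-z convention, degrees) between stems.

    Each stem is the list of its (i, j) base pairs; beta is the inter-helical
    bend angle between the two axes, alpha/gamma the twists about them.
    """
    from scipy.spatial.transform import Rotation

    residues = _rna_residues(load_model(model))
    R1 = _stem_frame(residues, stem1_pairs)
    R2 = _stem_frame(residues, stem2_pairs)
    # rotation carrying stem-1 frame onto stem-2 frame (axes stored as rows)
    rel = R2.T @ R1
    with warnings.catch_warnings():
        # coaxial stems (beta ~ 0) gimbal-lock alpha/gamma; scipy then fixes
        # gamma = 0, which is an acceptable convention here
        warnings.simplefilter("ignore", UserWarning)
        alpha, beta_, gamma = Rotation.from_matrix(rel).as_euler(
            "ZYZ", degrees=True)
    return float(alpha), float(beta_), float(gamma)


def sasa(
    model,
    residue: int,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> float:
    """Shrake-Rupley solvent-accessible surface area (A^2) of one residue.

    Spherical quadrature with ``n_points`` test points per atom and a 1.4 A
    water probe; the radius table can be overridden per element.
    """
    from Bio.PDB.SASA import ShrakeRupley

    model = load_model(model)
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points,
                      radii_dict=radii)
    try:
        sr.compute(model, level="A")
    except KeyError as err:
        raise KeyError(
            f"unknown element radius {err}; pass radii={{element: r}}"
        ) from None
    # any residue type qualifies here: SASA is purely geometric
    for chain in model:
        for res in chain:
            if res.id[1] == residue:
                return float(sum(a.sasa for a in res))
    raise KeyError(f"residue {residue} not found")


def compute_descriptors(
    models: dict[int, object],
    pair_distances=None,
    pucker_residues=(6, 7, 8, 9),
    stem1_pairs=None,
    stem2_pairs=None,
    sasa_residue: int | None = 23,
) -> pd.DataFrame:
    """Per-structure geometric descriptor matrix.

    ``models`` maps minimum id -> structure.  Default feature set follows
    the stemloop analysis: seven diagnostic base-pair distances, the sugar
    pucker of the bulge-adjacent residues, the three helix-bulge-helix Euler
    angles (when both stems are given), and the SASA of the bulge-flanking
    nucleotide.  Columns are fixed and ordered; any uncomputable feature
    raises rather than silently going missing.
    """
    if pair_distances is None:
        pair_distances = DEFAULT_PAIR_DISTANCES
    rows = []
    for mid in sorted(models):
        model = load_model(models[mid])
        residues = _rna_residues(model)
        row: dict[str, float] = {}
        for (i, j) in pair_distances:
            row[f"d_{i}_{j}"] = wc_edge_distance(model, i, j)
        for r in pucker_residues:
            if r not in residues:
                raise KeyError(f"pucker residue {r} missing in minimum {mid}")
            row[f"pucker_{r}"] = pucker_phase(residues[r])
        if stem1_pairs and stem2_pairs:
            a, b, g = interhelical_angles(model, stem1_pairs, stem2_pairs)
            row["alpha"], row["beta"], row["gamma"] = a, b, g
        if sasa_residue is not None:
            row[f"sasa_{sasa_residue}"] = sasa(model, sasa_residue)
        rows.append(pd.Series(row, name=mid))
    return pd.DataFrame(rows)


@dataclass
class PCAModel:
    """Standardised principal-component model of a descriptor matrix."""

    feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray          # (n_components, n_features)
    explained_var_ratio: np.ndarray
    dropped: list[str] = field(default_factory=list)


def fit_pca(X: pd.DataFrame, n_components: int | None = None) -> tuple[PCAModel, np.ndarray]:
    """Z-score features, then PCA.  Returns (model, training scores).

    Zero-variance columns are dropped with a warning (they carry no
    information and break standardisation).
    """
    from sklearn.decomposition import PCA

    if len(X) < 2:
        raise ValueError("PCA needs at least two structures")
    variances = X.var(axis=0, ddof=0)
    dropped = [c for c in X.columns if variances[c] <= 1e-300]
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}")
        X = X.drop(columns=dropped)
    means = X.mean(axis=0).to_numpy()
    scales = X.std(axis=0, ddof=0).to_numpy()
    Z = (X.to_numpy() - means) / scales
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Z)
    model = PCAModel(
        feature_names=list(X.columns),
        means=means,
        scales=scales,
        loadings=pca.components_,
        explained_var_ratio=pca.explained_variance_ratio_,
        dropped=dropped,
    )
    return model, scores


def project(model: PCAModel, X: pd.DataFrame) -> np.ndarray:
    """Project new rows with the stored standardisation and loadings."""
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise KeyError(f"projection input lacks features: {missing}")
    Z = (X[model.feature_names].to_numpy() - model.means) / model.scales
    return Z @ model.loadings.T
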