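"""Desk-scale stationary-point search on analytic potentials.

Builds kinetic transition networks end-to-end without a force field:
candidate transition states come from doubly nudged elastic bands (DNEB)
between pairs of minima, are refined to index-1 saddles by hybrid
eigenvector-following (HEF), and connected to their two minima by
steepest-descent paths along the unique downhill eigendirection.  The
exploration loop repeats over unconnected nearest pairs until the network's
heat-capacity curve stops changing.

Potentials are pluggable; a 1D double well and the classic two-dimensional
four-term exponential benchmark surface (three minima, two saddles) are
built in.  All benchmark stationary-point values used in tests are
established by the independent dense-grid + Newton oracle in
:func:`grid_newton_stationary_points`, never hardcoded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, root

from .ktn_io import KTN, Minimum, TransitionState

__all__ = [
    "Potential",
    "DoubleWell1D",
    "Benchmark2D",
    "get_potential",
    "SearchResult",
    "ExploreResult",
    "dneb",
    "hef_refine",
    "descend_connect",
    "explore",
    "grid_newton_stationary_points",
    "SaddleRejection",
]

GTOL = 1e-7


class SaddleRejection(RuntimeError):
    """Raised when refinement converges to a stationary point of wrong index."""


class Potential:
    """Callable-contract base class for analytic potentials.

    Subclasses implement ``energy``; ``gradient`` and ``hessian`` default to
    central finite differences, adequate for the low-dimensional surfaces
    this module targets.
    """

    dim: int = 1

    def energy(self, x: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = np.empty(self.dim)
        for i in range(self.dim):
            e = np.zeros(self.dim)
            e[i] = h
            g[i] = (self.energy(x + e) - self.energy(x - e)) / (2 * h)
        return g

    def hessian(self, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        H = np.empty((self.dim, self.dim))
        for i in range(self.dim):
            e = np.zeros(self.dim)
            e[i] = h
            H[:, i] = (self.gradient(x + e) - self.gradient(x - e)) / (2 * h)
        return 0.5 * (H + H.T)

    def check_gradient(self, x: np.ndarray, rtol: float = 1e-5) -> bool:
        """Central-difference consistency check of an analytic gradient."""
        x = np.asarray(x, dtype=float)
        fd = Potential.gradient.__get__(self)(x)
        g = self.gradient(x)
        scale = max(np.linalg.norm(g), 1.0)
        return bool(np.linalg.norm(fd - g) <= rtol * scale)


class DoubleWell1D(Potential):
    """E(x) = x^4 - x^2: minima at +-1/sqrt(2), saddle at 0."""

    dim = 1

    def energy(self, x):
        x = float(np.asarray(x).reshape(()))
        return x ** 4 - x ** 2

    def gradient(self, x, h=None):
        x = float(np.asarray(x).reshape(()))
        return np.array([4 * x ** 3 - 2 * x])

    def hessian(self, x, h=None):
        x = float(np.asarray(x).reshape(()))
        return np.array([[12 * x ** 2 - 2]])


class Benchmark2D(Potential):
    """The standard four-term exponential 2D test surface.

    ``E(x, y) = sum_k A_k exp(a_k (x - x0_k)^2 + b_k (x - x0_k)(y - y0_k)
    + c_k (y - y0_k)^2)``; it has three minima joined by two index-1
    saddles, making it the canonical shakedown target for saddle-search
    pipelines.
    """

    dim = 2
    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])
    #: region containing all stationary points of interest
    bounds = ((-1.8, 1.3), (-0.4, 2.2))

    def _terms(self, x, y):
        dx, dy = x - self.x0, y - self.y0
        # clamp the exponent: far outside the region of interest the surface
        # saturates instead of overflowing (all stationary points unaffected)
        arg = self.a * dx ** 2 + self.b * dx * dy + self.c * dy ** 2
        return self.A * np.exp(np.minimum(arg, 60.0))

    def energy(self, xy):
        x, y = np.asarray(xy, dtype=float)
        return float(self._terms(x, y).sum())

    def gradient(self, xy, h=None):
        x, y = np.asarray(xy, dtype=float)
        dx, dy = x - self.x0, y - self.y0
        t = self._terms(x, y)
        gx = (t * (2 * self.a * dx + self.b * dy)).sum()
        gy = (t * (self.b * dx + 2 * self.c * dy)).sum()
        return np.array([gx, gy])

    def hessian(self, xy, h=None):
        x, y = np.asarray(xy, dtype=float)
        dx, dy = x - self.x0, y - self.y0
        t = self._terms(x, y)
        u = 2 * self.a * dx + self.b * dy
        v = self.b * dx + 2 * self.c * dy
        hxx = (t * (u ** 2 + 2 * self.a)).sum()
        hyy = (t * (v ** 2 + 2 * self.c)).sum()
        hxy = (t * (u * v + self.b)).sum()
        return np.array([[hxx, hxy], [hxy, hyy]])


_POTENTIALS = {"doublewell": DoubleWell1D, "benchmark2d": Benchmark2D}


def get_potential(name: str) -> Potential:
    """Look up a registered potential by name."""
    try:
        return _POTENTIALS[name]()
    except KeyError:
        raise KeyError(
            f"unknown potential {name!r}; choose from {sorted(_POTENTIALS)}"
        ) from None


# ---------------------------------------------------------------------------
# DNEB

def _dneb_forces(pot: Potential, band: np.ndarray, k_spring: float) -> np.ndarray:
    n = band.shape[0]
    forces = np.zeros_like(band)
    for i in range(1, n - 1):
        tau = band[i + 1] - band[i - 1]
        tau /= max(np.linalg.norm(tau), 1e-12)
        g = pot.gradient(band[i])
        g_perp = g - (g @ tau) * tau
        d_next = band[i + 1] - band[i]
        d_prev = band[i] - band[i - 1]
        g_spring = -k_spring * (d_next - d_prev)
        spring_par = (g_spring @ tau) * tau
        spring_perp = g_spring - spring_par
        # doubly nudged: keep the spring-perpendicular part orthogonal to the
        # true perpendicular gradient, which damps corner cutting
        gp_norm = np.linalg.norm(g_perp)
        if gp_norm > 1e-12:
            ghat = g_perp / gp_norm
            spring_perp = spring_perp - (spring_perp @ ghat) * ghat
        forces[i] = -(g_perp) - spring_par + spring_perp
    return forces


def dneb(
    pot: Potential,
    x_a: np.ndarray,
    x_b: np.ndarray,
    n_images: int = 15,
    k_spring: float = 100.0,
    max_iter: int = 2000,
    gtol: float = 1e-4,
) -> tuple[np.ndarray, list[int]]:
    """Optimise a doubly nudged elastic band between two minima.

    Returns the optimised band (including endpoints) and the indices of
    interior images that are local energy maxima along it — the transition
    state candidates.  Endpoints must already be minima.
    """
    x_a = np.atleast_1d(np.asarray(x_a, dtype=float))
    x_b = np.atleast_1d(np.asarray(x_b, dtype=float))
    for x in (x_a, x_b):
        if np.linalg.norm(pot.gradient(x)) > 1e-4:
            raise ValueError("DNEB endpoints must be converged minima")
    if np.linalg.norm(x_a - x_b) < 1e-10:
        return np.vstack([x_a, x_b]), []
    ts = np.linspace(0.0, 1.0, n_images + 2)
    band = np.array([(1 - t) * x_a + t * x_b for t in ts])

    # damped descent on the projected forces with a hard cap on per-image
    # displacement: the projected force field is non-conservative, so a
    # bounded, monotone-step scheme beats momentum methods for robustness
    max_disp = 0.02 * max(np.linalg.norm(x_b - x_a) / (n_images + 1), 1e-3)
    dt = 1e-3
    for _ in range(max_iter):
        F = _dneb_forces(pot, band, k_spring)
        fnorm = np.linalg.norm(F)
        if fnorm < gtol:
            break
        step = dt * F
        biggest = np.max(np.linalg.norm(step, axis=1))
        if biggest > max_disp:
            step *= max_disp / biggest
        band += step

    energies = np.array([pot.energy(x) for x in band])
    candidates = [
        i for i in range(1, len(band) - 1)
        if energies[i] >= energies[i - 1] and energies[i] >= energies[i + 1]
    ]
    return band, candidates


# ---------------------------------------------------------------------------
# HEF refinement and descent

@dataclass
class SearchResult:
    """A converged saddle with its Hessian spectrum and connected minima."""

    saddle: np.ndarray
    energy: float
    eigenvalues: np.ndarray
    minus_side: np.ndarray | None = None
    plus_side: np.ndarray | None = None


def hef_refine(
    pot: Potential,
    x0: np.ndarray,
    gtol: float = GTOL,
    max_iter: int = 300,
    trust: float = 0.15,
    eig_tol: float = 1e-6,
) -> SearchResult:
    """Refine a candidate to an index-1 saddle by eigenvector-following.

    The step moves uphill along the lowest Hessian eigenvector and downhill
    (Newton-like) in the orthogonal complement, capped at a trust radius.
    Convergence to a stationary point whose Hessian index differs from 1
    raises :class:`SaddleRejection` with the offending spectrum.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    for _ in range(max_iter):
        g = pot.gradient(x)
        H = pot.hessian(x)
        lam, vec = np.linalg.eigh(H)
        if np.linalg.norm(g) < gtol:
            index = int((lam < -eig_tol).sum())
            if index != 1 or np.any(np.abs(lam) <= eig_tol):
                raise SaddleRejection(
                    f"converged to Hessian index {index} at {x} "
                    f"(eigenvalues {lam})"
                )
            return SearchResult(saddle=x, energy=pot.energy(x), eigenvalues=lam)
        gk = vec.T @ g
        step = np.empty_like(gk)
        # uphill along the softest mode, downhill in the complement
        step[0] = gk[0] / (abs(lam[0]) + 1e-8)
        step[1:] = -gk[1:] / (np.abs(lam[1:]) + 1e-8)
        s = vec @ step
        ns = np.linalg.norm(s)
        if ns > trust:
            s *= trust / ns
        x = x + s
    raise SaddleRejection(f"no convergence after {max_iter} HEF iterations at {x}")


def _minimize(pot: Potential, x0: np.ndarray) -> np.ndarray:
    res = minimize(pot.energy, x0, jac=lambda x: pot.gradient(x),
                   method="L-BFGS-B", options={"gtol": 1e-10, "maxiter": 2000})
    return np.atleast_1d(res.x)


def descend_connect(
    pot: Potential, result: SearchResult, eps: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Find the two minima connected through a saddle.

    Starts two minimisations displaced by ``+-eps * scale`` along the unique
    negative eigendirection (approximate steepest-descent connection); the
    two endpoints may coincide for degenerate rearrangements.  Accepts a
    :class:`SearchResult` or raw saddle coordinates.
    """
    if not isinstance(result, SearchResult):
        x = np.atleast_1d(np.asarray(result, dtype=float))
        result = SearchResult(saddle=x, energy=pot.energy(x),
                              eigenvalues=np.linalg.eigvalsh(pot.hessian(x)))
    lam, vec = np.linalg.eigh(pot.hessian(result.saddle))
    if (lam < -1e-6).sum() != 1:
        raise ValueError("descend_connect requires a valid index-1 saddle")
    v1 = vec[:, 0]
    scale = max(np.linalg.norm(result.saddle), 1.0)
    lo = _minimize(pot, result.saddle - eps * scale * v1)
    hi = _minimize(pot, result.saddle + eps * scale * v1)
    result.minus_side, result.plus_side = lo, hi
    return lo, hi


# ---------------------------------------------------------------------------
# exploration loop

@dataclass
class ExploreResult:
    """KTN emitted by :func:`explore` plus stationary-point coordinates."""

    ktn: KTN
    min_coords: list[np.ndarray]
    ts_coords: list[np.ndarray]
    converged: bool
    n_dneb: int = 0
    messages: list[str] = field(default_factory=list)


def _log_prod_freqs(eigenvalues: np.ndarray, skip_negative: bool) -> float:
    """ln prod nu_j with nu_j = sqrt(lambda_j)/(2 pi) over real modes."""
    lam = np.sort(eigenvalues)
    if skip_negative:
        lam = lam[1:]
    if np.any(lam <= 0):
        raise ValueError("non-positive eigenvalue among real modes")
    return float(np.sum(np.log(np.sqrt(lam) / (2 * math.pi))))


def _find_or_add(coords_list: list[np.ndarray], x: np.ndarray,
                 tol: float = 1e-4) -> tuple[int, bool]:
    for k, c in enumerate(coords_list):
        if np.linalg.norm(c - x) < tol:
            return k, False
    coords_list.append(x)
    return len(coords_list) - 1, True


def explore(
    pot: Potential,
    seeds,
    budget: int = 50,
    T_grid=None,
    cv_rtol: float = 1e-3,
    n_images: int = 15,
    k_spring: float = 100.0,
) -> ExploreResult:
    """Grow a KTN by repeated DNEB -> HEF -> descent over unconnected pairs.

    Pairs of known minima without a direct transition state are attempted
    nearest-first.  After each new connection the heat-capacity curve of the
    growing network is recomputed on ``T_grid``; the search stops when the
    curve changes by less than ``cv_rtol`` (relative, max over the grid)
    while the network is connected, or when the DNEB ``budget`` runs out
    (the partial KTN is then returned with ``converged=False``).
    """
    from .harmonic_thermo import heat_capacity_curve

    min_coords: list[np.ndarray] = []
    for s in seeds:
        x = _minimize(pot, np.atleast_1d(np.asarray(s, dtype=float)))
        _find_or_add(min_coords, x)
    ts_records: list[tuple[np.ndarray, float, np.ndarray, int, int]] = []
    attempted: set[tuple[int, int]] = set()
    messages: list[str] = []
    n_dneb = 0
    prev_cv = None
    converged = False

    def direct_edges() -> set[tuple[int, int]]:
        return {(min(a, b), max(a, b)) for (_, _, _, a, b) in ts_records}

    def build() -> KTN:
        minima = [
            Minimum(id=i + 1, V=pot.energy(x),
                    log_prod=_log_prod_freqs(
                        np.linalg.eigvalsh(pot.hessian(x)), skip_negative=False))
            for i, x in enumerate(min_coords)
        ]
        ts = [
            TransitionState(id=k + 1, V=e, log_prod=_log_prod_freqs(lam, True),
                            pg_order=1.0, min1=a + 1, min2=b + 1)
            for k, (x, e, lam, a, b) in enumerate(ts_records)
        ]
        return KTN(minima=minima, transition_states=ts, kappa=pot.dim)

    def cv_now() -> np.ndarray | None:
        ktn = build()
        if ktn.n_minima < 1:
            return None
        if T_grid is not None:
            grid = np.asarray(T_grid, dtype=float)
        else:
            spread = max(m.V for m in ktn.minima) - min(m.V for m in ktn.minima)
            scale = max(spread, 1.0) / 0.0019872041
            grid = np.linspace(0.05 * scale, 2.0 * scale, 16)
        return heat_capacity_curve(ktn, grid)

    while n_dneb < budget:
        pairs = sorted(
            (
                (np.linalg.norm(min_coords[a] - min_coords[b]), a, b)
                for a, b in itertools.combinations(range(len(min_coords)), 2)
                if (a, b) not in attempted and (a, b) not in direct_edges()
            ),
        )
        if not pairs:
            converged = True
            break
        _, a, b = pairs[0]
        attempted.add((a, b))
        n_dneb += 1
        try:
            band, cand = dneb(pot, min_coords[a], min_coords[b],
                              n_images=n_images, k_spring=k_spring)
        except ValueError as err:
            messages.append(f"dneb {a + 1}-{b + 1}: {err}")
            continue
        for ci in cand:
            try:
                sr = hef_refine(pot, band[ci])
            except SaddleRejection as err:
                messages.append(f"candidate rejected: {err}")
                continue
            lo, hi = descend_connect(pot, sr)
            ia, _ = _find_or_add(min_coords, lo)
            ib, _ = _find_or_add(min_coords, hi)
            dup = any(
                np.linalg.norm(x - sr.saddle) < 1e-4 for (x, *_rest) in ts_records
            )
            if not dup:
                ts_records.append((sr.saddle, sr.energy, sr.eigenvalues, ia, ib))
        cv = cv_now()
        if (prev_cv is not None and cv is not None
                and cv.shape == prev_cv.shape):
            delta = np.max(np.abs(cv - prev_cv) / np.maximum(np.abs(prev_cv), 1e-12))
            import networkx as nx

            if delta < cv_rtol and nx.is_connected(build().graph()):
                converged = True
                break
        prev_cv = cv

    ktn = build()
    for i, m in enumerate(ktn.minima):
        m.coords_ref = str(i)
    return ExploreResult(
        ktn=ktn,
        min_coords=min_coords,
        ts_coords=[x for (x, *_r) in ts_records],
        converged=converged,
        n_dneb=n_dneb,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# independent oracle

def grid_newton_stationary_points(
    pot: Potential,
    bounds,
    n_grid: int = 40,
    dedup_tol: float = 1e-5,
) -> dict[str, list[dict]]:
    """Exhaustively locate stationary points by dense grid + Newton polish.

    Runs a Newton root search on the gradient from every grid node, keeps
    converged points inside the bounds, deduplicates, and classifies each by
    Hessian index.  Independent of the DNEB/HEF machinery; serves as the
    ground-truth oracle for the benchmark surfaces.
    """
    axes = [np.linspace(lo, hi, n_grid) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    starts = np.stack([m.ravel() for m in mesh], axis=1)
    found: list[np.ndarray] = []
    for x0 in starts:
        sol = root(pot.gradient, x0, jac=pot.hessian, method="hybr",
                   tol=1e-12)
        if not sol.success:
            continue
        x = np.atleast_1d(sol.x)
        if any(not (lo - 1e-9 <= xi <= hi + 1e-9)
               for xi, (lo, hi) in zip(x, bounds)):
            continue
        if np.linalg.norm(pot.gradient(x)) > 1e-8:
            continue
        if any(np.linalg.norm(x - f) < dedup_tol for f in found):
            continue
        found.append(x)
    out: dict[str, list[dict]] = {"minima": [], "saddles": [], "higher": []}
    for x in found:
        lam = np.linalg.eigvalsh(pot.hessian(x))
        index = int((lam < -1e-8).sum())
        rec = {"x": x, "energy": pot.energy(x), "eigenvalues": lam,
               "index": index}
        key = {0: "minima", 1: "saddles"}.get(index, "higher")
        out[key].append(rec)
    for key in out:
        out[key].sort(key=lambda r: r["energy"])
    return out
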