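# Methods

This note records the models `ktnkit` implements, the conventions it pins
down, and what its synthetic-data tests do and do not demonstrate.

## The stationary-point description

A landscape is represented by its local minima and index-1 saddle points
(transition states).  Each stationary point stores its potential energy `V`
(kcal/mol), the log of the product of its real normal-mode frequencies
(`log_prod`, frequencies in s⁻¹; κ modes for a minimum, κ−1 for a saddle)
and its point-group order.  A transition state must lie at or above both
minima it connects; `validate_ktn` enforces this with discard/clamp/error
policies.  Transition states with `min1 == min2` mark degenerate
rearrangements and never contribute graph edges or rates.

File format: whitespace-separated rows, ids = 1-based line numbers.
Minima: `V log_prod pg_order [ignored...]`; transition states:
`V log_prod pg_order min1 min2 [ignored...]`.  Trailing columns are read
and ignored so externally produced databases load without reinterpretation.
Floats are written with shortest round-trip precision so read∘write is the
identity.

Constants: k_B = 0.0019872041 kcal mol⁻¹ K⁻¹; the Eyring prefactor
k_BT/h is evaluated in SI.  Default analysis temperature 310.15 K (37 °C,
the temperature of the experimental exchange measurements).

## Harmonic-superposition thermodynamics

The total partition function is the sum of classical harmonic-well terms.
Per minimum, with common factors dropped,

    ln w_i = −V_i/(k_B T) − log_prod_i − ln o_i ,

occupations are softmax of these log-weights (computed via logsumexp) and
F_i = −k_BT ln w_i, so only free-energy *differences* are meaningful.
Quantum and anharmonic corrections, and rotational partition functions,
are deliberately omitted: free-energy differences then depend only on the
stored columns.  The heat capacity is

    C_v/k_B = κ + (⟨V²⟩ − ⟨V⟩²)/(k_B T)² ,

the classical intra-well term plus the inter-well fluctuation term whose
peaks mark landscape transitions; it is cross-checked against a central
finite difference of ⟨E⟩(T) in the tests (agreement ≲1e-9 k_B).

## Kinetics

Harmonic TST rate out of minimum a through transition state t:

    k(a→) = (o_a/o_t) · exp(log_prod_a − log_prod_t) · exp(−(V_t − V_a)/k_BT).

These rates satisfy detailed balance with the harmonic weights identically;
the assembled rate matrix (parallel saddles summed, columns summing to
zero) shows residuals at machine precision.

Effective two-state rates between disjoint sets A, B are inverse mean
first-passage times: the MFPT vector to absorbing B solves the dense linear
system of the generator restricted to non-B states, and is averaged over A
with equilibrium weights conditioned on A.  Dense solves are used — at desk
scale (≲2×10³ states) they are simpler and more transparent than graph
transformation, and they are validated against matrix-exponential
propagation of the master equation.  The two-state identity
k_f/k_r = P_B/P_A holds exactly for two-minimum networks and in the
metastable limit generally; for networks with substantial intermediate
population the MFPT rates are approximations and the identity degrades
smoothly (this is inherent to the MFPT definition, not a numerical issue).

Rate↔barrier conversions use the Eyring relation with transmission
coefficient 1.  Two-state chemical exchange is split as k_f = p·k_ex,
k_r = (1−p)·k_ex.  With the published TAR parameters (k_ex = 474 s⁻¹,
p = 0.004, T = 310.15 K) this yields 17.79 and 14.39 kcal/mol; the CEST
value k_ex = 737 s⁻¹ shifts both by < 0.3 kcal/mol.

The *fastest path* between two minima maximises the product of branching
probabilities P(a→b) = k(a→b)/Σ_c k(a→c) (equivalently minimises
Σ −ln P over directed edges, Dijkstra).  Waiting times are ignored — this
is the "best path" notion of discrete path sampling.  Exact weight ties are
broken towards the lexicographically smallest transition-state id sequence;
parallel saddles are reported by their lowest-energy member.

## Free-energy regrouping

At temperature T, groups are lumped when the barrier between them is below
a threshold in *both* directions, where group free energies are
−k_BT·logsumexp over member weights and inter-group transition free
energies are −k_BT·logsumexp over all connecting saddles (parallel-path
entropy included).  Transition-state weights carry a −ln(k_BT/h) offset so
that for a single saddle between two lone minima F_ts − F_min equals the
Eyring barrier of the TST rate exactly; group-level barriers and
`barrier_to_rate` are then mutually consistent.

The fixed point is reached by a simultaneous-closure sweep: all qualifying
pairs are identified against the *current* partition and merged at once
(connected components of the qualifying-pair graph), then free energies are
recomputed.  This makes the result independent of any merge ordering by
construction.  Because the experimentally comparable barriers depend on the
chosen threshold, no default threshold is hard-coded; `barrier_scan` emits
barriers versus threshold between two anchor minima so the dependence is
explicit.  Reproducing regrouped barriers for a full-scale database is
therefore a scan, not a single magic number.

## Disconnectivity analysis

A superbasin at threshold E is a connected component of the graph
restricted to transition states with energy ≤ E (minima above E excluded).
The tree stacks superbasin partitions on a descending level grid with
spacing ΔE; each leaf pair's merge level brackets its exact minimax path
energy from below-plus-ΔE (verified against a Kruskal union-find oracle).
Funnel selection cuts the anchor's superbasin at an exact energy (not
snapped to the presentation grid).  Free-energy trees are built on the
quotient network of a regrouped partition.  Internal-node colours are
weighted means of member order-parameter values (uniform weights by
default, occupation weights optional) — a convention, since branch colour
aggregation is not otherwise defined.  Layout is data plus a deterministic
recursive-midpoint x-assignment; rendering is left to the host environment.

## RNA structural descriptors

*Base frames.* Origin = centroid of the six-membered-ring atoms (C2/C4/C6
minimum set), z = Newell normal over the ordered ring atoms, x = direction
to the Watson–Crick-edge nitrogen (N1 purines, N3 pyrimidines) projected
into the plane.

*Pair detection.* Bases are paired when each base's centre, in the other's
frame, lies inside the ellipsoid (x/a)² + (y/a)² + (z/b)² ≤ 1 with
additionally |z| ≤ 2 Å, mutually.  Defaults a = 6.5 Å, b = 3 Å: a canonical
WC pair has ring-centroid separation ≈ 5.6 Å (two ring radii plus a ~2.9 Å
N–N hydrogen bond), so the in-plane semi-axis must exceed that, while the
|z| cap keeps stacked neighbours (helical rise 2.8 Å) out.  All thresholds
sit in `PairingGeometry` and are the principal interpretation risk of this
module — fixture tests are written to be convention-independent.

*Classification.* Interacting edges from the azimuth of the partner
direction in each base's frame (WC |θ| ≤ 60°, Hoogsteen 60° < θ ≤ 180°,
Sugar otherwise); cis/trans from the sign of the ring-normal dot product
(antiparallel = cis).  Pairs with an in-plane offset < 1.5 Å (azimuth
unreliable) or near-perpendicular normals are reported as the catch-all
`XXX` category rather than forced into a class.  Dot-bracket output is
deliberately not used for any classification logic — wobbling makes it
ambiguous.

*Pucker.* Pseudorotation phase from the five endocyclic torsions,
P = atan2((ν4+ν1)−(ν3+ν0), 2ν2(sin36°+sin72°)), quadrant-resolved; rings
with amplitude < 1° raise instead of returning a meaningless phase.  Note
that mirror-imaging a ring negates every torsion and therefore shifts P by
180° (C3′-endo ↔ C3′-exo).

*Inter-helical angles.* Per stem, the axis is the leading singular vector
of the per-pair C1′ midpoints (oriented 5′→3′); the reference x is the
first pair's C1′ offset.  The relative rotation between stem frames is
decomposed in the intrinsic z-y-z Euler convention; β is the bend.  The
convention is pinned and tested against constructed rotations; α and γ are
convention-dependent and should only be compared within this package.

*SASA.* Shrake–Rupley via Bio.PDB with probe 1.4 Å and 960 sphere points;
the per-element radius table is overridable.

*PCA.* Features are z-scored (population ddof = 0), zero-variance columns
dropped with a warning, then an exact covariance eigendecomposition
(scikit-learn PCA).  The stored model (means, scales, loadings) projects
external ensembles into the training coordinates.

## Saddle-search core

Pluggable analytic potentials (energy required; gradient/Hessian default to
central differences).  Built in: the 1D double well x⁴ − x² and the
standard four-term exponential 2D benchmark surface with three minima and
two saddles.  Every benchmark stationary-point value used in tests comes
from the in-repo dense-grid + Newton oracle, never from literature tables.

* **DNEB**: straight-line initial band; the band feels the perpendicular
  true gradient, the parallel spring gradient, and the doubly-nudged
  portion of the perpendicular spring gradient.  The optimiser is damped
  descent with a hard per-image displacement cap — the projected force
  field is non-conservative, and bounded monotone steps proved more robust
  than momentum schemes on the steep benchmark surface.  Interior energy
  maxima become saddle candidates.  Quasi-continuous interpolation is out
  of scope: it exists to keep biomolecular interpolations physical and has
  no role on low-dimensional analytic surfaces.
* **HEF refinement**: steps uphill along the lowest Hessian eigenvector and
  Newton-like downhill in the orthogonal complement, trust-radius capped;
  convergence at gradient norm < 1e-7 with the Hessian index verified
  (anything ≠ 1 is rejected with its spectrum, not silently kept).
* **Connection**: two L-BFGS minimisations from saddle ± 1e-3·scale along
  the negative eigenvector.
* **explore** loop: unconnected minimum pairs attempted nearest-first;
  stops when the heat-capacity curve on a fixed temperature grid changes by
  < 0.1 % (relative, max over grid) with the network connected, or when the
  DNEB budget is exhausted (partial network flagged unconverged).  Emitted
  log-products use ν_j = √λ_j/2π with unit mass, κ = dim, point-group
  order 1.  The refinement heuristics of production discrete path sampling
  (trap removal, barrier short-cutting, enhanced local sampling) are
  collapsed into this single loop — adequate at desk scale.

## Synthetic data: what it emulates, what it does not

* **Funneled KTNs**: star topology per funnel (every member connects to the
  funnel's lowest minimum), one inter-funnel saddle per adjacent funnel
  pair at a fixed height above the global minimum.  This makes funnel
  membership and every pairwise minimax merge energy exact by construction,
  at the cost of realistic connectivity statistics.
* **Two-state networks**: minima/saddle energies and log-products chosen so
  harmonic TST rates equal the Eyring rates of the prescribed barriers
  exactly; generate→analyse is the identity to rounding error.
* **Random KTNs**: spanning tree plus extra edges, saddles 0.5–3 kcal/mol
  above the higher minimum, log-products uniform in ln(10¹²..10¹³)
  (prefactors of order 0.1–10 s⁻¹ relative to the saddle), optional deep
  well pair (−6 kcal/mol) for the metastable two-state regime.
* **RNA fixtures**: idealised nucleotides built in code — regular-polygon
  rings with 1.38 Å bonds, a 1.48 Å glycosidic bond, a five-atom ribose
  with a generic non-degenerate pucker — stacked with rise 2.81 Å and twist
  32.7° and paired at 2.9 Å WC-edge N–N distance with antiparallel normals.
  Bends are rigid rotations at a chosen step; unpaired residues are flipped
  out radially and staggered; register shifts re-pair shifted partners.

Passing tests on these fixtures demonstrates that the analysis stack
recovers constructed ground truth under ideal geometry.  They do not
demonstrate robustness to thermal noise, modified residues, non-ideal
sugar/backbone conformations, or crystallographic artifacts; the bulge and
bend constructions are geometric caricatures (a sharp bend can create
incidental base contacts at the junction, which the annotator will
faithfully report).  Energetics of the toy landscapes are not
sequence-dependent RNA thermodynamics.

## Problem sizes and numerical choices

Default test/acceptance workloads: 20 random networks of 6–20 minima for
kinetics oracles, 20 networks of 6–15 minima for topography oracles, a
25×25 oracle grid and budget-20 exploration on the benchmark surface, 6–16
nucleotide fixtures, and an 8-member bent-helix ensemble for PCA — sizes at
which every brute-force oracle is exact and fast.  Occupation
normalisation is exact to 1e-12; detailed-balance residuals are machine
precision; matrix-exponential fits use 20 log-spaced times in
[0.1, 3.2]/k_ex starting from the minor state, the window where the
exchange mode dominates the relaxation signal.

## Known limitations

* MFPT-based effective rates (and hence the k_f/k_r = P_B/P_A identity)
  are exact two-state quantities only in the metastable limit.
* Regrouped barriers depend on the lumping threshold; the scan replaces a
  default, and full-scale landscape reproduction requires the corresponding
  stationary-point database.
* Base-pair edge sectors, cis/trans sign, and the z-y-z Euler convention
  are pinned package conventions, not re-derivations of any external
  tool's internals; cross-tool comparisons should compare pair *sets*, not
  raw categories or α/γ values.
* The saddle-search core targets low-dimensional analytic surfaces; no
  force fields, solvent models, or Cartesian biomolecular searches.
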