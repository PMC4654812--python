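# Methods

`angiosprout` simulates angiogenic sprouting from an endothelial spheroid
with a two-dimensional Cellular Potts model (CPM) coupled to a secreted
chemoattractant field and, optionally, a per-cell VEGF–Dll4–Notch
signaling network, and quantifies tip-cell overtaking and cell kinetics
from the resulting label-matrix movies.  This note records the model, the
numerical choices, the calibrated parameters and what the package's
scaled-down test conditions do and do not establish.

## Cellular Potts model

Cells are connected patches of sites on a square lattice (site size
2 μm); σ(x) ∈ ℕ labels the owning cell, σ = 0 is extracellular matrix
(ECM).  The effective energy is

    H = Σ_(x,x') J(τ(σ(x)), τ(σ(x'))) (1 − δ(σ(x), σ(x')))
      + λ_size Σ_σ (A(σ) − a(σ))²
      + Σ_σ λ_length(σ) (L(σ) − l(σ))²

with τ ∈ {ECM, tip, stalk} the cell kind, A/a resting and actual area,
L/l target and current length.  Metropolis dynamics copy a randomly
chosen site's label into a random adjacent site; a copy is accepted with
probability min(1, exp(−ΔH/μ)), μ = 1.  One Monte Carlo step (MCS) makes
as many copy attempts as there are lattice sites and represents 30 s.

Numerical conventions:

- **Neighborhoods.** The copy neighborhood and the interfacial-energy
  neighborhood are both the Moore (8-site) neighborhood; each unordered
  site pair is counted once.
- **Boundary.** A one-site frozen ECM border; copies into or out of it
  are rejected.  The spheroid sits centrally, far from the border.
- **Cell length.** l = 4·sqrt(λ_max/a) with λ_max the largest eigenvalue
  of the cell's second-moment (inertia) tensor about its centroid —
  exact for ellipses.  The per-site moment 1/12 is included, so a single
  site has l = 4/√12 ≈ 1.15 (one site's extent).  Areas and moment sums
  are maintained incrementally (exact, since site coordinates are
  integers) with a full recomputation every 100 MCS as a consistency
  guard.
- **Connectivity.** A copy that would split the retracting cell locally
  (more than one arc of that cell's sites around the target site's Moore
  ring, or removal of its last site) adds a penalty of 10⁷, far beyond
  any thermal ΔH.  The check is local by design; it is conservative on
  diagonal contacts.
- **Randomness.** One seeded RNG drives the compiled Monte Carlo kernel;
  a second numpy generator (derived from the same run seed) handles
  initialization noise.  Identical configuration + seed gives bit-identical
  label grids.

## Chemoattractant field and chemotaxis

The cells secrete an attractant c(x) obeying

    ∂c/∂t = α·[cell] − ε·[ECM]·c + D ∇²c

solved by explicit forward Euler with a 5-point Laplacian on the CPM
lattice: Δt = 2 s, Δx = 2 μm, 15 steps per MCS, zero-flux boundaries.
The stability number D·Δt/Δx² (= 0.05 at defaults) is asserted ≤ 0.25 at
construction.  Decay acts in the ECM only, so the steady ECM profile
decays over sqrt(D/ε) ≈ 24 μm — one to two cell diameters — with
D = 10⁻¹³ m²/s and ε = 1.8·10⁻⁴ s⁻¹ (values from the prior
contact-inhibition sprouting literature).

Chemotaxis biases copy attempts by ΔH → ΔH + λ_c(c(source) − c(target)),
so extensions up the local gradient are favored.  The **contact
inhibition** variant applies the bias only where a cell meets ECM
(cell–cell interface copies are uninfluenced); the **cell elongation**
variant applies it everywhere and instead constrains cell length
(λ_length > 0).  λ_c is read per the moving cell's kind, which is how
the differential-sensitivity experiments act.

### Calibration of the secretion rate

The interfacial energies of the behavior-mode experiments (J between
0.2 and 1.0) and the chemotactic sensitivities (λ_c = 5–10) fix the
energy scale relative to μ = 1, but the secretion rate α is a free
calibration parameter at the package's reduced lattice scale.  The
contact model uses α = 3.6·10⁻⁴ s⁻¹, which keeps the rim chemotaxis
bias at order 1–3 — large enough for slow sprout extension, small
enough that (a) leader turnover stays rare (the model's hallmark) and
(b) the tip/stalk adhesion and sensitivity differences (ΔJ ≤ 0.8 per
bond) remain competitive in the mosaic experiments.  The elongation
model uses α = 1.08·10⁻³ s⁻¹, the regime in which elongated cells form
bundled sprouts and slide past one another (frequent overtakes).  Both
are config-exposed (`field_alpha`).  Because extension is slow at the
contact model's α, its kinetics runs use longer simulations (12,000
MCS, window 4,000–12,000); the elongation model's desk-scale
sprout-rich phase is early and transient — the network later coarsens
into a few thick strands — so its kinetics runs use the standard desk
window (2,000–6,000 MCS).

## VEGF–Dll4–Notch signaling

Each cell carries Dll4 (D), Notch (N) and NICD (S) levels; the VEGF
extension adds VEGFR2 (R) and VEGF activity (A).  Trans-interaction
between cells i, j is weighted by the shared membrane fraction
w_ij = |P_ij|²/(|P_i||P_j|), measured on the 4-neighborhood: |P_i| is
the number of boundary sites of cell i, and a boundary site contributes
once to |P_ij| for each distinct neighbor cell it touches (one-sided
counts are symmetrized by averaging).  The ODEs (rates per second) are
integrated by forward Euler, Δt = 3 s, 10 substeps per MCS, contacts
frozen within an MCS; negative Euler overshoots are clipped at zero and
counted.  NICD production is a Hill function of the summed trans signal
scaled by 1/d²; Dll4 and Notch cis-inhibit each other (k_c) and are
consumed by trans-signaling (k_t).  With uniform external VEGF V = 1,
VEGFR2 production is repressed by NICD, VEGF activity follows a Hill
function of R·V, and VEGF activity feeds back on Dll4 production.
*Vegfr2*⁺/⁻ cells halve both VEGFR2 production constants.

Cells switch phenotype once per MCS: tip if S is below a threshold,
stalk otherwise (the boundary value maps to stalk).  Initial conditions
are the no-contact fixed point of the cis-coupled D/N system plus 1%
multiplicative noise — lateral inhibition needs the symmetry broken.

### Parameter calibration

The rate constants are not identifiable from first principles at this
model's level of abstraction; they were calibrated once against three
qualitative anchors and then frozen: (a) a perturbed two-cell system
resolves into one high-Dll4/low-NICD and one low-Dll4/high-NICD cell,
(b) an even static ring alternates tip/stalk ("salt-and-pepper"), and
(c) Dll4 and VEGFR2 steady levels correlate positively across a mixed
population, with WT cells adopting the tip fate far more often than
*Vegfr2*⁺/⁻ cells.  The defaults (γ = 0.002 s⁻¹ decay scale, k_c = 100,
k_t = 60, d² = 0.15, α_S = 0.012, k_S = 0.01, Hill exponents 2–4) put
the trans signal at order one for spheroid-like contact geometries; the
NICD threshold default (1.0) separates the two modes of the resulting
bimodal NICD distribution, and `calibrate_nicd_threshold` re-derives it
from any calibration run as the midpoint of the exact 1D two-cluster
split (it refuses unimodal inputs).

## Sprout morphometry and leader identification

The union of cell sites is closed with a disk (radius r), skeletonized
to one-site width, terminal branches shorter than p are pruned, and
nodes within m sites are merged (r=4, p=10, m=10 for the contact model;
r=2, p=25, m=15 for the elongation model).  The "thinning radius" t of
the morphological recipe is retained as a parameter but skeletonization
runs to completion — iterating a homotopic thinning t times before
completing it yields the same skeleton.  Ends have degree 1, branches
degree ≥ 3; pass-through nodes are dissolved.  A sprout joins a branch
node B to an end node E (in a component with no branch node, the far
end stands in for B).

The leader is found geometrically: first guess G = cell containing E
(or the most frequent cell id among E's neighbors if E is in ECM); a
rasterized ray from B through E locates T, the farthest cell site
followed by ≥ 5 consecutive ECM sites (the lattice border counts as
ECM); cells with a site on the perpendicular line through T that
neighbor G (8-neighborhood) are candidates; candidates closer to B than
G in unit-weight cell-adjacency (Dijkstra) steps are dropped; among the
rest plus G, the cell owning the site with the largest Euclidean
distance to B wins, ties to the smaller id.  Sprout membership is the
leader plus its ten nearest neighbors by breadth-first expansion of the
contact graph, each layer ordered by contact size (descending, ties by
id).

Sprouts are tracked through time (frames every 20 MCS) by greedy
member-set matching: overlap |∩|/min(|A|,|B|) ≥ 0.5 continues a sprout,
otherwise a birth/death.  Sprouts tracked for fewer than 4 frames
(80 MCS) are skeleton transients: they still count in the literal
overtake-rate denominator ("sprouts present in the window") but are
excluded from occupancy scoring and axis-based kinetics, where an
80-MCS-stable identity is a precondition for the measurement.

## Kinetics statistics

Centers of mass are sampled every 20 MCS.  An overtake is a leader
change in which the outgoing leader held the tip ≥ 80 consecutive MCS
before and the incoming one ≥ 80 MCS after; shorter flickers are
protrusion noise and produce no event.  The rate divides events in the
analysis window by the sprouts present in it, rescaled to a
20,000-MCS reference window.  Tip lifetimes are tenure durations × 0.5
min/MCS; tenures truncated by sprout birth/death are flagged.

The sprout axis runs from the branch-node position (averaged over the
sprout's first and last frame) to the tip position (same frames).
Coordination is the angle θ ∈ [0, π] between a 20-MCS displacement and
the axis; std(θ/π) is reported separately for anterograde (θ < π/2) and
retrograde (θ > π/2) samples.  Directional motility classifies each
displacement: < 0.5 sites → stopped, otherwise by the sign of the axial
projection.  The MSD of axis-projected positions (re-timed from each
cell's first in-sprout sample, pooled over cells, sprouts and seeds) is
fitted with MSD(t) = 2Dt + (vt)², D, v ≥ 0, by weighted least squares
with per-lag variance ∝ MSD²/n — without weighting, the drift-dominated
long lags drown the diffusive signal.  Units convert via 2 μm/site and
30 s/MCS.

Tip occupancy pools, per run, the sprout leaders of five frames spaced
200 MCS apart at the end of the run — repeated draws from the same
steady state a single final frame samples, giving a more stable
percentage estimate.  Because a stable leader makes those draws
correlated within a sprout, the binomial tail P(X ≥ k),
X ~ B(n, mixing ratio), is computed on the strictly
one-draw-per-sprout final frame.

## Experiments and scaling

`ScenarioConfig` describes an experiment: model variant, signaling mode
(off / Dll4–Notch / VEGF–Dll4–Notch), behavior mode (uniform /
differential adhesion / differential chemosensitivity, the latter two
installing the published J and λ_c sets), WT:*Vegfr2*⁺/⁻ mixing ratio,
durations and seeds.  Runs start from a disc of 7×7-site cells
(fragments under ~half a cell are absorbed into neighbors), genotypes
drawn independently at the mixing ratio.

Two presets exist.  The **full** preset mirrors the reference
conditions: 400×400 lattice, spheroid radius 45, 30,000 MCS, analysis
window 10,000–30,000.  The **desk** preset — used by the test-suite and
the acceptance script — scales down to a 200×200 lattice, radius 25,
runs of 6,000–12,000 MCS, and 2–3 seeds per condition, so that a full
acceptance pass fits interactive budgets on one CPU.  At this scale the
absolute sprouting statistics shrink with the shortened observation
window (mean tip tenures, for instance, are truncated by run length),
so the desk-scale checks target the published *contrasts* — the
elongation model overtakes more and disperses faster than the contact
model; WT cells out-differentiate and out-occupy *Vegfr2*⁺/⁻ cells;
occupancy falls as WT cells are diluted — together with
order-of-magnitude agreement of rates and dispersion coefficients.
Desk-scale passes therefore support the mechanisms, not the exact
full-scale means; they also inherit everything the model itself
abstracts away (no cell division or death, 2D geometry, uniform
external VEGF, chemoattraction standing in for whatever short-range
attraction operates in vivo).

## Known limitations

- The local connectivity test can veto rare copies a global test would
  allow; with the penalty enabled cells never fragment, which is the
  intended invariant.
- Euler integration of the signaling ODEs is first-order; the test
  suite verifies the error halves with the step and stays ~10⁻² of the
  level scale at Δt = 3 s.
- Occupancy statistics at desk scale rest on tens of sprout–frame
  draws; percentages carry sampling errors of order ±10 points.
- The skeleton graph of a near-circular young spheroid is noisy;
  transient ends inflate the sprout census early in a run, which is why
  occupancy and axis statistics require 80-MCS sprout persistence.
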