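# Methods

`bzdna` analyses the conformational dynamics of DNA duplexes carrying an
A…A mismatch, the system in which a local B–Z junction can form at the
non-canonical pair. The package covers four linked analyses — backbone
substate calling, hydrogen-bond scheme lifetime profiling, transient-event
metrics, and 2D periodic WHAM over the two glycosyl torsions — together
with a synthetic-data layer that generates trajectories and biased samples
with known ground truth. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic fixtures do and do
not establish about real simulation data.

## Coordinate conventions

All angles are degrees in [0, 360); signed differences are taken with the
minimal periodic image, in (−180, 180]. Torsions follow the IUPAC sign
convention (cis = 0, positive clockwise viewed along the central bond);
the implementation is cross-checked in the test suite against an
independent plane-normal construction to 1e-9 degrees. Distances are in
Å, energies in kcal/mol, with k_B = 1.9872041e-3 kcal mol⁻¹ K⁻¹.
Residues are indexed 1-based per chain; strand b of a duplex is numbered
5′→3′ in its own direction, so strand-a residue i pairs strand-b residue
n+1−i in an n-mer.

## Backbone substates and glycosyl classes

Backbone torsions are computed per residue (α: O3′(i−1)-P-O5′-C5′;
γ: O5′-C5′-C4′-C3′; ε: C4′-C3′-O3′-P(i+1); ζ: C3′-O3′-P(i+1)-O5′(i+1);
χ: O4′-C1′-N9-C4 for purines, O4′-C1′-N1-C2 for pyrimidines). Terminal
residues lack α (5′ end) or ε/ζ (3′ end); these are reported as absent,
never zero. Each base step i→i+1 is assigned a rotamer-well quadruple
(ε_i, ζ_i, α_{i+1}, γ_{i+1}) and labeled:

    BI  = (t,  g−, g−, g+)    BII = (g−, t,  g−, g+)
    BIII= (g−, g−, g−, g+)    ZI  = (g−, g+, g+, t)

with every other quadruple labeled `other`. The literature defines these
substates by well names without numeric edges; we use the equal
tripartition g+ = [0°, 120°), t = [120°, 240°), g− = [240°, 360°),
centered on the canonical +60/180/−60 rotamers. The edges are module
constants and can be overridden.

Glycosyl classes are +syn = [20°, 100°), anti = [170°, 270°),
−syn = [270°, 340°), `other` elsewhere. The +syn windows match the
favored-region bounds used for the free-energy map; the anti/−syn split
at 270° inside the broad 190–340° region is a declared choice (the
region's two sub-minima are not numerically delimited in the source
analysis) and is configurable.

Sugar pucker uses the Altona–Sundaralingam pseudorotation: with ring
torsions ν0…ν4 of C4′-O4′-C1′-C2′-C3′,
tan P = [(ν4+ν1) − (ν3+ν0)] / [2ν2(sin 36° + sin 72°)], amplitude
τ_m = ν2 / cos P. South (C2′-endo, B-like) is P ∈ [126°, 198°), North
(C3′-endo, A/Z-like) P ∈ [342°, 360°) ∪ [0°, 54°). A planar ring
(τ_m < 1e-6°) raises an error rather than returning an arbitrary phase.

## Hydrogen-bond schemes and lifetimes

An A…A mismatch can pair through six directional donor…acceptor schemes
(N1…N6, N6…N1, N3…N6, N6…N3, N7…N6, N6…N7; the first atom is the ring
acceptor on adenine a, the N6 amine donates). Assignment is by distance
only: the minimum distance at or below 3.5 Å wins (ties broken by the
fixed scheme order above); if every distance exceeds 4.0 Å the frame is
`none` and counts toward the non-hydrogen-bonded density maps; minima in
the 3.5–4.0 Å gap are `none` but flagged borderline and excluded from
those maps. This reconciles the canonical 2.5–3.5 Å hydrogen-bond range
with the >4 Å non-bonded plotting rule; both cutoffs are arguments. An
optional donor–H–acceptor angle filter is deliberately absent by default
because the analysed structures carry no explicit hydrogens.

Lifetime profiles decompose a per-frame scheme timeline into maximal
runs; the mean lifetime of a scheme is its mean run length and its
occupancy the fraction of frames. No smoothing or minimum-run filter is
applied. On Markov-generated timelines with self-transition probability
p, the estimator recovers the geometric mean lifetime 1/(1−p) within
three standard errors at 1e5 frames (tested).

Canonical pairs are monitored through their Watson–Crick donor…acceptor
sets (G…C: O6…N4, N1…N3, N2…O2; A…T: N6…O4, N1…N3); a pair is broken
(open) when any distance exceeds 3.5 Å.

## Event metrics

The transient events named from trajectory inspection — base flipping,
extrusion into a groove, stacking, pair opening — have no standard
quantitative definitions, so all thresholds here are declared package
defaults, surfaced as arguments:

- **Flip pseudo-dihedral**: (5′-flanking pair centroid) – P – C1′ –
  (base-ring centroid); flipped when it deviates more than 90° from the
  closed-state reference value (by default the trajectory's first frame).
- **Extrusion**: with a closed-state reference frame, the displacement of
  the base centroid from its reference position projected on the
  major-groove direction of the flanking pairs (+ = major, − = minor), so
  a d-Å push into a groove reads ±d. Without a reference, the radial
  excess of the centroid over the flanking-pair base radius about the
  local helix axis, signed by groove half-space. The two definitions
  agree on sign; the projected form is preferred because a groove-ward
  displacement near the helix axis barely changes the radius. Extruded at
  |value| > 2.0 Å.
- **Stacking**: ring-centroid distance ≤ 4.5 Å and interplanar angle
  ≤ 30° (SVD plane normals).
- **Minor-groove width**: cross-strand P(i)…P(j−3) distances (the
  classical three-level stagger) minus a 5.8 Å phosphate-radius
  correction; on the idealized fixture this yields ≈ 5.9 Å, the canonical
  B-DNA minor groove.

The local helix axis is a least-squares line through up to four flanking
base-pair centroids rather than a global axis, because junction-distorted
duplexes are bent. All metrics are rigid-motion invariant (tested).

## Umbrella sampling and 2D periodic WHAM

Windows are the Cartesian product of restraint centers
{0°, Δ, …, 360°−Δ}² — 36 × 36 = 1296 windows at the default Δ = 10° —
with harmonic periodic bias U = ½k[d_p(χ_a−c_a)² + d_p(χ_b−c_b)²], d_p
the minimal image in radians and k = 100 kcal mol⁻¹ rad⁻² by default.
The coupled WHAM equations

    P(x) ∝ Σ_j n_j(x) / Σ_j N_j exp[(F_j − U_j(x)) / k_B T]
    exp(−F_j/k_B T) = Σ_x P(x) exp(−U_j(x)/k_B T)

are iterated on the window constants F_j until max|ΔF_j| < 1e-6 kcal/mol
(at most 1e5 iterations; non-convergence raises with the last residual).
The PMF is −k_B T ln P on a 72 × 72 grid (5° bins — finer than the window
spacing, coarse enough for 2500-sample windows), min-normalized over
sampled bins; unsampled bins are masked, never imputed. Numerical notes:

- Bias Boltzmann factors are held in a sparse matrix; entries with
  U > 50 k_B T are truncated to zero (for k = 100 the retained support is
  roughly ±45° per window, ~3% of the grid), keeping each iteration at
  two sparse mat-vecs.
- The iteration is the standard self-consistent (EM-like) update; an
  optional per-iteration check verifies the WHAM negative log-likelihood
  never increases (property-tested).
- The solution is gauge-fixed on the first populated window; the
  normalized PMF is invariant to the gauge choice (tested).
- With a single unbiased window the solution reduces exactly to
  −k_B T ln(histogram); a 2:1 bin ratio gives k_B T ln 2 = 0.4132
  kcal/mol at 300 K (tested to 1e-9).

Block errors follow the time-block protocol: the retained production
samples of every window are split into five equal consecutive blocks
(emulating 0.5-ns blocks of a 3-ns run) or three cumulative blocks; one
PMF is solved per block, each min-normalized (a common-gauge variant is
available by flag), and the per-bin standard deviation across blocks is
reported over bins sampled in all blocks.

Basins are connected components (8-neighbor, periodic wrap) of bins with
PMF ≤ 3 kcal/mol, labeled B1, B2, … by increasing minimum. Two barrier
notions are provided deliberately:

- `barrier_between`: the minimax path value between two basin minima over
  sampled bins (priority-first search), minus the higher minimum. This is
  the reachability barrier; on a multi-basin surface the optimal path
  between a diagonal pair of minima is an L-route through an intermediate
  basin, so minimax barriers of diagonal pairs cannot strictly exceed
  every adjacent barrier — a geometric fact, not a sampling artifact.
- `line_barrier` / `classify_transitions`: the maximum of the surface
  along the straight periodic segment between two minima, minus the
  higher endpoint. This is the direct-transition barrier that makes the
  favorable horizontal/vertical vs unfavorable diagonal distinction
  well-posed, and it is what the transition-topology checks use.

## Synthetic data: what it emulates, and what it does not

**Analytic surface.** G(χ_a, χ_b) = −k_B T ln Σ_m w_m exp(−[d_p(χ_a,μ_a)²
+ d_p(χ_b,μ_b)²]/2σ_m²), periodic by construction. The default spec
plants four basins at (60°, 240°) [+syn…anti, I], (240°, 240°)
[anti…anti, II], (60°, 60°) [+syn…+syn, III] and (240°, 60°)
[anti…+syn, IV] with σ = 22° and depths 0 / 0.9 / 1.4 / 0.25 kcal/mol
(w_m = e^{−depth/k_B T}, T = 300 K). These values are a modeling choice
fixed at design time so that (i) all four minima lie below the 3 kcal/mol
contour, (ii) the inter-basin saddles sit near 4–4.3 kcal/mol, so the
3 kcal/mol contour yields exactly four components, and (iii) direct
diagonal transitions cross a higher ridge (8–9 kcal/mol through the grid
center) than horizontal/vertical ones — reproducing the allowed/forbidden
transition topology by construction, not as an energetics claim about
real mismatched DNA. Exact minima and barriers are computable on a dense
grid and serve as the oracle for the WHAM recovery tests.

**Biased sampler.** Per-window Metropolis chains target
exp(−[G + U_bias]/k_B T). Step size starts at 5° and is auto-tuned during
burn-in (10% of the chain) to 30–60% acceptance; ten proposal moves are
made per retained sample, mirroring the MD practice of writing frames
every ~1 ps while integrating at 2 fs, so retained frames are effectively
decorrelated under the restraint (the restrained sample std is ~4.4° at
k = 100; the per-retained-frame random-walk displacement is ~11°). All
1296 chains advance in lockstep as one vectorized update, which makes the
full protocol — 3000 production frames per window, last 2500 retained —
run in well under a minute on one core. Under a stiff restraint
(k = 1e4) the sample std matches the Gaussian limit √(k_B T/k) within
10%, and an unbiased chain on a flat surface passes a χ² uniformity test
(both tested).

**Markov timelines and scripted trajectories.** Scheme timelines are
seeded Markov chains over the six schemes plus `none`. Geometric events
are rigid-body base transformations on the fiber duplex (flip: 180°
rotation about an in-plane axis through C1′; extrusion: translation along
±groove direction; opening: translation away from the partner; stacking:
translation over the 5′ neighbour), ramped in and out over two frames,
with a ground-truth sidecar of event frame ranges. Detection tests demand
agreement with the script to ±2 boundary frames and zero false positives
on unperturbed segments.

**Fiber duplex.** Bases are placed from standard planar base-pair
reference-frame templates propagated by rise 3.38 Å / twist 36° (the
strand-b partner is the 180°-about-x flip); each residue's
sugar-phosphate backbone is then grown from its base by internal
coordinates. The internal-coordinate constants (substituent torsion
offsets, a small helix x-displacement of −0.39 Å) were calibrated once,
by bounded least squares against the builder's design targets — ε/ζ/α/γ
in the BI wells (191°/252°/297°/76°), χ = 241° (anti), pseudorotation
P = 162° (C2′-endo), O3′(i)–P(i+1) = 1.60 Å, ring closure 1.45 Å — and
frozen. The resulting duplex classifies 100% BI on both strands, keeps
every Watson–Crick donor…acceptor distance in 2.87–3.05 Å, and shows a
5.9 Å corrected minor groove. A substituted (mismatch) base is re-anchored
on the displaced pyrimidine's glycosyl bond so the backbone is shared, and
its χ can be posed exactly by rigid rotation about C1′–N9. The builder is
a fixture generator: bond geometry is idealized, no refinement is done,
and its accuracy claim extends only to the class-level properties above.

**What passing tests do not show.** The synthetic layer has no force
field, solvent, sequence-dependent energetics, correlated backbone/base
motion, or bias-coordinate coupling beyond the two glycosyl angles.
Passing the WHAM recovery and block-error checks therefore demonstrates
the correctness of the estimators on data with the stated statistical
structure — not that a 3 ns restrained MD window equilibrates, nor that
the real mismatch surface has the planted topology.

## Problem sizes

The acceptance script and the end-to-end acceptance tests run the full
window protocol: 1296 windows, 3000 production frames each, last 2500
retained, five 500-frame blocks, 72 × 72 WHAM bins. Unit tests use
coarser grids (30–120° spacing) and shorter chains chosen for sub-second
execution of each case.

## Known limitations

- The fiber builder supports a single helical symmetry per build; bent or
  mixed B/Z starting models must come from outside.
- Scheme assignment is distance-only; bifurcated double hydrogen bonds
  are reported as the minimum-distance scheme with the competing schemes
  listed in a diagnostics column.
- The flip and extrusion metrics need intact flanking pairs; they are
  undefined (None) at terminal-adjacent residues.
- Minimax barriers refuse to cross unsampled bins and report infinity for
  disconnected basins instead of extrapolating.
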