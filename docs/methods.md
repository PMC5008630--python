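# Methods

## The coarse-grained pore model

The model reduces the pore domain of a four-fold Na_v channel to the
beads that matter for selectivity at the constriction site:

* **Backbone scaffold.** Two fixed anchor beads per chain (residues 180
  and 183) at radius 6 Å define the pore geometry and the filter center.
* **Inner ring (residue 180).** The DEKA/DERA motif is distributed over
  the chains as A = Glu180, B = Asp180, C = the cationic residue,
  D = Ala180, so the cationic side chain faces Glu180 across the pore and
  has the outer-ring glutamates of chains D and A as nearest neighbours.
  Carboxylates are oxygen pairs (−0.5 e each) tethered near radius 3.5 Å;
  Ala is a neutral placeholder bead; the wild type carries neutral Ser
  hydroxyl oxygens.
* **Cationic side chain.** Lys is a single amino-nitrogen bead on a
  freely swinging harmonic arm (length 5 Å, k = 2 kcal/mol/Å²) anchored
  at the backbone, so it can protrude to the pore axis — a minimal
  rendering of the long, flexible Lys side chain.  Arg is a planar triad
  of three sites (default +1/3 e each) held by stiffer tethers near the
  outer-ring wall between chains D and A, encoding the experimentally
  motivated preference of the guanidine group for the acidic outer ring;
  the e* variant concentrates 0.9 e on one site, and the 0.5e/0.05e
  variants scale the Lys charge.  Group charges per variant are enforced
  exactly (+1, +0.5, +0.05, +1 redistributed).
* **Solvent.** Neutral water-oxygen beads (σ = 3.1 Å, ε = 0.25 kcal/mol)
  confined by soft z-walls; they exist to compete with protein oxygens
  for the ion's first shell, not to be realistic water.
* **Ions.** Na⁺ and K⁺ are +1 beads whose Lennard-Jones radii are
  calibrated so that ion–oxygen contact distances land inside the
  quantum-chemistry coordinating ranges used by the coordination
  analysis: Na–O ≈ 2.5 Å (< 2.69 Å cutoff) and K–O ≈ 3.0 Å (< 3.22 Å).
  This calibration is the load-bearing choice of the model: it makes the
  smaller ion's carboxylate contacts ~1 kcal/mol per oxygen more
  favourable electrostatically, which is the physical origin of
  Na⁺-selectivity at a multi-carboxylate site, and it keeps the
  geometric coordination counts meaningful.

## The toy Hamiltonian

U = Coulomb + Lennard-Jones + tethers + z-walls + flat-bottom restraints,
with Coulomb = 332.06·q_iq_j/(ε_r·r_ij) under a uniform relative
dielectric ε_r = 10 (a single scalar that screens like a semi-aqueous
pore and keeps FEP legs comparable; configurable).  Minimum-image
periodicity applies in x and y only; z is bounded by soft harmonic walls
(membrane mimic — no pressure coupling, fixed box).  Lorentz–Berthelot
mixing; nonbonded interactions are excluded within a residue; a single
cutoff (half the lateral box length by default) truncates both nonbonded
terms.  Tethers are U = ½k(|x−a|−L)², giving point anchors (L = 0) or
swing arms (L > 0).

## Dynamics

Overdamped (position-)Langevin integration,
dx = F·dt/γ + √(2kT·dt/γ)·ξ, with γ = 2 ps⁻¹ and dt = 10 fs by default
at 310 K (kT = 0.6160 kcal/mol).  No momenta are propagated — only
configurational statistics are needed.  Per-atom forces are capped at
500 kcal/mol/Å to keep rare steep LJ contacts from destabilising the
Euler–Maruyama step; the cap engages only far from equilibrium and does
not bias equilibrium sampling in practice (the double-well occupancy
test verifies Boltzmann statistics end-to-end).  Trajectories are
bit-reproducible for a fixed (topology, protocol, seed).

## State model

Open/closed classification follows the (R, Z) descriptors of the
side-chain reporter: a soft-margin linear SVM (C = 10, raw Å units so
the boundary stays in physical units) gives the separator; each class's
95% region is bounded by the line parallel to the separator at the
class's 95% signed-distance quantile.  For separable data the two lines
leave an unassigned band between them (at level 1.0 the band is exactly
the max-margin band); for overlapping classes the lines can cross the
separator and frames claimed by both regions resolve by separator sign.
Because each region deliberately excludes ~5% of its own state, state
*populations* are reported over assigned frames.  How the original
analysis built its 95% regions from the SVM line is not stated in the
source; parallel-offset quantile lines are this package's
interpretation.

## Binding analysis

Sites are axial slabs relative to the per-frame filter center (the mean
of the four residue-180 backbone anchors; per-frame recomputation means
scaffold drift cannot masquerade as ion motion).  Site_OC, the outer
constriction site where the cation contacts the inner-ring carboxylates,
defaults to |Z| ≤ 2 Å, R ≤ 4 Å on the bundled geometry; all boundaries
are configuration values because the source defines the sites
structurally, not numerically.  Free-energy maps use 0.5 Å bins and
−kT·ln(count/count_max), with empty bins held at a 6 kcal/mol display
cap.  Binding modes are found by average-linkage hierarchical clustering
of per-frame distance vectors (ion → each residue-180 side-chain O/N
atom, fixed order) cut at 1.5 Å, over the final 75% of frames; clusters
rank by size (ties by first occurrence), the top two are the "main"
modes, and modes under 5% occupancy are flagged too small for FEP — the
clustering algorithm and cutoffs are this package's choices, as the
source names none.

## Coordination and hydrogen bonds

An oxygen coordinates the ion when its distance is at most the
species cutoff: 2.69 Å (Na⁺) and 3.22 Å (K⁺), the half-even-rounded
means of the quantum-chemical coordinating ranges 2.39–2.99 Å and
2.80–3.65 Å.  Counting is purely geometric and reported by oxygen role
(carboxylate / other protein / water); the chemical maxima (6 for Na⁺,
8 for K⁺) are properties of the ion, not caps on the count.  A binding
mode is "tightly coordinated" when its mean carboxylate count rounds
(half-up) to ≥ 3.  Hydrogen bonds use a heavy-atom donor–acceptor
distance ≤ 3.5 Å — the coarse model has no hydrogens, so no angle term
by default — and a frame is "bifurcate" when one donor group
simultaneously contacts acceptors from two residues.

## Free-energy perturbation

Na⁺→K⁺ interpolates only the ion's LJ parameters, σ(λ) and ε(λ) linear
in λ, charge fixed at +1 — no site appears or vanishes, so no soft core
is needed.  Default schedule: 21 equally spaced windows, 10 ps
equilibration + 40 ps production per window, samples every 100 fs.
Per-interval ΔG uses BAR solved self-consistently by bisection (Fermi
log-sums for stability), with exponential averaging as fallback when one
direction has no samples; per-window effective sample sizes below 10
attach convergence warnings.  The ion is held by a flat-bottom restraint
(zero within 1.5 Å of the mode's restraint center, harmonic wall
k = 10 kcal/mol/Å² outside), applied identically in the bound leg (pore,
restrained at the mode center from clustering) and the bulk leg (ion in
a small water-bead box), so restraint contributions cancel in
ΔΔG = ΔG_bound − ΔG_bulk.  Positive ΔΔG means Na⁺ preference.  Repeats
differ only by seed; three repeats give mean ± sample SD.  The original
FEP protocol details (λ schedule, window lengths, restraint constants)
are not in the available text; all values here are package defaults and
config-visible.

## Synthetic data: what it emulates and what it does not

Brownian-dynamics trajectories of the bead model emulate the statistical
structure of the original equilibrium simulations — ion residence at
discrete axial sites, competing carboxylate/water coordination, a
flexible centrally-protruding Lys versus a wall-bound Arg — at nanosecond
scale and bead resolution.  They do not emulate atomistic energetics,
explicit water structure, membrane lipids, or protein conformational
gating, so passing tests demonstrate the correctness and internal
consistency of the *analysis machinery* and the qualitative mechanism on
the model, not quantitative agreement with atomistic simulation: printed
atomistic ΔΔG magnitudes and occupancy percentages are explicitly out of
numeric scope.  Planted fixtures (labelled Gaussian state populations,
planted binding-mode geometries, analytic harmonic alchemies, a planted
double well) provide exact or quadrature-grade oracles for each analysis
stage.

## Problem sizes and numerical choices

Default runs sample 40 000 BD steps (0.4 ns) for trajectories, 10⁶
samples for Boltzmann-inversion recovery, 10⁶ steps for the double-well
occupancy check, and triplicate FEP with the window settings above —
sizes chosen so each oracle's statistical error sits well below its
acceptance band on a single CPU.  Ties: frames on a region boundary
classify open; cluster rank ties break by first occurrence; the mode
representative is the member nearest the centroid.  Degenerate inputs
(empty selections, single-class training data, inverted site intervals,
non-positive-definite covariances, duplicate repeat seeds) raise typed
errors rather than propagating silently.

## Known limitations

The DERA wall-anchored guanidine encodes the *outcome* of the bifurcate
outer-ring interaction rather than discovering it; the charge-variant
topologies (0.5e, 0.05e, e*) alter charges only, not geometry relaxation;
the bulk FEP leg uses a small droplet-like water box whose finite size
enters both legs' reference equally but is not a converged hydration
free energy; and BAR variance is reported per window but not propagated
into a rigorous leg-level error bar (repeat SD serves that role).
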