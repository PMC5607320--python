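# Methods

## The coarse-grained model

Each residue is a bead at its native Cα position. The potential energy is

    E_p = V_BB + V_NAT + V_NON + V_CHIR + V_MEMBR

* **Backbone** `V_BB = Σ k_BB (r_{i,i+1} − d0)²` with k_BB = 33.34 ε/Å² and
  d0 = 3.8 Å.
* **Native contacts** are residue pairs (j − i ≥ 2) with at least one
  heavy-atom pair closer than 1.244 × the sum of their van-der-Waals radii
  in the native structure (bundled element-level Tsai-style radii,
  overridable). Each contact contributes a Lennard-Jones term
  `4ε[(σ_ij/r)¹² − (σ_ij/r)⁶]` with σ_ij equal to the native Cα–Cα
  distance, so every contact has zero energy in the native state and its
  minimum slightly outside it (no 2^(−1/6) rescaling).
* **Non-native pairs** (j − i ≥ 2, not native) feel a purely repulsive,
  truncated and shifted LJ with σ0 = 5 Å and cut-off d_cut = 5.61 Å.
* **Chirality**: `V_CHIR = Σ k_CHIR C_i² Θ(−C_i C_i^NAT)` with
  C_i = ((v_{i−1}×v_i)·v_{i+1})/d0³ over the virtual bonds; the step
  function Θ is the standard Heaviside (1 for positive argument, else 0),
  so the term only penalizes a chirality whose sign opposes the native
  one. A literal alternative convention in which Θ returns −1 for
  non-positive arguments — which *rewards* matching chirality with negative
  energy and destabilizes straight segments — is preserved behind
  `chirality_theta="literal"` for sensitivity checks, but is not the
  default because it contradicts the established structure-based-model
  form.
* **Membrane**: an implicit slab z ∈ [z_min, z_max] (defaults −17.034 and
  15.896 Å) with 3 Å linear ramps. Hydrophobic residues flagged as
  membrane-contacting pay 0 inside the slab, a linear ramp up to ε_membr
  outside; hydrophilic contact residues feel the same profile times −1.
  The flags are assigned once, on the native structure: hydrophobicity by
  a positive Kyte–Doolittle index, membrane contact by the native Cα z
  lying within the ramp-extended slab. Residues outside the native contact
  set never feel the membrane, even if they enter the slab later — the
  assignment is a property of the native embedding, not of the
  instantaneous configuration. ε_membr is the model's single free
  parameter (hydrophobicity/cholesterol proxy; study values 4.03, 5.64,
  7.25, 10 ε).

Forces are analytic; at the ramp corners of the membrane term the
one-sided derivative from inside the ramp is used (the potential is
continuous, so the impulse error is bounded by the timestep). A fused
numba kernel evaluates everything; an independent numpy implementation of
each term backs the public per-term API, and a test pins the two paths
against each other.

## Dynamics and units

The Langevin equation `m r̈ = −γ ṙ + F_c + √(2γ k_B T) ξ` is integrated
with the Grønbech-Jensen/Farago (GJF) velocity-Verlet discretisation,
which reduces exactly to velocity Verlet at γ = 0 and samples
configurations without a leading-order timestep bias; measured kinetic
energy per degree of freedom at k_BT = 0.52 ε is 0.260 ± 0.002 ε.

Internally the system of units is reduced — energy ε, length Å, bead mass
m = 1 — with one time unit τ. User-facing parameters are accepted in
femtoseconds (dt = 15 fs, γ = 8.14·10⁻⁴ fs⁻¹, v_pull = 2.035·10⁻⁶ Å/fs)
and mapped through a single constant `fs_per_tau` (default 3000 fs,
i.e. τ ≈ 3 ps, the conventional Gō-model time unit for which these fs
values are mutually stable). Every per-step quantity the model pins down —
γ·dt = 0.0122, v_pull·dt = 3.05·10⁻⁵ Å — is independent of that constant.

Pulling attaches a harmonic spring (default k_pull = 0.2 ε/Å², chosen soft
enough to resolve individual ruptures and echoed in every output) to the
C-terminal bead; the anchor moves along +z at constant speed while the
N-terminal bead is held fixed. Recorded force is k_pull × (anchor −
bead z). The non-native pair list is a cell-list-backed neighbor list with
a 2.5 Å skin rebuilt every 100 steps; Gaussian impulses are drawn in
chunks from a seeded `numpy.random.Generator`, making every trajectory
bit-reproducible for a fixed seed.

**Scaled pulling.** At the reference speed a full unfolding takes ~4·10⁷
steps per replica. Scaled runs multiply the speed by S and divide γ by the
same S, which leaves the friction-force baseline (∝ γ·v) of the moving
unfolded segment exactly at its reference value; only the loading rate
relative to thermal barrier crossing increases, raising rupture forces
mildly (logarithmically) without reordering them. The bundled sweep and
test protocols use S = 150.

## Observables

* **Q** — the fraction of intact native contacts with sequence separation
  ≥ 3, a contact counting as intact while r < 1.5 σ_ij. Separation-2
  contacts are excluded from Q (and from the unfolded-stretch count)
  because 1.5 σ exceeds their distance even on a taut backbone, so they
  can never break and would put a floor under both quantities.
* **Unfolding temperature** — equilibrium Q, averaged over the last half
  of each run and over replicas per temperature, interpolated to its first
  downward crossing of 0.5.
* **Events** — force maxima on the lightly smoothed trace followed by a
  drop of more than 30% of the peak height, with prominence above 3× the
  local thermal force scale (median absolute difference / 0.6745); "major"
  events additionally exceed a 1.0 ε/Å floor. Each event carries n, the
  number of residues in the contiguous stretch from the pulled terminus
  whose breakable native contacts are all broken at the post-drop minimum.

## The SMFS pipeline

The worm-like chain enters through the Marko–Siggia interpolation
F = (k_BT/p)[¼(1−x/Lc)⁻² − ¼ + x/Lc] with p = 0.4 nm and k_BT =
4.114 pN·nm (25 °C). The inversion to contour length solves the cubic
monotonically by vectorized bisection (80 iterations, well below 0.1 nm
error). Per curve, all samples above a 10 pN floor are inverted and
accumulated, force-weighted, into an Lc histogram.

Rupture peaks are found on a Savitzky–Golay-smoothed trace (window 7,
order 2; height 20 pN, prominence 25 pN defaults) and each rising edge is
least-squares fitted over Lc with the bounded scalar minimizer; the peak
force is the raw-trace maximum near the smoothed peak. Filtering keeps
curves whose peaks all exceed 35 pN and whose final peak falls in a
configurable Lc window (≤ 200 nm for rhodopsin-style selections; the
200–300 nm window for CNG-state analyses, matching how those curves were
selected experimentally).

Clustering compares unit-mass Lc histograms on a dedicated grid (3 nm
bins by default, independent of the statistics bin width) by the best
shifted overlap Σ min(h_i, h_j); because each curve's attachment offset
can be up to 5 nm in either direction, the pairwise shift search spans
±10 nm. Average-linkage clustering is cut at distance 0.6 (1 − overlap).
Within a cluster, each member is aligned to the cluster medoid by its best
shift, the shifts re-centered to zero mean (so the cluster frame is not
biased by the medoid's own offset), and the aligned peak positions pooled.
Peak groups are the modes of a Gaussian kernel density over the pooled
positions (bandwidth = tolerance/3 with tolerance 6 nm); each peak joins
its nearest mode. Occurrence is the fraction of member curves contributing
to a group; groups below a 10% occurrence floor are dropped from reports.

Residue conversion divides Lc by a stretched length per residue: 0.4
nm/a.a. by convention, 0.36 nm/a.a. in rhodopsin-facing configurations
(348 residues ↔ 125 nm); both appear in output headers.

## Synthetic data

**Curves.** A template lists peak contour lengths with per-peak scatter,
occurrence probabilities, and rupture-force mean ± SD. Per curve, each
peak is included by an independent Bernoulli draw; rupture forces are
Gaussians truncated below at 35 pN (the filter threshold, so the filter
boundary is exercised); the force follows the WLC toward each included
peak and drops to baseline after rupture (published traces relax
essentially completely between peaks); Gaussian noise of 10 pN, a slow
linear baseline drift (±3 pN full scale), and a uniform ±5 nm attachment
offset are added; sampling step 0.5 nm. The bundled templates carry the
published per-peak statistics for the CNG subunit (closed/open) and for
rhodopsin pulled from the disc (N- and C-terminal) and plasma membranes;
where only a dataset-level force SD was published it is reused for every
peak of that template. What the generator does *not* emulate: correlated
1/f instrument noise, partial relaxation between peaks, multiple molecules
in one curve, and tip-chemistry-dependent detachment — so passing
recovery tests shows the pipeline handles the idealized statistical
structure, not every artifact of real recordings.

**Structure.** `seven_tm_bundle` builds a synthetic 348-residue,
seven-helix membrane protein: ideal helices (rise 1.5 Å, radius 2.3 Å,
100°/residue) on a ring of radius 10.2 Å with alternating direction and
one helix drawn 3.5 Å toward the core (the central-helix packing motif of
GPCR folds); loops are circular arcs with exact 3.8 Å spacing; terminal
tails are surface-lying helices; side chains are represented by Cβ and,
for bulky residues, a Cγ pseudo-atom, giving a realistic heavy-atom
contact density. Sequence hydrophobicity follows the architecture
(Kyte–Doolittle-hydrophobic cores with a minority of polar positions,
polar loops/tails). It is a stand-in for method validation — its melting
temperature and unfolding pathway are properties of this synthetic fold,
not of rhodopsin's.

**Ensembles.** `generate_ensemble` draws the inter-helix angle α from a
truncated Gaussian on [0, π] (mode 2.72 rad, SD 0.20 rad) and couples the
hydrophobic transmembrane SASA concavely (peak 2600 Å², curvature
900 Å²/rad², noise 40 Å²) and the hydrophilic SASA convexly to α, so the
most probable conformation exposes the most hydrophobic and least
hydrophilic area — the qualitative structure the reweighting analysis
assumes.

## Reweighting

Frame weights are w ∝ exp(κ(c)·(A_HPHOB − A_ref)) with κ(c) ≥ 0 a
β-scaled transfer free-energy coefficient per Å², zero at c = 0 and
monotone in c, supplied as a table (the bundled example table is
synthetic/illustrative, not measured partition data). Weights are
normalized with a max-shift before exponentiation. The state split
defaults to α < 2.6 rad for the active-like (metarhodopsin-II-like) state
— the side with lower hydrophobic exposure — and the population ratio is
reported normalized to its c = 0 value, which is exactly 1 by
construction.

SASA uses the Shrake–Rupley algorithm with a 1.4 Å probe and 960
golden-spiral sphere points per atom, with the same radii table as the
contact map; tests verify it against an independent dense Monte-Carlo
surface estimate within 2%.

## Problem sizes and checks

The test suite runs every simulation at scaled sizes chosen to probe the
claimed behavior rather than reproduce production trajectories: melting
scans use 6 temperatures × 2 replicas × 6·10⁴ steps; the membrane-strength
sweep uses 10 replicas at each of ε_membr ∈ {4.03, 5.64, 7.25, 10} ε at
speed factor 150 over 1350 Å of displacement; pipeline-recovery checks use
200-curve datasets. On the synthetic bundle the melting scan places the
Q = 0.5 crossing near 0.57 ε; the working temperature 0.52 ε sits below
it, as it should for a marginally stable membrane fold. The checked band
for the scaled scan is 0.65 ± 0.15 ε.

## Known limitations

* The implicit membrane has no lateral structure, no lipid particles and
  no deformable hole; the slab acts on natively-flagged residues only.
* Simulated forces are in reduced units (ε/Å); no pN conversion is
  applied unless the user supplies a factor, since the energy scale ε is
  not fixed in physical units by the model itself.
* The synthetic bundle's unfolding pathway is more symmetric than a real
  receptor's: its helices rupture at similar forces, so event counts at a
  given ε_membr need not match those of any particular protein.
* Peak detection below ~12 nm contour length is biased by the noise floor
  and the attachment offset; the first peak of short-Lc pathways is
  recovered with a positive bias of a few nm.
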