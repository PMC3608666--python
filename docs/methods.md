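# Methods

This note records the models, conventions and numerical choices behind
`idpmech`, in the order the pipeline runs them.  Units are Å for
coordinates and ps for time throughout; frames are 0-indexed and residue
numbering is kept verbatim from the input (no renumbering).

## Structural model and primitives

A `SystemModel` holds a two-chain topology (atoms, residues, masses,
physico-chemical residue classes) with reference coordinates; an
`Ensemble` stacks frames with strictly increasing timestamps.  Residue
classes: hydrophobic = {ALA, VAL, LEU, ILE, PRO, MET, PHE, TRP, CYS},
positive = {ARG, LYS, HIS}, negative = {ASP, GLU}, everything else
"other".  PDB input goes through Biopython; hydrogens, waters and
heteroatoms are dropped, and for disordered atoms the highest-occupancy
conformer is kept.

Superposition is a Kabsch least-squares fit with the reflection
sign-corrected away (det = +1 always).  Pairwise RMSD matrices use a
batched SVD closed form; because that form cancels catastrophically near
zero, entries below 10⁻⁴ Å are recomputed with the explicit fit (this is
what makes "identical frames → RMSD 0" hold to machine precision).
RMSF superposes all frames first onto frame 0 and then twice onto the
refined mean structure; the initial frame-0 alignment is what makes the
result exactly invariant under rigid motions of the whole ensemble.

## Contacts and Q kinetics

* Generic contact: minimum side-chain heavy-atom distance < 6.5 Å
  (strict), glycine represented by its Cα.  Intra-chain pairs need a
  sequence separation ≥ 2; all inter-chain pairs are eligible.  Pairs of
  two hydrophobic residues are typed "hydrophobic".
* Electrostatic contact: oppositely charged residues whose side-chain
  charge-group centres of mass (ARG: NE/CZ/NH1/NH2, LYS: NZ, HIS:
  ND1/NE2, ASP: OD1/OD2/CG, GLU: OE1/OE2/CD) lie within 11 Å.  Reduced
  models without these atoms fall back to all side-chain heavy atoms.
* Hydrogen bond: donor–acceptor heavy atoms < 3.5 Å and
  antecedent–donor–acceptor angle > 120°, a standard geometric
  definition.
* The native contact set is the generic rule evaluated on the reference
  structure, split into tertiary (intra-chain) and binding (inter-chain)
  scopes.  Qf/Qb are the per-frame fractions of native
  tertiary/binding contacts still satisfied.  A state with zero native
  contacts of a scope yields an undefined series, never 0/0.
  Qf pools the tertiary contacts of both chains by default; a `chain`
  argument restricts it when per-chain unfolding is wanted.

Kinetics are fitted in log space — ordinary least squares of ln Q on t —
because the single-exponential model is linear there and the slope
covariance gives closed-form errors; t½ = ln 2/k and
se(t½) = ln 2·se(k)/k².  The default window is the first 80 % of the
series; the drivers instead cut the window where the replica-mean Q drops
below 0.1, because beneath roughly one decade of decay the per-contact
counting floor (1/N contacts) biases the log fit.  Fits with k ≤ 0 are
flagged non-decaying rather than reported as half-times.

## Transition state and Φ

The Sammon map minimises E = (Σd\*)⁻¹ Σ (d\* − d)²/d\* over 2-D point
positions.  Initialisation is classical (Torgerson) metric scaling —
top-2 eigenvectors of the double-centred squared-distance matrix, with a
deterministic eigenvector sign convention — followed by gradient descent
with a backtracking line search (step halved until the stress decreases,
grown 1.2× after acceptance).  The line search is what guarantees the
stress history is monotonically non-increasing; iteration stops at
ΔE < 10⁻⁹ or 500 iterations.  Exact zero distances between distinct
frames are jittered by ~10⁻⁶ Å (seeded) with a warning.

Segmentation of the sequentially connected projection opens a new segment
where a consecutive-point displacement exceeds mean + jump_factor·SD
(jump_factor 2.0) of all displacements.  Two refinements keep the rule
usable: segments shorter than 3 points are absorbed into the neighbour
with the closer centroid, and adjacent segments whose centroids are
closer than the jump threshold are merged — without the latter, the few
per-cent of ordinary steps that cross the threshold inside a single basin
would fragment it.  Barrier times are midpoints between consecutive
segments; the TS ensemble is all frames within ±40 ps of the chosen
barrier (±2 frame intervals when the trajectory is sampled more coarsely).

Φᵢ = (Nᵢ^TS − Nᵢ^U)/(Nᵢ^F − Nᵢ^U) with Nᵢ^X the mean count of residue i's
native contacts satisfied in ensemble X (6.5 Å side-chain criterion).
Residues with no native contacts, or with |Nᵢ^F − Nᵢ^U| < 10⁻⁹, are
undefined (NaN), never zero.  Raw values are kept; the clamped profile
clips to [0, 1].  The folded reference is the room-temperature bound
ensemble and the unfolded reference the last 20 % of an unfolding
trajectory.

## CS/IF deviation statistics

Ten bound and ten apo frames are sampled evenly in time (sampling is
deterministic; seeds only ever affect synthetic data).  All RMSDs are
computed after all-Cα superposition; argmin ties break toward the earlier
apo timestamp.  Atoms are binned by distance from the mass-weighted
partner centroid of each bound frame: 100 half-open bins [b·0.5, (b+1)·0.5)
up to 50 Å, with a separate overflow group.

The KS stage needs a reference sample to test against; here each
bound–apo pair's per-atom deviations in a bin are
tested against the pooled apo-vs-apo deviations of the same bin.  That
baseline is the natural null ("is this deviation larger than the apo
ensemble's own spread?") and, because it pools all 45 apo pairs, it also
gives the test unequal sample sizes — which matters: with equal sizes the
two-sample KS statistic lives on a coarse 1/n grid and its P-values are
too discrete to be uniform under the null.  Per bin, the median P over
the 100 pairs and the fraction with P < 0.1 are reported; bins with fewer
than two atoms are undefined.

Δ magnitudes: CS = the RMSD values among the sampled apo conformers (the
spread available for selection, globally or over the local atom set);
IF = the residual RMSD between each bound frame and its most-similar apo
frame.  The histogram form Σfᵢxᵢ/N is evaluated with xᵢ equal to each
bin's member mean, so Δ reduces exactly to the difference of sample means
and is independent of the histogram bin width (asserted in tests; 0.25 Å
bins are used for the reported histograms).  The local scope is atoms
whose mean distance from the partner centroid over the sampled bound
frames is below 10 Å — roughly the first two coordination shells of an
interface.  Verdict labelling is purely the Δ signs: Δ_global > 0 ⇒
global conformational selection, Δ_local < 0 ⇒ local induced fit.

## Ensemble observables

φ/ψ are computed from backbone N/CA/C positions; a residue needs both
dihedrals (i.e. both neighbours in the same chain) or its dihedral
variation is undefined.  Variation is the mean of the circular standard
deviations of φ and ψ, in degrees, so the ±180° wrap is handled
correctly.  Helicity counts a residue-frame as helical iff
φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°] and the residue sits in a run of ≥ 3
consecutive helical residues; the window and run length are this
package's definition (sources report helicity without one), chosen to
accept the canonical α-helix (−57°, −47°) with margin.  The
distance-difference map is ⟨dᵢⱼ⟩_bound − ⟨dᵢⱼ⟩_apo over Cα pairs.  The
free-energy landscape is a 2-D histogram over (Rg, Cα RMSD to reference)
with 0.5 Å bins, F = −ln(P/P_max) in kT (no temperature is assumed for a
unit conversion), F = +∞ on empty cells, and basins as connected
components with F < 1 kT.

## Synthetic data: what it emulates and what it does not

The generator builds a reduced two-chain complex: ideal-helix and coil
segments from canonical backbone geometry (helix φ = −57°, ψ = −47°; coil
torsions drawn from the broad α/β region so chains stay compact), one
side-chain pseudo-atom per residue at an extended Cβ position carrying
the residue's side-chain mass.  That representation is sufficient for
every contact rule (glycine falls back to Cα; charge centres fall back to
the pseudo-atom).  The default system mirrors the study scale: a
58-residue three-helix chain A bound to a 54-residue two-helix chain B,
packed by a deterministic search (closest clash-free approach over 12
rotations × 5 axial shifts, choosing the placement that buries the most
chain-A atoms near chain B's centroid, requiring ≥ 5 binding contacts).
Random chain shapes occasionally cannot bury any atom within 10 Å of the
partner centroid; `build_study_complex` then deterministically retries
with derived seeds so the local scope of the CS/IF analysis is never
empty.

* CS/IF ensembles (50 frames spanning 10 ns): per-atom Gaussian
  displacements.  `cs_dominant` shares a large global deformation
  (1.5 Å per coordinate) between each bound frame and its apo twin;
  `if_dominant` deforms only bound-frame atoms within 12 Å of the partner
  centroid; `mixed` shares the far-field deformation and keeps the
  interface deformation private to the bound frames.  Thermal jitter is
  0.2 Å throughout.
* Unfolding trajectories (500 frames × 20 ps, rate 2.4·10⁻⁴ ps⁻¹, i.e. a
  ~2.9 ns half-time): each residue independently "melts" with rate k/2
  and jumps to a well-separated coil position (a jittered line, mutual
  spacing 8 Å, far from the native region), so a native contact survives
  exactly while both residues are unmelted and its marginal survival is
  e^(−kt).  Contacts sharing a residue are correlated, but the expected
  Q(t) is exactly exponential with the planted rate.
* Clustered trajectories: k = 3 basins as global deformations separated
  by 2.5 Å Cα RMSD with 0.5 Å within-basin spread (a 5× ratio — the
  boundary regime for segmentation), sequential dwells of ~40 frames with
  recorded switch frames.

Because the deviation models move atoms independently, they scramble
backbone torsions: dihedral-based observables (helicity, φ/ψ variation)
are meaningful on the reference structure and on mildly perturbed
ensembles, but read ~0 on the heavily deformed CS/IF ensembles.  Passing
tests therefore demonstrate the statistical machinery — contact
bookkeeping, rate recovery, embedding, segmentation, calibrated KS,
Δ signs — not physical realism: there is no excluded volume in the
ensembles, no force field, and no thermodynamic consistency between the
kinetic and structural generators.

## Problem sizes and determinism

The test suite runs the heavy property checks at reduced scale chosen for
statistical sufficiency: a 26+24-residue toy complex for oracle and
pipeline tests, 100-seed batches for kinetics recovery (400-frame series
over two decay times, σ = 0.01), cluster segmentation (120-frame
trajectories) and mechanism recovery, and 1000 replicates for the KS null
calibration (100-atom bins against an 800-atom pooled baseline, matching
the pipeline's unequal sample sizes).  `scripts/acceptance.py` re-runs
the same measurements plus the full-size (58+54) study system; a single
`--seed` drives every generator, and all generators are bit-reproducible
under a fixed seed.

## Known limitations

* The reduced side-chain representation cannot express rotamer effects;
  contact populations on real PDB ensembles will differ from toys.
* Log-space fitting requires Q > 0; deep-decay windows must be truncated
  (the drivers do this at Q = 0.1 automatically).
* Sammon mapping is O(n²) per iteration; trajectories beyond a few
  thousand strided frames should be strided harder.
* The KS map treats atoms within a bin as independent samples; spatial
  correlation among neighbouring atoms makes the per-bin P-values
  somewhat anti-conservative on strongly correlated deformations.
* The Δ statistic compares magnitudes, not mechanisms' kinetics; a
  flux-based CS/IF discrimination is out of scope.
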