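# Methods

This note records the models, parameter choices and numerical conventions
behind `dcxmt`, and what the synthetic-data tests do and do not establish
about real cryo-EM data.

## Lattice model

A microtubule is a cylindrical B-lattice of α/β-tubulin monomers: N
protofilaments (PFs) with axial monomer repeat a = 40 Å (dimer repeat
c = 2a = 80 Å), lateral rise r between bonded neighbours, and radius
ρ_N = 115·N/13 Å (linear scaling keeps the inter-PF arc spacing constant;
absolute radii do not enter any statistic computed here). Monomer (i, m)
of PF i sits at z = m·a + i·r, φ = 2πi/N + z·tanθ/ρ, with α on even and β
on odd layers. Because the start number S = 3 is odd, wrapping around the
cylinder meets a monomer shifted by three layers: every lateral bond is
homotypic (α–α/β–β) except the single wrap boundary — the seam — which is
heterotypic by construction for every N. The N − 1 homotypic bond rises
(r each) plus the seam-bond rise S·a − (N−1)·r sum to S·a exactly; in
dimer register the seam stagger is r + a.

**Supertwist.** r is frozen at the 13-PF closure value S·a/13 ≈ 9.231 Å
for all N, and the closure mismatch goes into a PF skew angle
tan θ_N = (S·a − N·r)/(2π ρ_N): θ₁₃ = 0 exactly; θ₁₄ ≈ −0.68°. The sign
convention (helical family) of non-13-PF lattices is configurable
(`supertwist_sign`), since it is not observable in any statistic computed
here beyond the moiré handedness.

**Decoration sites.** A DCX DC domain binds the vertex between four
tubulin dimers (two adjacent PFs × two dimer layers), never across the
seam; sites are placed at the centroid of the eight flanking monomers,
giving (N−1)·(L−1) sites for L dimer layers with the seam excluded.

**Moiré beat.** The lattice pattern repeats under rotation by one PF
spacing after an axial distance L_N = (2πρ_N)²/(N·|S·a − N·r|)
(≈ 0.47 µm for 14 PF). An orthographic projection superposes front and
back walls and its row-wise stripe power is insensitive to the lateral
mirror, so the *projected* envelope repeats at L_N/2
(`moire_beat_period`); the estimator in `moire_filter` measures this
half-period and is validated against the closed form (≈1 % at desk
geometry). The estimator needs several beats of axial extent
(≈ 10⁴ Å); short noisy boxes are flagged `reliable=False` via a
band-power presence test (a flat noise spectrum puts exactly the band's
area fraction of total power into the band; a 20 % excess is required).

## Synthetic segments

Each monomer contributes an isotropic Gaussian blob (σ = 8 Å, integral
1.0 density units·Å²); each Bernoulli(p)-decorated site contributes a
blob of half that integral, 25 Å outside the wall vertex (MAP density
sits on the outer surface, giving the 8 nm periodicity the occupancy
statistic measures). Blobs are summed in orthographic projection; i.i.d.
Gaussian noise is added last. Grey values are densities per Å², so they
are pixel-size independent. Defaults: a typical high-magnification
cryo-EM geometry (1.39 Å pixels, 652 px boxes); tests and the
acceptance script use the
desk geometry (2.78 Å, 160 px) for speed — problem sizes throughout
(50 segments per occupancy point, 400-segment mixtures, two-segment DFT
oracles) were chosen as the smallest that leave comfortable statistical
margins. `noise_sigma = 0.001` equals the whole-box RMS of a noiseless
default segment (per-pixel SNR ≈ 1, between raw-frame and class-average
regimes); it was fixed once from that measurement. Randomness: one root
`SeedSequence` per stack; architecture draws come from the root stream
and each segment renders from a spawned child seed recorded in the
ground truth, so any single segment is reproducible in isolation.

**What the generator does not emulate:** contrast transfer function and
defocus, ice/background texture, lattice defects and PF-number
transitions, bent MTs, GTP-state lattice compaction, and structured (non-
white) noise. Passing tests therefore demonstrate correctness of the
*statistics* under known geometry and white noise, not robustness to
microscope optics; classification accuracies on these images are upper
bounds on real-data performance.

## Occupancy statistic

The averaged power spectrum is Σ|FFT|²/N_pix over segments (Parseval:
the total of a one-image spectrum equals the sum of squared pixels). The
axial profile I(ν) sums power over a lateral band at each positive axial
frequency, DC excluded. A layer-line intensity integrates I(ν) over
|ν − ν₀| ≤ 0.1·ν₀ minus a linear background fitted on the
(0.1–0.3)·ν₀ flanks, clamped at zero. R = I(1/80)/I(1/40).

Lateral integration defaults to the full layer line. A near-meridional
band is tempting but unsound here: for the canonical 13_3 lattice the
inter-PF phase sum Σᵢ exp(2πi·ν·i·r) vanishes identically at ν = 1/40 Å⁻¹
(because S·a = N·r), so the meridional 4 nm signal is pure spectral
leakage and the ratio becomes fragile across architectures. With full
integration a mild architecture dependence remains (R differs by ~20 %
between 13- and 14-PF lattices at equal p in this CTF-free projection
model — the skew redistributes layer-line power); the test suite bounds
it at 35 % relative. R is a *relative* decoration scale: monotone in p
(strictly, over p ∈ {0…1} at 50 segments/point), zero for undecorated
lattices up to a noise floor, and invariant under global intensity
scaling. The noise floor is defined as the RMS of the unclamped
8-nm-window statistic over re-noised undecorated replicate stacks,
normalised by I(4 nm) — it captures both pure-noise power and
noise/lattice leakage cross terms. Subset errors split the stack in
stored order into k ≈ equal contiguous subsets (sizes n//k + 1 for the
first n mod k), deterministic by design.

## PF classification

References are noiseless, undecorated projections per architecture,
low-passed at 15 Å with a raised-cosine edge and block-binned. At full
scale the binning is 4× (5.56 Å binned pixel); the desk geometry uses 2×,
which lands on the same 5.56 Å binned pixel. Scoring maximises the
normalised cross-correlation over in-plane rotations (±10° in 2° steps;
boxed segments come axis-aligned) and circular shifts of ±1 dimer repeat
axially and ±2 binned px laterally. The "poor" floor is mean + 5 s.d. of
best scores of 32 pure-noise calibration images (scores are scale
invariant, so unit noise suffices; fixed internal seed). Fractions
including "poor" sum to 1 exactly. Under study conditions the classifier
is error-free on noiseless segments and recovers a seeded 400-segment
75/25 13/14-PF mixture exactly; accuracy degrades monotonically with
noise. This 2D projection-matching scheme is a deliberate desk-scale
substitute for supervised 3D classification; its acceptance surface is
recovery of known synthetic mixtures, not any experimental class split.

## Interface measurements

Footprint: residue of group A with any heavy atom within d_contact = 4 Å
of any group B heavy atom (k-d tree; verified against all-pairs brute
force on fixtures). Polar contacts: N/O–N/O pairs ≤ 3.5 Å (hydrogen
bonds, no hydrogen placement) and charged-group N (Lys NZ, Arg NE/NH,
His ND1/NE2 — His charged by default, configurable) against carboxylate
O (Asp/Glu) ≤ 4.0 Å (salt bridges); a pair meeting both criteria is one
salt bridge. "Ionic interactions" are counted as distinct residue pairs
with ≥1 salt bridge. Buried area: Shrake–Rupley SASA (960 Fibonacci
points/atom, probe 1.4 Å, element vdW radii C 1.70/N 1.55/O 1.52/S 1.80,
set name versioned in `ContactParams.radii_set`) as
[SASA(A) + SASA(B) − SASA(AB)]/2 — the per-side convention of standard
interface tools; the raw two-sided value is available. The sphere case
is exact to machine precision; agreement with an independent
Shrake–Rupley (biotite) is ~0.3 % on the toy complex; buried area is
rigid-motion invariant to <0.5 % (the point lattice is axis-fixed).

Superposition: Kabsch least squares on atoms paired by (chain, residue
number + declared offset, insertion code, atom name); unpairable atoms
are skipped and counted. Deviation maps report per-atom distances after
aligning on a separate selection (e.g. deviations of a MAP domain after
aligning on the tubulin subunits it binds). RMSD defaults to fitted;
`fit=False` gives the in-place value. Degenerate inputs (<3 pairs for a
fit, empty selections, overlapping groups) raise named errors rather
than returning numbers.

## Mutation atlas

Sites are classified on structures: **interface** if the residue is in
the 4 Å footprint of the MAP–lattice complex; else **core** if relative
accessibility (residue SASA in the isolated domain over the Tien et al.
2013 theoretical Gly-X-Gly maximum) is below τ_core = 0.20; else
**unassigned-surface**. Only the interface class has a sharp published
definition; τ_core is this package's declared criterion, and raising it
can only move sites from surface to core (the interface test is
independent of τ). Domain windows in human DCX isoform-2 numbering
(360 aa): NDC 48–153 (anchored at the residue-48 construct boundary),
CDC 170–260; offsets +5/+6 map the 365/366-residue isoforms. Sequence
identity uses a global Needleman–Wunsch alignment (BLOSUM62, gap
open −10, extend −0.5, frozen) with identity = identical columns /
alignment columns × 100.

**Synthetic stand-ins.** The packaged mutation table
(`data/dcx_mutations_synthetic.csv`) and domain FASTA
(`data/dc_domains_synthetic.fasta`) are constructed stand-ins, marked as
such in their filenames and headers: the table reproduces the published
census margins (78 mutations; 73 in-domain over 65 unique sites, 33 NDC
+ 32 CDC; 5 outside) so the summary arithmetic is exercised exactly, but
its individual substitutions are not clinical records, and the FASTA
sequences are seeded random draws, so the identity the package reports
for them (17.4 %) characterises the stand-ins, not DCX. Validation
against deposited coordinate models and the real isoform-2 sequence
requires those external files; the measurement functions accept any
PDB/mmCIF path and chain-role map, and the toy complex provides a fully
designed ground truth in their absence.

## Known limitations

* No optics model anywhere: occupancy ratios and classification scores
  are not comparable in absolute value to CTF-affected data.
* The occupancy ratio is relative; mapping R to absolute fractional
  occupancy requires a calibration curve rendered at known p (the
  generator provides exactly this).
* The moiré estimator assumes a single architecture per image and
  several beat periods of axial extent.
* Salt-bridge/H-bond detection is geometric (no hydrogens, no angles);
  counts at boundary distances are cutoff-sensitive by construction.
* The classifier searches a narrow rotation range appropriate for boxed,
  roughly axis-aligned segments; widen `rot_range` for free-floating
  images at linear cost.
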