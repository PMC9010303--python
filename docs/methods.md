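# Methods

## Base-pair series and nucleosome reference frames

All nucleosome-level geometry is built from C1′ atoms, the one atom per
nucleotide that is well resolved in essentially every nucleosome model.
The two DNA strands of a nucleosome are paired by antiparallel
register: strand-1 residue *j* (counting 5′→3′ in residue order) pairs
with strand-2 residue *N−1−j*.  The dyad is bp index 0 — the central
pair for odd *N*; for even *N* the index 0 is assigned to the 5′ member
of the central pair on strand 1, a deterministic documented choice.
The *base-pair center* is the midpoint of the two C1′ atoms.

The reference frame of a nucleosome is:

* **O** — centroid of the stably bound bp centers.  Note that for a
  partial wrap (the physical ~1.65 turns) this centroid is offset from
  the superhelix axis toward the side opposite the dyad; it coincides
  with the wrap's circle center only for uniform full-turn coverage.
* **z** — unit normal of the best-fit plane of the bp centers (smallest
  principal direction), signed so that the bp path from low to high
  index circulates clockwise when viewed from +z.  Because nucleosomal
  DNA is a left-handed superhelix, this makes twist signs comparable
  across structures.
* **y** — unit projection of (bp center at the dyad − O) onto the plane
  perpendicular to z.
* **x = y × z**, giving a right-handed orthonormal triad.

At least 20 stably bound base pairs spanning the dyad are required;
flexible terminal base pairs (CENP-A-like nucleosomes: 13 per end,
leaving 121 of 147 stably bound) remain in the series flagged
`stably_bound = False` and are excluded from the fit, so arbitrary
motion of unwrapped arms cannot tip the frame.

**Superhelical location.** SHL = bp index / 10.4 (one duplex turn per
superhelical location), continuous, dyad = 0, antisymmetric, |SHL| ≤
7.02 for a 147-bp wrap.  Binning for reporting ("SHL 4–5") uses
half-open unit bins [k, k+1) on |SHL|.

**Dyad and anti-dyad markers.** The dyad point is the centroid of the
C1′ atoms of bp −1..+1 (6 atoms; three pairs damp single-residue
noise).  The anti-dyad point defaults to the centroid of the C1′ atoms
at bp ±36 and ±37 — the disc position diametrically opposite the dyad,
≈ SHL ±3.5.  "Opposite the dyad" admits a second reading (the DNA
termini, SHL ±7), so the index set is an explicit parameter
(`anti_indices`) and either convention can be reproduced.

## Step parameters between nucleosome frames

The relative pose of frame 2 with respect to frame 1 is decomposed
about the *mid-frame*: the rotational midpoint of the two triads
(quaternion interpolation at t = ½, i.e. (R₂R₁ᵀ)^(1/2)R₁) with origin
at the origin midpoint.  Then

* rise = (O₂ − O₁)·z_mid; shift_x, shift_y = in-plane components, so
  the decomposition identity center_distance² = rise² + shift² is exact;
* tilt = total angle between z₁ and z₂ (atan2 form, accurate near 0°
  and 180°);
* twist = signed angle (right-hand rule about z_mid) between the
  projections of y₁ and y₂ onto the mid-plane.

Angles are in degrees, distances in Å.  This mirrors the mid-step
convention of DNA base-step analysis; the quantities are named after
their base-step analogues because no canonical formula exists for
nucleosome-level steps, and every output table records the convention.
The decomposition is invariant under global proper rigid motions and
antisymmetric under frame exchange (rise and twist negate, tilt and
center distance are preserved).

The generator's inverse (`step_to_transform`) finds the rigid motion
realizing a prescribed step exactly.  Tilt/twist prescribe only two of
the three rotational degrees of freedom; the third — the azimuth of the
tilt hinge in the mid-frame — defaults to 0 and is exposed as
`hinge_phase`.  The rotation is recovered numerically (trust-region
least squares on the rotation vector, residuals below 1e-8, typically
1e-13); a closed form exists only for the pure-twist case, which is
handled exactly.

## Ensemble alignment, sampling clouds, occupancy

Frames of a trajectory ensemble are aligned by least-squares (Kabsch)
superposition of the reference nucleosome's complete C1′ set onto the
same atoms in a reference frame (frame 0 by default).  The SVD
determinant correction excludes reflections.  The mobile nucleosome's
dyad/anti-dyad markers across aligned frames form the sampling cloud;
its RMS dispersion (root-mean-square distance to the cloud centroid)
and principal axes/extents summarize how much relative pose space the
stack explores — a bridged stack samples narrowly, an unbridged one
widely.

Contact occupancy of a (factor residue, target residue) pair is the
fraction of frames with at least one heavy-atom pair within the cutoff.
"Strong" contacts are those at occupancy ≥ 0.5; both the cutoff
(default 4.5 Å) and the threshold are flags recorded in outputs, since
neither has a single canonical value (occupancy, rather than mean
distance or interaction energy, is this package's operational
definition of contact strength).

Contact search uses a KD-tree at the cutoff radius; tests enforce exact
agreement with the all-pairs computation, so the tree is purely an
optimization.  Hydrogens are excluded by element.  Residue-level
aggregation uses the minimum atom–atom distance per residue pair.

## Bridge classification and SHL mapping

A factor's contacts are grouped per nucleosome: partners receiving any
histone contact are *specific* (the recognition interface), partners
touched only through DNA are *neighbors* (the bridging interface).  A
factor reaching ≥ 2 nucleosomes is a bridge; histone contacts on more
than one partner are flagged ambiguous rather than silently resolved.
Neighbor-DNA contacts are mapped through the neighbor's base-pair
series to continuous SHL; the reported span is [min, max] of |SHL|.

## Fiber analysis

Array order comes from the annotation (repeat index), not from tracing
linker connectivity — deposited array models often have disordered
linkers.  Nucleosomes flagged flexible (typically two per end of a
12-mer) are excluded from fits.

The start number compares median center distances: two-start (zig-zag)
when the (n, n+2) partner is closer than (n, n+1), one-start otherwise;
ties within tolerance are reported as ambiguous.

The helix fit estimates the fiber axis from second differences of
consecutive origins — for points on a circular helix these lie exactly
in the plane perpendicular to the axis, so the smallest principal
direction of their scatter recovers the axis exactly for noiseless
input (unlike a PCA of the origins themselves, which is biased for
finite helices).  Origins are then projected onto the axis-normal
plane, the circle center is fit algebraically, and azimuths are
unwrapped by nearest-branch continuation; rise and twist per nucleosome
are the mean consecutive increments, with the axis signed so rise is
positive.  `stacked_pair_distance` / `stacked_pair_angle` are the mean
origin–origin distance and mean inter-z-axis angle over (n, n+2) pairs
— this package's own operational definition of the spacing and
inclination of stacking partners, stated in every output.

Linker accounting is the exact integer identity
linker = repeat − wrapped (167 − 147 = 20 bp; 207 − 147 = 60 bp).

## Gradient profiles

Per-condition profiles are normalized to their maximum (I_i/I_max).
Replicates are combined by mean *after* normalization (the order is not
dictated by the data; after-normalization weights replicates equally
regardless of blot exposure).  Interpolation uses the Akima spline
(shape-preserving, exact at the knots, reproduces polylines on
collinear data; needs ≥ 5 points).  Migration shifts are summarized by
the intensity-weighted centroid fraction; the centroid difference
between conditions is a scalar whose sign gives the direction of the
shift (negative = toward lower-density fractions).  The underlying data
are distributions, not scalars, so the centroid is an operational
summary and is labelled as such in output metadata.

## The synthetic generator

The generator emulates the study conditions with pseudo-atomic
structures whose ground truth is known exactly:

* **Nucleosome** — both C1′ strands traced along an ideal left-handed
  superhelix: radius 41.9 Å, pitch 25.9 Å (canonical nucleosome
  core-particle values), 1.65 turns over 147 bp, C1′–C1′ separation
  10.5 Å across each pair with a 10.4-bp pseudo-twist of the separation
  direction.  Histones are 8 placeholder pseudo-atom chains (10 CA
  atoms each) on two rings inside the gyres.  The CENP-A preset flags
  13 bp per end flexible (121 stably bound) and displaces them onto
  straight tangential arms.
* **Stack** — nucleosome 2 is placed by the exact inverse of the step
  decomposition, so analysis round-trips the ground-truth step to
  numerical precision.  Defaults: rise 60 Å, twist 20°, tilt 0 — a
  face-to-face stack with room for the bridging factor.  The factor
  placeholder (residues 100–117, Lys/Arg names at the α6 basic-face
  positions 102–117) is placed 3.2 Å from a histone atom and a DNA
  atom of nucleosome 1 and from the C1′ atoms around the neighbor
  anchor on nucleosome 2 (default bp 47, SHL ≈ 4.5 — the
  mononucleosome stacking mode).
* **Fiber** — nucleosome *k* at azimuth k·twist on a cylinder, height
  k·rise, disc tilted off the axis by a preset angle; origins therefore
  lie exactly on a circular helix.  Presets: `cenpn_like` (rise 32 Å,
  twist 162°, radius 55 Å, disc tilt 20°, two factors per (n, n+2)
  pair anchored at bp ±65, SHL ≈ 6.3), `h1_like` (27 Å, 171°, 45 Å,
  8°, no factors — tighter, shallower stacking), `ladder` (twist
  exactly 180°: parallel stacks, zero net (n, n+2) twist).  The
  cenpn-like vs h1-like contrast encodes the qualitative orderings
  (larger stacked-pair distance, angle, and twist for the
  factor-bridged fiber); the H1-fiber comparison values are not
  available as printed numbers, so they are orderings, not targets.
* **Ensembles** — per frame, nucleosome 2's frame is perturbed with
  independent Gaussian noise per step parameter (nucleosome 1 held
  fixed, so the ensemble is born aligned), plus optional iid coordinate
  jitter of all mobile atoms.  Dispersion presets: `bridged`
  (σ_rise/shift 0.8 Å, σ_tilt 2°, σ_twist 3°) vs `unbridged`
  (6 Å, 12°, 20°) — chosen to emulate the order-of-magnitude contrast
  between factor-stabilized and free stacking in simulation.  All
  randomness flows from one mandatory seed; identical specs and seeds
  give byte-identical output.

What the generator does *not* emulate: full-atom sterics and sequence
(histones and factors are pseudo-atoms; DNA has only C1′), correlated
thermal motion (noise is iid Gaussian, not Langevin dynamics),
DNA-sequence-dependent mechanics, and linker DNA connecting array
nucleosomes.  Passing tests therefore demonstrate the correctness of
the geometric and contact machinery, not force-field realism; analyses
of real trajectories inherit whatever sampling quality the upstream
simulation had.

## Problem sizes and numerical choices

The test and acceptance workloads use 100 random stacks for
generator/analyzer closure (recovery < 1e-6, observed ~1e-11), a
12-mer fiber with 0.5 Å atomic jitter for helix recovery (< 5%
tolerance, observed < 0.1% because frame origins average ~150 atoms),
50 random complexes of 200–2000 atoms at four cutoffs for the contact
oracle (zero mismatches required), 300 frames for dispersion recovery
(sd within 25%; sampling error alone is ~4%) and 500 frames for the
isotropic-translation cloud check (RMS = σ√3 within 10%).  These sizes
make the full suite run in well under a minute while keeping the
statistical tolerances comfortably non-trivial.

Degenerate inputs fail loudly with typed errors: collinear bp centers
(no plane), mirror-image superposition targets (reflections excluded,
positive RMSD), coplanar fiber origins (no axis), all-zero gradient
profiles, topology mismatches between trajectory models, nucleosomes
with ≠ 2 DNA chains.

## Known limitations

* Base-pair-level duplex parameters (roll, slide, propeller) are out of
  scope; only nucleosome-level geometry is computed.
* Tetranucleosome-unit detection for H1-type fibers is not implemented;
  the h1-like preset encodes only the stacking-geometry contrast.
* Role maps for deposited models must be authored by inspection (see
  `examples/deposited_model_roles_template.yaml`); chain naming in
  depositions is not standardized and auto-detection risks silent
  misannotation.
* Ensembles are held in memory; trajectories beyond memory are out of
  scope.
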