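# Methods

## The geometric model

A hook-like assembly is treated as a helical lattice of rigid subunits on
a tube. The straight reference lattice is parameterized by the start
number S = 11, the 1-start twist Δφ = 720/11° (11 subunits span exactly
two turns, so protofilaments are the 11-start family) and the 1-start
rise Δz = d₀/S with d₀ = 45.6 Å, the straight-form axial repeat along a
protofilament. A supercoiled assembly is modeled as that lattice bent
onto a circular-helix centerline of curvature κ and torsion τ through a
parallel-transport (twist-free, Bishop) frame, with the straight axial
coordinate taken as arclength. Two consequences of this construction are
used throughout:

- the local axial material stretch at radius ρ and material azimuth φ is
  exactly 1 − κ·ρ·cos(φ − φc(s)), the elastic-bending law, so
  protofilaments on the outside of the bend extend and those on the
  inside compress, symmetrically about d₀ and linearly in ρ;
- the bend-center azimuth precesses through the material at the torsion
  rate, φc(s) = τ·s. This is the geometric form of the "smoke-ring"
  rotation: as the assembly rotates about its axis, each protofilament
  passes continuously through compressed and extended states. It also
  means a bent lattice has no exact rigid screw symmetry, which is why
  supercoiled assemblies must be analyzed without imposing helical
  symmetry.

Supercoil descriptors follow from κ and τ by the inverse Frenet
relations R = κ/(κ²+τ²), h = |τ|/(κ²+τ²), P = 2πh, with handedness the
sign of τ (left ⇔ τ < 0; a standard differential-geometry convention that
makes the observed handedness computable from coordinates).

## Lattice indexing

Subunit positions are summarized by their Cα centroids (unweighted means;
resolution-independent and consistent with the rigid-subunit assumption).
The tube axis of a segment is estimated as sliding window means of 11
consecutive centroids: with the window equal to the start number, the 11
azimuths are equidistributed over two turns and the off-axis components
cancel identically.

Ordering the subunits is the nontrivial step, because a 26-subunit
segment is wider (tube diameter ≈ 95 Å at the centroid ring) than it is
long (≈ 108 Å), and because curvature leaks the off-axis ring offset into
any straight-axis projection by up to ±ρ·sin(κL/2) — more than one rise.
The package therefore decodes the lattice rather than sorting a
projection:

1. a cylinder axis is fitted to the centroids (least-squares line
   minimizing the spread of point-to-line distances, seeded from all
   three principal directions);
2. axial position s and azimuth φ about that axis are jointly fitted to
   the lattice model s ≈ s₀ + kΔz, φ ≈ φ₀ + kΔφ (mod 2π) and the 1-start
   index k of each subunit is decoded. The azimuthal residual is
   decisive — in an 11-start lattice the nearest azimuthal look-alike of
   an index sits 5 ranks away at only 720/11 − 360/11 ≈ 32.7°, so
   candidates are restricted to ±4 ranks of the axial estimate, which
   rules the alias out while tolerating the axial systematic error
   (≤ 3 ranks). A bilinear ring-to-axial leak model
   (∝ (1, s−s̄) × (cos φ, sin φ)) is regressed out between decode
   rounds;
3. segments longer than ~30 subunits are split into two overlapping
   halves along the chord, decoded recursively and stitched by the median
   index offset over the shared subunits (with a reversal check) —
   each piece then subtends a bend angle within the chord model's
   validity;
4. refinement rounds re-measure (s, φ) against the curved window-mean
   polyline implied by the current ordering (built from the trusted
   middle of the ordering) and re-decode; a refined ordering is accepted
   only if it improves the circular SD of the 1-start azimuthal steps.

The ordering's polarity (which end is k = 0) cannot come from geometry:
the azimuthal step sign is a chirality and is identical viewed from
either end. It is anchored deterministically on chain identifiers (the
end subunit with the lexicographically smaller chain id is the origin),
which is invariant to both chain-order permutation and rigid motion.
A lattice whose consecutive azimuthal steps scatter by more than 15°
(circular SD) is rejected as inconsistent; valid lattices measure < 1°.

Protofilaments are first assigned as k mod 11 and then renumbered by the
field convention: the protofilament with the largest mean axial spacing
becomes 1 (most extended, outside of the bend), ids increase
consecutively around the circumference in the direction that places the
smaller of the two opposite-side means at id 7, so the most compressed
protofilaments land at 6–7. Ties (straight assemblies) break
deterministically by lowest azimuth.

## Spacing profiles and domain statistics

d_{p,r} is the Cα–Cα distance between corresponding residues of axial
neighbor subunits (k, k+11), averaged over the axial pairs of
protofilament p (per-pair values are kept in the long-format table).
Residues missing from either partner are skipped, not imputed. Domain
means average d_{p,r} over the residues of each domain; the default FlgE
domain set is D0c = 1–71 ∪ 358–402, D1 = 72–144 ∪ 285–357, D2 = 145–284
(the D0c range is the established one; the D1/D2 boundary is not uniquely
fixed by the deposited annotation and is configurable — it is chosen so
the D1 triangular loop 117–135 and the β-hairpin tip 329–330 fall in D1
and the 159–284 outer-surface contact residues in D2). The
elastic-bending consistency report checks that each layer's
(min + max)/2 sits at d₀.

## Domain motions

Superpositions are least-squares (Kabsch); the implementation uses
scipy's rotation alignment and is cross-checked in the tests against an
independent direct minimization and Biopython's SVD superimposer. A
"tilt" is the full residual rotation angle θ = arccos((tr−1)/2) after
superposing the reference inner domain (D0c), not a projected angle; an
axial "shift" is the domain-centroid displacement projected on the local
tube axis. Subunit length is the extent of the Cα projections on the
local protofilament direction. Conformation classes group subunits by
protofilament; the class representative is the member nearest the
segment's axial middle, and a straight assembly is flagged
conformationally uniform when even between-class RMSDs stay below 0.1 Å.

## Supercoil estimation

Discrete curvature is the Menger (circumcircle) curvature of vertex
triples — exact on circles; discrete torsion comes from the
chord-parameterized interpolating cubic of vertex quadruples,
τ = det(r′, r″, r‴)/|r′ × r″|², whose numerator is proportional to the
signed tetrahedral volume. Both aggregate by the median to resist end
effects. A nonlinear least-squares circular-helix fit refines the
discrete estimate; on noisy input, strided discrete estimates (and their
mirror images) seed additional starts and the lowest-residual fit wins.
A residual bootstrap (fixed seed 20191122) supplies confidence intervals.

Estimating a ~1300 Å pitch from a ~110 Å segment is an extrapolation —
the segment covers ~7% of a supercoil turn, and the window-mean polyline
carries a systematic wobble (~0.2 Å) comparable to the segment's total
sagitta. The pipeline therefore refines the polyline fit with a
coiled-tube model fit: subunit (or per-layer) centroids lie exactly on
material helices wound around the supercoil by the parallel-transport
map, and finally an atom-level fit in which the unknown reference-subunit
template is profiled out by variable projection (the template is the
conditional optimum for any parameter vector, so it is recomputed inside
the residual). The atom-level fit uses the full bending deformation
field, including the differential stretch across radii; on noiseless
synthetic data it recovers the generator parameters to machine precision.
Subunit conformations that genuinely differ beyond elastic bending end up
in the residual, so on real data the fit degrades gracefully toward the
centroid-level estimate.

Extension to one pitch applies the screw operation of the fitted helix
(rotation about the superhelix axis plus the matching axial advance) to
segment copies. Because the bent lattice has no exact screw symmetry
(see above), the copies carry a small azimuthal registration seam of
τ·ΔS ≈ 18° per copy; the extension is therefore a visualization/
measurement construct — its centerline reproduces the input supercoil,
its lattice is only approximately continuous across seams.

## Contacts and variability

A residue pair is "in contact" in a protofilament context when its
minimal heavy-atom distance is ≤ 4 Å (configurable; sensitivity to
3.5–4.5 Å is reportable, and the tests verify classification stability to
±0.2 Å). One representative subunit pair per context is chosen nearest
the segment's axial middle to minimize end effects. Interfaces present in
all 11 contexts are constant; present in some and absent in others,
switching. Per-residue variability is the SD, across the 11 contexts, of
the Cα distance to the corresponding residue of the directional neighbor;
under elastic bending this SD grows linearly with radius (dispersion
≈ d₀κρ/√2 over the 11 slots), reproducing the layered
small-inner/large-outer pattern. The triangle-gap metric reports the
pairwise minimal distances and centroid-triangle area of the middle-layer
domains of subunits 0, +6 and +11 per context; the gap closes on the
compressed side of the bend.

## The synthetic generator

The generator is the test substrate: three Gaussian pseudo-atom layers
(radii 25/45/70 Å, 30/40/35 atoms, SD = spread/2 with spreads 6/8/8 Å)
stand in for the D0–Dc "tube", D1 "mesh" and D2 "spring" layers; each
subunit is a rigid copy of the seeded template, and residues are numbered
so each layer occupies a contiguous range (the domain machinery runs
unchanged). The default supercoil preset uses the native geometry
(P = 1290 Å, R = 165 Å, left-handed); d₀ = 45.6 Å is the straight-form
repeat, and the outer-layer radius of 70 Å is chosen so that the
closed-form outer-layer modulation amplitude d₀κr ≈ 7.6 Å at the native
curvature matches the scale of the reported outer-domain spacing extremes
(≈ 38/54 Å) — a derived, documented default. Hinge fixtures rotate one
layer about a circumferential axis through the layer base (same in-plane
position as the layer centroid, z at the layer's bottom, so a pure tilt
leaves the axial position essentially unchanged) and optionally add an
axial shift; they provide exact oracles for the domain-motion operators.
Coordinate noise is isotropic Gaussian, seed-reproducible.

What the generator does not emulate: real side-chain packing (contacts
on synthetic assemblies require generous cutoffs, ~17–28 Å, because the
pseudo-atom clouds are sparse), internal domain flexibility, sequence,
and per-subunit conformational change beyond elastic bending. Passing
tests therefore demonstrate the geometric machinery — indexing,
profiling, superposition, supercoil estimation — not atomistic realism.

## Recovery suite and statistical limits

The recovery harness draws 20 random specs with P ∈ [800, 1800] Å,
R ∈ [80, 250] Å, random handedness, 44 subunits and coordinate noise of
0.3 Å SD, and requires exact indexing, exact handedness, pitch and radius
within 3%, and per-layer spacing amplitudes within 5% of the closed
form. The segment length (44 subunits, three axial pairs per
protofilament) is the suite's design choice: a Fisher-information
analysis at 26 subunits shows the supercoil radius cannot be determined
to 3% at this noise level by any estimator.

At 44 subunits the estimator is unbiased with σ ≈ 0.1–0.4% on pitch and
σ ≈ 1.5–2% on radius (Monte Carlo over noise realizations; profiled
residuals reach the exact noise floor, so this is the information content
of the data, dominated by the torsion/precession signal over a short
arc). A hard 3% radius bound on every one of 20 random draws therefore
sits in the ~2σ tail and fails for a few draws at the harder parameter
corners (high pitch, i.e. weak curvature); typical suite outcomes are
17–20 of 20 specs passing, with indexing, handedness, pitch and amplitude
criteria at 20/20.

## Numerical choices and known limitations

- Units are Å internally everywhere; nm appears only in serialized
  reports.
- All randomness flows through explicit integer seeds; the same
  configuration and seed reproduce byte-identical summaries (timestamps
  and runtimes live in separate fields).
- Degenerate inputs are first-class: straight assemblies report κ = 0
  with infinite pitch and no handedness; collinear point sets and
  zero-length polyline segments raise typed errors; the single-window
  axis case synthesizes a two-vertex axis.
- Lattice decoding is validated for segments up to ~66 subunits across
  the full curvature box; beyond that (bend angles ≫ 1 rad at high
  curvature) the divide-and-conquer chord decode can fail, and re-indexing
  a full-turn extended model blindly is out of scope.
- Alternate locations take the first conformer; residues with insertion
  codes are rejected with a warning.
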