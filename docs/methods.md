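# Methods

## Frames and spherical coordinates

The backbone frame at residue *i* is built from three consecutive Cα
positions: the tangent **t** points to the next Cα, the binormal **b** is the
normalised cross product of consecutive tangents, and **n** = **b** × **t**
closes a right-handed orthonormal triad.  Frames therefore exist only at
interior residues of a contiguous segment; termini, chain breaks and missing
Cα atoms leave the frame undefined rather than extrapolated.  Chain breaks
are recorded wherever consecutive Cα atoms are more than 4.5 Å apart — far
above the trans virtual bond (~3.80 Å) and the cis one (~2.9 Å), so cis
peptides are never mistaken for breaks — and no frame or angle ever spans a
break.

A direction on the frame-centred unit sphere is stored as latitude κ ∈ [0, π]
(0 at the tip of **t**) and longitude τ ∈ (−π, π] (0 on the **n** half-plane,
increasing counter-clockwise about **t**; the longitude of a pole is reported
as 0 by convention).  The virtual bond and torsion angles of the Cα trace are
the latitudes/longitudes of each next tangent: `cos κ = t_i·t_{i−1}` and
`cos |τ| = b_i·b_{i−1}`.  The defining dot products fix only |τ|; the sign is
taken from `(b_{i−1} × b_i)·t_{i−1}`, which realises the counter-clockwise
longitude convention and makes τ of a right-handed α-helix positive
(≈ +0.89 rad at the default helix geometry, with κ ≈ 1.55 inside the
occupied annulus of the backbone map).  When consecutive tangents are
collinear within 1e−7 the binormal is carried over from the nearest
preceding defined frame (discrete parallel transport), the frame is flagged,
and τ is reported undefined there.

Side chains are observed level by level (β, γ, δ, ε, ζ, η) along a fixed
observation path per residue type; at branch points the path follows the
atom that carries the next level (ILE uses CG1, TRP and HIS use CD2, PHE/TYR
use the equivalent CD1 branch).  Three framings are provided:

* **χ1 framing** — **t** along Cα→Cβ, reference direction the N atom
  projected perpendicular to **t**.  The longitude of a γ atom in this frame
  *equals* the standard χ1 dihedral exactly; this equivalence is enforced in
  the tests against an independent dihedral routine.  (The reference vector
  is deliberately the N direction: projecting the Cα−Cβ difference would be
  degenerate along the frame axis.)
* **χ2 / generic Z–X framing** — at observer atom X reached from atom Z,
  **t** points Z→X and **n** ∝ **t** × **t**_a with **t**_a the residue's
  backbone Frenet tangent.  This framing stays well-defined arbitrarily far
  up the side chain, but couples the longitude to the backbone: its χ2-level
  longitude agrees with the standard χ2 dihedral only up to a
  geometry-dependent rotation.  A dihedral-referenced variant
  (`dihedral_frame`) is provided where exact dihedral semantics are needed;
  it is what the χ2 oracle test uses.  The framing degenerates when **t** is
  parallel to **t**_a (within 1e−7); such residues are flagged and skipped.

Latitudes/longitudes are radians internally and degrees at all user-facing
tables and CLIs.

## Projection and compression

The stereographic projection from the south pole maps (κ, τ) to the plane
point of radius tan(κ/2) and angle τ; the north pole goes to the origin and
the south pole to infinity (an error under the identity compression).  The
two fixed latitude compressions, f(κ) = 1/(1+exp κ²) and f(κ) = 1/(1+κ⁴),
are implemented exactly as defined even though both are *decreasing* in κ,
which reverses the radial order (the north pole lands at radius
tan(0.25) ≈ 0.255): published density maps use these forms as-is, so the
package reproduces them rather than re-normalising.  Longitudes are always
preserved exactly.  Round-trip inversion is exact to 1e−12 for the identity
compression; the compressed variants invert through log/root expressions
whose conditioning deteriorates towards κ → 0, so their round trip is
checked at 1e−6 over the interior of the domain.  Mean distances from the
north pole (the circles drawn on compressed maps) are computed in compressed
planar radius.

## Density maps, statistics, outliers

Spherical histograms are equal-area by construction: uniform bins in
cos κ × τ (default 90 × 180; every bin subtends the same solid angle to
1e−12).  Smoothing places a von Mises–Fisher-style kernel
exp(κ_c(cos d − 1)) at each occupied bin centre with concentration
κ_c = 1/bandwidth², bandwidth 5° by default, and normalises the grid to sum
to one.  Smoothing cost scales with (occupied bins) × (grid size), which
keeps dense grids tractable for concentrated distributions.

Tetrahedral angles θ_NC (N–Cα–C), θ_Nβ (N–Cα–Cβ) and θ_βC (Cβ–Cα–C) are
plain arccos angles at the Cα vertex; summaries report the arithmetic mean
and the *population* standard deviation (divide by n) — at the sample sizes
of interest the distinction from the n−1 convention is far below the
reported precision.  Strata follow the analyses the maps support: secondary
structure, cis-proline, and All/PRO/Rest.

χ rotamers are classified by nearest window centre: g+ at +60°, g− at −60°,
t at 180°, each window ±60° wide; exact boundary longitudes (0, ±120, 180°)
go to the clockwise-lower label (g+ = (0, 120], g− = [−120, 0], t = rest),
so the three windows partition the circle.  The g+/g− sign assignment is a
package convention, switchable by flag, since the field uses both.

Outlier scoring converts an atom's smoothed reference density to a quantile
among the reference sample's own densities and flags atoms below a threshold
quantile (default 0.5 %).  Scoring a reference against itself therefore flags
roughly the threshold fraction, which is the calibration property the tests
check.  Atoms whose stratum has no reference map are reported unscorable
rather than silently passed.

## Placement library and reconstruction

Every heavy atom is encoded relative to its observation frame as (direction,
radius); encode/decode is an exact bijection for positive radius.  A
placement library stores, per stratum (atom level and name, residue class,
secondary structure, χ1 rotamer), the *modal* direction of the smoothed
density map — modes, not means, because rotamer distributions are multimodal
and a mean direction would fall between clusters — together with the mean
encoded radius, a resultant-length dispersion summary and the support count.
Strata under the minimum support (default 25) are dropped; generalised
entries (rotamer- and ss-wildcards) are kept as fallbacks, and lookup
generalises in the documented order rotamer → context → ss.

Reconstruction from a bare Cα trace builds the Frenet frames, places N, C, O
and Cβ of each interior residue from the backbone strata (O is placed in the
frame of the residue whose following peptide plane contains it), then climbs
each side chain placing the path atoms sequentially in Z–X frames anchored
on already-placed atoms, so the rebuild is a function of the Cα coordinates,
residue names and secondary-structure labels alone.  The rotamer stratum
defaults to the library's most populated rotamer for the (residue, ss) pair;
the choice is recorded in the per-atom provenance together with the fallback
depth.  Terminal residues (no frame) stay Cα-only.  Reconstruction is
exactly equivariant under proper rigid motions, and placement error on
matched synthetic data is bounded by the density-grid cell size — RMSD
decreases as the grid is refined, ≈ 0.1 Å at a 60 × 120 grid under 0.02 Å
training noise.

## Synthetic data

The generator provides the study conditions for all tests.  Helix traces are
closed-form circular helices whose defaults (rise 1.5353 Å, twist 99.768°,
radius 2.2755 Å) are the Cα geometry of an ideal-geometry backbone at
(φ, ψ) = (−57°, −47°): virtual bond 3.804 Å, (κ, τ) ≈ (1.55, 0.89) inside
the α region of the backbone map.  Strand traces are planar zigzags with a
prescribed virtual bond and turning angle κ (default 3.8 Å, 1.0 rad); their
planarity makes every interior τ exactly 0 or π, a useful chirality fixture.

Full backbones on a trace are built from rigid planar peptide units bridging
consecutive Cα atoms.  Within each unit the Cα–C, C–N and N–Cα lengths and
the Cα–C–N angle take their configured ideal values, ω is exactly 180°
(or exactly 0° for requested cis bonds, which require the matching ~2.9 Å
virtual bond in the trace), and the closure residual is absorbed by the
C–N–Cα angle (the root closest to its ideal 121.7° is selected; a second,
spurious closure root with a wildly non-ideal angle exists and is rejected).
Each unit retains one rotational degree of freedom about its virtual bond;
it is fixed by requiring the configured θ_NC angle *exactly* at every shared
Cα, solved in closed form.  The two admissible orientations per unit
(a peptide-plane flip) and the free first-unit rotation are resolved
deterministically: among all propagations that close the whole chain, prefer
the one with negative mean φ (the L-backbone convention) and, within that,
the largest worst-case closure margin.  Cβ is then solved in closed form
from θ_Nβ and θ_βC with the L-amino-acid chirality
((u_N × u_C)·u_β > 0), and γ/δ atoms are attached at user-specified χ1/χ2
via standard internal-coordinate (NeRF) placement.  Optional isotropic
Gaussian coordinate noise (seeded, bit-reproducible) is applied to every
atom after construction.

A second builder constructs backbones directly from (φ, ψ, ω) internal
coordinates; it is the source of extended fixtures, cis-bond fixtures, and
of the default ideal values themselves.  Ideal geometry ships as an editable
JSON config following the high-resolution small-molecule tradition
(θ_NC 110.5°, θ_Nβ 111.2°, θ_βC 110.1°, standard peptide lengths).

What the generator does *not* emulate: real rotamer population mixtures,
side-chain branch atoms off the observation path, solvent, B-factors,
correlated (anisotropic) coordinate error, and genuinely loop-like irregular
traces.  Passing tests therefore demonstrate the correctness and calibration
of the machinery — frames, projections, tables, library learning,
reconstruction — under controlled geometry, not the empirical distributions
of crystallographic data; analyses of real structures should be run on
high-resolution PDB subsets through the same pipeline (the parser enforces
a resolution cutoff and excludes entries that lack a resolution record when
a cutoff is requested).

## Numerical choices and limitations

* Frame tolerances: orthonormality and det = +1 to 1e−9; collinearity and
  framing degeneracy thresholds at 1e−7; rigid-motion invariance of all
  angles to 1e−9.
* cis/trans boundary at |ω| = 90°, the midpoint between the ideal isomers.
* Alternate locations resolve to the highest occupancy (alphabetical
  tie-break); model 1 only for multi-model files; hydrogens dropped.
* Left-handed helices are taken from PDB HELIX class 6; in headers without
  class information such residues fall to loop.
* Overlapping HELIX/SHEET ranges resolve to helix with a logged warning.
* Density weighting is per-atom, not per-chain.
* The reconstruction makes no attempt at steric-clash resolution, energy
  refinement or rotamer-tree search; it is a geometric proof of concept.
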