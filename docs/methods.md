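# Methods

## The model

Erythrocyte spectrin functions as an αβ₂ heterotetramer: two
antiparallel αβ heterodimers joined head to head, forming — through
the tetramerization repeat — an uninterrupted chain of 37 spectrin
repeats per strand (20 full α repeats + 16 full β repeats + 1
reconstituted repeat).  Each repeat is an antiparallel three-helix
coiled coil, ~106 residues, ~4.5 nm long and ~2.5 nm wide, delimited
by two conserved leucines; consecutive repeats are joined by a
5-residue linker.

The package implements the compact quaternary model of this tetramer
as a **two-start, right-handed supercoil** of rigid repeats, four
repeats per supercoil turn, and the analyses that surround it.  The
geometry is closed by three relations linking the molecular length L
(nm) to the per-turn pitch P, supercoil radius r and the per-turn
contour length C_L:

    P    = 4 L / 37
    C_L² = P² + (8 r)²
    r    = sqrt(C_L² − P²) / 8

C_L is fixed at 19.9 nm — the experimentally measured per-turn contour
length, which equals the length of four repeats (~5 nm per repeat
including one linker).  The second relation uses the *square* variant
of the contour closure (perimeter 8r) rather than the circular one
(2πr): the model is a discontinuous square arrangement of straight
segments, each segment one rigid repeat tangent to the radius-r
circle.  Extension is a pure pitch increase at fixed contour: as L
grows from the compact ~55–65 nm range to full extension, r falls
monotonically, reaching r = 0 (a straight filament) at
L = 37·C_L/4 = 184.075 nm — inside the classically quoted 180–200 nm
extended length.  The inter-repeat bend angle follows from the segment
geometry, cos θ = (P/4)²/(C_L/4)², giving 83.9° at L = 60 nm and 0° at
full extension.  No energy terms enter anywhere; models are screened
only for steric clashes.

### Placement and the roll convention

Each repeat is placed by: orienting its leucine-anchor axis along the
local segment direction, rolling it about that axis, translating its
anchor midpoint to radius r, then applying the per-repeat 90° azimuth
step and P/4 axial rise (azimuth increases with z for the right-handed
default).  "Roll" selects which bundle surface faces neighbouring
repeats.  Since the absolute sign of the roll scale is conventional,
the package anchors it by defining roll = −30° as the orientation in
which the B helix faces directly away from the supercoil axis
(`ROLL_REFERENCE`); under this convention the sterically allowed
window for idealized bundles at 65 nm comes out as [−60°, 0°] on a 30°
grid.

Strand B is generated as the exact 2-fold image of strand A: a 180°
rotation about an axis through the centre of mass perpendicular to the
long axis, at the height that produces a half-pitch (two-repeat) axial
offset.  This interleaves the strands diametrically and makes the
required 2-fold symmetry of the tetramer (the two actin-binding ends
must be equivalent) hold by construction.

### Clash detection

Clashes are Cα–Cα contacts below 4.0 Å between residues of different
repeats, found with a k-d tree and verified in tests against an
all-pairs scan.  Pairs in consecutive repeats of the same strand whose
through-linker sequence separation is ≤ 12 residues are exempt — they
are covalently connected through the 5-residue linker and necessarily
proximal.  Contacts between the *bodies* of adjacent repeats still
count; these near-joint contacts are what make the roll scan
informative.

## Synthetic structures

Real crystal-structure repeats are replaced by idealized bundles so
the entire pipeline runs with no external input.  `make_ideal_repeat`
builds an up-down-up bundle of three z-parallel helices (Cα radius
2.3 Å, 100°/residue): helices A and C as a close pair (axes 9 Å
apart), helix B across from them at the distance that sets the
requested ~25 Å width; the anchor Cα–Cα separation is set exactly to
the requested ~45 Å length.  N and C atoms are placed schematically on
the helical path — adequate for a Cα-resolution model; dihedral-exact
backbones are used only where dihedrals matter (below).  A 0.05 Å
seeded Gaussian jitter makes distinct seeds distinguishable while
keeping each seed fully deterministic.

Chains (`make_chain`) stack copies at 50 Å per repeat along the bundle
axis, joined by schematic 5-residue connectors; 37 repeats span
~185 nm.  The connectors are deliberately coarse (sub-physical Cα–Cα
spacing): an ideal α-helical linker cannot physically bridge this
idealized bundle arrangement, and nothing downstream reads chain-linker
stereochemistry.  The extended-strand assembler reproduces the same
~5 nm/repeat rise independently, by superposing the leading C helix of
each fresh template copy onto the trailing C helix of the growing
strand (Kabsch superposition via `scipy`'s rotation alignment).

## Restrained di-repeat refinement

Zero-length crosslinks between tandem repeats imply Cα–Cα upper bounds
of 11.0 Å (sd 0.1 Å) that a straight, helically linked di-repeat
cannot satisfy.  The refinement holds both repeats internally rigid
and varies only the 10 linker backbone dihedrals; the pose of repeat 2
follows deterministically from those dihedrals through an
ideal-geometry (NeRF) chain continuation plus a fixed attachment
transform calibrated so canonical α-helical dihedrals (φ = −57°,
ψ = −47°) reproduce the exact linear arrangement.  Chain connectivity
is therefore exact rather than restrained.

The objective has three terms:

- **flat-bottom distance restraints** — zero at or below the 11.0 Å
  bound, harmonic above with width 0.1 Å (the reported restraint is an
  upper bound, not a target);
- **soft-sphere clash penalty** — harmonic below 4.0 Å Cα–Cα between
  the two repeat bodies and the linker (4 junction residues exempt);
- **a weak template-dihedral term** (0.005 deg⁻², mean squared
  deviation of the linker dihedrals from canonical α).  Restrained
  template-based modelling always carries template restraints; without
  this term the feasible region of the two flat-bottom bounds is a
  penalty plateau and annealed ensembles drift to its centre
  (over-bent, ~110–135°) instead of settling at the minimal
  perturbation that satisfies the data.

Twenty starts perturb the canonical dihedrals by up to ±20°
(randomized starts around the linear template), each is annealed
(600 Metropolis steps, geometric cooling 25→0.5) and polished with
Powell's method; the selected model is the ensemble member with the
lowest average pairwise Cα RMSD to the others (repeat 1 is fixed, so
superposition on repeat 1 is implicit).  On the synthetic system this
protocol yields bends of 86–94° across seeds with both restrained
distances at or below 11.0 Å.

### Synthetic crosslink sites

The real crosslink pairs (K307–E431, K365–E442) cannot be transferred
to the synthetic bundle by literal fractional residue position — the
synthetic surface geometry differs and the literal-fraction pairs are
not jointly satisfiable at a ~90° bend.  The default sites preserve
the pairs' *geometric roles* instead: one mid-repeat contact (repeat-1
helix B against repeat-2 helix C; residues 36↔180) and one
hinge-proximal contact (96↔184).  Both are >11 Å apart in the linear
model, and both reach the 11.0 Å bound as the di-repeat closes to
~90° along the minimal-deviation bending path — the reported behaviour
of the real crosslinks (incompatible with a straight linker, satisfied
at the bend).  The mapping is exposed as a parameter
(`DEFAULT_CROSSLINK_SITES`).

For parameter-recovery experiments, reference ("true") bent di-repeats
at prescribed angles are generated by continuation from the straight
template under the same minimal-deviation objective plus a weak
closure pull on the crosslink sites: an observed zero-length crosslink
implies the crosslinked surfaces are in contact, so the reference bend
is taken in the plane that closes those surfaces.  Restraints derived
from a reference's actual distances then allow the refinement to be
tested for recovery of the reference angle.

### Linker classification

φ/ψ are computed from the NeRF-built linker backbone (the ψ of the
last linker residue uses an ideal-geometry continuation for the next
N, since the rigid repeat body's schematic N carries no dihedral
information).  Classification: mean φ ∈ [−70°, −45°] and mean
ψ ∈ [−60°, −30°] → α; otherwise mean φ ∈ [−90°, −65°] with a widened
ψ acceptance ([−90°, 0°]) → π; anything else → other.  A proline in
the linker is flagged as incompatible with the π class (π-helices
require φ ≈ −76°, unreachable for proline).

## Lattice stoichiometry

The membrane skeleton is idealized as a homogeneous triangular
("hexagonal-network") lattice over the A = 135 μm² erythrocyte
surface: junctional complexes on vertices, spectrin tetramers on
edges.  Vertex density of a triangular lattice of edge L is
2/(√3 L²), so a protein at N_v vertices implies
L = sqrt(2A/(√3 N_v)); edge-resident proteins (spectrin; ankyrin at
one copy per tetramer) use N_v = copies/3 (six edges per vertex, each
shared by two).  Copy-number ranges are resolved at their midpoint.
The closed form is validated in tests against explicit vertex/edge
counting on finite lattice patches and reproduces all 14 published
census lengths at printed precision.

## End-on image analysis

Synthetic end-on views are annuli with a Gaussian radial profile
(default ring radius 22 Å ≈ the measured 2.2 nm, 1σ width 4 Å) over a
flat background with additive Gaussian noise; controls are a filled
disk and pure noise.  Polarity is stain-high.  The analysis chain:
robust intensity centroid (pixels above median + 3·MAD), annular mean
profile (2 Å bins out to the nearest frame edge), background and
per-pixel noise from the outermost 10% of annuli.  A profile is
*hollow* when its largest interior local maximum exceeds the
background by 3 per-bin sigma and the central bin is depressed below
that peak by at least 2 combined-bin sigma; per-bin sigma scales the
outer-region pixel sd by 1/√(annulus pixel count), which protects the
one-pixel central bin from spurious hollowness calls.  Averaging the
29-particle set divides the effective noise by √29 before the same
assessment.

As a cross-check, the built 60 nm tetramer is projected end-on
(Cα 2-D histogram, Gaussian-smoothed, protein-high polarity: the
annular protein wall is the bright ring, mirroring the stain-exclusion
ring of real negative-stain views); the resulting profile is classified
hollow with its peak within 20% of the supercoil radius.

## Problem sizes and defaults

Default runs use full-scale problem sizes throughout: 106-residue
repeats, 37 repeats per strand (74-repeat tetramers, ~7.8k Cα), 130
lengths in the 55–184 nm sweep, 12 roll values, 29 ring particles, 20
refinement starts.  Parameter-recovery tests use 5 refinement starts
per seed and 5 seeds per angle to keep the suite quick; the refinement
protocol itself is unchanged.

## Known limitations

- Repeats are idealized bundles: surface detail, sequence variation
  (real repeats differ by 1–2 residues) and side chains are absent, so
  steric windows and crosslink geometry are qualitative analogues of
  the real system, not re-measurements.  In particular the printed
  2.2 nm EM ring radius is validated by parameter recovery on
  synthetic images, never re-measured from micrographs.
- The lateral register of the two strands in the *extended* two-strand
  model and the absolute roll sign are conventions, stated above.
- The stain model is additive ring + Gaussian noise; defocus, CTF and
  real stain texture are out of scope.
- Chain linkers in multi-repeat chains are schematic connectors;
  dihedral-level linker work happens only in the refinement module.
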