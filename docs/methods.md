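# Methods

## Model and scope

`fgbrush` works at one bead per residue: the backbone (Cα) bead carries all
chain geometry, and optional per-residue side-chain beads are carried
through only where they matter (residue–residue distances and solvent
accessibility both take the minimum / sum over all beads of a residue, so
they reduce to the backbone definitions on single-bead inputs). All
internal coordinates are Angstrom; nanometre values are accepted in YAML
config (keys ending `_nm`) and converted once at the boundary. Residue
numbering is 1-based in all I/O and reports. The brush axis is z for array
and bath geometries, and the ring axis is z for ring geometry.

The package deliberately contains no force field and no dynamics: it
builds *initial* states and analyses *given* bead configurations
(single frames or trajectories). Energetic or diffusive transport is out of
scope — the pore analysis answers only the geometric question of the
largest sphere that can pass.

## Worm-like-chain self-avoiding walk

Chains grow bead by bead under two local restraints — bond length
3.7 Å between consecutive beads and a fixed bend angle for every bead
triple — with the dihedral drawn uniformly on the allowed circle. The bend
angle defaults to 127°, the conventional coarse-grained backbone angle for
coil conformations, and is a config knob since published coil conventions
vary. Excluded volume is enforced by rejection: a candidate bead closer
than 8 Å to any bead of another chain, or to a bead of its own chain at
sequence separation greater than 2, is redrawn. The two-neighbour
exemption is forced by the geometry itself: bonded beads sit at 3.7 Å and
the angle fixes next-nearest neighbours at ≈ 6.6 Å, so a literal 8 Å rule
over all pairs would reject every chain. The exemption window is
configurable.

Failure policy (all configurable): 50 dihedral redraws per residue, then
backtrack 5 residues, then whole-chain restart (up to 100), after which a
`GrowthFailure` reports the deepest residue reached. Identical seeds give
bit-identical chains.

Multi-chain assemblies grow chains sequentially in a randomized order,
each chain seeing all previously grown chains as obstacles; the
randomized order avoids a systematic bias toward early chains, about which
nothing else is assumed. Tethered chains (ring, array) grow from the
anchor into the +z half-space and are stored with the C-terminal residue
at the anchor; the bath seeds each chain with a rigid three-bead fragment
(proper bond length and angle) at a uniform random position and
orientation in a periodic box, with all clash distances taken under the
minimum-image convention. Tethering is modelled as a rigid anchor of the
C-terminal residue; the cysteine linkers such constructs use
experimentally can be appended as sequence (`--append-cys`), but the
chemistry is out of scope — only the geometric constraint matters for the
analyses. Bath packing is screened before growth: if the bead excluded
volume exceeds a 0.35 packing fraction the builder refuses with the
attempted value, since rejection sampling would not terminate.

Ring layout: n_chains/n_rows anchors per row on concentric circles in the
z = 0 plane. By default the innermost radius is derived from the anchor
spacing, r = s / (2 sin(π/n_per_row)) (≈ 382 Å for 40 anchors at 60 Å), so
that the minimum anchor separation equals the requested spacing exactly;
a fixed radius can be supplied instead and is rejected when its chord falls
more than 1 % below the requested spacing. Outer rows sit row_spacing
(default 60 Å) further out. All geometry parameters are recorded in output
metadata.

## Bundle / cross-link decomposition

Contact rule: residues of different chains at distance < 6 Å (strict; a
pair at exactly 6.0 Å is a non-contact) are connected; the distance is the
minimum over the residues' beads, minimum-image when periodic. Each contact
endpoint is then connected to its immediate (±1) sequence neighbours. This
widening is applied once, not transitively — transitive application would
merge entire chains and erase the bundle/cross-link distinction the method
exists to draw. Neighbour search uses a k-d tree but is validated in the
tests against a brute-force all-pairs union-find oracle for exact equality.

Components with ≥ 2 distinct chains are bundles ("multiple parallel
chains"); single-chain components and isolated residues are cross-linking
region. No operational test of "linearly arranged / parallel" is imposed —
connectivity alone defines bundlehood, matching the graph procedure as
stated; a descriptive principal-axis elongation score is reported per
bundle but never used as a filter. Cross-link events are maximal
cross-link-labelled runs of one chain whose two flanking residues both lie
in bundles (possibly the same one).

Thickness histograms over a trajectory window are computed per frame,
normalized per frame to sum 1, then averaged so every frame carries equal
weight; averaging raw counts instead is available via a flag since either
convention is defensible. Amino-acid bundle propensities pool FG-motif
residues into `FG` / `FxFG` categories (for FxFG, its two F and its G; the
variable x residue stays under its own letter) and report non-motif F and
G as `F*` and `G*`.

Motif annotation scans left to right without overlap, with the
four-residue FxFG pattern taking precedence over a plain FG at the same
locus; GLFG-type repeats are reported as the FG they contain rather than
as a separate class.

## Pore characterization

The clearance lattice (default spacing 2 Å, about half a coarse-grained
bead radius) stores at each node its exact nearest-bead distance (k-d
tree, validated against a brute-force scan). By default beads are treated
as points, following the clearance definition as the shortest distance to
protein beads; a `subtract_radii` mode subtracts per-bead radii and clamps
at zero for physical realism. An empty frame gets the domain diagonal as
clearance cap.

The widest-bottleneck (maximin) path uses a Dijkstra variant: a max-heap
keyed on the best-known value B(v) = max over source→v paths of the
minimum clearance along the path, endpoints included; ties break on flat
node index so the witness path is reproducible. The default connectivity
is 6 (face neighbours) — a sphere moving between face-adjacent nodes stays
within clearance up to a spacing-bounded error, while 26-connectivity is
offered but optimistic at corners. Results always carry a ± one-spacing
accuracy statement.

The grid covers the analysis domain (the box for bath geometry, else the
bead bounding box) plus one margin layer; path search excludes the margin
in the non-permeation directions so a sphere cannot trivially walk around
the structure outside the original walls. Axial analysis uses the full
entry and exit faces as source and sink. Radial analysis (ring
geometries) sources from a cylindrical core of radius ¼ × inner radius
and sinks at a shell beyond the outermost bead; because the bottleneck
includes its endpoints, the lateral domain is padded
(max(4 × spacing, 0.4 × inner radius) by default) so the sink shell sits
in open space — without the padding the sink would hug the outer wall and
cap every bottleneck at the wall clearance regardless of the actual pore.
Window statistics report per-frame radii with mean and sample (ddof = 1)
standard deviation; a window of one frame reports std 0.

## Brush height, Rg, solvent accessibility

Brush height is |z_last − z_first| of the backbone beads per chain
(tether residues included when present), averaged over chains. Radius of
gyration is the RMS bead distance from the unweighted centroid; for N
equally spaced collinear beads it equals b·sqrt((N²−1)/12), which the
tests use as a closed-form oracle.

SASA uses Shrake–Rupley sphere-point quadrature over the coarse-grained
beads (via biotite, with per-bead-kind radii), 960 points per bead by
default (≤ 1 % quadrature error on an isolated bead against 4π(R+p)²).
Bead radius defaults to 2.3 Å and the probe to 2.6 Å — a coarse-grained
water bead; use 1.4 Å for atomistic realism. Both are config because no
single published convention fixes them for one-bead-per-residue models, so
absolute SASA values are convention-dependent; the meaningful output is the
*comparison* — the first phenylalanine of each FG/FxFG motif grouped by
bundle vs cross-linking region, where burial in a bundle must depress
accessibility. Groups with no members are omitted rather than reported as
NaN.

## Synthetic data: what it emulates, what it does not

The planted fixtures emulate the three structural motifs the analyses must
detect: parallel-chain bundles (straight chains on a close-packed lattice
below the contact cutoff), single cross-linking chains that leave one
bundle, traverse free space with a guaranteed clearance margin, and join
another (or the same) bundle, and channel phantoms — bead walls whose
narrowest cross-section has a known clearance radius, built from beads so
the pore algorithm runs through exactly the code path used on real frames.
Ground-truth labels are derived from the construction geometry (contact
runs plus the one-residue adjacency widening), never by running the
analysis being tested, and a construction-time brute-force check rejects
any requested routing that would violate the planted margins instead of
emitting wrong truth.

The fixtures do **not** mimic relaxed molecular-dynamics ensembles: chains
in fixtures are straight, contacts are regular, bead densities are far from
equilibrated brushes, and no thermal disorder is present beyond the
optional `jitter` operation (which displaces beads i.i.d. without
re-enforcing constraints). Passing the planted-recovery suites therefore
demonstrates the correctness of the graph and lattice algorithms, not that
real FG-nup assemblies form such structures.

## Problem sizes and numerical choices

The test and acceptance workloads use 50 × 100-residue SAW ensembles,
contact frames of ≤ ~200 residues for oracle equality, 8³–12³ lattices for
widest-path oracle equality, and phantom radii 5–40 Å at 2 Å lattice
spacing — sizes chosen so every check runs from scratch in seconds while
still exercising each code path; all builders and analyses accept the
full-scale parameters (120 × 614-residue assemblies) unchanged. Degenerate
inputs are defined rather than special-cased: an empty frame writes a
header-only PDB and yields a domain-capped clearance field; a solid wall
reports a pore radius below one lattice spacing; a single chain is never a
bundle. PDB output refuses coordinates outside the fixed-column range
rather than truncating, and frames with more than 62 chains split across
`_partNNN` files because the PDB chain-id column holds one character.

## Known limitations

- The SAW uses a fixed bend angle rather than a bending potential, so
  local stiffness is idealized; only the coil-level statistics are
  meaningful.
- Sequential multi-chain growth samples a biased subset of the joint
  excluded-volume ensemble (later chains grow in a more crowded
  environment); the randomized order removes anchor-position bias but not
  this density effect.
- The pore size is purely geometric and static per frame; a flexible mesh
  would admit larger cargo than the frozen-frame bottleneck suggests.
- 6-connectivity slightly underestimates and 26-connectivity slightly
  overestimates the continuous-space bottleneck; both converge with
  lattice refinement, and the reported ± one-spacing accuracy bounds the
  discretization error observed on phantoms.
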