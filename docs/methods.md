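# Methods

This note records the models, conventions and numerical choices behind
`dmportrait`, and what the synthetic fixtures do and do not emulate.

## Atomic parameters

Heavy atoms are typed by (residue name, atom name) against a shipped
table of Wildman–Crippen atomic logP contributions
(`data/wildman_crippen_residue_logp.json`).  The table is generated
(see `scripts/make_hydrophobicity_table.py`) from Gly-X-Gly tripeptides
so backbone atoms are typed in a peptide-bonded context, with every
hydrogen's contribution folded onto its bonded heavy atom.  This
united-atom convention lets deposited cryo-EM models, which carry no
hydrogens, be mapped without a protonation step; explicit hydrogens, if
present, contribute zero (their share is already counted).  Terminal
carboxylate oxygens (OXT) get the C-terminal glycine value; charged
N-termini are typed like chain nitrogens, a deliberate simplification
that touches two atoms per chain.  Van der Waals radii are an
element-based Bondi set (`data/vdw_radii.json`); all geometry reads
radii from the atom records only, so swapping the radius table is a
data change, not a code change.

## MHP field

`MHP(j) = Σ_i f_i exp(−r_ij / 2)` over protein heavy atoms with
`r_ij < 9 Å`; the cutoff is a hard truncation (no shifting), and the
inequality is strict.  Waters, ions and other heteroatoms never
contribute.  For multimeric pores the sum is split by the subunit that
owns the surface point (the subunit of the atom the ray hit): *self* =
own subunit, *induced* = all other subunits, and the reported total is
defined as their sum, which makes the decomposition identity exact by
construction.  Whether "induced" should include only the neighbouring
S6 segments or whole neighbouring subunits is genuinely open; whole
subunits are used, and the contributor set is a parameter
(`contributors` in `trace_map`) for users who want the narrower
reading.

## Cylindrical projection maps

Rays start on the local axis point, run orthogonal to the local axis
tangent through the nodes of a regular (z, θ) grid (defaults 0.5 Å,
2°), and stop at the nearest intersection with a van der Waals sphere.
The traced surface is the VdW surface, not the solvent-excluded one.
Intersection search uses a voxel grid (3 Å voxels) with
Amanatides–Woo 3DDDA traversal and early exit once the best hit lies
inside the voxel span already covered; a brute-force all-spheres scan
is the test oracle.  Tangent rays count as hits; a ray born inside a
sphere hits its exit point.  When the angular grid divides into
quadrants, the direction vectors of quadrants 1–3 are exact
quarter-turn images of quadrant 0, so C4-symmetric input yields maps
periodic to rounding error — a property the tests exploit.

1D profiles are the per-z mean of map values over non-miss angular
nodes ("integration over the rotation angle").  A mean rather than an
area-weighted sum is used; rows with no hits are flagged undefined
rather than zero-filled.

Single-helix maps use a straight axis through the helix Cα centre of
mass along the long principal axis of the Cα gyration tensor (sign
towards +z).  The map property is self MHP (own-subunit contributors
only), and contact zones are map nodes whose hit point lies within 7 Å
of any atom of the configured neighbour-residue range on the other
subunits.

## Pore radius

The axis is an interpolating spline (cubic where enough control points
exist) through the centres of mass of Cα quadruplets of the configured
axis residues, parameterised by z.  The radius at z is the largest
sphere placeable without VdW overlap, with the centre free to move in
the plane normal to the local tangent: a coarse 0.25 Å grid pre-search
locates the basin and Nelder–Mead polishes it, under a box constraint
(default ±2.5 Å) enforced by a linear penalty — the step limit keeps
the sphere in the lumen instead of escaping through inter-helix gaps,
which matters for narrow bundles.  Radii above 15 Å are capped and
flagged.  R_gate is the exact minimum over the gate region (ties:
lowest z reported).  Default z-step 0.25 Å.  Channel configs translate
gate residues to a z-window as Cα z ± 4 Å.  Against a dense grid
oracle the optimiser agrees to 0.05 Å on random systems; agreement
with published gate radii is expected at the 0.1–0.2 Å level because
the exact search parameters of the original profiling programs are not
published.

## Environment classes and 3D–1D scores

Per-residue features are computed in the full assembly with
Shrake–Rupley accessible areas (1.4 Å probe, biotite backend, shipped
radii): buried side-chain area = reference area − exposed area, where
the reference is the side-chain area of X in an *extended* Gly-X-Gly
tripeptide built by the package's own chain builder (self-consistent,
deterministic); glycine's "side chain" is its Cα.  The polar-covered
fraction is measured operationally: recompute the side-chain area with
all surrounding polar (N, O) atoms deleted, and take the area gained,
divided by the buried area (clipped to [0, 1]).  Waters are excluded
from the environment.  Secondary structure comes from a Cα-geometry
assignment (P-SEA via biotite) mapped to helix/sheet/other.  Class
thresholds (exposed < 40 Å² buried; partial < 114 Å²; polar splits
0.67, and 0.45/0.58 for buried) are shipped as data.

The residue/class score table shipped here
(`data/score3d1d_synthetic.json`) is **synthetic**: a documented
log-odds-style compatibility model (side-chain hydrophobicity vs class
burial and polarity, plus a small secondary-structure propensity),
generated by `scripts/make_score_table.py` and identified by name and
sha256 in every profile's metadata.  Correlation structure between
states — the quantity the analyses rest on — is meaningful under any
monotone-reasonable table; absolute score values are not comparable to
published 3D–1D scores.  Profiles are averaged over the four subunits;
missing residues are omitted, never zero-filled, and correlations drop
unpaired positions (≥ 3 required, zero-variance profiles rejected).

## ESA and densities

The molecular surface is a per-atom Fibonacci sampling of the VdW
sphere with probe-rolling rejection (a point survives if a 1.4 Å probe
along its outward normal clears all other atoms); each point carries
area 4πR²/n.  Default density 5 points/Å² (tests often use 2–3 for
speed).  Re-entrant probe patches are not generated; the isolated-
sphere area is exact and partial burial is resolved at the sampling
resolution.  Exact duplicate atoms are merged before sampling.

A surface point is water-exposed in a frame when a water oxygen lies
within 1.4 Å of it (the criterion is taken literally).  The analysed
region between the selectivity filter and the gate is an axial window
from the boundary residues' Cα z, recomputed per frame; the surface is
rebuilt from each frame's coordinates by default.  ESA(z) uses 1 Å
bins, the ESA-vs-MHP distribution 0.1 logP bins; ESA_H is the MHP > 0
part.  ΔESA between states is the difference of replica means of the
region-integrated areas (B − A), with the per-state replica standard
deviations combined in quadrature; at least two replicas per state are
required.

Density fields are frame-averaged particle counts per 1 Å³ voxel, so
the grid integral equals the mean particle count; axial profiles count
particles inside a pore cylinder (default 8 Å).  Permeation counts
full traversals of the gate interval with 2 Å hysteresis buffers past
each end, which suppresses boundary recrossing noise; reversing a
trajectory preserves the count and flips the direction label.

## π-bulge and state calls

Backbone H-bonds use the DSSP electrostatic model, E = 0.084·332·(1/r_ON
+ 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bonded when E < −0.5; the amide H
is placed 1.0 Å from N along the preceding C=O direction, so the
detector works on hydrogen-free models.  A π-bulge is ≥ 2 consecutive
residues accepting i→i+5 bonds.  The state rule table uses gate-width
brackets wide ≥ 2.0 Å / narrow ≤ 1.5 Å — heuristic brackets between
the reported open (≈ 2.8–2.9 Å) and closed (≈ 0.5–1.3 Å) regimes — and
treats a wide α-helical gate as transitional rather than open, since
extended hydrophobic α-gates dewet.  Hydration/conduction evidence may
be unknown for static input; the call is then flagged low-confidence.
The full discrete rule domain is enumerated by `rule_table()` and
tested exhaustively.

## Synthetic fixtures

Monomers are ideal helices from internal coordinates (N–Cα 1.458,
Cα–C 1.525, C–N 1.329 Å; α = (−57°, −47°), π = (−57°, −70°), the
latter verified to produce clean i→i+5 bonding) with heavy-atom side
chains grafted from CCD ideal residues.  Four copies are placed by
exact quarter-turn rotations, giving bit-exact C4 symmetry, and the
radial placement is calibrated by secant iteration against a dense-grid
inscribed-sphere measure over the constriction band until the minimal
pore radius matches the target (the HOLE-style profiler independently
confirms recovery within 0.1 Å).  The default 22-residue sequence puts
an Ile ring at the constriction and an Asn ring one helix turn above
it, with Leu/Ala elsewhere — the canonical π-state gate architecture —
and a polar variant swaps Ser/Asn onto the lumen face, flipping the
sign of the gate-band MHP.

Pseudo-hydration frames place water oxygens uniformly at random in a
lumen cylinder each frame (default 0.3 Å⁻³ — deliberately denser than
bulk water because uniform placement lacks the contact-shell packing
of real water; with the strict 1.4 Å contact criterion this density
wets reachable surfaces reliably), optionally excluding a dry z-band;
ions sit on the axis or walk along it; protein coordinates get seeded
Gaussian jitter (default 0.05 Å).  These frames reproduce the
*identities* of the trajectory analyses (frame averaging, area
conservation, saturation bounds, crossing counts) but none of the
physics: no hydrogen bonding, no dewetting transitions, no ion
coordination.  Tests passing on them validate the bookkeeping and
geometry of the ESA/density/permeation machinery, not the
thermodynamics of real pores; published ΔESA or conduction numbers can
only be reproduced from user-supplied MD trajectories.

## Problem sizes

The shipped tests and the acceptance script run on 14–22-residue
four-helix bundles (≈ 350–520 heavy atoms), 2–12 frame series, maps of
up to 180 × 51 nodes, and 1000-ray tracer oracles; these sizes were
chosen so the whole stack, including calibration, completes in a few
minutes on one CPU while every identity is still sharply testable.

## Known limitations

* The polar-covered fraction is an operational reading of the classic
  environment-class definition; other readings (e.g. per-point contact
  assignment) would shift class boundaries for marginal residues.
* The synthetic 3D–1D table (above) replaces the published one.
* Helix-axis estimation tilts slightly off the true screw axis for
  non-integer turn counts.
* The radius profiler enforces no path continuity between adjacent z
  planes (each plane is optimised independently).
* mmCIF/PDB reading resolves altlocs to highest occupancy and ignores
  insertion codes beyond author numbering.
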