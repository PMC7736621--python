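# Methods

This note documents the models, conventions and defaults behind
`synmorph`, and what the synthetic validation does and does not show.

## Coordinate and measurement conventions

All coordinates are nanometers. Scenes use a right-handed frame with the
presynaptic membrane reference plane at z = 0 and the cytoplasm at z > 0,
so invagination depth and vesicle height are plain z coordinates and depth
signs are unambiguous.

Vesicles are spheres; the membrane-to-membrane gap to an AZ is the exact
Euclidean distance from the center to the triangulated AZ surface minus
the radius. For spherical vesicles this equals the outer-leaflet-to-surface
distance, and the polyhedral distance itself is exact (vertex, edge and
face cases), computed with the standard closest-point-on-triangle region
analysis plus a conservative bounding-sphere cull that cannot change the
result. Negative gaps — interpenetration from segmentation jitter — clamp
to 0 for binning ("docked" means no measurable separation), while the raw
signed value is kept for quality control.

Distance bins [0, 2, 5, 10, 40, 60, 100] nm are closed on the right with
ties going to the lower bin, so the docked bin is exactly the [0, 2] nm
interval and cumulative counts are monotone by construction. The SV/GV
boundary is literal: diameter < 60 nm is an SV, 60 nm exactly is a GV, and
a prominent dense core overrides size (DCV). Densities are counts per µm²
of AZ area in 3D and counts per 100 nm of AZ profile length in 2D.
Normalization to the unstimulated control divides each per-AZ metric by
the control-condition mean, which therefore maps to 1.0.

## Pit model and morphometry

The generator's pit is a sphere of radius R joined to the membrane by a
cylindrical neck of pore radius p ≤ R and length L ≥ 0, giving closed
forms D = 2R, P = 2p, I = L + R + sqrt(R² − p²) and membrane area
2πR(R + sqrt(R² − p²)) + 2πpL. Three interpretable parameters span the
observed shape regimes: shallow D/P ≈ 1 caps are the L = 0, p → R limit,
and narrow-pored near-budding omegas the p ≪ R limit.

Measurement does not use the parameters. The surface is sliced into
height slabs of roughly one mesh edge; D is the largest lateral extent of
any slab, P the smallest extent at or below the D slab (the opening), and
I the tip height above the membrane plane, taken along the membrane
normal at the pore — a locally planar reconstruction of the membrane had
it spanned the pore. A surface that does not reach the membrane plane has
no identifiable pore and is rejected. In 2D the same slab logic runs on
section contours; sectioned D and I are provably ≤ their 3D values, which
the stereology tests confirm, so 2D morphometrics underestimate.

D/P classes are half-open with ties up: =1 (within a ±0.05 tolerance band,
since a measured ratio of exactly 1 is unattainable on meshes), 1–1.5,
1.5–2 (so a ratio of exactly 2 falls here), and > 2. The near-budding flag
is D/P > 1.5 with P < 100 nm. The pore center used for peri-AZ zoning
(≤ 200 nm from the nearest AZ boundary edge, closed at 200) is the
centroid of the minimal-width cross-section. Coated versus non-coated is
an input annotation, never inferred.

## Missing wedge and surface completion

A tilt range of ±t° leaves a blind region around the beam axis; faces
whose normals lie within (90 − t)° of the beam axis are flagged invalid.
The blind region is modelled as a cone, which slightly over-occludes
relative to the true single-axis wedge but depends on one parameter only.
Completed pit areas add, to the valid-face area, the invalid faces
projected radially onto a least-squares sphere fitted to the valid
vertices (algebraic fit refined by Gauss–Newton). With no occlusion the
completed area equals the mesh area exactly; meshes with under 40% valid
faces are rejected, and a degenerate fit (e.g. a planar patch) falls back
to the valid-face area with a warning. Whether this matches the spherical
interpolation implemented inside segmentation tools such as IMOD is
untested; it is this package's own stand-in for that step.

SV-equivalents divide a membrane area by π·(46 nm)², the surface of a
sphere at the mean docked-SV diameter; both the raw value and a rounded
count (floor 1 once raw ≥ 0.5) are reported.

## Synthetic scenes: what they emulate and what they do not

Scene defaults describe a well-powered resting hMFB active zone: one AZ of
0.08 ± 0.008 µm² (planar by default; spherical-cap curvature available),
30 SVs within 100 nm of the AZ with truncated-normal diameters
46 ± 5 nm, 3 GVs (75 ± 8 nm), 1 DCV, docked fraction 0.30 with membrane
gaps uniform on [0, 2] nm, undocked gaps uniform on (2, 100] nm, and
Poisson pit counts with R ≈ 44.7 ± 8 nm, p/R uniform on [0.35, 1],
L uniform on [0, 30] nm. Real docked-gap and undocked-distance
distributions are unknown; these are tunable placeholders, and the
docked-fraction and counts were chosen (from a power calculation, before
any validation run) so that the prescribed three-condition contrast — a
40% docked-density reduction at n = 25 AZs per condition — is detectable,
which is the regime the validation suite exercises. Published per-AZ
docked counts in this synapse type are lower and their contrasts were
partly non-significant at comparable n; passing the power test therefore
says the pipeline detects the effect under these conditions, not that any
real experiment at this n would.

Meshes default to ~2 nm edges for pits (comparable to the 1.554-nm
tomographic voxel; measurement tolerances are stated as 2× edge length)
and coarser edges for planar surfaces, which planarity represents exactly.
Sections are 60-nm slabs cut across the membrane: AZs appear as mid-slab
polylines, a sphere appears with its largest in-slab chord as apparent
diameter, and a pit contributes a connected omega contour only when the
slab's mid-plane cuts its neck. The "clear-cut membrane" inclusion rule
keeps AZ profiles whose surface tilt against the section plane stays below
30° (a configurable stand-in for an unstated visual criterion). No image
densities are rendered — the generator emulates segmented geometry, not
tomograms — so nothing here validates membrane tracing or detection.

Nuclei images are blurred noisy disks on a flat background: channel 0 a
nuclear stain, channel 1 a per-nucleus marker intensity drawn from a
positive or negative normal (defaults 120/40 ± 10 at background 10, well
within 8-bit depth). Nuclei in a left-strip "background" region are all
marker-negative, emulating nuclei outside the principal cell layer that
define the threshold. Placement enforces ≥ 2.4 mean radii separation, so
the watershed's count recovery is demonstrated for touching-but-resolvable
nuclei, not for dense clumps.

## Statistics

The gate runs a per-group one-sample KS test against a normal with
moments estimated from that group; all groups must pass (α = 0.05) for
the parametric branch. Plain KS with estimated moments is anticonservative
(it under-rejects, so the parametric branch is favored); a
Lilliefors-corrected switch is provided and documented, but the plain test
is the default because it is the stated procedure. The parametric branch
is one-way ANOVA with all-pairs t-tests, Welch by default (group variances
visibly differ in this kind of data) with a pooled-variance switch; the
nonparametric branch is Kruskal–Wallis with Dunn's all-pairs z-tests using
the tie-corrected rank variance. Both branches Bonferroni-adjust over all
pairwise comparisons of the metric. Under a 3-group normal null the full
gated procedure's family-wise error measures ≈ 4% (Bonferroni's
conservatism with correlated pairs), inside the 5 ± 1.5% acceptance band.

## Numerical and reproducibility choices

Sphere fits require ≥ 4 non-coplanar points and reject near-singular
systems ("sphere underdetermined"). Zero-area faces are dropped at mesh
construction; empty surfaces are errors. All generators are pure functions
of (spec, seed); the pipeline spawns per-condition, per-bouton child seeds
from one top-level seed, writes it into every manifest, and its output
bundles are byte-identical across reruns. Validation problem sizes — 200
pits, 10 scenes for pool recovery, 1000 section offsets, 50 power runs,
2000 null replicates, 20 nuclei images — were chosen as the package's own
balance between Monte-Carlo error and desk-scale runtime.

## Known limitations

* The wedge model is a cone, not the true single-axis wedge.
* 2D pit profiles are emitted only for neck-cutting sections; grazing
  cuts that would show a detached circle are dropped rather than scored.
* The generator places vesicles over the AZ footprint only, so lateral
  vesicle populations beyond the AZ rim are not emulated.
* Coat morphology, vesicle detection from densities, tomogram
  reconstruction and electrophysiology are out of scope; labels arrive
  as annotations.
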