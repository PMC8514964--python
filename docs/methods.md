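# Methods

`lungstereo` implements the complete design-based stereology cascade used to
quantify neonatal lung structure — Cavalieri lung volume, point-grid volume
densities, line-grid surface density, physical-disector (Euler characteristic)
alveolar counting, and the derived thickness/intercept/size identities — and a
synthetic voxel phantom whose every target quantity is known exactly, so each
estimator can be validated against brute-force ground truth instead of against
another stereological estimate.

## Estimators

All estimators are the classical design-based identities, applied to pooled
counts per lung and only then combined into derived quantities (per-animal
first, then group statistics):

| quantity | identity | counts |
|---|---|---|
| volume density | `V_V = P / P_ref` | test points on structure / reference |
| total | `X = X_V · V(ref)` | cascade from the Cavalieri lung volume |
| surface density | `S_V = 2I / (P_ref · l/p)` | intersections of test lines with the septal boundary; accounted line length is points × length-per-point (coherent grid) |
| septal thickness | `τ = 2V/S` | both faces of a septum belong to the airspace-facing surface |
| wall/sheath thickness | `τ = V/S` | one-sided endothelial reference surface |
| mean linear intercept | `Lm = 4V(air)/S(sept)` | duct + alveolar airspace, edema included |
| vessel diameter | `d = 4V(lumen)/S(endothelium)` | exact for cylinders, any obliquity |
| alveolar number | `N_V = Σ(I−B) / (2·V(dis))`, `N = N_V·V(par)` | bidirectional islands minus bridges; each closed cavity contributes one island per direction |
| mean alveolar volume | `v_N = V(airalv)/N` | number-weighted |

Counts and grid constants are handled in µm; reported volumes are cm³,
surfaces cm², densities cm⁻¹/cm⁻³, thicknesses µm. Grid constants follow
standard practice for this kind of study: a 36-point grid for coarse volume
densities (with a 4:1 coarse tier available for larger reference spaces), a
12-line grid with l/p = 9.37 µm for the septal surface, a 12×9 line grid with
l/p = 18.74 µm and a 16×16 point grid for vessels, a counting frame of
35 570.40 µm², a 4.5 µm disector height, and a >25 µm short-axis calibre
cutoff for vessel profiles.

## The phantom

A phantom is a fully labelled voxel block (default 1.5 µm voxels) standing in
for a fixed, resin-embedded neonatal lung:

* **Parenchyma** — a septal-tissue matrix carved with spherical cavities on a
  cubic lattice. 70% of lattice sites are individually identified alveoli,
  30% ductal airspace of the same calibre. Spheres are deliberate: every
  target quantity has a closed form, and an isotropic cavity population makes
  single-orientation test-line counting unbiased. Each (y,x) column of cells
  carries an independent uniform z-phase ("stagger"): a coherent lattice
  would alias with thin sections and inflate between-section variance several
  fold, while lateral spacing alone already guarantees the septal gap.
  The cavity radius is solved from the preset's septal-thickness and
  number-density targets on the nominal lattice cell, so mean alveolar volume
  is a pure function of the preset. Intra-alveolar edema is a concentric
  fluid ball (relative radius 0.75) in a random subset of alveoli, with an
  optional inflammatory-cell core; both are measured inside the airspace.
  `duct_open` mode adds one cylindrical mouth per alveolus into its nearest
  duct; number estimation in that mode is experimental (mouth openings change
  the Euler bookkeeping) and only `closed_cell` is validated.
* **Nonparenchyma** — a bronchovascular column of conducting-airway tissue
  threaded by near-axial cylindrical vessels (lumen, concentric wall,
  concentric perivascular sheath, flat wall caps). A whole "lung" is the two
  compartments side by side; block depth realizes the animal's lung volume.

**Ground truth.** Volumes are exhaustive voxel tallies. The ground-truth
surface is 3-axis transition (Crofton/Cauchy) counting — the same measurement
theory the 2I/L estimator realizes; on digitized spheres it agrees with
4πr² to better than 1%. A `faces` option (boundary voxel faces) is exact for
axis-aligned plates and is what the plate-identity check uses; face counting
overestimates curved isotropic surfaces by up to 50% and is not the default.
Mean thickness and diameter use the same V/S identities as the estimators, on
true totals.

## Group presets

The two presets (`normoxia`, `hyperoxia`) are derived from the embedded
reference table of group means (n = 8 lungs per group) for the preterm-rabbit
hyperoxia model of bronchopulmonary dysplasia. The phantom is a miniature
lung (~7·10⁴× smaller by volume), and a sphere packing cannot reach the ~86%
airspace fraction of real parenchyma — the thinnest mean septum a sphere
lattice can realize is about 0.6× the cavity radius. The presets therefore:

* keep **ratios** for septal thickness (2.03), number density, and lung
  volume (normoxia anchors: τ = 44 µm, N_V = 4.2·10⁻⁶ µm⁻³, V = 5.3·10⁷ µm³);
* share **one alveolar size** between groups: the reference study found no
  significant difference in mean alveolar volume or Lm, so the generative
  model assigns a common cavity radius. With a shared radius the
  sphere-lattice identity couples number density to septal thickness, which
  fixes the preset N_V ratio at 0.59 (the observed, non-significant N_V
  contrast of 1.13 is geometrically unreachable in this family);
* keep vessel dimensions **absolute** (lumen 76.3/60.1 µm, wall 4.80/6.03 µm,
  perivascular 9.93/19.53 µm), since individual vessels are resolvable at
  phantom scale;
* use the reference table's edema fractions (0.027/0.151 of total airspace)
  directly.

Between-animal variability multiplies each preset field by an independent
lognormal factor whose CV matches the corresponding reference row. Draws are
clamped at physical feasibility (septal packing floor, concentric-ball edema
capacity, vessel calibre at the column width); only extreme tails are
affected.

## Sampling design and scale

Slab-level SURS cuts the block into 30 µm slabs and keeps every other one
from a random start slab; one section per kept slab enters the Cavalieri
estimate with a weight proportional to its slab's (possibly clipped)
thickness. Field-level SURS places fields on a square lattice with a uniform
random offset.

Real-lung area sampling fractions (fractions of a percent at high
magnification) are tied to real-lung dimensions: applied to a ~400 µm block
they would return near-empty samples whose ratio estimates are degenerate.
The default `SamplingPlan` therefore scales the fractions so the *counted
totals* per lung match the order of magnitude of the real design
(~25–50 fields, thousands of points, ~10³ intersections, ~30 disector
windows, tens of Euler events per lung). A stage whose grids miss the
specimen entirely redraws its offsets — a zero-information sample is never
accepted.

Disector pair positions run on a full periodic plane lattice spanning the
block (12 µm period, 4.5 µm height); windows hanging past a face see empty
sections and contribute their in-block volume share only. Counting frames
tile each sampled position and may extend past the section onto the empty
slide canvas, so border profiles keep their full acceptance measure. The
frame rule (left+bottom forbidden edges with extensions) is implemented in
its exact set form and is tiling-exact for convex profiles; island/bridge
correspondence is judged on the whole sections, never inside the frame crop.
The accumulated disector volume uses exactly the pixel windows the counting
rule used, weighted by each frame's parenchymal area fraction and each
window's in-block axial fraction.

With this design, the mean of every parenchymal estimate over 200 seeded
sampling repetitions of one 256³ phantom lies within 3 standard errors of the
voxel ground truth (the acceptance suite recomputes this).

## Statistics

Per parameter: Shapiro–Wilk normality at α = 0.05 in each group; if both pass,
a two-sided equal-variance Student's t-test (Welch available via
`equal_var=False`), otherwise the Mann–Whitney rank-sum test; significance at
p ≤ 0.05 with no multiple-testing correction. This mirrors conventional
morphometry practice and is recorded per row for auditability; it is a
faithful-reproduction choice, not a statistical endorsement.

## Numerical choices

* Dominant-label projection for finite-thickness sections (deterministic,
  first-max tie-break); a nominal thickness at or below one voxel maps to
  exactly one plane, so thin sections never mix planes.
* 8-connectivity for airspace profiles (septa implicitly 4-connected);
  k-fold merges count k−1 bridge events.
* Pair correspondence by nonzero pixel overlap — valid because the disector
  height (4.5 µm) is small against the cavity calibre (~40 µm); profiles of
  different cavities can coincide only through the rare tail of the lattice
  jitter.
* Vessel profile diameter is the minimum-Feret (short-axis) caliper of the
  lumen via rotating calipers on the convex hull — invariant to cut obliquity
  for cylinders. Profile boundary length uses the 2D Cauchy (two-axis
  intercept) measure.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical seeds give bit-identical outputs.

## Known limitations

* Real alveoli are space-filling polyhedra; spheres cannot reproduce the
  absolute septal thickness (5 µm) and airspace fraction (86%) of real
  parenchyma simultaneously, so parenchymal absolute values live at phantom
  scale while contrasts track the reference ratios. Passing tests demonstrate
  estimator correctness, not histological realism.
* Vessels are near-axial, not isotropic: in-plane test lines overestimate
  their endothelial surface by up to 4/π and the Crofton ground truth
  underestimates it by ~15%, so absolute vessel surface/diameter/thickness
  values carry systematic offsets that are shared by both groups (contrast
  directions are preserved). An isotropic-orientation vessel population does
  not fit inside a narrow bronchovascular column.
* The simulated total-number contrast (hyperoxia/normoxia ≈ 0.33) is steeper
  than the reference contrast (0.62): with a shared alveolar size, doubling
  the septal thickness forces the number density down by the lattice
  identity. The significance *pattern* of the headline rows is the validated
  property.
* Tissue shrinkage, stained-image segmentation, and real-section alignment
  are out of scope: the pipeline consumes labelled rasters.
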