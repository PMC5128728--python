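# Methods

This document records the model behind `chromovol`, the synthetic-data
generator's scope, and the numerical choices that matter for the
results. Everything here describes the package's own design decisions.

## The physical model

A mitotic cell imaged by serial block-face SEM is modeled as:

* **chromosomes** — dark tubes (8-bit gray ≈ 80) around smooth space
  curves. A metaphase chromatid pair is a smooth tube with diameter
  ~N(1.15, 0.12) µm; a prophase chromosome is thinner, ~N(0.64, 0.19) µm,
  with a band-limited radial perturbation ("lumps") of relative
  amplitude 0.25 and correlation length 0.35 µm;
* **perichromosomal periphery** — a 150 nm shell of intermediate gray
  (≈ 120) coating each metaphase chromosome; absent at prophase and in
  the Ki-67-loss analogue;
* **nucleolus** — a sphere of radius 2.35 µm (≈ 54.4 µm³), lighter than
  chromatin by the observed ~36% gray-level contrast (80 vs 125);
* **nuclear envelope** — a thin dark spherical shell (radius 7.5 µm in
  the prophase field); prophase chromosomes are seeded on it, so nearly
  every object has at least one envelope contact patch;
* **background** at gray ≈ 200, plus additive Gaussian noise (sd 5)
  and 8-bit quantization.

Canonical stage conditions (the generator defaults):

| | prophase | metaphase | periphery-loss analogue |
| --- | --- | --- | --- |
| objects | 43 | 46 | 46, clumped |
| summed chromatin volume | 109.8 µm³ | 175.9 µm³ | 170 µm³ |
| diameter distribution | N(0.64, 0.19) µm | N(1.15, 0.12) µm | N(1.15, 0.12) µm |
| periphery shell | none | 150 nm | none |
| voxel pitch | (120, 48, 48) nm | (120, 48, 48) nm | (120, 48, 48) nm |

The voxel pitch is deliberately anisotropic (cutting step ≫ in-plane
pixel), which drives most of the numerical care below.

## Generator scope and guarantees

The generator exists to make the downstream chain testable, not to be
photorealistic. Its guarantees:

* **voxel-exact truth** — every voxel's label is known; truth volumes
  are voxel counts × voxel volume; truth surfaces/lengths are the
  analytic capsule values of the generating tube;
* **separability by construction** — random placement enforces at least
  one background voxel between objects (centerline KD-tree clearance
  checks with per-sample effective radii, plus a loop-back test based on
  the arc/chord ratio), and walk curvature is capped so the distance
  landscape has one H-maximum per chromosome in the h = 5–7 working
  range. The clumped variant removes the clearance margin, so touching
  objects merge — deliberately — and the segmentation under-counts;
* **determinism** — identical spec + seed give bit-identical volumes.

Packing failures raise `PackingError` with rejection diagnostics rather
than degrading silently. The prophase field steers walks smoothly inward
near the envelope sphere (no hard reflections, which would kink the
centerline), seeds each tube poking ~50 nm into the envelope shell, and
tapers the lump profile to zero at the tube ends so the seeded end keeps
its nominal radius and its envelope contact.

The synthetic iBAQ table draws per-protein baselines from a log-normal,
adds a per-experiment latent factor shared within each annotation block
(within-block correlation ρ = 0.9 for the histone and periphery blocks,
0 for the background block), and rescales each block by one constant so
its aggregate mass share (20 / 33 / 47%) is exact after noise — a
per-block constant leaves Pearson correlations untouched. Correlation
depends only on the factor/noise variance ratio, so the total log10 sd
is kept small (0.1) to keep shares stable. With 24 experiments the
sampling sd of a null correlation is ~0.21, so an edge threshold of 0.8
keeps spurious edges rare enough that components cannot percolate across
blocks.

## Segmentation

Threshold (Otsu by default; objects are dark, so the mask is
`data ≤ t`) → 26-connected components → marker-controlled watershed.
Markers are the H-maxima of the anisotropy-aware Euclidean distance
transform: morphological reconstruction of `dist − h` under `dist` with
a 26-connected footprint, then regional maxima at the same connectivity
(plateau connectivity must match the object connectivity, or one ridge
plateau splits into several markers). `h` is expressed in units of the
smallest voxel pitch by default; the working range 5–7 separates every
touching pair in the canonical fields. Two guarantees are enforced
structurally rather than hoped for:

* a component none of whose maxima survive keeps one fallback marker at
  its distance argmax — objects are never dropped;
* watershed output is re-labeled within each input component — objects
  are never merged across components.

Note the Otsu mask includes the dark periphery shell, so segmented
volumes exceed chromatin-truth volumes; counts are unaffected.

## Morphometry

* **volume** — voxel count × voxel volume (exact, additive);
* **surface** — marching cubes at iso-level 0.5 on the padded binary
  mask, then volume-preserving Taubin smoothing (λ = 0.5, ν = 0.53,
  10 × level iterations). Level 6 brings a 1 µm-radius sphere within
  0.5% of 4πr²; area decreases monotonically with level as staircase
  artefacts relax;
* **centerline** — the object is resampled to isotropic voxels, thinned,
  and the longest geodesic on the skeleton graph (double-sweep Dijkstra,
  26-neighbour edges with physical weights) is the axis. Three
  corrections matter on a coarse anisotropic grid:
  * the raw skeleton path staircases, inflating arclength by up to
    ~25%; the path is smoothed with a moving average whose window spans
    about two local radii of travel;
  * the distance transform along the (slightly off-axis, interpolated)
    path under-reads the true radius, because the EDT ridge is concave;
    radii are sampled from a 3×3×3 maximum-filtered EDT instead, and
    only wall-limited samples (far enough from both ends that the end
    cap is not the nearest boundary) enter the mean diameter;
  * 3D thinning retracts the centerline from the tips; each end is
    extended along the local tangent until the ray exits the mask.

  Together these hold length and diameter within 5% over 20 random
  orientations of a 5 × 1 µm tube at (60, 24, 24) nm pitch. Objects whose
  path is shorter than their diameter (blobs) are flagged degenerate and
  fall back to the longest extent;
* **radial position** — distance from each object's axis midpoint to the
  intensity-weighted centroid of all foreground (weights = darkness);
* **envelope contacts** — 26-connected patches of object voxels within
  one voxel diagonal of the envelope mask.

## Accounting

All algebra is closed-form and exact:

* packing density = DNA (Mb) / volume (µm³); the standard curve is fit
  through the origin (slope = Σxy/Σx²) because a zero-volume chromosome
  carries zero DNA;
* the complement is idealized as one cylinder of radius r = d̄/2 and
  length h = V/(πr²); a uniform shell of thickness t has volume
  πh((r+t)² − r²), inverted exactly as t = √(r² + V_s/(πh)) − r;
* the volume fraction in a shell of thickness t on a cylinder of radius
  r is 1 − ((r−t)/r)², strictly increasing in t;
* every percent difference carries an explicit base (the larger
  quantity), because headline percentages are meaningless without one.

## Pipeline

`RunConfig` (YAML-serializable) drives phantom → segmentation →
morphometry → accounting → optional proteomics. Per-stage seeds derive
from the master seed via `SeedSequence` with a CRC32 of the stage name
(process-stable, unlike `hash()`). The report contains no timestamps and
is serialized with sorted keys, so identical configs give byte-identical
`report.json`. Stage failures raise `StageError` naming the stage, with
earlier outputs already on disk.

## Limitations

* The phantom is a geometric analogue, not an image simulation: no
  point-spread function, charging, knife chatter, or section-thickness
  variation; noise is i.i.d. Gaussian.
* Truth surface areas are analytic capsule values; curvature corrections
  along gently curved centerlines are neglected (sub-percent at the
  curvature cap used).
* The cylinder-shell accounting idealizes the complement as a single
  uniform cylinder; it propagates no uncertainty from the diameter
  distribution.
* The correlation-network clustering uses hard thresholding and
  connected components — adequate for well-separated blocks, not a
  general graph-clustering method.
* `measure_axis` targets tubular objects; branched or ring-shaped
  objects yield the longest branch, not a medial decomposition.
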