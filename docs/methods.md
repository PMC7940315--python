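# Methods

## Image model

All stages operate on a five-axis array `(t, z, c, y, x)` with physical
voxel sizes in µm (width/height per pixel, depth per slice). A 2D image
is `z = 1`; a static image is `t = 1`. Voxel indices are 0-based and the
physical position of a voxel centre is `(index + 0.5) · voxel_size`, so
centres of mass and path geometry are unambiguous. TIFF calibration is
read from the ImageJ metadata dialect (resolution tags + z-spacing);
resolution tags with unit "none" and no ImageJ metadata are treated as
uncalibrated and fall back to 1 µm with a warning. Intensities are
non-negative and finite by contract.

## Segmentation

The foreground rule is `intensity ≥ threshold` everywhere. Histogram
methods operate on 256-bin histograms spanning the data range (the
ImageJ convention), and the selected cut bin is mapped back to intensity
units: the threshold is the lower edge of the first foreground bin.
Implemented methods: Otsu (between-class variance), IsoData (iterative
intermeans), Triangle (largest distance below the peak→tail line, with
tail-side flipping), Li (iterative minimum cross entropy), Mean, and
Renyi entropy (entropic thresholds of order ½, 1, 2 combined with the
classic closeness-weighted rule). Thresholds can be computed from the
stack histogram or from the maximum-intensity-projection histogram — the
projection raises the foreground fraction for sparse objects like cilia
— and either globally or per timepoint.

Hysteresis segmentation keeps voxels `≥ high` and voxels in
`[low, high)` that connect to a `≥ high` voxel through voxels `≥ low`;
connectivity defaults to 26 (exposed as a flag). It is implemented by
component labeling of the `≥ low` level set, which is mathematically the
definition; tests verify it against an independent brute-force BFS.

Canny3D chains per-slice 2D Gaussian smoothing (the z-axis of confocal
stacks is already optically blurred), 3D Sobel gradient magnitude
(degrading to the 2D gradient when `z = 1`), hysteresis on the gradient
image, and 3D hole filling. The hysteresis thresholds are derived from
the gradient image's own histogram — the hysteresis step follows edge
detection, so its statistics belong to the edge image. Hole filling
converts background cavities with no 6-connected path to the volume
border into foreground; this closes the edge shell into a solid object,
which is why edge-based segmentation produces larger reconstructions
that tolerate uneven labeling along the cilium.

Preprocessing options: rolling-ball background subtraction (per slice,
clipped at 0), flat-field division by a Gaussian-blurred copy (with an
epsilon guard), and per-slice Gaussian smoothing. Filter sizes are
accepted in pixels by the core; converting µm settings via the
calibration is the caller's (or CLI's) concern.

## Edits

Interactive corrections are replaced by an ordered log of ROI records
(polygon, z-range, frame, add/remove). Rasterization uses pixel-centre
containment with the even-odd rule. `remove` zeroes voxels; `add` sets
the dtype maximum in binary channels or copies intensities from the
retained raw channel in background-removed ones (hence `add` without a
source channel is an error). Replay is strictly ordered and
deterministic, so the edited channel is reproducible byte-for-byte from
the original plus the log; records serialize to JSON next to the `_ed`
output.

## Reconstruction

Foreground voxels (intensity > 0 in the reconstruction channel) are
merged into objects by flood-fill labeling with two variants:
*straight* (6-connectivity; 4 in 2D) and *straight + diagonal*
(26-connectivity; 8 in 2D). Diagonal filling retrieves incompletely
labeled cilia at the cost of occasionally merging neighbours. Objects
with fewer voxels than the minimum size are removed (`≥` keeps);
objects touching selected image borders (index 0 or length−1; z only
when `z > 1`) can be excluded, with counts reported. Time series are
linked by one 4D labeling pass whose structuring element combines the
spatial offsets of the chosen variant (plus the zero offset) with
temporal moves of ±1 frame. Object ids follow the raster-scan position
of each object's first voxel, so output ordering is reproducible.

## Centerline extraction

Each object (per timepoint) is rendered into a tight 8-bit box with a
one-voxel pad (object = 255), upscaled ×3 in all axes by trilinear
interpolation, and blurred with a 3D Gaussian whose sigma is 3× the
user's sigma (the grid is 3× finer); the z-sigma is separately
configurable and defaults to 0. The blur uses a constant-zero boundary:
the object sits in zero background, and reflective boundaries would
feed intensity back in and inflate the object at large sigmas. The
blurred volume is re-binarized at half maximum (128/255) — the paper of
record for this workflow does not state the level; the midpoint is
symmetric and is fixed here — and thinned.

Thinning is a topology-preserving 3D border thinning in six directional
sub-iterations: a voxel is deletable only if it is a border voxel in the
current direction, not a curve endpoint (≠ exactly one 26-neighbour),
and a simple point (its deletion preserves both the 26-connected
foreground and the 6-connected background in its 3×3×3 neighbourhood —
the Malandain–Bertrand characterization); candidates are re-checked
sequentially before deletion. Plates erode from their rims into curves,
so tubes thin to their centerline. The implementation is numba-compiled
and is cross-checked in the tests against the scikit-image thinning on
shapes both handle.

The skeleton voxel set becomes a graph on 26-adjacency with edge
weights equal to the calibrated Euclidean step length in the upscaled
grid (`voxel_size / 3` per axis), so diagonal and anisotropic steps are
measured correctly. Connected components are counted as separate
skeletons (a quality parameter); the largest is selected by tree
length. Because a 26-adjacency graph of a one-voxel-wide chain contains
redundant triangle shortcuts, tree length and the branch decomposition
(segments between nodes of degree ≠ 2) are measured on a deterministic
minimum spanning tree of the component — identical to the walked length
on clean chains — while shortest-path searches run on the full graph. A
straight line counts as one branch; a "Y" as three.

The centerline is the *largest shortest path*: over all pairs of
skeleton endpoints, the pair whose shortest on-skeleton connecting path
is longest (ties broken by the lexicographically smallest endpoint
pair). With a basal-stain channel the path end nearer the basal
centroid (brightest basal voxel near the object) becomes the base;
without one, the endpoint with the smaller (z, y, x) tuple is used and
the record is flagged `unoriented`, since the orientation-vector sign is
then arbitrary.

## Quantification

* **Volume** `N · w · h · d` (µm³); in 2D the numeric value carries area
  semantics. **Surface** = Σ exposed voxel faces (areas `w·h`, `w·d`,
  `h·d`); **surface voxels** = voxels with ≥ 1 exposed face.
* **Shape complexity index** `surface / (4π((3V)/(4π))^(2/3))` and
  **sphere radius** `(3V/4π)^(1/3)`; omitted for 2D. The analytic
  sphere scores exactly 1. Note that the index of *voxelized* spheres
  does not converge to 1 with resolution: the exposed-face (staircase)
  surface of a digitized sphere converges to 3/2 of the smooth surface,
  so finely voxelized spheres plateau near 1.5. The index is therefore
  a relative shape measure at a given voxelization, anchored at 1 only
  in the continuum.
* **Intensity statistics** per channel over the cilium's voxels; SD is
  the population SD (a convention fixed here); the top-10% mean uses
  the ⌈0.1·N⌉ (≥ 1) brightest voxels.
* **Background (soma) threshold**: per frame, the image is divided into
  a 5×5 (y, x) grid of cuboids spanning all z (remainders absorbed by
  the last row/column); from each cuboid the brightest ⌈10%⌉ (≥ 1)
  voxels outside all cilium objects are pooled; threshold = pooled mean
  + 1.5·SD. The in-plane grid matches the illumination-variation use
  of the rule. Undefined (all voxels ciliary) thresholds are flagged
  and dependent parameters suppressed.
* **Colocalized volume**: cilium voxels nonzero in another segmented
  channel (µm³ and %). **Colocalized volume vs background**: strict
  `> threshold` (the wording "higher intensity than" is strict, unlike
  the `≥` segmentation rule).
* **Profiles**: for each centerline point, the nearest z-slice is
  chosen and the intensity interpolated bilinearly among the four
  surrounding pixel centres; output profiles are additionally resampled
  by averaging into consecutive voxel-width arc bins (empty bins
  linearly interpolated). Integrated/average centerline intensity are
  the sum/mean of the raw per-point profile; colocalized centerline
  length assigns each point the arc segment to its successor.
* **Orientation and bending**: vector = tip − base; bending index =
  arc length / chord (≥ 1, infinite for closed paths, flagged).
* **Tangents**: at arc position s, the normalized vector between the
  interpolated points delta µm upstream and downstream (clamped at the
  ends), with delta user-set (default 1 µm).
* **Signed curvature**: with P1/P2 the points delta upstream/downstream
  and T1/T2 their unit tangents, magnitude = `|T2 − T1| / 2 / s(P1,P2)`
  where s is their arc separation; the sign is that of the z-component
  of T1 × T2 ("the sign of the cross product" is not a scalar in 3D;
  the z-component recovers the standard planar signed curvature and
  gives a fixed convention in 3D). The `/ 2 /` divisor is implemented
  literally as specified; on a circle of radius R with window delta the
  value is `sin(delta/R) / (2·delta)` → `1/(2R)` as delta → 0, i.e.
  half the geometric curvature. All tests target this literal value.

## Synthetic phantoms

Tubes are indicator volumes (voxel centre within `tube_radius` of a
dense centerline polyline sampled at ≤ ¼ voxel width), optionally
speckled (a seeded fraction of tube voxels zeroed before blurring, to
emulate uneven labeling), convolved with a Gaussian PSF stand-in, and
corrupted with additive Gaussian noise clipped at 0. Ground truth
(length, chord, curvature, voxel count) comes from closed forms — line:
chord; arc: `R·θ`; helix: `turns·√((2πR)² + pitch²)` — independent of
rendering. Defaults: calibration 0.1×0.1×0.5 µm (a typical 60× confocal
acquisition, deliberately anisotropic), tube radius 0.4 µm (the
apparent, diffraction-broadened calibre of a primary cilium; it also
guarantees ≥ 1-voxel z-coverage at the coarse slice spacing), peak 200,
PSF sigma 0.15 µm, noise SD 5. Scenes add an optional protein channel
covering each tube's proximal `fraction` of arc length — rendered
*sharp* (no PSF) because its boundary is the constructed truth for
colocalized-length checks — and an optional basal-stain channel with a
bright spot at each declared base.

What the phantoms do not emulate: optically realistic PSFs, Poisson
photon statistics, cell bodies/nuclei background, and axial intensity
falloff. Passing phantom tests therefore demonstrates the geometry and
accounting of the pipeline, not robustness to every real-microscopy
artifact.

## Numerical and design choices

* Histograms: 256 bins at all bit depths; degenerate (single-valued)
  histograms return that value with a warning.
* Hysteresis default connectivity 26; labeling variant names map
  "horizontal+vertical" → 6 and "+diagonal" → 26 (8/4 in 2D).
* Deterministic everywhere: object ids by raster scan, path ties by
  lexicographic endpoint order, seeded phantom noise. Two runs with the
  same config produce byte-identical tables.
* Problem sizes in the test suite (phantom stacks of ~10⁵–10⁶ voxels,
  tubes of 7–10 µm, 100–200 random volumes per oracle check) were
  chosen so the full suite validates every stage in well under a
  minute per criterion.

## Known limitations

* **Lattice arc-length inflation for steeply tilted structures.** The
  centerline is a 26-adjacent voxel chain, and its length is the sum of
  calibrated steps. In anisotropic stacks the available step directions
  are quantized: at voxel 0.1×0.1×0.5 µm the lattice diagonal has a
  physical slope of 5, so no chain can follow a 45° out-of-plane line
  without zig-zagging, and the measured length of such a tube exceeds
  its true length by ≥ ~28% (approaching the L1 length). The bias
  vanishes for in-plane structures (which the 2D checks confirm at
  2–4% error) and for isotropic voxels, and shrinks as the tilt
  direction approaches a lattice direction. Sub-voxel path smoothing
  would remove it but is deliberately out of scope; consumers measuring
  steeply tilted cilia in anisotropic stacks should expect this
  overestimate, which 2D-vs-3D comparisons on tilted phantoms make
  visible.
* Skeleton endpoints jitter by ±1–2 upscaled voxels between otherwise
  equivalent runs of the thinning (directional sub-iteration order is
  not rotation-equivariant); on short objects this dominates relative
  length error.
* Rounded tube caps introduce a ±tube-radius ambiguity in phantom
  length recovery: the medial axis of a capsule ends at the cap
  centres, but the discrete skeleton may extend into the caps.
* ImageJ parity is functional, not bit-exact: the rolling-ball and the
  threshold methods follow the published algorithms on 256-bin
  histograms, and only the six methods listed above are provided.
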