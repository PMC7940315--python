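# ciliametry

Quantification of cilia in multi-channel fluorescence microscopy stacks.

Primary and motile cilia are micrometre-scale membrane protrusions whose
length, shape and protein content report on ciliary signalling and
ciliopathies. `ciliametry` turns 2D, 3D or time-lapse stacks that contain
a cilia-marker channel (e.g. ARL13B or acetylated tubulin) into one row
of morphometric and intensity parameters per cilium, in a scriptable,
fully reproducible pipeline:

1. **Segment** (`ciliametry.preparator`) — optional background
   subtraction (rolling ball), flat-field division and per-slice
   smoothing, followed by histogram thresholding (Otsu, Triangle, Renyi
   entropy, IsoData, Li, Mean or a fixed value; stack or
   maximum-projection histogram), 3D hysteresis thresholding, or the
   edge-based *Canny3D* method (per-slice Gaussian → 3D Sobel → 3D
   hysteresis → 3D hole fill).
2. **Edit** (`ciliametry.editor`) — scripted, logged add/remove ROI
   corrections that replay byte-identically.
3. **Reconstruct & quantify** (`reconstruct`, `skeleton`, `quantify`) —
   3D/4D connected-component labeling (6- or 26-connectivity), size and
   border filters, per-object centerline extraction (×3 upscaling,
   Gaussian blur, topology-preserving 3D thinning, largest shortest
   path between skeleton endpoints), and the full parameter set.

Per cilium the pipeline reports: centre, voxel/metric volume, surface
and surface voxels, shape complexity index
`SCI = surface / (4π·((3V)/(4π))^(2/3))` (1 = perfect sphere), sphere
radius, per-channel intensity statistics (min/max/mean/SD/top-10%),
colocalized volume and background-relative colocalization (25-cuboid
soma threshold: mean + 1.5·SD of the pooled per-cuboid brightest 10% of
non-cilium voxels), skeleton quality parameters (# skeletons,
# branches, tree length), cilia length (arc length of the largest
shortest path), base→tip orientation vector, bending index
(arc/chord ≥ 1), intensity profiles resampled at voxel-width steps,
unit tangents and signed curvature along the centerline.

`ciliametry.synthetic` renders calibrated phantom stacks — tubes along
lines, arcs and helices with Gaussian PSF stand-in, noise, uneven
labeling, partial-colocalization and basal-stain channels — with
closed-form ground truth, so every stage is testable without microscopy
data.

## Worked example

```python
import numpy as np
from ciliametry import RunConfig, prepare_image, quantify_image
from ciliametry.config import SegmentationSettings
from ciliametry.synthetic import PhantomSpec, make_scene

specs = [
    PhantomSpec(kind="line", start=(1.5, 3.0, 3.0), end=(8.5, 3.0, 3.0)),
    PhantomSpec(kind="arc", radius=4.0, angle_span=np.pi / 2, offset=(2.0, 5.0, 3.0)),
]
image, truth, _ = make_scene(specs, shape_zyx=(12, 110, 130), seed=0)

cfg = RunConfig()
cfg.segmentation["reconstruction"] = SegmentationSettings(
    method="otsu", histogram_source="max_projection", include_unsegmented_copy=False
)
segmented = prepare_image(image, cfg)
results, profiles, resampled, counts = quantify_image(segmented, cfg)
```

The ground truth holds a 7.00 µm straight tube and a 6.28 µm quarter
arc (curvature 0.25 µm⁻¹); the result table prints:

```
 ID  Volume [µm³]  Cilia length [µm]  Cilia bending index  # branches  Shape complexity index
  1         4.565              7.047                1.002           1                   2.002
  2         4.470              6.561                1.165           5                   2.102
```

The straight tube is recovered at 7.05 µm with bending index 1.002
(straight) and a single skeleton branch; the arc is longer than its
chord (bending 1.165) and shows a few short side branches, which the
quality columns expose. Elongated tubes score SCI ≈ 2, far from the
spherical value 1.

The same pipeline runs from the shell:

```sh
ciliametry simulate --out scene.tif --n-tubes 3 --seed 5
ciliametry prepare scene.tif --config settings.yaml --output-dir out/
ciliametry quantify out/scene_CQP.tif --config settings.yaml --output-dir out/
```

`prepare` writes `*_CQP.tif` plus a reloadable `key=value` settings log;
`quantify` writes per-image TSV tables (wide per-cilium table, long
centerline table, resampled profiles) and a TIFF mask of the objects
surviving all filters.

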