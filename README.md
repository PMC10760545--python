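# punctaline

Detection and quantification of fluorescent puncta along traced linear
cellular structures (e.g. *C. elegans* nerve cords), as a scriptable Python
library and CLI.

The pipeline mirrors a classic ImageJ linescan workflow:

1. **project** — maximum-intensity projection of TIFF z-stacks;
2. **straighten** — resample each image along a traced polyline of stated
   width, so the structure lies along the horizontal axis;
3. **quality crop** — optional non-interactive crop/exclude decisions per
   image;
4. **detect** — Gaussian blur, Phansalkar local adaptive thresholding over a
   circular window, 8-connected components, minimum-size filter;
5. **measure** — per punctum: bounding-box width, maximum intensity, and the
   full width at half maximum (FWHM) of a 4-parameter Gaussian
   (`y = a + (b−a)·exp(−(x−c)²/2d²)`) fit to the left-to-right intensity
   profile. Puncta whose fitted FWHM exceeds the ROI width get `discard = 1`
   and can be filtered or replaced by the ROI width;
6. **density** — puncta per unit length of the straightened image.

A first-class synthetic-data module (`punctaline.synth`) renders
straightened-cord images with known punctum positions, amplitudes and
widths — including a low-contrast variant that reproduces the regime where
fixed-parameter detection visibly under-counts — so the whole chain is
testable without microscope data.

Two shipped presets, `nuIs24` (min size 0.2, sigma 1, radius 6, Phansalkar)
and `nuIs152` (min size 0.3, sigma 0.75, radius 1, Phansalkar), match the
settings used for the two published validation datasets.

## CLI

```sh
punctaline project --in raw/ --out projected/
punctaline straighten --image img.tif --path img_path.csv --width 9 --out img_straight.tif
punctaline detect --image img_straight.tif --config nuIs24 --out-rois rois.csv --out-mask mask.tif
punctaline measure --image img_straight.tif --rois rois.csv --mask mask.tif --out puncta.csv [--replace-discarded]
punctaline density --puncta puncta.csv --lengths lengths.csv --out density.csv
punctaline synth --spec spec.yaml --out synthetic.tif --truth truth.csv
punctaline preview-settings --image img_straight.tif --configs a.yaml --configs b.yaml --out-dir preview/
punctaline run --config run.yaml        # whole pipeline over a folder
```

Paths are supplied as CSV (`image_id, vertex_index, row, col, width_px`) or
JSON; interactive tracing is out of scope. Detection parameters come from a
preset name or a YAML/JSON file
(`min_size, sigma, radius, method, connectivity, phansalkar: {k, r, p, q}`).
All tabular outputs are plain CSV with a units column (`um`/`px`, depending
on whether the TIFF carries a pixel size); reruns on identical inputs are
byte-identical.

Example `run.yaml`:

```yaml
input_dir: projected/
output_dir: results/
path_file: paths.csv
params: nuIs24        # or an inline mapping
crop_file: crops.csv  # optional
replace_discarded: false
include_discarded_in_density: true
```

## Conventions

- Coordinates are 0-based `(row, col)`; rectangles are half-open
  `(row0, col0, height, width)`.
- Straightening samples at an arc-length step of exactly 1 px with bilinear
  interpolation; axis-aligned paths reproduce crops bit-exactly;
  out-of-bounds samples are zero-filled with a warning.
- Phansalkar thresholding normalizes intensities by the bit-depth maximum
  and uses population SD over a circular window truncated at borders
  (defaults k=0.25, r=0.5, p=2, q=10).
- `min_size` is interpreted as µm² when the image is calibrated, px²
  otherwise; outputs record which was used.
- Intensities are always measured on the original (unblurred) straightened
  image.
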