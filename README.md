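# nodulekit

Synthetic rendering and high-content image analysis of 3D ovarian-cancer
nodule cultures under photodynamic therapy (PDT).

The package has two halves that close a loop:

* **Generator** (`nodulekit.synthetic`) — seeded, ground-truth-annotated
  renders of nodule-field imagery: two-channel live/dead fields with
  region-resolved (core vs periphery) dose response, photosensitizer
  uptake maps (peripheral-decay and core-concentrating profiles backed by
  an analytic sphere-diffusion solution), paired PI/apoTRACE images, and
  51-band hyperspectral cubes of a ratiometric pH dye, all under a shared
  Poisson + Gaussian camera model.
* **Analysis** — the image pipeline such imagery is meant for:
  - `nodulekit.viability`: modal-background subtraction, well viability
    (live / (live + dead) intensity totals), NT-control normalization,
    pooled-variance Student's t-tests, interpolated LD50, and
    irradiance-series summaries (argmin / plateau onset).
  - `nodulekit.morphometry`: Otsu thresholding, 8-connected nodule
    segmentation, equivalent diameter / spherical volume / live:dead
    metrics, log-log power-law size-response fits, and a 1/e
    boundary-referenced penetration-depth estimator.
  - `nodulekit.ph`: 570/650 nm band-ratio images, parametric or tabulated
    ratio-to-pH calibration, radial pH profiles with core/edge medians.
  - `nodulekit.apoptosis`: per-channel Otsu + bitwise-AND apoptotic maps.
  - `nodulekit.dosimetry`: spectral fluence-rate correction between
    treatment wavelengths.

Default model constants live in `src/nodulekit/defaults.yaml`; they are
calibration data (fixed once via `nodulekit calibrate`), not code.

## CLI

One executable with subcommands:

```sh
nodulekit simulate --condition treated --dose 15 --seed 1 --out out/sim
nodulekit viability --plate out/run/plate.csv --out out/wells
nodulekit nodules --image out/sim/well.tif --out out/nodules
nodulekit ph --cube cube.tif --out out/ph
nodulekit apoptosis --image pair.tif --out out/apo
nodulekit all --seed 1 --out out/run        # simulate + score + morphometry
nodulekit calibrate --out calibrated.yaml   # re-fit d50 to the LD50 target
```

`--config path.yaml` (before the subcommand) merges a user YAML over the
built-in defaults; every run writes its resolved config next to its
outputs. Images are 16-bit grayscale TIFF, one page per channel with the
channel name in the page description; hyperspectral cubes are multi-page
TIFF with a `.bands.csv` sidecar (band_center_nm, bandwidth_nm).

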