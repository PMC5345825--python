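# feulgen

Feulgen image cytometry toolkit: segmentation of Feulgen-stained nuclei,
21-descriptor nuclear morphometry, integrated-optical-density (IOD) DNA
ploidy estimation against a normal-haemocyte reference, ploidy-histogram
peak detection, and stepwise linear discriminant classification — plus a
synthetic scene generator that renders Beer–Lambert-faithful brightfield
images with full ground truth, so the whole chain is testable without any
archival slides.

## Modules

| module                 | what it does |
|------------------------|--------------|
| `feulgen.synthetic`    | stage presets (normal/light/moderate/heavy) drawing DNA contents from ploidy mixtures; stoichiometric scene rendering (per-nucleus OD sums exactly to `od_per_C × dna_content`); feature-table sampling from published group statistics |
| `feulgen.optics`       | frame averaging, green-channel extraction, transmittance-ratio background correction, OD conversion (`OD = −log10(T)`) |
| `feulgen.segmentation` | Otsu threshold (exact integer arithmetic, dark class), edge-object removal, distance-transform watershed, inclusive size filter, dilation without merging, exclusion masks |
| `feulgen.morphometry`  | Moore boundary tracing through pixel centres; Perimeter/Area (polygon convention), MinR/MaxR, Feret/Breadth, convex hull, minimal bounding circle, and the 11 ratio descriptors |
| `feulgen.densitometry` | per-nucleus IOD, reference-standard calibration (1C = 0.96 pg), C-value/ploidy ratio, size-7 running-average ploidy histograms with two-scale peak detection |
| `feulgen.stats`        | descriptives, Welch t, two-sample Kolmogorov–Smirnov, one-way GLM contrasts, Wilks'-lambda stepwise LDA with resubstitution confusion matrices, cohort summaries |
| `feulgen.pipeline`     | YAML-configurable end-to-end runs with manifest, per-stage ploidy profiles and confusion matrices; demo fixture set |

## CLI

```bash
feulgen demo --out demo/ --seed 42              # 4 stages × 3 images + ground truth
feulgen simulate light --n-nuclei 50 --out sim/ # one rendered scene
feulgen segment sim/light.png --blank sim/light_blank.png --max-size 40000 --out sim/mask.png
feulgen measure sim/light.png sim/mask.png --blank sim/light_blank.png --out sim/features.csv
feulgen ploidy features.csv --out-prefix run    # profiles + peaks per stage
feulgen stats features.csv --classes stage --out-prefix run
feulgen run-all --preset all --seed 1 --out run/  # full synthetic pipeline
```

`run-all` writes per-image feature CSVs, a pooled table, per-stage ploidy
profiles and peaks, group statistics, confusion matrices and a
`manifest.json` recording every parameter of the run. Real images are
configured via a YAML `RunConfig` (`feulgen run-all --config cfg.yaml`),
each entry naming an image path, an optional blank-field image (or scalar),
and a stage label; reference calibration uses the images labelled `normal`.

## Conventions

- Coordinates are 0-based `(x right, y down)`, pixel centres at integers;
  default pixel size 0.45 µm (config).
- Area and Perimeter are polygon quantities on the boundary-pixel-centre
  outline (the raw pixel count is a separate column and is what the
  25–300 px size filter uses).
- Ploidy is reported strictly as the IOD ratio to the normal-haemocyte
  reference (reference mean ≡ 1); `Cs = IODs × Cp / IODp` with
  Cp = 0.96 pg.
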