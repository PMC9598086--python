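# osteotrace

Registration and spatial-statistical analysis of bone surface modifications
(BSMs) — tooth pits, tooth scores, cut marks, percussion marks — on 3D
long-bone point-cloud templates.

The package covers the full analysis stack for taphonomic point patterns:

- **Core model** (`osteotrace.core`, `osteotrace.io`): canonical anatomical
  frame (x = proximo-distal, y = medio-lateral, z = cranio-caudal, mm),
  validated mark/specimen records, an assemblage store with provenance
  logging, and readers/writers for PLY (ascii + binary), OBJ, XYZ, flat CSV
  and JSON.
- **Synthetic fixtures** (`osteotrace.simulate`): bone-like tube templates
  with flared epiphyses, CSR (binomial/Poisson) and Matérn-cluster point
  patterns, score populations with von Mises axial orientations (angle
  doubling), and interval crop sets with analytic overlap ground truth. All
  generators are seed-exact.
- **Survivorship** (`osteotrace.survivorship`): polygonal and interval
  cropping as index masks on the template cloud, superimposition heatmaps,
  and overlap-based MNE per (element, side).
- **3D point-pattern statistics** (`osteotrace.spatial`): K, G, F and pair
  correlation estimators with translation / border / Kaplan-Meier
  corrections, square-root transforms, and Monte Carlo CSR rank envelopes.
- **Axial profiles + wavelet coherence** (`osteotrace.profiles`,
  `osteotrace.coherence`): mark-count "time series" along a bone axis,
  relative profile comparison, and bivariate Morlet wavelet coherence with
  AR(1)-surrogate significance, phase arrows and cone of influence.
- **Embedding** (`osteotrace.embedding`): t-SNE on normalized mark
  coordinates (perplexity = ceil(sqrt(n)) by default) plus DBSCAN labelling
  of the 2D embedding.
- **Orientation** (`osteotrace.orientation`): axial circular moments
  (variance, dispersion, standardized skewness/kurtosis, central orientation
  pair), Rayleigh uniformity test (series tail approximation), randomized
  Mardia-Watson-Wheeler two-sample test, false positive risk from the
  minimum-Bayes-factor bound, and rose-diagram sector counts.

## CLI

All commands live under a single entry point:

```bash
osteotrace simulate --out demo/ --seed 1           # synthetic cloud + marks
osteotrace import-cloud bone.ply --element femur --side left --store store/
osteotrace register --store store/ --specimen SP1 --type score \
    --endpoints 10,2,0,20,4,2
osteotrace query --store store/ --mark-type score --format json
osteotrace crop --store store/ --crop crop.json
osteotrace heatmap --store store/ --out heatmap.csv
osteotrace csr --function K --sqrt --nsim 500 --seed 1 \
    --marks demo/marks.csv --out est.csv
osteotrace profile --marks demo/marks.csv --cloud demo/cloud.ply --out demo/
osteotrace wtc --profile-a demo/profile_pit.csv \
    --profile-b demo/profile_score.csv --nrands 10000 --seed 1 --out demo/
osteotrace embed --marks demo/marks.csv --iterations 1000 --eps 3 \
    --seed 1 --out demo/
osteotrace orient --template demo/cloud.ply --marks demo/marks.csv --out demo/
```

Multi-stage runs are driven by a JSON/YAML config (`osteotrace run --config
cfg.json`); every stochastic stage receives a seed derived from the master
seed, so reruns are byte-identical, and a manifest with SHA-256 hashes is
written next to the outputs. `osteotrace validate cfg.json` reports all
schema violations at once.

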