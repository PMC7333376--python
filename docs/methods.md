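# Methods

`cellqc` implements a cell-level quality-control workflow for
high-content screening (HCS) image assays.  Its premise: image-level QC
metrics (focus scores, intensity statistics, power-spectrum slopes)
confound genuine phenotypic variation with quality problems, so quality
should be judged per segmented object.  The workflow learns what valid
cells of each phenotype look like and calls everything that resembles no
phenotype an artifact; the per-image readout is the artifact-area ratio

    AR_cell = (total pixel area of artifact-labeled objects)
              / (total pixel area of all segmented objects)

a single number in [0, 1] used to rank images by quality and to gate
them (strictly greater-than a study-chosen threshold, e.g. 0.5 or 0.7).

## Pipeline

1. **Feature reduction** — image-level QC features are clustered by
   average linkage on distance 1 − |Pearson r| and cut at |r| = 0.9; one
   representative per cluster is kept (priority order PowerLogLogSlope,
   FocusScore, MeanIntensity, Correlation, SNR, then alphabetical) and
   Cell Count is appended.  Cell Count is kept explicit because most QC
   features co-vary with it.
2. **Image outlier filter** — a local outlier factor (LOF) screen in the
   selected feature space (standardized internally; n_neighbors 20,
   contamination 0.02) removes artifact-dominated images before any
   training data is drawn.  LOF is used because HCS images form clusters
   of very different densities (replicates, dose series), which defeats
   global parametric outlier tests.
3. **Phenotype sampler** — for each feature a 1-D Gaussian-KDE bandwidth
   h_i is chosen by 5-fold cross-validated likelihood over 20 log-spaced
   candidates; a sparse lattice with per-dimension spacing K·h_i
   (default K = 2) is grown one dimension at a time, pruning lattice
   points farther than r = sqrt(Σ h_i²) (raw feature units, h not K·h)
   from every image after each dimension is added.  Each retained grid
   point samples its nearest image (ties to the lowest image id, then
   deduplicated).  Near-uniform coverage of the occupied feature space
   is what retains rare phenotypes in the training sample.
4. **Phenotype grouping with human veto** — a full-covariance Gaussian
   mixture BIC scan (k = 1..k_max, default 20, five restarts each)
   bounds the group count n_up; a Dirichlet-process variational Bayesian
   mixture with n_up components then shrinks superfluous weights.
   Effective groups (posterior weight ≥ 1/(10·n_up) and ≥ 5 members)
   export their most central member images; a human includes or excludes
   each group.  The veto is a hard barrier: training with undecided
   groups is an error.  A test-only auto-verdict mode substitutes
   planted ground truth for CI.
5. **One-class SVM ensemble** — per included group, descriptors are
   standardized by a scaler fit on the group's collected cells, the
   cells are screened by LOF (score mode, see below), and an RBF
   one-class SVM is fit with nu = 1e-3 and gamma = 1/D_cell (one over
   the descriptor count).  nu is tiny because the sampled training cells
   are trusted and the boundary should envelop nearly all of them;
   raising nu (or gamma) tightens the boundary.
6. **Unanimity rule and scoring** — an object is an artifact only if it
   falls outside every phenotype boundary; membership in any one
   phenotype suffices for validity.  Adding an ensemble member can
   therefore only shrink the artifact set.  AR_cell, histograms,
   quantiles, gating and RGB mask overlays (artifacts green, valid cells
   blue, AR annotated in white) follow.

## Parameters that matter

| parameter | default | meaning / why |
| --- | --- | --- |
| correlation cut | 0.9 | |r| above which features are redundant |
| LOF n_neighbors (image, cell) | 20, 20 | neighbourhood of the density estimate |
| image contamination | 0.02 | expected fraction of artifact-dominated images |
| cell screen LOF threshold | 2.0 | score above which a training cell is dropped (LOF ≈ 1 means locally typical) |
| K | 2 | lattice spacing multiplier; larger K → smaller sample |
| KDE CV folds / candidates | 5 / 20 | bandwidth selection |
| k_max (BIC scan) | 20 | upper bound of the group-count scan |
| nu | 1e-3 | one-class training-error bound (trusted sample) |
| gamma | 1/D_cell | RBF width on standardized descriptors |
| min_train_cells | 50 | below this a group's envelope is degenerate; group dropped |
| AR gate threshold | 0.5 | strict >; assay-specific (0.7 for sparse-seeding assays) |

All randomness flows from one configured seed, fanned out per stage with
CRC-hashed stage names (31-bit children, reproducible across platforms).

## Numerical and design choices

* **Bandwidth candidate floor.**  Candidates span a floor to σ.  The
  floor is max(σ/100, smallest positive gap between distinct values):
  for quantized features (integer cell counts) cross-validated
  likelihood diverges as h → 0 on tied values, and a bandwidth below the
  quantization scale would only model discretization noise while making
  the sampling lattice explode to near-per-integer resolution.
* **Grid dimension order.**  The construction order is free in the
  method; the default adds dimensions in ascending bandwidth order.
  Adding a large-bandwidth dimension early inflates the cumulative
  pruning radius, after which every finer lattice multiplies essentially
  unpruned — intermediate products can grow by orders of magnitude.  An
  explicit order is accepted and logged; `build_grid` refuses (with a
  parameter error) to grow beyond 2×10⁷ retained points.
* **Raw-unit pruning radius.**  r = sqrt(Σ h_i²) is isotropic in raw
  feature units, so the largest-unit feature dominates r and the grid is
  effectively coarse along large-unit dimensions.  With heterogeneous
  QC units (SNR ~ 10, focus scores ~ 0.01) this is what keeps the
  sample a small fraction of the assay — and a small sample is the
  workflow's real defence against artifact objects inside training
  images (see next point).  With deliberately commensurate features the
  same lattice resolves nearly every image.  This scale sensitivity is a
  genuine property of the formula; `radius_scale` and explicit
  `dim_order` are the escape hatches.
* **Cell screen in score mode.**  Far-field artifacts at ~10% prevalence
  defeat a fixed-quantile LOF screen (a 2% quantile cannot remove 9%
  contamination) and, at high absolute counts, LOF itself (artifacts
  then have artifact neighbours, so their local-density ratio tends to
  1).  The default screen removes cells with LOF > 2 — adapting the
  removed fraction to the data — and works precisely in the small-sample
  regime the sampler produces.  The fixed-fraction screen remains
  available (`screen_contamination`), including contamination 0 as an
  explicit no-op.
* **Scaler before screen.**  The per-group scaler is fit on the
  collected (unscreened) cells; the SVM support on the screened subset.
  The scale then reflects the group's full observed dispersion, which
  keeps the effective kernel width permissive for held-out valid cells,
  while the boundary itself is anchored only on trusted cells.
* **Boundary epsilon.**  libsvm leaves points that lie exactly on the
  learned boundary a round-off below it (≈ −1e-4 at its default
  tolerance).  SVMs are fit with tol = 1e-8 and a decision value
  ≥ −1e-7 counts as inside; without this, nu = 1e-3 appears violated on
  its own training data.
* **Ties and degenerate inputs.**  Outlier flagging at the contamination
  quantile flags all tied scores (conservative).  Nearest-image ties
  break to the lowest image id.  Zero-object images get an undefined
  (NaN) AR_cell — an empty image carries no evidence of quality — and
  are excluded by default with reason "no objects".  Constant features
  are excluded from correlation clustering with a warning and refuse
  bandwidth fitting with a named error.

## The synthetic assay

`cellqc.simulate` emits seeded feature-space assays with exact ground
truth: five Gaussian image-phenotype clusters of unequal density
(weights 0.40/0.30/0.15/0.14/0.01 — one deliberately rare), 2% planted
out-of-cluster images drawn uniformly over an inflated bounding box,
per-image cell populations (Poisson, means 15–25 per image) from
per-phenotype descriptor Gaussians (8 descriptors including area), and
artifact objects drawn on a broad far-field shell ≥ 6σ from every
phenotype's descriptor mean with heavy-tailed (lognormal) areas.  The
per-image artifact fraction follows Beta(0.5, 5) (long-tailed, mean
≈ 9%); planted outlier images use Beta(5, 2) (artifact-dominated).
Image features carry heterogeneous units as real QC tables do.

Scaled down, deliberately: production assays run 10⁵–10⁶ images with
~700–1700 cells each; the default fixture is 1,500 images with ~20
cells each so the whole pipeline runs in seconds.  A green test
establishes that the machinery recovers planted structure in this
regime; it does not certify behaviour on morphology-correlated
descriptors, non-Gaussian phenotypes, spatially structured artifacts, or
batch effects — none of which the generator emulates.  A minimal
Gaussian-blob renderer plus naive threshold segmenter exists solely to
prove the pixel plumbing (masks, overlays, measurement) end to end;
it is not a segmentation benchmark.

## Known limitations

* The pruning-radius scale sensitivity above: feature sets mixing very
  large and very fine units can produce multi-million-point grids (slow)
  or, with adversarial orderings, memory-guard errors.
* LOF screening degrades as artifact prevalence and absolute counts
  grow; heavily contaminated assays should lower the image-filter
  contamination threshold first.
* The human veto is modeled as an editable YAML file plus representative
  image lists; there is no GUI.
* The iterative grid is a subset of the brute-force full-lattice prune;
  early pruning can lose points whose full-dimensional extension would
  survive (the shell of width ≈ h_D²/2r).  `build_grid_bruteforce`
  quantifies the difference on small problems.
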