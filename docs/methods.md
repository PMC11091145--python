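# Methods

## Scope and data model

`msiflux` analyzes pixel-by-feature MSI matrices as exported by imaging
software (header `x,y,<m/z>,...`, one row per pixel). It does not process raw
mass spectra: peak picking, recalibration and S/N estimation are assumed done
upstream, and the feature table (m/z, identity, kind, S/N, carbon count,
isotopologue index) is an *input*. Pixel coordinates are 0-based `(row, col)`;
pixel area is `pixel_size²` with a 5 µm default edge length.

## Preprocessing

Each pixel is divided by its total ion count (TIC). Zero-TIC pixels have
undefined fractions and are dropped with a reported count rather than kept as
zero vectors — clustering on them would be meaningless. The `normalized` flag
means "intensities are TIC fractions"; directly after normalization every
pixel sums to 1, and after feature selection the sums are ≤ 1 (fractions of
the full-spectrum TIC), matching the usual select-after-normalize workflow.

The count matrix for clustering is `⌊100 × fraction⌋`, i.e. truncation toward
zero, which is what an integer cast does. Lipid selection keeps features with
m/z ≥ 400 and S/N ≥ 3 that are not flagged as MALDI-matrix signals; a missing
S/N fails the filter. m/z annotation matches within ±20 ppm by default, the
smallest ppm error wins, and an exact tie is reported as ambiguous rather
than resolved arbitrarily. Hotspot removal clips values above the empirical
99 % quantile, computed with linear interpolation between order statistics so
results are bit-reproducible.

## Segmentation

Pixels are clustered on the variance-stabilized count matrix: `log1p` of
counts, centered and scaled per feature, PCA to 20 components (fewer if the
data are smaller), then k-means with a fixed seed and 10 restarts. Two
choices matter:

* **Determinism and permutation invariance.** Pixels are processed in
  canonical coordinate order and cluster ids are relabeled by first
  appearance in that order, so the same data in any row order yields the
  same assignment. UMAP is deliberately not on any computation path; the
  stored 2-D embedding is the first two principal components.
* **Annotation by markers.** A cluster is labeled with the phenotype whose
  marker features have the highest mean intensity in the cluster; the margin
  over the runner-up is kept, and ties at machine precision (or all-zero
  scores) leave the cluster unlabeled with a flag.

Differential features per cluster are log2 fold changes of means with a
1e-9 pseudo-count, two-sided Wilcoxon rank-sum p-values and Benjamini–
Hochberg adjustment (the multiple-testing procedure was an open choice).

Label transfer imputes a reference's metabolite channels onto a lipid-only
query: both are standardized with the reference's feature statistics, each
query pixel takes the `1/(d + ε)`-weighted mean of its k = 10 nearest
reference pixels. As a convex combination it is exact on the identity case
and never extrapolates beyond the reference's per-channel range. This
k-NN scheme replaces anchor-based transfer because it has the same contract
with a testable identity case and no stochastic components.

## Isotope correction

Only carbon isotopes are modeled: the tracers are ¹³C and TOF resolution
cannot separate heteroatom isotopologues. For a metabolite with *n* carbons,
column *j* of the forward matrix is the convolution of
`Binomial(j, purity + (1 − purity)·p13c)` (tracer carbons) with
`Binomial(n − j, p13c)` (remaining carbons), so tracer impurity and natural
abundance are handled by a single inversion. Defaults: `p13c = 0.0107`,
`purity = 0.99`.

Deconvolution uses non-negative least squares so noisy observations still
yield physical fractions, with the residual norm reported; a direct linear
solve is available for exactness checks. The corrected vector is renormalized
to sum to 1. An all-zero observation produces a *masked* result, not an
exception — undefined enrichment is data, and masks propagate through
cluster summaries. Correction happens before enrichment because fraction
enrichment is defined on true pools; the enrichment itself is
`intensity(M+k) / Σ intensities` and is scale-invariant. The labeled-carbon
contribution is `Σ k·f(M+k) / n`.

## Q-flux ratios

The four relative rates are computed from cluster-mean enrichments by
default (the cluster-average workflow); a per-pixel mode with symmetric
trimmed means is provided as an alternative since either convention is
defensible. Guards: fractions below `ε = 1e-6` in a denominator *or*
numerator invalidate a ratio with a reason — a zero forward flux contradicts
the steady-state model, so 0 is never reported as a rate — and
`V_GLS/V_IDH = r/(1−r)` is invalid when r ≥ 1 − ε. Note the m+5 enrichment
ratio r is bounded above by 1 at steady state (glutamate m+5 derives from
glutamine m+5), so a unit `V_GLS/V_OGDH` necessarily puts `V_GLS/V_IDH` at
its bound; the identity-chain test asserts exactly that.

## Synthetic data

The generator defines the conditions under which the pipeline is validated:

* **Tissue**: contiguous blob-like regions grown by seeded flood fill from
  random centers, one claim per type per round — mimicking tubular
  cross-sections without modeling anatomy. Every type keeps at least its
  seed pixel; growth balance makes each type ≥ 1 % of a 64×64 grid.
* **Flux ratios**: drawn per phenotype in [0.5, 1.5]. Because
  `V_GLS/V_IDH = r/(1−r)` must also land in that band, r is drawn on
  [0.5, 0.6] and the IDH ratio derived; the chain ratios are uniform on the
  band. With the default glutamine(m+5) = 0.5 every implied enrichment stays
  inside (0, 1).
* **Enrichments**: the Q-flux relations inverted —
  glutamate(m+5) = r·gln(m+5), succinate(m+4) = ratio·glu(m+5),
  malate(m+4) = ratio·succ(m+4) — with residual mass on M+0, since only the
  labeled channels enter the flux equations. Glucose-tracer-style channels
  carry no flux model and are supplied as plain fraction vectors.
* **Rendering**: phenotype lipid signatures (marker-dominated, with a shared
  tubular channel, a matrix-flagged decoy and a low-S/N decoy to exercise
  the filters) plus abundance-scaled, forward-convolved isotopologue
  channels; a log-normal TIC factor with CV 0.2; additive Gaussian noise of
  sd `noise_sd × signal`, truncated at zero as a detector would. Defaults
  `noise_sd = 0.01`, `tic_cv = 0.2` are conventional choices — the source
  instrument's noise characteristics are not published, so they are not
  fitted to anything.
* **Perfusion series**: 2-hourly samples; flow plateau at 400 mL/min
  (oxygen delivery ≈ 8 mL O₂/min at arterial pO₂ 645 mmHg, inside the
  5–15 mL O₂/min range expected for a kidney at a 75 mmHg set-point) with
  exponential decline after an optional failure day, uptake fading from
  1.0 toward 0.3 mL O₂/min, pH falling below 7.30 and lactate rising as the
  graft fails; weight gain scales to 28 % over 8 days.

What the generator does **not** emulate: spatial intensity gradients within
a phenotype, correlated (structured) noise, isobaric interferences, partial-
volume mixing at region boundaries, batch effects between sections, or any
reductive-carboxylation contribution to the TCA labels. Passing the recovery
benchmark therefore shows the chain is *correct and well-conditioned* under
realistic noise, not that real tissue meets these assumptions.

## Pipeline and reproducibility

`run_pipeline` executes simulate → preprocess → segment → correct → enrich →
qflux → physiology and writes every intermediate in a format its own module
re-reads. One seed fans out into per-stage child seeds via numpy's
`SeedSequence` (kept below 2³¹). The report JSON has sorted keys, no
timestamps and no paths, so identical configs give byte-identical bodies;
stage timings go to stderr only. Benchmarks run at 64×64 pixels with three
phenotypes (~1,300 pixels per phenotype), which already estimates cluster-
mean enrichments to ≲0.2 % — larger grids only slow the suite down without
changing what is being demonstrated.

## Physiology

Oxygen delivery is `pO₂ × 0.0031 × flow/100` (solubility in
mL O₂·dL⁻¹·mmHg⁻¹, flow converted to dL/min); uptake is computed literally
as delivery(arterial) − delivery(venous) so the linearity identity holds
bitwise, with a flag for reversed gradients. Vascular resistance is the
conventional MAP/flow. Weight gain is reported at full precision and as a
half-up-rounded integer percent. Sieving coefficients subtract the
pre-infusion background from both signals; negative numerators clamp to 0
with a flag, and a perfusate signal at background is invalid rather than a
division by ~0. The hemofiltration exchange fraction requires the reference
circuit volume explicitly — published "percent exchange" figures are
ambiguous about the volume they refer to, so no constant is guessed.

## Known limitations

* Carbon-only correction; no adduct or heteroatom handling.
* S/N and matrix co-localization are input flags, never estimated.
* k-means assumes roughly convex clusters in PCA space; heavily imbalanced
  or nested phenotypes may need a different clusterer behind the same
  interface.
* Flux ratios are relative rates at pseudo-steady state; no absolute fluxes,
  and no decomposition of reductive glutamine entry.
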