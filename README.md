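# msiflux

Spatially resolved ¹³C isotope tracing for MALDI mass spectrometry imaging
(MSI), built for ex vivo organ-perfusion studies: pixel-level lipidomic
segmentation into cell phenotypes, isotopologue deconvolution (natural
¹³C abundance + tracer purity), relative TCA-cycle flux ratios, and the
perfusion-physiology arithmetic (oxygen transport, vascular resistance,
glomerular sieving, weight gain) used to judge whether a machine-perfused
kidney is still metabolically alive.

## Who it is for

Groups running MALDI-MSI on tracer-incubated tissue — typically biopsies
from normothermic or subnormothermic machine perfusion — who need to go from
an exported pixel-by-feature intensity matrix to per-cell-type fraction
enrichments and relative enzyme rates, with every stage testable offline
against a synthetic forward model.

## The model

**Isotopologue correction.** For a metabolite with *n* carbons, each
unlabeled carbon is ¹³C with the natural abundance *p* ≈ 0.0107 and each
tracer-derived carbon is ¹³C with probability equal to the tracer purity
(0.99 for commercial U-¹³C tracers). The observed M+k distribution of a
truly M+j molecule is therefore a convolution of two binomials; stacking
those as columns gives a forward matrix **F** with observed = **F** · true,
inverted per pixel by non-negative least squares. Fraction enrichment of
M+k is its share of the corrected pool, summing to 1 over M+0…M+n.

**Q-flux.** After a 2 h U-¹³C₅-glutamine incubation the labeled pools reach
a pseudo-steady state and four relative TCA-cycle rates follow directly from
cluster-mean enrichments:

    V_GLS/V_OGDH  = glutamate(m+5) / glutamine(m+5)        = r
    V_GLS/V_IDH   = r / (1 − r)
    V_OGDH/V_SDHf = succinate(m+4) / glutamate(m+5)
    V_SDHf/V_MDH  = malate(m+4)   / succinate(m+4)

**Segmentation.** TIC-normalized intensities are turned into an integer
count matrix (⌊100 × fraction⌋), variance-stabilized (log1p + per-feature
scaling), reduced by PCA and partitioned by k-means — deterministic for a
fixed seed and invariant to pixel order. Metabolite channels can be
transferred from a labeled reference onto a lipid-only query by
distance-weighted k-nearest-neighbour imputation in the shared lipid space.

**Synthetic forward model.** `msiflux.synthetic` inverts the Q-flux
relations to build enrichments consistent with user-chosen flux ratios,
grows contiguous phenotype regions by seeded flood fill, applies the forward
isotope convolution, a log-normal per-pixel TIC factor and zero-truncated
Gaussian noise — so the whole pipeline can be scored against known truth
without any external data.

## Worked example

```python
from msiflux import qflux

fset = qflux.compute_flux_set({
    "glutamine_m5": 0.50, "glutamate_m5": 0.28,
    "succinate_m4": 0.22, "malate_m4": 0.18,
})
print(round(fset.gls_ogdh.value, 3), round(fset.gls_idh.value, 3),
      round(fset.ogdh_sdhf.value, 3), round(fset.sdhf_mdh.value, 3))
```

prints `0.56 1.273 0.786 0.818`: glutaminase runs at 56 % of the
α-ketoglutarate-dehydrogenase rate, and succinate dehydrogenase forward flux
at 82 % of malate dehydrogenase. The full chain on synthetic tissue
(`python examples/full_pipeline_demo.py`) prints

```
segmentation ARI: 1.000
worst flux-ratio relative error: 0.10%
```

meaning every pixel was assigned to its true phenotype and all twelve
phenotype-level flux ratios were recovered within 0.1 % of the generator's
truth at 1 % pixel noise. The other scripts in `examples/` cover isotope
correction, segmentation, and the perfusion-physiology calculations
(oxygen delivery ≈ 8 mL O₂/min at 400 mL/min flow, weight gain 28 %,
sieving 0 for 500 kDa dextran and ≈ 0.5 for 20 kDa dextran).

There is also a thin CLI: `msiflux simulate --out DIR` writes a synthetic
dataset, and `msiflux run --config config.toml` executes the full pipeline.

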