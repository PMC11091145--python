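"""Relative TCA-cycle rates from glutamine-tracer enrichments.

Cluster-mean fraction enrichments of glutamine(m+5), glutamate(m+5),
succinate(m+4) and malate(m+4) give four relative enzyme rates; a ratio of 1
means the two fluxes run at the same speed."""

from msiflux import qflux

enrichments = {
    "glutamine_m5": 0.50,
    "glutamate_m5": 0.28,
    "succinate_m4": 0.22,
    "malate_m4": 0.18,
}
fset = qflux.compute_flux_set(enrichments)
print(f"V_GLS/V_OGDH  = {fset.gls_ogdh.value:.3f}")
print(f"V_GLS/V_IDH   = {fset.gls_idh.value:.3f}")
print(f"V_OGDH/V_SDHf = {fset.ogdh_sdhf.value:.3f}")
print(f"V_SDHf/V_MDH  = {fset.sdhf_mdh.value:.3f}")
# e.g. V_GLS/V_OGDH = 0.56: about half of the alpha-ketoglutarate pool turns
# over from glutamine-derived glutamate per OGDH turn

invalid = qflux.compute_flux_set({**enrichments, "succinate_m4": 0.0})
print(f"zero succinate m+4 -> V_OGDH/V_SDHf invalid: {invalid.ogdh_sdhf.reason}")
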