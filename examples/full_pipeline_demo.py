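"""Run the whole pipeline on synthetic tissue and score flux recovery.

Simulates a 64×64 section whose phenotypes carry known TCA flux ratios, runs
segmentation, isotope correction, enrichment summaries and Q-flux, and
compares the recovered ratios with the generator's truth."""

import json
import tempfile

from msiflux.pipeline import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(seed=3, out_dir=tmp, width=64, height=64, n_types=3)
    report = run_pipeline(config)

print("estimated relative TCA rates per phenotype:")
for phenotype, doc in sorted(report["flux_ratios"].items()):
    vals = {k: round(doc[k]["value"], 3) for k in
            ("gls_ogdh", "gls_idh", "ogdh_sdhf", "sdhf_mdh")}
    print(f"  {phenotype}: {vals}")

rec = report["recovery"]
print(f"segmentation ARI: {rec['segmentation_ari']:.3f}")
print(f"worst flux-ratio relative error: {100 * rec['max_relative_error']:.2f}%")
# at 1% pixel noise and ~1300 pixels per phenotype the chain recovers every
# ratio to well under the 5% band the synthetic benchmark targets
print(json.dumps(report["physiology"], indent=2))
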