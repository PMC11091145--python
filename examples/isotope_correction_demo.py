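"""Correct an observed isotopologue pattern for natural abundance and purity.

A 5-carbon glutamate pool that is truly 30 % M+5 / 70 % M+0 is pushed through
the forward convolution (1.07 % natural ¹³C, 99 % tracer purity) and then
deconvolved back by non-negative least squares."""

import numpy as np

from msiflux import isotope

truth = np.array([0.7, 0, 0, 0, 0, 0.3])
model = isotope.build_forward_matrix(n_carbons=5, p13c=0.0107, tracer_purity=0.99)
observed = isotope.apply_forward(model, truth)
print("true fractions:    ", np.round(truth, 5))
print("observed fractions:", np.round(observed, 5))
# natural abundance moves ~5% of the M+0 pool into M+1/M+2; the impure tracer
# leaks some of the M+5 pool into M+4

result = isotope.correct_distribution(observed, model)
print("corrected:         ", np.round(np.asarray(result.fractions), 5))
print(f"residual norm: {result.residual:.2e}")

labeled = isotope.carbon_contribution(result.fractions, n_carbons=5)
print(f"labeled carbon fraction: {labeled:.3f}")  # 5 x 0.3 / 5 = 0.3
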