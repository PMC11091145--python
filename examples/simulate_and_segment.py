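"""Generate a synthetic MSI section and recover its cell phenotypes.

Builds a 48×48 tissue with three proximal-tubule phenotypes, TIC-normalizes
the pixel matrix, restricts to lipid-range features, clusters the pixels and
annotates clusters from marker lipids.  The adjusted Rand index against the
generator's labels says how cleanly the lipid signatures separate."""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from msiflux import msi, segmentation, synthetic

ds = synthetic.simulate_dataset(width=48, height=48, n_types=3, seed=11)
print(f"dataset: {ds.image.n_pixels} pixels x {ds.image.n_features} features")

normalized, n_dropped = msi.tic_normalize(ds.image)
lipids = msi.select_lipid_features(normalized, ds.features, min_mz=400, min_snr=3)
print(f"lipid features kept: {lipids.n_features} (dropped {n_dropped} empty pixels)")

cmap = segmentation.cluster_pixels(lipids, n_clusters=3, seed=0)
cmap = segmentation.annotate_clusters(cmap, lipids, ds.markers)
ari = adjusted_rand_score(ds.truth.pixel_labels, cmap.pixel_cluster)
print(f"adjusted Rand index vs ground truth: {ari:.3f}")

for cluster, phenotype in sorted(cmap.annotation.items()):
    share = 100.0 * np.mean(cmap.pixel_cluster == cluster)
    print(f"  cluster {cluster} -> {phenotype}: {share:.1f}% of pixels")
# an ARI of 1.0 means every pixel landed in its true phenotype;
# the percentages are the tissue composition the flood-fill generator drew
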