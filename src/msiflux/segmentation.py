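"""Pixel phenotyping from lipid profiles.

Pixels are clustered on a variance-stabilized count matrix (log1p of the
×100 integer counts, feature-standardized), reduced by PCA and partitioned
with k-means.  The combination is deterministic for a fixed seed and — by
fitting in a canonical coordinate order — invariant to pixel permutation.
Clusters are annotated by marker-feature intensity, and metabolite channels
can be transferred from a labeled reference image onto a query sharing the
lipid feature space via distance-weighted k-nearest-neighbour imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .msi import SpectralImage, to_count_matrix


@dataclass
class ClusterMap:
    """Per-pixel cluster ids plus optional cluster → phenotype annotation."""

    pixel_cluster: np.ndarray
    annotation: dict = field(default_factory=dict)
    margins: dict = field(default_factory=dict)
    unlabeled: set = field(default_factory=set)
    embedding: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixel_cluster = np.asarray(self.pixel_cluster, dtype=int)

    def phenotype_of(self, pixel: int) -> Optional[str]:
        return self.annotation.get(int(self.pixel_cluster[pixel]))

    def to_frame(self, coords: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": coords[:, 1],
                "y": coords[:, 0],
                "cluster": self.pixel_cluster,
                "phenotype": [
                    self.annotation.get(int(c), "") for c in self.pixel_cluster
                ],
            }
        )


def _stabilize(image: SpectralImage) -> np.ndarray:
    """log1p of the count matrix, centered and scaled to unit variance."""
    x = np.log1p(to_count_matrix(image).astype(float))
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    return (x - mean) / std


def cluster_pixels(
    image: SpectralImage,
    n_clusters: int,
    seed: int,
    n_components: int = 20,
) -> ClusterMap:
    """Partition pixels into ``n_clusters`` lipid phenotypes.

    Pixels are processed in canonical (row, col) order so that permuting the
    pixel rows of the input changes no assignment.  Cluster ids are relabeled
    by first appearance in that canonical order, making the ids themselves
    reproducible.  The stored 2-D embedding is the first two PCs.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if image.n_pixels < n_clusters:
        raise ValueError(
            f"{image.n_pixels} pixels cannot form {n_clusters} clusters"
        )
    x = _stabilize(image)
    order = np.lexsort((image.coords[:, 1], image.coords[:, 0]))
    n_comp = min(n_components, x.shape[1], x.shape[0])
    pca = PCA(n_components=n_comp, svd_solver="full")
    z = pca.fit_transform(x[order])
    km = KMeans(
        n_clusters=n_clusters, n_init=10, random_state=int(seed) % (2**31)
    )
    raw = km.fit_predict(z)

    # canonical relabel: cluster 0 is the first seen in coordinate order
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel)
    canon = np.array([relabel[lab] for lab in raw])

    labels = np.empty(image.n_pixels, dtype=int)
    labels[order] = canon
    embedding = np.empty((image.n_pixels, 2))
    embedding[order] = z[:, :2]
    return ClusterMap(pixel_cluster=labels, embedding=embedding)


def annotate_clusters(
    cmap: ClusterMap,
    image: SpectralImage,
    markers: Mapping[str, Sequence[str]],
    tie_tol: float = 1e-12,
) -> ClusterMap:
    """Label each cluster with the phenotype whose markers are brightest.

    ``markers`` maps phenotype name → list of feature names.  The score of a
    phenotype within a cluster is the mean intensity of its marker features
    over the cluster's pixels; the winning phenotype is recorded together
    with its margin over the runner-up.  A tie at machine precision (or an
    all-zero score vector) leaves the cluster unlabeled and flagged.
    """
    if image.feature_names is None:
        raise ValueError("annotation requires an image with feature names")
    idx = {}
    for phenotype, feats in markers.items():
        missing = [f for f in feats if f not in image.feature_names]
        if missing:
            raise ValueError(f"marker features not in image: {missing}")
        idx[phenotype] = [image.feature_index(f) for f in feats]

    annotation: dict[int, str] = {}
    margins: dict[int, float] = {}
    unlabeled: set[int] = set()
    phenotypes = list(markers)
    for cluster in np.unique(cmap.pixel_cluster):
        sel = cmap.pixel_cluster == cluster
        scores = np.array(
            [image.intensities[np.ix_(sel, idx[p])].mean() for p in phenotypes]
        )
        ranked = np.argsort(scores, kind="stable")[::-1]
        top, second = scores[ranked[0]], scores[ranked[1]] if len(scores) > 1 else 0.0
        margin = float(top - second)
        if top <= 0 or margin <= tie_tol:
            unlabeled.add(int(cluster))
            continue
        annotation[int(cluster)] = phenotypes[ranked[0]]
        margins[int(cluster)] = margin
    return replace(
        cmap, annotation=annotation, margins=margins, unlabeled=unlabeled
    )


def differential_features(
    image: SpectralImage,
    cmap: ClusterMap,
    cluster_id: int,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Per-feature log2 fold change and rank-sum p for one cluster vs the rest.

    log2FC uses the mean intensities with an ``eps`` pseudo-count so features
    absent on one side stay finite; p-values are two-sided Wilcoxon rank-sum
    with Benjamini-Hochberg adjustment reported alongside.
    """
    inside = cmap.pixel_cluster == cluster_id
    if inside.sum() < 2 or (~inside).sum() < 2:
        raise ValueError(
            f"cluster {cluster_id} needs >= 2 pixels inside and outside"
        )
    xi, xo = image.intensities[inside], image.intensities[~inside]
    log2fc = np.log2((xi.mean(axis=0) + eps) / (xo.mean(axis=0) + eps))
    pvals = stats.ranksums(xi, xo, axis=0).pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "feature": image.feature_names
            if image.feature_names is not None
            else [f"{v:.4f}" for v in image.mz],
            "mz": image.mz,
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
        }
    )


def transfer_labels(
    reference: SpectralImage,
    query: SpectralImage,
    k: int = 10,
    eps: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, Optional[list[str]]]:
    """Impute the reference's metabolite channels onto a lipid-only query.

    The shared lipid space is the m/z intersection of the two images; both
    are standardized with the *reference* feature means and variances, each
    query pixel finds its ``k`` nearest reference pixels there, and each
    metabolite channel is imputed as the ``1/(d + eps)``-weighted mean of the
    neighbours' values.  Being a convex combination, the imputation never
    leaves the range of the reference values per channel.

    Returns ``(imputed, metabolite_mz, metabolite_names)`` where ``imputed``
    is (query pixels × metabolite channels).
    """
    shared = np.isin(reference.mz, query.mz)
    if not shared.any():
        raise ValueError("reference and query share no features")
    met = ~shared
    q_cols = np.isin(query.mz, reference.mz[shared])

    ref_lip = reference.intensities[:, shared]
    qry_lip = query.intensities[:, q_cols]
    mean, std = ref_lip.mean(axis=0), ref_lip.std(axis=0)
    std[std == 0] = 1.0
    k = min(k, reference.n_pixels)
    nn = NearestNeighbors(n_neighbors=k).fit((ref_lip - mean) / std)
    dist, idx = nn.kneighbors((qry_lip - mean) / std)

    weights = 1.0 / (dist + eps)
    weights /= weights.sum(axis=1, keepdims=True)
    values = reference.intensities[:, met]
    imputed = np.einsum("qk,qkm->qm", weights, values[idx])
    names = (
        [n for n, m in zip(reference.feature_names, met) if m]
        if reference.feature_names is not None
        else None
    )
    return imputed, reference.mz[met], names
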