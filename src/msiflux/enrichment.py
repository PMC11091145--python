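"""Per-pixel fraction enrichments and their cluster-level summaries.

The workflow: correct every pixel's isotopologue channels for tracer purity
and natural ¹³C abundance, express them as fraction enrichments, average the
fractions within each phenotype cluster, and report log2 fold changes against
a baseline cluster.  Per-channel pseudo-images carry masked cells (no pixel,
or undefined enrichment) and are hotspot-clipped at a high quantile before
display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import numpy.ma as ma
import pandas as pd

from . import isotope
from .exceptions import NotNormalizedError
from .msi import SpectralImage, hotspot_clip


@dataclass
class EnrichmentResult:
    """Pixel-level corrected fractions plus the per-cluster summary table."""

    per_pixel: dict  # metabolite -> (n_pixels, n_carbons+1) masked fractions
    per_cluster: pd.DataFrame  # cluster, metabolite, k, mean, sd, n
    baseline: Optional[object] = None
    residuals: dict = field(default_factory=dict)


def pixel_enrichments(
    image: SpectralImage,
    features: pd.DataFrame,
    p13c: float = isotope.NATURAL_P13C,
    tracer_purity: float = isotope.DEFAULT_TRACER_PURITY,
    method: str = "nnls",
) -> tuple[dict, dict]:
    """Corrected per-pixel fraction enrichments for every isotopologue group.

    ``features`` is the feature table aligned by m/z to the image; rows with
    ``kind == "isotopologue"`` are grouped by metabolite name, each group is
    deconvolved with the forward matrix for its carbon count, and the result
    is a masked (pixels × channels) fraction array per metabolite.

    Returns ``(fractions, residuals)`` keyed by metabolite.
    """
    from .msi import _match_table

    aligned = _match_table(image, features)
    iso = aligned[aligned["kind"] == "isotopologue"]
    fractions: dict = {}
    residuals: dict = {}
    for metabolite, rows in iso.groupby("name", sort=True):
        n_carbons = int(rows["n_carbons"].iloc[0])
        ks = rows["isotopologue_index"].to_numpy(dtype=int)
        if sorted(ks) != list(range(n_carbons + 1)):
            raise ValueError(
                f"{metabolite}: need channels M+0..M+{n_carbons}, got {sorted(ks)}"
            )
        cols = rows.index.to_numpy()[np.argsort(ks)]
        block = image.intensities[:, cols]
        model = isotope.build_forward_matrix(n_carbons, p13c, tracer_purity, method)
        fractions[metabolite], residuals[metabolite] = isotope.correct_many(
            block, model
        )
    return fractions, residuals


def summarize_by_cluster(
    per_pixel: Mapping[str, ma.MaskedArray], labels: np.ndarray
) -> pd.DataFrame:
    """Mean ± sd fraction enrichment per (cluster, metabolite, isotopologue).

    Masked pixels are excluded from the statistics and counted out; a cluster
    with zero unmasked pixels for a channel is reported masked (NaN mean,
    ``n = 0``).
    """
    labels = np.asarray(labels)
    records = []
    for metabolite, fracs in per_pixel.items():
        fracs = ma.asarray(fracs)
        for cluster in np.unique(labels):
            block = fracs[labels == cluster]
            n_ok = int(block[:, 0].count())
            for k in range(block.shape[1]):
                col = block[:, k]
                if col.count() == 0:
                    records.append((cluster, metabolite, k, np.nan, np.nan, 0))
                else:
                    records.append(
                        (
                            cluster,
                            metabolite,
                            k,
                            float(col.mean()),
                            float(col.std(ddof=0)),
                            n_ok,
                        )
                    )
    return pd.DataFrame(
        records, columns=["cluster", "metabolite", "k", "mean", "sd", "n"]
    )


def log2fc_vs_baseline(
    per_cluster: pd.DataFrame, baseline, eps: float = 1e-9
) -> pd.DataFrame:
    """log2 fold change of each cluster mean against the baseline cluster.

    ``log2((mean + eps) / (baseline_mean + eps))`` per (metabolite, k); a
    zero mean is floored by ``eps`` and flagged.  The baseline cluster is 0
    by definition.  A masked baseline is a state error.
    """
    base = per_cluster[per_cluster["cluster"] == baseline]
    if base.empty:
        raise NotNormalizedError(f"baseline cluster {baseline!r} not present")
    if (base["n"] == 0).any() or base["mean"].isna().any():
        raise NotNormalizedError(f"baseline cluster {baseline!r} is masked")
    base_means = base.set_index(["metabolite", "k"])["mean"]

    out = per_cluster.copy()
    keys = list(zip(out["metabolite"], out["k"]))
    ref = np.array([base_means.get(key, np.nan) for key in keys])
    out["log2fc"] = np.log2((out["mean"].to_numpy() + eps) / (ref + eps))
    out["floored"] = (out["mean"].to_numpy() <= 0) | (ref <= 0)
    return out


def pseudo_image(
    values,
    coords: np.ndarray,
    quantile: float = 0.99,
    shape: Optional[tuple[int, int]] = None,
) -> ma.MaskedArray:
    """Place one channel's per-pixel values on a 2-D grid.

    Cells without a pixel — and pixels whose value is masked — stay masked
    (not zero).  Hotspot clipping at ``quantile`` is applied to the unmasked
    values before placement.  Permutation-invariant in pixel order.
    """
    values = ma.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=int)
    if values.size != coords.shape[0]:
        raise ValueError("values and coords disagree in length")
    if shape is None:
        shape = (int(coords[:, 0].max()) + 1, int(coords[:, 1].max()) + 1)

    unmasked = ~ma.getmaskarray(values)
    filled = values.compressed()
    if filled.size:
        clipped = hotspot_clip(filled, quantile)
        values = values.copy()
        values[unmasked] = clipped

    grid = ma.masked_all(shape)
    rows, cols = coords[unmasked, 0], coords[unmasked, 1]
    grid[rows, cols] = values[unmasked]
    return grid
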