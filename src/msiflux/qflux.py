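"""Relative TCA-cycle flux ratios from ¹³C₅-glutamine isotopologue enrichments.

After a 2 h incubation with U-¹³C₅-glutamine the labeled pools reach a
pseudo-steady state and four relative enzyme rates follow directly from
corrected fraction enrichments:

* ``V_GLS / V_OGDH  = glutamate(m+5) / glutamine(m+5)``
* ``V_GLS / V_IDH   = r / (1 - r)`` with ``r = glutamate(m+5)/glutamine(m+5)``
* ``V_OGDH / V_SDH(F) = succinate(m+4) / glutamate(m+5)``
* ``V_SDH(F) / V_MDH  = malate(m+4) / succinate(m+4)``

GLS = glutaminase, OGDH = α-ketoglutarate dehydrogenase, IDH = isocitrate
dehydrogenase, SDH(F) = succinate dehydrogenase forward flux, MDH = malate
dehydrogenase.  At steady state every forward flux is positive, so a zero
numerator or denominator is a model violation and is flagged invalid rather
than reported as 0 or ∞.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import numpy.ma as ma
import pandas as pd
from scipy import stats

#: Guard below which a fraction is treated as zero.
EPS = 1e-6

#: The four cluster-level enrichments the ratios consume.
REQUIRED_INPUTS = ("glutamine_m5", "glutamate_m5", "succinate_m4", "malate_m4")


@dataclass(frozen=True)
class FluxRatio:
    """A single relative rate; ``value is None`` marks an invalid ratio."""

    value: Optional[float]
    reason: Optional[str] = None

    @property
    def valid(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class FluxRatioSet:
    """The four relative TCA rates plus the enrichments they were built from."""

    gls_ogdh: FluxRatio
    gls_idh: FluxRatio
    ogdh_sdhf: FluxRatio
    sdhf_mdh: FluxRatio
    inputs: dict = field(default_factory=dict)
    eps: float = EPS

    def as_dict(self) -> dict:
        out: dict = {"inputs": dict(self.inputs)}
        for name in ("gls_ogdh", "gls_idh", "ogdh_sdhf", "sdhf_mdh"):
            ratio: FluxRatio = getattr(self, name)
            out[name] = {"value": ratio.value, "reason": ratio.reason}
        return out


def _clean(x) -> Optional[float]:
    """None / masked / NaN become None; everything else a float."""
    if x is None or x is ma.masked:
        return None
    x = float(x)
    if np.isnan(x):
        return None
    return x


def _ratio(num, den, eps: float) -> FluxRatio:
    num, den = _clean(num), _clean(den)
    if num is None or den is None:
        return FluxRatio(None, "masked input")
    if den <= eps:
        return FluxRatio(None, "zero denominator")
    if num <= eps:
        # a zero forward flux contradicts the steady-state model
        return FluxRatio(None, "zero numerator")
    return FluxRatio(num / den)


def v_gls_over_ogdh(glu_m5, gln_m5, eps: float = EPS) -> FluxRatio:
    """V_GLS / V_OGDH = glutamate(m+5) / glutamine(m+5)."""
    return _ratio(glu_m5, gln_m5, eps)


def v_gls_over_idh(glu_m5, gln_m5, eps: float = EPS) -> FluxRatio:
    """V_GLS / V_IDH = r / (1 - r), r = glutamate(m+5)/glutamine(m+5)."""
    r = v_gls_over_ogdh(glu_m5, gln_m5, eps)
    if not r.valid:
        return r
    if r.value >= 1.0 - eps:
        return FluxRatio(None, "ratio at bound (r >= 1)")
    return FluxRatio(r.value / (1.0 - r.value))


def v_ogdh_over_sdhf(succ_m4, glu_m5, eps: float = EPS) -> FluxRatio:
    """V_OGDH / V_SDH(F) = succinate(m+4) / glutamate(m+5)."""
    return _ratio(succ_m4, glu_m5, eps)


def v_sdhf_over_mdh(mal_m4, succ_m4, eps: float = EPS) -> FluxRatio:
    """V_SDH(F) / V_MDH = malate(m+4) / succinate(m+4)."""
    return _ratio(mal_m4, succ_m4, eps)


def compute_flux_set(
    enrichments: Mapping[str, float], eps: float = EPS
) -> FluxRatioSet:
    """All four ratios from a {input name: enrichment} mapping.

    ``enrichments`` must provide the keys in :data:`REQUIRED_INPUTS`; a
    missing or masked value invalidates every ratio that depends on it.
    """
    vals = {k: _clean(enrichments.get(k)) for k in REQUIRED_INPUTS}
    missing = [k for k in REQUIRED_INPUTS if k not in enrichments]

    def guard(ratio: FluxRatio, *needs: str) -> FluxRatio:
        lacking = [k for k in needs if k in missing]
        if lacking:
            return FluxRatio(None, f"missing input: {', '.join(lacking)}")
        return ratio

    gln, glu = vals["glutamine_m5"], vals["glutamate_m5"]
    succ, mal = vals["succinate_m4"], vals["malate_m4"]
    return FluxRatioSet(
        gls_ogdh=guard(v_gls_over_ogdh(glu, gln, eps), "glutamate_m5", "glutamine_m5"),
        gls_idh=guard(v_gls_over_idh(glu, gln, eps), "glutamate_m5", "glutamine_m5"),
        ogdh_sdhf=guard(
            v_ogdh_over_sdhf(succ, glu, eps), "succinate_m4", "glutamate_m5"
        ),
        sdhf_mdh=guard(v_sdhf_over_mdh(mal, succ, eps), "malate_m4", "succinate_m4"),
        inputs=vals,
        eps=eps,
    )


def _extract_inputs(per_cluster: pd.DataFrame, cluster) -> dict:
    """Pull the four Q-flux enrichments for one cluster from a summary table."""
    sub = per_cluster[per_cluster["cluster"] == cluster]
    wanted = {
        ("glutamine", 5): "glutamine_m5",
        ("glutamate", 5): "glutamate_m5",
        ("succinate", 4): "succinate_m4",
        ("malate", 4): "malate_m4",
    }
    out: dict = {}
    for (met, k), key in wanted.items():
        row = sub[(sub["metabolite"] == met) & (sub["k"] == k)]
        if len(row) == 1 and row["n"].iloc[0] > 0:
            out[key] = float(row["mean"].iloc[0])
    return out


def flux_by_cluster(per_cluster: pd.DataFrame, eps: float = EPS) -> dict:
    """Cluster-mean Q-flux: one :class:`FluxRatioSet` per cluster.

    ``per_cluster`` is the summary table produced by
    :func:`msiflux.enrichment.summarize_by_cluster` (columns ``cluster``,
    ``metabolite``, ``k``, ``mean``, ``sd``, ``n``).  This is the default
    mode; ratios are computed on the cluster-averaged enrichments.
    """
    return {
        cluster: compute_flux_set(_extract_inputs(per_cluster, cluster), eps)
        for cluster in pd.unique(per_cluster["cluster"])
    }


def per_pixel_flux(
    per_pixel: Mapping[str, ma.MaskedArray],
    labels: np.ndarray,
    trim: float = 0.05,
    eps: float = EPS,
) -> dict:
    """Alternative mode: per-pixel ratios summarized by trimmed mean.

    ``per_pixel`` maps metabolite name to a (pixels × channels) masked
    fraction array.  Ratios are formed pixel-wise where all inputs are
    unmasked and both terms exceed ``eps``, then reduced per cluster with a
    symmetric trimmed mean (``trim`` fraction cut from each tail).
    """
    labels = np.asarray(labels)
    needed = {"glutamine": 5, "glutamate": 5, "succinate": 4, "malate": 4}
    chans = {}
    for met, k in needed.items():
        if met not in per_pixel:
            raise ValueError(f"per-pixel enrichments missing {met!r}")
        chans[met] = ma.asarray(per_pixel[met])[:, k]

    def trimmed(values: np.ndarray) -> Optional[float]:
        if values.size == 0:
            return None
        return float(stats.trim_mean(values, trim))

    out = {}
    for cluster in np.unique(labels):
        sel = labels == cluster
        gln, glu = chans["glutamine"][sel], chans["glutamate"][sel]
        succ, mal = chans["succinate"][sel], chans["malate"][sel]

        def pixelwise(num, den):
            good = (
                ~ma.getmaskarray(num)
                & ~ma.getmaskarray(den)
                & (ma.filled(num, 0) > eps)
                & (ma.filled(den, 0) > eps)
            )
            return ma.filled(num, 0)[good] / ma.filled(den, 0)[good]

        r = pixelwise(glu, gln)
        r = r[r < 1.0 - eps]
        ratios = {
            "gls_ogdh": trimmed(pixelwise(glu, gln)),
            "gls_idh": trimmed(r / (1.0 - r)),
            "ogdh_sdhf": trimmed(pixelwise(succ, glu)),
            "sdhf_mdh": trimmed(pixelwise(mal, succ)),
        }
        out[cluster] = FluxRatioSet(
            **{
                k: FluxRatio(v) if v is not None else FluxRatio(None, "no valid pixels")
                for k, v in ratios.items()
            },
            inputs={},
            eps=eps,
        )
    return out
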