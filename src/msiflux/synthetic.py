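"""Ground-truth-bearing synthetic MSI datasets and perfusion time series.

The generator works at the feature-intensity level (no mass-spectral peak
shapes): a 2-D tissue of contiguous phenotype regions is grown by seeded
flood fill, each phenotype gets a lipid signature and a set of true
isotopologue enrichments built by *inverting* the steady-state Q-flux
relations, and the observed image applies — in order — the natural-abundance
/ tracer-purity forward convolution, a log-normal per-pixel TIC factor, and
additive zero-truncated Gaussian noise.  A :class:`GroundTruth` record keeps
everything a downstream recovery test needs.

Defaults mirror the study conditions: 5 µm pixels, ¹³C natural abundance
0.0107, 99 % tracer purity, glutamine-tracer incubation where glutamine(m+5)
reaches 0.5 of the pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

from . import isotope
from .exceptions import InfeasibleRatioError
from .msi import DEFAULT_PIXEL_SIZE_UM, FEATURE_COLUMNS, SpectralImage

#: Carbon counts of the metabolites the generator knows about.
METABOLITE_CARBONS = {
    "glutamine": 5,
    "glutamate": 5,
    "succinate": 4,
    "malate": 4,
    "aspartate": 4,
    "lactate": 3,
    "3PG": 3,
    "G3P": 3,
    "hexose": 6,
}

#: Monoisotopic [M-H]⁻ m/z of the M+0 species.
METABOLITE_MZ = {
    "glutamine": 145.0619,
    "glutamate": 146.0459,
    "succinate": 117.0193,
    "malate": 133.0142,
    "aspartate": 132.0302,
    "lactate": 89.0244,
    "3PG": 184.9857,
    "G3P": 171.0064,
    "hexose": 179.0561,
}

#: Mass shift per ¹³C.
C13_SHIFT = 1.00336

#: Relative base abundance of each metabolite pool in the rendered image.
METABOLITE_ABUNDANCE = {
    "glutamine": 10.0,
    "glutamate": 12.0,
    "succinate": 6.0,
    "malate": 6.0,
}

#: Phenotype names in assignment order (proximal tubule subsets first).
PHENOTYPE_NAMES = [
    "PT_1",
    "PT_2",
    "PT_3",
    "ECAD",
    "podocyte",
    "other",
    "stroma",
    "immune",
]

# marker lipids per phenotype: (name, m/z) — PT/podocyte markers follow the
# renal lipid channels commonly reported for these cell types
_MARKER_LIPIDS = [
    ("lipid_810.5", 810.5),
    ("lipid_766.5", 766.5),
    ("lipid_865.6", 865.6),
    ("lipid_744.6", 744.55),
    ("lipid_838.6", 838.6),
    ("lipid_790.5", 790.54),
    ("lipid_834.5", 834.53),
    ("lipid_746.6", 746.57),
]
_SHARED_LIPID = ("lipid_885.6", 885.6)


@dataclass(frozen=True)
class LipidPanel:
    """Per-phenotype lipid signatures over a shared feature list."""

    names: list
    mz: np.ndarray
    kind: list
    snr: np.ndarray
    signatures: np.ndarray  # (n_types, n_lipids)


def default_lipid_panel(n_types: int) -> LipidPanel:
    """Marker-dominated signatures: each phenotype over-expresses its own
    marker lipid; a shared tubular channel plus a MALDI-matrix signal and a
    low-S/N feature exercise the downstream filters."""
    if not 2 <= n_types <= len(_MARKER_LIPIDS):
        raise ValueError(f"n_types must be in [2, {len(_MARKER_LIPIDS)}]")
    markers = _MARKER_LIPIDS[:n_types]
    names = [n for n, _ in markers] + [
        _SHARED_LIPID[0],
        "matrix_551.5",
        "lowsnr_920.7",
    ]
    mz = np.array([v for _, v in markers] + [_SHARED_LIPID[1], 551.46, 920.7])
    kind = ["lipid"] * n_types + ["lipid", "matrix", "lipid"]
    snr = np.array([12.0] * n_types + [15.0, 9.0, 2.0])
    signatures = np.full((n_types, n_types + 3), 5.0)
    for t in range(n_types):
        signatures[t, t] = 60.0
    signatures[:, n_types] = 30.0  # shared tubular lipid
    signatures[:, n_types + 1] = 10.0  # matrix signal, uniform
    signatures[:, n_types + 2] = 8.0  # real but low-S/N feature
    return LipidPanel(names, mz, kind, snr, signatures)


@dataclass
class GroundTruth:
    """Everything the generator decided, for downstream recovery checks."""

    pixel_labels: np.ndarray  # (n_pixels,) phenotype index per pixel
    phenotypes: list
    true_flux_ratios: dict  # phenotype -> {ratio name -> value}
    true_enrichments: dict  # phenotype -> {metabolite -> fraction vector}
    tracer_purity: float
    p13c: float
    seed: int

    def validate(self, n_pixels: Optional[int] = None) -> None:
        if n_pixels is not None and self.pixel_labels.size != n_pixels:
            raise ValueError("pixel_labels does not cover every pixel")
        for phen, ratios in self.true_flux_ratios.items():
            for name, value in ratios.items():
                if not np.isfinite(value) or value <= 0:
                    raise ValueError(f"{phen}/{name}: flux ratio must be > 0")
        for phen, mets in self.true_enrichments.items():
            for met, vec in mets.items():
                vec = np.asarray(vec, dtype=float)
                if abs(vec.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{phen}/{met}: fractions must sum to 1")

    def to_json(self, path) -> None:
        doc = {
            "pixel_labels": self.pixel_labels.tolist(),
            "phenotypes": list(self.phenotypes),
            "true_flux_ratios": self.true_flux_ratios,
            "true_enrichments": {
                p: {m: np.asarray(v).tolist() for m, v in mets.items()}
                for p, mets in self.true_enrichments.items()
            },
            "tracer_purity": self.tracer_purity,
            "p13c": self.p13c,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            pixel_labels=np.asarray(doc["pixel_labels"], dtype=int),
            phenotypes=doc["phenotypes"],
            true_flux_ratios=doc["true_flux_ratios"],
            true_enrichments={
                p: {m: np.asarray(v) for m, v in mets.items()}
                for p, mets in doc["true_enrichments"].items()
            },
            tracer_purity=doc["tracer_purity"],
            p13c=doc["p13c"],
            seed=doc["seed"],
        )


def generate_tissue(width: int, height: int, n_types: int, seed: int) -> np.ndarray:
    """Grow contiguous blob-like phenotype regions by seeded flood fill.

    Each type starts from a random seed pixel and claims one random frontier
    neighbour per round, so regions stay connected and roughly balanced.
    Returns a (height, width) label grid covering every pixel; deterministic
    for a fixed seed.
    """
    if width < 8 or height < 8:
        raise ValueError("width and height must be >= 8")
    if not 2 <= n_types <= 8:
        raise ValueError("n_types must be in [2, 8]")
    rng = np.random.default_rng(seed)
    labels = np.full((height, width), -1, dtype=int)
    flat = rng.choice(width * height, size=n_types, replace=False)
    frontiers: list[list[tuple[int, int]]] = []
    for t, f in enumerate(flat):
        r, c = divmod(int(f), width)
        labels[r, c] = t
        frontiers.append([(r, c)])

    remaining = width * height - n_types
    while remaining > 0:
        grew = False
        for t in range(n_types):
            front = frontiers[t]
            while front:
                i = int(rng.integers(len(front)))
                r, c = front[i]
                nbrs = [
                    (rr, cc)
                    for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                    if 0 <= rr < height and 0 <= cc < width and labels[rr, cc] < 0
                ]
                if nbrs:
                    rr, cc = nbrs[int(rng.integers(len(nbrs)))]
                    labels[rr, cc] = t
                    front.append((rr, cc))
                    remaining -= 1
                    grew = True
                    break
                front[i] = front[-1]
                front.pop()
        if not grew:  # pragma: no cover - cannot happen on a connected grid
            break
    return labels


def sample_flux_ratios(
    rng: np.random.Generator, low: float = 0.5, high: float = 1.5
) -> dict:
    """Draw a consistent set of the four relative TCA rates in [low, high].

    V_GLS/V_OGDH is the m+5 enrichment ratio r, which the steady-state model
    bounds to (0, 1), and V_GLS/V_IDH = r/(1-r); keeping both inside
    [low, high] restricts r to [low, high/(1+high)].  The two chain ratios
    are drawn uniformly on [low, high].
    """
    r_hi = high / (1.0 + high)
    if not 0 < low < r_hi:
        raise ValueError(f"no feasible V_GLS/V_OGDH draw in [{low}, {r_hi}]")
    r = float(rng.uniform(low, r_hi))
    return {
        "gls_ogdh": r,
        "gls_idh": r / (1.0 - r),
        "ogdh_sdhf": float(rng.uniform(low, high)),
        "sdhf_mdh": float(rng.uniform(low, high)),
    }


def forward_isotopologues(
    true_flux_ratios: Mapping[str, float], gln_m5: float = 0.5
) -> dict:
    """Invert the Q-flux relations into consistent true enrichment vectors.

    Given the glutamine(m+5) pool fraction reached during the tracer
    incubation, the chain is
    ``glutamate(m+5) = gls_ogdh × gln_m5``,
    ``succinate(m+4) = ogdh_sdhf × glutamate(m+5)``,
    ``malate(m+4)   = sdhf_mdh × succinate(m+4)``;
    residual mass goes to M+0.  Feeding these through a perfect correction
    and the flux equations reproduces the input ratios exactly.
    """
    if not 0.0 < gln_m5 < 1.0:
        raise InfeasibleRatioError(f"glutamine m+5 must be in (0,1), got {gln_m5}")
    if "gls_ogdh" in true_flux_ratios:
        r = float(true_flux_ratios["gls_ogdh"])
    elif "gls_idh" in true_flux_ratios:
        q = float(true_flux_ratios["gls_idh"])
        r = q / (1.0 + q)
    else:
        raise InfeasibleRatioError("need gls_ogdh or gls_idh")
    chain = {
        "glutamate": (5, r * gln_m5),
        "succinate": (4, float(true_flux_ratios["ogdh_sdhf"]) * r * gln_m5),
    }
    chain["malate"] = (
        4,
        float(true_flux_ratios["sdhf_mdh"]) * chain["succinate"][1],
    )
    out = {"glutamine": _one_hot(5, 5, gln_m5)}
    for met, (n, value) in chain.items():
        if not 0.0 < value < 1.0:
            raise InfeasibleRatioError(
                f"{met} labeled fraction {value:.4f} outside (0, 1)"
            )
        out[met] = _one_hot(n, n, value)  # the labeled species is M+n
    return out


def _one_hot(n_carbons: int, k: int, value: float) -> np.ndarray:
    vec = np.zeros(n_carbons + 1)
    vec[k] = value
    vec[0] = 1.0 - value
    return vec


class RenderedDataset(NamedTuple):
    image: SpectralImage
    features: pd.DataFrame
    truth: GroundTruth


def render_dataset(
    labels: np.ndarray,
    lipid_panel: LipidPanel,
    metabolite_enrichments: Mapping[int, Mapping[str, np.ndarray]],
    noise_sd: float = 0.01,
    tic_cv: float = 0.2,
    seed: int = 0,
    p13c: float = isotope.NATURAL_P13C,
    tracer_purity: float = isotope.DEFAULT_TRACER_PURITY,
    true_flux_ratios: Optional[Mapping[int, Mapping[str, float]]] = None,
    metabolite_abundance: Optional[Mapping[str, float]] = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> RenderedDataset:
    """Render a label grid into a noisy pixel-by-feature image.

    Per pixel: the phenotype's base feature vector (lipid signature plus
    forward-convolved, abundance-scaled isotopologue channels) is multiplied
    by a log-normal TIC factor with coefficient of variation ``tic_cv`` and
    perturbed by Gaussian noise of sd ``noise_sd × signal``, truncated at
    zero.  The noiseless, convolution-free enrichments go into the returned
    :class:`GroundTruth`.
    """
    if noise_sd < 0 or tic_cv < 0:
        raise ValueError("noise_sd and tic_cv must be >= 0")
    labels = np.asarray(labels, dtype=int)
    n_types = int(labels.max()) + 1
    if lipid_panel.signatures.shape[0] != n_types:
        raise ValueError(
            f"panel has {lipid_panel.signatures.shape[0]} signatures for "
            f"{n_types} phenotypes"
        )
    for t in range(n_types):
        if t not in metabolite_enrichments:
            raise ValueError(f"no metabolite enrichments for phenotype {t}")
    abundance = dict(metabolite_abundance or METABOLITE_ABUNDANCE)

    # assemble feature axis: lipids + one channel per isotopologue.
    # channel_names are unique per feature (for the image); table names carry
    # the metabolite identity shared by its M+0..M+n channels.
    channel_names = list(lipid_panel.names)
    names = list(lipid_panel.names)
    mz = list(lipid_panel.mz)
    kinds = list(lipid_panel.kind)
    snrs = list(lipid_panel.snr)
    n_carb: list = [np.nan] * len(names)
    iso_k: list = [np.nan] * len(names)

    metabolites = sorted(metabolite_enrichments[0])
    models = {}
    for met in metabolites:
        n = METABOLITE_CARBONS[met]
        models[met] = isotope.build_forward_matrix(n, p13c, tracer_purity)
        for k in range(n + 1):
            channel_names.append(f"{met}_m{k}")
            names.append(met)
            mz.append(METABOLITE_MZ[met] + k * C13_SHIFT)
            kinds.append("isotopologue")
            snrs.append(8.0)
            n_carb.append(n)
            iso_k.append(k)

    base = np.zeros((n_types, len(names)))
    n_lip = len(lipid_panel.names)
    base[:, :n_lip] = lipid_panel.signatures
    col = n_lip
    for met in metabolites:
        n = METABOLITE_CARBONS[met]
        for t in range(n_types):
            truth_vec = np.asarray(metabolite_enrichments[t][met], dtype=float)
            observed = models[met].forward @ truth_vec
            base[t, col : col + n + 1] = abundance.get(met, 5.0) * observed
        col += n + 1

    order = np.argsort(mz, kind="stable")
    mz_arr = np.asarray(mz)[order]
    base = base[:, order]
    features = pd.DataFrame(
        {
            "mz": mz_arr,
            "name": np.asarray(names, dtype=object)[order],
            "n_carbons": np.asarray(n_carb)[order],
            "kind": np.asarray(kinds, dtype=object)[order],
            "snr": np.asarray(snrs)[order],
            "isotopologue_index": np.asarray(iso_k)[order],
        },
        columns=FEATURE_COLUMNS,
    )

    rows, cols_grid = np.indices(labels.shape)
    coords = np.column_stack([rows.ravel(), cols_grid.ravel()])
    flat_labels = labels.ravel()

    rng = np.random.default_rng(seed)
    signal = base[flat_labels]
    if tic_cv > 0:
        sigma = np.sqrt(np.log1p(tic_cv**2))
        tic = rng.lognormal(mean=0.0, sigma=sigma, size=(signal.shape[0], 1))
        signal = signal * tic
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, 1.0, size=signal.shape) * (
            noise_sd * signal
        )
        signal = np.clip(signal, 0.0, None)

    image = SpectralImage(
        coords=coords,
        mz=mz_arr,
        intensities=signal,
        pixel_size_um=pixel_size_um,
        feature_names=list(np.asarray(channel_names, dtype=object)[order]),
    )
    phen_names = PHENOTYPE_NAMES[:n_types]
    truth = GroundTruth(
        pixel_labels=flat_labels.copy(),
        phenotypes=phen_names,
        true_flux_ratios={
            phen_names[t]: dict((true_flux_ratios or {}).get(t, {}))
            for t in range(n_types)
        },
        true_enrichments={
            phen_names[t]: {
                m: np.asarray(v, dtype=float)
                for m, v in metabolite_enrichments[t].items()
            }
            for t in range(n_types)
        },
        tracer_purity=tracer_purity,
        p13c=p13c,
        seed=seed,
    )
    truth.validate(n_pixels=coords.shape[0])
    return RenderedDataset(image, features, truth)


class SimulatedDataset(NamedTuple):
    image: SpectralImage
    features: pd.DataFrame
    truth: GroundTruth
    markers: dict
    label_grid: np.ndarray


def simulate_dataset(
    width: int = 64,
    height: int = 64,
    n_types: int = 3,
    seed: int = 0,
    noise_sd: float = 0.01,
    tic_cv: float = 0.2,
    p13c: float = isotope.NATURAL_P13C,
    tracer_purity: float = isotope.DEFAULT_TRACER_PURITY,
    gln_m5: float = 0.5,
    ratio_low: float = 0.5,
    ratio_high: float = 1.5,
) -> SimulatedDataset:
    """One-call glutamine-tracer dataset: tissue + per-phenotype flux ratios
    + rendered image, with cluster-annotation markers included."""
    ss = np.random.SeedSequence(seed)
    s_tissue, s_ratio, s_render = (
        int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(3)
    )
    labels = generate_tissue(width, height, n_types, s_tissue)
    rng = np.random.default_rng(s_ratio)
    ratios = {
        t: sample_flux_ratios(rng, ratio_low, ratio_high) for t in range(n_types)
    }
    enrichments = {
        t: forward_isotopologues(ratios[t], gln_m5=gln_m5) for t in range(n_types)
    }
    panel = default_lipid_panel(n_types)
    rendered = render_dataset(
        labels,
        panel,
        enrichments,
        noise_sd=noise_sd,
        tic_cv=tic_cv,
        seed=s_render,
        p13c=p13c,
        tracer_purity=tracer_purity,
        true_flux_ratios=ratios,
    )
    truth = GroundTruth(
        pixel_labels=rendered.truth.pixel_labels,
        phenotypes=rendered.truth.phenotypes,
        true_flux_ratios=rendered.truth.true_flux_ratios,
        true_enrichments=rendered.truth.true_enrichments,
        tracer_purity=tracer_purity,
        p13c=p13c,
        seed=seed,
    )
    markers = {
        PHENOTYPE_NAMES[t]: [panel.names[t]] for t in range(n_types)
    }
    return SimulatedDataset(rendered.image, rendered.features, truth, markers, labels)


def generate_perfusion_timeseries(
    days: int, failure_day: Optional[float] = None, seed: int = 0
) -> "PerfusionTimeSeries":
    """Smooth parametric perfusion record with reproducible noise.

    Flow holds a plateau and declines after ``failure_day`` (if any), while
    lactate rises, pH falls and oxygen uptake fades — the hemodynamic
    trajectory of a graft failing on pump.  Sampled every 2 h.
    """
    from .physiology import MAP_SETPOINT, O2_SOLUBILITY, PerfusionTimeSeries

    if days < 1:
        raise ValueError("days must be >= 1")
    if failure_day is not None and failure_day > days:
        raise ValueError("failure_day cannot exceed days")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, days * 24.0 + 1e-9, 2.0)

    if failure_day is None:
        fail = np.zeros_like(t)
    else:
        dt = np.clip(t - failure_day * 24.0, 0.0, None)
        fail = 1.0 - np.exp(-dt / 36.0)

    # ~400 mL/min plateau at the 75 mmHg set-point puts oxygen delivery in
    # the 5-15 mL O2/min range expected for a perfused human kidney
    flow = np.clip(400.0 * (1.0 - 0.65 * fail) + rng.normal(0, 4.0, t.size), 0, None)
    po2_art = np.clip(645.0 + rng.normal(0, 5.0, t.size), 0, None)
    uptake = 1.0 - 0.7 * fail  # mL O2/min
    delta = uptake * 100.0 / (O2_SOLUBILITY * np.clip(flow, 1.0, None))
    po2_ven = np.clip(po2_art - delta + rng.normal(0, 5.0, t.size), 0, None)
    ph = 7.40 - 0.18 * fail + rng.normal(0, 0.005, t.size)
    lactate = np.clip(1.2 + 7.0 * fail + rng.normal(0, 0.1, t.size), 0, None)
    glucose = np.clip(5.0 + rng.normal(0, 0.15, t.size), 0, None)

    weight_initial = 283.0
    weight_final = weight_initial * (1.0 + 0.28 * days / 8.0)
    return PerfusionTimeSeries(
        time_h=t,
        flow_ml_min=flow,
        map_mmhg=np.full(t.size, MAP_SETPOINT),
        po2_art=po2_art,
        po2_ven=po2_ven,
        ph=ph,
        lactate_mmol_l=lactate,
        glucose_mmol_l=glucose,
        weight_initial_g=weight_initial,
        weight_final_g=weight_final,
    )
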