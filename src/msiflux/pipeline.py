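"""End-to-end orchestration: simulate → preprocess → segment → correct →
enrich → qflux → physiology → report.

A single :class:`RunConfig` seed fans out into per-stage child seeds, every
intermediate artifact is written in a format its own module can re-read, and
the report JSON is sorted and timestamp-free so identical configs produce
byte-identical report bodies.
"""

from __future__ import annotations

import json
import sys
import time
import tomllib
from contextlib import contextmanager
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import enrichment as enr
from . import msi, physiology, qflux, segmentation, synthetic
from .exceptions import StageError


@dataclass
class RunConfig:
    """Flat, validated parameter set for one pipeline run."""

    seed: int = 0
    out_dir: str = "msiflux_run"
    # synthetic input
    width: int = 48
    height: int = 48
    n_types: int = 3
    noise_sd: float = 0.01
    tic_cv: float = 0.2
    gln_m5: float = 0.5
    # preprocessing
    min_mz: float = 400.0
    min_snr: float = 3.0
    tol_ppm: float = 20.0
    # segmentation
    n_clusters: Optional[int] = None  # defaults to n_types
    k_transfer: int = 10
    # isotope correction
    p13c: float = 0.0107
    tracer_purity: float = 0.99
    # reporting
    quantile: float = 0.99
    baseline: str = "PT_1"
    # physiology
    days: int = 8
    failure_day: Optional[float] = 5.0
    # optional real input (skips simulation and recovery scoring)
    input_csv: Optional[str] = None
    input_features: Optional[str] = None

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if not 0.0 <= self.p13c < 0.5:
            raise ValueError("p13c out of range")
        if not 0.0 < self.tracer_purity <= 1.0:
            raise ValueError("tracer_purity out of range")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile out of range")
        if not 0.0 < self.gln_m5 < 1.0:
            raise ValueError("gln_m5 out of range")
        if self.noise_sd < 0 or self.tic_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.tol_ppm <= 0 or self.min_snr < 0:
            raise ValueError("tolerances must be positive")
        if self.k_transfer < 1:
            raise ValueError("k_transfer must be >= 1")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.failure_day is not None and self.failure_day > self.days:
            raise ValueError("failure_day cannot exceed days")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(f"input path does not exist: {self.input_csv}")
        if self.input_features is not None and not Path(self.input_features).exists():
            raise FileNotFoundError(
                f"input path does not exist: {self.input_features}"
            )

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def demo_config(out_dir: str, seed: int = 0) -> RunConfig:
    """The packaged demonstration configuration (all defaults)."""
    return RunConfig(seed=seed, out_dir=out_dir)


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc
    print(f"[msiflux] stage {name}: {time.perf_counter() - t0:.2f}s", file=sys.stderr)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, write intermediates and the report, return the
    report document.  Any stage error aborts with the stage name and cause."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s_sim, s_cluster, s_phys = _child_seeds(config.seed, 3)
    # paths are excluded from the report body: two runs of one config into
    # different directories must produce byte-identical reports
    params = {
        k: v
        for k, v in config.to_dict().items()
        if k not in ("out_dir", "input_csv", "input_features")
    }
    report: dict = {"config": params}
    truth = None
    markers = None

    with _stage("simulate"):
        if config.input_csv is not None:
            image = msi.read_pixel_csv(config.input_csv)
            features = msi.read_feature_table(config.input_features)
        else:
            ds = synthetic.simulate_dataset(
                width=config.width,
                height=config.height,
                n_types=config.n_types,
                seed=s_sim,
                noise_sd=config.noise_sd,
                tic_cv=config.tic_cv,
                p13c=config.p13c,
                tracer_purity=config.tracer_purity,
                gln_m5=config.gln_m5,
            )
            image, features, truth, markers = ds.image, ds.features, ds.truth, ds.markers
            msi.write_pixel_csv(image, out / "dataset.csv")
            msi.write_feature_table(features, out / "features.tsv")
            truth.to_json(out / "ground_truth.json")

    with _stage("preprocess"):
        norm, n_dropped = msi.tic_normalize(image)
        lipid_img = msi.select_lipid_features(
            norm, features, min_mz=config.min_mz, min_snr=config.min_snr
        )
        report["preprocess"] = {
            "n_pixels": norm.n_pixels,
            "n_dropped_zero_tic": n_dropped,
            "n_lipid_features": lipid_img.n_features,
            "n_features": norm.n_features,
        }

    with _stage("segment"):
        n_clusters = config.n_clusters or config.n_types
        cmap = segmentation.cluster_pixels(lipid_img, n_clusters, seed=s_cluster)
        if markers is not None:
            cmap = segmentation.annotate_clusters(cmap, lipid_img, markers)
        cmap.to_frame(norm.coords).to_csv(out / "clusters.csv", index=False)
        cluster_names = np.array(
            [
                cmap.annotation.get(int(c), f"cluster_{c}")
                for c in cmap.pixel_cluster
            ]
        )
        composition = {
            name: round(float(np.mean(cluster_names == name)) * 100.0, 2)
            for name in sorted(set(cluster_names))
        }
        report["segmentation"] = {
            "n_clusters": n_clusters,
            "composition_pct": composition,
        }

    with _stage("enrich"):
        per_pixel, _residuals = enr.pixel_enrichments(
            norm, features, p13c=config.p13c, tracer_purity=config.tracer_purity
        )
        per_cluster = enr.summarize_by_cluster(per_pixel, cluster_names)
        baseline = config.baseline
        if baseline not in set(cluster_names):
            baseline = sorted(set(cluster_names))[0]
        table = enr.log2fc_vs_baseline(per_cluster, baseline)
        table.to_csv(out / "enrichment.csv", index=False)
        report["enrichment"] = {"baseline": baseline}

    with _stage("qflux"):
        flux = qflux.flux_by_cluster(per_cluster)
        flux_doc = {str(c): fset.as_dict() for c, fset in flux.items()}
        with open(out / "flux.json", "w") as fh:
            json.dump(flux_doc, fh, sort_keys=True, indent=2)
        report["flux_ratios"] = flux_doc

    if truth is not None:
        with _stage("recovery"):
            coord_to_label = {
                (int(r), int(c)): int(lab)
                for (r, c), lab in zip(image.coords, truth.pixel_labels)
            }
            true_labels = np.array(
                [coord_to_label[(int(r), int(c))] for r, c in norm.coords]
            )
            ari = float(adjusted_rand_score(true_labels, cmap.pixel_cluster))
            errors: dict = {}
            for phen, true_ratios in truth.true_flux_ratios.items():
                if phen not in flux or not true_ratios:
                    continue
                est = flux[phen]
                errors[phen] = {
                    name: (
                        abs(getattr(est, name).value - true_val) / true_val
                        if getattr(est, name).valid
                        else None
                    )
                    for name, true_val in true_ratios.items()
                }
            flat = [e for d in errors.values() for e in d.values() if e is not None]
            report["recovery"] = {
                "segmentation_ari": ari,
                "relative_errors": errors,
                "max_relative_error": max(flat) if flat else None,
                "n_ratios_scored": len(flat),
            }

    with _stage("physiology"):
        ts = synthetic.generate_perfusion_timeseries(
            config.days, config.failure_day, seed=s_phys
        )
        ts.to_csv(out / "timeseries.csv")
        delivery = physiology.oxygen_delivery(ts.po2_art, ts.flow_ml_min)
        uptake = physiology.oxygen_uptake(
            ts.po2_art, ts.po2_ven, ts.flow_ml_min
        ).value
        resistance = physiology.vascular_resistance(ts.map_mmhg, ts.flow_ml_min)
        first_day = ts.time_h <= 24.0
        last_day = ts.time_h >= (config.days - 1) * 24.0
        gain = physiology.weight_gain_pct(ts.weight_initial_g, ts.weight_final_g)
        phys_doc = {
            "oxygen_delivery_ml_min_mean": round(float(delivery.mean()), 3),
            "oxygen_uptake_day1_ml_min": round(float(uptake[first_day].mean()), 3),
            "oxygen_uptake_last_day_ml_min": round(
                float(uptake[last_day].mean()), 3
            ),
            "vascular_resistance_mmhg_min_ml_mean": round(
                float(np.nanmean(resistance)), 4
            ),
            "weight_gain_pct": gain.percent_int,
            "hemofiltration_exchange_pct_per_h": physiology.exchange_fraction(
                40.0, 800.0
            ),
        }
        with open(out / "physiology.json", "w") as fh:
            json.dump(phys_doc, fh, sort_keys=True, indent=2)
        report["physiology"] = phys_doc

    with _stage("report"):
        body = json.dumps(report, sort_keys=True, indent=2)
        (out / "report.json").write_text(body + "\n")
        (out / "report.md").write_text(_markdown_summary(report))
    return report


def _markdown_summary(report: dict) -> str:
    lines = ["# msiflux run report", ""]
    pre = report.get("preprocess", {})
    lines.append(
        f"- pixels: {pre.get('n_pixels')} ({pre.get('n_dropped_zero_tic')} "
        "dropped for zero TIC)"
    )
    seg = report.get("segmentation", {})
    lines.append(f"- clusters: {seg.get('n_clusters')}")
    for name, pct in seg.get("composition_pct", {}).items():
        lines.append(f"  - {name}: {pct}%")
    lines.append("- relative TCA flux ratios (per phenotype):")
    for cluster, doc in sorted(report.get("flux_ratios", {}).items()):
        vals = ", ".join(
            f"{k}={doc[k]['value']:.3f}" if doc[k]["value"] is not None else f"{k}=n/a"
            for k in ("gls_ogdh", "gls_idh", "ogdh_sdhf", "sdhf_mdh")
        )
        lines.append(f"  - {cluster}: {vals}")
    rec = report.get("recovery")
    if rec:
        lines.append(
            f"- recovery: ARI={rec['segmentation_ari']:.3f}, "
            f"max relative flux error="
            f"{rec['max_relative_error']:.4f} over {rec['n_ratios_scored']} ratios"
        )
    phys = report.get("physiology", {})
    for key, val in sorted(phys.items()):
        lines.append(f"- {key}: {val}")
    return "\n".join(lines) + "\n"
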