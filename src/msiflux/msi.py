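"""Pixel-by-feature MSI matrices: I/O, TIC normalization, feature selection.

The on-disk dialect mirrors the common imaging-software CSV export: a header
row ``x,y,<m/z>,<m/z>,...`` followed by one row per pixel.  In memory a
:class:`SpectralImage` holds 0-based ``(row, col)`` pixel coordinates, a
strictly increasing m/z axis, and a pixels × features intensity matrix.

Feature identity (lipid vs metabolite vs isotopologue vs matrix signal,
carbon counts, signal-to-noise) lives in a separate feature table: a pandas
DataFrame with columns ``mz, name, n_carbons, kind, snr, isotopologue_index``.
S/N is taken as given in that table, not estimated here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyImageError,
    EmptySelectionError,
    FormatError,
    NotNormalizedError,
)

#: Edge length of one MALDI pixel in micrometres.
DEFAULT_PIXEL_SIZE_UM = 5.0

FEATURE_COLUMNS = ["mz", "name", "n_carbons", "kind", "snr", "isotopologue_index"]


@dataclass
class SpectralImage:
    """Pixel grid with one intensity vector per pixel over m/z features.

    ``normalized`` means intensities are TIC fractions; straight out of
    :func:`tic_normalize` every pixel sums to one, while after feature
    subsetting the sums are <= 1 (fractions of the full-spectrum TIC).
    """

    coords: np.ndarray  # (n_pixels, 2) int, (row, col), 0-based
    mz: np.ndarray  # (n_features,) strictly increasing
    intensities: np.ndarray  # (n_pixels, n_features), >= 0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    normalized: bool = False
    feature_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    # basic structural invariants; the sum-to-1 check lives in tic_normalize
    def validate(self) -> None:
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise FormatError("coords must be (n_pixels, 2)")
        if self.intensities.shape != (self.coords.shape[0], self.mz.size):
            raise FormatError("intensities shape does not match coords/mz")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise FormatError("mz axis must be strictly increasing")
        if np.any(self.intensities < 0) or not np.all(np.isfinite(self.intensities)):
            raise FormatError("intensities must be finite and non-negative")
        keys = {tuple(rc) for rc in self.coords}
        if len(keys) != self.coords.shape[0]:
            raise FormatError("duplicate pixel coordinates")
        if self.feature_names is not None and len(self.feature_names) != self.mz.size:
            raise FormatError("feature_names length does not match mz")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    @property
    def n_features(self) -> int:
        return self.mz.size

    def feature_index(self, name: str) -> int:
        if self.feature_names is None:
            raise KeyError("image carries no feature names")
        return self.feature_names.index(name)


class NormalizeResult(NamedTuple):
    image: SpectralImage
    n_dropped: int


def read_pixel_csv(
    path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> SpectralImage:
    """Read the ``x,y,<m/z>...`` pixel-matrix CSV dialect.

    m/z columns are parsed in file order, then sorted with the same
    permutation applied to the intensity columns.  Duplicate coordinates,
    negative intensities, and ragged rows are format errors.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: {exc}") from exc
    if frame.shape[1] < 3:
        raise FormatError(f"{path}: need x, y and at least one m/z column")
    cols = list(frame.columns)
    if [c.strip().lower() for c in cols[:2]] != ["x", "y"]:
        raise FormatError(f"{path}: header must start with x,y; got {cols[:2]}")
    if frame.isna().any().any():
        raise FormatError(f"{path}: ragged or non-numeric rows")
    try:
        mz = np.array([float(c) for c in cols[2:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric m/z header: {exc}") from exc

    x = frame.iloc[:, 0].to_numpy()
    y = frame.iloc[:, 1].to_numpy()
    coords = np.column_stack([y, x]).astype(int)  # (row, col) = (y, x)
    if not np.array_equal(coords, np.column_stack([y, x])):
        raise FormatError(f"{path}: coordinates must be integers")
    seen: dict[tuple, int] = {}
    for i, rc in enumerate(map(tuple, coords)):
        if rc in seen:
            raise FormatError(
                f"{path}: duplicate coordinate x={rc[1]}, y={rc[0]} "
                f"(rows {seen[rc]} and {i})"
            )
        seen[rc] = i

    intensities = frame.iloc[:, 2:].to_numpy(dtype=float)
    if np.any(intensities < 0):
        raise FormatError(f"{path}: negative intensity")
    order = np.argsort(mz, kind="stable")
    return SpectralImage(
        coords=coords,
        mz=mz[order],
        intensities=intensities[:, order],
        pixel_size_um=pixel_size_um,
    )


def write_pixel_csv(image: SpectralImage, path) -> None:
    """Write the CSV pixel-matrix dialect (header ``x,y,<m/z>...``)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"] + [f"{v:.6f}" for v in image.mz])
        for rc, row in zip(image.coords, image.intensities):
            writer.writerow(
                [int(rc[1]), int(rc[0])] + [f"{v:.15g}" for v in row]
            )


def tic_normalize(image: SpectralImage) -> NormalizeResult:
    """Divide each pixel by its total ion count.

    Pixels whose spectrum sums to zero have undefined fractions; they are
    dropped and counted.  Normalizing twice is a state error; normalization
    is idempotent in value (re-dividing by the new sums changes nothing).
    """
    if image.normalized:
        raise NotNormalizedError("image is already TIC-normalized")
    sums = image.intensities.sum(axis=1)
    keep = sums > 0
    if not keep.any():
        raise EmptyImageError("every pixel has zero total ion count")
    out = SpectralImage(
        coords=image.coords[keep],
        mz=image.mz,
        intensities=image.intensities[keep] / sums[keep, None],
        pixel_size_um=image.pixel_size_um,
        normalized=True,
        feature_names=image.feature_names,
    )
    return NormalizeResult(out, int((~keep).sum()))


def to_count_matrix(image: SpectralImage) -> np.ndarray:
    """Integer count matrix: ``floor(100 × TIC fraction)``, entries in [0, 100]."""
    if not image.normalized:
        raise NotNormalizedError("count matrix requires a TIC-normalized image")
    return np.floor(100.0 * image.intensities).astype(np.int64)


def _match_table(image: SpectralImage, table: pd.DataFrame) -> pd.DataFrame:
    """Align a feature table to the image's m/z axis (must cover all features)."""
    table_mz = table["mz"].to_numpy(dtype=float)
    rows = []
    for v in image.mz:
        hits = np.flatnonzero(np.isclose(table_mz, v, rtol=0, atol=1e-6))
        if hits.size == 0:
            raise ValueError(f"feature table does not cover m/z {v}")
        rows.append(hits[0])
    return table.iloc[rows].reset_index(drop=True)


def select_lipid_features(
    image: SpectralImage,
    table: pd.DataFrame,
    min_mz: float = 400.0,
    min_snr: float = 3.0,
) -> SpectralImage:
    """Restrict to lipid-range features: m/z >= ``min_mz``, S/N >= ``min_snr``,
    and not a MALDI-matrix signal.  Feature order is preserved."""
    aligned = _match_table(image, table)
    snr = pd.to_numeric(aligned["snr"], errors="coerce").to_numpy(dtype=float)
    keep = (
        (image.mz >= min_mz)
        & (np.nan_to_num(snr, nan=0.0) >= min_snr)
        & (aligned["kind"].astype(str).to_numpy() != "matrix")
    )
    if not keep.any():
        raise EmptySelectionError(
            f"no feature passes m/z >= {min_mz}, snr >= {min_snr}, kind != matrix"
        )
    names = (
        [n for n, k in zip(image.feature_names, keep) if k]
        if image.feature_names is not None
        else None
    )
    return SpectralImage(
        coords=image.coords,
        mz=image.mz[keep],
        intensities=image.intensities[:, keep],
        pixel_size_um=image.pixel_size_um,
        normalized=image.normalized,
        feature_names=names,
    )


class FeatureMatch(NamedTuple):
    """Best reference hit for one observed m/z (or an ambiguity marker)."""

    ref_index: Optional[int]
    ref_mz: Optional[float]
    name: Optional[str]
    ppm_error: Optional[float]
    ambiguous: bool = False


def annotate_features(
    observed_mz: Sequence[float],
    reference: pd.DataFrame,
    tol_ppm: float = 20.0,
) -> list[Optional[FeatureMatch]]:
    """Match observed m/z values to a reference table within ± ``tol_ppm``.

    Among multiple candidates the smallest ppm error wins; an exact tie
    leaves the feature unmatched with the ambiguity flag set.  Unmatched is a
    valid outcome (None).
    """
    ref_mz = reference["mz"].to_numpy(dtype=float)
    if np.any(ref_mz <= 0):
        raise ValueError("reference m/z must be positive")
    names = (
        reference["name"].tolist()
        if "name" in reference.columns
        else [None] * len(reference)
    )
    out: list[Optional[FeatureMatch]] = []
    for obs in observed_mz:
        ppm = np.abs(obs - ref_mz) / ref_mz * 1e6
        within = np.flatnonzero(ppm <= tol_ppm)
        if within.size == 0:
            out.append(None)
            continue
        best = within[np.argsort(ppm[within], kind="stable")]
        if best.size > 1 and ppm[best[0]] == ppm[best[1]]:
            out.append(FeatureMatch(None, None, None, float(ppm[best[0]]), True))
            continue
        i = int(best[0])
        out.append(FeatureMatch(i, float(ref_mz[i]), names[i], float(ppm[i])))
    return out


def hotspot_clip(values, quantile: float = 0.99) -> np.ndarray:
    """Clip values above the empirical ``quantile`` down to it.

    The quantile uses linear interpolation between order statistics (numpy's
    default), so behaviour is bit-reproducible.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {quantile}")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("hotspot_clip requires a non-empty input")
    cap = np.quantile(arr, quantile)
    return np.minimum(arr, cap)


@dataclass(frozen=True)
class DatasetStats:
    """Bookkeeping totals over a set of measured sections."""

    n_sections: int
    total_pixels: int
    mean_pixels_per_section: int
    section_areas_mm2: tuple
    mean_area_mm2: float


def dataset_stats(
    images: Sequence, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> DatasetStats:
    """Totals over sections: pixel counts and measured areas.

    ``images`` is a list of :class:`SpectralImage` (which must share a pixel
    size) or a list of per-section pixel counts, in which case
    ``pixel_size_um`` applies.  Area per section is ``pixels × pixel_size²``
    in mm²; the mean area is rounded to one decimal.
    """
    if len(images) == 0:
        raise ValueError("dataset_stats requires at least one section")
    if isinstance(images[0], SpectralImage):
        sizes = {img.pixel_size_um for img in images}
        if len(sizes) != 1:
            raise ValueError("sections must share a pixel size")
        pixel_size_um = sizes.pop()
        counts = [img.n_pixels for img in images]
    else:
        counts = [int(c) for c in images]
    total = int(sum(counts))
    n = len(counts)
    areas = tuple(c * pixel_size_um**2 / 1e6 for c in counts)  # µm² → mm²
    return DatasetStats(
        n_sections=n,
        total_pixels=total,
        mean_pixels_per_section=round(total / n),
        section_areas_mm2=areas,
        mean_area_mm2=round(sum(areas) / n, 1),
    )


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table TSV (columns ``mz, name, n_carbons, kind, snr,
    isotopologue_index``) and validate the isotopologue rows."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing feature-table columns {missing}")
    validate_feature_table(table)
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def validate_feature_table(table: pd.DataFrame) -> None:
    """Isotopologue rows must carry a carbon count and k <= n_carbons."""
    iso = table[table["kind"] == "isotopologue"]
    if iso["n_carbons"].isna().any() or iso["isotopologue_index"].isna().any():
        raise FormatError("isotopologue features need n_carbons and isotopologue_index")
    bad = iso[iso["isotopologue_index"] > iso["n_carbons"]]
    if len(bad):
        raise FormatError(
            f"isotopologue_index exceeds n_carbons for {bad['name'].tolist()}"
        )
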