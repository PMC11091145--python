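"""Natural-abundance and tracer-purity correction for ¹³C isotopologues.

A metabolite with ``n`` carbons is observed over mass channels M+0 ... M+n.
Two processes smear the true labeling pattern across channels:

* every *unlabeled* carbon is ¹³C with the natural abundance probability
  ``p13c`` (≈ 1.07 %), pushing intensity upward in mass;
* every *tracer-labeled* carbon is actually ¹³C only with probability
  ``tracer_purity`` (commercial tracers are typically 99 % pure), and
  otherwise behaves like a natural-abundance carbon.

Both processes are independent Bernoulli trials per carbon, so the observed
distribution for a molecule with ``j`` tracer-derived carbons is the
convolution of two binomials.  Stacking those distributions as columns gives
a forward matrix ``F`` with ``observed = F @ true``; correction inverts it,
by non-negative least squares by default so noisy inputs stay physical.

Fraction enrichment — the fraction of the metabolite pool in each
isotopologue — is computed on corrected pools and sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.ma as ma
from scipy import optimize, stats

#: Natural abundance of ¹³C.
NATURAL_P13C = 0.0107

#: Isotopic purity of the commercial U-¹³C tracers.
DEFAULT_TRACER_PURITY = 0.99


@dataclass(frozen=True)
class IsotopologueGroup:
    """One metabolite's M+0 ... M+n channel intensities.

    Parameters
    ----------
    metabolite
        Name, e.g. ``"glutamate"``.
    n_carbons
        Number of carbon atoms (glutamate 5, succinate/malate/aspartate 4,
        lactate/3PG/G3P 3, hexose 6, glutamine 5).
    intensities
        Vector of length ``n_carbons + 1``, non-negative and finite.
    """

    metabolite: str
    n_carbons: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size != self.n_carbons + 1:
            raise ValueError(
                f"{self.metabolite}: expected {self.n_carbons + 1} channels, "
                f"got {arr.size}"
            )
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError(f"{self.metabolite}: intensities must be finite and >= 0")
        object.__setattr__(self, "intensities", arr)


@dataclass(frozen=True)
class CorrectionModel:
    """Forward convolution matrix for one carbon count and tracer lot."""

    p13c: float
    tracer_purity: float
    n_carbons: int
    forward: np.ndarray = field(repr=False)
    method: str = "nnls"


@dataclass(frozen=True)
class CorrectionResult:
    """Corrected fraction vector plus the least-squares residual norm.

    ``fractions`` is fully masked when the observation carried no signal
    (undefined enrichment is a masked value, not an exception).
    """

    fractions: ma.MaskedArray
    residual: float


def build_forward_matrix(
    n_carbons: int,
    p13c: float = NATURAL_P13C,
    tracer_purity: float = DEFAULT_TRACER_PURITY,
    method: str = "nnls",
) -> CorrectionModel:
    """Build the forward (true → observed) isotopologue matrix.

    Column ``j`` is the observed M+k distribution of a molecule whose true
    labeling state is M+j: each of the ``j`` tracer carbons is ¹³C with
    probability ``purity + (1 - purity) * p13c`` and each of the ``n - j``
    remaining carbons with probability ``p13c``.  Columns sum to one.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if not 0.0 <= p13c < 0.5:
        raise ValueError(f"p13c must be in [0, 0.5), got {p13c}")
    if not 0.0 < tracer_purity <= 1.0:
        raise ValueError(f"tracer_purity must be in (0, 1], got {tracer_purity}")
    if method not in ("nnls", "solve"):
        raise ValueError(f"unknown method {method!r}")

    n = n_carbons
    p_lab = tracer_purity + (1.0 - tracer_purity) * p13c
    forward = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        labeled = stats.binom.pmf(np.arange(j + 1), j, p_lab)
        natural = stats.binom.pmf(np.arange(n - j + 1), n - j, p13c)
        forward[:, j] = np.convolve(labeled, natural)
    return CorrectionModel(p13c, tracer_purity, n, forward, method)


def apply_forward(model: CorrectionModel, fractions: np.ndarray) -> np.ndarray:
    """Forward-convolve a true fraction vector into the observed one."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[-1] != model.n_carbons + 1:
        raise ValueError("fraction vector length does not match model")
    return fractions @ model.forward.T


def correct_distribution(
    observed: IsotopologueGroup | np.ndarray,
    model: CorrectionModel,
    method: str | None = None,
) -> CorrectionResult:
    """Deconvolve an observed channel vector into true pool fractions.

    Solves ``forward @ x ≈ observed`` by NNLS (default) or a direct linear
    solve (exact but unconstrained), then renormalizes ``x`` to sum to one.
    """
    if isinstance(observed, IsotopologueGroup):
        if observed.n_carbons != model.n_carbons:
            raise ValueError(
                f"{observed.metabolite} has {observed.n_carbons} carbons, "
                f"model expects {model.n_carbons}"
            )
        vec = observed.intensities
    else:
        vec = np.asarray(observed, dtype=float)
        if vec.shape != (model.n_carbons + 1,):
            raise ValueError("observed vector length does not match model")

    if vec.sum() <= 0:
        return CorrectionResult(ma.masked_all(model.n_carbons + 1), float("nan"))

    how = method or model.method
    if how == "solve":
        x = np.linalg.solve(model.forward, vec)
    else:
        x, _ = optimize.nnls(model.forward, vec)
    residual = float(np.linalg.norm(model.forward @ x - vec))
    total = x.sum()
    if total <= 0:
        return CorrectionResult(ma.masked_all(model.n_carbons + 1), residual)
    return CorrectionResult(ma.asarray(x / total), residual)


def correct_many(
    intensities: np.ndarray, model: CorrectionModel, method: str | None = None
) -> tuple[ma.MaskedArray, np.ndarray]:
    """Correct a (pixels × channels) block row by row.

    Returns the corrected fractions as a masked array (rows with no signal
    fully masked) and the per-row residual norms.
    """
    intensities = np.asarray(intensities, dtype=float)
    n_rows = intensities.shape[0]
    out = ma.masked_all((n_rows, model.n_carbons + 1))
    residuals = np.full(n_rows, np.nan)
    for i in range(n_rows):
        res = correct_distribution(intensities[i], model, method=method)
        out[i] = res.fractions
        residuals[i] = res.residual
    return out, residuals


def fraction_enrichment(group: IsotopologueGroup | np.ndarray) -> ma.MaskedArray:
    """Fraction of the metabolite pool in each isotopologue.

    Element ``k`` is ``intensity(M+k) / Σ intensities``; the result sums to
    one.  A zero total yields a fully masked vector.  Scale-invariant.
    """
    vec = group.intensities if isinstance(group, IsotopologueGroup) else np.asarray(
        group, dtype=float
    )
    if np.any(vec < 0):
        raise ValueError("intensities must be non-negative")
    total = vec.sum()
    if total <= 0:
        return ma.masked_all(vec.size)
    return ma.asarray(vec / total)


def carbon_contribution(
    fractions: IsotopologueGroup | np.ndarray | ma.MaskedArray,
    n_carbons: int | None = None,
):
    """Fraction of the metabolite's carbon atoms that carry label.

    ``Σ_k k · fraction(M+k) / n_carbons``.  Masked input propagates.
    """
    if isinstance(fractions, IsotopologueGroup):
        n_carbons = fractions.n_carbons
        fractions = fraction_enrichment(fractions)
    vec = ma.asarray(fractions, dtype=float)
    if n_carbons is None:
        n_carbons = vec.size - 1
    if vec.size != n_carbons + 1:
        raise ValueError("fraction vector length does not match n_carbons")
    if vec.mask is not ma.nomask and vec.mask.all():
        return ma.masked
    k = np.arange(n_carbons + 1)
    return float((vec * k).sum() / n_carbons)
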