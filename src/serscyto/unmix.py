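"""Classical least-squares (CLS) deconvolution of SERS spectra.

A cell's total spectrum is modelled as a linear combination of the five
pure-nanotag reference spectra, S_total = C1*S1 + ... + C5*S5 + residual;
the weight factors C_i are the relative signal intensity of each nanotag
against its reference and serve as the per-integrin abundance proxy.  Both
unconstrained ordinary least squares and non-negative least squares are
available; weights represent physical signal fractions, so NNLS is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

if TYPE_CHECKING:  # pragma: no cover
    from .spectra import RamanSpectrum
    from .synthetic import ReferenceLibrary

__all__ = [
    "WeightProfile",
    "CellRecord",
    "CorrelationResult",
    "ratios_to_fractions",
    "cls_unmix",
    "unmix_spectra",
    "pearson_with_slope_p",
    "recovery_correlation",
]

#: Library matrices whose condition number exceeds this are rejected rather
#: than silently pseudo-inverted.
CONDITION_LIMIT = 1e8


@dataclass
class WeightProfile:
    """CLS weight factors for one spectrum, keyed by reporter."""

    weights: dict[str, float]  # reporter -> C_i, canonical library order
    residual_norm: float  # ||residual||_2
    relative_residual: float  # ||residual||_2 / ||S_total||_2
    mode: Literal["ols", "nnls"]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), float)
        if vals.size != 5 or not np.all(np.isfinite(vals)):
            raise ValueError("a weight profile holds exactly 5 finite weights")
        if self.mode == "nnls" and np.any(vals < -1e-12):
            raise ValueError("nnls profile contains negative weights")
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.weights.values()), float)


@dataclass
class CellRecord:
    """One cell: identity, five-marker profile, optional line label."""

    cell_id: str
    profile: WeightProfile | None = None
    label: str = "unknown"
    split: Literal["train", "test", "predict", "none"] = "none"

    VALID_LABELS = ("MM231", "MCF7", "SKBR3", "unknown")

    def __post_init__(self) -> None:
        if self.label not in self.VALID_LABELS:
            raise ValueError(f"label must be one of {self.VALID_LABELS}, got {self.label!r}")


@dataclass
class CorrelationResult:
    """Pearson correlation with the OLS line fit and slope p-value."""

    r: float
    p: float
    slope: float
    intercept: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r out of range: {self.r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p out of range: {self.p}")
        if self.n < 3:
            raise ValueError("need n >= 3")


def ratios_to_fractions(ratios: Sequence[float]) -> np.ndarray:
    """Normalise non-negative mixing ratios to fractions summing to 1."""
    r = np.asarray(ratios, dtype=float)
    if np.any(r < 0):
        raise ValueError(f"ratios must be non-negative, got {r.tolist()}")
    total = r.sum()
    if total <= 0:
        raise ValueError("ratios must not be all zero")
    return r / total


def _check_conditioning(matrix: np.ndarray, reporters: Sequence[str]) -> None:
    cond = np.linalg.cond(matrix)
    if cond > CONDITION_LIMIT:
        # name the most collinear pair to aid diagnosis
        norm = matrix / np.linalg.norm(matrix, axis=0, keepdims=True)
        corr = norm.T @ norm
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"reference library is rank-deficient (condition number {cond:.3g}); "
            f"most collinear reporters: {reporters[i]} and {reporters[j]}"
        )


def cls_unmix(
    spectrum: "RamanSpectrum",
    library: "ReferenceLibrary",
    mode: Literal["ols", "nnls"] = "nnls",
) -> WeightProfile:
    """Solve S_total = sum_i C_i S_i + residual for the weight factors.

    ``ols`` minimises the residual 2-norm unconstrained; ``nnls`` constrains
    every weight to be non-negative.  Spectrum and library must share one
    axis (resample first).
    """
    if mode not in ("ols", "nnls"):
        raise ValueError(f"mode must be 'ols' or 'nnls', got {mode!r}")
    if not np.array_equal(spectrum.wavenumbers, library.wavenumbers):
        raise ValueError("spectrum and library axes differ; resample to a shared grid first")
    M = library.matrix()
    _check_conditioning(M, list(library.reporters))
    y = spectrum.intensities
    if mode == "ols":
        coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    else:
        coef, _ = optimize.nnls(M, y)
    resid = y - M @ coef
    resid_norm = float(np.linalg.norm(resid))
    y_norm = float(np.linalg.norm(y))
    return WeightProfile(
        weights=dict(zip(library.reporters, (float(c) for c in coef))),
        residual_norm=resid_norm,
        relative_residual=resid_norm / y_norm if y_norm > 0 else 0.0,
        mode=mode,
    )


def unmix_spectra(
    spectra: Sequence["RamanSpectrum"],
    library: "ReferenceLibrary",
    mode: Literal["ols", "nnls"] = "nnls",
) -> pd.DataFrame:
    """Unmix many spectra; one row per spectrum, columns by integrin name."""
    from .synthetic import REPORTER_TO_INTEGRIN, MARKERS

    rows = []
    for spec in spectra:
        prof = cls_unmix(spec, library, mode=mode)
        by_integrin = {REPORTER_TO_INTEGRIN[rep]: w for rep, w in prof.weights.items()}
        rows.append(
            {
                "cell_id": spec.meta.get("name", ""),
                **{m: by_integrin[m] for m in MARKERS},
                "residual_norm": prof.residual_norm,
                "relative_residual": prof.relative_residual,
            }
        )
    return pd.DataFrame(rows)


def pearson_with_slope_p(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r plus the two-sided t-test p-value of the OLS slope (n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
    )


def recovery_correlation(
    panel_results: Sequence[tuple[Sequence[float], Sequence[float]]],
) -> CorrelationResult:
    """Correlate designed fractions against CLS-recovered fractions.

    Each item pairs a design's true fractions with the recovered weights for
    that mixture; recovered weights are renormalised to sum to 1 before the
    pooled comparison across all (design, tag) pairs.
    """
    true_all, rec_all = [], []
    for true_frac, recovered in panel_results:
        t = np.asarray(true_frac, float)
        r = np.asarray(recovered, float)
        total = r.sum()
        if total <= 0:
            raise ValueError("recovered weights sum to zero; cannot renormalise")
        true_all.append(t)
        rec_all.append(r / total)
    x = np.concatenate(true_all)
    y = np.concatenate(rec_all)
    if x.size < 3:
        raise ValueError("need at least 3 (design, tag) pairs")
    return pearson_with_slope_p(x, y)
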