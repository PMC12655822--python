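"""Raman spectrum container, delimited-text I/O, and preprocessing.

A spectrum is a strictly increasing wavenumber axis (cm^-1) with one
intensity value (arbitrary units) per axis point.  Preprocessing mirrors
the two steps a SERS acquisition pipeline applies before least-squares
deconvolution: multi-segment iterative-polynomial baseline subtraction and
boxcar (centered moving average) smoothing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AxisSpec",
    "RamanSpectrum",
    "read_spectrum_table",
    "write_spectrum_table",
    "resample_to_axis",
    "baseline_correct",
    "boxcar_smooth",
]


@dataclass(frozen=True)
class AxisSpec:
    """A uniform wavenumber grid: ``start, start+step, ... <= stop`` (cm^-1).

    The default (250, 3000, 7) is the acquisition grid of a portable Raman
    spectrometer recording 250-3000 cm^-1 at 7 cm^-1 resolution.
    """

    start: float = 250.0
    stop: float = 3000.0
    step: float = 7.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"axis start ({self.start}) must be < stop ({self.stop})")
        if not self.step > 0:
            raise ValueError(f"axis step must be positive, got {self.step}")

    def grid(self) -> np.ndarray:
        """Return the axis as an array of bin centers (stop included only
        when it falls on the grid)."""
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)

    @property
    def n_points(self) -> int:
        return self.grid().size


@dataclass
class RamanSpectrum:
    """Wavenumber axis (cm^-1) plus intensities (a.u.) plus metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError(
                f"axis length {self.wavenumbers.size} != intensity length "
                f"{self.intensities.size}"
            )
        if not np.all(np.isfinite(self.wavenumbers)) or not np.all(
            np.isfinite(self.intensities)
        ):
            raise ValueError("spectrum contains non-finite values")
        diffs = np.diff(self.wavenumbers)
        if np.any(diffs <= 0):
            bad = int(np.argmax(diffs <= 0)) + 1
            raise ValueError(
                f"wavenumber axis not strictly increasing at row {bad} "
                f"({self.wavenumbers[bad - 1]} -> {self.wavenumbers[bad]})"
            )

    def __len__(self) -> int:
        return self.wavenumbers.size

    def copy_with(self, intensities: np.ndarray, **meta) -> "RamanSpectrum":
        new_meta = {**self.meta, **meta}
        return RamanSpectrum(self.wavenumbers.copy(), np.asarray(intensities, float), new_meta)

    @property
    def peak_position(self) -> float:
        """Wavenumber of the global intensity maximum."""
        return float(self.wavenumbers[int(np.argmax(self.intensities))])


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return r"\s+"


def read_spectrum_table(path: str | Path) -> list[RamanSpectrum]:
    """Read one or more spectra from a delimited text file.

    Column 1 is the wavenumber (cm^-1); columns 2..k are intensities, one
    spectrum per column.  A header row is recognised when its first cell is
    ``wavenumber`` (case-insensitive); remaining header cells become the
    ``name`` metadata of each spectrum.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty spectrum table")
    sep = _sniff_delimiter(lines[0])
    if sep == r"\s+":  # normalise to comma so the exact (round-trip) parser applies
        import re

        text = "\n".join(re.sub(r"\s+", ",", ln.strip()) for ln in lines)
        sep = ","
    first_cell = lines[0].replace("\t", ",").split(",")[0].strip().lower()
    header = 0 if first_cell == "wavenumber" else None
    try:
        frame = pd.read_csv(
            io.StringIO(text), sep=sep, header=header, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:  # ragged rows
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from exc
    if frame.isna().any().any():
        bad_rows = frame.index[frame.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: ragged rows (missing values) at rows {bad_rows}")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need a wavenumber column plus >=1 intensity column")
    axis = frame.iloc[:, 0].to_numpy(dtype=float)
    diffs = np.diff(axis)
    if np.any(diffs <= 0):
        rows = (np.nonzero(diffs <= 0)[0] + 1).tolist()
        raise ValueError(f"{path}: wavenumber axis not strictly increasing at rows {rows}")
    spectra = []
    for j, col in enumerate(frame.columns[1:]):
        name = str(col) if header is not None else f"spectrum_{j}"
        spectra.append(
            RamanSpectrum(axis, frame[col].to_numpy(dtype=float), {"name": name, "source": str(path)})
        )
    return spectra


def write_spectrum_table(
    spectra: RamanSpectrum | Sequence[RamanSpectrum],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write spectra (sharing one axis) as delimited text, full precision."""
    if isinstance(spectra, RamanSpectrum):
        spectra = [spectra]
    axis = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, axis):
            raise ValueError("all spectra in one table must share the wavenumber axis")
    names = [s.meta.get("name", f"spectrum_{i}") for i, s in enumerate(spectra)]
    data = {"wavenumber": axis}
    for name, s in zip(names, spectra):
        data[name] = s.intensities
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_to_axis(spectrum: RamanSpectrum, axis_spec: AxisSpec) -> RamanSpectrum:
    """Linearly interpolate a spectrum onto a uniform target grid.

    Target points outside the source range are set to 0 and the fact is
    flagged in the metadata.  Raises if source and target do not overlap.
    """
    target = axis_spec.grid()
    lo, hi = spectrum.wavenumbers[0], spectrum.wavenumbers[-1]
    if target[-1] < lo or target[0] > hi:
        raise ValueError(
            f"no overlap between source axis [{lo}, {hi}] and target "
            f"[{target[0]}, {target[-1]}]"
        )
    values = np.interp(target, spectrum.wavenumbers, spectrum.intensities, left=0.0, right=0.0)
    outside = bool(target[0] < lo or target[-1] > hi)
    meta = {**spectrum.meta}
    if outside:
        meta["resample_zero_padded"] = True
    return RamanSpectrum(target, values, meta)


# ---------------------------------------------------------------------------
# baseline correction
# ---------------------------------------------------------------------------

def _segment_baseline(
    x: np.ndarray, y: np.ndarray, degree: int, n_iterations: int, tol: float
) -> np.ndarray:
    """Iterative polynomial baseline on one segment.

    Fit a polynomial to all points, then refit repeatedly with the points
    above the current fit removed (down-weighted to zero), so peaks stop
    inflating the estimate and the fit settles onto the continuum.
    """
    # center/scale x for numerical conditioning of the Vandermonde system
    span = float(np.ptp(x))
    xs = (x - x.mean()) / (span if span > 0 else 1.0)
    V = np.vander(xs, degree + 1)
    keep = np.ones(y.size, dtype=bool)
    fit = V @ np.linalg.lstsq(V, y, rcond=None)[0]
    for _ in range(n_iterations):
        resid = y - fit
        sigma = float(resid[keep].std())
        # peel points sitting above the continuum estimate; exclusions are
        # never revoked, so the kept set shrinks monotonically and the
        # iteration cannot cycle
        peel = keep & (resid > 3.0 * sigma + 1e-12)
        if not peel.any():
            break
        keep &= ~peel
        if keep.sum() < degree + 1:
            break
        new_fit = V @ np.linalg.lstsq(V[keep], y[keep], rcond=None)[0]
        if np.linalg.norm(new_fit - fit) / (np.linalg.norm(fit) or 1.0) < tol:
            fit = new_fit
            break
        fit = new_fit
    return fit


def baseline_correct(
    spectrum: RamanSpectrum,
    n_segments: int = 4,
    degree: int = 3,
    n_iterations: int = 50,
    floor_at_zero: bool = True,
    tol: float = 1e-6,
) -> RamanSpectrum:
    """Subtract a multi-segment iterative-polynomial baseline estimate.

    The axis is split into ``n_segments`` equal-width segments; each segment's
    baseline is estimated by iterative polynomial fitting with clipping of
    points above the current fit (so peaks do not inflate the baseline).
    Neighbouring segment fits are blended linearly over a 3-point overlap to
    avoid steps.  Corrected intensities are floored at 0 unless disabled.
    """
    n = len(spectrum)
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    seg_len = n // n_segments
    if seg_len < degree + 1:
        raise ValueError(
            f"too few points per segment: {seg_len} points for polynomial "
            f"degree {degree} (need >= {degree + 1})"
        )
    bounds = np.linspace(0, n - 1, n_segments + 1).round().astype(int)
    overlap = 1  # one extra point each side -> 3-point blend at each boundary
    baseline = np.zeros(n)
    weight_sum = np.zeros(n)
    for k in range(n_segments):
        i0 = max(bounds[k] - overlap, 0)
        i1 = min(bounds[k + 1] + overlap, n - 1)
        sl = slice(i0, i1 + 1)
        fit = _segment_baseline(
            spectrum.wavenumbers[sl], spectrum.intensities[sl], degree, n_iterations, tol
        )
        w = np.ones(i1 - i0 + 1)
        # taper to the edges shared with a neighbouring segment
        if i0 > 0:
            w[: 2 * overlap + 1] = np.linspace(0.0, 1.0, 2 * overlap + 1)
        if i1 < n - 1:
            w[-(2 * overlap + 1):] = np.linspace(1.0, 0.0, 2 * overlap + 1)
        baseline[sl] += w * fit
        weight_sum[sl] += w
    baseline /= np.where(weight_sum > 0, weight_sum, 1.0)
    corrected = spectrum.intensities - baseline
    if floor_at_zero:
        corrected = np.maximum(corrected, 0.0)
    return spectrum.copy_with(corrected, baseline_corrected=True)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def boxcar_smooth(spectrum: RamanSpectrum, window_points: int = 5) -> RamanSpectrum:
    """Centered moving average; the window shrinks symmetrically at the edges."""
    w = window_points
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window_points must be odd and >= 1, got {w}")
    n = len(spectrum)
    if w > n:
        raise ValueError(f"window_points ({w}) exceeds spectrum length ({n})")
    y = spectrum.intensities
    half = w // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = y[i - h : i + h + 1].mean()
    return spectrum.copy_with(out, boxcar_window=w)
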