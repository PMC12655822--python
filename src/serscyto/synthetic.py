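"""Synthetic SERS nanotag spectra, designed mixtures, and cell populations.

Five Raman reporters encode five integrin surface markers on breast-cancer
cells; each reporter's strongest band sits at its characteristic shift
(DTDC 510, SiNC 684, BHQ3 1094, QXL680 1140, QSY21 1496 cm^-1).  This module
builds reference spectra for the pure nanotags, linear mixtures of them at
designed ratios (the forward model of classical least-squares unmixing),
and per-cell five-marker weight-factor populations for the three cell lines
MM231, MCF7 and SKBR3.

Only each reporter's strongest band position is an instrument fact; the
minor bands in the default models are invented fixtures chosen so the five
spectra remain linearly well separated, and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .spectra import AxisSpec, RamanSpectrum
from .unmix import ratios_to_fractions

__all__ = [
    "Peak",
    "ReporterModel",
    "ReferenceLibrary",
    "PopulationConfig",
    "REPORTER_ORDER",
    "CHARACTERISTIC_SHIFT",
    "REPORTER_TO_INTEGRIN",
    "MARKERS",
    "CELL_LINES",
    "DEFAULT_LINE_MEANS",
    "DEFAULT_PANEL_DESIGNS",
    "default_reporter_models",
    "default_reference_library",
    "make_reference",
    "mix_spectra",
    "make_mixture_panel",
    "simulate_cell_population",
]

#: Canonical reporter order (ascending characteristic shift); all weight
#: vectors passed to / returned from the unmixing layer follow this order.
REPORTER_ORDER: tuple[str, ...] = ("DTDC", "SiNC", "BHQ3", "QXL680", "QSY21")

#: Strongest Raman band of each reporter, cm^-1.
CHARACTERISTIC_SHIFT: dict[str, float] = {
    "DTDC": 510.0,
    "SiNC": 684.0,
    "BHQ3": 1094.0,
    "QXL680": 1140.0,
    "QSY21": 1496.0,
}

#: Integrin monomer each reporter's nanotag targets.
REPORTER_TO_INTEGRIN: dict[str, str] = {
    "DTDC": "beta5",
    "SiNC": "alpha3",
    "BHQ3": "beta1",
    "QXL680": "beta3",
    "QSY21": "beta4",
}

#: Marker (integrin) column order used in per-cell weight tables.
MARKERS: tuple[str, ...] = ("alpha3", "beta1", "beta3", "beta4", "beta5")

CELL_LINES: tuple[str, ...] = ("MM231", "MCF7", "SKBR3")

#: Default mean weight factor per marker for each cell line.  These are
#: synthetic calibrations reproducing the qualitative expression pattern of
#: the three lines (beta1 highest everywhere, beta4 near zero everywhere,
#: beta5 elevated in MCF7, beta3 low in MM231/SKBR3); they are not measured
#: values.
DEFAULT_LINE_MEANS: dict[str, dict[str, float]] = {
    "MM231": {"alpha3": 0.45, "beta1": 0.55, "beta3": 0.02, "beta4": 0.05, "beta5": 0.25},
    "MCF7": {"alpha3": 0.20, "beta1": 0.50, "beta3": 0.15, "beta4": 0.02, "beta5": 0.40},
    "SKBR3": {"alpha3": 0.30, "beta1": 0.60, "beta3": 0.02, "beta4": 0.02, "beta5": 0.03},
}

#: Default mixture-panel designs (ratios in REPORTER_ORDER).  The fourth
#: entry of design 2 realises the 1:6:1:1:1 QXL680-dominant validation mix.
DEFAULT_PANEL_DESIGNS: tuple[tuple[float, ...], ...] = (
    (1, 1, 1, 1, 1),
    (1, 1, 1, 6, 1),
    (6, 1, 1, 1, 1),
    (1, 6, 1, 1, 1),
    (1, 1, 6, 1, 1),
    (1, 1, 1, 1, 6),
    (2, 1, 4, 1, 2),
    (5, 3, 1, 0, 1),
)


class Peak(NamedTuple):
    center: float  # cm^-1
    amplitude: float  # a.u.
    fwhm: float  # cm^-1


@dataclass(frozen=True)
class ReporterModel:
    """Line-shape model of one reporter's SERS spectrum."""

    name: str
    integrin: str
    peaks: tuple[Peak, ...]
    line_shape: Literal["lorentzian", "gaussian"] = "lorentzian"

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("reporter model needs at least one peak")
        amps = [p.amplitude for p in self.peaks]
        if any(a <= 0 for a in amps):
            raise ValueError("all peak amplitudes must be positive")
        if any(p.fwhm <= 0 for p in self.peaks):
            raise ValueError("all FWHM must be positive")
        if amps.count(max(amps)) != 1:
            raise ValueError("exactly one peak must be the global maximum")

    @property
    def main_peak(self) -> Peak:
        return max(self.peaks, key=lambda p: p.amplitude)

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        x = np.asarray(wavenumbers, float)
        y = np.zeros_like(x)
        for c, a, fwhm in self.peaks:
            if self.line_shape == "lorentzian":
                g = fwhm / 2.0
                y += a * g**2 / ((x - c) ** 2 + g**2)
            else:
                y += a * np.exp(-4.0 * np.log(2.0) * (x - c) ** 2 / fwhm**2)
        return y


# Minor-band positions are invented fixtures (documented above); they are
# mutually non-overlapping across reporters so the library stays well
# conditioned for least squares.
_DEFAULT_PEAKS: dict[str, tuple[Peak, ...]] = {
    "DTDC": (Peak(510, 1.00, 18), Peak(770, 0.35, 18), Peak(1350, 0.20, 18)),
    "SiNC": (Peak(684, 1.00, 18), Peak(905, 0.30, 18), Peak(1585, 0.25, 18)),
    "BHQ3": (Peak(1094, 1.00, 18), Peak(450, 0.20, 18), Peak(1720, 0.30, 18)),
    "QXL680": (Peak(1140, 1.00, 18), Peak(620, 0.25, 18), Peak(1925, 0.30, 18)),
    "QSY21": (Peak(1496, 1.00, 18), Peak(820, 0.25, 18), Peak(2120, 0.30, 18)),
}


def default_reporter_models() -> dict[str, ReporterModel]:
    """The five default reporter models in canonical order."""
    return {
        name: ReporterModel(name, REPORTER_TO_INTEGRIN[name], _DEFAULT_PEAKS[name])
        for name in REPORTER_ORDER
    }


def make_reference(model: ReporterModel, axis_spec: AxisSpec = AxisSpec()) -> RamanSpectrum:
    """Evaluate a reporter model on a grid; deterministic for a fixed model."""
    main = model.main_peak
    if not (axis_spec.start <= main.center <= axis_spec.stop):
        raise ValueError(
            f"{model.name}: characteristic peak at {main.center} cm^-1 lies "
            f"outside the axis [{axis_spec.start}, {axis_spec.stop}]"
        )
    grid = axis_spec.grid()
    return RamanSpectrum(
        grid,
        model.evaluate(grid),
        {"name": model.name, "integrin": model.integrin, "provenance": "simulated"},
    )


@dataclass
class ReferenceLibrary:
    """The five pure-nanotag reference spectra S1..S5 on one shared axis."""

    axis_spec: AxisSpec
    references: dict[str, RamanSpectrum]  # reporter -> spectrum, canonical order
    provenance: Literal["simulated", "measured"] = "simulated"

    def __post_init__(self) -> None:
        missing = [r for r in REPORTER_ORDER if r not in self.references]
        if missing:
            raise ValueError(f"reference library missing reporters: {missing}")
        grid = self.axis_spec.grid()
        for name, spec in self.references.items():
            if not np.array_equal(spec.wavenumbers, grid):
                raise ValueError(f"{name}: reference not on the library axis")
            if np.any(spec.intensities < 0):
                raise ValueError(f"{name}: reference spectrum has negative intensities")
            expected = CHARACTERISTIC_SHIFT.get(name)
            if expected is not None:
                if abs(spec.peak_position - expected) > self.axis_spec.step:
                    raise ValueError(
                        f"{name}: strongest band at {spec.peak_position} cm^-1, "
                        f"expected {expected} cm^-1 (+/- one bin)"
                    )
        self.references = {r: self.references[r] for r in REPORTER_ORDER}

    @property
    def reporters(self) -> tuple[str, ...]:
        return tuple(self.references)

    @property
    def integrins(self) -> tuple[str, ...]:
        return tuple(REPORTER_TO_INTEGRIN[r] for r in self.references)

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.axis_spec.grid()

    def matrix(self) -> np.ndarray:
        """(n_points, 5) matrix with one reference spectrum per column."""
        return np.column_stack([s.intensities for s in self.references.values()])

    @property
    def global_max(self) -> float:
        """Largest intensity anywhere in the library; the noise-scale anchor."""
        return float(max(s.intensities.max() for s in self.references.values()))


def default_reference_library(axis_spec: AxisSpec = AxisSpec()) -> ReferenceLibrary:
    models = default_reporter_models()
    refs = {name: make_reference(m, axis_spec) for name, m in models.items()}
    return ReferenceLibrary(axis_spec, refs, "simulated")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _smooth_random_baseline(n: int, rng: np.random.Generator, n_knots: int = 6) -> np.ndarray:
    """A smooth random curve in [0, 1] built from a cubic spline over knots."""
    knots_x = np.linspace(0, n - 1, n_knots)
    knots_y = rng.uniform(0.0, 1.0, n_knots)
    return np.clip(CubicSpline(knots_x, knots_y)(np.arange(n)), 0.0, None)


def mix_spectra(
    library: ReferenceLibrary,
    weights: Sequence[float],
    noise_sd: float = 0.0,
    baseline_amp: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RamanSpectrum:
    """Forward model: S_total = sum_i C_i S_i + noise + smooth baseline.

    ``noise_sd`` and ``baseline_amp`` are expressed as fractions of the
    library's global peak intensity.  With both at zero the output is exactly
    linear in the weights.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (5,):
        raise ValueError(f"weights must be length 5, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    y = library.matrix() @ w
    scale = library.global_max
    if noise_sd > 0 or baseline_amp > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd * scale, y.size)
        if baseline_amp > 0:
            y = y + baseline_amp * scale * _smooth_random_baseline(y.size, rng)
    return RamanSpectrum(
        library.wavenumbers,
        y,
        {"name": "mixture", "weights": tuple(float(v) for v in w)},
    )


def make_mixture_panel(
    library: ReferenceLibrary,
    ratio_designs: Sequence[Sequence[float]] = DEFAULT_PANEL_DESIGNS,
    noise_sd: float = 0.015,
    seed: int | None = None,
) -> list[tuple[np.ndarray, RamanSpectrum]]:
    """Build designed mixtures: each design's ratios are normalised to
    fractions summing to 1, then fed through the forward model."""
    rng = np.random.default_rng(seed)
    panel = []
    for design in ratio_designs:
        fractions = ratios_to_fractions(design)
        panel.append((fractions, mix_spectra(library, fractions, noise_sd=noise_sd, rng=rng)))
    return panel


# ---------------------------------------------------------------------------
# cell populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Statistical description of the synthetic three-line cell population.

    ``line_means`` maps cell line -> marker -> mean weight factor; a common
    ``sd`` applies to every marker; draws are truncated-normal by rejection
    within ``bounds`` (default [0, 0.79], the observed single-cell weight
    range).
    """

    line_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LINE_MEANS.items()}
    )
    sd: float = 0.06
    bounds: tuple[float, float] = (0.0, 0.79)
    n_per_line: int = 300
    noise_sd: float = 0.015
    baseline_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"bounds must satisfy 0 <= lo < hi <= 1, got {self.bounds}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_per_line < 0:
            raise ValueError("n_per_line must be >= 0")
        for line, means in self.line_means.items():
            for marker in MARKERS:
                if marker not in means:
                    raise ValueError(f"{line}: missing marker {marker}")
                if not (lo <= means[marker] <= hi):
                    raise ValueError(
                        f"{line}.{marker}: mean {means[marker]} outside bounds {self.bounds}"
                    )


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal draws by rejection sampling."""
    if sd == 0:
        return np.full(n, mean)
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(mean, sd, max(n, 64))
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


def simulate_cell_population(
    config: PopulationConfig,
    library: ReferenceLibrary | None = None,
    return_spectra: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[RamanSpectrum]]:
    """Draw a labelled synthetic cell population.

    Returns a DataFrame with columns ``cell_id, label, split`` plus the five
    marker weight columns; bit-reproducible for a fixed config seed.  With
    ``return_spectra=True`` also returns one mixed SERS spectrum per cell
    (weights mapped from marker order to reporter order), which requires a
    reference library.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    rows = []
    for line in config.line_means:
        draws = {
            m: _truncated_normal(config.line_means[line][m], config.sd, lo, hi, config.n_per_line, rng)
            for m in MARKERS
        }
        for i in range(config.n_per_line):
            rows.append(
                {
                    "cell_id": f"{line}_{i:04d}",
                    "label": line,
                    "split": "none",
                    **{m: draws[m][i] for m in MARKERS},
                }
            )
    frame = pd.DataFrame(rows, columns=["cell_id", "label", "split", *MARKERS])
    if not return_spectra:
        return frame
    if library is None:
        library = default_reference_library()
    integrin_to_reporter = {v: k for k, v in REPORTER_TO_INTEGRIN.items()}
    spectra = []
    for _, row in frame.iterrows():
        by_reporter = {integrin_to_reporter[m]: row[m] for m in MARKERS}
        w = [by_reporter[r] for r in REPORTER_ORDER]
        spec = mix_spectra(
            library, w, noise_sd=config.noise_sd, baseline_amp=config.baseline_amp, rng=rng
        )
        spec.meta["name"] = row["cell_id"]
        spectra.append(spec)
    return frame, spectra
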