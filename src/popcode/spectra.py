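"""One-dimensional spatial-frequency amplitude spectra of gratings and filtered noise.

All spectra live on a shared grid of spatial frequencies that is uniform on
the log2 (octave) axis.  Gratings are represented as line spectra (a single
delta-like bin carrying the grating's Michelson contrast); noise backgrounds
are represented as amplitude *densities* per octave, so that integrals of a
noise spectrum against a tuning function are independent of grid resolution.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import numpy as np

__all__ = [
    "ParameterError",
    "FrequencyGrid",
    "NoiseSpec",
    "AmplitudeSpectrum",
    "make_frequency_grid",
    "default_grid",
    "grating_spectrum",
    "noise_spectrum",
    "octave_distance",
]


class ParameterError(ValueError):
    """Invalid parameter or argument value."""


@dataclass(frozen=True)
class FrequencyGrid:
    """Spatial-frequency grid, equally spaced in octaves.

    Attributes
    ----------
    frequencies : ndarray
        Strictly increasing bin centers in cycles per degree (c/deg).
    log2_step : float
        Grid spacing in octaves.
    f_min, f_max : float
        Range bounds in c/deg.
    """

    frequencies: np.ndarray
    log2_step: float
    f_min: float
    f_max: float

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.ndim != 1 or f.size < 2:
            raise ParameterError("grid needs at least two frequencies")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ParameterError("frequencies must be positive and strictly increasing")
        ratios = f[1:] / f[:-1]
        if not np.allclose(np.log2(ratios), self.log2_step, rtol=0, atol=1e-12):
            raise ParameterError("grid is not uniform on the log2 axis")

    @property
    def log2_frequencies(self) -> np.ndarray:
        return np.log2(self.frequencies)

    def __len__(self) -> int:
        return self.frequencies.size

    def nearest_index(self, f: float) -> int:
        """Index of the bin whose center is nearest to ``f`` on the log2 axis."""
        if f <= 0:
            raise ParameterError("frequency must be positive")
        return int(np.argmin(np.abs(self.log2_frequencies - np.log2(f))))

    def contains(self, f: float) -> bool:
        return self.frequencies[0] <= f <= self.frequencies[-1]


def make_frequency_grid(f_min: float, f_max: float, points_per_octave: int) -> FrequencyGrid:
    """Build a frequency grid covering ``[f_min, f_max]`` c/deg.

    The grid is uniform in octaves with ``points_per_octave`` bins per
    octave; the first bin center sits exactly at ``f_min``.
    """
    if not (0 < f_min < f_max):
        raise ParameterError(f"invalid frequency range [{f_min}, {f_max}]")
    if points_per_octave < 8:
        raise ParameterError("points_per_octave must be at least 8")
    n_oct = np.log2(f_max / f_min)
    n_pts = int(round(n_oct * points_per_octave)) + 1
    step = 1.0 / points_per_octave
    freqs = f_min * 2.0 ** (step * np.arange(n_pts))
    return FrequencyGrid(frequencies=freqs, log2_step=step, f_min=f_min, f_max=f_max)


def default_grid() -> FrequencyGrid:
    """Default analysis grid: 0.125-64 c/deg at 64 points per octave (577 bins).

    Wide enough that all neuron preferred frequencies (0.25-60 c/deg) and the
    broadband-noise upper bound (27.4 c/deg) lie strictly inside.
    """
    return make_frequency_grid(0.125, 64.0, 64)


_NOISE_KINDS = ("none", "broadband", "lowpass", "highpass", "notched")


@dataclass(frozen=True)
class NoiseSpec:
    """Specification of a (filtered) visual-noise background.

    ``kind`` is one of ``none``, ``broadband``, ``lowpass``, ``highpass`` or
    ``notched``.  Broadband noise is flat up to ``upper_bound`` (27.4 c/deg);
    low-/high-pass noise removes components above/below ``cutoff`` (5.5 c/deg);
    notched noise removes a ``notch_width``-octave band around
    ``notch_center``.  ``power_density`` sets the relative in-band amplitude
    density (dimensionless; the absolute physical scale is absorbed into the
    encoder's noise-scaling parameters).  ``lower_bound`` optionally truncates
    the band from below (used for symmetric noise-band constructions).
    """

    kind: str
    cutoff: float = 5.5
    notch_center: float = 5.5
    notch_width: float = 4.0
    upper_bound: float = 27.4
    lower_bound: float = 0.0
    power_density: float = 1.0

    def __post_init__(self):
        if self.kind not in _NOISE_KINDS:
            raise ParameterError(f"unknown noise kind {self.kind!r}")
        if self.kind in ("lowpass", "highpass") and self.cutoff <= 0:
            raise ParameterError("lowpass/highpass noise requires cutoff > 0")
        if self.kind == "notched" and (self.notch_center <= 0 or self.notch_width <= 0):
            raise ParameterError("notched noise requires positive notch_center and notch_width")
        if self.power_density < 0:
            raise ParameterError("power_density must be non-negative")

    @property
    def notch_edges(self) -> tuple[float, float]:
        half = 0.5 * self.notch_width
        return (self.notch_center * 2.0 ** (-half), self.notch_center * 2.0 ** half)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpec":
        return cls(**d)


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """Amplitude spectrum on a frequency grid.

    ``kind`` distinguishes line spectra (``"line"``: bin values are delta
    masses, used for gratings) from densities (``"density"``: bin values are
    amplitude per octave, used for noise).  The distinction matters only for
    integration against tuning functions.
    """

    grid: FrequencyGrid
    amplitude: np.ndarray
    kind: str = "density"

    def __post_init__(self):
        amp = np.asarray(self.amplitude, dtype=float)
        object.__setattr__(self, "amplitude", amp)
        if amp.shape != self.grid.frequencies.shape:
            raise ParameterError("amplitude length must match grid length")
        if not np.all(np.isfinite(amp)) or np.any(amp < 0):
            raise ParameterError("amplitudes must be finite and non-negative")
        if self.kind not in ("line", "density"):
            raise ParameterError("spectrum kind must be 'line' or 'density'")

    @property
    def total(self) -> float:
        """Total mass: plain sum for line spectra, octave integral for densities."""
        if self.kind == "line":
            return float(self.amplitude.sum())
        return float(np.trapezoid(self.amplitude, self.grid.log2_frequencies))


def grating_spectrum(f_g: float, contrast: float, grid: FrequencyGrid) -> AmplitudeSpectrum:
    """Line spectrum of a grating: contrast in the single bin nearest ``f_g``."""
    if not grid.contains(f_g):
        raise ParameterError(f"grating frequency {f_g} outside grid range")
    if not (0.0 <= contrast <= 1.0):
        raise ParameterError("contrast must lie in [0, 1]")
    amp = np.zeros(len(grid))
    if contrast > 0:
        amp[grid.nearest_index(f_g)] = contrast
    return AmplitudeSpectrum(grid=grid, amplitude=amp, kind="line")


def _band_coverage(grid: FrequencyGrid, intervals) -> np.ndarray:
    """Fraction of each grid bin (an octave interval of width log2_step
    centred on the bin) covered by the union of frequency ``intervals``.

    Sub-bin edge resolution keeps band integrals stable under grid
    refinement and makes complementary bands tile exactly.
    """
    x = grid.log2_frequencies
    h = grid.log2_step
    lo_edge = x - h / 2
    hi_edge = x + h / 2
    cov = np.zeros_like(x)
    for (a, b) in intervals:
        if b <= a:
            continue
        la, lb = np.log2(a), np.log2(b)
        cov += np.clip(np.minimum(hi_edge, lb) - np.maximum(lo_edge, la), 0.0, h) / h
    return np.clip(cov, 0.0, 1.0)


def noise_spectrum(spec: NoiseSpec, grid: FrequencyGrid) -> AmplitudeSpectrum:
    """Amplitude-density spectrum of a noise background.

    Band edges are resolved at sub-bin precision (edge bins carry the
    covered fraction of the in-band density), so low-pass and high-pass
    bands tile broadband noise exactly and band integrals converge under
    grid refinement.  The low-pass band is closed at the cutoff.
    """
    eps = grid.frequencies[0] * 2.0 ** (-grid.log2_step)
    lb = max(spec.lower_bound, eps)
    ub = spec.upper_bound
    if spec.kind == "none":
        intervals = []
    elif spec.kind == "broadband":
        intervals = [(lb, ub)]
    elif spec.kind == "lowpass":
        intervals = [(lb, min(spec.cutoff, ub))]
    elif spec.kind == "highpass":
        intervals = [(max(spec.cutoff, lb), ub)]
    else:  # notched
        n_lo, n_hi = spec.notch_edges
        intervals = [(lb, min(n_lo, ub)), (max(n_hi, lb), ub)]
    cov = _band_coverage(grid, intervals)
    return AmplitudeSpectrum(grid=grid, amplitude=spec.power_density * cov)


def octave_distance(f1: float, f2: float) -> float:
    """Signed distance log2(f1/f2) in octaves; antisymmetric in its arguments."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if np.any(f1 <= 0) or np.any(f2 <= 0):
        raise ParameterError("frequencies must be positive")
    out = np.log2(f1 / f2)
    return float(out) if out.ndim == 0 else out
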