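"""Normalization-model encoder for a bank of V1-like spatial-frequency channels.

Each model neuron has a Gaussian spatial-frequency tuning function on the
octave axis (full width at half height ``bw_exc`` for the excitatory
receptive field, ``bw_gain`` for the divisive gain-control pool).  The mean
firing rate of neuron *i* to a grating of frequency ``f_g`` and Michelson
contrast ``c`` in a noise background ``N`` is

    R_i = R_sp + a_exc * E_N
          + R_max * (c E_s)^p / (c50^p + (c G_s)^p + (a_inh G_N)^p)

where ``E_s``/``G_s`` are the excitatory and gain-pool drives to the grating
and ``E_N``/``G_N`` the corresponding drives to the noise spectrum.  Filter
drives are normalized so a full-contrast grating at the preferred frequency
yields a drive of exactly one.  Spike-count variance over the stimulus
duration follows the mean-proportional law ``var = k_fano * mean``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .spectra import (
    AmplitudeSpectrum,
    FrequencyGrid,
    NoiseSpec,
    ParameterError,
    default_grid,
    noise_spectrum,
)

__all__ = [
    "FWHH_TO_SIGMA",
    "PopulationParams",
    "PopulationResponse",
    "tuning_value",
    "linear_filter_response",
    "noise_drives",
    "mean_rates",
    "contrast_response",
    "population_response",
    "sample_response",
]

#: Conversion from full width at half height (octaves) to Gaussian sigma.
FWHH_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_F_PREF_RANGE = (0.25, 60.0)


def _preferred_frequencies(n_neurons: int, placement: str) -> np.ndarray:
    lo, hi = _F_PREF_RANGE
    if placement == "log":
        return 2.0 ** np.linspace(np.log2(lo), np.log2(hi), n_neurons)
    if placement == "linear":
        return np.linspace(lo, hi, n_neurons)
    raise ParameterError("placement must be 'log' or 'linear'")


@dataclass(frozen=True)
class PopulationParams:
    """Tuning and normalization parameters of the encoding population.

    Fixed physiological constants default to the study conditions: maximal
    rate 100 Hz, spontaneous rate 1 Hz (1% of maximal), Fano-like variance
    constant 1.5, stimulus duration 50 ms, transducer exponent 2, and 100
    neurons with preferred frequencies covering 0.25-60 c/deg (uniform in
    octaves by default).
    """

    f_pref: np.ndarray
    bw_exc: float = 0.9
    bw_gain: float = 2.9
    c50: float = 0.03
    a_exc: float = 4.5
    a_inh: float = 0.12
    r_max: float = 100.0
    r_sp: float = 1.0
    k_fano: float = 1.5
    t_dur: float = 0.05
    p_exp: float = 2.0

    def __post_init__(self):
        f = np.asarray(self.f_pref, dtype=float)
        object.__setattr__(self, "f_pref", f)
        if f.ndim != 1 or np.any(np.diff(f) < 0):
            raise ParameterError("f_pref must be a sorted 1-D array")
        lo, hi = _F_PREF_RANGE
        if np.any(f < lo - 1e-9) or np.any(f > hi + 1e-9):
            raise ParameterError(f"preferred frequencies must lie in [{lo}, {hi}] c/deg")
        for name in ("bw_exc", "bw_gain", "c50", "a_exc", "a_inh",
                     "r_max", "r_sp", "k_fano", "t_dur"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.p_exp < 1:
            raise ParameterError("p_exp must be >= 1")

    @property
    def n_neurons(self) -> int:
        return self.f_pref.size

    @classmethod
    def paper_defaults(cls, n_neurons: int = 100, placement: str = "log",
                       **overrides) -> "PopulationParams":
        """Population with the study's fixed values and fitted tuning defaults.

        ``r_sp`` is tied to 1% of ``r_max`` unless overridden explicitly.
        """
        f_pref = _preferred_frequencies(n_neurons, placement)
        if "r_max" in overrides and "r_sp" not in overrides:
            overrides["r_sp"] = 0.01 * overrides["r_max"]
        return cls(f_pref=f_pref, **overrides)

    def replace(self, **changes) -> "PopulationParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class PopulationResponse:
    """Expected spike counts and count variances for one stimulus interval."""

    mean_count: np.ndarray
    variance: np.ndarray
    params_ref: str = ""
    stimulus_ref: str = ""

    def __post_init__(self):
        m = np.asarray(self.mean_count, dtype=float)
        v = np.asarray(self.variance, dtype=float)
        object.__setattr__(self, "mean_count", m)
        object.__setattr__(self, "variance", v)
        if m.shape != v.shape:
            raise ParameterError("mean_count and variance must have the same shape")


def tuning_value(f_pref, bandwidth, f):
    """Gaussian tuning gain in (0, 1] at frequency ``f``.

    The tuning function is Gaussian on the octave axis with full width at
    half height ``bandwidth`` (octaves) and peak value exactly 1 at
    ``f = f_pref``.
    """
    f_pref = np.asarray(f_pref, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(f_pref <= 0) or np.any(f <= 0) or bandwidth <= 0:
        raise ParameterError("tuning_value requires strictly positive arguments")
    sigma = bandwidth * FWHH_TO_SIGMA
    d = np.log2(f / f_pref)
    out = np.exp(-(d * d) / (2.0 * sigma * sigma))
    return float(out) if out.ndim == 0 else out


def linear_filter_response(spectrum: AmplitudeSpectrum, f_pref: float,
                           bandwidth: float) -> float:
    """Drive of a linear filter by an amplitude spectrum.

    Line spectra are summed bin-wise; density spectra are integrated over the
    octave axis (trapezoidal rule).  The result is normalized by the drive a
    full-contrast grating at ``f_pref`` would produce, so the response to
    such a grating is exactly one.
    """
    if spectrum.amplitude.size == 0:
        raise ParameterError("empty spectrum")
    grid = spectrum.grid
    gains = tuning_value(f_pref, bandwidth, grid.frequencies)
    # Denominator: a contrast-1 grating at f_pref occupies the nearest bin.
    denom = gains[grid.nearest_index(f_pref)]
    if spectrum.kind == "line":
        drive = float(np.dot(spectrum.amplitude, gains))
    else:
        drive = float(np.trapezoid(spectrum.amplitude * gains, grid.log2_frequencies))
    return drive / denom


def noise_drives(params: PopulationParams, noise: NoiseSpec,
                 grid: Optional[FrequencyGrid] = None) -> tuple[np.ndarray, np.ndarray]:
    """Excitatory and gain-pool drives (E_N, G_N) of every neuron to a noise background."""
    grid = grid or default_grid()
    spec = noise_spectrum(noise, grid)
    x = grid.log2_frequencies
    sig_e = params.bw_exc * FWHH_TO_SIGMA
    sig_g = params.bw_gain * FWHH_TO_SIGMA
    d = x[None, :] - np.log2(params.f_pref)[:, None]
    d2 = d * d
    w = np.full(x.size, grid.log2_step)  # trapezoid weights on the octave axis
    w[0] *= 0.5
    w[-1] *= 0.5
    amp_w = spec.amplitude * w
    e_n = np.exp(-d2 / (2.0 * sig_e * sig_e)) @ amp_w
    g_n = np.exp(-d2 / (2.0 * sig_g * sig_g)) @ amp_w
    return e_n, g_n


def mean_rates(params: PopulationParams, f_g: float, contrast: float,
               noise: NoiseSpec, grid: Optional[FrequencyGrid] = None,
               noise_drive: Optional[tuple[np.ndarray, np.ndarray]] = None) -> np.ndarray:
    """Mean firing rate (Hz) of every neuron to a grating in noise.

    ``f_g`` may be ``None`` (or ``contrast`` zero) for a blank interval.
    Grating drives are evaluated in closed form (the grating is a spectral
    line), which makes rates independent of grid resolution.
    """
    if contrast < 0 or contrast > 1:
        raise ParameterError("contrast must lie in [0, 1]")
    if noise_drive is None:
        e_n, g_n = noise_drives(params, noise, grid)
    else:
        e_n, g_n = noise_drive
    if f_g is None or contrast == 0.0:
        e_s = np.zeros(params.n_neurons)
        g_s = np.zeros(params.n_neurons)
    else:
        e_s = tuning_value(params.f_pref, params.bw_exc, f_g)
        g_s = tuning_value(params.f_pref, params.bw_gain, f_g)
    p = params.p_exp
    num = (contrast * e_s) ** p
    den = params.c50 ** p + (contrast * g_s) ** p + (params.a_inh * g_n) ** p
    return params.r_sp + params.a_exc * e_n + params.r_max * num / den


def contrast_response(params: PopulationParams, neuron_index: int, f_g: float,
                      contrast: float, noise: NoiseSpec,
                      grid: Optional[FrequencyGrid] = None) -> float:
    """Mean firing rate (Hz) of one neuron; see :func:`mean_rates`."""
    if not (0 <= neuron_index < params.n_neurons):
        raise ParameterError(f"neuron index {neuron_index} out of range")
    return float(mean_rates(params, f_g, contrast, noise, grid)[neuron_index])


def population_response(params: PopulationParams, f_g: Optional[float],
                        contrast: float, noise: NoiseSpec,
                        grid: Optional[FrequencyGrid] = None,
                        noise_drive: Optional[tuple] = None) -> PopulationResponse:
    """Expected spike counts and variances over one stimulus interval."""
    rates = mean_rates(params, f_g, contrast, noise, grid, noise_drive=noise_drive)
    mean = rates * params.t_dur
    return PopulationResponse(
        mean_count=mean,
        variance=params.k_fano * mean,
        params_ref=f"pop(n={params.n_neurons})",
        stimulus_ref=f"grating({f_g},{contrast}) in {noise.kind}",
    )


def sample_response(resp: PopulationResponse, seed) -> np.ndarray:
    """Sample realized spike counts (Gaussian approximation, untruncated).

    ``seed`` may be an integer seed or a ``numpy.random.Generator``;
    identical seeds yield identical draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(resp.mean_count, np.sqrt(resp.variance))
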