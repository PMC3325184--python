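"""Likelihood-based population decoding of spatial frequency.

The decoder assumes independent Poisson spiking and is ignorant of the
external noise background: its internal model of neuron *i*'s mean response
to a grating of frequency *f* is the noise-free normalization-model rate at
a fixed reference contrast.  The response-dependent part of the Poisson log
likelihood of *f* is then a weighted sum of spike counts,

    L(f) = sum_i n_i * h_i(f),      h_i(f) = log(lambda_i(f) / lambda_floor),

where ``lambda_i(f)`` is the assumed mean count and ``lambda_floor`` the
spontaneous count, so ``h_i`` is a bounded, localized bump peaking at the
neuron's preferred frequency (additive constants cancel in all likelihood
ratios).  Discrete log-likelihood values are obtained by integrating L
against a unit-mass Gaussian read-out function on the octave axis whose full
width at half height is the read-out width; zero width is the ideal
point-evaluation limit.  Two-interval decisions compare interval
log-likelihood ratios, and an efficiency parameter in (0, 1] rescales the
decision signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .encoding import (
    FWHH_TO_SIGMA,
    PopulationParams,
    population_response,
    tuning_value,
)
from .spectra import FrequencyGrid, NoiseSpec, ParameterError, default_grid

__all__ = [
    "DegenerateConditionError",
    "ReadOutSpec",
    "DecoderSpec",
    "ReducedLogLikelihood",
    "DiscriminationCondition",
    "DetectionCondition",
    "log_tuning",
    "reduced_log_likelihood",
    "readout_weights",
    "read_out",
    "weighting_profile",
    "llr_interval",
    "discriminate_trial",
    "detect_trial",
    "predict_choice_probability",
    "predicted_psychometric",
    "predicted_pse",
]

#: Read-out widths at or below this value (octaves) are treated as the ideal limit.
IDEAL_WIDTH = 1e-9

#: Default decoder template contrast (fraction); see DecoderSpec.ref_contrast.
DEFAULT_REF_CONTRAST = 0.15


class DegenerateConditionError(ValueError):
    """Decision variable has zero variance but nonzero mean."""


@dataclass(frozen=True)
class ReadOutSpec:
    """Gaussian read-out function(s): FWHH width in octaves and center frequencies."""

    width: float
    centers: tuple

    def __post_init__(self):
        if self.width < 0:
            raise ParameterError("read-out width must be >= 0")
        if any(c <= 0 for c in self.centers):
            raise ParameterError("read-out centers must be positive frequencies")


@dataclass(frozen=True)
class DecoderSpec:
    """Decoder configuration.

    ``width``: read-out FWHH in octaves (0 = ideal point evaluation).
    ``efficiency``: factor in (0, 1] multiplying the decision d-prime.
    ``mode``: ``analytic`` (closed-form Gaussian decision variable) or
    ``monte_carlo`` (``n_sims`` simulated trials).
    ``ref_contrast``: grating contrast assumed by the decoder's internal
    response templates (the experiment's average grating contrast).
    """

    width: float = 4.2
    efficiency: float = 1.0
    mode: str = "analytic"
    n_sims: int = 10_000
    ref_contrast: float = DEFAULT_REF_CONTRAST

    def __post_init__(self):
        if self.width < 0:
            raise ParameterError("read-out width must be >= 0")
        if not (0 < self.efficiency <= 1):
            raise ParameterError("efficiency must lie in (0, 1]")
        if self.mode not in ("analytic", "monte_carlo"):
            raise ParameterError("mode must be 'analytic' or 'monte_carlo'")
        if self.mode == "monte_carlo" and self.n_sims < 1000:
            raise ParameterError("monte_carlo mode requires n_sims >= 1000")
        if not (0 < self.ref_contrast <= 1):
            raise ParameterError("ref_contrast must lie in (0, 1]")


@dataclass(frozen=True)
class ReducedLogLikelihood:
    """Reduced log-likelihood function of spatial frequency on a grid.

    Values carry an arbitrary additive offset; every downstream decision is
    invariant under adding a constant.
    """

    grid: FrequencyGrid
    value: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "value", v)
        if v.shape != self.grid.frequencies.shape:
            raise ParameterError("value length must match grid length")
        if not np.all(np.isfinite(v)):
            raise ParameterError("reduced log likelihood must be finite everywhere")


@dataclass(frozen=True)
class DiscriminationCondition:
    """One discrimination cell: standard vs comparison grating, each in its own noise."""

    f_standard: float
    f_comparison: float
    noise_standard: NoiseSpec
    noise_comparison: NoiseSpec
    contrast: float


@dataclass(frozen=True)
class DetectionCondition:
    """One detection cell: grating of ``contrast`` at ``f_target`` vs blank, same noise."""

    f_target: float
    contrast: float
    noise: NoiseSpec


def log_tuning(params: PopulationParams, f, ref_contrast: float = DEFAULT_REF_CONTRAST):
    """Decoder log-tuning h_i(f) for every neuron (rows) at frequencies ``f`` (columns).

    ``h_i(f) = log(1 + (r_max/r_sp) * S_i(f))`` with ``S_i`` the noise-free
    normalized response drive at the reference contrast.  Bounded and
    localized: it decays to zero away from the preferred frequency, with
    Gaussian tails, so the corresponding pooling weights are concentrated on
    neurons tuned near ``f``.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any(f <= 0):
        raise ParameterError("frequencies must be positive")
    e = tuning_value(params.f_pref[:, None], params.bw_exc, f[None, :])
    g = tuning_value(params.f_pref[:, None], params.bw_gain, f[None, :])
    p = params.p_exp
    c = ref_contrast
    s = (c * e) ** p / (params.c50 ** p + (c * g) ** p)
    return np.log1p((params.r_max / params.r_sp) * s)


def reduced_log_likelihood(counts, params: PopulationParams,
                           grid: Optional[FrequencyGrid] = None,
                           ref_contrast: float = DEFAULT_REF_CONTRAST) -> ReducedLogLikelihood:
    """Reduced log-likelihood function L(f) = sum_i counts_i * h_i(f) on the grid.

    Linear in the count vector.
    """
    grid = grid or default_grid()
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (params.n_neurons,):
        raise ParameterError(
            f"counts must have length {params.n_neurons}, got {counts.shape}")
    a = log_tuning(params, grid.frequencies, ref_contrast)
    return ReducedLogLikelihood(grid=grid, value=counts @ a)


def readout_weights(grid: FrequencyGrid, center: float, width: float) -> np.ndarray:
    """Quadrature weight vector q such that ``read_out(L) = q @ L.value``.

    The read-out integral treats L as piecewise linear between grid points
    and integrates it exactly against a Gaussian of FWHH ``width`` (octaves)
    centred at ``center``, renormalized to unit mass over the grid.  For
    ``width`` at the ideal limit the weights reduce to linear interpolation
    at ``center``.
    """
    if not grid.contains(center):
        raise ParameterError(f"read-out center {center} outside grid range")
    if width < 0:
        raise ParameterError("read-out width must be >= 0")
    x = grid.log2_frequencies
    c = np.log2(center)
    q = np.zeros(x.size)
    if width <= IDEAL_WIDTH:
        j = int(np.searchsorted(x, c))
        if j == 0:
            q[0] = 1.0
        elif j >= x.size:
            q[-1] = 1.0
        else:
            t = (c - x[j - 1]) / (x[j] - x[j - 1])
            q[j - 1] = 1.0 - t
            q[j] = t
        return q
    sigma = width * FWHH_TO_SIGMA
    z = (x - c) / sigma
    cdf = ndtr(z)
    pdf = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    m0 = np.diff(cdf)                         # per-segment Gaussian mass
    i1 = c * m0 - sigma * np.diff(pdf)        # per-segment first moment
    h = np.diff(x)
    a = (x[1:] * m0 - i1) / h                 # coefficient of left node
    b = (i1 - x[:-1] * m0) / h                # coefficient of right node
    q[:-1] += a
    q[1:] += b
    total = cdf[-1] - cdf[0]
    if total <= 0:
        raise ParameterError("read-out function has no mass on the grid")
    return q / total


def read_out(L: ReducedLogLikelihood, center: float, width: float) -> float:
    """Gaussian-weighted read-out of the reduced log likelihood at ``center``."""
    q = readout_weights(L.grid, center, width)
    return float(q @ L.value)


def weighting_profile(center: float, width: float, params: PopulationParams,
                      grid: Optional[FrequencyGrid] = None,
                      ref_contrast: float = DEFAULT_REF_CONTRAST) -> np.ndarray:
    """Per-neuron pooling weights equivalent to the read-out integral.

    Satisfies ``w @ counts == read_out(reduced_log_likelihood(counts), ...)``
    for every count vector (linear-functional identity).
    """
    grid = grid or default_grid()
    q = readout_weights(grid, center, width)
    a = log_tuning(params, grid.frequencies, ref_contrast)
    return a @ q


def llr_interval(counts, f_high: float, f_low: float, decoder: DecoderSpec,
                 params: PopulationParams,
                 grid: Optional[FrequencyGrid] = None) -> float:
    """Interval log-likelihood ratio: read-out at f_high minus read-out at f_low."""
    if f_high <= f_low:
        raise ParameterError("llr_interval requires f_high > f_low")
    grid = grid or default_grid()
    L = reduced_log_likelihood(counts, params, grid, decoder.ref_contrast)
    return read_out(L, f_high, decoder.width) - read_out(L, f_low, decoder.width)


def _coin(rng) -> int:
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return int(rng.integers(2))


def discriminate_trial(counts_1, counts_2, f_high: float, f_low: float,
                       decoder: DecoderSpec, params: PopulationParams,
                       grid: Optional[FrequencyGrid] = None, rng=0) -> int:
    """2AFC frequency decision: interval (1 or 2) with the larger interval LLR.

    Exact ties are broken by a seeded fair coin.
    """
    z1 = llr_interval(counts_1, f_high, f_low, decoder, params, grid)
    z2 = llr_interval(counts_2, f_high, f_low, decoder, params, grid)
    if z1 == z2:
        return 1 + _coin(rng)
    return 1 if z1 > z2 else 2


def detect_trial(counts_1, counts_2, f_target: float, decoder: DecoderSpec,
                 params: PopulationParams,
                 grid: Optional[FrequencyGrid] = None, rng=0) -> int:
    """2AFC detection decision: interval with the larger read-out at the target frequency."""
    grid = grid or default_grid()
    r = []
    for counts in (counts_1, counts_2):
        L = reduced_log_likelihood(counts, params, grid, decoder.ref_contrast)
        r.append(read_out(L, f_target, decoder.width))
    if r[0] == r[1]:
        return 1 + _coin(rng)
    return 1 if r[0] > r[1] else 2


Condition = Union[DiscriminationCondition, DetectionCondition]


def _decision_moments(params: PopulationParams, decoder: DecoderSpec,
                      condition: Condition, grid: FrequencyGrid):
    """Mean and variance of the linear decision variable, plus its weight vector.

    For discrimination the decision variable is z(comparison interval) -
    z(standard interval) with z = LLR for (f_high, f_low); positive D means
    "comparison judged higher".  For detection it is the read-out difference
    (target interval minus blank interval); positive D means a correct choice.
    """
    if isinstance(condition, DiscriminationCondition):
        fs, fc = condition.f_standard, condition.f_comparison
        resp_c = population_response(params, fc, condition.contrast,
                                     condition.noise_comparison, grid)
        resp_s = population_response(params, fs, condition.contrast,
                                     condition.noise_standard, grid)
        if fs == fc:
            dw = np.zeros(params.n_neurons)
        else:
            f_hi, f_lo = max(fs, fc), min(fs, fc)
            dw = (weighting_profile(f_hi, decoder.width, params, grid, decoder.ref_contrast)
                  - weighting_profile(f_lo, decoder.width, params, grid, decoder.ref_contrast))
        mu = float(dw @ (resp_c.mean_count - resp_s.mean_count))
        var = float((dw * dw) @ (resp_c.variance + resp_s.variance))
        resp_a, resp_b = resp_c, resp_s
    elif isinstance(condition, DetectionCondition):
        resp_t = population_response(params, condition.f_target, condition.contrast,
                                     condition.noise, grid)
        resp_b = population_response(params, None, 0.0, condition.noise, grid)
        dw = weighting_profile(condition.f_target, decoder.width, params, grid,
                               decoder.ref_contrast)
        mu = float(dw @ (resp_t.mean_count - resp_b.mean_count))
        var = float((dw * dw) @ (resp_t.variance + resp_b.variance))
        resp_a = resp_t
    else:
        raise ParameterError(f"unknown condition type {type(condition).__name__}")
    return mu, var, dw, resp_a, resp_b


def predict_choice_probability(params: PopulationParams, decoder: DecoderSpec,
                               condition: Condition,
                               grid: Optional[FrequencyGrid] = None,
                               seed: int = 0) -> float:
    """Probability of the designated choice for a two-interval condition.

    Discrimination conditions return the probability that the comparison is
    judged higher in frequency; detection conditions return the probability
    of a correct interval choice.  In ``analytic`` mode the decision variable
    is Gaussian (it is linear in the spike counts) and the probability is
    ``Phi(efficiency * mu_D / sigma_D)``; in ``monte_carlo`` mode trials are
    simulated at the spike-count level.
    """
    grid = grid or default_grid()
    mu, var, dw, resp_a, resp_b = _decision_moments(params, decoder, condition, grid)
    if var <= 0:
        if mu == 0:
            return 0.5
        raise DegenerateConditionError(
            "decision variable has zero variance but nonzero mean")
    if decoder.mode == "analytic":
        return float(ndtr(decoder.efficiency * mu / np.sqrt(var)))
    rng = np.random.default_rng(seed)
    n = decoder.n_sims
    counts_a = rng.normal(resp_a.mean_count, np.sqrt(resp_a.variance), (n, dw.size))
    counts_b = rng.normal(resp_b.mean_count, np.sqrt(resp_b.variance), (n, dw.size))
    d = (counts_a - counts_b) @ dw
    eff = decoder.efficiency
    if eff < 1.0:
        d = d + rng.normal(0.0, np.sqrt(var * (1.0 / eff ** 2 - 1.0)), n)
    ties = d == 0
    return float(np.mean(d > 0) + 0.5 * np.mean(ties))


def predicted_psychometric(params: PopulationParams, decoder: DecoderSpec,
                           standard: float, comparisons: Sequence[float],
                           noise_standard: NoiseSpec, noise_comparison: NoiseSpec,
                           contrast: float,
                           grid: Optional[FrequencyGrid] = None) -> np.ndarray:
    """Model choice-proportion curve: P(comparison judged higher) per comparison."""
    grid = grid or default_grid()
    return np.array([
        predict_choice_probability(
            params, decoder,
            DiscriminationCondition(standard, float(fc), noise_standard,
                                    noise_comparison, contrast),
            grid)
        for fc in comparisons
    ])


def predicted_pse(params: PopulationParams, decoder: DecoderSpec, standard: float,
                  noise_standard: NoiseSpec, noise_comparison: NoiseSpec,
                  contrast: float, grid: Optional[FrequencyGrid] = None,
                  bracket: tuple = (1.2, 25.0)) -> float:
    """Comparison frequency (c/deg) at which the choice proportion crosses 50%.

    Found by root-finding on the analytic choice probability over log2
    comparison frequency.
    """
    grid = grid or default_grid()
    dec = DecoderSpec(width=decoder.width, efficiency=decoder.efficiency,
                      mode="analytic", n_sims=decoder.n_sims,
                      ref_contrast=decoder.ref_contrast)

    def excess(log2_fc):
        fc = 2.0 ** log2_fc
        return predict_choice_probability(
            params, dec,
            DiscriminationCondition(standard, fc, noise_standard,
                                    noise_comparison, contrast),
            grid) - 0.5

    lo, hi = np.log2(bracket[0]), np.log2(bracket[1])
    flo, fhi = excess(lo), excess(hi)
    if flo == 0:
        return float(bracket[0])
    if fhi == 0:
        return float(bracket[1])
    if flo * fhi > 0:
        raise DegenerateConditionError(
            "choice-proportion curve does not cross 50% within the bracket")
    return float(2.0 ** brentq(excess, lo, hi, xtol=1e-10))
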