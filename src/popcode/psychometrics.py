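"""Weibull psychometric fitting, thresholds, matching frequencies and bootstrap tests.

Two fit regimes are used.  Performance curves (proportion correct in 2AFC)
have a fixed guess rate ``gamma = 0.5``; choice-proportion curves (proportion
"comparison judged higher", running 0 to 1) use ``gamma = 0``.  In both
regimes the cumulative Weibull

    psi(x) = gamma + (1 - gamma - lambda) * (1 - exp(-(x/alpha)^beta))

is fitted by binomial maximum likelihood with the lapse rate ``lambda``
bounded above (Wichmann-Hill convention, default 0.06).  Discrimination
curves are fitted on the log2-frequency abscissa; matching frequencies (PSE)
are reported back in c/deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .spectra import ParameterError

__all__ = [
    "PsychometricFit",
    "BootstrapResult",
    "weibull",
    "fit_weibull",
    "fit_weibull_fixed_pse",
    "matching_frequency",
    "threshold",
    "parametric_bootstrap",
    "WeibullBootstrapGenerator",
    "pse_monte_carlo_test",
    "binomial_ci",
    "learning_regression",
]

LAPSE_BOUND = 0.06
_BETA_MAX = 50.0
_BETA_MIN = 0.05


def weibull(x, alpha: float, beta: float, gamma: float, lamda: float):
    """Cumulative Weibull psychometric function.

    ``gamma + (1 - gamma - lamda) * (1 - exp(-(x/alpha)**beta))`` for x > 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or alpha <= 0 or beta <= 0:
        raise ParameterError("weibull requires positive x, alpha and beta")
    out = gamma + (1.0 - gamma - lamda) * (-np.expm1(-((x / alpha) ** beta)))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood Weibull fit of one psychometric dataset.

    ``x_scale`` records the abscissa convention: ``"linear"`` (e.g. contrast)
    or ``"log2"`` (log2 spatial frequency, used for discrimination curves).
    """

    alpha: float
    beta: float
    gamma: float
    lamda: float
    log_likelihood: float
    deviance: float
    n_trials: int
    x: np.ndarray = field(default_factory=lambda: np.array([]))
    n: np.ndarray = field(default_factory=lambda: np.array([]))
    k: np.ndarray = field(default_factory=lambda: np.array([]))
    x_scale: str = "linear"
    converged: bool = True

    def predict(self, x):
        return weibull(x, self.alpha, self.beta, self.gamma, self.lamda)


def _binom_loglik(k, n, p):
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _saturated_loglik(k, n):
    with np.errstate(divide="ignore", invalid="ignore"):
        ph = k / n
        t1 = np.where(k > 0, k * np.log(np.where(ph > 0, ph, 1.0)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log(np.where(ph < 1, 1.0 - ph, 1.0)), 0.0)
    return float(np.sum(t1 + t2))


def fit_weibull(x, n, k, gamma: float = 0.5, lapse_bound: float = LAPSE_BOUND,
                n_starts: int = 5, seed: int = 0, x_scale: str = "linear",
                xatol: float = 1e-7, fatol: float = 1e-10,
                maxiter: int = 2000) -> PsychometricFit:
    """Binomial maximum-likelihood Weibull fit.

    Parameters
    ----------
    x, n, k : array-like
        Stimulus levels (positive abscissa), trials per level, successes per
        level.  At least three distinct levels are required.
    gamma : float
        Fixed guess rate (0.5 for performance curves, 0 for choice curves).
    lapse_bound : float
        Upper bound for the lapse rate.
    n_starts : int
        Multi-start count; starts vary mainly in the slope ``beta``.

    Degenerate data (all successes or all failures at every level) yield a
    flagged non-converged fit rather than an exception; a slope estimate
    pinned at its upper bound is likewise flagged.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    if x.size < 3 or np.unique(x).size < 3:
        raise ParameterError("need at least 3 distinct stimulus levels")
    if np.any(x <= 0):
        raise ParameterError("stimulus levels must be positive (use log2 frequency)")
    if np.any(k < 0) or np.any(k > n) or np.any(n <= 0):
        raise ParameterError("invalid trial counts")

    def unpack(theta):
        alpha = np.exp(theta[0])
        beta = _BETA_MIN + (_BETA_MAX - _BETA_MIN) * expit(theta[1])
        lam = lapse_bound * expit(theta[2])
        return alpha, beta, lam

    def nll(theta):
        alpha, beta, lam = unpack(theta)
        with np.errstate(over="ignore"):  # steep slopes overflow harmlessly
            p = gamma + (1.0 - gamma - lam) * (-np.expm1(-((x / alpha) ** beta)))
        return -_binom_loglik(k, n, p)

    rng = np.random.default_rng(seed)
    # Anchor the location start where the data cross mid-performance.
    mid = gamma + 0.5 * (1.0 - gamma)
    ph = k / n
    order = np.argsort(x)
    cross = np.interp(mid, ph[order], x[order]) if np.any(np.diff(ph[order]) != 0) \
        else float(np.median(x))
    cross = float(np.clip(cross, x.min(), x.max()))
    starts = [np.array([np.log(cross), logit(np.clip((b - _BETA_MIN) / (_BETA_MAX - _BETA_MIN),
                                                     1e-4, 1 - 1e-4)), logit(0.2)])
              for b in (1.0, 3.0, 8.0)]
    while len(starts) < n_starts:
        starts.append(np.array([
            np.log(cross) + rng.normal(0, 0.5),
            rng.normal(0, 1.5),
            rng.normal(-1.5, 1.0),
        ]))

    best = None
    for s in starts[:n_starts]:
        res = minimize(nll, s, method="Nelder-Mead",
                       options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta, lam = unpack(best.x)
    ll = -best.fun
    ll_sat = _saturated_loglik(k, n)
    dev = max(2.0 * (ll_sat - ll), 0.0)
    degenerate = np.all(k == n) or np.all(k == 0)
    pinned = beta > 0.98 * _BETA_MAX
    return PsychometricFit(
        alpha=float(alpha), beta=float(beta), gamma=gamma, lamda=float(lam),
        log_likelihood=ll, deviance=dev, n_trials=int(n.sum()),
        x=x, n=n, k=k, x_scale=x_scale,
        converged=bool(best.success and not degenerate and not pinned),
    )


def fit_weibull_fixed_pse(x, n, k, pse_x: float, lapse_bound: float = LAPSE_BOUND,
                          n_starts: int = 3) -> PsychometricFit:
    """Choice-proportion Weibull fit constrained to cross 50% at ``pse_x``.

    The location ``alpha`` is determined by the slope and lapse so that the
    fitted curve passes through 0.5 exactly at ``pse_x`` (on the fitting
    abscissa); only slope and lapse are free.  This is the null model of the
    matching-frequency Monte-Carlo test.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    if pse_x <= 0:
        raise ParameterError("pse_x must be positive on the fitting abscissa")

    def alpha_of(beta, lam):
        frac = 0.5 / (1.0 - lam)
        return pse_x / (-np.log1p(-frac)) ** (1.0 / beta)

    def unpack(theta):
        beta = _BETA_MIN + (_BETA_MAX - _BETA_MIN) * expit(theta[0])
        lam = lapse_bound * expit(theta[1])
        return beta, lam

    def nll(theta):
        beta, lam = unpack(theta)
        alpha = alpha_of(beta, lam)
        with np.errstate(over="ignore"):
            p = (1.0 - lam) * (-np.expm1(-((x / alpha) ** beta)))
        return -_binom_loglik(k, n, p)

    best = None
    for b0 in (1.0, 3.0, 8.0)[:n_starts]:
        s = np.array([logit((b0 - _BETA_MIN) / (_BETA_MAX - _BETA_MIN)), logit(0.2)])
        res = minimize(nll, s, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 1500})
        if best is None or res.fun < best.fun:
            best = res
    beta, lam = unpack(best.x)
    alpha = alpha_of(beta, lam)
    ll = -best.fun
    dev = max(2.0 * (_saturated_loglik(k, n) - ll), 0.0)
    return PsychometricFit(alpha=float(alpha), beta=float(beta), gamma=0.0,
                           lamda=float(lam), log_likelihood=ll, deviance=dev,
                           n_trials=int(n.sum()), x=x, n=n, k=k,
                           converged=bool(best.success))


def pse_monte_carlo_test(x, n, k, standard_x: float, n_resamples: int = 999,
                         seed: int = 0, x_scale: str = "linear") -> dict:
    """Parametric Monte-Carlo test of a matching-frequency shift.

    Fits the unconstrained choice-proportion Weibull (observed PSE), then a
    null model constrained to a PSE at ``standard_x``; simulates
    ``n_resamples`` datasets from the null, refits each unconstrained, and
    reports the two-sided Monte-Carlo p-value of the observed shift (with
    the +1 correction) along with the percentile CI of the PSE under
    resampling of the unconstrained fit generator.
    """
    fit = fit_weibull(x, n, k, gamma=0.0, x_scale=x_scale)
    pse_obs = matching_frequency(fit)
    null = fit_weibull_fixed_pse(x, n, k, standard_x)
    null = PsychometricFit(**{**null.__dict__, "x_scale": x_scale})
    gen = WeibullBootstrapGenerator(null)

    def pse_abscissa(f):
        # extremity is measured on the fitting abscissa, where the shift is
        # symmetric (octaves for log2-frequency fits)
        v = matching_frequency(f)
        return float(np.log2(v)) if x_scale == "log2" else v

    res = parametric_bootstrap(gen, pse_abscissa, n_resamples, seed=seed,
                               observed=pse_abscissa(fit),
                               null_value=float(standard_x))
    return {"pse": pse_obs, "p_value": res.p_value, "n_failed": res.n_failed,
            "null_samples": res.samples, "fit": fit, "null_fit": null}


def matching_frequency(fit: PsychometricFit) -> float:
    """Comparison frequency (c/deg) yielding a 50% choice proportion.

    Only defined for choice-proportion fits (``gamma = 0``); uses the
    closed-form inversion of the Weibull at 0.5.
    """
    if fit.gamma != 0.0:
        raise ParameterError("matching frequency requires a choice-proportion fit (gamma=0)")
    target = 0.5
    frac = (target - fit.gamma) / (1.0 - fit.gamma - fit.lamda)
    if not (0 < frac < 1):
        raise ParameterError("fitted curve does not cross the 50% choice proportion")
    x50 = fit.alpha * (-np.log1p(-frac)) ** (1.0 / fit.beta)
    return float(2.0 ** x50) if fit.x_scale == "log2" else float(x50)


def threshold(fit: PsychometricFit, level: float) -> float:
    """Stimulus level at which the fitted curve reaches ``level`` (closed form)."""
    if not (fit.gamma < level < 1.0 - fit.lamda):
        raise ParameterError(
            f"level {level} outside the fitted curve's range "
            f"({fit.gamma}, {1.0 - fit.lamda})")
    frac = (level - fit.gamma) / (1.0 - fit.gamma - fit.lamda)
    return float(fit.alpha * (-np.log1p(-frac)) ** (1.0 / fit.beta))


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile CI and Monte-Carlo p-value from a parametric bootstrap."""

    n_resamples: int
    statistic: float
    ci_low: float
    ci_high: float
    p_value: Optional[float]
    n_failed: int
    samples: np.ndarray


class WeibullBootstrapGenerator:
    """Parametric resampler for a fitted Weibull psychometric dataset.

    Simulates binomial datasets of the original design from the fitted curve
    and refits them with the same regime.
    """

    def __init__(self, fit: PsychometricFit, lapse_bound: float = LAPSE_BOUND,
                 refit_options: Optional[dict] = None):
        if fit.x.size == 0:
            raise ParameterError("fit must carry its design (x, n)")
        self.fit = fit
        self.lapse_bound = lapse_bound
        # bootstrap refits trade some optimizer precision for speed
        self.refit_options = {"n_starts": 2, "xatol": 1e-4, "fatol": 1e-8,
                              "maxiter": 600}
        self.refit_options.update(refit_options or {})
        self._p = fit.predict(fit.x)

    def simulate(self, rng: np.random.Generator):
        return rng.binomial(self.fit.n.astype(int), self._p)

    def refit(self, k) -> PsychometricFit:
        return fit_weibull(self.fit.x, self.fit.n, k, gamma=self.fit.gamma,
                           lapse_bound=self.lapse_bound,
                           x_scale=self.fit.x_scale, **self.refit_options)


def parametric_bootstrap(generator, statistic: Callable, n_resamples: int,
                         seed: int = 0, observed: Optional[float] = None,
                         null_value: Optional[float] = None) -> BootstrapResult:
    """Parametric Monte-Carlo bootstrap: simulate -> refit -> statistic.

    Percentile confidence intervals are taken at 2.5/97.5%; if ``observed``
    and ``null_value`` are given, a two-sided Monte-Carlo p-value is computed
    with the +1 correction, ``p = (1 + #{|s - null| >= |observed - null|}) /
    (1 + R)``.  Resamples whose refit fails to converge are recorded in
    ``n_failed`` and excluded with a warning.
    """
    if n_resamples < 1:
        raise ParameterError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    samples, failed = [], 0
    for _ in range(n_resamples):
        data = generator.simulate(rng)
        refit = generator.refit(data)
        if getattr(refit, "converged", True):
            samples.append(statistic(refit))
        else:
            failed += 1
    if failed:
        warnings.warn(f"{failed} of {n_resamples} bootstrap refits did not converge")
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ParameterError("all bootstrap refits failed")
    lo, hi = np.percentile(samples, [2.5, 97.5])
    p = None
    if observed is not None and null_value is not None:
        extreme = np.abs(samples - null_value) >= abs(observed - null_value)
        p = (1.0 + int(extreme.sum())) / (1.0 + samples.size)
    return BootstrapResult(n_resamples=n_resamples, statistic=observed if observed is not None
                           else float(np.median(samples)),
                           ci_low=float(lo), ci_high=float(hi), p_value=p,
                           n_failed=failed, samples=samples)


def binomial_ci(p_hat: float, n: int) -> tuple[float, float]:
    """Two-sided 95% normal-approximation binomial CI, clipped to [0, 1]."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not (0.0 <= p_hat <= 1.0):
        raise ParameterError("p_hat must lie in [0, 1]")
    half = 1.959963984540054 * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return (float(max(p_hat - half, 0.0)), float(min(p_hat + half, 1.0)))


def learning_regression(trial_outcomes, subset_size: int = 60,
                        n_sims: int = 999, seed: int = 0) -> dict:
    """Least-squares learning-curve slope with a Monte-Carlo test.

    Proportion correct is computed for each complete consecutive subset of
    ``subset_size`` trials and regressed linearly on subset index.  The
    p-value is parametric Monte-Carlo under a constant-probability Bernoulli
    null (two-sided on the slope, +1 correction).
    """
    y = np.asarray(trial_outcomes, dtype=float)
    n_sub = y.size // subset_size
    if n_sub < 2:
        raise ParameterError("need at least 2 complete subsets")
    used = y[: n_sub * subset_size].reshape(n_sub, subset_size)
    props = used.mean(axis=1)
    idx = np.arange(n_sub, dtype=float)
    slope, intercept = np.polyfit(idx, props, 1)
    p_bar = float(used.mean())
    rng = np.random.default_rng(seed)
    sims = rng.random((n_sims, n_sub, subset_size)) < p_bar
    sim_props = sims.mean(axis=2)
    xc = idx - idx.mean()
    sim_slopes = (sim_props - sim_props.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    p = (1.0 + int(np.sum(np.abs(sim_slopes) >= abs(slope)))) / (1.0 + n_sims)
    return {"slope": float(slope), "intercept": float(intercept),
            "p_value": float(p), "n_subsets": int(n_sub),
            "proportions": props}
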