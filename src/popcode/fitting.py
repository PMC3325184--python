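"""Joint fitting of the population-code model to detection and discrimination data.

`PopulationCodeModel` is built from trial-level datasets (statsmodels
style); its `fit()` minimizes the total binomial deviance — detection plus
discrimination — over the free parameters (excitatory and gain-pool tuning
bandwidths, semisaturation contrast, the two noise-scaling parameters,
read-out width and decoder efficiency) with a multi-start Nelder-Mead
simplex on log/logit-transformed parameters, and returns a
`PopulationCodeResults` carrying deviances, AIC and a summary table.
Constrained variants (e.g. read-out width frozen at the near-zero ideal
limit) support the nested-model comparisons of the ideal-observer analysis.

The deviance evaluation is fully vectorized over condition cells so that a
single evaluation costs ~1 ms; the per-cell analytic choice probabilities
are identical (to rounding) to `decoding.predict_choice_probability`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr
from scipy.stats import binom

from .decoding import (
    DEFAULT_REF_CONTRAST,
    DecoderSpec,
    IDEAL_WIDTH,
    predicted_pse,
)
from .encoding import FWHH_TO_SIGMA, PopulationParams
from .psychometrics import fit_weibull
from .spectra import FrequencyGrid, ParameterError, default_grid, noise_spectrum
from .synth import STANDARD_NOISE, TrialDataset, make_design

__all__ = [
    "FREE_PARAMETER_NAMES",
    "DEFAULT_BOUNDS",
    "ModelParams",
    "PopulationCodeModel",
    "PopulationCodeResults",
    "model_deviance",
    "joint_fit",
    "constrained_fit",
    "compare_models",
    "nested_monte_carlo_test",
    "ideal_observer_analysis",
    "fit_weibull_reference",
]

#: Parameters that are free in the unconstrained joint fit, in canonical order.
FREE_PARAMETER_NAMES = ("bw_exc", "bw_gain", "c50", "a_exc", "a_inh",
                        "width", "efficiency")

DEFAULT_BOUNDS = {
    "bw_exc": (0.2, 4.0),
    "bw_gain": (0.4, 10.0),
    "c50": (0.003, 0.3),
    "a_exc": (0.2, 50.0),
    "a_inh": (0.005, 2.0),
    "width": (1e-3, 8.0),
    "efficiency": (1e-3, 1.0),
}

_TRANSFORMS = {name: ("logit" if name == "efficiency" else "log")
               for name in FREE_PARAMETER_NAMES}

#: "Infinitely small" read-out width is frozen at this value (octaves) in
#: constrained fits: the grid-resolution floor keeps the read-out integral stable.
NEAR_ZERO_WIDTH = 1e-3


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the population-code observer model.

    Combines the encoder's `PopulationParams` and the decoder's
    `DecoderSpec` with the fitting metadata: which parameters are free,
    their box bounds and their fitting transforms (log for positive scales,
    logit for the efficiency fraction).
    """

    population: PopulationParams
    decoder: DecoderSpec
    free_mask: dict = field(default_factory=lambda: {n: True for n in FREE_PARAMETER_NAMES})
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    transforms: dict = field(default_factory=lambda: dict(_TRANSFORMS))

    def __post_init__(self):
        for name, free in self.free_mask.items():
            if name not in FREE_PARAMETER_NAMES:
                raise ParameterError(f"unknown parameter {name!r}")
            if free:
                lo, hi = self.bounds.get(name, (None, None))
                if lo is None or not np.isfinite([lo, hi]).all():
                    raise ParameterError(f"free parameter {name!r} needs finite bounds")
                if name not in self.transforms:
                    raise ParameterError(f"free parameter {name!r} needs a transform")
        elo, ehi = self.bounds.get("efficiency", (1e-3, 1.0))
        if ehi > 1.0 or elo <= 0.0:
            raise ParameterError("efficiency must be bounded within (0, 1]")

    def value(self, name: str) -> float:
        if name in ("width", "efficiency"):
            return getattr(self.decoder, name)
        return getattr(self.population, name)

    def with_values(self, **values) -> "ModelParams":
        dec_changes = {k: v for k, v in values.items() if k in ("width", "efficiency")}
        pop_changes = {k: v for k, v in values.items() if k not in dec_changes}
        pop = self.population.replace(**pop_changes) if pop_changes else self.population
        dec = replace(self.decoder, **dec_changes) if dec_changes else self.decoder
        return replace(self, population=pop, decoder=dec)

    @classmethod
    def defaults(cls, n_neurons: int = 100, placement: str = "log",
                 width: float = 4.2, efficiency: float = 1.0,
                 ref_contrast: float = DEFAULT_REF_CONTRAST,
                 **pop_overrides) -> "ModelParams":
        pop = PopulationParams.paper_defaults(n_neurons, placement, **pop_overrides)
        dec = DecoderSpec(width=width, efficiency=efficiency, ref_contrast=ref_contrast)
        return cls(population=pop, decoder=dec)


def _binomial_deviance(n, k, p):
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(np.where(k > 0, k, 1.0) / (n * p)), 0.0)
        t2 = np.where(n - k > 0,
                      (n - k) * np.log(np.where(n - k > 0, n - k, 1.0) / (n * (1.0 - p))),
                      0.0)
    return float(2.0 * np.sum(t1 + t2))


def _readout_matrix(x: np.ndarray, centers_log2: np.ndarray, width: float) -> np.ndarray:
    """Columns of read-out quadrature weights for several centers at one width."""
    g, c = x.size, centers_log2.size
    q = np.zeros((g, c))
    if width <= IDEAL_WIDTH:
        j = np.searchsorted(x, centers_log2)
        j = np.clip(j, 1, g - 1)
        t = (centers_log2 - x[j - 1]) / (x[j] - x[j - 1])
        cols = np.arange(c)
        q[j - 1, cols] = 1.0 - t
        q[j, cols] = t
        return q
    sigma = width * FWHH_TO_SIGMA
    z = (x[:, None] - centers_log2[None, :]) / sigma
    cdf = ndtr(z)
    pdf = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    m0 = np.diff(cdf, axis=0)
    i1 = centers_log2[None, :] * m0 - sigma * np.diff(pdf, axis=0)
    h = np.diff(x)[:, None]
    a = (x[1:, None] * m0 - i1) / h
    b = (i1 - x[:-1, None] * m0) / h
    q[:-1] += a
    q[1:] += b
    return q / (cdf[-1] - cdf[0])[None, :]


class PopulationCodeModel:
    """Population-code observer model bound to detection/discrimination data.

    Parameters
    ----------
    detection, discrimination : TrialDataset or None
        Trial-level 2AFC datasets.  At least one must be given.
    grid : FrequencyGrid, optional
        Spatial-frequency grid for spectra and likelihood functions.
    n_neurons, placement :
        Size and preferred-frequency placement of the encoding population.
    ref_contrast : float, optional
        Decoder template / simulation contrast; defaults to the average
        grating contrast of the discrimination data.
    fixed : dict, optional
        Overrides for the fixed physiological constants (r_max, r_sp,
        k_fano, t_dur, p_exp).
    """

    def __init__(self, detection: Optional[TrialDataset] = None,
                 discrimination: Optional[TrialDataset] = None,
                 grid: Optional[FrequencyGrid] = None,
                 n_neurons: int = 100, placement: str = "log",
                 ref_contrast: Optional[float] = None,
                 bounds: Optional[dict] = None,
                 fixed: Optional[dict] = None):
        if detection is None and discrimination is None:
            raise ParameterError("need at least one dataset")
        self.grid = grid or default_grid()
        self.detection = detection
        self.discrimination = discrimination
        self.bounds = dict(DEFAULT_BOUNDS)
        if bounds:
            self.bounds.update(bounds)
        self._fixed = dict(fixed or {})
        self._template = PopulationParams.paper_defaults(n_neurons, placement,
                                                         **self._fixed)
        self.noise_specs = dict(STANDARD_NOISE)
        for ds in (detection, discrimination):
            if ds is not None:
                self.noise_specs.update(ds.noise_specs)

        self.disc_cells = discrimination.cells() if discrimination is not None else None
        self.det_cells = detection.cells() if detection is not None else None
        if ref_contrast is not None:
            self.ref_contrast = float(ref_contrast)
        elif self.disc_cells is not None:
            w = self.disc_cells["n"].to_numpy(float)
            self.ref_contrast = float(
                np.average(self.disc_cells["contrast"].to_numpy(float), weights=w))
        else:
            self.ref_contrast = DEFAULT_REF_CONTRAST
        self._prepare()

    # ------------------------------------------------------------------ setup
    def _prepare(self):
        grid = self.grid
        x = grid.log2_frequencies
        self._x = x
        self._xp = np.log2(self._template.f_pref)
        self._d2 = (x[None, :] - self._xp[:, None]) ** 2
        w = np.full(x.size, grid.log2_step)
        w[0] *= 0.5
        w[-1] *= 0.5
        kinds = set()
        if self.disc_cells is not None:
            kinds |= set(self.disc_cells["noise_standard"]) | set(
                self.disc_cells["noise_comparison"])
        if self.det_cells is not None:
            kinds |= set(self.det_cells["noise"])
        self._kinds = sorted(kinds)
        self._masses = {k: noise_spectrum(self.noise_specs[k], grid).amplitude * w
                        for k in self._kinds}
        kidx = {k: i for i, k in enumerate(self._kinds)}

        freqs = set()
        if self.disc_cells is not None:
            self._f_standard = float(self.disc_cells["f_standard"].iloc[0])
            freqs |= {self._f_standard}
            freqs |= set(float(v) for v in self.disc_cells["f_comparison"])
        if self.det_cells is not None:
            self._f_target = float(self.det_cells["f_target"].iloc[0])
            freqs |= {self._f_target}
        self._freqs = np.array(sorted(freqs))
        fidx = {f: i for i, f in enumerate(self._freqs)}
        self._dg2 = (np.log2(self._freqs)[None, :] - self._xp[:, None]) ** 2

        if self.disc_cells is not None:
            dc = self.disc_cells
            self._disc_n = dc["n"].to_numpy(float)
            self._disc_k = dc["k"].to_numpy(float)
            self._disc_hi = np.array([fidx[max(self._f_standard, float(f))]
                                      for f in dc["f_comparison"]])
            self._disc_lo = np.array([fidx[min(self._f_standard, float(f))]
                                      for f in dc["f_comparison"]])
            self._disc_fc = np.array([fidx[float(f)] for f in dc["f_comparison"]])
            self._disc_fs = np.array([fidx[self._f_standard]] * len(dc))
            self._disc_ns = np.array([kidx[k] for k in dc["noise_standard"]])
            self._disc_nc = np.array([kidx[k] for k in dc["noise_comparison"]])
            self._disc_equal = dc["f_comparison"].to_numpy(float) == self._f_standard
        if self.det_cells is not None:
            tc = self.det_cells
            self._det_n = tc["n"].to_numpy(float)
            self._det_k = tc["k"].to_numpy(float)
            self._det_c = tc["contrast"].to_numpy(float)
            self._det_noise = np.array([kidx[k] for k in tc["noise"]])
            self._det_fi = fidx[self._f_target]

    # ------------------------------------------------------------ evaluation
    def _probabilities(self, values: dict):
        """Analytic choice probabilities for every condition cell."""
        t = self._template
        bw_e = values["bw_exc"] * FWHH_TO_SIGMA
        bw_g = values["bw_gain"] * FWHH_TO_SIGMA
        c50, a_exc, a_inh = values["c50"], values["a_exc"], values["a_inh"]
        width, eff = values["width"], values["efficiency"]
        p = t.p_exp
        cref = self.ref_contrast

        te = np.exp(-self._d2 / (2.0 * bw_e * bw_e))
        tg = np.exp(-self._d2 / (2.0 * bw_g * bw_g))
        en = np.stack([te @ self._masses[k] for k in self._kinds])  # (K, n)
        gn = np.stack([tg @ self._masses[k] for k in self._kinds])
        es = np.exp(-self._dg2 / (2.0 * bw_e * bw_e))  # (n, F)
        gs = np.exp(-self._dg2 / (2.0 * bw_g * bw_g))

        s_grid = (cref * te) ** p / (c50 ** p + (cref * tg) ** p)
        a = np.log1p((t.r_max / t.r_sp) * s_grid)  # (n, G)
        q = _readout_matrix(self._x, np.log2(self._freqs), width)  # (G, F)
        wmat = a @ q  # (n, F) pooling weights per read-out center

        def mean_counts(f_idx, contrast, kind_idx):
            # f_idx, contrast, kind_idx: arrays over cells -> (cells, n)
            num = (contrast[:, None] * es[:, f_idx].T) ** p
            den = c50 ** p + (contrast[:, None] * gs[:, f_idx].T) ** p \
                + (a_inh * gn[kind_idx]) ** p
            r = t.r_sp + a_exc * en[kind_idx] + t.r_max * num / den
            return r * t.t_dur

        out = {}
        if self.disc_cells is not None:
            c = np.full(self._disc_fc.size, cref)
            m_comp = mean_counts(self._disc_fc, c, self._disc_nc)
            m_std = mean_counts(self._disc_fs, c, self._disc_ns)
            dw = (wmat[:, self._disc_hi] - wmat[:, self._disc_lo]).T  # (cells, n)
            mu = np.sum(dw * (m_comp - m_std), axis=1)
            var = np.sum(dw * dw * t.k_fano * (m_comp + m_std), axis=1)
            pr = np.where(var > 0, ndtr(eff * mu / np.sqrt(np.where(var > 0, var, 1.0))), 0.5)
            pr = np.where(self._disc_equal, 0.5, pr)
            out["discrimination"] = pr
        if self.det_cells is not None:
            fi = np.full(self._det_c.size, self._det_fi)
            m_sig = mean_counts(fi, self._det_c, self._det_noise)
            m_blank = mean_counts(fi, np.zeros_like(self._det_c), self._det_noise)
            w0 = wmat[:, self._det_fi]
            mu = np.sum(w0[None, :] * (m_sig - m_blank), axis=1)
            var = np.sum((w0 * w0)[None, :] * t.k_fano * (m_sig + m_blank), axis=1)
            out["detection"] = np.where(
                var > 0, ndtr(eff * mu / np.sqrt(np.where(var > 0, var, 1.0))), 0.5)
        return out

    def _values_of(self, params: ModelParams) -> dict:
        return {n: params.value(n) for n in FREE_PARAMETER_NAMES}

    def deviance(self, params: ModelParams) -> dict:
        """Per-dataset and total binomial deviance at the given parameters.

        The saturated model uses the observed proportions; model
        probabilities of exactly 0 or 1 are clipped at machine-safe bounds.
        """
        probs = self._probabilities(self._values_of(params))
        dev_disc = dev_det = 0.0
        if "discrimination" in probs:
            dev_disc = _binomial_deviance(self._disc_n, self._disc_k,
                                          probs["discrimination"])
        if "detection" in probs:
            dev_det = _binomial_deviance(self._det_n, self._det_k, probs["detection"])
        return {"detection": dev_det, "discrimination": dev_disc,
                "total": dev_det + dev_disc}

    def log_likelihood(self, params: ModelParams) -> float:
        """Cell-level binomial log likelihood (including binomial coefficients)."""
        probs = self._probabilities(self._values_of(params))
        ll = 0.0
        if "discrimination" in probs:
            ll += float(binom.logpmf(self._disc_k, self._disc_n,
                                     np.clip(probs["discrimination"], 1e-12, 1 - 1e-12)).sum())
        if "detection" in probs:
            ll += float(binom.logpmf(self._det_k, self._det_n,
                                     np.clip(probs["detection"], 1e-12, 1 - 1e-12)).sum())
        return ll

    def predict(self, params: ModelParams) -> dict:
        """Per-cell predicted probabilities alongside the observed proportions."""
        probs = self._probabilities(self._values_of(params))
        out = {}
        if self.disc_cells is not None:
            df = self.disc_cells.copy()
            df["p_model"] = probs["discrimination"]
            df["p_observed"] = df["k"] / df["n"]
            out["discrimination"] = df
        if self.det_cells is not None:
            df = self.det_cells.copy()
            df["p_model"] = probs["detection"]
            df["p_observed"] = df["k"] / df["n"]
            out["detection"] = df
        return out

    # ---------------------------------------------------------------- fitting
    def _pack(self, values: dict, names) -> np.ndarray:
        out = []
        for n in names:
            v = values[n]
            if _TRANSFORMS[n] == "log":
                out.append(np.log(v))
            else:
                lo, hi = 1e-6, 1.0
                out.append(logit(np.clip(v, lo, 1 - 1e-9)))
        return np.array(out)

    def _unpack(self, theta: np.ndarray, names) -> dict:
        out = {}
        for v, n in zip(theta, names):
            out[n] = float(np.exp(v)) if _TRANSFORMS[n] == "log" else float(expit(v))
        return out

    def fit(self, start: Optional[ModelParams] = None, restarts: int = 20,
            seed: int = 0, fixed_params: Optional[dict] = None,
            maxiter: int = 3000, fatol: float = 1e-6,
            xatol: float = 1e-5) -> "PopulationCodeResults":
        """Best-of-restarts Nelder-Mead minimization of the total deviance.

        ``fixed_params`` freezes named parameters at given values (the
        constrained fits of the ideal-observer analysis); the remaining
        parameters stay free.  Starting points are the canonical defaults,
        the optional ``start``, and log-uniform draws within the bounds
        seeded by ``seed``; the result is deterministic for a fixed seed.
        """
        if restarts < 1:
            raise ParameterError("need at least one restart")
        fixed_params = dict(fixed_params or {})
        for name in fixed_params:
            if name not in FREE_PARAMETER_NAMES:
                raise ParameterError(f"unknown parameter {name!r}")
        free_names = [n for n in FREE_PARAMETER_NAMES if n not in fixed_params]
        if not free_names:
            raise ParameterError("over-constrained: no free parameters remain")

        base = start or ModelParams.defaults(ref_contrast=self.ref_contrast,
                                             **self._fixed)
        base = base.with_values(**fixed_params)
        base_values = self._values_of(base)

        tlo = self._pack({n: self.bounds[n][0] for n in free_names}, free_names)
        thi = self._pack({n: self.bounds[n][1] for n in free_names}, free_names)

        def objective(theta):
            values = dict(base_values)
            values.update(self._unpack(theta, free_names))
            probs = self._probabilities(values)
            dev = 0.0
            if "discrimination" in probs:
                dev += _binomial_deviance(self._disc_n, self._disc_k,
                                          probs["discrimination"])
            if "detection" in probs:
                dev += _binomial_deviance(self._det_n, self._det_k, probs["detection"])
            if not np.isfinite(dev):
                return 1e12
            pen = np.sum(np.maximum(theta - thi, 0.0) ** 2) \
                + np.sum(np.maximum(tlo - theta, 0.0) ** 2)
            return dev + 1e4 * pen

        rng = np.random.default_rng(seed)
        starts = [self._pack({n: base_values[n] for n in free_names}, free_names)]
        while len(starts) < restarts:
            starts.append(tlo + rng.random(len(free_names)) * (thi - tlo))

        best, n_eval = None, 0
        for s in starts[:restarts]:
            res = minimize(objective, s, method="Nelder-Mead",
                           options={"maxiter": maxiter, "fatol": fatol,
                                    "xatol": xatol, "adaptive": True})
            n_eval += res.nfev
            if best is None or res.fun < best.fun:
                best = res

        fitted_values = dict(base_values)
        fitted_values.update(self._unpack(best.x, free_names))
        free_mask = {n: (n in free_names) for n in FREE_PARAMETER_NAMES}
        params = ModelParams(
            population=base.population.replace(
                **{k: v for k, v in fitted_values.items()
                   if k not in ("width", "efficiency")}),
            decoder=replace(base.decoder, width=fitted_values["width"],
                            efficiency=fitted_values["efficiency"]),
            free_mask=free_mask, bounds=dict(self.bounds))
        dev = self.deviance(params)
        ll = self.log_likelihood(params)
        return PopulationCodeResults(
            model=self, params=params, free_names=tuple(free_names),
            free_estimates={n: fitted_values[n] for n in free_names},
            fixed_values={n: fitted_values[n] for n in fixed_params},
            deviance_detection=dev["detection"],
            deviance_discrimination=dev["discrimination"],
            deviance_total=dev["total"], log_likelihood=ll,
            aic=-2.0 * ll + 2.0 * len(free_names), n_free=len(free_names),
            restarts=restarts, converged=bool(best.success), seed=seed,
            n_function_evals=n_eval)


@dataclass
class PopulationCodeResults:
    """Fitted population-code model: estimates, deviances, AIC and diagnostics."""

    model: PopulationCodeModel
    params: ModelParams
    free_names: tuple
    free_estimates: dict
    fixed_values: dict
    deviance_detection: float
    deviance_discrimination: float
    deviance_total: float
    log_likelihood: float
    aic: float
    n_free: int
    restarts: int
    converged: bool
    seed: int
    n_function_evals: int = 0

    def predict(self) -> dict:
        return self.model.predict(self.params)

    def ideal_observer_analysis(self, widths: Sequence[float] = (0.0, 0.5, 1.5, 3.0, 4.2),
                                grid: Optional[FrequencyGrid] = None) -> pd.DataFrame:
        return ideal_observer_analysis(self.params, widths,
                                       grid=grid or self.model.grid,
                                       ref_contrast=self.model.ref_contrast)

    def summary(self) -> str:
        lines = [
            "Population-code model fit",
            "=" * 58,
            f"{'free parameters':<28}{self.n_free}",
            f"{'restarts':<28}{self.restarts}",
            f"{'converged':<28}{self.converged}",
            f"{'deviance (detection)':<28}{self.deviance_detection:.2f}",
            f"{'deviance (discrimination)':<28}{self.deviance_discrimination:.2f}",
            f"{'deviance (total)':<28}{self.deviance_total:.2f}",
            f"{'log likelihood':<28}{self.log_likelihood:.2f}",
            f"{'AIC':<28}{self.aic:.2f}",
            "-" * 58,
            f"{'parameter':<14}{'estimate':>12}  {'status':<8}",
        ]
        units = {"bw_exc": "oct", "bw_gain": "oct", "c50": "", "a_exc": "Hz",
                 "a_inh": "", "width": "oct", "efficiency": ""}
        for n in FREE_PARAMETER_NAMES:
            v = self.params.value(n)
            status = "free" if n in self.free_names else "fixed"
            lines.append(f"{n:<14}{v:>12.4g}  {status:<8}{units[n]}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "free_estimates": self.free_estimates,
            "fixed_values": self.fixed_values,
            "all_parameters": {n: self.params.value(n) for n in FREE_PARAMETER_NAMES},
            "deviance_detection": self.deviance_detection,
            "deviance_discrimination": self.deviance_discrimination,
            "deviance_total": self.deviance_total,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_free": self.n_free,
            "restarts": self.restarts,
            "converged": self.converged,
            "seed": self.seed,
            "ref_contrast": self.model.ref_contrast,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def plot_fit(self, ax=None):
        """Observed vs predicted proportions per cell (diagnostic scatter)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, df in self.predict().items():
            ax.plot(df["p_model"], df["p_observed"], "o", label=name, alpha=0.6)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("model probability")
        ax.set_ylabel("observed proportion")
        ax.legend()
        return ax


# ------------------------------------------------------------------ wrappers

def model_deviance(params: ModelParams, detection_data: Optional[TrialDataset],
                   discrimination_data: Optional[TrialDataset],
                   grid: Optional[FrequencyGrid] = None) -> dict:
    """Binomial deviance of a parameter set against the datasets."""
    model = PopulationCodeModel(detection=detection_data,
                                discrimination=discrimination_data, grid=grid,
                                n_neurons=params.population.n_neurons,
                                ref_contrast=params.decoder.ref_contrast)
    return model.deviance(params)


def joint_fit(detection_data, discrimination_data, start: Optional[ModelParams] = None,
              grid: Optional[FrequencyGrid] = None, **fit_kwargs) -> PopulationCodeResults:
    """Jointly fit the model to detection and discrimination data."""
    model = PopulationCodeModel(detection=detection_data,
                                discrimination=discrimination_data, grid=grid)
    return model.fit(start=start, **fit_kwargs)


def constrained_fit(detection_data, discrimination_data, constraints: dict,
                    start: Optional[ModelParams] = None,
                    grid: Optional[FrequencyGrid] = None,
                    **fit_kwargs) -> PopulationCodeResults:
    """Joint fit with listed parameters frozen (e.g. {'width': 1e-3})."""
    model = PopulationCodeModel(detection=detection_data,
                                discrimination=discrimination_data, grid=grid)
    return model.fit(start=start, fixed_params=constraints, **fit_kwargs)


def compare_models(fits: Sequence, reference=None) -> pd.DataFrame:
    """AIC comparison table for fits of the same data.

    ``reference`` may be a theory-free Weibull-per-condition fit from
    :func:`fit_weibull_reference`.  Monte-Carlo significance of a nested
    pair is computed by :func:`nested_monte_carlo_test`.
    """
    rows = []
    datasets = {(id(f.model.detection), id(f.model.discrimination)) for f in fits}
    if len(datasets) > 1:
        raise ParameterError("compare_models requires fits of identical data")
    for i, f in enumerate(fits):
        rows.append({"name": f"model_{i}", "n_free": f.n_free,
                     "deviance": f.deviance_total, "aic": f.aic})
    if reference is not None:
        rows.append({"name": "weibull_reference", "n_free": reference["n_free"],
                     "deviance": reference["deviance"], "aic": reference["aic"]})
    df = pd.DataFrame(rows)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df


def fit_weibull_reference(detection: Optional[TrialDataset],
                          discrimination: Optional[TrialDataset]) -> dict:
    """Theory-free reference: an independent Weibull per condition curve.

    Detection conditions are fitted over contrast (guess rate 0.5);
    discrimination pairings over log2 comparison frequency as choice
    proportions (guess rate 0).  Provides the upper-limit AIC used to judge
    the population-code model's goodness of fit.
    """
    ll = 0.0
    n_free = 0
    dev = 0.0
    if detection is not None:
        for _, g in detection.cells().groupby("noise"):
            f = fit_weibull(g["contrast"], g["n"], g["k"], gamma=0.5)
            p = np.clip(f.predict(g["contrast"].to_numpy(float)), 1e-12, 1 - 1e-12)
            ll += float(binom.logpmf(g["k"], g["n"], p).sum())
            dev += f.deviance
            n_free += 3
    if discrimination is not None:
        cells = discrimination.cells()
        for _, g in cells.groupby(["noise_standard", "noise_comparison"]):
            if g["f_comparison"].nunique() < 3:
                continue
            x = np.log2(g["f_comparison"].to_numpy(float))
            f = fit_weibull(x, g["n"], g["k"], gamma=0.0, x_scale="log2")
            p = np.clip(f.predict(x), 1e-12, 1 - 1e-12)
            ll += float(binom.logpmf(g["k"], g["n"], p).sum())
            dev += f.deviance
            n_free += 3
    return {"log_likelihood": ll, "deviance": dev, "n_free": n_free,
            "aic": -2.0 * ll + 2.0 * n_free}


def nested_monte_carlo_test(model: PopulationCodeModel,
                            null_results: PopulationCodeResults,
                            alt_results: PopulationCodeResults,
                            n_sims: int = 39, seed: int = 0,
                            refit_restarts: int = 1,
                            null_samples: Optional[np.ndarray] = None) -> dict:
    """Parametric Monte-Carlo test of a constrained (null) vs free model.

    Simulates datasets from the null fit, refits both models (warm-started),
    and compares the observed deviance difference against the null
    distribution; the p-value uses the +1 correction.  A precomputed
    ``null_samples`` array may be supplied to share one null calibration
    across replicate datasets of the same design.
    """
    from .synth import simulate_observer  # local import to keep module load light

    delta_obs = null_results.deviance_total - alt_results.deviance_total
    if null_samples is None:
        null_samples = simulate_null_deviance_gaps(
            model, null_results, alt_results, n_sims=n_sims, seed=seed,
            refit_restarts=refit_restarts)
    extreme = int(np.sum(null_samples >= delta_obs))
    p = (1.0 + extreme) / (1.0 + null_samples.size)
    return {"delta_deviance": float(delta_obs), "p_value": float(p),
            "null_samples": null_samples}


def simulate_null_deviance_gaps(model: PopulationCodeModel,
                                null_results: PopulationCodeResults,
                                alt_results: PopulationCodeResults,
                                n_sims: int, seed: int,
                                refit_restarts: int = 1,
                                fit_options: Optional[dict] = None) -> np.ndarray:
    """Null distribution of the constrained-minus-free deviance difference.

    Each resample is simulated from the constrained (null) fit and refitted
    under both models, warm-started (the free refit starts from the null
    refit with the frozen parameters released).  ``fit_options`` tunes the
    refit precision; the default trades optimizer tolerance for speed, which
    is adequate because the observed deviance gaps under the alternative are
    orders of magnitude larger than the null spread.
    """
    from .synth import simulate_observer

    opts = {"maxiter": 600, "fatol": 1e-3, "xatol": 1e-3}
    opts.update(fit_options or {})
    null_params = null_results.params
    fixed = dict(null_results.fixed_values)
    rng = np.random.default_rng(seed)
    gaps = []
    disc_design = _design_from_cells(model, "discrimination")
    det_design = _design_from_cells(model, "detection")
    for _ in range(n_sims):
        s1, s2, s3 = rng.integers(2 ** 31 - 1, size=3)
        disc = simulate_observer((null_params.population, null_params.decoder),
                                 disc_design, int(s1), grid=model.grid) \
            if disc_design is not None else None
        det = simulate_observer((null_params.population, null_params.decoder),
                                det_design, int(s2), grid=model.grid) \
            if det_design is not None else None
        m = PopulationCodeModel(detection=det, discrimination=disc, grid=model.grid,
                                ref_contrast=model.ref_contrast)
        r_null = m.fit(start=null_params, restarts=refit_restarts, seed=int(s3),
                       fixed_params=fixed, **opts)
        # Free refit starts from the null refit with the frozen parameters
        # released to mid-scale values so the simplex can move off the bound.
        released = {n: np.sqrt(np.prod(model.bounds[n])) for n in fixed}
        r_alt = m.fit(start=r_null.params.with_values(**released),
                      restarts=refit_restarts, seed=int(s3), **opts)
        gaps.append(r_null.deviance_total - r_alt.deviance_total)
    return np.asarray(gaps)


def _design_from_cells(model: PopulationCodeModel, task: str):
    """Reconstruct a simulation design matching the model's condition cells."""
    from .synth import Design

    if task == "discrimination":
        if model.disc_cells is None:
            return None
        dc = model.disc_cells
        pairs = dc[["noise_standard", "noise_comparison"]].drop_duplicates()
        pairings = tuple((f"{a}|{b}", a, b) for a, b in pairs.to_numpy())
        tpc = int(round(dc["n"].mean()))
        return Design(task="discrimination", standard_freq=model._f_standard,
                      comparison_freqs=tuple(sorted(dc["f_comparison"].unique())),
                      pairings=pairings, contrast=model.ref_contrast,
                      trials_per_cell=tpc)
    if model.det_cells is None:
        return None
    tc = model.det_cells
    levels = {k: tuple(sorted(g["contrast"])) for k, g in tc.groupby("noise")}
    tpc = int(round(tc["n"].mean()))
    return Design(task="detection", standard_freq=model._f_target,
                  noise_conditions=tuple(sorted(levels)), contrast_levels=levels,
                  trials_per_cell=tpc)


def ideal_observer_analysis(params: ModelParams, widths: Sequence[float],
                            grid: Optional[FrequencyGrid] = None,
                            ref_contrast: Optional[float] = None,
                            design=None) -> pd.DataFrame:
    """Read-out width sweep: predicted PSE biases and overall proportion correct.

    For each width, all other parameters stay at ``params``; the
    discrimination design (default: the main study preset) is re-predicted
    and the main-condition matching-frequency biases (octaves, relative to
    the standard) plus the design-weighted proportion correct are tabulated.
    """
    from .decoding import DiscriminationCondition, predict_choice_probability

    grid = grid or default_grid()
    cref = ref_contrast if ref_contrast is not None else params.decoder.ref_contrast
    design = design or make_design("discrimination_main", contrast=cref)
    specs = dict(STANDARD_NOISE)
    rows = []
    for width in widths:
        if width < 0:
            raise ParameterError("widths must be >= 0")
        dec = replace(params.decoder, width=float(width))
        pcs = []
        for label, ns, nc in design.pairings:
            for fc in design.comparison_freqs:
                p = predict_choice_probability(
                    params.population, dec,
                    DiscriminationCondition(design.standard_freq, float(fc),
                                            specs[ns], specs[nc], design.contrast),
                    grid)
                pcs.append(p if fc > design.standard_freq else 1.0 - p)
        row = {"width": float(width), "pct_correct": float(np.mean(pcs))}
        for label, ns, nc in design.pairings:
            if ns == nc:
                continue
            pse = predicted_pse(params.population, dec, design.standard_freq,
                                specs[ns], specs[nc], design.contrast, grid)
            row[f"bias_{label}"] = float(np.log2(pse / design.standard_freq))
        rows.append(row)
    return pd.DataFrame(rows)
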