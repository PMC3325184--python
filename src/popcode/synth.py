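"""Synthetic 2AFC observers: experimental designs and model-generated trial data.

The generator reproduces the study designs — a spatial-frequency
discrimination experiment (8 log-spaced comparison frequencies, 1.9-15.6
c/deg, around a 5.5 c/deg standard, six noise pairings, 4800 trials), a
contrast detection experiment (no-noise / broadband / notched noise with
16/16/9 contrast levels, 4100 trials) and a strong-bias control experiment
(one comparison frequency, 1500 trials) — and simulates an observer whose
choices are Bernoulli draws with probabilities given by the encoder+decoder
model.  A slower spike-level mode samples population responses per trial and
decides through the same linear read-out, cross-validating the analytic
choice probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .decoding import (
    DecoderSpec,
    DetectionCondition,
    DiscriminationCondition,
    _decision_moments,
    predict_choice_probability,
)
from .encoding import PopulationParams
from .spectra import FrequencyGrid, NoiseSpec, ParameterError, default_grid

__all__ = [
    "Design",
    "TrialDataset",
    "make_design",
    "simulate_observer",
    "parameter_recovery_experiment",
    "TRIAL_COLUMNS",
]

#: Documented trial-level CSV schema (also the reader contract for real data).
TRIAL_COLUMNS = [
    "trial", "task", "noise_i1", "noise_i2", "f_standard", "f_comparison",
    "contrast", "standard_interval", "correct_interval", "choice", "correct",
]

STANDARD_NOISE = {
    "none": NoiseSpec("none"),
    "broadband": NoiseSpec("broadband"),
    "lowpass": NoiseSpec("lowpass"),
    "highpass": NoiseSpec("highpass"),
    "notched": NoiseSpec("notched"),
}

#: Noise pairings of the discrimination experiments: (label, standard, comparison).
DISCRIMINATION_PAIRINGS = [
    ("main_lowpass", "lowpass", "broadband"),
    ("main_highpass", "highpass", "broadband"),
    ("control_lowpass", "broadband", "lowpass"),
    ("control_highpass", "broadband", "highpass"),
    ("baseline_broadband", "broadband", "broadband"),
    ("baseline_nonoise", "none", "none"),
]

#: Default grating contrast of the discrimination experiments (fraction);
#: roughly the model observer's own 84%-correct broadband detection threshold.
DISCRIMINATION_CONTRAST = 0.15

#: Detection contrast ladders per noise condition (fractions), log-spaced to
#: bracket the psychometric range of each condition.
DETECTION_LEVELS = {
    "none": np.geomspace(0.0015, 0.04, 16),
    "broadband": np.geomspace(0.015, 0.4, 16),
    "notched": np.geomspace(0.0025, 0.07, 9),
}


@dataclass(frozen=True)
class Design:
    """A 2AFC experimental design (one task)."""

    task: str
    standard_freq: float = 5.5
    comparison_freqs: tuple = ()
    pairings: tuple = ()
    contrast: float = DISCRIMINATION_CONTRAST
    noise_conditions: tuple = ()
    contrast_levels: dict = field(default_factory=dict)
    trials_per_cell: int = 100
    block_size: int = 50

    def __post_init__(self):
        if self.task not in ("discrimination", "detection"):
            raise ParameterError("task must be 'discrimination' or 'detection'")
        if self.trials_per_cell < 1:
            raise ParameterError("trials_per_cell must be >= 1")
        if self.task == "discrimination" and (not self.comparison_freqs or not self.pairings):
            raise ParameterError("discrimination design needs comparison_freqs and pairings")
        if self.task == "detection" and not self.noise_conditions:
            raise ParameterError("detection design needs noise_conditions")

    @property
    def n_cells(self) -> int:
        if self.task == "discrimination":
            return len(self.comparison_freqs) * len(self.pairings)
        return sum(len(self.contrast_levels[c]) for c in self.noise_conditions)

    @property
    def n_trials(self) -> int:
        return self.n_cells * self.trials_per_cell


def make_design(preset: Optional[str] = None, **fields) -> Design:
    """Build a design from a named preset or explicit fields.

    Presets: ``discrimination_main`` (8 comparisons x 6 pairings x 100 =
    4800 trials), ``detection`` (41 contrast cells x 100 = 4100 trials),
    ``control_strong_bias`` (1 comparison x 6 pairings x 250 = 1500 trials).
    """
    if preset is None:
        if not fields:
            raise ParameterError("either a preset name or explicit fields are required")
        return Design(**fields)
    if preset == "discrimination_main":
        base = dict(
            task="discrimination",
            comparison_freqs=tuple(np.geomspace(1.9, 15.6, 8)),
            pairings=tuple(DISCRIMINATION_PAIRINGS),
            trials_per_cell=100,
        )
    elif preset == "detection":
        base = dict(
            task="detection",
            noise_conditions=("none", "broadband", "notched"),
            contrast_levels={k: tuple(v) for k, v in DETECTION_LEVELS.items()},
            trials_per_cell=100,
        )
    elif preset == "control_strong_bias":
        base = dict(
            task="discrimination",
            comparison_freqs=(4.7,),
            pairings=tuple(DISCRIMINATION_PAIRINGS),
            trials_per_cell=250,
        )
    else:
        raise ParameterError(f"unknown design preset {preset!r}")
    base.update(fields)
    return Design(**base)


@dataclass
class TrialDataset:
    """Trial-level records of a 2AFC experiment plus provenance.

    ``generator_params`` identifies the generating model (or ``"human"``
    for real data); ``noise_specs`` maps noise-kind labels to full
    :class:`NoiseSpec` objects.
    """

    df: pd.DataFrame
    task: str
    seed: Optional[int] = None
    generator_params: str = "human"
    noise_specs: dict = field(default_factory=lambda: dict(STANDARD_NOISE))

    def __post_init__(self):
        missing = [c for c in TRIAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ParameterError(f"trial data missing column(s): {', '.join(missing)}")
        bad = self.df["correct"] != (self.df["choice"] == self.df["correct_interval"])
        if bool(bad.any()):
            raise ParameterError("correctness flag inconsistent with choice/correct_interval")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def proportion_correct(self) -> float:
        return float(self.df["correct"].mean())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, task: Optional[str] = None,
                 noise_specs: Optional[dict] = None) -> "TrialDataset":
        df = pd.read_csv(path)
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ParameterError(
                f"malformed trial CSV {path}: missing column(s) {', '.join(missing)}")
        tasks = df["task"].unique()
        if task is None:
            if tasks.size != 1:
                raise ParameterError("trial CSV mixes tasks; pass task= explicitly")
            task = str(tasks[0])
        else:
            df = df[df["task"] == task].reset_index(drop=True)
        kwargs = {} if noise_specs is None else {"noise_specs": noise_specs}
        return cls(df=df, task=task, **kwargs)

    def cells(self) -> pd.DataFrame:
        """Aggregate trials into condition cells.

        Discrimination: one row per (pairing noise pair, comparison
        frequency) with ``n`` trials and ``k`` choices of "comparison
        higher".  Detection: one row per (noise condition, contrast) with
        ``n`` trials and ``k`` correct choices.
        """
        df = self.df
        if self.task == "discrimination":
            std_int = df["standard_interval"].to_numpy()
            noise = df[["noise_i1", "noise_i2"]].to_numpy()
            rows = np.arange(len(df))
            noise_std = noise[rows, std_int - 1]
            noise_comp = noise[rows, 2 - std_int]
            comp_higher = (df["choice"].to_numpy() != std_int).astype(int)
            g = pd.DataFrame({
                "noise_standard": noise_std,
                "noise_comparison": noise_comp,
                "f_standard": df["f_standard"],
                "f_comparison": df["f_comparison"],
                "contrast": df["contrast"],
                "comp_higher": comp_higher,
            }).groupby(["noise_standard", "noise_comparison", "f_standard",
                        "f_comparison", "contrast"], as_index=False).agg(
                n=("comp_higher", "size"), k=("comp_higher", "sum"))
            return g
        g = self.df.groupby(["noise_i1", "contrast"], as_index=False).agg(
            n=("correct", "size"), k=("correct", "sum"))
        g = g.rename(columns={"noise_i1": "noise"})
        g["f_target"] = self.df["f_standard"].iloc[0]
        return g


def _params_pair(params) -> tuple[PopulationParams, DecoderSpec]:
    if isinstance(params, tuple):
        return params
    return params.population, params.decoder


def _cell_table(params, design: Design, noise_specs: dict,
                grid: FrequencyGrid) -> list[dict]:
    """Per-cell condition descriptors with analytic choice probabilities."""
    pop, dec = _params_pair(params)
    cells = []
    if design.task == "discrimination":
        for label, ns_kind, nc_kind in design.pairings:
            for fc in design.comparison_freqs:
                cond = DiscriminationCondition(
                    design.standard_freq, float(fc),
                    noise_specs[ns_kind], noise_specs[nc_kind], design.contrast)
                p = predict_choice_probability(pop, dec, cond, grid)
                cells.append(dict(pairing=label, noise_standard=ns_kind,
                                  noise_comparison=nc_kind, f_comparison=float(fc),
                                  contrast=design.contrast, p_comp_higher=p,
                                  condition=cond))
    else:
        for kind in design.noise_conditions:
            for c in design.contrast_levels[kind]:
                cond = DetectionCondition(design.standard_freq, float(c),
                                          noise_specs[kind])
                p = predict_choice_probability(pop, dec, cond, grid)
                cells.append(dict(noise=kind, contrast=float(c),
                                  p_correct=p, condition=cond))
    return cells


def simulate_observer(params, design: Design, seed: int,
                      noise_specs: Optional[dict] = None,
                      grid: Optional[FrequencyGrid] = None,
                      mode: str = "bernoulli") -> TrialDataset:
    """Simulate a model observer running the full design.

    ``mode="bernoulli"`` (default) draws each choice from the analytic
    choice probability — exactly the generative structure assumed by the
    fitting likelihood.  ``mode="spikes"`` samples population spike counts
    per trial and decides through the linear read-out, which cross-validates
    the analytic layer.  Interval order is randomized per trial and
    recorded; the dataset is reproducible under a fixed seed.
    """
    if mode not in ("bernoulli", "spikes"):
        raise ParameterError("mode must be 'bernoulli' or 'spikes'")
    grid = grid or default_grid()
    noise_specs = noise_specs or dict(STANDARD_NOISE)
    pop, dec = _params_pair(params)
    rng = np.random.default_rng(seed)
    cells = _cell_table(params, design, noise_specs, grid)
    records = []
    for cell in cells:
        m = design.trials_per_cell
        if design.task == "discrimination":
            fs, fc = design.standard_freq, cell["f_comparison"]
            if mode == "bernoulli":
                comp_higher = rng.random(m) < cell["p_comp_higher"]
            else:
                comp_higher = _simulate_spike_choices(pop, dec, cell["condition"],
                                                      grid, m, rng)
            std_interval = rng.integers(1, 3, m)
            comp_interval = 3 - std_interval
            choice = np.where(comp_higher, comp_interval, std_interval)
            correct_interval = np.where(fc > fs, comp_interval, std_interval)
            noise_i1 = np.where(std_interval == 1, cell["noise_standard"],
                                cell["noise_comparison"])
            noise_i2 = np.where(std_interval == 2, cell["noise_standard"],
                                cell["noise_comparison"])
            records.append(pd.DataFrame({
                "task": design.task, "noise_i1": noise_i1, "noise_i2": noise_i2,
                "f_standard": fs, "f_comparison": fc, "contrast": cell["contrast"],
                "standard_interval": std_interval,
                "correct_interval": correct_interval, "choice": choice,
                "correct": choice == correct_interval, "pairing": cell["pairing"],
            }))
        else:
            if mode == "bernoulli":
                success = rng.random(m) < cell["p_correct"]
            else:
                success = _simulate_spike_choices(pop, dec, cell["condition"],
                                                  grid, m, rng)
            target_interval = rng.integers(1, 3, m)
            choice = np.where(success, target_interval, 3 - target_interval)
            records.append(pd.DataFrame({
                "task": design.task, "noise_i1": cell["noise"],
                "noise_i2": cell["noise"], "f_standard": design.standard_freq,
                "f_comparison": np.nan, "contrast": cell["contrast"],
                "standard_interval": target_interval,
                "correct_interval": target_interval, "choice": choice,
                "correct": choice == target_interval,
            }))
    df = pd.concat(records, ignore_index=True)
    df = df.sample(frac=1.0, random_state=np.random.RandomState(seed)).reset_index(drop=True)
    df.insert(0, "trial", np.arange(len(df)))
    return TrialDataset(df=df, task=design.task, seed=seed,
                        generator_params=f"model(width={dec.width},eff={dec.efficiency})",
                        noise_specs=noise_specs)


def _simulate_spike_choices(pop: PopulationParams, dec: DecoderSpec, condition,
                            grid: FrequencyGrid, n_trials: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Spike-level simulation of the designated-choice outcomes for one cell."""
    mu, var, dw, resp_a, resp_b = _decision_moments(pop, dec, condition, grid)
    if var <= 0:
        return rng.random(n_trials) < 0.5
    ca = rng.normal(resp_a.mean_count, np.sqrt(resp_a.variance), (n_trials, dw.size))
    cb = rng.normal(resp_b.mean_count, np.sqrt(resp_b.variance), (n_trials, dw.size))
    d = (ca - cb) @ dw
    if dec.efficiency < 1.0:
        d = d + rng.normal(0.0, np.sqrt(var * (1.0 / dec.efficiency ** 2 - 1.0)), n_trials)
    ties = d == 0
    if ties.any():
        d[ties] = rng.standard_normal(int(ties.sum()))
    return d > 0


def parameter_recovery_experiment(true_params, n_replicates: int, seed: int,
                                  discrimination_preset: str = "discrimination_main",
                                  detection_preset: str = "detection",
                                  grid: Optional[FrequencyGrid] = None,
                                  **fit_kwargs) -> dict:
    """Simulate paper-scale datasets from known parameters and refit them.

    Returns per-replicate parameter estimates plus bias and RMSE summaries —
    the end-to-end check that the generating model is identifiable from data
    of the study's size.
    """
    from .fitting import PopulationCodeModel  # deferred: fitting imports synth

    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    grid = grid or default_grid()
    pop, dec = _params_pair(true_params)
    disc_design = make_design(discrimination_preset, contrast=dec.ref_contrast)
    det_design = make_design(detection_preset)
    rng = np.random.default_rng(seed)
    rows = []
    results = []
    for r in range(n_replicates):
        s_disc, s_det, s_fit = rng.integers(2 ** 31 - 1, size=3)
        disc = simulate_observer((pop, dec), disc_design, int(s_disc), grid=grid)
        det = simulate_observer((pop, dec), det_design, int(s_det), grid=grid)
        model = PopulationCodeModel(detection=det, discrimination=disc, grid=grid)
        res = model.fit(seed=int(s_fit), **fit_kwargs)
        est = res.free_estimates
        est["replicate"] = r
        est["deviance_total"] = res.deviance_total
        est["converged"] = res.converged
        rows.append(est)
        results.append(res)
    table = pd.DataFrame(rows)
    truth = {"bw_exc": pop.bw_exc, "bw_gain": pop.bw_gain, "c50": pop.c50,
             "a_exc": pop.a_exc, "a_inh": pop.a_inh, "width": dec.width,
             "efficiency": dec.efficiency}
    summary = {}
    for name, tv in truth.items():
        if name in table:
            err = table[name].to_numpy() - tv
            summary[name] = {"true": tv, "mean": float(table[name].mean()),
                             "bias": float(err.mean()),
                             "rmse": float(np.sqrt(np.mean(err ** 2)))}
    return {"estimates": table, "summary": summary, "results": results}
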