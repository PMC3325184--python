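"""YAML run configuration with strict validation and provenance records."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import yaml

from .spectra import FrequencyGrid, NoiseSpec, ParameterError, make_frequency_grid

__all__ = ["RunConfig", "load_config", "provenance_record", "write_provenance"]

_SECTIONS = {
    "seed": {None},
    "grid": {"f_min", "f_max", "points_per_octave"},
    "population": {"n_neurons", "placement", "bw_exc", "bw_gain", "c50",
                   "a_exc", "a_inh", "r_max", "r_sp", "k_fano", "t_dur", "p_exp"},
    "decoder": {"width", "efficiency", "mode", "n_sims", "ref_contrast"},
    "designs": {"discrimination", "detection", "contrast", "trials_per_cell"},
    "noise": {"kind", "cutoff", "notch_center", "notch_width", "upper_bound",
              "lower_bound", "power_density"},
    "fit": {"restarts", "maxiter", "fatol", "xatol", "fixed"},
    "bootstrap": {"n_resamples"},
    "output": {"directory"},
}


@dataclass
class RunConfig:
    """Validated run configuration.

    Unknown keys at any level are rejected rather than ignored, so typos in
    a config file fail loudly.
    """

    seed: int = 0
    grid: dict = field(default_factory=lambda: {"f_min": 0.125, "f_max": 64.0,
                                                "points_per_octave": 64})
    population: dict = field(default_factory=dict)
    decoder: dict = field(default_factory=dict)
    designs: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=lambda: {"n_resamples": 999})
    output: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def make_grid(self) -> FrequencyGrid:
        return make_frequency_grid(**self.grid)

    def noise_specs(self) -> dict:
        """Named NoiseSpec overrides from the config's ``noise`` section."""
        return {label: NoiseSpec(**block) for label, block in self.noise.items()}


def _check_keys(section: str, mapping: dict) -> None:
    allowed = _SECTIONS[section]
    unknown = set(mapping) - allowed
    if unknown:
        raise ParameterError(
            f"unknown config key(s) in '{section}': {', '.join(sorted(unknown))}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ParameterError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    cfg = RunConfig(raw=raw)
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    for section in ("grid", "population", "decoder", "designs", "fit",
                    "bootstrap", "output"):
        if section in raw:
            if not isinstance(raw[section], dict):
                raise ParameterError(f"config section '{section}' must be a mapping")
            _check_keys(section, raw[section])
            merged = dict(getattr(cfg, section))
            merged.update(raw[section])
            setattr(cfg, section, merged)
    if "noise" in raw:
        blocks = raw["noise"]
        if not isinstance(blocks, dict):
            raise ParameterError("config section 'noise' must map labels to specs")
        for label, block in blocks.items():
            if not isinstance(block, dict):
                raise ParameterError(f"noise block {label!r} must be a mapping")
            _check_keys("noise", block)
        cfg.noise = blocks
    return cfg


def _package_version() -> str:
    try:
        return version("popcode")
    except PackageNotFoundError:
        return "unknown"


def provenance_record(config: RunConfig, seed: int) -> dict:
    """Provenance: config hash, seed and package version."""
    blob = json.dumps(config.raw, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "package_version": _package_version(),
    }


def write_provenance(out_path, config: RunConfig, seed: int) -> Path:
    """Write ``<out>.provenance.json`` next to a result file."""
    out_path = Path(out_path)
    prov_path = out_path.with_suffix(out_path.suffix + ".provenance.json")
    with open(prov_path, "w") as fh:
        json.dump(provenance_record(config, seed), fh, indent=2)
    return prov_path
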