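"""Flat key-value run configuration with a validated schema.

The on-disk format is one ``key = value`` per line, ``#`` comments allowed.
Every key is validated against the schema below (type, constraint, units);
unknown keys are rejected by name, and constraint violations report both the
key and the violated relation.  Model parameters left unset (blank default)
are derived at run time by the steady-state initializer.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field
from typing import Any, Callable

import numpy as np

from .gabor import GaborConfig
from .kernel import KernelParams
from .dynamics import ModelParams
from .scenes import AmoebaSpec, SceneConfig
from .optimize import OptimizerConfig

__all__ = ["ConfigError", "RunConfig", "parse_config", "serialize_config", "SCHEMA"]


class ConfigError(ValueError):
    """Invalid configuration: unknown key, bad type, or violated constraint."""


@dataclass(frozen=True)
class _Key:
    name: str
    typ: str  # int | float | str | optfloat
    default: Any
    constraint: Callable[[Any], bool] | None = None
    describe: str = ""
    units: str = ""


def _pos(x):
    return x > 0


def _nonneg(x):
    return x >= 0


SCHEMA: list[_Key] = [
    _Key("seed", "int", 0, _nonneg, "seed >= 0 (root of all random substreams)"),
    _Key("output_dir", "str", "out", None, "artifact directory"),
    # lattice & scene
    _Key("L", "int", 128, _pos, "L > 0", "sites"),
    _Key("n_targets", "int", 1, _pos, "n_targets >= 1"),
    _Key("n_clutter_sources", "int", 1, _nonneg, "n_clutter_sources >= 0"),
    _Key("k_max", "int", 5, _nonneg, "k_max >= 0"),
    _Key("coeff_sd", "float", 3.0, _pos, "coeff_sd > 0", "sites"),
    _Key("r_min_frac", "float", 0.10, lambda x: 0 < x < 0.5, "0 < r_min_frac < 0.5", "fraction of L"),
    _Key("r_max_frac", "float", 0.25, lambda x: 0 < x < 0.5, "0 < r_max_frac < 0.5", "fraction of L"),
    _Key("ratio_min", "float", 0.5, lambda x: 0 < x <= 1, "0 < ratio_min <= 1"),
    _Key("occlusion_fraction", "float", 0.25, lambda x: 0 <= x < 1, "0 <= occlusion_fraction < 1"),
    _Key("occlusion_segments_min", "int", 2, _pos, "occlusion_segments_min >= 1"),
    _Key("occlusion_segments_max", "int", 4, _pos, "occlusion_segments_max >= 1"),
    _Key("region_size", "int", 16, _pos, "region_size > 0 and divides L", "sites"),
    _Key("neighbor_margin_deg", "float", 20.0, _nonneg, "neighbor_margin_deg >= 0", "degrees"),
    _Key("exclusion_radius", "float", 8.0, _nonneg, "exclusion_radius >= 0", "sites"),
    _Key("parallel_margin_deg", "float", 15.0, _nonneg, "parallel_margin_deg >= 0", "degrees"),
    _Key("s0", "float", 1.0, _pos, "s0 > 0", "rate units"),
    # model (blank -> derived by init_params)
    _Key("sigma", "optfloat", None, _pos, "sigma > 0", "sites"),
    _Key("R_min", "optfloat", None, _nonneg, "R_min >= 0", "sites"),
    _Key("zeta", "optfloat", None, _pos, "zeta > 0", "rate/time"),
    _Key("E_th", "optfloat", None, _pos, "E_th > 0", "input units"),
    _Key("g1", "optfloat", None, _nonneg, "g1 >= 0", "1/time"),
    _Key("g2", "optfloat", None, _nonneg, "g2 >= 0", "1/(time*rate)"),
    _Key("dt", "float", 1.0, _pos, "dt > 0", "time"),
    _Key("n_angle_bins", "int", 64, lambda x: x >= 4, "n_angle_bins >= 4"),
    _Key("inhibition_radius", "optfloat", None, _pos, "inhibition_radius > 0 (blank = whole lattice)", "sites"),
    # simulation & evaluation
    _Key("n_steps", "int", 100, _nonneg, "n_steps >= 0", "iterations"),
    _Key("record_every", "int", 10, _pos, "record_every >= 1", "iterations"),
    _Key("n_scenes", "int", 5, _nonneg, "n_scenes >= 0"),
    _Key("cutoff_mode", "str", "absolute", lambda x: x in ("absolute", "relative"), "cutoff_mode in {absolute, relative}"),
    _Key("cutoff_min", "float", 0.05, _pos, "cutoff_min > 0"),
    _Key("cutoff_max", "float", 0.95, _pos, "cutoff_max > 0"),
    _Key("cutoff_step", "float", 0.05, _pos, "cutoff_step > 0"),
    _Key("tol", "int", 1, _nonneg, "tol >= 0", "sites"),
    # optimizer
    _Key("temperature", "float", 0.005, _pos, "temperature > 0"),
    _Key("perturb_frac", "float", 0.01, lambda x: 0 < x < 1, "0 < perturb_frac < 1"),
    _Key("n_iterations", "int", 100, _nonneg, "n_iterations >= 0"),
    _Key("n_scenes_per_eval", "int", 3, _pos, "n_scenes_per_eval >= 1"),
    # gabor front-end
    _Key("gabor_n_angles", "int", 12, lambda x: x >= 2, "gabor_n_angles >= 2"),
    _Key("gabor_wavelength", "float", 6.0, _pos, "gabor_wavelength > 0", "pixels"),
    _Key("gabor_envelope_sd", "float", 3.0, _pos, "gabor_envelope_sd > 0", "pixels"),
    _Key("binarize_threshold", "float", 0.5, lambda x: 0 <= x <= 1, "0 <= binarize_threshold <= 1"),
]

_BY_NAME = {k.name: k for k in SCHEMA}


@dataclass
class RunConfig:
    """Validated flat parameter set covering the whole pipeline."""

    values: dict = _dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {k.name: k.default for k in SCHEMA}
        for name, v in self.values.items():
            if name not in _BY_NAME:
                raise ConfigError(f"unknown key: {name!r}")
            full[name] = v
        for name, v in full.items():
            key = _BY_NAME[name]
            if v is None:
                continue
            if key.constraint is not None and not key.constraint(v):
                raise ConfigError(f"constraint violated for {name!r}: {key.describe}")
        if full["L"] % full["region_size"] != 0:
            raise ConfigError("constraint violated for 'region_size': region_size > 0 and divides L")
        if not full["r_min_frac"] < full["r_max_frac"]:
            raise ConfigError("constraint violated for 'r_min_frac': r_min_frac < r_max_frac")
        if full["occlusion_segments_min"] > full["occlusion_segments_max"]:
            raise ConfigError(
                "constraint violated for 'occlusion_segments_min': occlusion_segments_min <= occlusion_segments_max"
            )
        self.values = full

    def __getattr__(self, name):
        values = object.__getattribute__(self, "__dict__").get("values", {})
        if name in values:
            return values[name]
        raise AttributeError(name)

    # ------------------------------------------------------------------ #
    # converters to the typed configs used by each module
    # ------------------------------------------------------------------ #
    def scene_config(self) -> SceneConfig:
        v = self.values
        return SceneConfig(
            L=v["L"],
            n_targets=v["n_targets"],
            n_clutter_sources=v["n_clutter_sources"],
            amoeba=AmoebaSpec(
                k_max=v["k_max"],
                coeff_sd=v["coeff_sd"],
                r_min_frac=v["r_min_frac"],
                r_max_frac=v["r_max_frac"],
                ratio_min=v["ratio_min"],
            ),
            occlusion_fraction=v["occlusion_fraction"],
            occlusion_segments=(v["occlusion_segments_min"], v["occlusion_segments_max"]),
            region_size=v["region_size"],
            neighbor_margin_deg=v["neighbor_margin_deg"],
            exclusion_radius=v["exclusion_radius"],
            parallel_margin_deg=v["parallel_margin_deg"],
            s0=v["s0"],
        )

    def model_params_explicit(self) -> ModelParams | None:
        """ModelParams when all six core constants are set; else None."""
        v = self.values
        names = ("sigma", "R_min", "zeta", "E_th", "g1", "g2")
        if any(v[n] is None for n in names):
            return None
        kernel = KernelParams(sigma=v["sigma"], R_min=v["R_min"], n_angle_bins=v["n_angle_bins"])
        return ModelParams(
            kernel=kernel,
            zeta=v["zeta"],
            E_th=v["E_th"],
            g1=v["g1"],
            g2=v["g2"],
            dt=v["dt"],
            inhibition_radius=v["inhibition_radius"],
        )

    def optimizer_config(self) -> OptimizerConfig:
        v = self.values
        return OptimizerConfig(
            temperature=v["temperature"],
            perturb_frac=v["perturb_frac"],
            n_iterations=v["n_iterations"],
            n_scenes_per_eval=v["n_scenes_per_eval"],
            base_seed=v["seed"],
            scene_config=self.scene_config(),
            n_steps=v["n_steps"],
            record_every=v["record_every"],
            cutoffs=tuple(self.cutoffs()),
            tol=v["tol"],
        )

    def gabor_config(self) -> GaborConfig:
        v = self.values
        return GaborConfig(
            n_angles=v["gabor_n_angles"],
            wavelength=v["gabor_wavelength"],
            envelope_sd=v["gabor_envelope_sd"],
        )

    def cutoffs(self) -> np.ndarray:
        v = self.values
        n = int(round((v["cutoff_max"] - v["cutoff_min"]) / v["cutoff_step"])) + 1
        return np.round(v["cutoff_min"] + v["cutoff_step"] * np.arange(n), 10)


def _parse_value(key: _Key, raw: str):
    raw = raw.strip()
    if raw == "" or raw.lower() == "none":
        if key.typ.startswith("opt"):
            return None
        raise ConfigError(f"key {key.name!r} needs a value of type {key.typ}")
    try:
        if key.typ == "int":
            return int(raw)
        if key.typ in ("float", "optfloat"):
            return float(raw)
        return raw
    except ValueError as exc:
        raise ConfigError(f"type mismatch for {key.name!r}: expected {key.typ}, got {raw!r}") from exc


def parse_config(text: str) -> RunConfig:
    """Parse flat ``key = value`` text; empty text yields all defaults."""
    values: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        name, raw = (part.strip() for part in line.split("=", 1))
        if name not in _BY_NAME:
            raise ConfigError(f"unknown key: {name!r}")
        values[name] = _parse_value(_BY_NAME[name], raw)
    return RunConfig(values)


def serialize_config(cfg: RunConfig) -> str:
    """Lossless textual form (round-trips through :func:`parse_config`)."""
    lines = []
    for key in SCHEMA:
        v = cfg.values[key.name]
        rendered = "" if v is None else (f"{v!r}" if isinstance(v, float) else str(v))
        comment = f"  # {key.describe}" + (f" [{key.units}]" if key.units else "")
        lines.append(f"{key.name} = {rendered}{comment}")
    return "\n".join(lines) + "\n"
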