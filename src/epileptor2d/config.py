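"""Configuration schema, validation, presets and run metadata.

A run is described by a YAML (or JSON) mapping with sections ``model``,
``domain``, ``parameters``, ``noise``, ``lesion``, ``recording`` and
``run``.  Unknown sections or keys are rejected with the offending name.
Parameter keys accept the conventional symbols of the model's parameter
table verbatim (``tau_K``, ``D_K``, ``G_syn/g_L``, ``lambda``, ...) in the
table's units: diffusion in cm^2/s and the membrane time constant in ms;
everything else already matches the internal second/millimetre system.

An empty file resolves to the baseline: the synaptic variant (model 2) on
the 6 x 6 mm, 80 x 80 sheet with the 0.3 mm excitation disk.  Presets are
shipped as data files so scenario setups stay auditable::

    standard         the baseline domain
    narrow_strip     6 x 0.6 mm strip for front-speed scans
    partial_lesion   a 3 mm connectivity cut the wave must travel around
    complete_lesion  a full-width cut with zoned bath potassium,
                     inhomogeneous noise and fast, strong potassium
                     sensitivity (tau_K = 10 s, gK_leak/gL = 3,
                     D_K = 2e-5 cm^2/s)
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .engine import Domain, STABILITY_LIMIT, build_domain
from .params import ModelParameters

__all__ = ["RunConfig", "load_and_validate", "load_preset", "describe",
           "PRESET_NAMES"]

PRESET_NAMES = ("standard", "narrow_strip", "partial_lesion",
                "complete_lesion")

#: Accepted parameter-table spellings -> canonical names.
PARAMETER_ALIASES = {
    "tau_K": "tau_K", "tau_Na": "tau_Na",
    "tau_m": "tau_m", "C/g_L": "tau_m",
    "tau_D": "tau_D", "D_K": "D_K",
    "delta_K": "delta_K", "delta_Na": "delta_Na", "delta_x": "delta_x",
    "sigma/g_L": "sigma_over_gL", "sigma_over_gL": "sigma_over_gL",
    "rho": "rho", "gamma": "gamma",
    "G_syn/g_L": "Gsyn_over_gL", "Gsyn_over_gL": "Gsyn_over_gL",
    "c_IE": "c_IE",
    "g_K,leak/g_L": "gK_leak_over_gL", "gK_leak_over_gL": "gK_leak_over_gL",
    "K_o0": "K_o0", "K_bath": "K_bath", "Na_i0": "Na_i0",
    "nu_max": "nu_max",
    "lambda": "lambda_conn", "lambda_conn": "lambda_conn",
    "V_th": "V_th", "k_v": "k_v",
}

#: Table units for the two parameters whose config units differ from the
#: internal system: value_internal = value_config * factor.
_UNIT_FACTORS = {"tau_m": 1e-3,   # ms -> s
                 "D_K": 100.0}    # cm^2/s -> mm^2/s

_DOMAIN_KEYS = {"width", "height", "nx", "ny", "excitation_center",
                "excitation_radius", "Gsyn_center", "Gsyn_periphery",
                "Kbath_center", "Kbath_periphery", "probes"}
_NOISE_KEYS = {"mode", "convention"}
_LESION_KEYS = {"kind", "start", "end", "axis", "position",
                "blocks_diffusion"}
_RECORDING_KEYS = {"probe_stride", "ray_dt", "snapshot_dt", "roi_window"}
_RUN_KEYS = {"dt", "total_time", "seed"}
_MODEL_KEYS = {"variant"}
_SECTIONS = {"model", "domain", "parameters", "noise", "lesion",
             "recording", "run", "preset"}


@dataclass
class RunConfig:
    """Fully resolved run description (config-level units)."""

    model_variant: int = 2
    # domain
    width: float = 6.0
    height: float = 6.0
    nx: int = 80
    ny: int = 80
    excitation_center: Optional[Tuple[float, float]] = None
    excitation_radius: float = 0.3
    Gsyn_center: float = 5.0
    Gsyn_periphery: float = 1.0
    Kbath_center: Optional[float] = None
    Kbath_periphery: Optional[float] = None   # None -> uniform K_bath
    probes: Optional[List[Tuple[str, float, float]]] = None
    # Table-unit parameter overrides, canonical names
    parameters: Dict[str, float] = dc_field(default_factory=dict)
    # noise
    noise_mode: str = "homogeneous"
    noise_convention: str = "per_step"
    # lesion
    lesion: Optional[dict] = None
    # recording
    probe_stride: int = 1
    ray_dt: float = 0.25
    snapshot_dt: float = 1.0
    roi_window: Optional[Tuple[float, float]] = None
    # run
    dt: float = 1e-3
    total_time: float = 300.0
    seed: int = 0
    preset: Optional[str] = None

    # ------------------------------------------------------------------
    def make_params(self) -> ModelParameters:
        """Internal-unit parameter set with overrides applied."""
        overrides = {}
        for name, value in self.parameters.items():
            overrides[name] = value * _UNIT_FACTORS.get(name, 1.0)
        return ModelParameters(model_variant=self.model_variant, **overrides)

    def make_domain(self) -> Domain:
        p = self.make_params()
        periphery = (self.Kbath_periphery if self.Kbath_periphery is not None
                     else p.K_bath)
        return build_domain(
            width=self.width, height=self.height, nx=self.nx, ny=self.ny,
            excitation_center=self.excitation_center,
            excitation_radius=self.excitation_radius,
            Gsyn_center=self.Gsyn_center, Gsyn_periphery=self.Gsyn_periphery,
            Kbath_center=self.Kbath_center, Kbath_periphery=periphery,
            lesion_geometry=self.lesion, probes=self.probes)

    def validate(self) -> None:
        if self.model_variant not in (1, 2, 3):
            raise ValueError(f"model variant must be 1, 2 or 3, "
                             f"got {self.model_variant}")
        if self.dt <= 0:
            raise ValueError("run.dt must be positive")
        if self.total_time < 0:
            raise ValueError("run.total_time must be non-negative")
        p = self.make_params()        # validates parameter ranges
        dom = self.make_domain()      # validates geometry
        if self.model_variant in (1, 3):
            stability = p.D_K * self.dt / dom.dx ** 2
            if stability >= STABILITY_LIMIT:
                raise ValueError(
                    f"key 'D_K': explicit diffusion unstable, "
                    f"D_K*dt/dx^2 = {stability:.3g} >= {STABILITY_LIMIT}")
        if self.noise_mode not in ("homogeneous", "inhomogeneous"):
            raise ValueError(f"key 'noise.mode': unknown mode "
                             f"{self.noise_mode!r}")
        if self.noise_convention not in ("per_step", "step_invariant"):
            raise ValueError(f"key 'noise.convention': unknown convention "
                             f"{self.noise_convention!r}")

    # ------------------------------------------------------------------
    def echo(self) -> dict:
        """Serializable resolved configuration; round-trips losslessly."""
        out = {
            "model": {"variant": self.model_variant},
            "domain": {
                "width": self.width, "height": self.height,
                "nx": self.nx, "ny": self.ny,
                "excitation_center": (list(self.excitation_center)
                                      if self.excitation_center else None),
                "excitation_radius": self.excitation_radius,
                "Gsyn_center": self.Gsyn_center,
                "Gsyn_periphery": self.Gsyn_periphery,
                "Kbath_center": self.Kbath_center,
                "Kbath_periphery": self.Kbath_periphery,
                "probes": ([list(p) for p in self.probes]
                           if self.probes else None),
            },
            "parameters": dict(self.parameters),
            "noise": {"mode": self.noise_mode,
                      "convention": self.noise_convention},
            "lesion": copy.deepcopy(self.lesion),
            "recording": {"probe_stride": self.probe_stride,
                          "ray_dt": self.ray_dt,
                          "snapshot_dt": self.snapshot_dt,
                          "roi_window": (list(self.roi_window)
                                         if self.roi_window else None)},
            "run": {"dt": self.dt, "total_time": self.total_time,
                    "seed": self.seed},
        }
        return out

    def with_overrides(self, **table_params: float) -> "RunConfig":
        """Copy with parameter-table overrides (config units)."""
        cfg = copy.deepcopy(self)
        for key, value in table_params.items():
            canonical = PARAMETER_ALIASES.get(key)
            if canonical is None:
                raise ValueError(f"unknown parameter key {key!r}")
            cfg.parameters[canonical] = float(value)
        cfg.validate()
        return cfg


def _reject_unknown(mapping: dict, allowed: set, section: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ValueError(f"unknown key {key!r} in section '{section}' "
                             f"(allowed: {sorted(allowed)})")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _preset_dict(name: str) -> dict:
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; "
                         f"available: {PRESET_NAMES}")
    ref = importlib.resources.files("epileptor2d.presets") / f"{name}.yaml"
    data = yaml.safe_load(ref.read_text()) or {}
    return data


def load_and_validate(source) -> RunConfig:
    """Resolve a config file, path, mapping or None into a RunConfig.

    Defaults are the parameter table and the standard domain; a ``preset``
    key merges the named preset underneath the user's own keys.  Unknown
    keys, unit violations and diffusion-stability violations raise with the
    offending key named.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = copy.deepcopy(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _reject_unknown(raw, _SECTIONS, "<root>")

    preset = raw.pop("preset", None)
    if preset is not None:
        raw = _merge(_preset_dict(preset), raw)
        raw.pop("preset", None)

    cfg = RunConfig(preset=preset)

    model = raw.get("model") or {}
    _reject_unknown(model, _MODEL_KEYS, "model")
    cfg.model_variant = int(model.get("variant", cfg.model_variant))

    dom = raw.get("domain") or {}
    _reject_unknown(dom, _DOMAIN_KEYS, "domain")
    for key in ("width", "height", "excitation_radius", "Gsyn_center",
                "Gsyn_periphery"):
        if key in dom:
            setattr(cfg, key, float(dom[key]))
    for key in ("nx", "ny"):
        if key in dom:
            setattr(cfg, key, int(dom[key]))
    if dom.get("excitation_center") is not None:
        cfg.excitation_center = tuple(map(float, dom["excitation_center"]))
    if dom.get("Kbath_center") is not None:
        cfg.Kbath_center = float(dom["Kbath_center"])
    if dom.get("Kbath_periphery") is not None:
        cfg.Kbath_periphery = float(dom["Kbath_periphery"])
    if dom.get("probes") is not None:
        cfg.probes = [(str(p[0]), float(p[1]), float(p[2]))
                      for p in dom["probes"]]

    pars = raw.get("parameters") or {}
    for key, value in pars.items():
        canonical = PARAMETER_ALIASES.get(key)
        if canonical is None:
            raise ValueError(f"unknown key {key!r} in section 'parameters' "
                             f"(accepted: {sorted(PARAMETER_ALIASES)})")
        cfg.parameters[canonical] = float(value)

    noise = raw.get("noise") or {}
    _reject_unknown(noise, _NOISE_KEYS, "noise")
    cfg.noise_mode = noise.get("mode", cfg.noise_mode)
    cfg.noise_convention = noise.get("convention", cfg.noise_convention)

    lesion = raw.get("lesion")
    if lesion:
        _reject_unknown(lesion, _LESION_KEYS, "lesion")
        cfg.lesion = copy.deepcopy(lesion)

    rec = raw.get("recording") or {}
    _reject_unknown(rec, _RECORDING_KEYS, "recording")
    if "probe_stride" in rec:
        cfg.probe_stride = int(rec["probe_stride"])
    for key in ("ray_dt", "snapshot_dt"):
        if key in rec:
            setattr(cfg, key, float(rec[key]))
    if rec.get("roi_window") is not None:
        cfg.roi_window = tuple(map(float, rec["roi_window"]))

    run_sec = raw.get("run") or {}
    _reject_unknown(run_sec, _RUN_KEYS, "run")
    if "dt" in run_sec:
        cfg.dt = float(run_sec["dt"])
    if "total_time" in run_sec:
        cfg.total_time = float(run_sec["total_time"])
    if "seed" in run_sec and run_sec["seed"] is not None:
        cfg.seed = int(run_sec["seed"])
    else:
        # records must always be replayable: missing seeds are generated
        # here and echoed into every output
        cfg.seed = int(np.random.SeedSequence().entropy % (2 ** 31))

    cfg.validate()
    return cfg


def load_preset(name: str, seed: Optional[int] = None) -> RunConfig:
    """Load a named preset; optionally force the seed."""
    raw = _preset_dict(name)
    if seed is not None:
        raw.setdefault("run", {})["seed"] = int(seed)
    cfg = load_and_validate(raw)
    cfg.preset = name
    return cfg


def describe(cfg: RunConfig) -> str:
    """Human-readable summary of a resolved configuration."""
    p = cfg.make_params()
    dom = cfg.make_domain()
    variant_text = {
        1: ("potassium diffusion only: theta = nu, connectivity solve "
            "inactive"),
        2: ("axo-dendritic spread only: theta = phi via the screened-"
            "Poisson solve; diffusion term inactive"),
        3: "combined: theta = phi and potassium diffusion active",
    }[cfg.model_variant]
    lines = [
        f"model variant {cfg.model_variant} ({variant_text})",
        f"domain {dom.width:g} x {dom.height:g} mm, {dom.nx} x {dom.ny} "
        f"cells, dx = {dom.dx:g} mm",
        f"excitation disk R = {dom.excitation_radius:g} mm at "
        f"{dom.excitation_center}, "
        f"{int((dom.Gsyn_map == cfg.Gsyn_center).sum())} elevated cells",
        f"V_K0 = {p.V_K0:.2f} mV (from K_o0 = {p.K_o0:g} mM)",
        f"tau_K = {p.tau_K:g} s, tau_Na = {p.tau_Na:g} s, "
        f"tau_m = {p.tau_m * 1e3:g} ms, tau_D = {p.tau_D:g} s",
        f"D_K = {p.D_K:g} mm^2/s"
        + (" (inactive in this variant)" if cfg.model_variant == 2 else ""),
        f"lambda = {p.lambda_conn:g} mm"
        + (" (inactive in this variant)" if cfg.model_variant == 1 else ""),
        f"K_bath = {p.K_bath:g} mM, sigma/g_L = {p.sigma_over_gL:g} mV, "
        f"c_IE = {p.c_IE:g}, gK_leak/g_L = {p.gK_leak_over_gL:g}",
        f"noise: {cfg.noise_mode} ({cfg.noise_convention})",
        f"lesion: {cfg.lesion['kind'] if cfg.lesion else 'none'}",
        f"run: T = {cfg.total_time:g} s, dt = {cfg.dt * 1e3:g} ms, "
        f"seed = {cfg.seed}",
    ]
    return "\n".join(lines)
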