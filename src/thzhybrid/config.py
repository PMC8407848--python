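"""Structured YAML configuration: sections [pulse], [stack], [kk], [grid],
[imaging], with units as a user writes them (THz, ps, um) normalised to the
internal SI conventions (rad/s, s, m).  Unknown keys are rejected with the
offending key path, so typos fail loudly."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import THZ, ComplexIndex, KKSettings, Layer, LayerStack, RetrievalGrid
from .forward import PulseSpec

__all__ = ["Config", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "pulse": {
        "f_min_thz": 0.3,
        "f_max_thz": 1.0,
        "amplitude": 1.0,
        "t_span_ps": 120.0,
        "dt_ps": 0.05,
        "t0_ps": 15.0,
        "edge_db": -20.0,
    },
    "stack": {
        "n1": 1.0, "kappa1": 0.0,
        "n2": 1.8, "kappa2": 0.08, "thickness_um": 100.0,
        "n3": 2.6, "kappa3": 0.15,
        "theta1_deg": 0.0,
        "polarisation": "s",
        "walkoff": None,
    },
    "kk": {
        "anchor_thz": None,          # None: band centre
        "epsilon": 0.01,
        "max_iterations": 12,
        "offset_range_um": [-1000.0, 1000.0],
        "n_candidates": 256,
        "shrink": 4.0,
        "n_air": 1.0,
        "extrapolation": "taper",
        "omega_max_factor": 8.0,
        "analysis_band_thz": [0.1, 1.6],
    },
    "grid": {
        "n_min": 1.0, "n_max": 4.0, "n_step": 0.01,
        "kappa_min": 0.0, "kappa_max": 1.0, "kappa_step": 0.005,
        "refine_levels": 2,
    },
    "imaging": {
        "band_thz": [0.3, 1.0],
        "map_freqs_thz": [0.3, 0.4, 0.5],
        "low_snr_fraction": 0.01,
    },
    "seed": 0,
    "noise_rms": 0.0,
    "window": "tukey",
}


@dataclass
class Config:
    """Validated, unit-normalised settings for the whole pipeline."""

    pulse: PulseSpec
    stack: LayerStack
    kk: KKSettings
    grid: RetrievalGrid
    band: tuple[float, float]          # Hz
    analysis_band: tuple[float, float]  # Hz
    map_freqs_thz: list[float]
    low_snr_fraction: float
    seed: int
    noise_rms: float
    window: str
    raw: dict = field(default_factory=dict)


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        out[key] = dval
    for key, uval in user.items():
        here = f"{path}{key}"
        if key not in defaults:
            raise ValueError(f"unknown config key: {here!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(uval, dict):
                raise ValueError(f"config section {here!r} must be a mapping")
            out[key] = _merge(defaults[key], uval, here + ".")
        else:
            out[key] = uval
    return out


def _build(cfg: dict) -> Config:
    p = cfg["pulse"]
    pulse = PulseSpec(**p)

    s = cfg["stack"]
    if s["kappa1"] != 0:
        raise ValueError("stack.kappa1: incidence medium must be lossless")
    stack = LayerStack(
        layers=[
            Layer(ComplexIndex(s["n1"], s["kappa1"])),
            Layer(ComplexIndex(s["n2"], s["kappa2"]),
                  thickness=s["thickness_um"] * 1e-6),
            Layer(ComplexIndex(s["n3"], s["kappa3"])),
        ],
        theta1=np.deg2rad(s["theta1_deg"]),
        polarisation=s["polarisation"],
        walkoff=s["walkoff"],
    )

    k = cfg["kk"]
    if k["epsilon"] <= 0:
        raise ValueError(f"kk.epsilon must be > 0, got {k['epsilon']}")
    lo, hi = k["offset_range_um"]
    kk = KKSettings(
        omega1=None if k["anchor_thz"] is None else 2 * np.pi * k["anchor_thz"] * THZ,
        epsilon=k["epsilon"],
        max_iterations=k["max_iterations"],
        offset_range=(lo * 1e-6, hi * 1e-6),
        n_candidates=k["n_candidates"],
        shrink=k["shrink"],
        n_air=k["n_air"],
        extrapolation=k["extrapolation"],
        omega_max_factor=k["omega_max_factor"],
    )

    g = cfg["grid"]
    grid = RetrievalGrid(
        n_values=np.arange(g["n_min"], g["n_max"] + 1e-12, g["n_step"]),
        kappa_values=np.arange(g["kappa_min"], g["kappa_max"] + 1e-12, g["kappa_step"]),
        refine_levels=g["refine_levels"],
    )

    im = cfg["imaging"]
    band = (im["band_thz"][0] * THZ, im["band_thz"][1] * THZ)
    ab = k["analysis_band_thz"]
    analysis_band = (ab[0] * THZ, ab[1] * THZ)

    return Config(
        pulse=pulse,
        stack=stack,
        kk=kk,
        grid=grid,
        band=band,
        analysis_band=analysis_band,
        map_freqs_thz=list(im["map_freqs_thz"]),
        low_snr_fraction=im["low_snr_fraction"],
        seed=int(cfg["seed"]),
        noise_rms=float(cfg["noise_rms"]),
        window=cfg["window"],
        raw=cfg,
    )


def load_config(path=None, overrides: dict | None = None) -> Config:
    """Load and validate a YAML config; missing keys take defaults.

    ``overrides`` (same nested structure) take precedence over the file --
    the command line wins over the config file.
    """
    user: dict = {}
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config root must be a mapping")
    cfg = _merge(DEFAULT_CONFIG, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    try:
        return _build(cfg)
    except (TypeError, KeyError) as e:
        raise ValueError(f"invalid configuration: {e}") from e
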