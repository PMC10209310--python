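"""YAML run-configuration loading.

Recognised keys (all optional, with package defaults)::

    physics:
      brems_model: kramers          # the only shipped continuum model
      line_fraction: 0.10           # Au L share of emitted photons
      coherent_enabled: true
    source:
      kv: 50
      fwhm_kev: 5.0
      photons_per_history: 1
    device:
      type: probe | applicator
      diameter_cm: 2.5
      shell_cm: null                # null -> policy default
      al_cm: null                   # null -> 0.1 for diameters <= 3 cm
    transport:
      n_batches: 10
      coverage_k: 3.0
      scoring: collision | tracklength
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .geometry import Scene, applicator_scene, bare_probe_scene
from .source import DEFAULT_LINE_FRACTION, ElectronSourceSpec
from .transport import TransportConfig


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    brems = cfg.get("physics", {}).get("brems_model", "kramers")
    if brems != "kramers":
        raise ValueError(f"unknown bremsstrahlung model {brems!r}")
    return cfg


def source_spec(cfg: dict) -> ElectronSourceSpec:
    s = cfg.get("source", {})
    return ElectronSourceSpec(kv=int(s.get("kv", 50)),
                              fwhm_kev=float(s.get("fwhm_kev", 5.0)))


def line_fraction(cfg: dict) -> float:
    return float(cfg.get("physics", {}).get("line_fraction", DEFAULT_LINE_FRACTION))


def coherent_enabled(cfg: dict) -> bool:
    return bool(cfg.get("physics", {}).get("coherent_enabled", True))


def build_scene(cfg: dict) -> Scene:
    d = cfg.get("device", {})
    kind = d.get("type", "probe")
    if kind == "probe":
        return bare_probe_scene()
    if kind == "applicator":
        return applicator_scene(float(d["diameter_cm"]),
                                shell_cm=d.get("shell_cm"),
                                al_cm=d.get("al_cm"))
    raise ValueError(f"unknown device type {kind!r}")


def transport_config(cfg: dict) -> TransportConfig:
    t = cfg.get("transport", {})
    interactions = ("pe", "incoh", "coh") if coherent_enabled(cfg) else ("pe", "incoh")
    return TransportConfig(
        n_batches=int(t.get("n_batches", 10)),
        coverage_k=float(t.get("coverage_k", 1.0)),
        scoring=t.get("scoring", "collision"),
        interactions=interactions,
    )
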