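"""YAML config loading for resonator/oscillator parameter sets.

Schema (all values cm^-1)::

    omega0: 1730.0
    gamma_r: 400.0
    gamma_a: 40.0
    oscillators:
      - {omega_m: 1730.0, gamma_m: 10.0, mu: 25.0}
    grid: {start: 800.0, stop: 4000.0, step: 1.9}
"""

from __future__ import annotations

import numpy as np
import yaml

from .tcmt import CoupledSystem, MolecularOscillator, Resonator

__all__ = ["load_system_config", "system_from_dict", "grid_from_dict"]


def system_from_dict(cfg: dict) -> CoupledSystem:
    try:
        res = Resonator(float(cfg["omega0"]), float(cfg["gamma_r"]),
                        float(cfg["gamma_a"]))
    except KeyError as exc:
        raise KeyError(f"config missing required key {exc}") from None
    oscs = tuple(
        MolecularOscillator(float(o["omega_m"]), float(o["gamma_m"]),
                            float(o["mu"]))
        for o in cfg.get("oscillators", []) or [])
    return CoupledSystem(res, oscs)


def grid_from_dict(cfg: dict | None) -> np.ndarray | None:
    if not cfg:
        return None
    start, stop = float(cfg["start"]), float(cfg["stop"])
    step = float(cfg["step"])
    if not (stop > start and step > 0):
        raise ValueError("grid needs stop > start and step > 0")
    n = int(round((stop - start) / step)) + 1
    return np.linspace(start, stop, n)


def load_system_config(path) -> tuple[CoupledSystem, np.ndarray | None]:
    """Read a YAML config -> (CoupledSystem, optional grid)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return system_from_dict(cfg), grid_from_dict(cfg.get("grid"))
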