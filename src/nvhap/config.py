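"""YAML configuration: blocks ``io``, ``sim``, ``surveillance``, ``causal``.

Every block is optional; omitted keys take the dataclass defaults.  Example::

    io:
      spo2_normal: 97
    surveillance:
      spo2_drop: 3.0
      abx_lookback: 2
    causal:
      horizon: 60
      n_knots: 4
    sim:
      n_hospitalizations: 5000
      theta_death: 2.0
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .attributable import CausalParams
from .surveillance import SurveillanceParams
from .synthetic_data import SimConfig


@dataclasses.dataclass
class IOParams:
    data_dir: str = "."
    spo2_normal: float = 97.0


_BLOCKS = {
    "io": IOParams,
    "sim": SimConfig,
    "surveillance": SurveillanceParams,
    "causal": CausalParams,
}


def _build(cls, values: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - names
    if unknown:
        raise ValueError(f"unknown key(s) for {cls.__name__}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in values.items()
    }
    return cls(**coerced)


def load_config(path=None) -> dict:
    """Load a YAML config file into the four parameter dataclasses."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_BLOCKS)
    if unknown:
        raise ValueError(f"unknown config block(s): {sorted(unknown)}")
    return {name: _build(cls, raw.get(name) or {}) for name, cls in _BLOCKS.items()}
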