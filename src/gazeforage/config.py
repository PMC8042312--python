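"""YAML/JSON configuration loading.

A configuration file may carry any of the blocks ``scene``, ``decision``
and ``spatial`` plus top-level simulation keys (``duration_s``,
``start``, ``seed``, ``race_during_flight``), e.g.::

    scene:
      duration_s: 20
      fps: 30
      n_faces: 3
    decision:
      phi: 0.18
      eta: 5
      kappa: 15
      a: 1.7
    spatial:
      k_b_local: 40

Omitted keys fall back to the package defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import yaml

from .landscape import SceneSpec
from .simulator import SimConfig

__all__ = ["load_config", "scene_spec_from_config", "sim_config_from_config"]


def load_config(path) -> dict:
    """Parse a YAML (or JSON) configuration file into a plain dict."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: top level must be a mapping")
    return dict(data)


def scene_spec_from_config(config: Mapping) -> SceneSpec:
    return SceneSpec.from_dict(config.get("scene", {}))


def sim_config_from_config(config: Mapping) -> SimConfig:
    keys = {"decision", "spatial", "duration_s", "start", "seed", "race_during_flight"}
    block = {k: v for k, v in config.items() if k in keys}
    return SimConfig.from_dict(block)


def dump_json(obj, path) -> None:
    """Write a JSON report, converting numpy scalars/arrays along the way."""
    import numpy as np

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.generic):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
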