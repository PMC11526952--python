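"""Run configuration: YAML/JSON loading, validation, block constructors.

Conventions: fractions everywhere internally — percent appears only at
display boundaries (see :func:`gdforecast.projection.display_percent`).
Coordinates may be WGS84 lon/lat but are treated as planar for gridding.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .landscape import Landscape, build_lattice
from .params import Params, params_for_theta
from .scenarios import Horizons, ScenarioSpec

__all__ = ["ConfigError", "load_config", "landscape_from_config",
           "params_from_config", "scenario_from_config", "horizons_from_config"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


def load_config(path) -> dict:
    """Read a YAML or JSON config file into a dict."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix == ".json":
            cfg = json.loads(text)
        else:
            cfg = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as e:
        raise ConfigError(f"{path}: cannot parse config: {e}") from e
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(cfg).__name__}")
    return cfg


def landscape_from_config(cfg: dict) -> Landscape:
    block = cfg.get("landscape", {})
    try:
        if "mask" in block and block["mask"] is not None:
            return Landscape.from_dict(block)
        return build_lattice(int(block.get("rows", 10)), int(block.get("cols", 10)))
    except (ValueError, KeyError, TypeError) as e:
        raise ConfigError(f"invalid landscape block: {e}") from e


def params_from_config(cfg: dict, landscape: Landscape) -> Params:
    """Params from the config's ``params`` block.

    Either ``mu`` or ``theta`` (with mu derived for the landscape's deme
    count) must be given; ``mig`` may be a rate, or the separate
    ``target_fst`` key asks the caller to tune it.
    """
    block = dict(cfg.get("params", {}))
    try:
        deme_size = float(block.get("deme_size", 25.0))
        mig = float(block.get("mig", 0.01))
        if "theta" in block and "mu" not in block:
            return params_for_theta(float(block["theta"]), landscape.n_demes,
                                    deme_size, mig)
        return Params(mu=float(block.get("mu", 1e-8)), deme_size=deme_size, mig=mig)
    except (ValueError, TypeError) as e:
        raise ConfigError(f"invalid params block: {e}") from e


def horizons_from_config(cfg: dict) -> Horizons:
    block = cfg.get("horizons", {})
    try:
        return Horizons(short=float(block.get("short", 0.0)),
                        medium=float(block.get("medium", 2200)),
                        long=float(block.get("long", 13800)))
    except (ValueError, TypeError) as e:
        raise ConfigError(f"invalid horizons block: {e}") from e


def scenario_from_config(cfg: dict, seed: int | None = None) -> ScenarioSpec:
    block = dict(cfg.get("scenario", {}))
    try:
        return ScenarioSpec(
            scenario=block.get("scenario", "edge_contraction"),
            loss_fraction=float(block.get("loss_fraction", 0.5)),
            cell_block=float(block.get("cell_block", 1.0 / 100.0)),
            rate=float(block.get("rate", 0.01)),
            seed=int(block.get("seed", seed or 0)),
            horizons=horizons_from_config(cfg),
            edge=block.get("edge", "west"),
            restore_mode=block.get("restore_mode", "natural"),
        )
    except (ValueError, TypeError) as e:
        raise ConfigError(f"invalid scenario block: {e}") from e
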