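"""JSON run configuration.

Unknown keys produce warnings, not errors; validation collects every
problem before failing so a user fixes one round, not many.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

from .datamodel import HyperParams
from .exceptions import ConfigurationError
from .tuning import AXIS_ORDER, ParamSpace

MODES = ("train", "predict", "cv", "tune-grid", "tune-bayes", "generate")

_KNOWN_KEYS = {
    "mode", "matrix", "labels", "bands", "folds", "categories", "tsv",
    "model_in", "model_out", "params", "space", "n_folds_external",
    "n_folds_internal", "n_repeats", "seed", "n_workers", "out_dir",
    "band_aware", "max_iter", "n_init", "synth",
}

_REQUIRED: dict[str, tuple[str, ...]] = {
    "train": ("seed",),
    "predict": ("model_in",),
    "cv": ("seed",),
    "tune-grid": ("space", "seed"),
    "tune-bayes": ("space", "seed"),
    "generate": ("synth", "seed"),
}


@dataclass
class RunConfig:
    mode: str
    raw: dict[str, Any] = field(default_factory=dict)

    # data sources
    matrix: Optional[str] = None
    labels: Optional[str] = None
    bands: Optional[str] = None
    folds: Optional[str] = None
    categories: Optional[str] = None
    tsv: Optional[str] = None
    model_in: Optional[str] = None
    model_out: Optional[str] = None

    params: Optional[HyperParams] = None
    space: Optional[ParamSpace] = None
    synth: Optional[dict] = None

    n_folds_external: int = 10
    n_folds_internal: int = 9
    n_repeats: int = 1
    seed: Optional[int] = None
    n_workers: int = 1
    out_dir: str = "."
    band_aware: bool = False
    max_iter: int = 60
    n_init: int = 10


def _parse_space(obj: dict) -> ParamSpace:
    axes = {}
    for name in AXIS_ORDER:
        if name not in obj:
            raise ConfigurationError(f"space is missing axis {name!r}")
        axis = obj[name]
        if isinstance(axis, dict):
            axes[name] = (int(axis["lo"]), int(axis["hi"]))
        else:
            axes[name] = [int(v) for v in axis]
    return ParamSpace(**axes)


def load_config(path: str | Path, mode: str) -> RunConfig:
    """Load and validate a JSON config for the given run mode."""
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; expected one of {MODES}")
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a JSON object")
    for key in raw:
        if key not in _KNOWN_KEYS:
            warnings.warn(f"config key {key!r} is not recognised and will be ignored")

    problems: list[str] = []
    cfg = RunConfig(mode=mode, raw=raw)
    for key in (
        "matrix", "labels", "bands", "folds", "categories", "tsv",
        "model_in", "model_out", "out_dir",
    ):
        if key in raw:
            setattr(cfg, key, str(raw[key]))
    for key in ("n_folds_external", "n_folds_internal", "n_repeats", "seed",
                "n_workers", "max_iter", "n_init"):
        if key in raw:
            try:
                setattr(cfg, key, int(raw[key]))
            except (TypeError, ValueError):
                problems.append(f"{key} must be an integer, got {raw[key]!r}")
    if "band_aware" in raw:
        cfg.band_aware = bool(raw["band_aware"])
    if "params" in raw:
        try:
            cfg.params = HyperParams(**{k: int(v) for k, v in raw["params"].items()})
        except (TypeError, AttributeError, ConfigurationError) as exc:
            problems.append(f"params: {exc}")
    if "space" in raw:
        try:
            cfg.space = _parse_space(raw["space"])
        except (TypeError, KeyError, ConfigurationError) as exc:
            problems.append(f"space: {exc}")
    if "synth" in raw:
        if isinstance(raw["synth"], dict):
            cfg.synth = raw["synth"]
        else:
            problems.append("synth must be a JSON object of generator parameters")

    for key in _REQUIRED[mode]:
        if getattr(cfg, key) is None:
            problems.append(f"mode {mode!r} requires config key {key!r}")
    if mode != "generate" and cfg.tsv is None and cfg.matrix is None and mode != "predict":
        problems.append(f"mode {mode!r} requires a data source ('tsv' or 'matrix'+'labels')")
    if cfg.matrix is not None and cfg.labels is None and cfg.tsv is None:
        problems.append("'matrix' requires a companion 'labels' file")
    if problems:
        raise ConfigurationError("invalid configuration:\n  - " + "\n  - ".join(problems))
    return cfg
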