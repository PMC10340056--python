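"""YAML run-configuration schema for the command-line interface.

A run config is a flat YAML mapping; every tunable constant of the
pipeline (optimizer budgets, stagnation rule, training budgets, split
ratio, synthetic-data settings) is surfaced here so runs can be pinned
and reproduced from a single file plus a single global seed.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .synth import SyntheticSpec
from .tuning import PipelineConfig

__all__ = ["load_run_config", "EXAMPLE_CONFIG"]

_PIPELINE_KEYS = {
    "split_ratio", "val_fraction", "ber_population", "ber_iterations",
    "coa_population", "coa_iterations", "trial_epochs", "final_epochs",
    "seed", "output_dir",
}
_SYNTH_KEYS = {"n_classes", "images_per_class", "image_size", "difficulty"}

EXAMPLE_CONFIG = """\
# histotune run configuration
seed: 0
split_ratio: 0.8          # training fraction (0.8 or 0.7 are conventional)
val_fraction: 0.2         # carved from the training portion for tuning fitness
ber_population: 5
ber_iterations: 5
coa_population: 5
coa_iterations: 5
trial_epochs: 5           # per-trial training budget during tuning
final_epochs: 12
output_dir: runs/demo
synthetic:                # omit and set data_dir to use a real image folder
  n_classes: 5
  images_per_class: 64
  image_size: 32
  difficulty: 0.2
"""


def load_run_config(path) -> PipelineConfig:
    """Parse a YAML run config into a :class:`PipelineConfig`.

    Raises ``ValueError`` with the offending key for schema violations.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")

    known = _PIPELINE_KEYS | {"synthetic", "data_dir", "base_widths", "groups"}
    for key in raw:
        if key not in known:
            raise ValueError(f"{path}: unknown key {key!r}")

    kwargs = {k: raw[k] for k in _PIPELINE_KEYS if k in raw}
    if "base_widths" in raw:
        kwargs["base_widths"] = tuple(raw["base_widths"])
    if "groups" in raw:
        kwargs["groups"] = raw["groups"]

    if "data_dir" in raw and "synthetic" in raw:
        raise ValueError(f"{path}: give either data_dir or synthetic, not both")
    if "data_dir" in raw:
        kwargs["data"] = raw["data_dir"]
    elif "synthetic" in raw:
        synth = raw["synthetic"] or {}
        for key in synth:
            if key not in _SYNTH_KEYS:
                raise ValueError(f"{path}: unknown synthetic key {key!r}")
        kwargs["data"] = SyntheticSpec(seed=int(raw.get("seed", 0)), **synth)

    return PipelineConfig(**kwargs)
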