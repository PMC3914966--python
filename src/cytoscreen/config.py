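"""Run configuration: a TOML file with sensible screening defaults.

Every threshold defaults to the assay's published value, so a minimal
config needs only ``pixel_size_um``. Configs round-trip unchanged through
:func:`save_config`/:func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError
from .phenotypes import ClassificationRules
from .segmentation import SegmentationParams


@dataclass
class RunConfig:
    pixel_size_um: float = 0.66
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    rules: ClassificationRules = field(default_factory=ClassificationRules)
    z_cutoff: float = 2.0
    replicate_agg: str = "mean"
    batch_scope: str = "batch"
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise InputError("pixel_size_um must be positive")
        if not self.z_cutoff > 0:
            raise InputError("z_cutoff must be positive")
        if self.replicate_agg not in ("mean", "median", "per_well_any"):
            raise InputError("replicate_agg must be 'mean', 'median' or 'per_well_any'")
        if self.batch_scope not in ("batch", "plate"):
            raise InputError("batch_scope must be 'batch' or 'plate'")


def load_config(path: str | Path) -> RunConfig:
    """Read a TOML config; unknown keys are rejected."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    seg = data.pop("segmentation", {})
    rules = data.pop("rules", {})
    try:
        return RunConfig(
            segmentation=SegmentationParams(**seg),
            rules=ClassificationRules(**rules),
            **data,
        )
    except TypeError as exc:
        raise InputError(f"invalid config key: {exc}") from exc


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return f'"{v}"'


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as TOML (None-valued optionals are omitted)."""
    lines = []
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if f.name in ("segmentation", "rules"):
            continue
        lines.append(f"{f.name} = {_toml_value(v)}")
    for section in ("segmentation", "rules"):
        lines.append(f"\n[{section}]")
        for f in dataclasses.fields(getattr(config, section)):
            v = getattr(getattr(config, section), f.name)
            if v is None:
                continue
            lines.append(f"{f.name} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")
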