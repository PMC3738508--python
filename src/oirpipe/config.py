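"""Run configuration: one human-readable YAML file per pipeline run.

Every paper-gap parameter (segmentation weights, closing radius, tuft
thresholds, number of principal components, ...) is surfaced here so a
run is fully auditable. Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import ChanVeseParams

_QUANTIFY_KEYS = {
    "closing_radius": 12,
    "tuft_q": 0.95,
    "tuft_min_area": 10,
    "tuft_max_area": 500,
    "haem_dark_q": 0.005,
    "haem_min_area": 10,
}
_SMIA_KEYS = {"k": 5, "record_every": 5, "peripheral_fraction": 0.55,
              "open_radius": 1}
_STATS_KEYS = {"alpha": 0.05, "pca_var_target": 0.90, "n_pcs": None}
_SYNTH_KEYS = {"image_size": 256, "n_sections": 4}


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end pipeline run."""

    seed: int = 0
    preset: str = "mouse"
    n_per_group: int = 3
    log_level: str = "INFO"
    synth: dict = field(default_factory=lambda: dict(_SYNTH_KEYS))
    # mu tuned for thin vessels; see oirpipe.segmentation.VESSEL_CV_PARAMS
    segmentation: dict = field(default_factory=lambda: {"mu": 0.02})
    quantify: dict = field(default_factory=lambda: dict(_QUANTIFY_KEYS))
    smia: dict = field(default_factory=lambda: dict(_SMIA_KEYS))
    stats: dict = field(default_factory=lambda: dict(_STATS_KEYS))

    def __post_init__(self) -> None:
        if self.preset not in ("mouse", "rat"):
            raise ValueError("preset must be 'mouse' or 'rat'")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        cv_fields = {f.name for f in dataclasses.fields(ChanVeseParams)}
        _reject_unknown("segmentation", self.segmentation, cv_fields)
        for name, defaults in (
            ("synth", _SYNTH_KEYS),
            ("quantify", _QUANTIFY_KEYS),
            ("smia", _SMIA_KEYS),
            ("stats", _STATS_KEYS),
        ):
            block = getattr(self, name)
            _reject_unknown(name, block, set(defaults))
            merged = dict(defaults)
            merged.update(block)
            setattr(self, name, merged)

    @property
    def chan_vese_params(self) -> ChanVeseParams:
        return ChanVeseParams(**self.segmentation)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        _reject_unknown("config", raw, known)
        required = {"seed", "preset", "n_per_group", "synth", "quantify",
                    "smia", "stats"}
        missing = required - set(raw)
        if missing:
            raise ValueError(f"config missing required blocks/keys: {sorted(missing)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _reject_unknown(name: str, block: dict, known: set) -> None:
    if not isinstance(block, dict):
        raise ValueError(f"{name} block must be a mapping")
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown keys in {name} block: {sorted(unknown)}")
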