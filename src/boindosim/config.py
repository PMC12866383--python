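"""Run configuration: validated YAML/JSON loading with strict keys."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .boin import BoinDesign
from .dosimetry import DosimetryConfig
from .trial import DoseLevel, build_ladder

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """Schema violation; the message names the offending key."""


_DESIGN_KEYS = {
    "phi", "phi1", "phi2", "elim_cutoff", "elim_min_n",
    "max_per_dl", "max_total", "min_cohort",
}
_DOSIMETRY_KEYS = {
    "physical_half_life_h", "dose_factors", "ebrt_thresholds",
    "default_model", "anchor_window_h",
}
_TOP_KEYS = {"design", "ladder", "dosimetry", "scenario_path", "out_dir", "seed", "verbosity"}

#: Provisional 7-level ladder: intrapatient step-up rung first, then six
#: single-activity rungs; >= 3 cycles at the five lowest, 2 at the top two.
DEFAULT_LADDER = [
    {"cycle1_activity_gbq": 1.85, "later_cycle_activity_gbq": 5.55, "planned_cycles": 4},
    {"cycle1_activity_gbq": 9.25, "planned_cycles": 3},
    {"cycle1_activity_gbq": 11.1, "planned_cycles": 3},
    {"cycle1_activity_gbq": 14.8, "planned_cycles": 3},
    {"cycle1_activity_gbq": 18.5, "planned_cycles": 3},
    {"cycle1_activity_gbq": 22.2, "planned_cycles": 2},
    {"cycle1_activity_gbq": 25.9, "planned_cycles": 2},
]


@dataclass
class RunConfig:
    """Everything one run needs; the seed is recorded in all outputs."""

    design: BoinDesign = field(default_factory=BoinDesign)
    ladder: list[DoseLevel] = field(
        default_factory=lambda: build_ladder(DEFAULT_LADDER)
    )
    dosimetry: DosimetryConfig = field(default_factory=DosimetryConfig)
    scenario_path: Optional[str] = None
    out_dir: str = "out"
    seed: int = 0
    verbosity: int = 1


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    Unknown keys are rejected; missing sections fall back to defaults; a
    referenced scenario file must exist at load time.
    """
    path = Path(path)
    raw: Any = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    design_raw = raw.get("design", {})
    _check_keys(design_raw, _DESIGN_KEYS, "design")
    try:
        design = BoinDesign(**design_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"design: {exc}") from exc
    dosim_raw = raw.get("dosimetry", {})
    _check_keys(dosim_raw, _DOSIMETRY_KEYS, "dosimetry")
    try:
        dosimetry = DosimetryConfig(**dosim_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"dosimetry: {exc}") from exc
    try:
        ladder = build_ladder(raw.get("ladder", DEFAULT_LADDER))
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"ladder: {exc}") from exc
    scenario_path = raw.get("scenario_path")
    if scenario_path is not None and not Path(scenario_path).exists():
        raise ConfigError(f"scenario_path: file not found: {scenario_path}")
    return RunConfig(
        design=design,
        ladder=ladder,
        dosimetry=dosimetry,
        scenario_path=scenario_path,
        out_dir=raw.get("out_dir", "out"),
        seed=int(raw.get("seed", 0)),
        verbosity=int(raw.get("verbosity", 1)),
    )


def _to_plain(cfg: RunConfig) -> dict:
    return {
        "design": {k: v for k, v in asdict(cfg.design).items()},
        "ladder": [
            {
                "cycle1_activity_gbq": dl.cycle1_activity_gbq,
                "later_cycle_activity_gbq": dl.later_cycle_activity_gbq,
                "planned_cycles": dl.planned_cycles,
            }
            for dl in cfg.ladder
        ],
        "dosimetry": {
            "physical_half_life_h": cfg.dosimetry.physical_half_life_h,
            "dose_factors": dict(cfg.dosimetry.dose_factors),
            "ebrt_thresholds": dict(cfg.dosimetry.ebrt_thresholds),
            "default_model": cfg.dosimetry.default_model,
            "anchor_window_h": cfg.dosimetry.anchor_window_h,
        },
        "scenario_path": cfg.scenario_path,
        "out_dir": cfg.out_dir,
        "seed": cfg.seed,
        "verbosity": cfg.verbosity,
    }


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config that round-trips identically through load_config."""
    plain = _to_plain(cfg)
    if plain["scenario_path"] is None:
        del plain["scenario_path"]
    Path(path).write_text(yaml.safe_dump(plain, sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash identifying the configuration (for manifests)."""
    blob = json.dumps(_to_plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
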