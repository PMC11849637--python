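"""Run configuration: a YAML file with package defaults filled in.

An empty file (or ``load_config(None)``) yields the package defaults:
full-scheme prescription 5 x 725 cGy, 4 mm isotropic GTV margin, (2, 3, 2) mm
LR/AP/SI PTV margins, the clinical constraint table, drift targets
3.0 +- 2.2 mm (PV1) and 3.5 +- 2.0 mm (PV2), a 96^3 grid at 2 mm, and a
15-patient x 5-fraction cohort.  Unknown keys and out-of-range values are
rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import yaml

from .dose import PlanParams
from .grids import ImageGrid
from .motion import MotionParams, PhaseMotionParams
from .phantom import PhantomParams
from .structures import MarginSpec
from .workflow import Constraint, default_constraints

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a cohort run needs, validated."""

    grid: ImageGrid = field(default_factory=ImageGrid.centered)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    motion: MotionParams = field(default_factory=MotionParams)
    plan: PlanParams = field(default_factory=PlanParams)
    margins: MarginSpec = field(default_factory=MarginSpec)
    constraints: tuple[Constraint, ...] = ()
    n_patients: int = 15
    n_fractions: int = 5
    search_radius_mm: float = 15.0
    subvoxel: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.constraints:
            object.__setattr__(
                self, "constraints", tuple(default_constraints(self.plan.prescription_cGy))
            )
        if self.n_patients < 1 or self.n_fractions < 1:
            raise ConfigError("n_patients and n_fractions must be >= 1")
        if self.search_radius_mm <= 0:
            raise ConfigError(f"search_radius_mm must be > 0, got {self.search_radius_mm}")


def _build_dataclass(cls, data: dict, context: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) under '{context}': {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as err:
        raise ConfigError(f"invalid value under '{context}': {err}") from err


_TOP_LEVEL = {
    "grid",
    "phantom",
    "motion",
    "plan",
    "margins",
    "constraints",
    "cohort",
    "registration",
    "seed",
}


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``None`` or an empty file yields all package defaults.
    """
    raw = {}
    if path is not None:
        if not os.path.exists(path):
            raise FileNotFoundError(f"no such config file: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping at top level")
    unknown = set(raw) - _TOP_LEVEL
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    grid_cfg = dict(raw.get("grid", {}))
    unknown = set(grid_cfg) - {"shape", "spacing"}
    if unknown:
        raise ConfigError(f"unknown key(s) under 'grid': {sorted(unknown)}")
    try:
        grid = ImageGrid.centered(
            shape=tuple(grid_cfg.get("shape", (96, 96, 96))),
            spacing=tuple(grid_cfg.get("spacing", (2.0, 2.0, 2.0))),
        )
    except ValueError as err:
        raise ConfigError(f"invalid value under 'grid': {err}") from err

    motion_cfg = dict(raw.get("motion", {}))
    for phase_key in ("pv1", "pv2"):
        if phase_key in motion_cfg:
            motion_cfg[phase_key] = _build_dataclass(
                PhaseMotionParams, dict(motion_cfg[phase_key]), f"motion.{phase_key}"
            )
    motion = _build_dataclass(MotionParams, motion_cfg, "motion")

    constraints = tuple(
        _build_dataclass(Constraint, dict(entry), f"constraints[{i}]")
        for i, entry in enumerate(raw.get("constraints", []))
    )

    cohort_cfg = dict(raw.get("cohort", {}))
    unknown = set(cohort_cfg) - {"n_patients", "n_fractions"}
    if unknown:
        raise ConfigError(f"unknown key(s) under 'cohort': {sorted(unknown)}")
    reg_cfg = dict(raw.get("registration", {}))
    unknown = set(reg_cfg) - {"search_radius_mm", "subvoxel"}
    if unknown:
        raise ConfigError(f"unknown key(s) under 'registration': {sorted(unknown)}")

    try:
        return RunConfig(
            grid=grid,
            phantom=_build_dataclass(PhantomParams, dict(raw.get("phantom", {})), "phantom"),
            motion=motion,
            plan=_build_dataclass(PlanParams, dict(raw.get("plan", {})), "plan"),
            margins=_build_dataclass(MarginSpec, dict(raw.get("margins", {})), "margins"),
            constraints=constraints,
            n_patients=int(cohort_cfg.get("n_patients", 15)),
            n_fractions=int(cohort_cfg.get("n_fractions", 5)),
            search_radius_mm=float(reg_cfg.get("search_radius_mm", 15.0)),
            subvoxel=bool(reg_cfg.get("subvoxel", True)),
            seed=int(raw.get("seed", 0)),
        )
    except ConfigError:
        raise
    except (ValueError, TypeError) as err:
        raise ConfigError(str(err)) from err
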