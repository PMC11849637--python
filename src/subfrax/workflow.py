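"""The sub-fractionation workflow: one fraction, five evaluated cases.

Each simulated fraction follows the clinical sequence:

1. **ATS** — the daily plan is built on the PRE anatomy (conformal dose on
   the PTV) and evaluated on the PRE contours.
2. **PV1 / ATP1** — intrafraction motion moves the anatomy; a translation-
   only registration of the prostate estimates the drift; the plan dose is
   rigidly shifted by the estimated translation (isocenter shift); the first
   sub-fraction is delivered.
3. **PV2 / ATP2** — the cumulative PRE->PV2 motion is sampled, registered
   and corrected the same way for the second sub-fraction.

For every sub-fraction two evaluations are recorded, mirroring the case
matrix of the clinical analysis:

* **approved** — the shifted dose against the PRE contours rigidly shifted
  by the registration translation (what the clinic sees when approving);
* **corrected** — the shifted dose against contours propagated through the
  full (non-rigid) ground-truth displacement field, with the target
  structures (GTV+margin, CTV, PTV) re-created from the propagated
  prostate/GTV by the margin recipe, and the OARs warped, not re-created.

Constraint evaluation uses the full-treatment-scheme limits with their
clinical tolerances (e.g. CTV V_3444cGy >= 99 %, tolerated down to 98.9 %).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .dose import PlanParams, add_mc_noise, plan_dose, shift_dose
from .dvh import d_cc, d_mean, v_dose
from .grids import DoseGrid, ImageGrid, StructureSet
from .motion import (
    MotionParams,
    RigidMotion,
    invert_field,
    mean_displacement,
    sample_motion,
    shift_mask,
    warp_mask,
)
from .phantom import PhantomParams, cohort_patients
from .registration import register_translation
from .structures import MarginSpec, recreate_targets

__all__ = [
    "Constraint",
    "default_constraints",
    "v95_reference_cGy",
    "compute_case_metrics",
    "evaluate_constraints",
    "SubfractionRecord",
    "run_fraction",
    "run_cohort",
    "summarize",
    "CASES",
    "ANATOMY_STRUCTURES",
]

CASES = ("ATS", "approved_ATP1", "corrected_ATP1", "approved_ATP2", "corrected_ATP2")
ANATOMY_STRUCTURES = ("prostate", "gtv", "bladder", "rectum", "sphincter", "body")

#: metrics evaluated for every case
METRIC_KEYS = ("ctv_v95", "ptv_v95", "bladder_d5cc", "rectum_d1cc", "sphincter_dmean")


def v95_reference_cGy(prescription_cGy: float = 3625.0) -> int:
    """95 % of the full-scheme prescription, rounded to the nearest cGy."""
    return int(round(0.95 * prescription_cGy))


def subfraction_dose_cGy(fraction_dose_cGy: float = 725.0, n_subfractions: int = 2) -> float:
    """Dose delivered per sub-fraction (each daily fraction is split evenly)."""
    if fraction_dose_cGy <= 0 or n_subfractions < 1:
        raise ValueError("fraction dose must be > 0 and n_subfractions >= 1")
    return fraction_dose_cGy / n_subfractions


@dataclass(frozen=True)
class Constraint:
    """One clinical dose-volume constraint.

    ``metric`` is one of ``V_D`` (parameter = threshold cGy, limit in %),
    ``D_cc`` (parameter = volume cc, limit in cGy) or ``D_mean`` (limit in
    cGy).  ``direction`` is ">=" or "<="; ``tolerance`` adjusts the limit in
    the permissive direction for the with-tolerance pass (e.g. -0.1 on a
    >= 99 % limit gives a 98.9 % floor).
    """

    key: str
    structure: str
    metric: str
    limit: float
    direction: str
    parameter: float | None = None
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.metric not in ("V_D", "D_cc", "D_mean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.direction not in (">=", "<="):
            raise ValueError(f"direction must be '>=' or '<=', got {self.direction!r}")
        if self.metric in ("V_D", "D_cc") and (self.parameter is None or self.parameter <= 0):
            raise ValueError(f"constraint {self.key}: metric {self.metric} needs a positive parameter")
        if self.direction == ">=" and self.tolerance > 0:
            raise ValueError(f"constraint {self.key}: tolerance on a >= limit must be <= 0")
        if self.direction == "<=" and self.tolerance < 0:
            raise ValueError(f"constraint {self.key}: tolerance on a <= limit must be >= 0")

    def evaluate(self, value: float) -> dict[str, bool]:
        limit_tol = self.limit + self.tolerance
        if self.direction == ">=":
            return {"strict": value >= self.limit, "tolerance": value >= limit_tol}
        return {"strict": value <= self.limit, "tolerance": value <= limit_tol}


def default_constraints(prescription_cGy: float = 3625.0) -> list[Constraint]:
    """The clinical constraint set for the full 5 x 725 cGy scheme."""
    v95 = v95_reference_cGy(prescription_cGy)
    return [
        Constraint("ctv_v95", "ctv", "V_D", 99.0, ">=", parameter=v95, tolerance=-0.1),
        Constraint("ptv_v95", "ptv", "V_D", 99.0, ">=", parameter=v95, tolerance=-3.0),
        Constraint("bladder_d5cc", "bladder", "D_cc", 3700.0, "<=", parameter=5.0),
        Constraint("rectum_d1cc", "rectum", "D_cc", 3800.0, "<=", parameter=1.0),
        Constraint("sphincter_dmean", "sphincter", "D_mean", 2000.0, "<="),
    ]


def compute_case_metrics(
    dose: DoseGrid, structures: StructureSet, constraints: list[Constraint]
) -> dict[str, float]:
    """Evaluate every constrained metric of one case."""
    out: dict[str, float] = {}
    for c in constraints:
        mask = structures[c.structure]
        if c.metric == "V_D":
            out[c.key] = v_dose(dose, mask, c.parameter)
        elif c.metric == "D_cc":
            out[c.key] = d_cc(dose, mask, c.parameter)
        else:
            out[c.key] = d_mean(dose, mask)
    return out


def evaluate_constraints(
    metrics: dict[str, float], constraints: list[Constraint]
) -> dict[str, dict[str, bool]]:
    """Strict and with-tolerance pass flags for every constraint."""
    result = {}
    for c in constraints:
        if c.key not in metrics:
            raise KeyError(f"metric '{c.key}' missing from the evaluated metrics")
        result[c.key] = c.evaluate(metrics[c.key])
    return result


@dataclass
class SubfractionRecord:
    """Metrics and pass flags for one case of one sub-fraction."""

    patient: int
    fraction: int
    subfraction: int  # 0 for the ATS case, 1 or 2 for ATP cases
    case: str
    metrics: dict[str, float]
    passes: dict[str, dict[str, bool]]
    motion: dict[str, float] = dataclass_field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "patient": self.patient,
            "fraction": self.fraction,
            "subfraction": self.subfraction,
            "case": self.case,
        }
        row.update(self.metrics)
        for key, flags in self.passes.items():
            row[f"{key}_pass"] = flags["strict"]
            row[f"{key}_pass_tol"] = flags["tolerance"]
        row.update({f"motion_{k}": v for k, v in self.motion.items()})
        return row


def _motion_summary(rigid: RigidMotion | None, mean_disp: float, amplitude: float) -> dict:
    if rigid is None:
        return {}
    t = rigid.translation_mm
    r = rigid.rotation_deg
    return {
        "t_lr": t[0],
        "t_ap": t[1],
        "t_si": t[2],
        "rot_lr": r[0],
        "rot_ap": r[1],
        "rot_si": r[2],
        "deformation_amplitude": amplitude,
        "mean_prostate_displacement": mean_disp,
    }


def run_fraction(
    structures_pre: StructureSet,
    motion_params: MotionParams = MotionParams(),
    plan_params: PlanParams = PlanParams(),
    margins: MarginSpec = MarginSpec(),
    constraints: list[Constraint] | None = None,
    seed: int = 0,
    patient: int = 0,
    fraction: int = 0,
    search_radius_mm: float = 15.0,
    subvoxel: bool = True,
    approved_eval: str = "plan_frame",
) -> list[SubfractionRecord]:
    """Simulate one fraction and evaluate the five-case matrix.

    ``structures_pre`` must contain the anatomy structures; targets are
    re-created here if absent.  Returns one record for the ATS case and one
    per (sub-fraction x {approved, corrected}).

    ``approved_eval`` selects how the approved case is scored.  A rigid shift
    applied to the dose and the contours together leaves every dose-volume
    metric unchanged, so ``"plan_frame"`` (default) evaluates the unshifted
    pair directly — the exact form of that identity.  ``"room_frame"``
    resamples both onto the grid after shifting; it is the same reading up
    to voxelization, and quantifies the resampling artifact instead.
    """
    if approved_eval not in ("plan_frame", "room_frame"):
        raise ValueError(f"approved_eval must be 'plan_frame' or 'room_frame', got {approved_eval!r}")
    if constraints is None:
        constraints = default_constraints(plan_params.prescription_cGy)
    if "ptv" not in structures_pre:
        structures_pre = recreate_targets(structures_pre, margins)
    grid = structures_pre.grid
    rng_pv1, rng_pv2, rng_noise = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)
    ]

    ats = plan_dose(structures_pre["ptv"], plan_params)
    if plan_params.mc_noise_rel > 0:
        ats = add_mc_noise(ats, plan_params.mc_noise_rel, rng_noise)

    records = [
        SubfractionRecord(
            patient,
            fraction,
            0,
            "ATS",
            m := compute_case_metrics(ats, structures_pre, constraints),
            evaluate_constraints(m, constraints),
        )
    ]

    centroid = structures_pre["prostate"].centroid_mm()
    bladder_center = structures_pre["bladder"].centroid_mm()
    for sub, (phase, rng) in enumerate([("pv1", rng_pv1), ("pv2", rng_pv2)], start=1):
        try:
            phase_params = motion_params.phase(phase)
            rigid, field = sample_motion(
                motion_params,
                phase,
                centroid,
                grid=grid,
                rng=rng,
                bladder_center_mm=bladder_center,
            )
            inverse = invert_field(field)
            warped = StructureSet(grid)
            for name in ANATOMY_STRUCTURES:
                warped.add(warp_mask(structures_pre[name], field, inverse=inverse))

            t = register_translation(
                structures_pre["prostate"],
                warped["prostate"],
                search_radius_mm=search_radius_mm,
                subvoxel=subvoxel,
            )
            atp_dose = shift_dose(ats, t)
            motion_info = _motion_summary(
                rigid,
                mean_displacement(field, structures_pre["prostate"]),
                phase_params.deformation_amplitude_mm,
            )
            motion_info.update({"t_est_lr": t[0], "t_est_ap": t[1], "t_est_si": t[2]})

            # approved: the shifted plan scored on PRE contours carried along
            # with it (rigid shift of dose and contours together)
            if approved_eval == "room_frame":
                approved = StructureSet(grid)
                for name in structures_pre.names():
                    approved.add(shift_mask(structures_pre[name], t))
                m_app = compute_case_metrics(atp_dose, approved, constraints)
            else:
                m_app = compute_case_metrics(ats, structures_pre, constraints)
            records.append(
                SubfractionRecord(
                    patient,
                    fraction,
                    sub,
                    f"approved_ATP{sub}",
                    m_app,
                    evaluate_constraints(m_app, constraints),
                    dict(motion_info),
                )
            )

            # corrected: contours propagated through the true field; targets
            # re-created from the propagated prostate/GTV by the margin recipe
            corrected = recreate_targets(warped, margins)
            m_cor = compute_case_metrics(atp_dose, corrected, constraints)
            records.append(
                SubfractionRecord(
                    patient,
                    fraction,
                    sub,
                    f"corrected_ATP{sub}",
                    m_cor,
                    evaluate_constraints(m_cor, constraints),
                    dict(motion_info),
                )
            )
        except Exception as err:
            raise RuntimeError(
                f"patient {patient}, fraction {fraction}, sub-fraction {sub} "
                f"({phase}): {err}"
            ) from err
    return records


def run_cohort(
    n_patients: int = 15,
    n_fractions: int = 5,
    phantom_params: PhantomParams = PhantomParams(),
    motion_params: MotionParams = MotionParams(),
    plan_params: PlanParams = PlanParams(),
    margins: MarginSpec = MarginSpec(),
    constraints: list[Constraint] | None = None,
    seed: int = 0,
    grid: ImageGrid | None = None,
    search_radius_mm: float = 15.0,
    subvoxel: bool = True,
    approved_eval: str = "plan_frame",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort (default 15 patients x 5 fractions x 2 sub-fractions).

    Returns the per-record table (one row per sub-fraction x case) and the
    cohort summary.  Fully deterministic under ``seed``.
    """
    if n_patients < 1 or n_fractions < 1:
        raise ValueError("n_patients and n_fractions must be >= 1")
    if constraints is None:
        constraints = default_constraints(plan_params.prescription_cGy)
    root = np.random.SeedSequence(seed)
    phantom_seed, fraction_seed = root.spawn(2)
    patients = cohort_patients(
        n_patients, phantom_params, seed=phantom_seed.generate_state(1)[0] % (2**31)
    )
    fraction_seeds = fraction_seed.spawn(n_patients * n_fractions)

    records: list[SubfractionRecord] = []
    for p, (pgrid, structures) in enumerate(patients):
        structures = recreate_targets(structures, margins)
        for f in range(n_fractions):
            fseed = fraction_seeds[p * n_fractions + f].generate_state(1)[0] % (2**31)
            records.extend(
                run_fraction(
                    structures,
                    motion_params,
                    plan_params,
                    margins,
                    constraints,
                    seed=int(fseed),
                    patient=p,
                    fraction=f,
                    search_radius_mm=search_radius_mm,
                    subvoxel=subvoxel,
                    approved_eval=approved_eval,
                )
            )
    df = pd.DataFrame([r.to_row() for r in records])
    return df, summarize(df, constraints)


def summarize(records: pd.DataFrame, constraints: list[Constraint] | None = None) -> dict:
    """Cohort summary: per-case coverage statistics, with-tolerance pass
    rates, and paired approved-minus-corrected metric drops."""
    if len(records) == 0:
        raise ValueError("summarize: no records")
    if constraints is None:
        constraints = default_constraints()

    summary: dict = {"n_records": int(len(records)), "cases": {}, "drops": {}}
    for case, group in records.groupby("case"):
        entry = {
            "n": int(len(group)),
            "ctv_v95_mean": float(group["ctv_v95"].mean()),
            "ctv_v95_sd": float(group["ctv_v95"].std(ddof=1)) if len(group) > 1 else 0.0,
            "ptv_v95_mean": float(group["ptv_v95"].mean()),
            "ptv_v95_sd": float(group["ptv_v95"].std(ddof=1)) if len(group) > 1 else 0.0,
            "pass_rates_tol": {
                c.key: float(group[f"{c.key}_pass_tol"].mean()) for c in constraints
            },
        }
        summary["cases"][case] = entry

    # paired approved-minus-corrected drops per sub-fraction
    keys = ["patient", "fraction", "subfraction"]
    for sub in (1, 2):
        app = records[records["case"] == f"approved_ATP{sub}"].set_index(keys)
        cor = records[records["case"] == f"corrected_ATP{sub}"].set_index(keys)
        if len(app) == 0 or len(cor) == 0:
            continue
        joined = app.join(cor, lsuffix="_app", rsuffix="_cor", how="inner")
        drops = {}
        for key in METRIC_KEYS:
            diff = joined[f"{key}_app"] - joined[f"{key}_cor"]
            drops[key] = float(diff.mean())
        summary["drops"][f"ATP{sub}"] = {"n_pairs": int(len(joined)), "mean": drops}
    return summary


def write_outputs(records: pd.DataFrame, summary: dict, out_dir) -> None:
    """Write records.csv and summary.json into ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    records.to_csv(os.path.join(out_dir, "records.csv"), index=False)
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
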