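"""Opioid rotation with incomplete cross-tolerance.

Switching opioids at the full equianalgesic dose risks overdose because
tolerance to the old drug transfers only partially to the new one.  The
starting dose of the new drug is therefore set at a fraction of the
equianalgesic dose; three preset schemes (30%, 50%, 100%) span cautious to
direct conversion, and the plan can be switched mid-course as the patient
responds.

Methadone is explicitly unsupported: its equianalgesic ratio varies
nonlinearly with dose, so a constant-factor conversion would be unsafe.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .errors import ValidationError
from .formulary import Formulary, from_ome, to_ome
from .taper import TaperPlan, TaperPolicy, generate_taper

_EPS = 1e-9


@dataclass(frozen=True)
class RotationScheme:
    """Fraction of the equianalgesic dose at which the new opioid starts."""

    cross_tolerance_fraction: float
    label: str = ""

    def __post_init__(self):
        if not 0 < self.cross_tolerance_fraction <= 1:
            raise ValidationError(
                f"cross_tolerance_fraction must be in (0, 1], got {self.cross_tolerance_fraction}"
            )
        if not self.label:
            object.__setattr__(self, "label", f"{round(self.cross_tolerance_fraction * 100)}%")


#: conservative / intermediate / direct presets
PRESET_SCHEMES: tuple[RotationScheme, ...] = (
    RotationScheme(0.30, "30%"),
    RotationScheme(0.50, "50%"),
    RotationScheme(1.00, "100%"),
)


def _warn_if_methadone(*drugs: str) -> None:
    for d in drugs:
        if d == "methadone":
            warnings.warn(
                "methadone conversion is nonlinear and not supported by this "
                "package; any constant-factor result would be unsafe",
                UserWarning,
                stacklevel=3,
            )


def rotate_dose(
    from_drug: str,
    from_dose_mg: float,
    to_drug: str,
    scheme: RotationScheme,
    formulary: Formulary,
) -> float:
    """Starting 24-h dose of ``to_drug`` in mg when rotating from ``from_drug``.

    Computed as the equianalgesic dose (via the OME scale) multiplied by
    the scheme's cross-tolerance fraction; exact, unrounded — tablet
    rounding happens in the formulation mapper.
    """
    if from_dose_mg <= 0:
        raise ValidationError(f"from_dose_mg must be > 0, got {from_dose_mg}")
    _warn_if_methadone(from_drug, to_drug)
    equianalgesic_mg = from_ome(to_drug, to_ome(from_drug, from_dose_mg, formulary), formulary)
    return equianalgesic_mg * scheme.cross_tolerance_fraction


def build_rotation_plans(
    from_drug: str,
    from_dose_mg: float,
    to_drug: str,
    formulary: Formulary,
    policy: TaperPolicy,
) -> dict[str, TaperPlan]:
    """One taper plan per preset scheme, keyed by scheme label.

    Each plan's baseline is the rotated starting dose expressed in mg-OME
    (so the three baselines are exactly 0.30/0.50/1.00 × the equianalgesic
    OME); the taper itself runs through :func:`generate_taper` unchanged.
    """
    plans: dict[str, TaperPlan] = {}
    for scheme in PRESET_SCHEMES:
        dose_mg = rotate_dose(from_drug, from_dose_mg, to_drug, scheme, formulary)
        baseline_ome = to_ome(to_drug, dose_mg, formulary)
        plans[scheme.label] = generate_taper(
            baseline_ome, policy, plan_id=f"rotation-{scheme.label}"
        )
    return plans


def switch_plan(plan: TaperPlan, day: int, policy: TaperPolicy | None = None) -> TaperPlan:
    """Re-anchor a plan at the dose in effect on ``day``.

    Used when the clinician switches scheme (or policy) mid-course in
    response to the patient: the remaining trajectory is regenerated from
    the current day's dose, so the switched plan is dose-continuous —
    its day-``day`` dose equals the old plan's.  Days before ``day`` keep
    the old plan's steps.
    """
    if not 0 <= day <= plan.last_day:
        raise ValidationError(f"day {day} outside plan span [0, {plan.last_day}]")
    current = plan.dose_on(day)
    policy = policy if policy is not None else plan.policy
    if current <= policy.target_ome + _EPS:
        return plan
    tail = generate_taper(current, policy, plan_id=f"{plan.plan_id}-switched")
    prefix = plan.steps[:day]
    shifted_tail = tuple(
        replace(s, day=s.day + day) for s in tail.steps
    )
    return TaperPlan(
        steps=prefix + shifted_tail,
        baseline_ome=plan.baseline_ome,
        policy=policy,
        plan_id=f"{plan.plan_id}-switched",
    )
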