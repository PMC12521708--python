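"""Linear opioid taper schedules.

The central modelling decision: every reduction step removes a **constant**
amount Δ = ``reduction_fraction × baseline``, where the baseline is the
stabilized 24-hour consumption at the start of the taper.  A "25% taper"
therefore reaches zero in exactly 4 reductions from any baseline — the dose
trajectory is linear in time, not geometric.  Percent-of-current-dose
(compounding) tapers never terminate and are a common misreading; this
module guards against it explicitly in its tests.

Two clinical presets are shipped:

* **acute pain** — 25% of baseline removed every 2nd day;
* **chronic pain** — 10% of baseline removed every 3rd day.

The taper target is 0 mg-OME for opioid-naive patients and the
prehospitalization dose for chronic users.  A discharge "grace period"
holds the dose in effect on the discharge day for extra days before
reductions continue.  Throughout the taper a back-up (rescue) allowance of
1/10–1/6 of the starting dose is carried, dropped once the fixed dose
reaches target.

All doses are exact mg-OME per 24 h; conversion to administrable tablets
happens downstream in :mod:`oeptools.formulation`.
"""
from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .errors import ValidationError
from .formulary import Formulary, to_ome

#: bracket for the back-up (rescue) allowance, as a fraction of the
#: starting dose
BACKUP_FRACTION_MIN = 1.0 / 10.0
BACKUP_FRACTION_MAX = 1.0 / 6.0
#: shipped default: midpoint-ish point inside the bracket
BACKUP_FRACTION_DEFAULT = 1.0 / 8.0

_EPS = 1e-9


class OpioidStatus(str, enum.Enum):
    NAIVE = "naive"
    CHRONIC_USER = "chronic_user"


class PainType(str, enum.Enum):
    ACUTE = "acute"
    CHRONIC = "chronic"


class EntryKind(str, enum.Enum):
    FIXED = "fixed"
    BACKUP = "backup"


@dataclass(frozen=True)
class ConsumptionEntry:
    """One drug's total consumption over the last-24-hour window."""

    drug: str
    dose_mg: float
    kind: EntryKind = EntryKind.FIXED

    def __post_init__(self):
        if self.dose_mg < 0:
            raise ValidationError(f"dose_mg must be >= 0, got {self.dose_mg}")
        object.__setattr__(self, "kind", EntryKind(self.kind))


@dataclass(frozen=True)
class PatientCase:
    """The patient-level inputs the taper is individualized on."""

    opioid_status: OpioidStatus
    pain_type: PainType
    last24h: tuple[ConsumptionEntry, ...] = ()
    prehospital_ome: float = 0.0
    discharge_day: Optional[int] = None
    pain_stable_hours: float = 0.0
    cognitive_impairment: bool = False

    def __post_init__(self):
        object.__setattr__(self, "opioid_status", OpioidStatus(self.opioid_status))
        object.__setattr__(self, "pain_type", PainType(self.pain_type))
        object.__setattr__(self, "last24h", tuple(self.last24h))
        if self.prehospital_ome < 0:
            raise ValidationError(f"prehospital_ome must be >= 0, got {self.prehospital_ome}")
        if self.opioid_status is OpioidStatus.NAIVE and self.prehospital_ome != 0:
            raise ValidationError("an opioid-naive patient must have prehospital_ome == 0")
        if self.discharge_day is not None and self.discharge_day < 0:
            raise ValidationError(f"discharge_day must be >= 0, got {self.discharge_day}")
        if self.pain_stable_hours < 0:
            raise ValidationError("pain_stable_hours must be >= 0")

    def to_dict(self) -> dict:
        return {
            "opioid_status": self.opioid_status.value,
            "pain_type": self.pain_type.value,
            "prehospital_ome": self.prehospital_ome,
            "last24h": [
                {"drug": e.drug, "dose_mg": e.dose_mg, "kind": e.kind.value} for e in self.last24h
            ],
            "discharge_day": self.discharge_day,
            "pain_stable_hours": self.pain_stable_hours,
            "cognitive_impairment": self.cognitive_impairment,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PatientCase":
        return cls(
            opioid_status=data["opioid_status"],
            pain_type=data["pain_type"],
            last24h=tuple(
                ConsumptionEntry(e["drug"], float(e["dose_mg"]), e.get("kind", "fixed"))
                for e in data.get("last24h", [])
            ),
            prehospital_ome=float(data.get("prehospital_ome", 0.0)),
            discharge_day=data.get("discharge_day"),
            pain_stable_hours=float(data.get("pain_stable_hours", 0.0)),
            cognitive_impairment=bool(data.get("cognitive_impairment", False)),
        )


@dataclass(frozen=True)
class TaperPolicy:
    """Parameters of one linear reduction plan.

    ``reduction_fraction`` is the fraction of the *post-stabilization
    baseline* removed at each step (so the step size in mg is constant);
    ``step_interval_days`` the days between successive reductions;
    ``grace_days`` the extra hold applied around discharge;
    ``target_ome`` where the taper stops (0 = cessation).
    """

    reduction_fraction: float
    step_interval_days: int
    grace_days: int = 0
    first_reduction_day: int = 1
    target_ome: float = 0.0
    backup_fraction: float = BACKUP_FRACTION_DEFAULT

    def __post_init__(self):
        if not 0 < self.reduction_fraction <= 1:
            raise ValidationError(f"reduction_fraction must be in (0, 1], got {self.reduction_fraction}")
        if self.step_interval_days < 1:
            raise ValidationError(f"step_interval_days must be >= 1, got {self.step_interval_days}")
        if self.grace_days < 0:
            raise ValidationError(f"grace_days must be >= 0, got {self.grace_days}")
        if self.first_reduction_day < 1:
            raise ValidationError(f"first_reduction_day must be >= 1, got {self.first_reduction_day}")
        if self.target_ome < 0:
            raise ValidationError(f"target_ome must be >= 0, got {self.target_ome}")
        if not BACKUP_FRACTION_MIN - _EPS <= self.backup_fraction <= BACKUP_FRACTION_MAX + _EPS:
            raise ValidationError(
                f"backup_fraction must lie in [1/10, 1/6], got {self.backup_fraction}"
            )

    def to_dict(self) -> dict:
        return {
            "reduction_fraction": self.reduction_fraction,
            "step_interval_days": self.step_interval_days,
            "grace_days": self.grace_days,
            "first_reduction_day": self.first_reduction_day,
            "target_ome": self.target_ome,
            "backup_fraction": self.backup_fraction,
        }


#: acute-pain preset: 25% of baseline every other day
ACUTE_POLICY = TaperPolicy(reduction_fraction=0.25, step_interval_days=2)
#: chronic-pain preset: 10% of baseline every third day
CHRONIC_POLICY = TaperPolicy(reduction_fraction=0.10, step_interval_days=3)


@dataclass(frozen=True)
class TaperStep:
    """One day of the plan: day index, fixed dose, back-up allowance."""

    day: int
    fixed_ome: float
    backup_ome: float


@dataclass(frozen=True)
class TaperPlan:
    """A dense, day-indexed reduction schedule.

    ``steps`` holds one entry per day from day 0 (baseline establishment)
    to the day the fixed dose first equals ``policy.target_ome``.
    """

    steps: tuple[TaperStep, ...]
    baseline_ome: float
    policy: TaperPolicy
    plan_id: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "steps", tuple(self.steps))
        if not self.steps:
            raise ValidationError("a plan must contain at least one step")
        days = [s.day for s in self.steps]
        if days != sorted(set(days)) or days[0] != 0 or days != list(range(len(days))):
            raise ValidationError("plan steps must be dense and day-indexed from 0")

    # -- accessors -------------------------------------------------------
    def dose_on(self, day: int) -> float:
        """Fixed dose in effect on ``day`` (held at target after the end)."""
        if day < 0:
            raise ValidationError("day must be >= 0")
        if day >= len(self.steps):
            return self.steps[-1].fixed_ome
        return self.steps[day].fixed_ome

    @property
    def last_day(self) -> int:
        return self.steps[-1].day

    @property
    def reduction_days(self) -> tuple[int, ...]:
        """Days on which the fixed dose decreases relative to the day before."""
        out = []
        for prev, cur in zip(self.steps, self.steps[1:]):
            if cur.fixed_ome < prev.fixed_ome - _EPS:
                out.append(cur.day)
        return tuple(out)

    @property
    def dose_levels(self) -> tuple[float, ...]:
        """Distinct dose levels in order of appearance (a strictly decreasing sequence)."""
        levels = [self.steps[0].fixed_ome]
        for s in self.steps[1:]:
            if abs(s.fixed_ome - levels[-1]) > _EPS:
                levels.append(s.fixed_ome)
        return tuple(levels)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "plan_id": self.plan_id,
            "baseline_ome": self.baseline_ome,
            "policy": self.policy.to_dict(),
            "steps": [
                {"day": s.day, "fixed_ome": s.fixed_ome, "backup_ome": s.backup_ome}
                for s in self.steps
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_csv(self) -> str:
        lines = ["day,fixed_ome,backup_ome"]
        lines += [f"{s.day},{s.fixed_ome:g},{s.backup_ome:g}" for s in self.steps]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_dict(cls, data: dict) -> "TaperPlan":
        return cls(
            steps=tuple(
                TaperStep(int(s["day"]), float(s["fixed_ome"]), float(s["backup_ome"]))
                for s in data["steps"]
            ),
            baseline_ome=float(data["baseline_ome"]),
            policy=TaperPolicy(**data["policy"]),
            plan_id=data.get("plan_id", "custom"),
        )


# ---------------------------------------------------------------------------
# operations

def baseline_from_24h(case: PatientCase, formulary: Formulary) -> float:
    """Starting (baseline) dose: total last-24-hour consumption in mg-OME.

    Fixed and back-up consumption both count — the patient's actual
    requirement, not the nominal fixed prescription, anchors the taper.
    """
    if not case.last24h:
        raise ValidationError("no last-24h consumption entries: baseline is not derivable")
    return sum(to_ome(e.drug, e.dose_mg, formulary) for e in case.last24h)


def is_stabilized(
    case: PatientCase,
    backup_count_24h: int,
    backup_ome_24h: float,
    fixed_ome_24h: float,
    *,
    window_hours: float = 48.0,
    max_backup_fraction: float = 0.10,
    max_backup_count: int = 2,
) -> bool:
    """Is the patient stable enough to start reducing?

    The qualitative rule — stable pain for 24–48 h with minimal back-up
    use — is parameterized as: pain stable for at least ``window_hours``
    (default 48, clinically never below 24), back-up consumption at most
    ``max_backup_fraction`` of the fixed dose, and at most
    ``max_backup_count`` back-up doses in the window.
    """
    if fixed_ome_24h <= 0:
        raise ValidationError("fixed_ome_24h must be > 0")
    if backup_count_24h < 0 or backup_ome_24h < 0:
        raise ValidationError("back-up usage must be >= 0")
    if window_hours < 24:
        raise ValidationError("stabilization window must be at least 24 h")
    return (
        case.pain_stable_hours >= window_hours
        and backup_ome_24h <= max_backup_fraction * fixed_ome_24h + _EPS
        and backup_count_24h <= max_backup_count
    )


def select_policy(case: PatientCase, baseline_ome: float) -> TaperPolicy:
    """Choose the preset policy for a case.

    Acute pain takes the rapid preset (25%/2d), chronic pain the gradual
    one (10%/3d).  The target is the prehospitalization dose (0 for naive
    patients).  A 2-day discharge grace period is attached whenever a
    discharge day is known.
    """
    if baseline_ome <= 0:
        raise ValidationError("baseline_ome must be > 0")
    preset = ACUTE_POLICY if case.pain_type is PainType.ACUTE else CHRONIC_POLICY
    return replace(
        preset,
        target_ome=case.prehospital_ome,
        grace_days=2 if case.discharge_day is not None else 0,
    )


def plan_id_for(case: PatientCase) -> str:
    """Fig-style plan label: 1/2 = gradual, 3/4 = rapid; 2/4 carry a grace period."""
    rapid = case.pain_type is PainType.ACUTE
    grace = case.discharge_day is not None
    return {
        (False, False): "plan1",
        (False, True): "plan2",
        (True, False): "plan3",
        (True, True): "plan4",
    }[(rapid, grace)]


def _n_reductions(span: float, delta: float) -> int:
    # ceil with a float-noise guard so e.g. span/delta == 3.0000000001 -> 3
    ratio = span / delta
    return max(1, math.ceil(ratio - 1e-9))


def _linear_schedule(
    start_ome: float,
    target_ome: float,
    delta: float,
    first_reduction_day: int,
    step_interval_days: int,
) -> list[tuple[int, float]]:
    """(reduction_day, dose_after) pairs for a constant-step linear descent.

    The final step is clamped so the trajectory lands exactly on the
    target and never overshoots below it.
    """
    n = _n_reductions(start_ome - target_ome, delta)
    out = []
    for r in range(1, n + 1):
        day = first_reduction_day + (r - 1) * step_interval_days
        dose = max(start_ome - r * delta, target_ome)
        if abs(dose - target_ome) <= _EPS:
            dose = target_ome
        out.append((day, dose))
    return out


def _densify(
    baseline_ome: float,
    reductions: Sequence[tuple[int, float]],
    target_ome: float,
    backup_ome: float,
) -> list[TaperStep]:
    """Expand (day, dose) reduction events into one step per day.

    Back-up allowance is carried while the fixed dose is above target and
    dropped (0) from the day the target is reached.
    """
    last_day = reductions[-1][0] if reductions else 0
    dose_by_day = {}
    current = baseline_ome
    events = dict(reductions)
    for day in range(last_day + 1):
        if day in events:
            current = events[day]
        dose_by_day[day] = current
    return [
        TaperStep(
            day=day,
            fixed_ome=dose,
            backup_ome=backup_ome if dose > target_ome + _EPS else 0.0,
        )
        for day, dose in dose_by_day.items()
    ]


def generate_taper(baseline_ome: float, policy: TaperPolicy, plan_id: str = "custom") -> TaperPlan:
    """Generate the dense linear reduction plan for one baseline.

    Step size Δ = ``reduction_fraction × baseline_ome`` (constant; linear
    in the baseline, *not* of the current dose).  Reductions fall on days
    ``first_reduction_day + k·step_interval_days``; the dose after r
    reductions is ``max(baseline − r·Δ, target)``; the plan ends the first
    day the dose equals the target.  The total number of reductions is
    ``ceil((baseline − target)/Δ)``.
    """
    if baseline_ome <= policy.target_ome:
        raise ValidationError(
            f"nothing to reduce: baseline {baseline_ome} <= target {policy.target_ome}"
        )
    delta = policy.reduction_fraction * baseline_ome
    reductions = _linear_schedule(
        baseline_ome, policy.target_ome, delta, policy.first_reduction_day, policy.step_interval_days
    )
    steps = _densify(
        baseline_ome, reductions, policy.target_ome, policy.backup_fraction * baseline_ome
    )
    return TaperPlan(steps=tuple(steps), baseline_ome=baseline_ome, policy=policy, plan_id=plan_id)


def apply_grace_period(plan: TaperPlan, discharge_day: int, grace_days: int) -> TaperPlan:
    """Delay every reduction scheduled strictly after discharge by ``grace_days``.

    The dose in effect on the discharge day is held for the extra days;
    the sequence (and multiset) of dose levels is unchanged — only the
    timing shifts.  Framed clinically: a short breather before reductions
    continue, easing the hospital-to-community transition.
    """
    if grace_days <= 0:
        raise ValidationError(f"grace_days must be > 0, got {grace_days}")
    if not 0 <= discharge_day <= plan.last_day:
        raise ValidationError(
            f"discharge_day {discharge_day} outside plan span [0, {plan.last_day}]"
        )
    old = list(zip(plan.reduction_days, [plan.steps[d].fixed_ome for d in plan.reduction_days]))
    shifted = [
        (day + grace_days if day > discharge_day else day, dose) for day, dose in old
    ]
    if shifted == old:
        return plan
    steps = _densify(
        plan.baseline_ome,
        shifted,
        plan.policy.target_ome,
        plan.policy.backup_fraction * plan.baseline_ome,
    )
    policy = replace(plan.policy, grace_days=grace_days)
    return TaperPlan(steps=tuple(steps), baseline_ome=plan.baseline_ome, policy=policy, plan_id=plan.plan_id)


def build_plan(case: PatientCase, formulary: Formulary, policy: Optional[TaperPolicy] = None) -> TaperPlan:
    """End-to-end convenience: baseline -> policy -> plan -> grace period."""
    baseline = baseline_from_24h(case, formulary)
    if policy is None:
        policy = select_policy(case, baseline)
    plan = generate_taper(baseline, policy, plan_id=plan_id_for(case))
    if case.discharge_day is not None and policy.grace_days > 0:
        if case.discharge_day <= plan.last_day:
            plan = apply_grace_period(plan, case.discharge_day, policy.grace_days)
    return plan


def tiered_taper(
    maintenance_ome: float,
    current_ome: float,
    acute_policy: TaperPolicy = ACUTE_POLICY,
    chronic_policy: Optional[TaperPolicy] = None,
) -> TaperPlan:
    """Two-phase taper for chronic users with an acute pain episode.

    Phase 1 removes the acute *excess* (current − maintenance) rapidly:
    Δ₁ = ``acute_policy.reduction_fraction × excess`` at acute intervals,
    down to the maintenance dose.  Phase 2, if a chronic policy with a
    lower target is supplied, continues from maintenance toward that
    target under the chronic policy (Δ₂ = fraction × maintenance).  The
    concatenated trajectory is non-increasing and continuous at the
    boundary.
    """
    if current_ome <= maintenance_ome:
        raise ValidationError(
            f"current dose {current_ome} must exceed maintenance {maintenance_ome}"
        )
    if maintenance_ome <= 0:
        raise ValidationError("maintenance_ome must be > 0")
    excess = current_ome - maintenance_ome
    delta1 = acute_policy.reduction_fraction * excess
    phase1 = _linear_schedule(
        current_ome, maintenance_ome, delta1,
        acute_policy.first_reduction_day, acute_policy.step_interval_days,
    )
    reductions = list(phase1)
    final_target = maintenance_ome
    if chronic_policy is not None and chronic_policy.target_ome < maintenance_ome - _EPS:
        final_target = chronic_policy.target_ome
        boundary_day = phase1[-1][0]
        delta2 = chronic_policy.reduction_fraction * maintenance_ome
        phase2 = _linear_schedule(
            maintenance_ome, chronic_policy.target_ome, delta2,
            boundary_day + chronic_policy.step_interval_days, chronic_policy.step_interval_days,
        )
        reductions += phase2
    steps = _densify(
        current_ome, reductions, final_target, acute_policy.backup_fraction * current_ome
    )
    policy = replace(acute_policy, target_ome=final_target)
    return TaperPlan(steps=tuple(steps), baseline_ome=current_ome, policy=policy, plan_id="tiered")


def backup_dose(baseline_ome: float, fraction: float = BACKUP_FRACTION_DEFAULT) -> float:
    """Back-up (rescue) allowance: ``fraction × baseline``, fraction in [1/10, 1/6]."""
    if baseline_ome <= 0:
        raise ValidationError("baseline_ome must be > 0")
    if not BACKUP_FRACTION_MIN - _EPS <= fraction <= BACKUP_FRACTION_MAX + _EPS:
        raise ValidationError(f"back-up fraction must lie in [1/10, 1/6], got {fraction}")
    return fraction * baseline_ome
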