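"""Map exact computed daily doses onto administrable tablet regimens.

A taper engine that outputs 37.5 mg/day is useless at the bedside unless
37.5 mg can actually be dispensed.  This module packs a daily dose into
commercially available strengths, minimizing pill burden (total unit
count) subject to a relative deviation tolerance, and distributes the
units over fixed clock-time slots — fixed times rather than "every 8
hours", per patient feedback.

Any residual deviation from the prescribed dose is surfaced in the output
(``achieved_mg``), never silently rounded away; if no combination lands
within tolerance the mapper raises, listing the nearest achievable totals.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import InfeasibleRegimenError, ValidationError
from .formulary import OpioidSpec

#: maximum total daily units considered; beyond this, pill burden itself
#: defeats the purpose of the regimen
MAX_UNITS = 8

_EPS = 1e-9

#: fixed administration clock times by slot count (patient-preferred
#: explicit times; 2 slots = morning/evening, etc.)
DEFAULT_SLOT_TIMES: dict[int, tuple[tuple[str, str], ...]] = {
    1: (("08:00", "morning"),),
    2: (("08:00", "morning"), ("20:00", "evening")),
    3: (("08:00", "morning"), ("14:00", "afternoon"), ("20:00", "evening")),
    4: (("08:00", "morning"), ("12:00", "midday"), ("16:00", "afternoon"), ("20:00", "evening")),
}


@dataclass(frozen=True)
class AdministrationSlot:
    clock_time: str
    label: str = ""

    def __post_init__(self):
        parts = self.clock_time.split(":")
        ok = (
            len(parts) == 2
            and parts[0].isdigit() and parts[1].isdigit()
            and 0 <= int(parts[0]) <= 23 and 0 <= int(parts[1]) <= 59
            and len(parts[0]) == 2 and len(parts[1]) == 2
        )
        if not ok:
            raise ValidationError(f"clock_time must be a valid HH:MM string, got {self.clock_time!r}")


@dataclass(frozen=True)
class FormulationAssignment:
    """Units to take at one slot: [(strength_mg, count), ...]."""

    slot: AdministrationSlot
    units: tuple[tuple[float, int], ...]
    achieved_mg: float
    with_food: Optional[bool] = None

    def __post_init__(self):
        object.__setattr__(self, "units", tuple((float(s), int(c)) for s, c in self.units))
        for strength, count in self.units:
            if count < 1:
                raise ValidationError("unit counts must be positive integers")
            if strength <= 0:
                raise ValidationError("strengths must be positive")
        total = sum(s * c for s, c in self.units)
        if abs(total - self.achieved_mg) > 1e-6:
            raise ValidationError(
                f"achieved_mg {self.achieved_mg} inconsistent with units (sum {total})"
            )


def _enumerate_multisets(strengths: Sequence[float], max_units: int):
    """Yield (counts, total_mg, n_units) for every multiset with <= max_units units."""
    n = len(strengths)

    def rec(i: int, counts: list[int], used: int):
        if i == n:
            yield tuple(counts), sum(c * s for c, s in zip(counts, strengths)), used
            return
        for c in range(0, max_units - used + 1):
            counts[i] = c
            yield from rec(i + 1, counts, used + c)
        counts[i] = 0

    yield from rec(0, [0] * n, 0)


def _split_units_lpt(unit_list: list[float], n_slots: int) -> list[list[float]]:
    """Longest-processing-time split of units across slots, balancing mg.

    Deterministic: units sorted descending, each placed on the currently
    lightest slot (lowest index on ties).
    """
    slots: list[list[float]] = [[] for _ in range(n_slots)]
    loads = [0.0] * n_slots
    for u in sorted(unit_list, reverse=True):
        i = min(range(n_slots), key=lambda j: (loads[j], j))
        slots[i].append(u)
        loads[i] += u
    return slots


def _unevenness(counts: tuple[int, ...], strengths: Sequence[float], n_slots: int) -> float:
    unit_list = [s for s, c in zip(strengths, counts) for _ in range(c)]
    loads = [sum(slot) for slot in _split_units_lpt(unit_list, n_slots)]
    return max(loads) - min(loads)


def map_daily_dose(
    dose_mg: float,
    drug: OpioidSpec,
    n_slots: int = 2,
    tolerance: float = 0.15,
    single_strength: bool = False,
    max_units: int = MAX_UNITS,
) -> list[FormulationAssignment]:
    """Pack a daily dose into available strengths across ``n_slots`` slots.

    Returns the assignment minimizing total unit count subject to
    ``|achieved − dose| <= tolerance × dose``.  Ties are broken by (a)
    preferring not to exceed the prescribed dose (under-dosing is the safe
    direction when deprescribing), then (b) fewer distinct strengths, then
    (c) the more even mg split across slots.  ``single_strength=True``
    restricts the search to one strength (simplified regimens for
    cognitively impaired patients).  A dose of 0 returns an empty list.

    Raises :class:`InfeasibleRegimenError` when nothing lands within
    tolerance, listing the nearest achievable daily totals.
    """
    if dose_mg < 0:
        raise ValidationError(f"dose_mg must be >= 0, got {dose_mg}")
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    if n_slots not in DEFAULT_SLOT_TIMES:
        raise ValidationError(f"n_slots must be in {sorted(DEFAULT_SLOT_TIMES)}, got {n_slots}")
    if not drug.formulations:
        raise ValidationError(f"{drug.name!r} has no formulations to map onto")
    if dose_mg == 0:
        return []

    # safety guard: extended-release units must be >= 8 h apart; the fixed
    # 3- and 4-slot grids are closer than that
    releases = {f.release for f in drug.formulations}
    if n_slots >= 3 and releases == {"extended"}:
        raise InfeasibleRegimenError(
            f"{drug.name!r} has only extended-release formulations, which cannot "
            f"be given at {n_slots} slots < 8 h apart; use 1-2 slots"
        )

    strengths = drug.strengths_mg
    tol_abs = tolerance * dose_mg
    best = None
    best_key = None
    achievable: set[float] = set()
    for counts, total, n_units in _enumerate_multisets(strengths, max_units):
        if n_units == 0:
            continue
        achievable.add(total)
        n_distinct = sum(1 for c in counts if c > 0)
        if single_strength and n_distinct > 1:
            continue
        if abs(total - dose_mg) > tol_abs + _EPS:
            continue
        key = (
            n_units,
            0 if total <= dose_mg + _EPS else 1,
            n_distinct,
            round(_unevenness(counts, strengths, n_slots), 9),
            round(abs(total - dose_mg), 9),
            counts,  # deterministic final tie-break
        )
        if best_key is None or key < best_key:
            best, best_key = counts, key
    if best is None:
        nearest = sorted(achievable, key=lambda t: (abs(t - dose_mg), t))[:4]
        raise InfeasibleRegimenError(
            f"no combination of {drug.name!r} strengths {list(strengths)} achieves "
            f"{dose_mg:g} mg within ±{tolerance:.0%}"
            + (" under a single strength" if single_strength else "")
            + f"; nearest achievable daily totals: {[f'{t:g}' for t in nearest]}",
            nearest=tuple(nearest),
        )

    unit_list = [s for s, c in zip(strengths, best) for _ in range(c)]
    split = _split_units_lpt(unit_list, n_slots)
    slot_defs = DEFAULT_SLOT_TIMES[n_slots]
    assignments = []
    for (clock, label), units in zip(slot_defs, split):
        if not units:
            continue
        grouped: dict[float, int] = {}
        for u in units:
            grouped[u] = grouped.get(u, 0) + 1
        pairs = tuple(sorted(grouped.items(), reverse=True))
        assignments.append(
            FormulationAssignment(
                slot=AdministrationSlot(clock, label),
                units=pairs,
                achieved_mg=sum(units),
            )
        )
    return assignments


def total_achieved(assignments: Sequence[FormulationAssignment]) -> float:
    return sum(a.achieved_mg for a in assignments)


def distinct_strengths(assignments: Sequence[FormulationAssignment]) -> set[float]:
    return {s for a in assignments for s, _ in a.units}


def simplify_regimen(
    assignments: Sequence[FormulationAssignment],
    drug: OpioidSpec,
    dose_mg: float,
    tolerance: float = 0.15,
    n_slots: Optional[int] = None,
) -> list[FormulationAssignment]:
    """Re-solve a regimen under the single-strength constraint.

    Intended for cognitively impaired patients where mixing strengths
    invites intake errors.  Returns the input unchanged if it already uses
    one strength; raises (recommending a relaxed tolerance) if no single
    strength fits.
    """
    if not assignments:
        raise ValidationError("cannot simplify an empty regimen")
    if len(distinct_strengths(assignments)) <= 1:
        return list(assignments)
    if n_slots is None:
        n_slots = len(assignments)
    try:
        return map_daily_dose(
            dose_mg, drug, n_slots=n_slots, tolerance=tolerance, single_strength=True
        )
    except InfeasibleRegimenError as exc:
        raise InfeasibleRegimenError(
            f"{exc}; consider relaxing the tolerance (currently {tolerance:.0%})",
            nearest=exc.nearest,
        ) from exc


def regimen_markdown(assignments: Sequence[FormulationAssignment], drug: OpioidSpec) -> str:
    """Render a regimen as a Markdown table (slot, units, achieved mg)."""
    lines = [
        "| Time | Units | Dose (mg) |",
        "|------|-------|-----------|",
    ]
    for a in assignments:
        units = " + ".join(f"{c} × {s:g} mg" for s, c in a.units)
        lines.append(f"| {a.slot.clock_time} | {units} {drug.name} | {a.achieved_mg:g} |")
    lines.append(f"| **total** | | **{total_achieved(assignments):g}** |")
    return "\n".join(lines) + "\n"


def regimen_csv(assignments: Sequence[FormulationAssignment]) -> str:
    lines = ["slot,strength_mg,count,achieved_mg"]
    for a in assignments:
        for s, c in a.units:
            lines.append(f"{a.slot.clock_time},{s:g},{c},{a.achieved_mg:g}")
    return "\n".join(lines) + "\n"
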