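"""Seeded synthetic inputs for every consumer in the toolkit.

Patient cases emulate the case mix the taper engine is designed for:
acute and chronic pain, naive and chronic users, last-24-hour baselines of
20–120 mg-OME split between fixed and back-up consumption.  Delphi panels
emulate the statistical structure the consensus rule assumes: a planted
subset of items on which respondents agree with high probability, the
rest rated without agreement, and a second round that perturbs unchanged
items slightly.  Every generator is bit-reproducible under a fixed seed
via a single explicit :class:`numpy.random.Generator` — no global state.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import DelphiDataset
from .errors import ValidationError
from .formulary import Formulary
from .taper import ConsumptionEntry, EntryKind, OpioidStatus, PainType, PatientCase


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic generators.

    Panel defaults mirror a mid-sized single-institution Delphi: 13
    respondents rating 49 items on a 7-point scale.  ``consensus_strength``
    is the probability a respondent rates a planted item at/above the
    agreement cut; ``offplant_strength`` the same for non-planted items.
    """

    seed: int = 0
    n_patients: int = 12
    n_respondents: int = 13
    n_items: int = 49
    planted_consensus_items: frozenset[int] = frozenset()
    consensus_strength: float = 0.95
    offplant_strength: float = 0.30
    round2_perturbation: float = 0.15
    missing_rate: float = 0.0

    def __post_init__(self):
        for name in ("consensus_strength", "offplant_strength", "round2_perturbation", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 1 or self.n_respondents < 1 or self.n_items < 1:
            raise ValidationError("n_patients, n_respondents, n_items must be positive")
        object.__setattr__(self, "planted_consensus_items", frozenset(self.planted_consensus_items))
        if any(not 0 <= i < self.n_items for i in self.planted_consensus_items):
            raise ValidationError("planted_consensus_items must be item indices in [0, n_items)")


def make_patient_cases(spec: FixtureSpec, formulary: Formulary) -> list[PatientCase]:
    """Generate a deterministic mixed list of patient cases.

    Baselines (total last-24-h OME) are drawn uniformly in 20–120 mg-OME
    and split ~85/15 between a fixed and a back-up entry; chronic users
    get a prehospital dose strictly below the baseline.
    """
    rng = np.random.default_rng(spec.seed)
    drugs = formulary.names()
    backup_drugs = tuple(
        n for n in drugs if formulary[n].is_backup_suitable
    ) or drugs
    cases = []
    for _ in range(spec.n_patients):
        pain = PainType.ACUTE if rng.random() < 0.5 else PainType.CHRONIC
        status = OpioidStatus.NAIVE if rng.random() < 0.5 else OpioidStatus.CHRONIC_USER
        baseline = float(rng.uniform(20.0, 120.0))
        fixed_frac = float(rng.uniform(0.80, 0.95))
        fixed_drug = str(rng.choice(drugs))
        backup_drug = str(rng.choice(backup_drugs))
        entries = (
            ConsumptionEntry(
                fixed_drug,
                baseline * fixed_frac / formulary[fixed_drug].ome_factor,
                EntryKind.FIXED,
            ),
            ConsumptionEntry(
                backup_drug,
                baseline * (1 - fixed_frac) / formulary[backup_drug].ome_factor,
                EntryKind.BACKUP,
            ),
        )
        prehospital = 0.0
        if status is OpioidStatus.CHRONIC_USER:
            prehospital = float(rng.uniform(0.1, 0.5) * baseline)
        discharge = int(rng.integers(1, 4)) if rng.random() < 0.5 else None
        cases.append(
            PatientCase(
                opioid_status=status,
                pain_type=pain,
                last24h=entries,
                prehospital_ome=prehospital,
                discharge_day=discharge,
                pain_stable_hours=float(rng.choice([24.0, 48.0, 72.0])),
                cognitive_impairment=bool(rng.random() < 0.1),
            )
        )
    return cases


def make_delphi_panel(spec: FixtureSpec) -> DelphiDataset:
    """Generate a two-round Likert panel with planted consensus structure.

    Round 1: on planted items each respondent rates in {5, 6, 7} with
    probability ``consensus_strength`` and in {1..4} otherwise; non-planted
    items use ``offplant_strength``.  Round 2 re-draws reworded items
    (``item_changed`` = not planted) and perturbs unchanged items by ±1
    with probability ``round2_perturbation`` (clipped to the scale), so a
    perturbation of 0 reproduces round 1 exactly on unchanged items.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []

    def draw(p_agree: float) -> int:
        if rng.random() < p_agree:
            return int(rng.integers(5, 8))
        return int(rng.integers(1, 5))

    round1 = np.zeros((spec.n_respondents, spec.n_items), dtype=float)
    for item in range(spec.n_items):
        p = spec.consensus_strength if item in spec.planted_consensus_items else spec.offplant_strength
        for resp in range(spec.n_respondents):
            round1[resp, item] = draw(p)

    round2 = round1.copy()
    for item in range(spec.n_items):
        changed = item not in spec.planted_consensus_items
        p = spec.consensus_strength if not changed else spec.offplant_strength
        for resp in range(spec.n_respondents):
            if changed:
                round2[resp, item] = draw(p)
            elif rng.random() < spec.round2_perturbation:
                step = -1 if rng.random() < 0.5 else 1
                round2[resp, item] = float(np.clip(round1[resp, item] + step, 1, 7))

    for rnd, mat in ((1, round1), (2, round2)):
        for resp in range(spec.n_respondents):
            for item in range(spec.n_items):
                rating: float = mat[resp, item]
                if spec.missing_rate and rng.random() < spec.missing_rate and resp > 0:
                    rating = np.nan  # respondent 0 always answers: no all-missing items
                rows.append(
                    {
                        "respondent_id": f"r{resp:02d}",
                        "item_id": f"item{item:02d}",
                        "round": rnd,
                        "rating": rating,
                        "item_changed": item not in spec.planted_consensus_items,
                    }
                )
    return DelphiDataset(ratings=pd.DataFrame(rows))


def default_planted_items(n_planted: int = 43, n_items: int = 49) -> frozenset[int]:
    """First ``n_planted`` item indices; 43/49 mirrors a first Delphi round
    in which six items miss consensus and go back for rewording."""
    if n_planted > n_items:
        raise ValidationError("cannot plant more items than exist")
    return frozenset(range(n_planted))
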