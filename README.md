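# oeptools

An **opioid exit plan (OEP) toolkit**: generates individualized, linear
opioid dose-reduction schedules for patients started on opioids in
hospital, plus the supporting pieces a deprescribing service needs —
equianalgesic rotation with incomplete cross-tolerance, conversion of
exact doses into administrable tablet regimens, a patient-facing handout,
and the consensus / reliability / readability statistics used when such
frameworks are built and validated.

It is written for hospital pharmacists, prescribers, and researchers
building opioid stewardship tooling. It is a calculation library with a
thin CLI, not a medical device: every output is a proposal to be reviewed
by a clinician.

## The model

All doses are compared on the **oral morphine equivalent (OME)** scale,
`ome_mg = dose_mg × factor(drug)`, with per-drug factors loaded from a
versioned table (a CDC oral-route table ships as package data).

**Taper schedules are linear.** From a stabilized baseline `B` (the
patient's total fixed + back-up consumption over the last 24 h, in
mg-OME), each reduction removes a constant step

```
Δ = f · B,    dose after r reductions = max(B − r·Δ, target)
```

so a fraction `f = 0.25` reaches the target in exactly
`ceil((B − target)/Δ)` = 4 reductions from any baseline (target 0). This
is deliberately *not* a percent-of-current-dose (compounding) taper, which
would never terminate. Two presets are shipped:

| preset  | step | interval | typical use |
|---------|------|----------|-------------|
| acute   | 25% of baseline | every 2nd day | opioid-naive, acute pain |
| chronic | 10% of baseline | every 3rd day | chronic pain, long exposure |

The target is 0 for opioid-naive patients and the prehospitalization dose
for chronic users. A 2-day **grace period** at discharge holds the
current dose before reductions continue; a **tiered taper** removes a
chronic user's acute excess rapidly before resuming the gradual plan.
A back-up (rescue) allowance of 1/10–1/6 of the baseline (default 1/8)
is carried until the target is reached. When rotating opioids the new
drug starts at 30%, 50%, or 100% of the equianalgesic dose to respect
incomplete cross-tolerance.

Exact daily doses are then packed into commercially available tablet
strengths (minimum pill count within a ±15% default tolerance, deviation
always surfaced, under-dosing preferred on ties) at fixed clock times.

The `consensus` module implements the Delphi consensus rule (≥80% of
respondents at/above the agreement cut **and** mean ≥ 4.5 on a 7-point
scale), round-to-round stability as Pearson or ICC(A,1) with F-based
confidence intervals, percent agreement and the Brennan–Prediger
coefficient `(P_o − 1/q)/(1 − 1/q)`; the `handout` module implements
Flesch Reading Ease (English) and the Amstad recalibration (German).

## Worked example

```python
import oeptools as o

f = o.default_formulary()
case = o.PatientCase(
    opioid_status="naive", pain_type="acute",
    last24h=[o.ConsumptionEntry("morphine", 40, "fixed"),
             o.ConsumptionEntry("morphine", 10, "backup")],
    pain_stable_hours=48,
)
baseline = o.baseline_from_24h(case, f)          # 50.0 mg-OME
plan = o.generate_taper(baseline, o.ACUTE_POLICY, "plan3")
print([(s.day, s.fixed_ome) for s in plan.steps])
```

prints

```
[(0, 50.0), (1, 37.5), (2, 37.5), (3, 25.0), (4, 25.0), (5, 12.5), (6, 12.5), (7, 0.0)]
```

— baseline 50 mg-OME on day 0, four 12.5 mg reductions on days 1, 3, 5
and 7, cessation on day 7. With a discharge on day 1 and the 2-day grace
period (`o.apply_grace_period(plan, 1, 2)`), the 37.5 mg level is held
through day 4 and the plan ends on day 9 with the same dose levels.
Rotating instead to oxycodone
(`o.rotate_dose("morphine", 60, "oxycodone", o.PRESET_SCHEMES[1], f)`)
gives 20.0 mg/24 h — 60 OME → 40 mg equianalgesic oxycodone × 0.5
cross-tolerance.

The same pipeline from the shell:

```sh
oep plan --patient case.json --out out/
oep rotate --from-drug morphine --from-dose 60 --to-drug oxycodone --out rot/
oep formulate --drug morphine --dose 37.5
oep handout --plan out/plan.json --drug morphine --tolerance 0.25 --out handout.md
oep fixtures --seed 1 --out fx/ && oep delphi --ratings fx/delphi_ratings.csv
```

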