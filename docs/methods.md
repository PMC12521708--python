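# Methods

This note documents the models and numerical choices behind `oeptools`,
the assumptions they rest on, and what the synthetic test data does and
does not establish.

## Dose scale and conversion

Every computation runs on the oral morphine equivalent (OME) scale:
`ome_mg = dose_mg × factor(drug)`, factors loaded from a versioned table.
Oral morphine anchors the scale (factor exactly 1.0, enforced as an
invariant). Only the oral route is supported; parenteral and transdermal
conversion, and methadone's dose-dependent nonlinear ratio, are out of
scope (a rotation request naming methadone triggers a warning).

The shipped table uses the CDC oral-route factors (2016 guideline
edition; the 2022 edition revises some entries) with tablet strengths
typical of the Swiss/European market. The table is configuration, not
code: correctness is defined relative to whatever table is loaded, and
the test suite uses explicit fixture factors so no test depends on the
shipped values.

Doses are carried as exact reals (mg-OME per 24 h) through the taper and
rotation stages; rounding to administrable units happens once, at the
formulation-mapping stage.

## Taper model

A taper is parameterized by `(f, s, g, d₁, T, b)`:

* `f` — reduction fraction ∈ (0, 1]; presets 0.25 (acute) and 0.10
  (chronic), within the clinically endorsed 5–25% band;
* `s` — stabilization interval in days between reductions; presets 2
  (acute) and 3 (chronic);
* `g` — grace days around discharge (2 when a discharge day is known);
* `d₁` — day of the first reduction (default 1; day 0 establishes the
  baseline);
* `T` — target dose in mg-OME (0 = cessation for naive patients, the
  prehospitalization dose for chronic users);
* `b` — back-up allowance fraction ∈ [1/10, 1/6], default 1/8.

**Linearity.** The step removed at each reduction is the constant
`Δ = f·B` where `B` is the post-stabilization baseline — *not* `f` times
the current dose. The dose after `r` reductions is `max(B − r·Δ, T)`,
reductions land on days `d₁ + k·s`, and the plan ends the first day the
dose equals `T`, after `ceil((B − T)/Δ)` reductions. Consequences worth
stating: the trajectory is a straight line in time; a 25% taper always
takes 4 reductions to zero and a 10% taper 10, regardless of baseline;
and when `(B − T)` is not a multiple of `Δ` the final step is smaller
(clamped — the plan lands exactly on `T`, never below).

**Baseline.** The sum of *all* last-24-hour consumption, fixed and
back-up alike, converted to OME. Back-up use is part of the patient's
actual requirement; ignoring it would start the taper below where the
patient really is.

**Stabilization predicate.** The qualitative entry criterion ("stable
pain, minimal back-up use for 24–48 h") is parameterized with defaults:
pain stable ≥ 48 h (the window cannot be configured below 24 h), back-up
OME ≤ 10% of the fixed dose, and ≤ 2 back-up doses in the window. These
defaults are documented choices, not evidence-derived constants, and all
three are arguments.

**Grace period.** Every reduction scheduled strictly *after* the
discharge day is delayed by `g` days; the dose in effect on the discharge
day is held for the extra days. This preserves the multiset and order of
dose levels — only timing shifts. The alternative reading (insert the
hold before the discharge day) was rejected because the clinical intent
is a pause *before reductions continue* in the community.

**Chronic start day.** The first chronic-preset reduction is day 1, like
the acute preset, with subsequent reductions on days 4, 7, …  The source
material fixes "every third day" but not the start; starting both presets
on day 1 keeps the four trajectories aligned at the left edge. The start
day is configurable (`first_reduction_day`).

**Tiered taper.** For chronic users with an acute excess: phase 1
removes the excess `E = current − maintenance` with step `f_acute·E` at
acute intervals (so it always takes `ceil(1/f_acute)` reductions); phase
2, if requested, continues from the maintenance dose toward the chronic
target with step `f_chronic·maintenance`, its first reduction one chronic
interval after the phase boundary. The trajectory is continuous at the
boundary by construction.

**Back-up allowance.** `b·B` throughout the taper, dropped to 0 the day
the fixed dose reaches target. It deliberately does not shrink with the
fixed dose — the allowance is framed as a fraction of the *initial* dose
for the whole reduction. The bracket [1/10, 1/6] is enforced at
validation; callers asking for 1/4 get an error, not a clamp.

## Rotation

`rotate_dose` composes the two exact conversions (drug A → OME → drug B)
and multiplies by the scheme's cross-tolerance fraction (presets 0.30,
0.50, 1.00; custom fractions in (0, 1] allowed). The fraction applies
*before* any formulation rounding. Mid-course switching is implemented
as re-anchoring: the remaining plan is regenerated from the dose in
effect on the switch day, guaranteeing dose continuity; alternatives
(e.g. splicing remaining steps proportionally) were rejected as harder
to explain to a patient.

## Formulation mapping

The mapper minimizes total unit count subject to
`|achieved − dose| ≤ tol·dose` (default tol = 0.15; the acceptable
deviation is a documented, configurable choice — the clinical sources
leave rounding "at discretion"). Ties are broken by (a) achieved ≤ dose
(under-dosing is the safe direction when deprescribing), then (b) fewer
distinct strengths, then (c) the more even mg split across slots, then a
deterministic lexicographic tie-break. The search enumerates all unit
multisets up to 8 total units (strength lists are short, so exhaustive
enumeration is exact and fast); tests verify it against an independently
written brute force. Units are distributed over fixed clock-time slots
(08:00/20:00 for 2 slots, etc.) by a deterministic longest-first
balancing pass. Note that minimizing units can prefer one larger tablet
over an exact two-tablet match (e.g. 1 × 60 mg for a 50 mg dose at
tol 0.25); the achieved dose is always displayed so the prescriber sees
the deviation. Infeasibility raises an error listing the nearest
achievable totals — never silent rounding. Extended-release-only drugs
are refused at ≥ 3 slots because the fixed slot grids are closer than
8 h apart. Degenerate input: dose 0 maps to an empty regimen.

## Handout

Markdown, deterministic (byte-identical for identical inputs), one
section per plan day: tablet counts at explicit HH:MM times (never
"every N hours"), the day's back-up allowance, and a food note; plus a
one-line normalization of pain spikes and a functional-goal line.
English and German strings are built in; the handout is a template for
clinical review, not finished patient prose.

## Readability

Two variants, never mixed: Flesch Reading Ease
`206.835 − 1.015·(W/S) − 84.6·(Y/W)` and the Amstad German recalibration
`180 − (W/S) − 58.5·(Y/W)`. Scores are only comparable within a
variant, so every report carries its variant. Counting rules are
documented data: sentences = whitespace tokens ending in `.!?` not on
the locale's abbreviation list (min 1); words = tokens with alphanumeric
content; syllables = maximal vowel-letter groups per word (locale vowel
sets include `y`, German adds `äöü`; German diphthongs merge by
adjacency; English drops a word-final silent `e` unless preceded by a
consonant + `l` or it is the only vowel group; min 1 per word). The
counts are heuristic approximations of linguistic units, chosen for
bit-exact reproducibility rather than linguistic perfection; deltas
between drafts report absolute and integer-rounded percent change.

## Consensus statistics

* **Item consensus** (7-point Likert): fraction of non-missing ratings at
  or above the agreement cut (default 5) must reach the proportion
  threshold (default 0.80) *and* the item mean must reach 4.5. The
  underlying rule statement is ambiguous about what the 80% applies to;
  this package reads it as 80% of respondents at/above the cut, with all
  three parameters (cut, proportion, mean threshold) exposed. Missing
  ratings are excluded pairwise, never imputed.
* **Round rate**: consensus items / items, percent reported to 1 decimal
  (decimal half-up rounding, matching how such percentages are printed).
* **Stability** between rounds is computed on unchanged items only,
  pairing per-item mean ratings, as either Pearson `r` (with its
  standard Fisher-z interval via `scipy.stats.pearsonr`) or ICC(A,1) —
  two-way random, single measure, absolute agreement — with the F-based
  interval; the implementation reproduces `pingouin`'s ICC(A,1) to 1e-9
  on random tables (checked in the test suite). Reports always name the
  estimator, since "inter-rater reliability" alone does not identify
  one. Identical rounds return exactly 1.0 with a collapsed interval;
  zero-variance item means raise an error naming the degenerate side.
  The stability threshold for closing a Delphi is 0.70.
* **Coder agreement**: raw percent agreement and Brennan–Prediger
  `κ = (P_o − 1/q)/(1 − 1/q)` (uniform-chance correction over `q`
  categories; approaches `P_o` as `q` grows, which is why the two
  reported numbers converge for fine coding trees).

## Synthetic data

The generators define the study conditions for all tests: Delphi panels
of 13 respondents × 49 items (round 2 = round 1 ± 1 with probability
0.15 on unchanged items; non-planted items are redrawn as "reworded"),
planted consensus probability 0.95 (0.30 off-plant), and patient cases
with baselines uniform in 20–120 mg-OME split ~85/15 fixed/back-up.
They reproduce the *statistical structure* the methods assume — they do
not emulate real rating psychology, correlated respondents, dropout,
or real consumption patterns (multi-drug regimens, PRN clustering).
Passing tests therefore establish algorithmic correctness, not clinical
validity on real data.

The acceptance script uses 120 random baselines, 50 random two-drug
formularies, and 200 random packing instances — sizes chosen so the
whole run completes in seconds while exercising each code path far past
the point where structural failures would surface.

## Known limitations

No pharmacokinetics (half-lives, organ-function adjustment is left to
the clinician via the reduction fraction); no route conversion; no
withdrawal-symptom prediction; no non-opioid analgesic scheduling; the
readability counts are heuristics and will disagree with dictionary-based
syllabifiers on loanwords; tablet splitting is never proposed.
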