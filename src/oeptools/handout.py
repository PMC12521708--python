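"""Patient-facing reduction-plan handout and readability metrics.

The handout turns a taper plan plus tablet regimens into a Markdown
document a patient can follow: explicit clock times (never "every N
hours"), a daily back-up allowance, food instructions, a plain-language
explanation that occasional pain spikes are normal, and a functional goal.
Output is deterministic — identical inputs yield byte-identical text.

The readability side implements the Flesch Reading Ease score in its
original English calibration and the Amstad recalibration for German.
The two scales are not interchangeable, so the variant is always carried
with the score.  Sentence/word/syllable counting is heuristic but fully
documented and bit-reproducible; the syllable rules (vowel sets,
diphthong merging, the English silent-e adjustment) live in module-level
constants so counts can be audited.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from .errors import ValidationError
from .formulation import FormulationAssignment
from .taper import TaperPlan

Variant = Literal["flesch_en", "amstad_de"]

# --------------------------------------------------------------------------
# text-unit counting rules (documented data, not code)

#: letters treated as vowels per locale ('y' is vocalic in both)
VOWELS = {
    "en": set("aeiouy"),
    "de": set("aeiouyäöü"),
}

#: tokens that end with '.' but do not terminate a sentence
ABBREVIATIONS = {
    "en": {"e.g.", "i.e.", "etc.", "vs.", "dr.", "mr.", "mrs.", "ms.", "approx.", "mg.", "no."},
    "de": {"z.b.", "bzw.", "ca.", "dr.", "evtl.", "ggf.", "inkl.", "usw.", "vgl.", "u.a.", "d.h.", "mg.", "nr."},
}

_WORD_STRIP = re.compile(r"^\W+|\W+$", re.UNICODE)
_TERMINATOR = re.compile(r"[.!?]+$")


def _syllables_in_word(word: str, locale: str) -> int:
    """Count syllables as maximal vowel-letter groups.

    English additionally drops a word-final silent 'e' (unless the word
    ends in consonant+'le', or the 'e' is the only vowel group).  German
    diphthongs (ei, ie, au, eu, äu, ...) are adjacent vowels and are
    already merged by the grouping rule.  Every word counts at least one
    syllable.
    """
    vowels = VOWELS[locale]
    letters = [c for c in word.lower() if c.isalpha()]
    if not letters:
        return 0
    groups = 0
    prev_vowel = False
    for c in letters:
        is_vowel = c in vowels
        if is_vowel and not prev_vowel:
            groups += 1
        prev_vowel = is_vowel
    if locale == "en" and groups > 1 and letters[-1] == "e":
        if not (len(letters) >= 2 and letters[-2] == "l" and (len(letters) < 3 or letters[-3] not in vowels)):
            groups -= 1
    return max(groups, 1)


def count_text_units(text: str, locale: str = "en") -> tuple[int, int, int]:
    """(sentences, words, syllables) for a plain-text document.

    Sentences: whitespace tokens ending in ``. ! ?`` whose lowercased form
    is not on the locale's abbreviation list (minimum 1 for non-empty
    text).  Words: tokens containing at least one letter or digit after
    stripping surrounding punctuation.  Syllables: summed per word via
    :func:`_syllables_in_word`.  Invariant to trailing whitespace and to
    line wrapping (all whitespace is equivalent).
    """
    if locale not in VOWELS:
        raise ValidationError(f"unsupported locale {locale!r}; expected one of {sorted(VOWELS)}")
    if not text or not text.strip():
        raise ValidationError("cannot count text units of empty text")
    tokens = text.split()
    abbrevs = ABBREVIATIONS[locale]
    sentences = 0
    words = 0
    syllables = 0
    for tok in tokens:
        if _TERMINATOR.search(tok) and tok.lower() not in abbrevs:
            sentences += 1
        core = _WORD_STRIP.sub("", tok)
        if core and any(c.isalnum() for c in core):
            words += 1
            syllables += _syllables_in_word(core, locale)
    sentences = max(sentences, 1)
    return sentences, words, syllables


@dataclass(frozen=True)
class ReadabilityReport:
    sentences: int
    words: int
    syllables: int
    score: float
    variant: Variant

    def to_dict(self) -> dict:
        return {
            "sentences": self.sentences,
            "words": self.words,
            "syllables": self.syllables,
            "score": self.score,
            "variant": self.variant,
        }


def flesch_score(counts: tuple[int, int, int], variant: Variant) -> float:
    """Reading-ease score from (sentences, words, syllables).

    ``flesch_en``: 206.835 − 1.015·(words/sentences) − 84.6·(syllables/words);
    ``amstad_de``: 180 − (words/sentences) − 58.5·(syllables/words).
    Higher = easier; ~40–50 corresponds to average newspaper prose on both
    scales.
    """
    sentences, words, syllables = counts
    if sentences < 1 or words < 1:
        raise ValidationError("flesch_score requires at least one sentence and one word")
    asl = words / sentences
    asw = syllables / words
    if variant == "flesch_en":
        return 206.835 - 1.015 * asl - 84.6 * asw
    if variant == "amstad_de":
        return 180.0 - asl - 58.5 * asw
    raise ValidationError(f"unknown variant {variant!r}")


def readability_report(text: str, locale: str = "de") -> ReadabilityReport:
    """Count units and score in one step; German uses the Amstad variant."""
    counts = count_text_units(text, locale)
    variant: Variant = "amstad_de" if locale == "de" else "flesch_en"
    return ReadabilityReport(*counts, score=flesch_score(counts, variant), variant=variant)


def readability_delta(
    before: ReadabilityReport, after: ReadabilityReport
) -> tuple[int, int, int, int, int, int]:
    """(Δsentences, %Δ, Δwords, %Δ, Δsyllables, %Δ) between two drafts.

    Percent change = 100·(after − before)/before, rounded to the nearest
    integer for display.  Both reports must use the same variant —
    deltas across scoring scales are meaningless.
    """
    if before.variant != after.variant:
        raise ValidationError(
            f"variant mismatch: {before.variant} vs {after.variant}"
        )
    out = []
    for b, a in (
        (before.sentences, after.sentences),
        (before.words, after.words),
        (before.syllables, after.syllables),
    ):
        out.append(a - b)
        out.append(round(100.0 * (a - b) / b))
    return tuple(out)  # type: ignore[return-value]


# --------------------------------------------------------------------------
# handout rendering

_STRINGS = {
    "en": {
        "title": "Your opioid reduction plan",
        "intro": (
            "This plan reduces your opioid dose step by step. Occasional pain "
            "spikes are normal during the reduction; your back-up medication "
            "is there for exactly these situations."
        ),
        "goal": "Your goal: stay active and keep doing your daily activities.",
        "day": "Day",
        "backup": "Back-up allowance (if needed)",
        "done": "Reduction complete. Continue only as agreed with your physician.",
        "with_food": "Take with food.",
        "without_food": "Take on an empty stomach.",
        "any_food": "May be taken with or without food.",
        "ome_note": "Doses shown as oral morphine equivalents (mg OME) unless a tablet count is given.",
    },
    "de": {
        "title": "Ihr Opioid-Reduktionsplan",
        "intro": (
            "Dieser Plan reduziert Ihre Opioid-Dosis Schritt für Schritt. "
            "Gelegentliche Schmerzspitzen sind normal; Ihre Reservemedikation "
            "ist genau für diese Situationen gedacht."
        ),
        "goal": "Ihr Ziel: aktiv bleiben und Ihre Alltagsaktivitäten fortführen.",
        "day": "Tag",
        "backup": "Reserve (bei Bedarf)",
        "done": "Reduktion abgeschlossen. Nur nach Absprache mit Ihrer Ärztin oder Ihrem Arzt fortfahren.",
        "with_food": "Mit dem Essen einnehmen.",
        "without_food": "Auf nüchternen Magen einnehmen.",
        "any_food": "Einnahme mit oder ohne Essen möglich.",
        "ome_note": "Dosen in oralen Morphinäquivalenten (mg OME), sofern keine Tablettenzahl angegeben ist.",
    },
}


def _food_note(assignments: Sequence[FormulationAssignment], strings: Mapping[str, str]) -> str:
    flags = {a.with_food for a in assignments}
    if flags == {True}:
        return strings["with_food"]
    if flags == {False}:
        return strings["without_food"]
    return strings["any_food"]


def render_handout(
    plan: TaperPlan,
    assignments_by_day: Mapping[int, Sequence[FormulationAssignment]],
    drug_name: str,
    locale: str = "en",
) -> str:
    """Render the day-by-day patient handout as Markdown.

    ``assignments_by_day`` must cover every day of the plan (an empty list
    is allowed only on days whose fixed dose is the target).  Times are
    explicit HH:MM clock times; the back-up allowance and a food note are
    printed per day.
    """
    if locale not in _STRINGS:
        raise ValidationError(f"unsupported locale {locale!r}; expected one of {sorted(_STRINGS)}")
    s = _STRINGS[locale]
    lines = [f"# {s['title']}", "", s["intro"], "", s["goal"], "", s["ome_note"], ""]
    for step in plan.steps:
        if step.day not in assignments_by_day:
            raise ValidationError(f"no formulation assignment provided for plan day {step.day}")
        assignments = assignments_by_day[step.day]
        lines.append(f"## {s['day']} {step.day}")
        if not assignments:
            if step.fixed_ome > plan.policy.target_ome + 1e-9:
                raise ValidationError(
                    f"day {step.day} has fixed dose {step.fixed_ome:g} but no assignments"
                )
            lines.append(s["done"])
        else:
            for a in assignments:
                units = " + ".join(f"{c} × {strength:g} mg" for strength, c in a.units)
                lines.append(f"- **{a.slot.clock_time}** — {units} {drug_name} ({a.achieved_mg:g} mg)")
            lines.append(f"- {_food_note(assignments, s)}")
        if step.backup_ome > 0:
            lines.append(f"- {s['backup']}: {step.backup_ome:g} mg OME")
        lines.append("")
    return "\n".join(lines)
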