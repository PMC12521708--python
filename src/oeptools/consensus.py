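"""Delphi consensus rule, round-to-round stability, and coder agreement.

Consensus on a 7-point Likert item requires *both* a supermajority of
respondents at or above the agreement cut (default: >= 80% rating >= 5)
and a mean rating of at least 4.5 ("partially agree").  Missing ratings
are excluded pairwise from the denominator, never imputed.

Stability between survey rounds is computed on unchanged items only
(items reworded between rounds are excluded), either as the Pearson
correlation of per-item mean ratings or as ICC(A,1) — the two-way,
single-measure, absolute-agreement intraclass correlation (McGraw & Wong
case 2A) with its F-based confidence interval.  A panel is considered
stable, and the Delphi can close, when the coefficient reaches 0.70.

Intercoder agreement for qualitative coding is reported as raw percent
agreement alongside the Brennan–Prediger coefficient
``kappa = (P_o − 1/q)/(1 − 1/q)``, which corrects for uniform chance over
``q`` categories.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

LIKERT_MIN, LIKERT_MAX = 1, 7

RATINGS_COLUMNS = ("respondent_id", "item_id", "round", "rating", "item_changed")


@dataclass
class DelphiDataset:
    """Long-format Likert ratings: respondent × item × round.

    ``ratings`` columns: respondent_id, item_id, round (1 or 2), rating
    (1..7 or NaN for missing), item_changed (bool: reworded between
    rounds).
    """

    ratings: pd.DataFrame

    def __post_init__(self):
        missing = set(RATINGS_COLUMNS) - set(self.ratings.columns)
        if missing:
            raise ValidationError(f"ratings table missing columns: {sorted(missing)}")
        vals = self.ratings["rating"].dropna()
        if not vals.between(LIKERT_MIN, LIKERT_MAX).all():
            raise ValidationError(f"ratings must lie in [{LIKERT_MIN}, {LIKERT_MAX}] or be missing")
        if not self.ratings["round"].isin([1, 2]).all():
            raise ValidationError("round must be 1 or 2")
        changed = self.ratings.groupby("item_id")["item_changed"].nunique()
        if (changed > 1).any():
            bad = changed[changed > 1].index.tolist()
            raise ValidationError(f"items with inconsistent item_changed flags: {bad}")

    @property
    def items(self) -> list:
        return sorted(self.ratings["item_id"].unique())

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_respondents(self) -> int:
        return self.ratings["respondent_id"].nunique()

    def item_changed(self, item_id) -> bool:
        rows = self.ratings.loc[self.ratings["item_id"] == item_id, "item_changed"]
        if rows.empty:
            raise ValidationError(f"unknown item {item_id!r}")
        return bool(rows.iloc[0])

    def item_ratings(self, item_id, round: int) -> np.ndarray:
        mask = (self.ratings["item_id"] == item_id) & (self.ratings["round"] == round)
        return self.ratings.loc[mask, "rating"].to_numpy(dtype=float)

    def item_means(self, round: int, unchanged_only: bool = False) -> pd.Series:
        df = self.ratings[self.ratings["round"] == round]
        if unchanged_only:
            df = df[~df["item_changed"]]
        return df.groupby("item_id")["rating"].mean()

    # -- IO --------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "DelphiDataset":
        df = pd.read_csv(path)
        if "item_changed" in df.columns:
            df["item_changed"] = df["item_changed"].astype(bool)
        return cls(ratings=df)

    def to_csv(self, path: str | Path) -> None:
        self.ratings.to_csv(path, index=False)


@dataclass(frozen=True)
class ItemConsensus:
    consensus: bool
    prop_agree: float
    mean_rating: float


@dataclass(frozen=True)
class RoundConsensus:
    k_consensus: int
    n_items: int
    percent: float  # 100·k/n rounded to 1 decimal
    per_item: dict = field(default_factory=dict, hash=False, compare=False)


def item_consensus(
    ratings: Sequence[float] | np.ndarray,
    agree_cut: int = 5,
    prop_threshold: float = 0.80,
    mean_threshold: float = 4.5,
) -> ItemConsensus:
    """Apply the consensus rule to one item's ratings.

    ``prop_agree`` is the fraction of non-missing ratings at or above
    ``agree_cut`` (default 5, the first clearly-agree point on the 7-point
    scale); consensus requires ``prop_agree >= prop_threshold`` *and*
    mean rating ``>= mean_threshold``.
    """
    arr = np.asarray(ratings, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValidationError("item has no non-missing ratings")
    if ((arr < LIKERT_MIN) | (arr > LIKERT_MAX)).any():
        raise ValidationError(f"ratings must lie in [{LIKERT_MIN}, {LIKERT_MAX}]")
    prop = float(np.mean(arr >= agree_cut))
    mean = float(arr.mean())
    return ItemConsensus(
        consensus=(prop >= prop_threshold and mean >= mean_threshold),
        prop_agree=prop,
        mean_rating=mean,
    )


def round_consensus_rate(
    dataset: DelphiDataset,
    round: int = 1,
    agree_cut: int = 5,
    prop_threshold: float = 0.80,
    mean_threshold: float = 4.5,
) -> RoundConsensus:
    """Consensus rule applied to every item of one round."""
    if round not in set(dataset.ratings["round"]):
        raise ValidationError(f"round {round} not present in dataset")
    per_item = {
        item: item_consensus(
            dataset.item_ratings(item, round), agree_cut, prop_threshold, mean_threshold
        )
        for item in dataset.items
    }
    k = sum(1 for r in per_item.values() if r.consensus)
    n = len(per_item)
    return RoundConsensus(
        k_consensus=k,
        n_items=n,
        percent=round_half_up(100.0 * k / n, 1),
        per_item=per_item,
    )


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal-style rounding (0.05 -> 0.1) for reported percentages."""
    factor = 10.0 ** ndigits
    return np.floor(x * factor + 0.5) / factor


# --------------------------------------------------------------------------
# stability

def icc_a1(data: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(A,1): two-way random, single measure, absolute agreement.

    ``data`` is an n_subjects × k_raters matrix without missing values.
    Point estimate and the F-based confidence interval follow the
    standard two-way ANOVA decomposition (rows = subjects, columns =
    raters).  Degenerate inputs (zero residual variance, e.g. identical
    columns) return a collapsed interval at the point estimate.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3 or data.shape[1] < 2:
        raise ValidationError("icc_a1 needs an (n >= 3) x (k >= 2) matrix")
    if np.isnan(data).any():
        raise ValidationError("icc_a1 does not accept missing values")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise ValidationError("degenerate ratings: zero total variance across subjects")
    icc = (msr - mse) / denom
    if mse <= 1e-12 and msc <= 1e-12:
        # rounds identical: perfect absolute agreement, interval collapses
        return 1.0, 1.0, 1.0
    # McGraw & Wong (1996) case 2A single-measure interval
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a):
        return float(icc), float(icc), float(icc)
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den if v_den > 0 else 1.0
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), float(lower), float(upper)


def test_retest_stability(
    dataset: DelphiDataset,
    method: Literal["pearson", "icc_a1"] = "icc_a1",
    stability_threshold: float = 0.70,
) -> tuple[float, float, float, bool]:
    """Round-1 vs round-2 stability on unchanged items.

    Items reworded between rounds are excluded (their ratings measure the
    new wording, not stability).  Per-item mean ratings across respondents
    form the paired vectors.  Returns (coefficient, ci_low, ci_high,
    stable) where ``stable = coefficient >= stability_threshold``.
    """
    means1 = dataset.item_means(1, unchanged_only=True)
    means2 = dataset.item_means(2, unchanged_only=True)
    common = means1.index.intersection(means2.index)
    if len(common) < 3:
        raise ValidationError(
            f"need >= 3 unchanged items rated in both rounds, found {len(common)}"
        )
    x = means1.loc[common].to_numpy(dtype=float)
    y = means2.loc[common].to_numpy(dtype=float)
    if method == "pearson":
        if np.allclose(x, y):
            coef, lo, hi = 1.0, 1.0, 1.0
        else:
            if np.std(x) == 0 or np.std(y) == 0:
                side = "round 1" if np.std(x) == 0 else "round 2"
                raise ValidationError(f"zero variance in {side} item means; correlation undefined")
            res = stats.pearsonr(x, y)
            ci = res.confidence_interval()
            coef, lo, hi = float(res.statistic), float(ci.low), float(ci.high)
    elif method == "icc_a1":
        coef, lo, hi = icc_a1(np.column_stack([x, y]))
    else:
        raise ValidationError(f"unknown stability method {method!r}")
    return coef, lo, hi, coef >= stability_threshold


# --------------------------------------------------------------------------
# coder agreement

def percent_agreement(codes_a: Sequence, codes_b: Sequence) -> float:
    """Fraction of units assigned identical codes by two coders."""
    if len(codes_a) != len(codes_b):
        raise ValidationError(
            f"coding vectors differ in length: {len(codes_a)} vs {len(codes_b)}"
        )
    if len(codes_a) == 0:
        raise ValidationError("need at least one coded unit")
    return sum(a == b for a, b in zip(codes_a, codes_b)) / len(codes_a)


def brennan_prediger(codes_a: Sequence, codes_b: Sequence, q: int) -> float:
    """Brennan–Prediger chance-corrected agreement over ``q`` categories.

    ``kappa = (P_o − 1/q)/(1 − 1/q)``; range [−1/(q−1), 1].  Unlike
    Cohen's kappa the chance term is uniform over categories, so the
    coefficient approaches raw agreement as q grows.
    """
    if q < 2:
        raise ValidationError(f"q (number of categories) must be >= 2, got {q}")
    observed = set(codes_a) | set(codes_b)
    if len(observed) > q:
        raise ValidationError(f"{len(observed)} distinct codes observed but q={q}")
    p_o = percent_agreement(codes_a, codes_b)
    return (p_o - 1.0 / q) / (1.0 - 1.0 / q)


# --------------------------------------------------------------------------
# reporting

def consensus_report(dataset: DelphiDataset, **rule_kwargs) -> dict:
    """JSON-ready report: per-round consensus plus stability (both methods).

    Per-item means are reported with normal-theory 95% confidence
    intervals, matching the anonymized pooled feedback shown to
    respondents between rounds.
    """
    report: dict = {"n_items": dataset.n_items, "n_respondents": dataset.n_respondents, "rounds": {}}
    for rnd in sorted(set(dataset.ratings["round"])):
        rc = round_consensus_rate(dataset, rnd, **rule_kwargs)
        items = {}
        for item, res in rc.per_item.items():
            arr = dataset.item_ratings(item, rnd)
            arr = arr[~np.isnan(arr)]
            if arr.size > 1 and arr.std(ddof=1) > 0:
                half = stats.t.ppf(0.975, arr.size - 1) * arr.std(ddof=1) / np.sqrt(arr.size)
            else:
                half = 0.0
            items[str(item)] = {
                "consensus": res.consensus,
                "prop_agree": res.prop_agree,
                "mean": res.mean_rating,
                "ci95": [res.mean_rating - half, res.mean_rating + half],
            }
        report["rounds"][str(rnd)] = {
            "k_consensus": rc.k_consensus,
            "n_items": rc.n_items,
            "percent": rc.percent,
            "items": items,
        }
    if {1, 2} <= set(dataset.ratings["round"]):
        try:
            for method in ("pearson", "icc_a1"):
                coef, lo, hi, stable = test_retest_stability(dataset, method)  # type: ignore[arg-type]
                report.setdefault("stability", {})[method] = {
                    "coefficient": coef, "ci95": [lo, hi], "stable": stable,
                }
        except ValidationError as exc:
            report["stability"] = {"error": str(exc)}
    return report
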