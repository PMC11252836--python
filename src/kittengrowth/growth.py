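"""Growth-rate construction, Tukey-fence outlier screening, species-level
quartile groups, and the descriptive LBW vs NBW comparisons.

The relative growth rate between Day x and Day y is

    GR x-y = 100 * (w_y - w_x) / w_x   (percent of the Day-x weight),

computed for the five study intervals 0-1, 1-2, 0-2, 2-7 and 0-7, plus the
seven single-day rates. A kitten is dropped from analysis if any of its five
interval rates falls strictly outside the Tukey fences
[Q25 - m*IQR, Q75 + m*IQR] of that rate's species-level distribution; a
missing rate is never grounds for exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, KittenGrowthError
from .records import BwCategory, KittenRecord

#: The five study intervals (day x, day y).
INTERVALS: tuple[tuple[int, int], ...] = ((0, 1), (1, 2), (0, 2), (2, 7), (0, 7))
INTERVAL_NAMES: tuple[str, ...] = tuple(f"{a}-{b}" for a, b in INTERVALS)
#: Single-day intervals Day d -> d+1.
DAILY_NAMES: tuple[str, ...] = tuple(f"{d}-{d + 1}" for d in range(7))


def growth_rate(w_x: float, w_y: float) -> float:
    """Relative growth 100*(w_y - w_x)/w_x; negative when weight is lost."""
    if not (w_x > 0):
        raise KittenGrowthError(f"starting weight must be positive, got {w_x}")
    return 100.0 * (w_y - w_x) / w_x


@dataclass
class GrowthProfile:
    """Five interval growth rates plus daily rates for one kitten."""

    kitten_id: str
    gr: dict[str, float] = field(default_factory=dict)
    daily_gr: dict[str, float] = field(default_factory=dict)
    outlier_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def excluded(self) -> bool:
        return any(self.outlier_flags.values())


def compute_profile(record: KittenRecord) -> GrowthProfile:
    profile = GrowthProfile(kitten_id=record.kitten_id)
    for a, b in INTERVALS:
        wa, wb = record.weights.get(a), record.weights.get(b)
        if wa is not None and wb is not None:
            profile.gr[f"{a}-{b}"] = growth_rate(wa, wb)
    for d in range(7):
        wa, wb = record.weights.get(d), record.weights.get(d + 1)
        if wa is not None and wb is not None:
            profile.daily_gr[f"{d}-{d + 1}"] = growth_rate(wa, wb)
    return profile


def compute_profiles(records: Iterable[KittenRecord]) -> list[GrowthProfile]:
    return [compute_profile(rec) for rec in records]


def tukey_fences(values: Sequence[float], multiplier: float = 1.5) -> tuple[float, float]:
    """Outlier fences [Q25 - m*IQR, Q75 + m*IQR], linear-interpolation
    quantiles. Requires at least 4 values."""
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if arr.size < 4:
        raise InsufficientDataError(f"need >= 4 values for fences, got {arr.size}")
    q25, q75 = np.quantile(arr, [0.25, 0.75], method="linear")
    iqr = q75 - q25
    return float(q25 - multiplier * iqr), float(q75 + multiplier * iqr)


def flag_outliers(
    profiles: Sequence[GrowthProfile], multiplier: float = 1.5
) -> dict[str, tuple[float, float]]:
    """Set per-interval outlier flags in place, one species-level pass.

    Fences are computed on the pre-exclusion pooled distribution of each of
    the five interval rates; a value strictly outside its fences flags the
    kitten for that interval. Returns the fences per interval (intervals with
    under 4 observed values get no fences and never flag anyone).
    """
    fences: dict[str, tuple[float, float]] = {}
    for name in INTERVAL_NAMES:
        pooled = [p.gr[name] for p in profiles if name in p.gr]
        if len(pooled) < 4:
            continue
        fences[name] = tukey_fences(pooled, multiplier)
    for p in profiles:
        for name, (low, high) in fences.items():
            v = p.gr.get(name)
            p.outlier_flags[name] = v is not None and (v < low or v > high)
    return fences


def exclude_outlier_kittens(
    profiles: Sequence[GrowthProfile], multiplier: float = 1.5
) -> tuple[list[GrowthProfile], list[GrowthProfile]]:
    """Second selection round: drop kittens with an outlying value on any of
    the five rates. Missing values never exclude."""
    flag_outliers(profiles, multiplier)
    retained = [p for p in profiles if not p.excluded]
    excluded = [p for p in profiles if p.excluded]
    return retained, excluded


@dataclass(frozen=True)
class QuartileGrouping:
    """Species-level quartile breakpoints and the 1-4 group labels.

    Group 1: value <= Q1; group 2: Q1 < value <= Q2; group 3: Q2 < value
    <= Q3; group 4: value > Q3.
    """

    interval: str
    q1: float
    q2: float
    q3: float
    assignment: Mapping[str, int]

    def group_of(self, value: float) -> int:
        if value <= self.q1:
            return 1
        if value <= self.q2:
            return 2
        if value <= self.q3:
            return 3
        return 4


def quartile_groups(values: Mapping[str, float], interval: str = "") -> QuartileGrouping:
    """Quartile-group a kitten_id -> growth-rate mapping at species level."""
    vals = np.asarray(list(values.values()), dtype=float)
    if vals.size < 4:
        raise InsufficientDataError(f"need >= 4 values for quartiles, got {vals.size}")
    q1, q2, q3 = (float(q) for q in np.quantile(vals, [0.25, 0.5, 0.75], method="linear"))

    def group_of(v: float) -> int:
        return 1 if v <= q1 else 2 if v <= q2 else 3 if v <= q3 else 4

    assignment = {k: group_of(v) for k, v in values.items()}
    return QuartileGrouping(interval, q1, q2, q3, assignment)


# ---------------------------------------------------------------------------
# Welch comparison and effect size


@dataclass(frozen=True)
class EffectSize:
    cohens_d: float
    label: str

    @staticmethod
    def label_of(d: float) -> str:
        a = abs(d)
        if a < 0.2:
            return "negligible"
        if a < 0.5:
            return "small"
        if a < 0.8:
            return "medium"
        return "large"


def cohens_d(a: Sequence[float], b: Sequence[float]) -> EffectSize:
    """Cohen's d with the pooled-SD convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    d = float((a.mean() - b.mean()) / math.sqrt(sp2))
    return EffectSize(d, EffectSize.label_of(d))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    effect: EffectSize


def welch_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch two-sample t-test (Satterthwaite df, two-sided) plus Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, s in (("first", a), ("second", b)):
        if s.size < 2:
            raise InsufficientDataError(f"{name} sample needs n >= 2, got {s.size}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        # degenerate but well-defined: no evidence of any difference
        return WelchResult(0.0, float(a.size + b.size - 2), 1.0, EffectSize(0.0, "negligible"))
    if va == 0 and vb == 0:
        raise InsufficientDataError("both samples have zero variance")
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = float((a.mean() - b.mean()) / math.sqrt(se2))
    df = float(se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return WelchResult(t, df, p, cohens_d(a, b))


# ---------------------------------------------------------------------------
# Descriptive report


def _summary(vals: np.ndarray) -> dict:
    return {
        "n": int(vals.size),
        "mean": float(vals.mean()) if vals.size else math.nan,
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else math.nan,
    }


def describe_growth(
    profiles: Sequence[GrowthProfile],
    bw_categories: Mapping[str, BwCategory],
) -> dict:
    """Per-interval descriptive table: overall and per-category mean/SD/n,
    the Welch LBW-vs-NBW comparison with its effect-size label, the fraction
    of kittens that lost weight, plus daily-rate means with paired t-tests
    between consecutive days (pairwise-complete kittens).
    """
    report: dict = {"intervals": {}, "daily": {}}
    for name in INTERVAL_NAMES:
        rows = [(p.kitten_id, p.gr[name]) for p in profiles if name in p.gr]
        all_vals = np.asarray([v for _, v in rows], dtype=float)
        lbw = np.asarray(
            [v for k, v in rows if bw_categories.get(k) is BwCategory.LBW], dtype=float
        )
        nbw = np.asarray(
            [v for k, v in rows if bw_categories.get(k) is BwCategory.NBW], dtype=float
        )
        entry = {
            "all": _summary(all_vals),
            "LBW": _summary(lbw),
            "NBW": _summary(nbw),
            "negative_fraction": float((all_vals < 0).mean()) if all_vals.size else math.nan,
        }
        if lbw.size >= 2 and nbw.size >= 2:
            w = welch_test(lbw, nbw)
            entry["welch"] = {
                "t": w.t,
                "df": w.df,
                "p": w.p,
                "cohens_d": w.effect.cohens_d,
                "effect_label": w.effect.label,
            }
        report["intervals"][name] = entry

    daily_values = {
        name: {p.kitten_id: p.daily_gr[name] for p in profiles if name in p.daily_gr}
        for name in DAILY_NAMES
    }
    pooled = np.concatenate(
        [np.asarray(list(v.values()), dtype=float) for v in daily_values.values() if v]
        or [np.asarray([], dtype=float)]
    )
    report["daily"]["overall_mean"] = float(pooled.mean()) if pooled.size else math.nan
    report["daily"]["overall_sd"] = float(pooled.std(ddof=1)) if pooled.size > 1 else math.nan
    report["daily"]["per_day"] = {
        name: _summary(np.asarray(list(v.values()), dtype=float))
        for name, v in daily_values.items()
    }
    paired = {}
    for d in range(6):
        a_name, b_name = DAILY_NAMES[d], DAILY_NAMES[d + 1]
        common = sorted(set(daily_values[a_name]) & set(daily_values[b_name]))
        if len(common) >= 2:
            a = np.asarray([daily_values[a_name][k] for k in common])
            b = np.asarray([daily_values[b_name][k] for k in common])
            t, p = stats.ttest_rel(a, b)
            paired[f"{a_name} vs {b_name}"] = {
                "n": len(common),
                "t": float(t),
                "p": float(p),
                "cohens_d": cohens_d(a, b).cohens_d if a.var() + b.var() > 0 else 0.0,
            }
    report["daily"]["paired_tests"] = paired
    return report
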