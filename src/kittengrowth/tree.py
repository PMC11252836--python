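"""Cost-sensitive classification stumps and cross-validated growth-rate
alarm thresholds.

A threshold on one growth rate is derived as the split of a depth-1 CART on
that rate, with the 10:1 false-negative : false-positive cost matrix realized
as altered class priors: the death-class prior is inflated by the cost ratio
and renormalized, which for the Gini criterion is equivalent to weighting
every death ``fn_cost/fp_cost`` times a survivor. Candidate cutpoints are
midpoints between adjacent distinct sorted values; children smaller than
``min_leaf`` are inadmissible; criterion ties break toward the smallest
cutpoint.

The final alarm threshold is the median of the cutpoints fitted on the
training sides of a (by default stratified) k-fold partition, after which
screening performance (Se/Sp/PPV/NPV, mortality below/above, multiplication
term) is measured on the full dataset with the at-risk rule
``growth rate < threshold``; a value equal to the threshold is not at risk.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold, StratifiedKFold

from .config import CartConfig
from .errors import KittenGrowthError, NoSplitError
from .growth import INTERVAL_NAMES, GrowthProfile
from .records import BwCategory, KittenRecord, Status


def _as_outcome_array(outcomes: Sequence) -> np.ndarray:
    """Accept 0/1, bools, or 'dead'/'alive' labels; 1 means death."""
    out = []
    for o in outcomes:
        if isinstance(o, str):
            if o not in ("dead", "alive"):
                raise KittenGrowthError(f"unknown outcome label {o!r}")
            out.append(1 if o == "dead" else 0)
        else:
            out.append(int(bool(o)))
    return np.asarray(out, dtype=int)


def _best_split_scan(
    values: np.ndarray,
    y: np.ndarray,
    fn_cost: float,
    fp_cost: float,
    min_leaf: int,
) -> tuple[float | None, str | None]:
    """Single pass over sorted candidate midpoints minimizing the
    prior-weighted Gini impurity of the induced partition.

    Returns ``(cutpoint, None)`` or ``(None, reason)``.
    """
    n = values.size
    n1 = int(y.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return None, "single outcome class"
    if n < 2 * min_leaf:
        return None, f"fewer than 2*min_leaf={2 * min_leaf} observations"
    # altered priors: empirical priors scaled by the loss of their class
    pi1 = n1 * fn_cost / (n1 * fn_cost + n0 * fp_cost)
    pi0 = 1.0 - pi1
    w1, w0 = pi1 / n1, pi0 / n0  # per-observation weight by class

    order = np.argsort(values, kind="stable")
    v = values[order]
    cls = y[order]
    cum_w1 = np.cumsum(np.where(cls == 1, w1, 0.0))
    cum_w0 = np.cumsum(np.where(cls == 1, 0.0, w0))

    parent = 1.0 - pi1**2 - pi0**2

    # criterion ties (common with rounded data) break toward the smallest
    # cutpoint: a later candidate must improve by more than the float noise
    # accumulated in the cumulative sums
    tol = 1e-10
    best_cut = None
    best_imp = parent - 1e-12  # require a strict impurity reduction
    for i in range(min_leaf - 1, n - min_leaf):
        if v[i + 1] <= v[i]:
            continue  # not between distinct values
        w1L, w0L = cum_w1[i], cum_w0[i]
        pL = w1L + w0L
        pR = 1.0 - pL
        w1R, w0R = pi1 - w1L, pi0 - w0L
        gini_L = 1.0 - (w1L / pL) ** 2 - (w0L / pL) ** 2
        gini_R = 1.0 - (w1R / pR) ** 2 - (w0R / pR) ** 2
        imp = pL * gini_L + pR * gini_R
        if imp < best_imp - tol:
            best_imp = imp
            best_cut = 0.5 * (v[i] + v[i + 1])
    if best_cut is None:
        return None, "no admissible split reduces impurity"
    return float(best_cut), None


class CostSensitiveStump(BaseEstimator, ClassifierMixin):
    """Depth-1 cost-sensitive CART on a single growth rate.

    Predicts death (class 1) when the value is strictly below the fitted
    ``threshold_``. When no admissible split reduces impurity, ``threshold_``
    is None and everything is predicted surviving.
    """

    def __init__(self, fn_cost: float = 10.0, fp_cost: float = 1.0, min_leaf: int = 7):
        self.fn_cost = fn_cost
        self.fp_cost = fp_cost
        self.min_leaf = min_leaf

    def fit(self, X, y) -> "CostSensitiveStump":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise KittenGrowthError("expected a single growth-rate feature")
        y = _as_outcome_array(y)
        if X.shape[0] != y.size:
            raise KittenGrowthError("X and y lengths differ")
        self.classes_ = np.array([0, 1])
        self.threshold_, self.no_split_reason_ = _best_split_scan(
            X[:, 0], y, self.fn_cost, self.fp_cost, self.min_leaf
        )
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.threshold_ is None:
            return np.zeros(X.shape[0], dtype=int)
        return (X[:, 0] < self.threshold_).astype(int)


def best_split(
    values: Sequence[float], outcomes: Sequence, config: CartConfig | None = None
) -> float | None:
    """Cutpoint of the cost-weighted Gini-optimal stump, or None."""
    config = config or CartConfig()
    config.validate()
    stump = CostSensitiveStump(config.fn_cost, config.fp_cost, config.min_leaf)
    stump.fit(np.asarray(values, dtype=float), outcomes)
    return stump.threshold_


class MedianThresholdCV(BaseEstimator, ClassifierMixin):
    """K-fold median aggregation of cost-sensitive stump cutpoints.

    Each fold's training side fits one stump; the alarm threshold is the
    median of the fold cutpoints (mean of the middle pair for an even count).
    Folds without an admissible split are recorded as NaN, excluded from the
    median with a warning; more than half failing aborts with diagnostics.
    """

    def __init__(
        self,
        fn_cost: float = 10.0,
        fp_cost: float = 1.0,
        n_folds: int = 10,
        min_leaf: int = 7,
        stratified: bool = True,
        random_state: int = 0,
    ):
        self.fn_cost = fn_cost
        self.fp_cost = fp_cost
        self.n_folds = n_folds
        self.min_leaf = min_leaf
        self.stratified = stratified
        self.random_state = random_state

    def fit(self, X, y) -> "MedianThresholdCV":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = _as_outcome_array(y)
        if self.stratified:
            splitter = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.random_state
            )
        else:
            splitter = KFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.random_state
            )
        folds: list[float] = []
        reasons: list[str | None] = []
        for train_idx, _ in splitter.split(X, y):
            cut, reason = _best_split_scan(
                X[train_idx, 0], y[train_idx], self.fn_cost, self.fp_cost, self.min_leaf
            )
            folds.append(math.nan if cut is None else cut)
            reasons.append(reason)
        self.fold_thresholds_ = folds
        self.fold_reasons_ = reasons
        valid = [f for f in folds if not math.isnan(f)]
        n_missing = len(folds) - len(valid)
        if n_missing > len(folds) // 2:
            raise NoSplitError(
                f"{n_missing}/{len(folds)} folds yielded no split: "
                + "; ".join(r for r in reasons if r)
            )
        if n_missing:
            warnings.warn(
                f"{n_missing}/{len(folds)} folds yielded no split; "
                "median taken over the remaining folds",
                stacklevel=2,
            )
        self.threshold_ = float(np.median(valid))
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return (X[:, 0] < self.threshold_).astype(int)


# ---------------------------------------------------------------------------
# Screening performance


@dataclass(frozen=True)
class ConfusionCounts:
    """Kitten counts; positive = predicted death = growth rate below the
    threshold."""

    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class CartThresholdResult:
    bw_category: str
    gr_interval: str
    n: int
    fold_thresholds: list[float] = field(default_factory=list)
    threshold: float | None = None
    mortality_below: float | None = None  # percent
    n_below: int = 0
    mortality_above: float | None = None  # percent
    n_above: int = 0
    multiplication_term: float | None = None
    confusion: ConfusionCounts | None = None
    se: float | None = None
    sp: float | None = None
    ppv: float | None = None
    npv: float | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        if self.confusion is not None:
            d["confusion"] = dict(self.confusion.__dict__)
        return d


def screening_report(
    values: Sequence[float],
    outcomes: Sequence,
    threshold: float,
    bw_category: str = "",
    gr_interval: str = "",
) -> CartThresholdResult:
    """Confusion counts and screening metrics of ``value < threshold`` as a
    death predictor, on the full dataset."""
    if not math.isfinite(threshold):
        raise KittenGrowthError("threshold must be finite")
    v = np.asarray(values, dtype=float)
    y = _as_outcome_array(outcomes)
    below = v < threshold
    tp = int((below & (y == 1)).sum())
    fp = int((below & (y == 0)).sum())
    fn = int((~below & (y == 1)).sum())
    tn = int((~below & (y == 0)).sum())
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    n_below, n_above = tp + fp, tn + fn
    result = CartThresholdResult(
        bw_category=bw_category,
        gr_interval=gr_interval,
        n=int(v.size),
        threshold=float(threshold),
        n_below=n_below,
        n_above=n_above,
        confusion=counts,
    )
    result.se = tp / (tp + fn) if tp + fn else None
    result.sp = tn / (tn + fp) if tn + fp else None
    result.ppv = tp / (tp + fp) if tp + fp else None
    result.npv = tn / (tn + fn) if tn + fn else None
    if n_below:
        result.mortality_below = 100.0 * tp / n_below
    if n_above:
        result.mortality_above = 100.0 * fn / n_above
    if result.mortality_above and result.mortality_below is not None:
        result.multiplication_term = result.mortality_below / result.mortality_above
    if not n_below or not n_above:
        result.error = "one side of the threshold is empty; ratio undefined"
    return result


def cv_median_threshold(
    values: Sequence[float],
    outcomes: Sequence,
    config: CartConfig | None = None,
    bw_category: str = "",
    gr_interval: str = "",
) -> CartThresholdResult:
    """Cross-validated median threshold plus screening performance."""
    config = config or CartConfig()
    config.validate()
    model = MedianThresholdCV(
        fn_cost=config.fn_cost,
        fp_cost=config.fp_cost,
        n_folds=config.n_folds,
        min_leaf=config.min_leaf,
        stratified=config.stratified,
        random_state=config.seed,
    ).fit(np.asarray(values, dtype=float), outcomes)
    result = screening_report(
        values, outcomes, model.threshold_, bw_category=bw_category, gr_interval=gr_interval
    )
    result.fold_thresholds = model.fold_thresholds_
    return result


def threshold_table(
    records: Sequence[KittenRecord],
    profiles: Sequence[GrowthProfile],
    config: CartConfig | None = None,
) -> list[CartThresholdResult]:
    """One threshold per (birth-weight category) x (growth interval): the ten
    potential alarm thresholds, LBW and NBW analyzed separately, each on the
    kittens with that growth rate present. Per-cell failures are reported in
    the result's ``error`` field; the remaining cells still compute."""
    config = config or CartConfig()
    by_id = {p.kitten_id: p for p in profiles}
    results: list[CartThresholdResult] = []
    for category in (BwCategory.LBW, BwCategory.NBW):
        subset = [
            rec
            for rec in records
            if rec.bw_category is category
            and rec.status_2mo is not Status.UNKNOWN
            and rec.kitten_id in by_id
        ]
        for name in INTERVAL_NAMES:
            pairs = [
                (by_id[rec.kitten_id].gr[name], 1 if rec.status_2mo is Status.DEAD else 0)
                for rec in subset
                if name in by_id[rec.kitten_id].gr
            ]
            values = [v for v, _ in pairs]
            outcomes = [o for _, o in pairs]
            try:
                results.append(
                    cv_median_threshold(
                        values, outcomes, config,
                        bw_category=category.value, gr_interval=name,
                    )
                )
            except (KittenGrowthError, ValueError) as err:
                results.append(
                    CartThresholdResult(
                        bw_category=category.value,
                        gr_interval=name,
                        n=len(values),
                        error=str(err),
                    )
                )
    return results
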