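"""Joint effect of birth-weight category and growth-rate quartile on 0-2
month mortality.

The model is a binomial GLM with logit link on the 2x4 factorial (birth
weight LBW/NBW x growth-rate quartile group 1-4), including the interaction —
a saturated model, so fitted cell probabilities coincide with empirical cell
death fractions whenever no cell is separated. Coefficients are estimated by
iteratively reweighted least squares on the cell-aggregated binomial counts;
estimated marginal means per cell are linear transforms of the coefficients
with delta-method standard errors, compared pairwise with a configurable
multiplicity adjustment (Tukey's studentized-range method by default, as is
customary for marginal-means post hocs) and summarized by a compact letter
display.

Also here: per-period 2x2 chi-square comparisons of death-timing
distributions, binomial confidence intervals (Wald / Wilson) and the
mortality-ratio arithmetic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit as logit_fn

from .config import GlmConfig
from .errors import (
    InsufficientDataError,
    KittenGrowthError,
    RankDeficiencyError,
    SeparationError,
)
from .growth import QuartileGrouping
from .records import BwCategory, KittenRecord, Status

#: Fixed cell order: NBW is the reference category, group 1 the reference group.
CATEGORIES = ("NBW", "LBW")
GROUPS = (1, 2, 3, 4)
CELLS = tuple((c, g) for c in CATEGORIES for g in GROUPS)

#: Death periods for the timing comparison (inclusive day bounds).
PERIOD_BINS = ((0, 2), (3, 21), (22, 60))
PERIOD_LABELS = tuple(f"{a}-{b}d" for a, b in PERIOD_BINS)


def _design_row(cat: str, grp: int, ref_cat: str, ref_grp: int) -> np.ndarray:
    """Treatment-coded row: intercept, bw main effect, 3 group effects,
    3 interactions."""
    other_groups = [g for g in GROUPS if g != ref_grp]
    bw = 1.0 if cat != ref_cat else 0.0
    g_ind = [1.0 if grp == g else 0.0 for g in other_groups]
    return np.array([1.0, bw, *g_ind, *(bw * gi for gi in g_ind)])


@dataclass
class GlmFit:
    """Fitted 2x4 factorial logistic model."""

    coef: np.ndarray  # length 8, treatment coding
    cov: np.ndarray | None  # 8x8, None when separated
    names: list[str]
    cell_n: dict[tuple[str, int], int]
    cell_deaths: dict[tuple[str, int], int]
    deviance: float
    converged: bool
    n_iter: int
    separated: bool
    separated_cells: list[tuple[str, int]]
    ref_cat: str = "NBW"
    ref_grp: int = 1
    iteration_trace: list[float] = field(default_factory=list)

    def cell_logit(self, cat: str, grp: int) -> float:
        p = self.cell_deaths[(cat, grp)] / self.cell_n[(cat, grp)]
        if p <= 0.0:
            return -math.inf
        if p >= 1.0:
            return math.inf
        if self.separated:
            # finite coefficients are not estimable; the saturated-model cell
            # logit is still the empirical one
            return float(logit_fn(p))
        return float(_design_row(cat, grp, self.ref_cat, self.ref_grp) @ self.coef)

    def cell_prob(self, cat: str, grp: int) -> float:
        return float(expit(self.cell_logit(cat, grp)))


def prepare_period_data(
    records: Sequence[KittenRecord],
    gr_values: Mapping[str, float],
    grouping: QuartileGrouping,
    period_start_day: int,
) -> list[tuple[str, int, int]]:
    """Rows (bw_category, group, died) for the Day-k .. 2-month analysis.

    Eligible kittens have a known status, the named growth rate, an assigned
    category, and were alive after Day k — deaths at exactly Day k count as
    prior deaths and are excluded, as are dead kittens with unknown death day
    (survival to Day k cannot be verified for them).
    """
    rows = []
    for rec in records:
        if rec.bw_category not in (BwCategory.LBW, BwCategory.NBW):
            continue
        if rec.status_2mo is Status.UNKNOWN or rec.kitten_id not in gr_values:
            continue
        if rec.status_2mo is Status.DEAD:
            if rec.death_day is None or rec.death_day <= period_start_day:
                continue
            died = 1
        else:
            died = 0
        rows.append((rec.bw_category.value, grouping.assignment[rec.kitten_id], died))
    return rows


def fit_interaction_glm(
    rows: Sequence[tuple[str, int, int]],
    config: GlmConfig | None = None,
    ref_cat: str = "NBW",
    ref_grp: int = 1,
) -> GlmFit:
    """Fit the saturated birth-weight x growth-group logistic model by IRLS
    on cell-aggregated binomial counts.

    Raises :class:`RankDeficiencyError` naming the cell if any of the 8 cells
    is empty. A cell with empirical mortality 0 or 1 marks the fit as
    separated: the finite coefficients are not estimable and the fit carries
    +/-inf cell logits instead.
    """
    config = config or GlmConfig()
    cell_n = {cell: 0 for cell in CELLS}
    cell_deaths = {cell: 0 for cell in CELLS}
    for cat, grp, died in rows:
        if (cat, grp) not in cell_n:
            raise KittenGrowthError(f"unknown cell ({cat}, {grp})")
        cell_n[(cat, grp)] += 1
        cell_deaths[(cat, grp)] += died
    empty = [cell for cell in CELLS if cell_n[cell] == 0]
    if empty:
        raise RankDeficiencyError(
            f"empty factorial cell(s) {empty}: interaction design is rank deficient"
        )
    separated_cells = [
        cell for cell in CELLS if cell_deaths[cell] in (0, cell_n[cell])
    ]
    names = _coef_names(ref_cat, ref_grp)
    X = np.vstack([_design_row(c, g, ref_cat, ref_grp) for c, g in CELLS])
    n = np.array([cell_n[cell] for cell in CELLS], dtype=float)
    y = np.array([cell_deaths[cell] for cell in CELLS], dtype=float)

    if separated_cells:
        return GlmFit(
            coef=np.full(8, np.nan),
            cov=None,
            names=names,
            cell_n=cell_n,
            cell_deaths=cell_deaths,
            deviance=math.nan,
            converged=False,
            n_iter=0,
            separated=True,
            separated_cells=separated_cells,
            ref_cat=ref_cat,
            ref_grp=ref_grp,
        )

    # IRLS on grouped binomial data; the saturated grouped deviance is 0.
    def deviance_of(eta: np.ndarray) -> float:
        mu = expit(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            term1 = np.where(y > 0, y * np.log(y / (n * mu)), 0.0)
            term2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - n * mu)), 0.0)
        return float(2.0 * (term1 + term2).sum())

    beta = np.zeros(8)
    dev = deviance_of(X @ beta)
    trace = [dev]
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        eta = X @ beta
        mu = expit(eta)
        w = n * mu * (1.0 - mu)
        z = eta + (y - n * mu) / w
        xtw = X.T * w
        beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        dev_new = deviance_of(X @ beta_new)
        step = 1.0
        while dev_new > dev + 1e-12 and step > 1e-6:  # half-step on divergence
            step /= 2.0
            beta_try = beta + step * (beta_new - beta)
            dev_new = deviance_of(X @ beta_try)
            beta_new = beta_try
        beta = beta_new
        trace.append(dev_new)
        if abs(dev - dev_new) < config.tolerance:
            dev = dev_new
            converged = True
            break
        dev = dev_new
    if not converged:
        raise KittenGrowthError(
            f"IRLS did not converge in {config.max_iterations} iterations; "
            f"deviance trace {trace}"
        )
    mu = expit(X @ beta)
    w = n * mu * (1.0 - mu)
    cov = np.linalg.inv((X.T * w) @ X)
    return GlmFit(
        coef=beta,
        cov=cov,
        names=names,
        cell_n=cell_n,
        cell_deaths=cell_deaths,
        deviance=dev,
        converged=True,
        n_iter=it,
        separated=False,
        separated_cells=[],
        ref_cat=ref_cat,
        ref_grp=ref_grp,
        iteration_trace=trace,
    )


def _coef_names(ref_cat: str, ref_grp: int) -> list[str]:
    other_cat = [c for c in CATEGORIES if c != ref_cat][0]
    other_groups = [g for g in GROUPS if g != ref_grp]
    return (
        ["(Intercept)", f"bw[{other_cat}]"]
        + [f"gr[{g}]" for g in other_groups]
        + [f"bw[{other_cat}]:gr[{g}]" for g in other_groups]
    )


class InteractionLogit:
    """Estimator-style wrapper: ``fit(rows)`` then ``fit_``, ``emm_``."""

    def __init__(self, config: GlmConfig | None = None, alpha: float = 0.05):
        self.config = config or GlmConfig()
        self.alpha = alpha

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "alpha": self.alpha}

    def set_params(self, **params) -> "InteractionLogit":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, rows: Sequence[tuple[str, int, int]]) -> "InteractionLogit":
        self.fit_ = fit_interaction_glm(rows, self.config)
        self.emm_ = None if self.fit_.separated else emm_pairwise(
            self.fit_, alpha=self.alpha, adjust=self.config.adjust_method
        )
        return self


# ---------------------------------------------------------------------------
# Estimated marginal means


@dataclass
class EmmResult:
    cells: list[tuple[str, int]]
    logit_mean: dict[tuple[str, int], float]
    logit_se: dict[tuple[str, int], float]
    prob_mean: dict[tuple[str, int], float]
    contrasts: list[dict]  # cell_a, cell_b, estimate, se, z, p_raw, p_adj
    letters: dict[tuple[str, int], str]
    alpha: float
    adjust: str


def _adjust_pvalues(z_abs: np.ndarray, method: str, k_means: int) -> np.ndarray:
    raw = 2.0 * stats.norm.sf(z_abs)
    m = z_abs.size
    if method == "none":
        return raw
    if method == "tukey":
        # studentized-range adjustment on k means, asymptotic df
        return stats.studentized_range.sf(z_abs * math.sqrt(2.0), k_means, np.inf)
    if method == "bonferroni":
        return np.minimum(1.0, raw * m)
    if method == "holm":
        order = np.argsort(raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise KittenGrowthError(f"unknown adjustment {method!r}")


def compact_letter_display(
    items: Sequence, significant: set[tuple[int, int]]
) -> dict:
    """Insert-and-absorb compact letter display.

    Items sharing a letter are never a significant pair; non-significant
    pairs share a letter whenever the greedy sweep allows.
    """
    sets: list[set[int]] = [set(range(len(items)))]
    for i, j in sorted(significant):
        new_sets: list[set[int]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.append(s - {i})
                new_sets.append(s - {j})
            else:
                new_sets.append(s)
        # absorb sets contained in another
        sets = [
            s
            for k, s in enumerate(new_sets)
            if s and not any(s < t or (s == t and k2 < k) for k2, t in enumerate(new_sets) if k2 != k)
        ]
    sets.sort(key=lambda s: min(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {idx: "" for idx in range(len(items))}
    for letter, s in zip(alphabet, sets):
        for idx in sorted(s):
            letters[idx] += letter
    return {items[idx]: letters[idx] for idx in range(len(items))}


def emm_pairwise(fit: GlmFit, alpha: float = 0.05, adjust: str = "tukey") -> EmmResult:
    """All 28 pairwise cell contrasts of the factorial with adjusted p-values
    and the letter display shown atop mortality bar plots."""
    if fit.separated:
        raise SeparationError(
            f"cells {fit.separated_cells} have empirical mortality 0 or 1; "
            "collapse cells before computing marginal means"
        )
    L = np.vstack([_design_row(c, g, fit.ref_cat, fit.ref_grp) for c, g in CELLS])
    eta = L @ fit.coef
    cov_eta = L @ fit.cov @ L.T
    se = np.sqrt(np.diag(cov_eta))

    pairs = list(itertools.combinations(range(len(CELLS)), 2))
    est = np.array([eta[i] - eta[j] for i, j in pairs])
    cse = np.array(
        [math.sqrt(cov_eta[i, i] + cov_eta[j, j] - 2.0 * cov_eta[i, j]) for i, j in pairs]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(cse > 0, est / cse, 0.0)
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = _adjust_pvalues(np.abs(z), adjust, k_means=len(CELLS))

    significant = {
        pairs[k] for k in range(len(pairs)) if p_adj[k] < alpha
    }
    letters = compact_letter_display(list(CELLS), significant)

    contrasts = [
        {
            "cell_a": CELLS[i],
            "cell_b": CELLS[j],
            "estimate": float(est[k]),
            "se": float(cse[k]),
            "z": float(z[k]),
            "p_raw": float(p_raw[k]),
            "p_adj": float(p_adj[k]),
        }
        for k, (i, j) in enumerate(pairs)
    ]
    return EmmResult(
        cells=list(CELLS),
        logit_mean={cell: float(eta[k]) for k, cell in enumerate(CELLS)},
        logit_se={cell: float(se[k]) for k, cell in enumerate(CELLS)},
        prob_mean={cell: float(expit(eta[k])) for k, cell in enumerate(CELLS)},
        contrasts=contrasts,
        letters=letters,
        alpha=alpha,
        adjust=adjust,
    )


# ---------------------------------------------------------------------------
# Death-timing distributions


@dataclass(frozen=True)
class PeriodDistribution:
    """Deaths with known timing, binned into 0-2 / 3-21 / 22-60 days."""

    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise KittenGrowthError("period counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts)

    @classmethod
    def from_records(cls, records: Sequence[KittenRecord]) -> "PeriodDistribution":
        counts = [0, 0, 0]
        for rec in records:
            if rec.status_2mo is Status.DEAD and rec.death_day is not None:
                for k, (a, b) in enumerate(PERIOD_BINS):
                    if a <= rec.death_day <= b:
                        counts[k] += 1
                        break
        return cls(tuple(counts))


def period_distribution_test(
    dist_a: PeriodDistribution, dist_b: PeriodDistribution
) -> dict[str, dict]:
    """Per-period 2x2 chi-square comparing the share of deaths falling in the
    period between the two categories (no continuity correction, so the
    statistic is exactly sum (O-E)^2/E)."""
    if dist_a.total == 0 or dist_b.total == 0:
        raise InsufficientDataError("both categories need at least one timed death")
    out = {}
    for k, label in enumerate(PERIOD_LABELS):
        table = np.array(
            [
                [dist_a.counts[k], dist_a.total - dist_a.counts[k]],
                [dist_b.counts[k], dist_b.total - dist_b.counts[k]],
            ],
            dtype=float,
        )
        expected = stats.contingency.expected_freq(table)
        if (expected == 0).any():
            raise InsufficientDataError(
                f"period {label}: zero expected count; use an exact test"
            )
        if table[0].sum() == 0 or table[1].sum() == 0:
            raise InsufficientDataError(f"period {label}: empty margin")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        out[label] = {"chi2": float(chi2), "p": float(p), "table": table.astype(int).tolist()}
    return out


# ---------------------------------------------------------------------------
# Rates, intervals, ratios


def binomial_ci(k: int, n: int, method: str = "wald", level: float = 0.95) -> tuple[float, float]:
    """Binomial confidence interval for k/n, returned in percent.

    ``wald``: p +/- z*sqrt(p(1-p)/n), clipped to [0, 100].
    ``wilson``: score interval.
    """
    if not (0 <= k <= n) or n <= 0:
        raise KittenGrowthError(f"invalid counts k={k}, n={n}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = k / n
    if method == "wald":
        half = z * math.sqrt(p * (1.0 - p) / n)
        lo, hi = p - half, p + half
    elif method == "wilson":
        denom = 1.0 + z**2 / n
        center = (p + z**2 / (2.0 * n)) / denom
        half = z * math.sqrt(p * (1.0 - p) / n + z**2 / (4.0 * n**2)) / denom
        lo, hi = center - half, center + half
    else:
        raise KittenGrowthError(f"unknown CI method {method!r}")
    return max(0.0, lo) * 100.0, min(1.0, hi) * 100.0


def mortality_ratio(rate_a_pct: float, rate_b_pct: float) -> float:
    """Ratio of two mortality rates (percent scale); rounding is left to
    presentation."""
    if rate_b_pct <= 0:
        raise KittenGrowthError("denominator rate must be positive")
    return rate_a_pct / rate_b_pct
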