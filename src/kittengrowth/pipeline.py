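"""End-to-end cohort analysis: selection, classification, growth metrics,
mortality modelling and alarm thresholds, collected into one JSON-able
report."""

from __future__ import annotations

import math
from typing import Sequence

from . import glm as glm_mod
from . import growth as growth_mod
from . import io as io_mod
from . import tree as tree_mod
from .config import AnalysisConfig
from .errors import KittenGrowthError, RankDeficiencyError, SeparationError
from .records import BreedThresholdTable, BwCategory, KittenRecord, Sex, Status

#: (growth interval, first day of the mortality window) for the three
#: survivor-conditioned factorial analyses.
GLM_ANALYSES = (("0-1", 1), ("0-2", 2), ("0-7", 7))


def prepare_cohort(
    records: Sequence[KittenRecord],
    table: BreedThresholdTable,
    config: AnalysisConfig | None = None,
):
    """Selection -> classification -> growth profiles -> outlier exclusion.

    Returns ``(selection_log, classified_records, retained_records,
    retained_profiles, excluded_profiles, fences)``.
    """
    config = config or AnalysisConfig()
    selection = io_mod.apply_selection(records)
    classified = io_mod.classify_cohort(selection.retained, table)
    profiles = growth_mod.compute_profiles(classified)
    fences = growth_mod.flag_outliers(profiles, config.iqr_multiplier)
    retained_profiles = [p for p in profiles if not p.excluded]
    excluded_profiles = [p for p in profiles if p.excluded]
    keep_ids = {p.kitten_id for p in retained_profiles}
    retained_records = [r for r in classified if r.kitten_id in keep_ids]
    return selection, classified, retained_records, retained_profiles, excluded_profiles, fences


def mortality_summary(records: Sequence[KittenRecord], config: AnalysisConfig) -> dict:
    """Overall and per-category 0-2 month mortality, CIs, the LBW:NBW ratio,
    death-timing distributions and their per-period comparisons."""
    known = [r for r in records if r.status_2mo is not Status.UNKNOWN]
    deaths = [r for r in known if r.status_2mo is Status.DEAD]
    n, k = len(known), len(deaths)
    out: dict = {
        "n": n,
        "deaths": k,
        "mortality_pct": 100.0 * k / n if n else math.nan,
        "ci_pct": glm_mod.binomial_ci(k, n, config.ci_method) if n else None,
    }
    timed = [r for r in deaths if r.death_day is not None]
    out["deaths_with_known_day"] = len(timed)
    out["neonatal_share_pct"] = (
        100.0 * sum(1 for r in timed if r.death_day <= 21) / len(timed) if timed else math.nan
    )
    per_cat: dict = {}
    for cat in (BwCategory.LBW, BwCategory.NBW):
        sub = [r for r in known if r.bw_category is cat]
        d = sum(1 for r in sub if r.status_2mo is Status.DEAD)
        per_cat[cat.value] = {
            "n": len(sub),
            "deaths": d,
            "mortality_pct": 100.0 * d / len(sub) if sub else math.nan,
            "ci_pct": glm_mod.binomial_ci(d, len(sub), config.ci_method) if sub else None,
        }
    out["by_category"] = per_cat
    lbw, nbw = per_cat["LBW"], per_cat["NBW"]
    if nbw["n"] and nbw["mortality_pct"] > 0 and lbw["n"]:
        out["lbw_nbw_ratio"] = glm_mod.mortality_ratio(
            lbw["mortality_pct"], nbw["mortality_pct"]
        )
    dist = {
        cat.value: glm_mod.PeriodDistribution.from_records(
            [r for r in known if r.bw_category is cat]
        )
        for cat in (BwCategory.LBW, BwCategory.NBW)
    }
    out["period_counts"] = {c: list(d.counts) for c, d in dist.items()}
    try:
        out["period_tests"] = glm_mod.period_distribution_test(dist["LBW"], dist["NBW"])
    except KittenGrowthError as err:
        out["period_tests"] = {"error": str(err)}
    return out


def factorial_analyses(
    records: Sequence[KittenRecord],
    profiles: Sequence[growth_mod.GrowthProfile],
    config: AnalysisConfig,
) -> dict:
    """The three birth-weight x growth-quartile logistic analyses with EMM
    letters and a mortality-bar table per cell."""
    by_id = {p.kitten_id: p for p in profiles}
    out: dict = {}
    for interval, start_day in GLM_ANALYSES:
        values = {
            p.kitten_id: p.gr[interval] for p in profiles if interval in p.gr
        }
        entry: dict = {"interval": interval, "period_start_day": start_day}
        try:
            grouping = growth_mod.quartile_groups(values, interval)
            entry["quartiles"] = {"q1": grouping.q1, "q2": grouping.q2, "q3": grouping.q3}
            rows = glm_mod.prepare_period_data(records, values, grouping, start_day)
            fit = glm_mod.fit_interaction_glm(rows, config.glm)
            entry["n"] = len(rows)
            entry["coefficients"] = dict(zip(fit.names, [float(c) for c in fit.coef]))
            entry["deviance"] = fit.deviance
            entry["converged"] = fit.converged
            entry["separated"] = fit.separated
            cells_table = []
            emm = None
            if not fit.separated:
                emm = glm_mod.emm_pairwise(fit, config.alpha, config.glm.adjust_method)
                entry["contrasts"] = emm.contrasts
            else:
                entry["separated_cells"] = [list(c) for c in fit.separated_cells]
            for cat, grp in glm_mod.CELLS:
                n_cell = fit.cell_n[(cat, grp)]
                d_cell = fit.cell_deaths[(cat, grp)]
                cells_table.append(
                    {
                        "bw_category": cat,
                        "group": grp,
                        "n": n_cell,
                        "deaths": d_cell,
                        "mortality_pct": 100.0 * d_cell / n_cell,
                        "ci_pct": glm_mod.binomial_ci(d_cell, n_cell, config.ci_method),
                        "letter": emm.letters[(cat, grp)] if emm else None,
                    }
                )
            entry["cells"] = cells_table
        except (KittenGrowthError, RankDeficiencyError, SeparationError) as err:
            entry["error"] = str(err)
        out[interval] = entry
    return out


def run_pipeline(
    records: Sequence[KittenRecord],
    table: BreedThresholdTable,
    config: AnalysisConfig | None = None,
) -> dict:
    """Full analysis of one cohort; every table the pipeline produces plus a
    machine-readable exclusion log."""
    config = (config or AnalysisConfig()).validate()
    selection, classified, retained, profiles, excl_profiles, fences = prepare_cohort(
        records, table, config
    )
    males = sum(1 for r in classified if r.sex is Sex.MALE)
    females = sum(1 for r in classified if r.sex is Sex.FEMALE)
    lbw_n = sum(1 for r in classified if r.bw_category is BwCategory.LBW)
    categories = {r.kitten_id: r.bw_category for r in classified}
    report = {
        "selection": {
            "input": len(records),
            "retained": len(selection.retained),
            "excluded": [
                {"kitten_id": rec.kitten_id, "reason": reason}
                for rec, reason in selection.excluded
            ],
        },
        "population": {
            "n": len(classified),
            "litters": len({r.litter_id for r in classified}),
            "males": males,
            "females": females,
            "sex_ratio": males / females if females else math.nan,
            "lbw_n": lbw_n,
            "lbw_prevalence_pct": 100.0 * lbw_n / len(classified) if classified else math.nan,
        },
        "outlier_exclusion": {
            "fences": {k: list(v) for k, v in fences.items()},
            "excluded": [p.kitten_id for p in excl_profiles],
            "retained_n": len(profiles),
        },
        "growth": growth_mod.describe_growth(profiles, categories),
        "mortality": mortality_summary(classified, config),
        "glm": factorial_analyses(retained, profiles, config),
        "thresholds": [
            r.to_dict() for r in tree_mod.threshold_table(retained, profiles, config.cart)
        ],
    }
    return report
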