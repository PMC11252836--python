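"""Synthetic kitten cohorts with the statistical structure of a multi-breed
cattery study.

The generator emulates, at the kitten level:

* litter structure (normal litter sizes, mean 4.5, SD 1.5, truncated at 1);
* breed-specific birth-weight distributions spanning roughly 36-182 g, with
  each breed's low-birth-weight threshold placed at its 19.5th percentile so
  LBW prevalence is ~19.5% by construction;
* early growth as a multiplicative random walk, w(d+1) = w(d) * (1 + g_d/100)
  with independent Gaussian daily growth rates per birth-weight category; the
  daily mean/SD defaults are inverted in closed form from weekly GR 0-7
  targets of 99.9 (SD 30.4) for LBW and 86.9 (SD 23) for NBW;
* 0-2 month mortality through a logit-linear function of category and the
  latent week-one growth rate (or a planted step function for
  parameter-recovery experiments), calibrated so category death rates are
  19.2% (LBW) and 4.4% (NBW), i.e. ~7.4% overall with a 4.4x ratio;
* death timing drawn per category over the periods 0-2, 3-21 and 22-60 days,
  concentrating deaths in the neonatal period (~82% by day 21);
* missing weighings after Day 0, at random per day.

Weights after the death day are never recorded. All randomness flows from one
root seed; each litter draws from its own deterministically spawned
sub-stream, so cohorts are reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.special import roots_hermite

from .errors import ConfigError
from .records import BwCategory, KittenRecord, Sex, Status

#: Death periods in days (inclusive bounds): early neonatal, late neonatal,
#: post-neonatal up to the 2-month horizon.
PERIODS = ((0, 2), (3, 21), (22, 60))


def weekly_to_daily(mean7: float, sd7: float) -> tuple[float, float]:
    """Invert weekly GR 0-7 mean/SD (percent) to the per-day mean/SD of
    independent multiplicative increments.

    With X_d = 1 + g_d/100 iid, E prod X_d = m^7 and
    Var prod X_d = (m^2 + s^2)^7 - m^14, which solve in closed form.
    """
    m = (1.0 + mean7 / 100.0) ** (1.0 / 7.0)
    s2 = (m**14 + (sd7 / 100.0) ** 2) ** (1.0 / 7.0) - m**2
    if s2 <= 0:
        raise ConfigError("weekly SD too small for independent daily increments")
    return (m - 1.0) * 100.0, math.sqrt(s2) * 100.0


def daily_to_weekly(mean_d: float, sd_d: float) -> tuple[float, float]:
    """Forward moments of the 7-day product for daily mean/SD in percent."""
    m = 1.0 + mean_d / 100.0
    s2 = (sd_d / 100.0) ** 2
    mean7 = (m**7 - 1.0) * 100.0
    var7 = (m**2 + s2) ** 7 - m**14
    return mean7, 100.0 * math.sqrt(var7)


@dataclass(frozen=True)
class BreedSpec:
    name: str
    bw_mean_g: float
    bw_sd_g: float
    lbw_threshold_g: float


@dataclass(frozen=True)
class DailyGrowth:
    """Per-day growth-rate distribution (percent) for one BW category."""

    mean: float
    sd: float


@dataclass(frozen=True)
class PlantedStep:
    """Step-function mortality on one realized growth rate; a known truth for
    threshold-recovery experiments."""

    gr_name: str
    cutpoint: float
    risk_below: float
    risk_above: float


@dataclass(frozen=True)
class MortalityModel:
    """logit P(death) = baseline + shift * 1[LBW] + slope * GR0-7 (latent)."""

    baseline_logit: float
    lbw_logit_shift: float
    gr_slope_logit: float
    planted_step: PlantedStep | None = None


def calibrate_mortality(
    nbw_rate: float,
    lbw_rate: float,
    gr_slope_logit: float,
    nbw_weekly: tuple[float, float],
    lbw_weekly: tuple[float, float],
) -> MortalityModel:
    """Solve baseline and LBW shift so that marginal category death rates hit
    their targets given the logit slope on week-one growth.

    The weekly growth rate is treated as Gaussian for the calibration
    integral (Gauss-Hermite quadrature); the simulated distribution is a
    product of Gaussian factors, close enough at these SDs.
    """
    nodes, weights = roots_hermite(64)
    weights = weights / math.sqrt(math.pi)

    def marginal(b: float, mean: float, sd: float) -> float:
        g = mean + math.sqrt(2.0) * sd * nodes
        return float(weights @ expit(b + gr_slope_logit * g))

    def solve(rate: float, mean: float, sd: float) -> float:
        return brentq(lambda b: marginal(b, mean, sd) - rate, -30.0, 10.0, xtol=1e-12)

    base = solve(nbw_rate, *nbw_weekly)
    lbw_base = solve(lbw_rate, *lbw_weekly)
    return MortalityModel(
        baseline_logit=base,
        lbw_logit_shift=lbw_base - base,
        gr_slope_logit=gr_slope_logit,
    )


def _default_breeds() -> tuple[BreedSpec, ...]:
    # three synthetic breeds spanning the plausible feline 36-182 g range;
    # threshold at the 19.5th percentile of each breed's birth-weight normal
    from scipy.stats import norm

    z = norm.ppf(0.195)
    specs = []
    for name, mean, sd in (("SmallSynth", 85.0, 13.0),
                           ("MediumSynth", 101.0, 14.0),
                           ("LargeSynth", 120.0, 16.0)):
        specs.append(BreedSpec(name, mean, sd, round(mean + z * sd, 1)))
    return tuple(specs)


def _default_daily() -> dict[str, DailyGrowth]:
    lbw = weekly_to_daily(99.9, 30.4)
    nbw = weekly_to_daily(86.9, 23.0)
    return {"LBW": DailyGrowth(*lbw), "NBW": DailyGrowth(*nbw)}


def _default_mortality() -> MortalityModel:
    daily = _default_daily()
    return calibrate_mortality(
        nbw_rate=0.044,
        lbw_rate=0.192,
        gr_slope_logit=-0.02,
        nbw_weekly=daily_to_weekly(daily["NBW"].mean, daily["NBW"].sd),
        lbw_weekly=daily_to_weekly(daily["LBW"].mean, daily["LBW"].sd),
    )


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the target cohort structure: ~5,500 kittens in ~1,223
    litters, 19.5% LBW, ~7.4% overall 0-2 month mortality with a ~4.4x
    LBW:NBW ratio, and neonatal-concentrated death timing.
    """

    n_litters: int = 1223
    litter_mean: float = 4.5
    litter_sd: float = 1.5
    breeds: tuple[BreedSpec, ...] = field(default_factory=_default_breeds)
    daily_gr: dict[str, DailyGrowth] = field(default_factory=_default_daily)
    mortality: MortalityModel = field(default_factory=_default_mortality)
    death_timing: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"LBW": (0.50, 0.38, 0.12), "NBW": (0.35, 0.40, 0.25)}
    )
    missing_prob: float = 0.08  # per weighing day 1..7
    sex_unknown_prob: float = 0.06
    male_to_female: float = 1.1
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_litters < 1:
            raise ConfigError("n_litters must be >= 1")
        if self.litter_mean < 1 or self.litter_sd <= 0:
            raise ConfigError("litter size distribution invalid")
        if not self.breeds:
            raise ConfigError("at least one breed required")
        for cat in ("LBW", "NBW"):
            if cat not in self.daily_gr:
                raise ConfigError(f"daily_gr missing category {cat}")
            if self.daily_gr[cat].sd <= 0:
                raise ConfigError(f"daily_gr[{cat}].sd must be positive")
            timing = self.death_timing.get(cat)
            if timing is None or len(timing) != len(PERIODS):
                raise ConfigError(f"death_timing[{cat}] must give {len(PERIODS)} periods")
            if any(not (0.0 <= p <= 1.0) for p in timing):
                raise ConfigError(f"death_timing[{cat}] probabilities outside [0,1]")
            if abs(sum(timing) - 1.0) > 1e-9:
                raise ConfigError(f"death_timing[{cat}] must sum to 1")
        if not (0.0 <= self.missing_prob <= 1.0):
            raise ConfigError("missing_prob outside [0,1]")
        if not (0.0 <= self.sex_unknown_prob <= 1.0):
            raise ConfigError("sex_unknown_prob outside [0,1]")
        step = self.mortality.planted_step
        if step is not None:
            for r in (step.risk_below, step.risk_above):
                if not (0.0 <= r <= 1.0):
                    raise ConfigError("planted step risks must lie in [0,1]")
            if not step.risk_below > step.risk_above:
                raise ConfigError("planted step requires risk_below > risk_above")
            if not math.isfinite(step.cutpoint):
                raise ConfigError("planted step cutpoint must be finite")
        return self


def plant_threshold_scenario(
    config: SimConfig,
    gr_name: str,
    cutpoint: float,
    risk_below: float,
    risk_above: float,
) -> SimConfig:
    """Return a copy of ``config`` whose mortality is a step function of the
    named realized growth rate (e.g. ``"0-7"``): risk_below under the
    cutpoint, risk_above at or over it."""
    from .growth import INTERVALS  # local import to avoid a cycle

    if gr_name not in {f"{a}-{b}" for a, b in INTERVALS}:
        raise ConfigError(f"unknown growth-rate interval {gr_name!r}")
    step = PlantedStep(gr_name, cutpoint, risk_below, risk_above)
    new = dataclasses.replace(
        config, mortality=dataclasses.replace(config.mortality, planted_step=step)
    )
    return new.validate()


def _latent_gr(weights: np.ndarray, name: str) -> float:
    a, b = (int(x) for x in name.split("-"))
    return 100.0 * (weights[b] - weights[a]) / weights[a]


def simulate_cohort(config: SimConfig) -> list[KittenRecord]:
    """Generate one cohort. Deterministic for a fixed (config, seed)."""
    config.validate()
    root = np.random.default_rng(config.seed)
    litter_streams = np.random.SeedSequence(config.seed).spawn(config.n_litters)

    p_unknown = config.sex_unknown_prob
    p_male = (1.0 - p_unknown) * config.male_to_female / (1.0 + config.male_to_female)
    p_female = 1.0 - p_unknown - p_male

    records: list[KittenRecord] = []
    for li in range(config.n_litters):
        breed = config.breeds[root.integers(len(config.breeds))]
        size = max(1, int(round(root.normal(config.litter_mean, config.litter_sd))))
        rng = np.random.default_rng(litter_streams[li])
        litter_id = f"L{li:04d}"
        for ki in range(size):
            bw = rng.normal(breed.bw_mean_g, breed.bw_sd_g)
            while bw <= 30.0:  # biologically implausible tail; redraw
                bw = rng.normal(breed.bw_mean_g, breed.bw_sd_g)
            category = BwCategory.LBW if bw < breed.lbw_threshold_g else BwCategory.NBW
            growth = config.daily_gr[category.value]
            g = np.clip(rng.normal(growth.mean, growth.sd, size=7), -95.0, None)
            latent = bw * np.cumprod(np.concatenate(([1.0], 1.0 + g / 100.0)))

            step = config.mortality.planted_step
            if step is not None:
                p_death = (
                    step.risk_below
                    if _latent_gr(latent, step.gr_name) < step.cutpoint
                    else step.risk_above
                )
            else:
                m = config.mortality
                logit = (
                    m.baseline_logit
                    + (m.lbw_logit_shift if category is BwCategory.LBW else 0.0)
                    + m.gr_slope_logit * _latent_gr(latent, "0-7")
                )
                p_death = float(expit(logit))
            dead = rng.random() < p_death

            death_day = None
            if dead:
                period = PERIODS[
                    rng.choice(len(PERIODS), p=np.asarray(config.death_timing[category.value]))
                ]
                death_day = int(rng.integers(period[0], period[1] + 1))

            weights = {0: float(latent[0])}
            last_day = 7 if death_day is None else min(7, death_day)
            for d in range(1, last_day + 1):
                if rng.random() >= config.missing_prob:
                    weights[d] = float(latent[d])

            u = rng.random()
            sex = Sex.MALE if u < p_male else Sex.FEMALE if u < p_male + p_female else Sex.UNKNOWN

            records.append(
                KittenRecord(
                    kitten_id=f"{litter_id}K{ki}",
                    litter_id=litter_id,
                    breed=breed.name,
                    sex=sex,
                    weights=weights,
                    status_2mo=Status.DEAD if dead else Status.ALIVE,
                    death_day=death_day,
                    bw_category=category,
                )
            )
    return records


def breed_threshold_table(config: SimConfig):
    """The breed threshold CSV content implied by a simulation config."""
    from .records import BreedThresholdTable

    return BreedThresholdTable({b.name: b.lbw_threshold_g for b in config.breeds})
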