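"""Synthetic participants: latent perceptual parameters and responses.

An :class:`Observer` bundles everything the two tasks need: the
blind-spot entry angle (drives the sweep task), a critical-spacing
function of eccentricity (drives the crowding task), psychometric shape
parameters, the true seating distance and its session-to-session drift,
and the covariates the cohort analyses use (age, dyslexia).

Crowding performance is modelled as a 2AFC Weibull psychometric
function of log spacing,

    p(s) = 0.5 + (0.5 - lapse) * F(s),
    F(s) = 1 - (1 - F*) ** ((s / c)**beta),

anchored so that at the critical spacing ``c`` (and the default lapse of
0.01) p equals 0.5**(1/3) = 0.794 -- the convergence point of the 1-up
3-down staircase.  "Critical spacing" is thereby operationally identical
to the spacing the staircase estimates.

The population generator encodes the structure the cohort analyses are
meant to recover: critical spacing proportional to eccentricity (the
mean latent Bouma ratio, 0.38 by default, is calibrated so the measured
cohort means come out at ~0.40-0.44 of eccentricity once the short
staircase's small upward measurement bias is included), an additive
dyslexia shift (+0.26 deg at 6%
prevalence), a shallow quadratic age effect around a configurable vertex
age, blind-spot entry angles from a truncated normal (13.59 +/- 0.96 deg,
range [11.53, 16.01]), and seating distances from a truncated normal
matching the observed online range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .staircase import convergence_probability

#: Guess rate of the two-alternative gap task (gap up vs gap down).
GUESS_RATE = 0.5

#: Default lapse rate; the psychometric anchor below uses this value.
DEFAULT_LAPSE = 0.01

#: Equilibrium accuracy of the 1-up 3-down rule, 0.5**(1/3).
P_CONVERGENCE = convergence_probability(3)

# F(critical spacing) such that p(critical spacing) hits the staircase
# convergence point when the lapse rate is at its default.
_F_AT_CS = (P_CONVERGENCE - GUESS_RATE) / (1.0 - GUESS_RATE - DEFAULT_LAPSE)

PHASES = ("pre", "mid", "post")


@dataclass
class Observer:
    """Latent parameters of one simulated participant."""

    blindspot_entry_deg: float = 13.5
    bouma_ratio: float = 0.38
    psychometric_slope: float = 3.5
    lapse_rate: float = DEFAULT_LAPSE
    true_distance_mm: float = 530.0
    distance_drift_sd_mm: float = 44.0
    age_years: float = 26.0
    dyslexia: bool = False
    dyslexia_effect_deg: float = 0.26
    age_quadratic_coeff: float = 2.5e-4
    age_ref_years: float = 26.0

    #: Fixed by the task design (two response alternatives).
    guess_rate: float = field(default=GUESS_RATE, init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_rate <= 0.06:
            raise ValueError(f"lapse_rate must be in [0, 0.06], got {self.lapse_rate}")
        if not self.psychometric_slope > 0:
            raise ValueError(
                f"psychometric_slope must be > 0, got {self.psychometric_slope}"
            )

    def critical_spacing_deg(self, eccentricity_deg: float) -> float:
        """Crowding threshold at an eccentricity, degrees.

        Bouma-proportional term plus additive dyslexia and quadratic
        age contributions; floored at a small positive value.
        """
        cs = eccentricity_deg * self.bouma_ratio
        if self.dyslexia:
            cs += self.dyslexia_effect_deg
        cs += self.age_quadratic_coeff * (self.age_years - self.age_ref_years) ** 2
        return max(cs, 1e-6)


def p_correct(observer: Observer, spacing_deg: float,
              eccentricity_deg: float) -> float:
    """Probability of a correct gap report at a given spacing.

    Monotone non-decreasing in spacing, from the 0.5 guess rate at zero
    spacing to the 1 - lapse asymptote; passes through ~0.794 at the
    observer's critical spacing (exactly when lapse = 0.01).
    """
    if spacing_deg < 0:
        raise ValueError(f"spacing_deg must be >= 0, got {spacing_deg}")
    if spacing_deg == 0:
        return GUESS_RATE
    cs = observer.critical_spacing_deg(eccentricity_deg)
    f = 1.0 - (1.0 - _F_AT_CS) ** ((spacing_deg / cs) ** observer.psychometric_slope)
    return GUESS_RATE + (1.0 - GUESS_RATE - observer.lapse_rate) * f


def respond_crowding(observer: Observer, spacing_deg: float,
                     eccentricity_deg: float,
                     rng: np.random.Generator) -> bool:
    """One Bernoulli crowding response; reproducible under a fixed rng."""
    return bool(rng.random() < p_correct(observer, spacing_deg, eccentricity_deg))


def drift_distance(observer: Observer, phase: str,
                   rng: np.random.Generator) -> float:
    """True seating distance during one blind-spot phase, mm.

    Per-phase i.i.d. Gaussian drift around the observer's nominal
    distance; the marginal distribution does not depend on phase order.
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    d = observer.true_distance_mm + rng.normal(0.0, observer.distance_drift_sd_mm)
    return max(d, 50.0)


@dataclass
class PopulationConfig:
    """Population-level parameters of the synthetic cohort.

    Defaults encode the reference study conditions: latent Bouma ratio
    0.38 +/- 0.08 across observers, 6% dyslexia prevalence with a
    +0.26 deg threshold shift, ages ~ N(26.3, 12.4) truncated to
    [7, 71] with a shallow quadratic crowding-age curve, blind-spot
    entry angles ~ N(13.59, 0.96) truncated to [11.53, 16.01] deg, and
    seating distances ~ N(473, 89) mm truncated to [174, 683].
    """

    n: int = 1000
    bouma_ratio_mean: float = 0.38
    bouma_ratio_sd: float = 0.08
    bouma_ratio_range: tuple = (0.15, 0.75)
    dyslexia_prevalence: float = 0.06
    dyslexia_effect_deg: float = 0.26
    age_mean: float = 26.3
    age_sd: float = 12.4
    age_min: float = 7.0
    age_max: float = 71.0
    age_quadratic_coeff: float = 2.5e-4
    age_ref_years: float = 26.0
    blindspot_mean_deg: float = 13.59
    blindspot_sd_deg: float = 0.96
    blindspot_range_deg: tuple = (11.53, 16.01)
    distance_mean_mm: float = 473.0
    distance_sd_mm: float = 89.0
    distance_range_mm: tuple = (174.0, 683.0)
    distance_drift_sd_mm: float = 44.0
    lapse_range: tuple = (0.0, 0.02)
    slope_mean: float = 3.5
    slope_sd: float = 0.5
    slope_range: tuple = (2.0, 5.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError(f"n must be > 0, got {self.n}")
        if not 0 <= self.dyslexia_prevalence <= 1:
            raise ValueError(
                f"dyslexia_prevalence must be in [0, 1], got {self.dyslexia_prevalence}"
            )
        for name in ("lapse_range",):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"{name} must be within [0, 1], got {(lo, hi)}")


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_population(cfg: PopulationConfig,
                        rng: np.random.Generator | None = None) -> list[Observer]:
    """Draw a cohort of observers; identical under identical seeds."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    entry = _truncnorm(rng, cfg.blindspot_mean_deg, cfg.blindspot_sd_deg,
                       *cfg.blindspot_range_deg, size=n)
    ratio = _truncnorm(rng, cfg.bouma_ratio_mean, cfg.bouma_ratio_sd,
                       *cfg.bouma_ratio_range, size=n)
    age = _truncnorm(rng, cfg.age_mean, cfg.age_sd, cfg.age_min, cfg.age_max, size=n)
    dist = _truncnorm(rng, cfg.distance_mean_mm, cfg.distance_sd_mm,
                      *cfg.distance_range_mm, size=n)
    slope = _truncnorm(rng, cfg.slope_mean, cfg.slope_sd, *cfg.slope_range, size=n)
    dyslexia = rng.random(n) < cfg.dyslexia_prevalence
    lapse = rng.uniform(*cfg.lapse_range, size=n)
    return [
        Observer(
            blindspot_entry_deg=float(entry[i]),
            bouma_ratio=float(ratio[i]),
            psychometric_slope=float(slope[i]),
            lapse_rate=float(lapse[i]),
            true_distance_mm=float(dist[i]),
            distance_drift_sd_mm=cfg.distance_drift_sd_mm,
            age_years=float(age[i]),
            dyslexia=bool(dyslexia[i]),
            dyslexia_effect_deg=cfg.dyslexia_effect_deg,
            age_quadratic_coeff=cfg.age_quadratic_coeff,
            age_ref_years=cfg.age_ref_years,
        )
        for i in range(n)
    ]


def population_to_df(observers: Sequence[Observer]) -> pd.DataFrame:
    """Flatten a cohort to a DataFrame (one row per observer)."""
    return pd.DataFrame(
        {
            "observer_id": [f"obs-{i:04d}" for i in range(len(observers))],
            "age": [o.age_years for o in observers],
            "dyslexia": [o.dyslexia for o in observers],
            "bouma_ratio": [o.bouma_ratio for o in observers],
            "blindspot_entry_deg": [o.blindspot_entry_deg for o in observers],
            "true_distance_mm": [o.true_distance_mm for o in observers],
            "lapse": [o.lapse_rate for o in observers],
        }
    )
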