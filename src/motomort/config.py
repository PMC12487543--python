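"""Simulation configuration and ground-truth containers for the synthetic study.

The default configuration emulates the study conditions the pipeline is built
for: roughly 300 cities nested in 7 countries observed 2010-2019, negative
binomial motorcyclist death counts from a log-linear model with a city random
intercept, about 11% of external-cause deaths garbage-coded, per-city death
registration completeness below one with the true correction factor recorded,
male rates about 8x female rates peaking in the 20-24 age group, and one
strong exposure correlation (patch density vs intersection density, 0.7).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .standards import AGE_GROUPS, EXPOSURE_NAMES

#: Default true per-1-SD log rate ratios of the city exposures (transit is
#: per presence).  Magnitudes are in the range typical of adjusted city-level
#: built-environment associations with road mortality.
DEFAULT_BETA: dict[str, float] = {
    "nearest_neighbor_distance": math.log(1.07),
    "patch_density": math.log(1.02),
    "circuity": math.log(0.97),
    "street_length_avg": math.log(0.93),
    "intersection_density": math.log(0.91),
    "street_node_avg": math.log(1.04),
    "population_density": math.log(0.92),
    "transit_presence": math.log(0.94),
    "travel_delay_index": math.log(0.98),
    "gdp_per_capita": math.log(0.98),
    "social_environment_index": math.log(0.88),
}

#: Relative age profile of the motorcyclist baseline rate, peaking at 20-24.
DEFAULT_AGE_PROFILE: tuple[float, ...] = (
    0.02, 0.05, 0.35, 0.80, 1.00, 0.95, 0.85, 0.75, 0.60, 0.50, 0.40, 0.30,
    0.25, 0.20, 0.15, 0.12, 0.10,
)

#: Baseline rates of the other simulated cause groups, relative to the
#: motorcyclist baseline.  Other road users share the age profile, country
#: offsets, city intercept and exposure response (road environment is common
#: to all road users); non-traffic external deaths carry country offsets only.
DEFAULT_OTHER_RT_FACTORS: dict[str, float] = {
    "pedestrian": 1.0, "bicyclist": 0.15, "car_occupant": 0.9, "other_rt": 0.2,
}

#: Flat non-road-traffic external death rates per 100,000 by sex.
DEFAULT_NON_RT_RATE: dict[str, float] = {"M": 45.0, "F": 15.0}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-country city study."""

    n_countries: int = 7
    cities_per_country: int = 43
    years: tuple[int, int] = (2010, 2019)
    age_groups: Sequence[str] = AGE_GROUPS
    #: true exposure effects, log RR per 1 SD (per presence for transit)
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    #: SD of the city random intercept on the log-rate scale
    sigma_city: float = 0.3
    #: SD of the fixed country log-offsets; the default keeps the share of
    #: city-rate variance between countries low (within-country ICC ~ 0.1)
    sigma_country: float = 0.13
    #: NB2 dispersion: Var = mu + alpha * mu^2
    alpha_nb: float = 0.5
    #: fraction of external-cause deaths garbage-coded
    p_illdefined: float = 0.11
    #: among garbage-coded road-traffic deaths, share sent to partially-defined
    partial_share: float = 0.5
    #: optional dependence of garbage propensity on the city's (z-scored)
    #: social-environment index; > 0 means poorer cities code worse
    p_illdefined_gradient: float = 0.0
    #: per-city death-registration completeness; None -> drawn per city
    completeness: Mapping[str, float] | None = None
    completeness_range: tuple[float, float] = (0.85, 1.0)
    #: target exposure correlations, keyed by frozenset-able name pairs
    exposure_corr: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("patch_density", "intersection_density"): 0.7})
    #: male baseline rate in the peak (20-24) age group, per 100,000 per year
    baseline_peak_rate: float = 15.0
    male_female_ratio: float = 8.0
    age_profile: Sequence[float] = DEFAULT_AGE_PROFILE
    other_rt_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OTHER_RT_FACTORS))
    non_rt_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NON_RT_RATE))
    #: lognormal city-size distribution (median, sigma of log), min 100k
    city_pop_median: float = 300_000.0
    city_pop_sigma: float = 0.8
    annual_pop_growth: float = 0.01
    #: fraction of cities with motorcycle registration data
    registration_coverage: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1 or self.cities_per_country < 1:
            raise ValueError("n_countries and cities_per_country must be >= 1")
        if len(tuple(self.age_groups)) != 17:
            raise ValueError("age_groups must have exactly 17 entries")
        if len(self.age_profile) != 17:
            raise ValueError("age_profile must have exactly 17 entries")
        if not (0.0 <= self.p_illdefined < 1.0):
            raise ValueError("p_illdefined must be in [0, 1)")
        if not (0.0 <= self.partial_share <= 1.0):
            raise ValueError("partial_share must be in [0, 1]")
        if self.sigma_city < 0 or self.sigma_country < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.alpha_nb < 0:
            raise ValueError("alpha_nb must be >= 0")
        lo, hi = self.completeness_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("completeness_range must satisfy 0 < lo <= hi <= 1")
        if self.completeness is not None:
            bad = {c: v for c, v in self.completeness.items() if not 0.0 < v <= 1.0}
            if bad:
                raise ValueError(f"completeness values outside (0, 1]: {bad}")
        if self.years[1] < self.years[0]:
            raise ValueError("years must be an inclusive (first, last) range")
        unknown = set(self.beta) - set(EXPOSURE_NAMES)
        if unknown:
            raise ValueError(f"beta refers to unknown exposures: {sorted(unknown)}")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def n_cities(self) -> int:
        return self.n_countries * self.cities_per_country


@dataclass
class GroundTruth:
    """Everything the generator knew; consumed only by tests, never the pipeline."""

    beta: dict[str, float]
    country_effects: dict[str, float]
    city_intercepts: dict[str, float]
    completeness: dict[str, float]
    #: pre-thinning, pre-garbage-coding death totals by cause group
    true_totals: dict[str, int]
    #: pre-thinning, pre-garbage-coding motorcyclist deaths per city
    true_moto_by_city: dict[str, int]
    #: total true person-years (population summed over years)
    true_person_years: float
    sigma_city: float
    alpha_nb: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["true_totals"] = {k: int(v) for k, v in d["true_totals"].items()}
        d["true_moto_by_city"] = {k: int(v) for k, v in d["true_moto_by_city"].items()}
        return cls(**d)


def build_correlation_matrix(
    targets: Mapping[tuple[str, str], float],
    names: Sequence[str] = EXPOSURE_NAMES,
) -> np.ndarray:
    """Assemble the full exposure correlation matrix from sparse pair targets.

    Raises ValueError naming the offending pairs if the resulting matrix is
    not positive semi-definite.
    """
    names = list(names)
    idx = {n: i for i, n in enumerate(names)}
    corr = np.eye(len(names))
    for (a, b), r in targets.items():
        if a not in idx or b not in idx:
            raise ValueError(f"unknown exposure pair ({a}, {b})")
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation target out of range for ({a}, {b}): {r}")
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-10:
        involved = sorted({n for pair in targets for n in pair})
        raise ValueError(
            "exposure correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3g}); offending submatrix over {involved}")
    return corr
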