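"""Corrected person-years and crude / age-specific / age-standardized rates.

Person-years for a city are the sum over calendar years of the yearly
population estimate multiplied by that year's registration-completeness
correction factor; rates are deaths per 100,000 person-years.  Direct
standardization weights a city's age-specific rates by a fixed external
standard population (the packaged WHO world standard for 2000-2025 by
default), so that age-structure differences between cities do not drive rate
comparisons.  The registration-denominator variant divides by motorcycle
registration-years instead of person-years.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .standards import load_standard_population

logger = logging.getLogger(__name__)


def build_person_years(population: pd.DataFrame,
                       correction_factors: pd.DataFrame | None,
                       default_factor: float | None = None) -> pd.DataFrame:
    """Aggregate corrected person-years to (city, sex, age group).

    ``population`` has columns city_id, year, sex, age_group, population;
    ``correction_factors`` has city_id, year, factor (> 0).  A (city, year)
    without a factor uses ``default_factor`` with a warning, or raises if
    that is None.
    """
    if (population["population"] < 0).any():
        raise ValueError("negative population counts")
    pop = population.copy()
    if correction_factors is not None:
        if (correction_factors["factor"] <= 0).any():
            raise ValueError("correction factors must be > 0")
        pop = pop.merge(correction_factors[["city_id", "year", "factor"]],
                        on=["city_id", "year"], how="left")
    else:
        pop["factor"] = np.nan
    missing = pop["factor"].isna()
    if missing.any():
        if default_factor is None:
            pairs = pop.loc[missing, ["city_id", "year"]].drop_duplicates()
            raise ValueError(
                f"missing correction factors for {len(pairs)} city-years "
                f"(e.g. {pairs.head(3).to_dict('records')})")
        logger.warning("using default correction factor %.3f for %d rows",
                       default_factor, int(missing.sum()))
        pop.loc[missing, "factor"] = default_factor
    pop["person_years"] = pop["population"] * pop["factor"]
    cols = ["city_id", "sex", "age_group"]
    if "country_id" in pop.columns:
        cols = ["city_id", "country_id", "sex", "age_group"]
    return (pop.groupby(cols, observed=True, sort=True)["person_years"]
               .sum().reset_index())


def crude_rate(deaths: float, person_years: float) -> float:
    """Deaths per 100,000 person-years."""
    if person_years < 0:
        raise ValueError("person-years must be non-negative")
    if person_years == 0:
        if deaths > 0:
            raise ZeroDivisionError("rate undefined: deaths with zero person-years")
        return 0.0
    return 1e5 * deaths / person_years


def age_specific_rates(deaths_by_age: pd.Series,
                       py_by_age: pd.Series) -> pd.Series:
    """Rates per 100,000 by age group; zero person-years with deaths is an error."""
    deaths_by_age, py_by_age = deaths_by_age.align(py_by_age, fill_value=0.0)
    bad = (py_by_age == 0) & (deaths_by_age > 0)
    if bad.any():
        raise ZeroDivisionError(
            f"deaths with zero person-years in age groups {list(bad[bad].index)}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = 1e5 * deaths_by_age / py_by_age
    return r.where(py_by_age > 0)  # NaN marks genuinely undefined groups


def age_standardize(age_rates: pd.Series,
                    standard: dict[str, float] | None = None) -> float:
    """Directly standardized rate: weighted mean of age-specific rates.

    ``age_rates`` is indexed by age-group label (per 100,000).  Weights are
    normalized to unit sum.  An age group with positive standard weight but
    an undefined (NaN/missing) rate raises, naming the group: an absent rate
    is not a zero rate.
    """
    std = standard if standard is not None else load_standard_population()
    weights = pd.Series(std, dtype=float)
    weights = weights / weights.sum()
    rates = age_rates.reindex(weights.index)
    undefined = rates.isna() & (weights > 0)
    if undefined.any():
        raise ValueError(
            "age-specific rate undefined for standard-weighted groups "
            f"{list(undefined[undefined].index)}")
    return float((weights * rates).sum())


def standardized_rates_by_city(counts: pd.DataFrame,
                               person_years: pd.DataFrame,
                               by_sex: bool = False,
                               standard: dict[str, float] | None = None,
                               ) -> pd.DataFrame:
    """Age-standardized rate per city (optionally per sex).

    ``counts`` holds (city_id[, sex], age_group, n_motorcyclist) pooled over
    the study period — typically draw-specific or draw-averaged redistributed
    counts; ``person_years`` comes from :func:`build_person_years`.
    """
    std = standard if standard is not None else load_standard_population()
    keys = ["city_id", "sex"] if by_sex else ["city_id"]
    d = (counts.groupby(keys + ["age_group"], observed=True)["n_motorcyclist"]
               .sum())
    p = (person_years.groupby(keys + ["age_group"], observed=True)["person_years"]
                      .sum())
    lev = list(range(len(keys))) if len(keys) > 1 else 0
    rows = []
    for key, py_age in p.groupby(level=lev):
        py_age = py_age.droplevel(lev)
        key = key if isinstance(key, tuple) else (key,)
        try:
            d_age = d.loc[key]
        except KeyError:
            d_age = pd.Series(0.0, index=py_age.index)
        rates = age_specific_rates(d_age, py_age)
        rows.append((*key, age_standardize(rates, std)))
    return pd.DataFrame(rows, columns=keys + ["std_rate"])


def registration_rate(deaths: float, registration_years: float) -> float:
    """Deaths per 100,000 motorcycle registration-years."""
    if registration_years <= 0:
        raise ValueError("registration-years must be > 0")
    return 1e5 * deaths / registration_years


def registration_rates_by_city(counts_avg: pd.DataFrame,
                               registrations: pd.Series,
                               n_years: int) -> pd.DataFrame:
    """Both-sex all-age rates per 100,000 registration-years.

    ``registrations`` maps city_id to the absolute registered-motorcycle
    count (a single reference-year level, held constant over ``n_years``).
    Cities with missing registrations are excluded with a logged notice.
    """
    deaths = counts_avg.groupby("city_id", observed=True)["n_motorcyclist"].sum()
    reg = registrations.dropna()
    excluded = sorted(set(deaths.index) - set(reg.index))
    if excluded:
        logger.info("registration denominator missing for %d cities: %s...",
                    len(excluded), excluded[:5])
    cities = deaths.index.intersection(reg.index)
    rows = [(c, registration_rate(float(deaths[c]), float(reg[c]) * n_years))
            for c in cities]
    return pd.DataFrame(rows, columns=["city_id", "registration_rate"])


def summarize_rates(city_rates: pd.DataFrame,
                    by: list[str] | None = None,
                    value: str = "std_rate") -> pd.DataFrame:
    """Median and IQR of city-level rates, e.g. by country and sex.

    Rates must already be averaged across redistribution draws.  Quantiles
    use linear interpolation (numpy default, type 7).
    """
    by = by or ["country_id"]
    def q(s, p):
        return float(np.quantile(s.to_numpy(float), p))
    out = (city_rates.groupby(by, observed=True)[value]
           .agg(n="size",
                median=lambda s: q(s, 0.5),
                q25=lambda s: q(s, 0.25),
                q75=lambda s: q(s, 0.75))
           .reset_index())
    return out
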