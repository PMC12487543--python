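"""Per-draw model fitting and Rubin's-rule pooling across redistributions.

Each of the M redistribution draws yields a motorcyclist death count per
city x sex x age stratum; the NB mixed model is fitted to every draw and the
exposure coefficients are pooled with Rubin's rule: pooled estimate Q-bar is
the mean across draws, total variance T = W + (1 + 1/M) B with W the mean
within-draw variance and B the between-draw variance, and the classic Rubin
degrees of freedom (M - 1)(1 + W / ((1 + 1/M) B))^2.  Confidence intervals
are built on the log-RR scale with the t quantile and exponentiated.

Model 1 fits one exposure at a time (adjusted for country, sex, age);
Model 2 includes all exposures simultaneously.  Exposures are z-scored once
on the full analysis city set (denominators are draw-invariant), except the
binary transit indicator.  A registration subanalysis restricts to cities
with motorcycle registration data and adds the motorization rate; the
street-layout sensitivity analysis refits Model 2 on subsets of the four
interrelated street variables.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import causes, demography
from .nbmm import NBMixedModel
from .standards import (AGE_GROUPS, BINARY_EXPOSURES, EXPOSURE_NAMES,
                        MOTORIZATION_COL, STREET_LAYOUT_VARS)

logger = logging.getLogger(__name__)

CONVERGENCE_QUORUM = 0.9


def standardize_exposures(exposures: pd.DataFrame,
                          columns=None,
                          binary=BINARY_EXPOSURES,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """z-score exposures over the analysis city set (sample SD, ddof=1).

    Binary indicators are left as 0/1.  Returns the transformed frame and a
    (mean, sd) table so per-SD rate ratios can be mapped back to raw units.
    Zero-variance columns raise, naming the column.
    """
    if len(exposures) < 2:
        raise ValueError("standardization needs >= 2 cities")
    columns = list(columns) if columns is not None else [
        c for c in EXPOSURE_NAMES if c in exposures.columns]
    out = exposures.copy()
    scale_rows = []
    for c in columns:
        col = out[c].astype(float)
        if c in binary:
            scale_rows.append((c, 0.0, 1.0))
            continue
        m, sd = col.mean(), col.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"zero-variance exposure: {c}")
        out[c] = (col - m) / sd
        scale_rows.append((c, float(m), float(sd)))
    scales = pd.DataFrame(scale_rows, columns=["term", "mean", "sd"])
    return out, scales


@dataclass
class PooledFit:
    """Rubin-pooled estimate for one exposure term."""

    term: str
    model_tag: str
    q_bar: float
    W: float
    B: float
    T: float
    df: float
    m: int
    n_draws_used: int

    @property
    def rr(self) -> float:
        return float(np.exp(self.q_bar))

    @property
    def ci(self) -> tuple[float, float]:
        q = stats.norm.ppf(0.975) if np.isinf(self.df) \
            else stats.t.ppf(0.975, self.df)
        half = q * np.sqrt(self.T)
        return float(np.exp(self.q_bar - half)), float(np.exp(self.q_bar + half))

    def as_row(self) -> dict:
        lo, hi = self.ci
        return {"term": self.term, "model_tag": self.model_tag, "rr": self.rr,
                "ci_low": lo, "ci_high": hi, "q_bar": self.q_bar, "W": self.W,
                "B": self.B, "T": self.T, "df": self.df, "m": self.m,
                "n_draws_used": self.n_draws_used}


def rubins_rule(estimates, variances, term: str = "", model_tag: str = "",
                ) -> PooledFit:
    """Combine per-draw estimates and variances.

    Q-bar = mean estimate, W = mean variance, B = sample variance of the
    estimates, T = W + (1 + 1/M) B; df = (M-1)(1 + W/((1+1/M)B))^2 for B > 0
    and infinity when B = 0 (all draws identical) or M = 1.
    """
    est = np.asarray(estimates, float)
    var = np.asarray(variances, float)
    if est.shape != var.shape or est.ndim != 1 or len(est) < 1:
        raise ValueError("estimates and variances must be equal-length 1-D")
    bad = np.where(~np.isfinite(est) | ~np.isfinite(var))[0]
    if len(bad):
        raise ValueError(f"non-finite inputs at draw indices {list(map(int, bad))}")
    if (var < 0).any():
        raise ValueError("negative variances")
    m = len(est)
    q_bar = float(est.mean())
    w = float(var.mean())
    b = float(est.var(ddof=1)) if m > 1 else 0.0
    t = w + (1.0 + 1.0 / m) * b
    if b > 0 and m > 1:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    else:
        df = np.inf
    return PooledFit(term=term, model_tag=model_tag, q_bar=q_bar, W=w, B=b,
                     T=t, df=float(df), m=m, n_draws_used=m)


# --------------------------------------------------------------------------
# study container and design construction


@dataclass
class StudyData:
    """Draw-level counts plus draw-invariant denominators and exposures."""

    counts_by_draw: pd.DataFrame      # draw, city_id, country_id, sex, age_group, n
    person_years: pd.DataFrame        # city_id, country_id, sex, age_group, py
    exposures_z: pd.DataFrame         # city-level, standardized
    exposure_scales: pd.DataFrame
    n_draws: int
    draw_summaries: list = field(default_factory=list)
    dropped_strata: int = 0


def prepare_study(deaths: pd.DataFrame, population: pd.DataFrame,
                  factors: pd.DataFrame, exposures: pd.DataFrame,
                  n_draws: int = 100, seed: int = 0,
                  pooling_years: int = 3, two_stage: bool = True,
                  year_range=None) -> StudyData:
    """Classify causes, redistribute garbage codes, build corrected
    person-years and standardized exposures."""
    classified = causes.classify_table(deaths)
    probs = causes.build_redistribution_probs(
        classified, pooling_years=pooling_years, year_range=year_range)
    counts, summaries = causes.redistribute(
        classified, probs, n_draws=n_draws, seed=seed, two_stage=two_stage)
    py = demography.build_person_years(population, factors)
    z, scales = standardize_exposures(exposures)
    return StudyData(counts_by_draw=counts, person_years=py, exposures_z=z,
                     exposure_scales=scales, n_draws=n_draws,
                     draw_summaries=summaries)


def build_design(py: pd.DataFrame, counts_one_draw: pd.DataFrame,
                 exposures_z: pd.DataFrame, exposure_terms: list[str],
                 ):
    """Assemble (y, X, offset, groups, names) for one draw's fit.

    The outcome grid is every stratum with positive person-years; strata
    without redistributed deaths count zero.  Fixed effects: intercept,
    country indicators (reference: first alphabetically), male indicator
    (reference female), age-group indicators (reference youngest), then the
    exposure terms.
    """
    df = py.merge(
        counts_one_draw[["city_id", "sex", "age_group", "n_motorcyclist"]],
        on=["city_id", "sex", "age_group"], how="left")
    df["n_motorcyclist"] = df["n_motorcyclist"].fillna(0.0)
    dropped = int((df["person_years"] <= 0).sum())
    if dropped:
        logger.info("dropping %d zero person-year strata", dropped)
        df = df[df["person_years"] > 0]
    df = df.merge(exposures_z[["city_id"] + exposure_terms], on="city_id",
                  how="left")
    df = df.sort_values(["city_id", "sex", "age_group"], kind="mergesort",
                        ignore_index=True)

    cols = [np.ones(len(df))]
    names = ["const"]
    for c in sorted(df["country_id"].unique())[1:]:
        cols.append((df["country_id"] == c).to_numpy(float))
        names.append(f"country[{c}]")
    cols.append((df["sex"] == "M").to_numpy(float))
    names.append("sex[M]")
    ages = [a for a in AGE_GROUPS if a in set(df["age_group"])]
    for a in ages[1:]:
        cols.append((df["age_group"] == a).to_numpy(float))
        names.append(f"age[{a}]")
    for t in exposure_terms:
        cols.append(df[t].to_numpy(float))
        names.append(t)
    X = np.column_stack(cols)
    y = df["n_motorcyclist"].to_numpy(float)
    offset = np.log(df["person_years"].to_numpy(float))
    groups = df["city_id"].to_numpy()
    return y, X, offset, groups, names, dropped


def _pool_term_fits(fits: list, terms: list[str], model_tag: str,
                    n_draws: int, variance_mode: str) -> list[PooledFit]:
    converged = [f for f in fits if f.converged]
    if len(converged) < CONVERGENCE_QUORUM * n_draws:
        raise RuntimeError(
            f"{model_tag}: only {len(converged)}/{n_draws} draws converged "
            f"(quorum {CONVERGENCE_QUORUM:.0%})")
    if len(converged) < n_draws:
        logger.warning("%s: pooling over %d/%d converged draws", model_tag,
                       len(converged), n_draws)
    pooled = []
    for term in terms:
        est = [float(f.beta[term]) for f in converged]
        idx = converged[0].exog_names.index(term)
        cov = "cov_robust" if variance_mode == "robust" else "cov_model"
        var = [float(getattr(f, cov)[idx, idx]) for f in converged]
        pf = rubins_rule(est, var, term=term, model_tag=model_tag)
        pf.m = n_draws
        pf.n_draws_used = len(converged)
        pooled.append(pf)
    return pooled


def _fit_draws(study: StudyData, exposure_terms: list[str], model_tag: str,
               variance_mode: str = "robust",
               py: pd.DataFrame | None = None,
               exposures_z: pd.DataFrame | None = None,
               counts: pd.DataFrame | None = None,
               n_quad: int = 15) -> list[PooledFit]:
    py = py if py is not None else study.person_years
    exposures_z = exposures_z if exposures_z is not None else study.exposures_z
    counts = counts if counts is not None else study.counts_by_draw
    fits = []
    start = None
    for d in sorted(counts["draw"].unique()):
        cd = counts[counts["draw"] == d]
        y, X, off, grp, names, _ = build_design(py, cd, exposures_z,
                                                exposure_terms)
        model = NBMixedModel(y, X, off, grp, exog_names=names, n_quad=n_quad)
        res = model.fit(start_params=start)
        if res.converged:
            start = res.params
        fits.append(res)
    return _pool_term_fits(fits, exposure_terms, model_tag,
                           len(counts["draw"].unique()), variance_mode)


def run_model1(study: StudyData, exposures: list[str] | None = None,
               variance_mode: str = "robust") -> list[PooledFit]:
    """Single-exposure models, one per exposure, each Rubin-pooled."""
    exposures = exposures if exposures is not None else [
        c for c in EXPOSURE_NAMES if c in study.exposures_z.columns]
    pooled = []
    for term in exposures:
        pooled += _fit_draws(study, [term], f"M1:{term}", variance_mode)
    return pooled


def collinearity_diagnostics(exposures_z: pd.DataFrame,
                             terms: list[str]) -> dict:
    Z = exposures_z[terms].to_numpy(float)
    Zc = Z - Z.mean(axis=0)
    corr = np.corrcoef(Zc, rowvar=False)
    vif = np.diag(np.linalg.pinv(corr))
    return {"condition_number": float(np.linalg.cond(Zc)),
            "max_vif": float(np.max(vif)),
            "vif": dict(zip(terms, map(float, vif)))}


def run_model2(study: StudyData, exposures: list[str] | None = None,
               variance_mode: str = "robust") -> list[PooledFit]:
    """Multivariable model with all exposures simultaneously."""
    exposures = exposures if exposures is not None else [
        c for c in EXPOSURE_NAMES if c in study.exposures_z.columns]
    diag = collinearity_diagnostics(study.exposures_z, [
        t for t in exposures if t not in BINARY_EXPOSURES])
    logger.info("Model 2 collinearity: condition number %.1f, max VIF %.2f",
                diag["condition_number"], diag["max_vif"])
    return _fit_draws(study, exposures, "M2", variance_mode)


def run_subanalysis(study: StudyData, variance_mode: str = "robust",
                    min_cities: int = 10) -> list[PooledFit]:
    """Registration subanalysis: restrict to cities with motorcycle
    registration data and add the (z-scored) motorization rate to Model 1
    and Model 2."""
    z = study.exposures_z
    if MOTORIZATION_COL not in z.columns:
        raise ValueError("no motorcycle registration column in exposures")
    sub = z[z[MOTORIZATION_COL].notna()].copy()
    if len(sub) < min_cities:
        raise ValueError(
            f"registration subanalysis needs >= {min_cities} cities with "
            f"data; found {len(sub)}")
    m, sd = sub[MOTORIZATION_COL].mean(), sub[MOTORIZATION_COL].std(ddof=1)
    if not sd > 0:
        raise ValueError("zero-variance exposure: " + MOTORIZATION_COL)
    sub[MOTORIZATION_COL] = (sub[MOTORIZATION_COL] - m) / sd
    cities = set(sub["city_id"])
    py = study.person_years[study.person_years["city_id"].isin(cities)]
    counts = study.counts_by_draw[study.counts_by_draw["city_id"].isin(cities)]
    exposures = [c for c in EXPOSURE_NAMES if c in sub.columns]
    out = _fit_draws(study, [MOTORIZATION_COL], "M1-sub", variance_mode,
                     py=py, exposures_z=sub, counts=counts)
    out += _fit_draws(study, exposures + [MOTORIZATION_COL], "M2-sub",
                      variance_mode, py=py, exposures_z=sub, counts=counts)
    return out


def run_sensitivity(study: StudyData, street_subsets: list[list[str]],
                    variance_mode: str = "robust") -> list[PooledFit]:
    """Street-layout sensitivity: Model 2 refitted per street-variable subset."""
    if not street_subsets:
        logger.info("sensitivity: empty subset list, nothing to do")
        return []
    out = []
    for subset in street_subsets:
        bad = set(subset) - set(STREET_LAYOUT_VARS)
        if bad:
            raise ValueError(f"not street-layout variables: {sorted(bad)}")
        tag = "sensitivity:" + "+".join(subset)
        # canonical term order: a full street subset reproduces Model 2 exactly
        terms = [c for c in EXPOSURE_NAMES
                 if c in study.exposures_z.columns
                 and (c not in STREET_LAYOUT_VARS or c in subset)]
        out += _fit_draws(study, terms, tag, variance_mode)
    return out


def pooled_to_frame(pooled: list[PooledFit]) -> pd.DataFrame:
    return pd.DataFrame([p.as_row() for p in pooled])


# --------------------------------------------------------------------------
# end-to-end run


def run_pipeline(config, n_draws: int = 100, outdir=None, seed=None,
                 with_subanalysis: bool = True) -> dict:
    """Simulate, redistribute, compute rates, fit Models 1 and 2, pool.

    Returns the result tables; if ``outdir`` is given, writes
    results_model1.csv / results_model2.csv / results_sub.csv / rates.csv
    and summary.json with stable formatting (byte-identical given the same
    config and seed).
    """
    from . import descriptives, synthetic

    seed = config.seed if seed is None else seed
    exposures, deaths, population, factors, truth = synthetic.generate_study(
        config)
    study = prepare_study(deaths, population, factors, exposures,
                          n_draws=n_draws, seed=seed,
                          year_range=tuple(config.years))

    counts_avg = causes.average_over_draws(study.counts_by_draw)
    std_rates = demography.standardized_rates_by_city(
        counts_avg, study.person_years)
    std_rates = std_rates.merge(
        study.person_years[["city_id", "country_id"]].drop_duplicates(),
        on="city_id")
    rate_summary = demography.summarize_rates(std_rates, by=["country_id"])

    m1 = run_model1(study)
    m2 = run_model2(study)
    sub = []
    if with_subanalysis:
        try:
            sub = run_subanalysis(study)
        except ValueError as e:
            logger.info("subanalysis skipped: %s", e)

    results = {
        "model1": pooled_to_frame(m1),
        "model2": pooled_to_frame(m2),
        "sub": pooled_to_frame(sub) if sub else pd.DataFrame(),
        "std_rates": std_rates,
        "rate_summary": rate_summary,
        "icc": descriptives.within_country_icc(
            std_rates["std_rate"], std_rates["country_id"]),
        "study": study,
        "truth": truth,
    }
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        fmt = "%.12g"
        results["model1"].to_csv(os.path.join(outdir, "results_model1.csv"),
                                 index=False, float_format=fmt)
        results["model2"].to_csv(os.path.join(outdir, "results_model2.csv"),
                                 index=False, float_format=fmt)
        results["sub"].to_csv(os.path.join(outdir, "results_sub.csv"),
                              index=False, float_format=fmt)
        # long-format rate table: crude and standardized per city
        crude_city = (counts_avg.groupby("city_id")["n_motorcyclist"].sum()
                      .to_frame("deaths")
                      .join(study.person_years.groupby("city_id")
                            ["person_years"].sum().rename("denominator")))
        crude_city["rate"] = 1e5 * crude_city["deaths"] / crude_city["denominator"]
        rows = []
        for cid, r in crude_city.iterrows():
            rows.append(("city", cid, "both", "all", "population",
                         r["rate"], r["deaths"], r["denominator"]))
        for _, r in std_rates.iterrows():
            rows.append(("city", r["city_id"], "both", "age-standardized",
                         "population", r["std_rate"], np.nan, np.nan))
        rates_long = pd.DataFrame(rows, columns=[
            "level", "unit_id", "sex", "age", "denominator_type", "rate",
            "deaths", "denominator"])
        rates_long.to_csv(os.path.join(outdir, "rates.csv"), index=False,
                          float_format=fmt)
        summary = {
            "n_cities": int(std_rates["city_id"].nunique()),
            "n_draws": n_draws,
            "icc": results["icc"],
            "draw_summaries": study.draw_summaries,
        }
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    return results
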