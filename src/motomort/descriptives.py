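"""Descriptive surfaces: quartile tables with Wald tests, Pearson
correlations, within-country ICC and sex/age rate profiles.

Cities are split into quartiles of the age-standardized motorcyclist
mortality rate by rank, so group sizes differ by at most one (337 cities
give 84/84/84/85).  The between-quartile Wald test regresses the rank-based
inverse-normal transform of each exposure on three quartile indicators and
jointly tests those coefficients with a heteroskedasticity-robust (HC3)
covariance; the transform makes the test invariant to monotone re-scaling
of skewed exposures.  The intraclass correlation uses one-way
random-effects ANOVA estimators on log rates: the share of total variance
in city rates attributable to between-country differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .standards import BINARY_EXPOSURES, EXPOSURE_NAMES, MOTORIZATION_COL


def assign_quartiles(values: pd.Series) -> tuple[pd.Series, np.ndarray]:
    """Rank-based quartile membership (1..4) and the value boundaries.

    Sizes differ by at most one, with the remainder in the top quartile;
    membership depends only on ranks, hence is invariant under strictly
    monotone transforms of the ranking variable.
    """
    n = len(values)
    if n < 8:
        raise ValueError(f"quartiles need >= 8 cities, got {n}")
    base = n // 4
    sizes = [base, base, base, n - 3 * base]
    order = np.argsort(values.to_numpy(), kind="mergesort")
    q = np.empty(n, int)
    start = 0
    for i, s in enumerate(sizes, start=1):
        q[order[start:start + s]] = i
        start += s
    labels = pd.Series(q, index=values.index, name="quartile")
    bounds = np.quantile(values.to_numpy(float), [0.0, 0.25, 0.5, 0.75, 1.0])
    return labels, bounds


def _inverse_normal(x: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse normal transform (average ranks for ties)."""
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 0.375) / (len(x) + 0.25))


def quartile_wald_p(exposure: np.ndarray, quartile: np.ndarray) -> float:
    """Joint robust Wald P value that exposure differs across quartiles."""
    y = _inverse_normal(np.asarray(exposure, float))
    if np.allclose(y, y[0]):
        return 1.0
    dummies = np.column_stack([(quartile == q).astype(float)
                               for q in (2, 3, 4)])
    X = sm.add_constant(dummies)
    res = sm.OLS(y, X).fit(cov_type="HC3")
    if np.allclose(res.params[1:], 0.0):
        return 1.0
    wt = res.wald_test(np.eye(4)[1:], scalar=True)
    return float(wt.pvalue)


def quartile_table(city_rates: pd.Series, exposures: pd.DataFrame,
                   columns=None) -> pd.DataFrame:
    """Median (IQR) of each exposure within rate quartiles, plus Wald P.

    ``city_rates`` is indexed by city_id; ``exposures`` must carry the same
    cities.  Binary exposures report count and percent instead of medians.
    """
    expo = exposures.set_index("city_id").loc[city_rates.index]
    quart, bounds = assign_quartiles(city_rates)
    columns = list(columns) if columns is not None else [
        c for c in (*EXPOSURE_NAMES, MOTORIZATION_COL) if c in expo.columns]
    rows = []
    for c in columns:
        vals = expo[c]
        mask = vals.notna()
        row = {"exposure": c}
        for q in (1, 2, 3, 4):
            sel = vals[mask & (quart == q)]
            row[f"n_q{q}"] = len(sel)
            if c in BINARY_EXPOSURES:
                row[f"q{q}"] = (f"{int(sel.sum())} "
                                f"({100 * sel.mean():.1f}%)" if len(sel) else "")
            else:
                med = sel.median()
                lo, hi = sel.quantile([0.25, 0.75])
                row[f"q{q}"] = f"{med:.2f} ({lo:.2f} to {hi:.2f})"
        row["wald_p"] = quartile_wald_p(vals[mask].to_numpy(),
                                        quart[mask].to_numpy())
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["quartile_bounds"] = bounds
    out.attrs["quartile_sizes"] = quart.value_counts().sort_index().tolist()
    return out


def correlation_matrix(exposures: pd.DataFrame, columns=None,
                       ) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations; zero-variance columns are NaN."""
    columns = list(columns) if columns is not None else [
        c for c in EXPOSURE_NAMES if c in exposures.columns
        and c not in BINARY_EXPOSURES]
    sub = exposures[columns].astype(float)
    if len(sub) < 3:
        raise ValueError("correlations need >= 3 cities")
    corr = sub.corr(method="pearson", min_periods=3)
    for c in columns:
        if sub[c].std(ddof=1) == 0:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
    return corr


def correlation_bands(corr: pd.DataFrame) -> pd.DataFrame:
    """Band |r| as weak (<0.3), moderate (0.3-0.6) or strong (>0.6)."""
    rows = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if pd.isna(r):
                band = "undefined"
            elif abs(r) > 0.6:
                band = "strong"
            elif abs(r) >= 0.3:
                band = "moderate"
            else:
                band = "weak"
            rows.append({"var1": a, "var2": b, "r": r, "band": band})
    return pd.DataFrame(rows)


def within_country_icc(city_rates, countries, log_scale: bool = True) -> float:
    """One-way random-effects ANOVA ICC of city rates within countries.

    sigma2_between / (sigma2_between + sigma2_within) with variance
    components from the unbalanced one-way ANOVA estimators; a negative
    between component is truncated at zero.  Computed on log rates by
    default (variance stabilization); ``log_scale=False`` uses the natural
    scale.
    """
    y = np.asarray(city_rates, float)
    g = np.asarray(countries)
    if log_scale:
        if (y <= 0).any():
            raise ValueError("log-scale ICC requires strictly positive rates")
        y = np.log(y)
    labels, idx = np.unique(g, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("ICC needs >= 2 countries")
    n_i = np.bincount(idx)
    if (n_i >= 2).sum() < 2:
        raise ValueError("ICC needs >= 2 countries with >= 2 cities")
    n = len(y)
    means = np.bincount(idx, weights=y) / n_i
    grand = y.mean()
    ssb = float((n_i * (means - grand) ** 2).sum())
    ssw = float(((y - means[idx]) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - (n_i ** 2).sum() / n) / (k - 1)
    s2b = max(0.0, (msb - msw) / n0)
    return float(s2b / (s2b + msw)) if (s2b + msw) > 0 else 0.0


def rate_profiles(rates: pd.DataFrame,
                  value: str = "rate") -> dict:
    """Summaries of draw-averaged rates by sex and age group.

    ``rates`` is city-level with columns sex, age_group and the rate value.
    Returns boxplot statistics per sex x age group, the peak age group per
    sex (a list when tied), and the pooled male/female rate ratio.
    """
    stats_rows = []
    peaks = {}
    for sex, sub in rates.groupby("sex"):
        med = sub.groupby("age_group", observed=True)[value].median()
        for a, mv in med.items():
            qs = sub.loc[sub["age_group"] == a, value]
            if qs.empty:
                continue
            stats_rows.append({
                "sex": sex, "age_group": a, "median": float(mv),
                "q25": float(qs.quantile(0.25)), "q75": float(qs.quantile(0.75)),
            })
        top = med.max()
        peaks[sex] = sorted(med.index[np.isclose(med, top)].tolist())
    out = {"by_group": pd.DataFrame(stats_rows), "peak_age_group": peaks}
    pooled = rates.groupby("sex")[value].mean()
    if "M" in pooled.index and "F" in pooled.index and pooled["F"] > 0:
        out["male_female_ratio"] = float(pooled["M"] / pooled["F"])
    return out


def write_descriptives(outdir, city_rates: pd.Series,
                       exposures: pd.DataFrame, countries,
                       with_html: bool = True) -> dict:
    """Write descriptives.csv, correlations.csv, icc.json (and an HTML
    report) for a set of city rates and exposures; returns the tables."""
    import json
    import os
    os.makedirs(outdir, exist_ok=True)
    qt = quartile_table(city_rates, exposures)
    corr = correlation_matrix(exposures)
    icc = within_country_icc(city_rates, countries)
    qt.to_csv(os.path.join(outdir, "descriptives.csv"), index=False)
    corr.to_csv(os.path.join(outdir, "correlations.csv"))
    with open(os.path.join(outdir, "icc.json"), "w") as fh:
        json.dump({"icc_within_country": icc, "scale": "log",
                   "n_cities": int(len(city_rates))}, fh, indent=1)
    if with_html:
        html_report({"City characteristics by rate quartile": qt,
                     "Exposure correlations": corr.round(3),
                     "Correlation bands": correlation_bands(corr)},
                    os.path.join(outdir, "descriptives.html"))
    return {"quartile_table": qt, "correlations": corr, "icc": icc}


def html_report(tables: dict[str, pd.DataFrame], path) -> None:
    """Write all descriptive tables into one HTML file."""
    parts = ["<html><body>"]
    for name, tab in tables.items():
        parts.append(f"<h2>{name}</h2>")
        parts.append(tab.to_html(float_format=lambda v: f"{v:.4g}"))
    parts.append("</body></html>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
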