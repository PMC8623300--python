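"""PI-controlled phenological and phenoclimatic linear models.

Two fixed model families, fitted by OLS on a specimen table:

* temporal-shift model:  DOY ~ year + PI + elevation + latitude + longitude
* phenoclimatic model:   DOY ~ PI + winter_ppt + spring_tmax

Each can be fitted with the PI computed from manual or from predicted
(detector) counts, giving two versions per family.  Coefficients are in raw
units (days/year, days/PI unit, days/m, days/degree, days/degC, days/mm);
no centring or scaling is applied, so estimates read directly as rates.

Per-term partial R2 is the fraction of the reduced model's residual sum of
squares removed by adding the focal term:

    partial R2 = (SSE_reduced - SSE_full) / SSE_reduced

computed by refitting the model without that term.  95% confidence
intervals use t quantiles with residual degrees of freedom.

Derived ecological quantities:

* ``shift_per_century`` — a year coefficient (days/year) scaled to
  days per 100 years, reported as a magnitude.
* ``progression_days`` — the PI coefficient is the number of days the
  species takes to advance one PI unit; three PI units span the whole
  bud-to-ripe-fruit cycle, so the full cycle is 3x that.
* ``compare_models`` — closed-interval overlap of 95% CIs between two
  fits, the criterion used to ask whether detector-derived PIs change any
  ecological conclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenology import SpecimenRecord, phenological_index

__all__ = [
    "RegressionSummary",
    "ModelComparison",
    "specimen_frame",
    "temporal_shift_model",
    "phenoclimatic_model",
    "shift_per_century",
    "progression_days",
    "compare_models",
    "model_report",
]

TEMPORAL_TERMS = ("year", "pi", "elevation", "latitude", "longitude")
PHENOCLIMATIC_TERMS = ("pi", "winter_ppt", "spring_tmax")


@dataclass(frozen=True)
class RegressionSummary:
    """A fitted OLS model: per-term inference plus fit diagnostics.

    ``table`` is indexed by term (including ``const``) with columns
    estimate, se, ci_low, ci_high, t_ratio, p_value, partial_r2 (NaN for
    the intercept).
    """

    formula: str
    pi_source: str
    table: pd.DataFrame
    full_model_r2: float
    n: int
    residual_df: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def ci(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return (float(row["ci_low"]), float(row["ci_high"]))


@dataclass(frozen=True)
class ModelComparison:
    """Per-term 95%-CI overlap between two fitted models."""

    terms: pd.DataFrame  # index: term; columns: ci_low_a, ci_high_a, ci_low_b, ci_high_b, overlap
    all_overlap: bool


def specimen_frame(
    records: Sequence[SpecimenRecord],
    pi_source: Literal["manual", "predicted"] = "manual",
) -> pd.DataFrame:
    """Model-ready data frame: metadata columns plus a ``pi`` column.

    Specimens whose counts of the requested source have zero total (PI
    undefined) are dropped.
    """
    rows = []
    for rec in records:
        counts = rec.counts(pi_source)
        if counts.total() == 0:
            continue
        rows.append(
            dict(
                id=rec.id, year=rec.year, doy=rec.doy, latitude=rec.latitude,
                longitude=rec.longitude, elevation=rec.elevation,
                spring_tmax=rec.spring_tmax, winter_ppt=rec.winter_ppt,
                pi=phenological_index(counts).value,
            )
        )
    return pd.DataFrame(rows)


def _fit_ols(data: pd.DataFrame, response: str, terms: Sequence[str],
             pi_source: str) -> RegressionSummary:
    n = len(data)
    if n < len(terms) + 2:
        raise ValueError(f"need at least {len(terms) + 2} records, got {n}")

    X = sm.add_constant(data[list(terms)], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        constant = [t for t in terms if data[t].nunique() <= 1]
        raise ValueError(
            "rank-deficient design matrix"
            + (f"; constant/collinear terms: {constant}" if constant else "")
        )
    y = data[response]
    fit = sm.OLS(y, X).fit()

    ci = fit.conf_int(alpha=0.05)
    sse_full = float(np.sum(fit.resid**2))
    partial = {}
    for term in terms:
        reduced_terms = [t for t in terms if t != term]
        Xr = sm.add_constant(data[reduced_terms], has_constant="add")
        fit_r = sm.OLS(y, Xr).fit()
        sse_r = float(np.sum(fit_r.resid**2))
        partial[term] = (sse_r - sse_full) / sse_r if sse_r > 0 else 0.0

    table = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "t_ratio": fit.tvalues,
            "p_value": fit.pvalues,
            "partial_r2": pd.Series(partial),
        }
    )
    return RegressionSummary(
        formula=f"{response} ~ " + " + ".join(terms),
        pi_source=pi_source,
        table=table,
        full_model_r2=float(fit.rsquared),
        n=n,
        residual_df=int(fit.df_resid),
    )


def temporal_shift_model(
    records: Sequence[SpecimenRecord],
    pi_source: Literal["manual", "predicted"] = "manual",
) -> RegressionSummary:
    """Fit DOY ~ year + PI + elevation + latitude + longitude.

    The year coefficient estimates the temporal shift in flowering date
    (days/year) while the PI term controls for the phenological status of
    each sheet at collection.
    """
    data = specimen_frame(records, pi_source)
    return _fit_ols(data, "doy", TEMPORAL_TERMS, pi_source)


def phenoclimatic_model(
    records: Sequence[SpecimenRecord],
    pi_source: Literal["manual", "predicted"] = "manual",
) -> RegressionSummary:
    """Fit DOY ~ PI + winter_ppt + spring_tmax.

    The climate coefficients estimate phenological sensitivity: days of
    flowering-date change per mm of winter precipitation and per degC of
    spring maximum temperature.
    """
    data = specimen_frame(records, pi_source)
    return _fit_ols(data, "doy", PHENOCLIMATIC_TERMS, pi_source)


def shift_per_century(year_ci: Sequence[tuple[float, float]] | tuple[float, float]) -> tuple[float, float]:
    """Days of flowering-date shift per 100 years implied by year-term CIs.

    Accepts one (low, high) CI or several (one per model); returns the
    [min, max] magnitude over every supplied bound, scaled by 100.
    """
    cis = _as_ci_list(year_ci)
    mags = [abs(b) * 100.0 for ci in cis for b in ci]
    return (min(mags), max(mags))


def progression_days(
    pi_ci: Sequence[tuple[float, float]] | tuple[float, float],
) -> dict[str, tuple[float, float]]:
    """Days per PI unit and full-cycle days implied by PI-coefficient CIs.

    The per-unit interval spans [min lower bound, max upper bound] across
    the supplied models; the full reproductive cycle covers the 3 PI units
    from all-buds (1) to all-mature-fruits (4), hence 3x.
    """
    cis = _as_ci_list(pi_ci)
    per_unit = (min(ci[0] for ci in cis), max(ci[1] for ci in cis))
    return {
        "days_per_pi_unit": per_unit,
        "full_cycle_days": (3.0 * per_unit[0], 3.0 * per_unit[1]),
    }


def _as_ci_list(ci) -> list[tuple[float, float]]:
    if isinstance(ci, tuple) and len(ci) == 2 and np.isscalar(ci[0]):
        return [ci]
    out = [tuple(map(float, c)) for c in ci]
    if not out:
        raise ValueError("no confidence intervals supplied")
    return out


def compare_models(a: RegressionSummary, b: RegressionSummary) -> ModelComparison:
    """Closed-interval overlap of 95% CIs for every term shared by two fits.

    Intervals that merely touch count as overlapping.  ``all_overlap`` is
    the verdict over shared non-intercept terms: True means the two models
    are statistically indistinguishable on every common effect.
    """
    shared = [t for t in a.table.index if t in b.table.index and t != "const"]
    if not shared:
        raise ValueError("models share no terms to compare")
    rows = {}
    for term in shared:
        lo_a, hi_a = a.ci(term)
        lo_b, hi_b = b.ci(term)
        overlap = (lo_a <= hi_b) and (lo_b <= hi_a)
        rows[term] = dict(ci_low_a=lo_a, ci_high_a=hi_a,
                          ci_low_b=lo_b, ci_high_b=hi_b, overlap=overlap)
    table = pd.DataFrame.from_dict(rows, orient="index")
    return ModelComparison(terms=table, all_overlap=bool(table["overlap"].all()))


def model_report(summary: RegressionSummary) -> pd.DataFrame:
    """Flat per-term table (term, estimate, SE, CI, t, p, partial R2)."""
    out = summary.table.reset_index(names="term")
    out.insert(0, "model", summary.formula)
    out.insert(1, "pi_source", summary.pi_source)
    return out
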