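"""Time-course and ancillary models.

Productivity-richness relationship in the first growth period, yield
trajectories over the weeks of the experiment (linear mixed model with a
per-microcosm random intercept), the binomial extinction model, and the
trend of isolate yields with source-community diversity.  Richness enters
every model as log(richness); time as continuous weeks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ._stepwise import backward_eliminate
from .interactions import monoculture_means  # noqa: F401  (re-exported convenience)


@dataclass
class TrendFit:
    """A fitted trend model: coefficient table plus fit statistics."""

    label: str
    coefficients: pd.DataFrame  # term, estimate, se, stat, df, p
    aic: float
    llf: float
    extra: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def coefficient(self, term: str) -> pd.Series:
        hit = self.coefficients[self.coefficients["term"] == term]
        if hit.empty:
            raise KeyError(f"no coefficient for term {term!r} in {self.label}")
        return hit.iloc[0]

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "coefficients": self.coefficients.to_dict(orient="records"),
            "aic": self.aic,
            "llf": self.llf,
            "extra": self.extra,
            "flags": list(self.flags),
        }


def _coef_table(res, df_resid, stat_name="t") -> pd.DataFrame:
    rows = []
    for term in res.params.index:
        stat = float(res.tvalues[term])
        if stat_name == "t":
            p = 2.0 * scipy.stats.t.sf(abs(stat), df_resid)
        else:
            p = 2.0 * scipy.stats.norm.sf(abs(stat))
        rows.append(
            {
                "term": term,
                "estimate": float(res.params[term]),
                "se": float(res.bse[term]),
                "stat": stat,
                "df": df_resid,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def _prepare(yields: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    richness = design.groupby("composition_id")["richness"].first()
    frame = yields.merge(richness.rename("richness"), left_on="composition_id", right_index=True)
    frame["log_richness"] = np.log(frame["richness"].astype(float))
    frame = frame.rename(columns={"yield": "y"})
    return frame


def fit_initial_richness_model(yields: pd.DataFrame, design: pd.DataFrame) -> TrendFit:
    """Productivity-richness relationship in the first growth period.

    Linear model ``yield ~ environment * log(richness)`` on week-0 yields of
    all microcosms; reports the environment-by-richness interaction F test
    (do the slopes differ among environments?) alongside the per-term t
    tests.
    """
    frame = _prepare(yields[yields["week"] == 0], design)
    envs = set(frame["environment"].unique())
    if len(envs) < 3:
        raise ValueError(f"all three environments required; found {sorted(envs)}")
    if frame["richness"].nunique() < 2:
        raise ValueError("no richness variance: need at least two richness levels")
    full = smf.ols("y ~ C(environment) * log_richness", data=frame).fit()
    reduced = smf.ols("y ~ C(environment) + log_richness", data=frame).fit()
    ftest = full.compare_f_test(reduced)
    fit = TrendFit(
        label="initial_richness",
        coefficients=_coef_table(full, int(full.df_resid)),
        aic=float(full.aic),
        llf=float(full.llf),
        extra={
            "interaction_F": float(ftest[0]),
            "interaction_p": float(ftest[1]),
            "interaction_df": (int(ftest[2]), int(full.df_resid)),
        },
    )
    return fit


_TIME_FIXED_TERMS = [
    "week",
    "C(environment)",
    "log_richness",
    "week:C(environment)",
    "week:log_richness",
    "C(environment):log_richness",
    "week:C(environment):log_richness",
]


def fit_time_mixed_model(
    yields: pd.DataFrame, design: pd.DataFrame, simplify: bool = True
) -> TrendFit:
    """Yield trajectories over weeks: linear mixed model with fixed effects
    time x environment x log(richness) and a per-microcosm random intercept.

    Fixed effects are fitted by maximum likelihood and simplified by
    AIC-based backward elimination (respecting marginality); the simplified
    model is refitted by REML for reporting.  A random-intercept variance
    estimated at the zero boundary is flagged, not an error.
    """
    frame = _prepare(yields, design)
    per_micro = frame.groupby("microcosm_id")["week"].nunique()
    if (per_micro < 2).any():
        raise ValueError("every microcosm needs at least two time points")

    def _fit(terms, reml=False):
        rhs = " + ".join(terms) if terms else "1"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return smf.mixedlm(f"y ~ {rhs}", data=frame, groups=frame["microcosm_id"]).fit(
                reml=reml
            )

    if simplify:
        kept, _ = backward_eliminate(_TIME_FIXED_TERMS, _fit)
    else:
        kept = list(_TIME_FIXED_TERMS)
    res = _fit(kept, reml=True)
    flags = []
    if float(np.asarray(res.cov_re).squeeze()) < 1e-10:
        flags.append("random-intercept variance at zero boundary")
    coef = _coef_table(res, int(res.df_resid), stat_name="t")
    coef = coef[coef["term"] != "Group Var"]
    return TrendFit(
        label="time_mixed",
        coefficients=coef,
        aic=float(res.aic) if np.isfinite(res.aic) else np.nan,
        llf=float(res.llf),
        extra={"retained_terms": kept, "random_intercept_var": float(np.asarray(res.cov_re).squeeze())},
        flags=flags,
    )


def extinction_glm(survival: pd.DataFrame, design: pd.DataFrame) -> TrendFit:
    """Binomial model of extinction on log richness and environment.

    Fitted at the microcosm level: the number of extinct members out of the
    starting richness, ``extinct/richness ~ environment * log(richness)``.
    Reports per-term z and P and the fitted extinct fraction at S=12 in each
    environment.
    """
    counts = (
        survival.groupby(["microcosm_id", "composition_id", "environment"])
        .agg(n=("survived", "size"), survivors=("survived", "sum"))
        .reset_index()
    )
    counts["extinct"] = counts["n"] - counts["survivors"]
    counts["log_richness"] = np.log(counts["n"].astype(float))
    if counts["extinct"].sum() == 0 or counts["survivors"].sum() == 0:
        raise ValueError("both outcome classes (survival and extinction) required")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = smf.glm(
            "extinct + survivors ~ C(environment) * log_richness",
            data=counts,
            family=sm.families.Binomial(),
        ).fit()
    flags = []
    if any("separation" in str(w.message).lower() for w in caught):
        flags.append("possible separation")
    pred = counts.drop_duplicates("environment")[["environment"]].copy()
    pred["log_richness"] = np.log(12.0)
    fitted12 = {
        env: float(p)
        for env, p in zip(pred["environment"], res.predict(pred))
    }
    return TrendFit(
        label="extinction_glm",
        coefficients=_coef_table(res, int(res.df_resid), stat_name="z"),
        aic=float(res.aic),
        llf=float(res.llf),
        extra={"extinct_fraction_at_12": fitted12},
        flags=flags,
    )


def isolate_yield_trend(isolates: pd.DataFrame, design: pd.DataFrame) -> TrendFit:
    """Trend of isolate yields, relative to the matched ancestor, with the
    diversity of the source community.

    Linear model ``b/ancestral ~ log(source richness) + environment``; rows
    with a zero ancestral yield are excluded (flagged).  The key quantity is
    the richness slope and its t test.
    """
    richness = design.groupby("composition_id")["richness"].first()
    frame = isolates.merge(
        richness.rename("richness"), left_on="composition_id", right_index=True
    )
    flags = []
    zero = frame["ancestral_yield"] <= 0
    if zero.any():
        flags.append(f"excluded {int(zero.sum())} isolates with zero ancestral yield")
        frame = frame[~zero]
    if frame["richness"].nunique() < 2:
        raise ValueError("single source-richness level: no diversity contrast")
    frame = frame.copy()
    frame["relative"] = frame["yield"] / frame["ancestral_yield"]
    frame["log_richness"] = np.log(frame["richness"].astype(float))
    res = smf.ols("relative ~ log_richness + C(environment)", data=frame).fit()
    slope = res.params["log_richness"]
    return TrendFit(
        label="isolate_trend",
        coefficients=_coef_table(res, int(res.df_resid)),
        aic=float(res.aic),
        llf=float(res.llf),
        extra={
            "richness_slope": float(slope),
            "richness_t": float(res.tvalues["log_richness"]),
            "richness_p": float(res.pvalues["log_richness"]),
            "n": int(res.nobs),
        },
        flags=flags,
    )
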