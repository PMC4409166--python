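"""Counterfactual partition of change in community yields.

The core inference: a baseline linear model of community yields against the
additive expectation (sum of members' monoculture yields), with slopes and
intercepts varying by environment and log richness, is fitted at week 0
("model 0").  Frozen week-0 coefficients are then applied to counterfactual
additive sums to predict week-5 yields under single mechanisms:

* model 1 — extinction only: ``beta_t0(E, S, sum a_{i,0} d eps)``;
* model 2 — additive evolution of monoculture yields: ``beta_t0(E, S, sum a_{i,5} d)``;
* model 3 — as model 2 with yields of isolates from each community (b);
* model 4 — new slopes and intercepts at week 5 (systematic change in
  interactions within environment and richness treatments);
* model 5 — new coefficients per composition and environment (interaction
  change specific to particular species combinations).

Each prediction is scored by regressing the observed change in community
yields, ``A_{j,5} - A_{j,0}``, on the predicted change; adjusted R² of those
regressions is the currency of the variance-decomposition ledger:
extinction = R²(m1), additive evolution = R²(m2 or m3, lower AIC), systematic
interaction change = R²(m4) - R²(m2), composition-specific interaction
change = R²(m5) - R²(m4), residual = 1 - R²(m5).

Only communities (richness >= 2) enter these models; monocultures enter
through the monoculture yield means a and the isolate yields b.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ._stepwise import backward_eliminate
from .interactions import monoculture_means
from .simulate import ExperimentTables

#: Counterfactual scenario name -> additive-sum column of the community frame.
SCENARIO_COLUMNS = {
    "extinction_only": "add0_eps",
    "additive_mono": "add5_mono",
    "additive_isolate": "add5_iso",
    "extinction_plus_additive_mono": "add5_mono_eps",
    "extinction_plus_additive_isolate": "add5_iso_eps",
}

#: Full term set of the baseline model: intercept and slope on the additive
#: sum, both varying freely with environment and log richness.
BASELINE_TERMS = [
    "additive",
    "C(environment)",
    "log_richness",
    "additive:C(environment)",
    "additive:log_richness",
    "C(environment):log_richness",
    "additive:C(environment):log_richness",
]


def community_frame(
    tables: ExperimentTables,
    isolate_fallback: str = "ancestral",
    min_richness: int = 2,
) -> pd.DataFrame:
    """One row per community microcosm with observed yields and every
    counterfactual additive sum.

    ``isolate_fallback`` fills the isolate-based sum for extinct species
    (no isolate exists): ``"ancestral"`` substitutes the week-0 monoculture
    yield, ``"zero"`` omits the species.  A *surviving* species without an
    isolate row is an error.
    """
    design, yields, survival = tables.design, tables.yields, tables.survival
    members = design.groupby("composition_id")["species_id"].apply(list).to_dict()
    richness = design.groupby("composition_id")["richness"].first().to_dict()
    amean = {
        (r.environment, int(r.week), r.species_id): r.a
        for r in monoculture_means(yields, design).itertuples(index=False)
    }
    surv = {
        (r.microcosm_id, r.species_id): int(r.survived)
        for r in survival.itertuples(index=False)
    }
    iso = None
    if tables.isolates is not None:
        iso = {
            (mid, sp): b
            for mid, sp, b in tables.isolates[
                ["microcosm_id", "species_id", "yield"]
            ].itertuples(index=False, name=None)
        }

    wide = yields.pivot_table(
        index=["microcosm_id", "composition_id", "environment", "replicate"],
        columns="week",
        values="yield",
    )
    if 0 not in wide.columns or 5 not in wide.columns:
        raise ValueError("yield table must contain both week 0 and week 5")
    wide = wide.rename(columns={0: "A0", 5: "A5"}).reset_index()
    rows = []
    for rec in wide.itertuples(index=False):
        S = richness[rec.composition_id]
        if S < min_richness:
            continue
        mem = members[rec.composition_id]
        env = rec.environment
        eps = {s: surv.get((rec.microcosm_id, s), 0) for s in mem}
        a0 = {s: amean[(env, 0, s)] for s in mem}
        a5 = {s: amean[(env, 5, s)] for s in mem}
        row = {
            "microcosm_id": rec.microcosm_id,
            "composition_id": rec.composition_id,
            "environment": env,
            "replicate": rec.replicate,
            "richness": S,
            "log_richness": math.log(S),
            "surviving_richness": max(1, sum(eps.values())),
            "A0": float(rec.A0),
            "A5": float(rec.A5),
        }
        row["add0"] = sum(a0[s] for s in mem)
        row["add0_eps"] = sum(a0[s] for s in mem if eps[s])
        row["add5_mono"] = sum(a5[s] for s in mem)
        row["add5_mono_eps"] = sum(a5[s] for s in mem if eps[s])
        if iso is not None:
            tot = tot_eps = 0.0
            for s in mem:
                if eps[s]:
                    if (rec.microcosm_id, s) not in iso:
                        raise KeyError(
                            f"isolate yield missing for surviving species "
                            f"({s}, {rec.microcosm_id})"
                        )
                    b = iso[(rec.microcosm_id, s)]
                    tot += b
                    tot_eps += b
                elif isolate_fallback == "ancestral":
                    tot += a0[s]
            row["add5_iso"] = tot
            row["add5_iso_eps"] = tot_eps
        else:
            row["add5_iso"] = np.nan
            row["add5_iso_eps"] = np.nan
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame["log_surviving_richness"] = np.log(frame["surviving_richness"])
    return frame


def _check_full_rank(result, terms) -> None:
    exog = result.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, r, piv = scipy.linalg.qr(exog, pivoting=True)
        names = np.asarray(result.model.exog_names)
        dependent = sorted(names[piv[rank:]])
        raise ValueError(
            f"rank-deficient design: collinear columns {dependent} in terms {terms}"
        )


@dataclass
class InteractionModelFit:
    """A fitted yield-vs-additive-expectation model (model 0/4/5 family)."""

    result: object
    terms: list
    time_of_fit: int
    response: str
    additive_column: str

    @property
    def n_obs(self) -> int:
        return int(self.result.nobs)

    @property
    def adjusted_r2(self) -> float:
        return float(self.result.rsquared_adj)

    @property
    def aic(self) -> float:
        return float(self.result.aic)

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def slope(self) -> float:
        """Coefficient on the additive sum (0 if the term was eliminated)."""
        return float(self.params.get("additive", 0.0))

    @property
    def intercept(self) -> float:
        return float(self.params.get("Intercept", 0.0))

    def predict(self, frame: pd.DataFrame, additive_column: str | None = None) -> np.ndarray:
        """Predict yields with the *frozen* fitted coefficients, optionally
        swapping in a counterfactual additive sum; never refits."""
        df = frame.copy()
        col = additive_column or self.additive_column
        df["additive"] = df[col].astype(float)
        return np.asarray(self.result.predict(df))


def _fit_terms(frame: pd.DataFrame, terms) -> object:
    rhs = " + ".join(terms) if terms else "1"
    return smf.ols(f"y ~ {rhs}", data=frame).fit()


def fit_baseline(
    frame: pd.DataFrame,
    response: str = "A0",
    additive: str = "add0",
    simplify: bool = True,
    terms: list | None = None,
    time_of_fit: int = 0,
) -> InteractionModelFit:
    """Fit the baseline model (model 0): community yields against the
    additive sum with environment- and log-richness-dependent slopes and
    intercepts, simplified by stepwise AIC.

    Under exact-additive data the simplified model recovers slope 1 and
    intercept 0.
    """
    if frame["environment"].nunique() < 1 or len(frame) < 3:
        raise ValueError("need at least 3 community observations")
    per_env = frame.groupby("environment")[additive].nunique()
    if (per_env < 2).any():
        raise ValueError(
            f"need >= 2 distinct additive sums per environment; got {dict(per_env)}"
        )
    data = frame.copy()
    data["y"] = data[response].astype(float)
    data["additive"] = data[additive].astype(float)
    full_terms = list(terms) if terms is not None else list(BASELINE_TERMS)
    if frame["environment"].nunique() < 2:
        full_terms = [t for t in full_terms if "C(environment)" not in t]
    full = _fit_terms(data, full_terms)
    _check_full_rank(full, full_terms)
    if simplify:
        kept, res = simplify_by_aic(full_terms, data)
    else:
        kept, res = full_terms, full
    return InteractionModelFit(res, kept, time_of_fit, response, additive)


def simplify_by_aic(terms, data: pd.DataFrame):
    """Backward elimination by AIC with marginality respected; returns
    (retained terms, fitted OLS result)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # log(0) AIC on perfect fits
        return backward_eliminate(list(terms), lambda ts: _fit_terms(data, ts))


def counterfactual_prediction(
    model0: InteractionModelFit, scenario: str, frame: pd.DataFrame
) -> np.ndarray:
    """Predicted week-5 yields under a named counterfactual scenario using
    the frozen week-0 coefficients."""
    if scenario not in SCENARIO_COLUMNS:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIO_COLUMNS)}"
        )
    col = SCENARIO_COLUMNS[scenario]
    if frame[col].isna().any():
        raise ValueError(f"scenario {scenario!r} needs column {col!r} (isolate table missing?)")
    return model0.predict(frame, additive_column=col)


def refit_with_time(
    frame: pd.DataFrame,
    model0: InteractionModelFit,
    additive: str = "add5_mono",
    by_composition: bool = False,
) -> InteractionModelFit:
    """Refit at week 5 with new coefficients (models 4 and 5).

    Model 4 keeps the retained term structure of the simplified baseline and
    re-estimates its coefficients on week-5 data.  Model 5
    (``by_composition=True``) allows interactions to change within each
    particular composition and environment; because the additive sum is
    constant across the replicates of a composition in an environment, the
    per-composition coefficients collapse to a composition-by-environment
    cell-means model.
    """
    data = frame.copy()
    data["y"] = data["A5"].astype(float)
    data["additive"] = data[additive].astype(float)
    if by_composition:
        terms = ["C(composition_id)", "C(environment)", "C(composition_id):C(environment)"]
        res = _fit_terms(data, terms)
    else:
        terms = list(model0.terms)
        res = _fit_terms(data, terms)
    return InteractionModelFit(res, terms, 5, "A5", additive)


@dataclass
class EvaluationRow:
    """One row of the model-comparison table: the regression of observed on
    predicted change in community yields."""

    model: str
    description: str
    n: int
    slope: float
    intercept: float
    t: float
    p: float
    adjusted_r2: float
    aic: float
    flag: str = ""

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "description": self.description,
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "t": self.t,
            "p": self.p,
            "adjusted_r2": self.adjusted_r2,
            "aic": self.aic,
            "flag": self.flag,
        }


def evaluate_counterfactual(
    observed_change: np.ndarray,
    predicted_change: np.ndarray,
    model: str = "",
    description: str = "",
    include_intercept: bool = True,
) -> EvaluationRow:
    """Regress observed on predicted change in community yields; report the
    slope t test, adjusted R² and AIC of that regression."""
    obs = np.asarray(observed_change, dtype=float)
    pred = np.asarray(predicted_change, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted changes must be paired")
    n = len(obs)
    if n < 3:
        raise ValueError("need at least 3 paired changes")
    if np.ptp(pred) == 0:
        return EvaluationRow(
            model, description, n, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            flag="zero_variance_prediction",
        )
    exog = sm.add_constant(pred) if include_intercept else pred[:, None]
    res = sm.OLS(obs, exog).fit()
    slope_idx = 1 if include_intercept else 0
    return EvaluationRow(
        model=model,
        description=description,
        n=n,
        slope=float(res.params[slope_idx]),
        intercept=float(res.params[0]) if include_intercept else 0.0,
        t=float(res.tvalues[slope_idx]),
        p=float(res.pvalues[slope_idx]),
        adjusted_r2=float(res.rsquared_adj),
        aic=float(res.aic),
    )


@dataclass
class PartitionLedger:
    """Percentages of variance in the change of community yields attributed
    to each mechanism.

    The four community-level components (additive, systematic interaction,
    composition-specific interaction, residual) sum to 100; the extinction
    share is nested within the others (the combination models include it)
    and is reported separately, not added to the sum.
    """

    pct_extinction: float
    pct_additive: float
    pct_interaction_systematic: float
    pct_interaction_composition: float
    pct_residual: float
    warnings: list = field(default_factory=list)

    def components(self) -> dict:
        return {
            "pct_extinction": self.pct_extinction,
            "pct_additive": self.pct_additive,
            "pct_interaction_systematic": self.pct_interaction_systematic,
            "pct_interaction_composition": self.pct_interaction_composition,
            "pct_residual": self.pct_residual,
        }

    def mechanism_components(self) -> dict:
        """The mechanism shares (residual excluded): basis for attribution."""
        d = self.components()
        d.pop("pct_residual")
        return d

    def as_dict(self) -> dict:
        d = self.components()
        d["warnings"] = list(self.warnings)
        return d


def decompose_variance(m1, m2, m4, m5) -> PartitionLedger:
    """Turn the adjusted R² of the four evaluation regressions into the
    variance-partition ledger.

    Arguments may be :class:`EvaluationRow` or plain adjusted R² values;
    ``m2`` should already be the lower-AIC choice of the two additive
    models.  A negative increment (adjusted R² inverting the nesting order)
    is reported as-is with a warning recorded on the ledger.
    """
    r2 = [x.adjusted_r2 if isinstance(x, EvaluationRow) else float(x) for x in (m1, m2, m4, m5)]
    r1, r2a, r4, r5 = r2
    notes = []
    if r4 < r2a:
        notes.append("adjusted R2 of model 4 below additive model; negative increment")
    if r5 < r4:
        notes.append("adjusted R2 of model 5 below model 4; negative increment")
    return PartitionLedger(
        pct_extinction=100.0 * r1,
        pct_additive=100.0 * r2a,
        pct_interaction_systematic=100.0 * (r4 - r2a),
        pct_interaction_composition=100.0 * (r5 - r4),
        pct_residual=100.0 * (1.0 - r5),
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# Whole-data mixed-model test for changing interactions
# ---------------------------------------------------------------------------


@dataclass
class TimeInteractionResult:
    statistic: float
    df: int
    pvalue: float
    method: str = "mixed_lrt"
    note: str = ""


_TIME_TERMS_FULL = [
    "additive",
    "C(environment)",
    "log_richness",
    "week",
    "additive:C(environment)",
    "additive:log_richness",
    "additive:week",
]


def time_long_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Stack the community frame to one row per microcosm per week, with the
    additive covariate fixed at its week-5 monoculture basis."""
    rows = []
    for rec in frame.itertuples(index=False):
        for week, col in ((0, "A0"), (5, "A5")):
            rows.append(
                {
                    "microcosm_id": rec.microcosm_id,
                    "environment": rec.environment,
                    "log_richness": rec.log_richness,
                    "week": week,
                    "additive": rec.add5_mono,
                    "y": getattr(rec, col),
                }
            )
    return pd.DataFrame(rows)


def time_interaction_test(frame: pd.DataFrame) -> TimeInteractionResult:
    """Likelihood-ratio test for a change in interaction strengths.

    Fits ``A_{j,t} = beta(E, S, t, sum a_{i,5} d)`` with a per-microcosm
    random intercept by maximum likelihood, against the same model without
    the time terms.  Additive evolution of species yields is absorbed by the
    week-5 additive covariate, so a significant time effect indicates a
    change in interactions.  Falls back to a fixed-effects comparison when
    the mixed fit fails.
    """
    long = time_long_frame(frame)
    full_rhs = " + ".join(_TIME_TERMS_FULL)
    null_rhs = " + ".join(t for t in _TIME_TERMS_FULL if "week" not in t)
    df = 2  # week main effect + additive:week

    def _fit_ml(rhs):
        model = smf.mixedlm(f"y ~ {rhs}", data=long, groups=long["microcosm_id"])
        res = model.fit(reml=False)
        if not res.converged:
            # direct-search rescue for fits the gradient optimizer abandons
            try:
                alt = model.fit(reml=False, method="powell")
                if alt.llf > res.llf:
                    res = alt
            except Exception:
                pass
        return res

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = _fit_ml(full_rhs)
            null = _fit_ml(null_rhs)
        lr = 2.0 * (full.llf - null.llf)
        note = ""
        if float(np.asarray(full.cov_re).squeeze()) < 1e-10:
            note = "random-effect variance at boundary"
        if lr < 0:
            lr = 0.0  # optimizer slack on a true null
        return TimeInteractionResult(float(lr), df, float(scipy.stats.chi2.sf(lr, df)), "mixed_lrt", note)
    except Exception as exc:  # singular fit: fixed-effects fallback
        warnings.warn(f"mixed model failed ({exc}); fixed-effects LRT fallback")
        full = smf.ols(f"y ~ {full_rhs}", data=long).fit()
        null = smf.ols(f"y ~ {null_rhs}", data=long).fit()
        lr = max(0.0, 2.0 * (full.llf - null.llf))
        return TimeInteractionResult(
            float(lr), df, float(scipy.stats.chi2.sf(lr, df)), "ols_lrt",
            "mixed model failed; fixed-effects comparison",
        )


# ---------------------------------------------------------------------------
# Model object tying the pipeline together
# ---------------------------------------------------------------------------


class CounterfactualPartition:
    """Counterfactual variance-partition model for one experiment.

    Parameters
    ----------
    tables
        An :class:`ExperimentTables` (simulated or read from CSVs) holding
        design, yields at weeks 0 and 5, survival, and optionally isolates.
    isolate_fallback
        How the isolate-based additive sum treats extinct species (see
        :func:`community_frame`).
    include_intercept
        Whether the observed-vs-predicted evaluation regressions include an
        intercept.

    Examples
    --------
    >>> from ecoevo.simulate import SimulationConfig, simulate_experiment
    >>> tables = simulate_experiment(SimulationConfig(scenario="mixed", seed=1))
    >>> res = CounterfactualPartition(tables).fit()
    >>> res.ledger.pct_additive  # doctest: +SKIP
    """

    def __init__(
        self,
        tables: ExperimentTables,
        isolate_fallback: str = "ancestral",
        include_intercept: bool = True,
    ):
        self.tables = tables
        self.include_intercept = include_intercept
        self.frame = community_frame(tables, isolate_fallback=isolate_fallback)

    @classmethod
    def from_tables(cls, yields, design, survival, isolates=None, **kwargs):
        return cls(
            ExperimentTables(design=design, yields=yields, survival=survival, isolates=isolates),
            **kwargs,
        )

    def fit(self, simplify: bool = True) -> "PartitionResults":
        frame = self.frame
        model0 = fit_baseline(frame, simplify=simplify)
        obs_change = (frame["A5"] - frame["A0"]).to_numpy()
        a0 = frame["A0"].to_numpy()
        have_iso = not frame["add5_iso"].isna().any()

        rows: dict[str, EvaluationRow] = {}

        def _eval(name, scenario, description):
            pred = counterfactual_prediction(model0, scenario, frame)
            rows[name] = evaluate_counterfactual(
                obs_change, pred - a0, name, description, self.include_intercept
            )

        _eval("model1", "extinction_only", "Extinction only")
        _eval("model2", "additive_mono", "Monoculture changes only")
        if have_iso:
            _eval(
                "model3",
                "additive_isolate",
                "Monoculture changes only (measured from community isolates)",
            )
        # additive model: the lower-AIC of models 2 and 3
        if have_iso and rows["model3"].aic < rows["model2"].aic:
            additive_name, additive_col = "model3", "add5_iso"
        else:
            additive_name, additive_col = "model2", "add5_mono"

        model4 = refit_with_time(frame, model0, additive=additive_col)
        rows["model4"] = evaluate_counterfactual(
            obs_change,
            model4.predict(frame) - a0,
            "model4",
            "Monoculture plus species interactions changes",
            self.include_intercept,
        )
        model5 = refit_with_time(frame, model0, additive=additive_col, by_composition=True)
        rows["model5"] = evaluate_counterfactual(
            obs_change,
            model5.predict(frame) - a0,
            "model5",
            "Monoculture + species interactions by composition",
            self.include_intercept,
        )
        ledger = decompose_variance(
            rows["model1"], rows[additive_name], rows["model4"], rows["model5"]
        )
        return PartitionResults(self, model0, model4, model5, rows, additive_name, ledger)

    def time_interaction_test(self) -> TimeInteractionResult:
        return time_interaction_test(self.frame)

    def sensitivity_exclude_extinct(self, simplify: bool = True) -> "PartitionResults":
        """Re-run the partition excluding end-extinct species from the
        week-0 additive sums and using final (surviving) richness."""
        return sensitivity_exclude_extinct(self, simplify=simplify)


class PartitionResults:
    """Fitted counterfactual partition: evaluation table and ledger."""

    def __init__(self, model, model0, model4, model5, rows, additive_name, ledger):
        self.model = model
        self.model0 = model0
        self.model4 = model4
        self.model5 = model5
        self.rows = rows
        self.additive_model = additive_name
        self.ledger = ledger

    @property
    def evaluation_table(self) -> pd.DataFrame:
        order = [k for k in ("model1", "model2", "model3", "model4", "model5") if k in self.rows]
        return pd.DataFrame([self.rows[k].as_dict() for k in order]).set_index("model")

    def summary(self) -> str:
        lines = ["Counterfactual partition of change in community yields", ""]
        lines.append(f"baseline (model 0) retained terms: {self.model0.terms}")
        lines.append(f"additive model chosen by AIC: {self.additive_model}")
        lines.append("")
        tab = self.evaluation_table[["n", "slope", "t", "p", "adjusted_r2", "aic", "flag"]]
        lines.append(tab.to_string(float_format=lambda v: f"{v:.4g}"))
        lines.append("")
        lines.append("variance of the change in community yields attributed to:")
        led = self.ledger
        lines.append(f"  extinction (nested, not summed): {led.pct_extinction:8.2f} %")
        lines.append(f"  additive evolution of yields:    {led.pct_additive:8.2f} %")
        lines.append(f"  interaction change (systematic): {led.pct_interaction_systematic:8.2f} %")
        lines.append(f"  interaction change (composition):{led.pct_interaction_composition:8.2f} %")
        lines.append(f"  residual among replicates:       {led.pct_residual:8.2f} %")
        for w in led.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)

    def as_report(self) -> dict:
        return {
            "ledger": self.ledger.as_dict(),
            "additive_model": self.additive_model,
            "baseline_terms": list(self.model0.terms),
            "evaluation": [row.as_dict() for row in self.rows.values()],
        }


def sensitivity_exclude_extinct(
    model: CounterfactualPartition, simplify: bool = True
) -> PartitionResults:
    """Sensitivity analysis: species extinct by the end are excluded from
    the week-0 additive sums and final richness replaces starting richness.

    With no extinctions this reproduces the main analysis exactly.
    """
    variant = CounterfactualPartition.__new__(CounterfactualPartition)
    variant.tables = model.tables
    variant.include_intercept = model.include_intercept
    frame = model.frame.copy()
    frame["add0"] = frame["add0_eps"]
    frame["add5_mono"] = frame["add5_mono_eps"]
    frame["add5_iso"] = frame["add5_iso_eps"]
    frame["log_richness"] = frame["log_surviving_richness"]
    variant.frame = frame
    return variant.fit(simplify=simplify)


def per_species_coefficient_model(tables: ExperimentTables) -> pd.DataFrame:
    """Sensitivity model with a separate coefficient per species.

    Community yields at both weeks are modelled on each species'
    presence-weighted ancestral monoculture yield (``a_{i,0} d_{i,j}``) with
    a per-species time interaction and a per-microcosm random intercept, so
    a species whose community contribution changed shows a non-zero time
    coefficient.  Returns a coefficient table with one time-trend row per
    species (``flag='inestimable'`` where the species appears in no
    community).
    """
    frame = community_frame(tables)
    design = tables.design
    species = sorted(design.loc[design["richness"] == 1, "species_id"].unique())
    members = design.groupby("composition_id")["species_id"].apply(set).to_dict()
    amean = {
        (r.environment, int(r.week), r.species_id): r.a
        for r in monoculture_means(tables.yields, design).itertuples(index=False)
    }
    rows = []
    for rec in frame.itertuples(index=False):
        for week, col in ((0, "A0"), (5, "A5")):
            row = {
                "microcosm_id": rec.microcosm_id,
                "environment": rec.environment,
                "log_richness": rec.log_richness,
                "week": week,
                "y": getattr(rec, col),
            }
            for s in species:
                row[f"x_{s}"] = (
                    amean[(rec.environment, 0, s)] if s in members[rec.composition_id] else 0.0
                )
            rows.append(row)
    long = pd.DataFrame(rows)
    estimable = [s for s in species if long[f"x_{s}"].abs().sum() > 0]
    terms = ["C(environment)", "log_richness", "week"]
    terms += [f"x_{s}" for s in estimable]
    terms += [f"x_{s}:week" for s in estimable]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.mixedlm(
            "y ~ " + " + ".join(terms), data=long, groups=long["microcosm_id"]
        ).fit(reml=False)
    out = []
    for s in species:
        term = f"x_{s}:week"
        if s in estimable and term in res.params.index:
            out.append(
                {
                    "species_id": s,
                    "time_coefficient": float(res.params[term]),
                    "se": float(res.bse[term]),
                    "z": float(res.tvalues[term]),
                    "p": float(res.pvalues[term]),
                    "flag": "",
                }
            )
        else:
            out.append(
                {
                    "species_id": s,
                    "time_coefficient": np.nan,
                    "se": np.nan,
                    "z": np.nan,
                    "p": np.nan,
                    "flag": "inestimable",
                }
            )
    return pd.DataFrame(out)
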