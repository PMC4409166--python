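"""Additive expectations and species-interaction indices.

The no-interaction null for a community's yield is the sum of its members'
monoculture yields, ``sum_i a_i d_ij``.  The interaction index is the ratio
of observed to additive yield: 1 means additive growth (no net interaction),
< 1 a negative interaction (e.g. resource competition), > 1 synergy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class InteractionIndex:
    """Observed vs additive yield of one community microcosm."""

    observed: float
    additive: float
    ratio: float
    classification: str
    microcosm_id: str | None = None
    week: int | None = None


def additive_expectation(
    a: Mapping[str, float],
    members: Sequence[str],
    survival: Mapping[str, int] | None = None,
) -> float:
    """Sum of monoculture yields over a community's members.

    With a ``survival`` mask, only surviving members contribute (the
    extinction term of the counterfactual models).
    """
    total = 0.0
    for s in members:
        if s not in a:
            raise KeyError(f"no monoculture yield for species {s!r}")
        if survival is not None and not survival.get(s, 0):
            continue
        total += float(a[s])
    return total


def interaction_index(
    observed: float,
    additive: float,
    tolerance: float = 0.0,
    microcosm_id: str | None = None,
    week: int | None = None,
) -> InteractionIndex:
    """Ratio of observed to additive yield, classified as negative /
    additive / synergistic with a symmetric tolerance band around 1."""
    if additive <= 0:
        raise ValueError(
            f"interaction index undefined: additive expectation {additive} <= 0"
        )
    ratio = float(observed) / float(additive)
    if ratio < 1.0 - tolerance:
        cls = "negative"
    elif ratio > 1.0 + tolerance:
        cls = "synergistic"
    else:
        cls = "additive"
    return InteractionIndex(float(observed), float(additive), ratio, cls, microcosm_id, week)


def monoculture_means(yields: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean monoculture yield per (environment, week, species), averaged
    over replicate monoculture microcosms.

    Returns a frame with columns environment, week, species_id, a.
    """
    mono = design.loc[design["richness"] == 1, ["composition_id", "species_id"]]
    rows = yields.merge(mono, on="composition_id", how="inner")
    out = (
        rows.groupby(["environment", "week", "species_id"], as_index=False)["yield"]
        .mean()
        .rename(columns={"yield": "a"})
    )
    return out


def compute_indices(
    yields: pd.DataFrame,
    design: pd.DataFrame,
    isolates: pd.DataFrame | None = None,
    week: int = 0,
    basis: str = "monoculture",
    tolerance: float = 0.0,
) -> pd.DataFrame:
    """Interaction indices for every community microcosm at one week.

    ``basis`` selects the additive expectation for week-5 indices:
    ``"isolate"`` sums the yields of isolates taken from that community
    (extinct members contribute nothing), ``"monoculture"`` sums week-``week``
    monoculture yields of all original members.  Week-0 indices always use
    week-0 monoculture yields.
    """
    if basis not in ("monoculture", "isolate"):
        raise ValueError(f"unknown basis {basis!r}")
    amean = monoculture_means(yields, design)
    amean = amean[amean["week"] == week]
    a_lookup = {
        (r.environment, r.species_id): r.a for r in amean.itertuples(index=False)
    }
    members = design.groupby("composition_id")["species_id"].apply(list)
    richness = design.groupby("composition_id")["richness"].first()
    b_lookup = {}
    if basis == "isolate":
        if isolates is None:
            raise ValueError("isolate basis requested but no isolate table given")
        b_lookup = {
            (mid, sp): b
            for mid, sp, b in isolates[["microcosm_id", "species_id", "yield"]].itertuples(
                index=False, name=None
            )
        }
    rows = []
    obs = yields[(yields["week"] == week)].merge(
        richness.rename("richness"), left_on="composition_id", right_index=True
    )
    obs = obs[obs["richness"] >= 2].rename(columns={"yield": "observed"})
    for rec in obs.itertuples(index=False):
        mem = members[rec.composition_id]
        if basis == "isolate":
            additive = sum(
                b_lookup.get((rec.microcosm_id, s), 0.0) for s in mem
            )
        else:
            additive = additive_expectation(
                {s: a_lookup[(rec.environment, s)] for s in mem}, mem
            )
        idx = interaction_index(
            rec.observed, additive, tolerance, rec.microcosm_id, week
        )
        rows.append(
            {
                "microcosm_id": rec.microcosm_id,
                "composition_id": rec.composition_id,
                "environment": rec.environment,
                "richness": int(rec.richness),
                "week": int(week),
                "observed": idx.observed,
                "additive": idx.additive,
                "ratio": idx.ratio,
                "classification": idx.classification,
            }
        )
    return pd.DataFrame(rows)


def index_summary(
    indices: pd.DataFrame,
    by: Sequence[str] = ("environment", "richness", "week"),
    log_ratio: bool = False,
) -> pd.DataFrame:
    """Per-group mean index, Student-t 95 % CI, and one-sample t test of the
    null ratio = 1 (d.f. = n - 1).

    Singleton groups report the mean only, with ``ci_available = False``.
    With ``log_ratio=True`` the test and CI are computed on log ratios (null
    log ratio = 0) and the CI back-transformed.
    """
    rows = []
    for key, grp in indices.groupby(list(by)):
        vals = grp["ratio"].to_numpy(dtype=float)
        if log_ratio:
            vals = np.log(vals)
            null = 0.0
        else:
            null = 1.0
        n = len(vals)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["n"] = n
        mean = float(np.mean(vals))
        if n >= 2:
            se = float(np.std(vals, ddof=1) / np.sqrt(n))
            tcrit = scipy.stats.t.ppf(0.975, n - 1)
            lo, hi = mean - tcrit * se, mean + tcrit * se
            if se > 0:
                t = (mean - null) / se
                p = 2.0 * scipy.stats.t.sf(abs(t), n - 1)
            else:
                t, p = 0.0, 1.0
            row.update(
                mean=float(np.exp(mean)) if log_ratio else mean,
                ci_low=float(np.exp(lo)) if log_ratio else lo,
                ci_high=float(np.exp(hi)) if log_ratio else hi,
                t=float(t),
                df=n - 1,
                p=float(p),
                ci_available=True,
            )
        else:
            row.update(
                mean=float(np.exp(mean)) if log_ratio else mean,
                ci_low=np.nan,
                ci_high=np.nan,
                t=np.nan,
                df=n - 1,
                p=np.nan,
                ci_available=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def synergy_proportion_model(
    indices: pd.DataFrame,
    formula: str = "synergy ~ week + C(environment) + np.log(richness)",
):
    """Binomial-error model of the probability a community grows
    synergistically (ratio > 1), fitted by maximum likelihood.

    Returns the fitted GLM results, with a ``separation_flag`` attribute set
    when the fit shows signs of complete separation.
    """
    frame = indices.copy()
    frame["synergy"] = (frame["ratio"] > 1.0).astype(int)
    if frame["synergy"].nunique() < 2:
        raise ValueError(
            "cannot model synergy proportion: only one outcome class present"
        )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = smf.glm(formula, data=frame, family=sm.families.Binomial()).fit()
    fitted = res.fittedvalues
    separated = bool(np.any((fitted < 1e-10) | (fitted > 1 - 1e-10))) or any(
        "separation" in str(w.message).lower() for w in caught
    )
    res.separation_flag = separated
    if separated:
        warnings.warn(
            "possible complete separation in synergy model; "
            "coefficients reported but unreliable",
            stacklevel=2,
        )
    return res
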