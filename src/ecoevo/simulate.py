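"""Synthetic serial-transfer experiment generator.

Simulates the full community-evolution experiment — monoculture and
community yields at the start and end of the selection period, end-point
survival, isolate growth assays and within-period OD trajectories — under
switchable mechanism scenarios, so that every downstream analysis stage can
be exercised and its mechanism attribution validated against known truth.

The generative model mirrors the quantities the analysis estimates:

* monoculture yields ``a_{i,t}(E)`` drift multiplicatively between week 0
  and week 5 (additive evolution);
* a community's expected yield is a single multiplicative interaction
  factor ``theta(S, E) = theta1(E) * S**(-lam(E))`` applied to the additive
  sum of its members' monoculture yields (negative interactions: theta < 1),
  optionally drifting by week 5 (interaction evolution);
* each member of a community survives to week 5 with probability
  ``logistic(alpha_E - gamma_E * log S)`` (ecological sorting);
* isolates regrown alone yield ``a_{i,5} * (1 + isolate_decline * log S)``
  (yield decline with source-community diversity).

Noise has a per-microcosm component shared across weeks (tube effects) and
an independent per-observation component.  Both are expressed as fractions
of the experiment's mean monoculture yield and applied as constant
(homoscedastic) absorbance noise: plate-reader error is close to absolute
in OD units, and it keeps the generator within the error model the
analysis-stage linear and mixed models assume.  Defaults are calibrated to the anchor rates of the tree-hole
bacteria experiment: diculture yields 52.3/58.0/75.1 % of additive in
beech/pH5/spruce, 13.0/14.5/16.1 % at twelve species, and extinction rising
from ~0 in monocultures to 74/84/86 % at twelve species.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import core
from .core import ENVIRONMENTS
from .design import DesignSpec, design_frame, expand_microcosms, generate_design

SCENARIOS = (
    "sorting_only",
    "additive_evolution",
    "interaction_evolution",
    "mixed",
    "neutral_additive",
)

#: (theta at S=2, theta at S=12) per environment: the anchor rates from
#: which the power-law interaction curve is solved.
DEFAULT_INTERACTION_ANCHORS = {
    "beech": (0.523, 0.130),
    "ph5": (0.580, 0.145),
    "spruce": (0.751, 0.161),
}

#: Extinct fraction at S=12 per environment under the default calibration.
DEFAULT_EXTINCTION_AT_12 = {"beech": 0.74, "ph5": 0.84, "spruce": 0.86}

#: Shared logistic intercept: survival probability logistic(4.6) > 0.99 at S=1.
_SURVIVAL_INTERCEPT = 4.6


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def curve_from_anchors(theta2: float, theta12: float) -> tuple[float, float]:
    """Solve theta1, lam of ``theta(S) = theta1 * S**(-lam)`` from the values
    at S=2 and S=12."""
    lam = math.log(theta2 / theta12) / math.log(6.0)
    return theta2 * 2.0**lam, lam


def extinction_slope(extinct_at_12: float, alpha: float = _SURVIVAL_INTERCEPT) -> float:
    """Logistic slope on log richness giving ``extinct_at_12`` extinction at S=12."""
    return (alpha - _logit(1.0 - extinct_at_12)) / math.log(12.0)


@dataclass
class SimulationConfig:
    """Everything that defines one simulated experiment.

    Fields left at ``None`` are resolved in ``__post_init__`` from the
    scenario and seed, so a constructed config is always fully explicit and
    can be recorded verbatim as the ground truth of a run.

    Parameters
    ----------
    scenario
        Which change mechanisms operate between week 0 and week 5:
        ``sorting_only`` (extinction only, 50 % at S=12),
        ``additive_evolution`` (per-species yield drift ~ N(1.30, 0.15)),
        ``interaction_evolution`` (theta doubled by week 5),
        ``mixed`` (all mechanisms at the default calibration), or
        ``neutral_additive`` (theta = 1 and nothing changes).
    base_yields
        Mean week-0 monoculture yield per environment and species
        (absorbance).  Default: uniform 0.1-0.4 per species, spruce scaled
        by 0.5 (yields on spruce tea are uniformly lower).
    interaction_curve
        ``{environment: (theta1, lam)}`` of theta(S,E); applied to
        communities (S >= 2) only.
    yield_drift
        Multiplicative change in each species' monoculture yield by week 5.
    interaction_drift
        Multiplicative change in theta by week 5, per environment.
    extinction_model
        ``{environment: (alpha, gamma)}`` of the survival logistic on log
        richness, or ``None`` for no extinction.
    isolate_decline
        Slope of isolate relative yield on log source richness (<= 0).
    noise_sd, microcosm_sd
        Per-observation and per-microcosm (shared across weeks) noise, as
        fractions of the mean monoculture base yield; applied as constant
        absorbance noise to every observation.
    detection_limit
        Relative abundance below which a species is scored extinct when
        plated out; recorded for provenance (extinction is simulated as a
        calibrated Bernoulli draw, so the limit is implicit in the rates).
    """

    design_spec: DesignSpec | None = None
    scenario: str = "mixed"
    base_yields: Mapping[str, Mapping[str, float]] | None = None
    interaction_curve: Mapping[str, tuple[float, float]] | None = None
    yield_drift: Mapping[str, float] | None = None
    interaction_drift: Mapping[str, float] | None = None
    extinction_model: Mapping[str, tuple[float, float]] | None = None
    no_extinction: bool | None = None
    isolate_decline: float = -0.05
    noise_sd: float = 0.05
    microcosm_sd: float = 0.03
    detection_limit: float = 1e-4
    weeks: tuple = (0, 5)
    od_start: float = 0.02
    od_reading_sd: float = 0.002
    include_transfers: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.noise_sd < 0 or self.microcosm_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.design_spec is None:
            self.design_spec = DesignSpec(seed=self.seed)
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 91]))
        species = self.design_spec.species
        if self.base_yields is None:
            draw = rng.uniform(0.1, 0.4, size=len(species))
            self.base_yields = {
                env: {
                    s: float(draw[i] * (0.5 if env == "spruce" else 1.0))
                    for i, s in enumerate(species)
                }
                for env in ENVIRONMENTS
            }
        if self.interaction_curve is None:
            if self.scenario == "neutral_additive":
                self.interaction_curve = {env: (1.0, 0.0) for env in ENVIRONMENTS}
            else:
                self.interaction_curve = {
                    env: curve_from_anchors(*DEFAULT_INTERACTION_ANCHORS[env])
                    for env in ENVIRONMENTS
                }
        if self.yield_drift is None:
            if self.scenario == "additive_evolution":
                drifts = np.clip(rng.normal(1.30, 0.15, size=len(species)), 0.5, None)
            elif self.scenario == "mixed":
                drifts = np.clip(rng.normal(1.10, 0.10, size=len(species)), 0.5, None)
            else:
                drifts = np.ones(len(species))
            self.yield_drift = {s: float(d) for s, d in zip(species, drifts)}
        if self.interaction_drift is None:
            if self.scenario == "interaction_evolution":
                self.interaction_drift = {env: 2.0 for env in ENVIRONMENTS}
            elif self.scenario == "mixed":
                self.interaction_drift = {"beech": 1.0, "ph5": 1.5, "spruce": 1.0}
            else:
                self.interaction_drift = {env: 1.0 for env in ENVIRONMENTS}
        elif not isinstance(self.interaction_drift, Mapping):
            self.interaction_drift = {env: float(self.interaction_drift) for env in ENVIRONMENTS}
        if self.no_extinction is None:
            self.no_extinction = self.scenario in (
                "additive_evolution",
                "interaction_evolution",
                "neutral_additive",
            )
        if self.extinction_model is None and not self.no_extinction:
            if self.scenario == "sorting_only":
                gamma = extinction_slope(0.50)
                self.extinction_model = {env: (_SURVIVAL_INTERCEPT, gamma) for env in ENVIRONMENTS}
            else:
                self.extinction_model = {
                    env: (_SURVIVAL_INTERCEPT, extinction_slope(DEFAULT_EXTINCTION_AT_12[env]))
                    for env in ENVIRONMENTS
                }

    # -- expected values ---------------------------------------------------

    @property
    def noise_scale(self) -> float:
        """Mean monoculture base yield across species and environments: the
        reference scale for the noise fractions."""
        vals = [v for env in self.base_yields.values() for v in env.values()]
        return float(np.mean(vals))

    @property
    def resid_sd(self) -> float:
        """Absolute per-observation noise sd (absorbance units)."""
        return self.noise_sd * self.noise_scale

    @property
    def micro_sd(self) -> float:
        """Absolute per-microcosm (tube) effect sd (absorbance units)."""
        return self.microcosm_sd * self.noise_scale

    def monoculture_mean(self, species: str, environment: str, week: int) -> float:
        """Expected monoculture yield a_{i,t}(E)."""
        base = self.base_yields[environment][species]
        return base * self.yield_drift[species] ** (week / 5.0)

    def theta(self, richness: int, environment: str, week: int) -> float:
        """Interaction factor theta(S, E, t); 1 for monocultures."""
        if richness < 2:
            return 1.0
        theta1, lam = self.interaction_curve[environment]
        value = theta1 * richness ** (-lam)
        return value * self.interaction_drift[environment] ** (week / 5.0)

    def survival_probability(self, richness: int, environment: str) -> float:
        """Probability that one member of an S-species community persists."""
        if self.no_extinction or self.extinction_model is None:
            return 1.0
        alpha, gamma = self.extinction_model[environment]
        return _logistic(alpha - gamma * math.log(richness))

    def community_mean(
        self,
        members: Sequence[str],
        environment: str,
        week: int,
        survived: Mapping[str, int] | None = None,
    ) -> float:
        """Expected community yield: theta times the additive sum, with the
        week-5 sum restricted to survivors."""
        total = 0.0
        for s in members:
            alive = 1 if (survived is None or week != 5) else int(survived[s])
            total += self.monoculture_mean(s, environment, week) * alive
        return self.theta(len(members), environment, week) * total

    def truth(self) -> dict:
        """JSON-serialisable record of the generating scenario and parameters."""
        d = {
            "scenario": self.scenario,
            "seed": int(self.seed),
            "base_yields": self.base_yields,
            "interaction_curve": {k: list(v) for k, v in self.interaction_curve.items()},
            "yield_drift": self.yield_drift,
            "interaction_drift": dict(self.interaction_drift),
            "extinction_model": None
            if self.no_extinction or self.extinction_model is None
            else {k: list(v) for k, v in self.extinction_model.items()},
            "isolate_decline": self.isolate_decline,
            "noise_sd": self.noise_sd,
            "microcosm_sd": self.microcosm_sd,
            "detection_limit": self.detection_limit,
            "weeks": list(self.weeks),
            "design": {
                "n_species": self.design_spec.n_species,
                "richness_levels": sorted(self.design_spec.richness_levels),
                "partitions_per_level": self.design_spec.partitions_per_level,
                "replicates": self.design_spec.replicates,
                "seed": self.design_spec.seed,
            },
        }
        return d


# ---------------------------------------------------------------------------
# Elementary simulators
# ---------------------------------------------------------------------------


def simulate_survival(
    config: SimulationConfig,
    composition,
    environment: str,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Bernoulli end-point survival for each member of one microcosm.

    At least one species survives per microcosm (a tube cannot end sterile
    while still yielding biomass); the draw is repeated if all members die.
    """
    members = sorted(composition.members)
    p = config.survival_probability(len(members), environment)
    while True:
        draws = rng.random(len(members)) < p
        if draws.any():
            return {s: int(v) for s, v in zip(members, draws)}


def simulate_monoculture_yields(
    config: SimulationConfig,
    week: int,
    rng: np.random.Generator,
    microcosms: Sequence | None = None,
    microcosm_effects: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Yield observations for all monoculture microcosms at one week."""
    if microcosms is None:
        design = [c for c in generate_design(config.design_spec) if c.richness == 1]
        microcosms = expand_microcosms(design, config.design_spec.replicates)
    rows = []
    for m in microcosms:
        species = m.composition_id.split("M-")[-1]
        mean = config.monoculture_mean(species, m.environment, week)
        u = 0.0 if microcosm_effects is None else microcosm_effects.get(m.microcosm_id, 0.0)
        value = mean + u + (rng.normal(0.0, config.resid_sd) if config.noise_sd > 0 else 0.0)
        rows.append(
            {
                "microcosm_id": m.microcosm_id,
                "composition_id": m.composition_id,
                "environment": m.environment,
                "replicate": m.replicate,
                "week": int(week),
                "yield": max(0.0, float(value)),
            }
        )
    return pd.DataFrame(rows, columns=core.YIELD_COLUMNS)


def simulate_community_yield(
    config: SimulationConfig,
    composition,
    environment: str,
    week: int,
    survived: Mapping[str, int] | None,
    rng: np.random.Generator,
    microcosm_effect: float = 0.0,
) -> float:
    """One community yield observation A_{j,t}, clamped at zero."""
    mean = config.community_mean(sorted(composition.members), environment, week, survived)
    noise = rng.normal(0.0, config.resid_sd) if config.noise_sd > 0 else 0.0
    return max(0.0, mean + microcosm_effect + noise)


def simulate_isolate_yields(
    config: SimulationConfig,
    survival: pd.DataFrame,
    richness: Mapping[str, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Week-5 growth assays of isolates from each microcosm, survivors only.

    ``b_{i,j,5} = a_{i,5}(E) * (1 + isolate_decline * log S_j)`` plus assay
    noise; the matched ancestral assay re-measures ``a_{i,0}(E)``.
    """
    rows = []
    for rec in survival.itertuples(index=False):
        if not rec.survived:
            continue
        s_j = richness[rec.composition_id]
        mean_b = config.monoculture_mean(rec.species_id, rec.environment, 5) * (
            1.0 + config.isolate_decline * math.log(s_j)
        )
        mean_anc = config.monoculture_mean(rec.species_id, rec.environment, 0)
        sd = config.resid_sd
        b = mean_b + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        anc = mean_anc + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        rows.append(
            {
                "microcosm_id": rec.microcosm_id,
                "composition_id": rec.composition_id,
                "environment": rec.environment,
                "species_id": rec.species_id,
                "yield": max(0.0, float(b)),
                "ancestral_yield": max(0.0, float(anc)),
            }
        )
    return pd.DataFrame(rows, columns=core.ISOLATE_COLUMNS)


def simulate_od_series(
    config: SimulationConfig,
    target_yield: float,
    rng: np.random.Generator | None = None,
    n_daily: int = 5,
    rate: float = 2.2,
    midpoint: float = 2.0,
) -> np.ndarray:
    """Daily OD readings of one growth period following a logistic rise.

    The trajectory runs from ``od_start`` to ``od_start + target_yield``
    over ``n_daily`` days (readings at day 0 through day ``n_daily``), with
    the endpoints pinned so that ``compute_yield`` inverts the target
    exactly when the reading noise is zero.
    """
    if target_yield < 0:
        raise ValueError("target_yield must be >= 0")
    days = np.arange(n_daily + 1, dtype=float)
    raw = 1.0 / (1.0 + np.exp(-rate * (days - midpoint)))
    shape = (raw - raw[0]) / (raw[-1] - raw[0])
    series = config.od_start + target_yield * shape
    if rng is not None and config.od_reading_sd > 0:
        noise = rng.normal(0.0, config.od_reading_sd, size=series.shape)
        noise[0] = 0.0  # the inoculation density is set, not read
        series = np.maximum(series + noise, 1e-6)
    return series


# ---------------------------------------------------------------------------
# Whole-experiment simulation
# ---------------------------------------------------------------------------


@dataclass
class ExperimentTables:
    """All tables of one (simulated or real) experiment."""

    design: pd.DataFrame
    yields: pd.DataFrame
    survival: pd.DataFrame
    isolates: pd.DataFrame | None = None
    transfers: pd.DataFrame | None = None
    truth: dict | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        core.write_design_table(self.design, outdir / "design.csv")
        core.write_yield_table(self.yields, outdir / "yields.csv")
        core.write_survival_table(self.survival, outdir / "survival.csv")
        if self.isolates is not None:
            core.write_isolate_table(self.isolates, outdir / "isolates.csv")
        if self.transfers is not None:
            core.write_transfer_table(self.transfers, outdir / "transfers.csv")
        if self.truth is not None:
            (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))

    @classmethod
    def read(cls, indir) -> "ExperimentTables":
        indir = Path(indir)
        truth = None
        if (indir / "truth.json").exists():
            truth = json.loads((indir / "truth.json").read_text())
        return cls(
            design=core.read_design_table(indir / "design.csv"),
            yields=core.read_yield_table(indir / "yields.csv"),
            survival=core.read_survival_table(indir / "survival.csv"),
            isolates=core.read_isolate_table(indir / "isolates.csv")
            if (indir / "isolates.csv").exists()
            else None,
            transfers=core.read_transfer_table(indir / "transfers.csv")
            if (indir / "transfers.csv").exists()
            else None,
            truth=truth,
        )


def simulate_experiment(config: SimulationConfig) -> ExperimentTables:
    """Run one full simulated experiment, deterministic given ``config.seed``."""
    ss = np.random.SeedSequence([int(config.seed), 7])
    r_survival, r_micro, r_yield, r_isolate, r_od = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    spec = config.design_spec
    design = generate_design(spec)
    comp_by_id = {c.composition_id: c for c in design}
    microcosms = expand_microcosms(design, spec.replicates)

    # end-point survival per microcosm
    surv_rows = []
    surv_by_micro: dict[str, dict[str, int]] = {}
    for m in microcosms:
        comp = comp_by_id[m.composition_id]
        outcome = simulate_survival(config, comp, m.environment, r_survival)
        surv_by_micro[m.microcosm_id] = outcome
        for s in sorted(comp.members):
            surv_rows.append(
                {
                    "microcosm_id": m.microcosm_id,
                    "composition_id": m.composition_id,
                    "environment": m.environment,
                    "species_id": s,
                    "survived": outcome[s],
                }
            )
    survival = pd.DataFrame(surv_rows, columns=core.SURVIVAL_COLUMNS)

    # persistent tube effects shared by the weekly observations
    effects = {
        m.microcosm_id: (
            float(r_micro.normal(0.0, config.micro_sd)) if config.microcosm_sd > 0 else 0.0
        )
        for m in microcosms
    }

    yield_rows = []
    for m in microcosms:
        comp = comp_by_id[m.composition_id]
        for week in config.weeks:
            value = simulate_community_yield(
                config,
                comp,
                m.environment,
                week,
                surv_by_micro[m.microcosm_id],
                r_yield,
                effects[m.microcosm_id],
            )
            yield_rows.append(
                {
                    "microcosm_id": m.microcosm_id,
                    "composition_id": m.composition_id,
                    "environment": m.environment,
                    "replicate": m.replicate,
                    "week": int(week),
                    "yield": value,
                }
            )
    yields = pd.DataFrame(yield_rows, columns=core.YIELD_COLUMNS)

    richness = {c.composition_id: c.richness for c in design}
    isolates = simulate_isolate_yields(config, survival, richness, r_isolate)

    transfers = None
    if config.include_transfers:
        t_rows = []
        for mid, week, value in yields[["microcosm_id", "week", "yield"]].itertuples(
            index=False, name=None
        ):
            series = simulate_od_series(config, value, r_od)
            for k, od in enumerate(series):
                t_rows.append(
                    {
                        "microcosm_id": mid,
                        "period_index": int(week),
                        "reading_index": k,
                        "od": float(od),
                    }
                )
        transfers = pd.DataFrame(t_rows, columns=core.TRANSFER_COLUMNS)

    return ExperimentTables(
        design=design_frame(design),
        yields=yields,
        survival=survival,
        isolates=isolates,
        transfers=transfers,
        truth=config.truth(),
    )
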