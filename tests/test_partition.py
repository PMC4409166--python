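import numpy as np
import pandas as pd
import pytest

from ecoevo.partition import (
    BASELINE_TERMS,
    CounterfactualPartition,
    EvaluationRow,
    community_frame,
    counterfactual_prediction,
    decompose_variance,
    evaluate_counterfactual,
    fit_baseline,
    per_species_coefficient_model,
    refit_with_time,
    time_interaction_test,
)
from ecoevo.simulate import SimulationConfig, simulate_experiment


def _synthetic_baseline_frame(rng, n=225, slope=1.0, intercept=0.0, noise=0.0):
    env = rng.choice(["beech", "ph5", "spruce"], n)
    S = rng.choice([2, 3, 6, 12], n)
    add = rng.uniform(0.2, 1.2, n)
    y = intercept + slope * add + (rng.normal(0, noise, n) if noise else 0.0)
    return pd.DataFrame(
        {"environment": env, "log_richness": np.log(S), "A0": y, "add0": add}
    )


class TestFitBaseline:
    def test_exact_additive_recovers_identity(self, exact_additive_tables):
        frame = community_frame(exact_additive_tables)
        model0 = fit_baseline(frame)
        assert model0.slope == pytest.approx(1.0, abs=1e-8)
        assert model0.intercept == pytest.approx(0.0, abs=1e-8)

    def test_constructed_half_slope(self):
        frame = _synthetic_baseline_frame(np.random.default_rng(0), slope=0.5)
        model0 = fit_baseline(frame)
        assert model0.slope == pytest.approx(0.5, abs=1e-8)
        assert model0.intercept == pytest.approx(0.0, abs=1e-8)

    def test_richness_decay_gives_negative_richness_slope_interaction(self):
        # theta(S) = theta1 * S^-lambda: the slope on the additive sum must
        # become shallower with richness
        tables = simulate_experiment(
            SimulationConfig(seed=2, noise_sd=0.0, microcosm_sd=0.0, include_transfers=False)
        )
        frame = community_frame(tables)
        model0 = fit_baseline(frame, simplify=False)
        assert model0.params["additive:log_richness"] < 0

    def test_too_few_distinct_additive_sums_rejected(self):
        frame = pd.DataFrame(
            {
                "environment": ["beech"] * 4,
                "log_richness": np.log([2, 2, 3, 3]),
                "A0": [0.3, 0.31, 0.29, 0.3],
                "add0": [0.5] * 4,
            }
        )
        with pytest.raises(ValueError, match="distinct additive sums"):
            fit_baseline(frame)


class TestSimplifyByAic:
    def test_null_environment_terms_mostly_dropped(self):
        rng = np.random.default_rng(1)
        n_seeds = 60
        dropped = {t: 0 for t in BASELINE_TERMS if "environment" in t}
        all_dropped = 0
        additive_always = True
        for _ in range(n_seeds):
            frame = _synthetic_baseline_frame(rng, noise=0.02)
            kept = fit_baseline(frame).terms
            for t in dropped:
                dropped[t] += t not in kept
            all_dropped += not any("environment" in t for t in kept)
            additive_always &= "additive" in kept
        # AIC retains a pure-noise 2-df term with probability ~e^-2, and
        # marginality keeps main effects while their interactions survive,
        # so elimination of the whole environment structure is frequent but
        # far from certain
        assert dropped["additive:C(environment):log_richness"] / n_seeds >= 0.65
        for t, count in dropped.items():
            assert count / n_seeds >= 0.35, t
        assert all_dropped / n_seeds >= 0.3
        assert additive_always  # the true signal term is never eliminated

    def test_strong_effects_fully_retained(self):
        rng = np.random.default_rng(2)
        retained_full = 0
        for _ in range(10):
            n = 300
            env = rng.choice(["beech", "ph5", "spruce"], n)
            S = rng.choice([2, 3, 6, 12], n)
            add = rng.uniform(0.2, 1.2, n)
            env_fx = pd.Series(env).map({"beech": 0.0, "ph5": 0.5, "spruce": -0.5}).to_numpy()
            logS = np.log(S)
            y = (
                0.3
                + env_fx
                + 0.5 * logS
                + add * (1.0 + env_fx + 0.4 * logS + 0.3 * env_fx * logS)
                + env_fx * logS
                + rng.normal(0, 0.02, n)
            )
            frame = pd.DataFrame(
                {"environment": env, "log_richness": logS, "A0": y, "add0": add}
            )
            retained_full += set(fit_baseline(frame).terms) == set(BASELINE_TERMS)
        assert retained_full >= 9

    def test_single_term_model_returned_as_is(self):
        frame = _synthetic_baseline_frame(np.random.default_rng(3), noise=0.02)
        model0 = fit_baseline(frame, terms=["additive"])
        assert model0.terms == ["additive"]


class TestCounterfactualPrediction:
    def test_all_survivors_reproduces_fitted_values(self, exact_additive_tables):
        frame = community_frame(exact_additive_tables)
        model0 = fit_baseline(frame)
        pred = counterfactual_prediction(model0, "extinction_only", frame)
        assert np.allclose(pred, model0.result.fittedvalues, atol=1e-10)

    def test_single_extinction_drops_prediction_by_lost_yield(self, exact_additive_tables):
        frame = community_frame(exact_additive_tables).copy()
        model0 = fit_baseline(frame)  # slope 1, intercept 0
        lost = 0.2
        frame.loc[frame.index[0], "add0_eps"] = frame.loc[frame.index[0], "add0"] - lost
        pred = counterfactual_prediction(model0, "extinction_only", frame)
        base = counterfactual_prediction(model0, "additive_mono", frame)
        assert pred[0] == pytest.approx(base[0] - lost, abs=1e-8)

    def test_no_evolution_limit_equals_baseline_fit(self, exact_additive_tables):
        frame = community_frame(exact_additive_tables)
        model0 = fit_baseline(frame)
        pred = counterfactual_prediction(model0, "additive_mono", frame)
        assert np.allclose(pred, model0.result.fittedvalues, atol=1e-10)

    def test_unknown_scenario_rejected(self, exact_additive_tables):
        frame = community_frame(exact_additive_tables)
        model0 = fit_baseline(frame)
        with pytest.raises(ValueError, match="unknown scenario"):
            counterfactual_prediction(model0, "rapture", frame)

    def test_frozen_coefficients_propagate_unchanged(self, exact_additive_tables):
        # fit the baseline on doubled yields: a wrong-by-construction beta
        frame = community_frame(exact_additive_tables).copy()
        doubled = frame.copy()
        doubled["A0"] = 2.0 * doubled["A0"]
        wrong = fit_baseline(doubled)
        assert wrong.slope == pytest.approx(2.0, abs=1e-8)
        pred = counterfactual_prediction(wrong, "additive_mono", frame)
        # predictions carry the wrong slope; nothing was refitted
        assert np.allclose(pred, 2.0 * frame["add5_mono"], atol=1e-8)


class TestEvaluateCounterfactual:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        change = rng.normal(0, 1, 20)
        row = evaluate_counterfactual(change, change)
        assert row.slope == pytest.approx(1.0)
        assert row.adjusted_r2 == pytest.approx(1.0)

    def test_constant_prediction_flagged(self):
        row = evaluate_counterfactual(np.arange(10.0), np.zeros(10))
        assert row.flag == "zero_variance_prediction"
        assert np.isnan(row.adjusted_r2)

    def test_statistics_match_brute_force_on_ten_points(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 10)
        y = 0.5 * x + rng.normal(0, 0.3, 10)
        row = evaluate_counterfactual(y, x)
        # brute-force simple regression
        n = 10
        xc, yc = x - x.mean(), y - y.mean()
        slope = (xc * yc).sum() / (xc * xc).sum()
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        rss = float(resid @ resid)
        tss = float(yc @ yc)
        r2 = 1 - rss / tss
        adj = 1 - (1 - r2) * (n - 1) / (n - 2)
        aic = n * np.log(rss / n) + n * np.log(2 * np.pi) + n + 2 * 2
        assert row.slope == pytest.approx(slope, abs=1e-8)
        assert row.intercept == pytest.approx(intercept, abs=1e-8)
        assert row.adjusted_r2 == pytest.approx(adj, abs=1e-8)
        assert row.aic == pytest.approx(aic, abs=1e-8)

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_counterfactual(np.zeros(5), np.zeros(4))


class TestDecomposeVariance:
    def test_worked_arithmetic_example(self):
        ledger = decompose_variance(0.0035, 0.177, 0.320, 0.795)
        assert ledger.pct_extinction == pytest.approx(0.35, abs=1e-9)
        assert ledger.pct_additive == pytest.approx(17.7, abs=1e-9)
        assert ledger.pct_interaction_systematic == pytest.approx(14.3, abs=1e-9)
        assert ledger.pct_interaction_composition == pytest.approx(47.5, abs=1e-9)
        assert ledger.pct_residual == pytest.approx(20.5, abs=1e-9)

    def test_equal_r2_gives_zero_increments(self):
        ledger = decompose_variance(0.1, 0.3, 0.3, 0.3)
        assert ledger.pct_interaction_systematic == 0.0
        assert ledger.pct_interaction_composition == 0.0

    def test_perfect_model5_leaves_no_residual(self):
        assert decompose_variance(0.0, 0.2, 0.5, 1.0).pct_residual == 0.0

    def test_non_monotone_increment_warned_not_hidden(self):
        ledger = decompose_variance(0.0, 0.4, 0.3, 0.35)
        assert ledger.pct_interaction_systematic == pytest.approx(-10.0)
        assert ledger.warnings

    def test_conservation_identity(self, mixed_tables):
        ledger = CounterfactualPartition(mixed_tables).fit().ledger
        total = (
            ledger.pct_additive
            + ledger.pct_interaction_systematic
            + ledger.pct_interaction_composition
            + ledger.pct_residual
        )
        assert total == pytest.approx(100.0, abs=0.1)

    def test_accepts_evaluation_rows(self):
        rows = [
            EvaluationRow("m", "", 10, 1, 0, 1, 0.5, r2, -100.0) for r2 in (0.0035, 0.177, 0.320, 0.795)
        ]
        assert decompose_variance(*rows).pct_residual == pytest.approx(20.5, abs=1e-9)


class TestRefitWithTime:
    def test_doubled_theta_doubles_refit_slope(self):
        config = SimulationConfig(
            scenario="interaction_evolution",
            seed=3,
            noise_sd=0.0,
            microcosm_sd=0.0,
            include_transfers=False,
        )
        frame = community_frame(simulate_experiment(config))
        model0 = fit_baseline(frame)
        model4 = refit_with_time(frame, model0)
        # theta doubled at week 5 and monoculture yields unchanged: every
        # slope-related coefficient doubles
        assert model4.params["additive"] == pytest.approx(2.0 * model0.params["additive"], rel=1e-6)

    def test_no_change_scenario_preserves_coefficients(self, exact_additive_tables):
        frame = community_frame(exact_additive_tables)
        model0 = fit_baseline(frame)
        model4 = refit_with_time(frame, model0)
        assert model4.params["additive"] == pytest.approx(model0.params["additive"], abs=1e-8)

    def test_nesting_monotonicity_of_raw_r2(self, mixed_tables):
        frame = community_frame(mixed_tables)
        model0 = fit_baseline(frame)
        model4 = refit_with_time(frame, model0)
        model5 = refit_with_time(frame, model0, by_composition=True)
        # regress the same response on each model's prediction, least squares
        a5 = frame["A5"].to_numpy()
        m2_pred = counterfactual_prediction(model0, "additive_mono", frame)
        r2_m2 = np.corrcoef(a5, m2_pred)[0, 1] ** 2
        assert model5.result.rsquared >= model4.result.rsquared >= r2_m2


class TestTimeInteractionTest:
    def test_identical_weeks_give_near_zero_statistic(self, mixed_tables):
        frame = community_frame(mixed_tables).copy()
        frame["A5"] = frame["A0"]
        res = time_interaction_test(frame)
        assert res.statistic == pytest.approx(0.0, abs=1e-2)
        assert res.pvalue > 0.99

    def test_interaction_evolution_detected(self):
        config = SimulationConfig(scenario="interaction_evolution", seed=11, include_transfers=False)
        frame = community_frame(simulate_experiment(config))
        res = time_interaction_test(frame)
        assert res.pvalue < 1e-6


class TestSensitivity:
    def test_identity_without_extinctions(self):
        config = SimulationConfig(scenario="additive_evolution", seed=5, include_transfers=False)
        model = CounterfactualPartition(simulate_experiment(config))
        main = model.fit().ledger.components()
        sens = model.sensitivity_exclude_extinct().ledger.components()
        for key in main:
            assert sens[key] == pytest.approx(main[key], abs=1e-9)

    def test_masking_extinct_species_removes_extinction_signal(self):
        # excluding end-extinct species from the week-0 sums removes the very
        # contrast model 1 scores, so the extinction share must fall
        config = SimulationConfig(scenario="sorting_only", seed=6, include_transfers=False)
        model = CounterfactualPartition(simulate_experiment(config))
        main = model.fit().ledger
        sens = model.sensitivity_exclude_extinct().ledger
        assert sens.pct_extinction < main.pct_extinction
        assert main.pct_extinction > 50.0

    def test_surviving_richness_floor_is_one(self, mixed_tables):
        frame = community_frame(mixed_tables)
        assert (frame["surviving_richness"] >= 1).all()
        assert (frame["log_surviving_richness"] >= 0).all()


class TestPerSpeciesCoefficients:
    def test_neutral_time_coefficients_centred_on_zero(self):
        config = SimulationConfig(scenario="neutral_additive", seed=8, include_transfers=False)
        table = per_species_coefficient_model(simulate_experiment(config))
        assert len(table) == 12
        assert (table["flag"] == "").all()
        assert abs(table["z"]).max() < 4.0
        assert abs(table["z"].mean()) < 1.0

    def test_single_drifting_species_identified(self):
        hits = 0
        for seed in (21, 22, 23):
            drift = {f"s{i:02d}": 1.0 for i in range(1, 13)}
            drift["s05"] = 2.0
            config = SimulationConfig(
                scenario="additive_evolution",
                seed=seed,
                yield_drift=drift,
                no_extinction=True,
                include_transfers=False,
            )
            table = per_species_coefficient_model(simulate_experiment(config))
            best = table.loc[table["time_coefficient"].idxmax()]
            if best["species_id"] == "s05" and best["z"] > 2:
                hits += 1
        assert hits >= 2


class TestPartitionModelObject:
    def test_fit_produces_five_row_table(self, mixed_tables):
        res = CounterfactualPartition(mixed_tables).fit()
        assert list(res.evaluation_table.index) == [
            "model1",
            "model2",
            "model3",
            "model4",
            "model5",
        ]
        assert "variance" in res.summary()

    def test_missing_isolates_omits_model3(self, mixed_tables):
        tables = type(mixed_tables)(
            design=mixed_tables.design,
            yields=mixed_tables.yields,
            survival=mixed_tables.survival,
            isolates=None,
        )
        res = CounterfactualPartition(tables).fit()
        assert "model3" not in res.rows
        assert res.additive_model == "model2"

    def test_isolate_missing_for_survivor_is_an_error(self, mixed_tables):
        # drop the isolate of a surviving member of a *community* microcosm
        richness = mixed_tables.design.groupby("composition_id")["richness"].first()
        iso = mixed_tables.isolates.merge(
            richness.rename("richness"), left_on="composition_id", right_index=True
        )
        victim = iso[iso["richness"] >= 2].index[0]
        broken = type(mixed_tables)(
            design=mixed_tables.design,
            yields=mixed_tables.yields,
            survival=mixed_tables.survival,
            isolates=mixed_tables.isolates.drop(index=victim),
        )
        with pytest.raises(KeyError, match="isolate yield missing"):
            CounterfactualPartition(broken)
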