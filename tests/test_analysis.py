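"""Behavioral indices and regression procedures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskrl.analysis import (
    hierarchical_trait_regression,
    learning_rate_contrast,
    parameter_behavior_regression,
    reflection_effect,
    summarize_behavior,
    trait_correlation_screen,
)
from riskrl.models import ParameterVector, get_model
from riskrl.simulate import simulate_subject
from riskrl.task import GAIN, LOSS, ChoiceRecord, SubjectDataset, build_schedule
from tests.conftest import simulate_many


def _oracle_agent(domain, seed):
    """Simulated agent that always takes the higher-expected-value option."""
    from riskrl.task import option_expected_value

    sched = build_schedule(domain, seed)
    records = []
    rng = np.random.default_rng(seed)
    for t, (left, right) in enumerate(sched.trials):
        ev_l = option_expected_value(left, domain)
        ev_r = option_expected_value(right, domain)
        if ev_l == ev_r:
            chosen = left if rng.random() < 0.5 else right
        else:
            chosen = left if ev_l > ev_r else right
        from riskrl.task import Option, draw_outcome

        outcome = draw_outcome(Option.make(chosen, domain), rng)
        records.append(ChoiceRecord(t + 1, domain, (left, right), chosen, outcome))
    return records


class TestSummarizeBehavior:
    def test_oracle_agent_is_perfect(self):
        data = SubjectDataset(
            "oracle", _oracle_agent(GAIN, 1) + _oracle_agent(LOSS, 2)
        )
        summary = summarize_behavior([data])
        assert (summary.advantageous["prop"] == 1.0).all()

    def test_uniform_agent_near_half_on_probe(self):
        model = get_model("hybrid_beta_identity")
        pv = ParameterVector.from_natural(
            model, dict(alpha_p=0.3, alpha_n=0.3, beta=0.0, kappa=1.0)
        )
        datasets = simulate_many(model, pv, 200, seed0=40)
        summary = summarize_behavior(datasets)
        for domain in (GAIN, LOSS):
            props = summary.risk_proportion(domain)
            n = 30 * 200
            se = np.sqrt(0.25 / n)
            assert abs(props.mean() - 0.5) < 3 * se

    def test_hand_built_counts(self):
        """Six hand-chosen trials: proportions equal the hand counts."""
        records = [
            ChoiceRecord(1, GAIN, ("Z1", "T10"), "T10", 1),   # adv 0v10
            ChoiceRecord(2, GAIN, ("Z1", "T10"), "Z1", 0),    # dis 0v10
            ChoiceRecord(3, GAIN, ("R", "T10"), "R", 2),      # probe risky
            ChoiceRecord(106, GAIN, ("R", "T10"), "T10", 1),  # probe sure, 2nd half
            ChoiceRecord(110, GAIN, ("T10", "W20"), "W20", 2),  # adv 10v20
            ChoiceRecord(1, LOSS, ("R", "T10"), "R", -2),     # probe risky
        ]
        summary = summarize_behavior([SubjectDataset("hand", records)])
        adv = summary.advantageous.set_index(["domain", "half", "trial_type"])
        assert adv.loc[(GAIN, "first", "0v10"), "prop"] == 0.5
        assert adv.loc[(GAIN, "second", "10v20"), "prop"] == 1.0
        assert np.isnan(adv.loc[(GAIN, "first", "0v20"), "prop"])  # empty cell
        risk = summary.risk.set_index(["domain", "half"])
        assert risk.loc[(GAIN, "first"), "prop"] == 1.0
        assert risk.loc[(GAIN, "second"), "prop"] == 0.0
        assert risk.loc[(GAIN, "all"), "prop"] == 0.5
        assert summary.reflection["hand"] == pytest.approx(1.0 - 0.5)

    def test_trial_count_partition(self, hybrid, hybrid_params, schedules):
        """Advantageous + tie (0v0) + probe (Rv10) counts = 210 per block."""
        data = simulate_subject(hybrid_params, hybrid, schedules, seed=3)
        summary = summarize_behavior([data])
        for domain in (GAIN, LOSS):
            adv_n = summary.advantageous.query("domain == @domain")["n_trials"].sum()
            probe_n = summary.risk.query("domain == @domain and half == 'all'")[
                "n_trials"
            ].sum()
            tie_n = sum(
                1 for r in data.records
                if r.domain == domain and set(r.pair) == {"Z1", "Z2"}
            )
            assert adv_n + probe_n + tie_n == 210


class TestContrastAndReflection:
    @pytest.mark.parametrize(
        "ap, an, expected", [(0.5, 0.5, 0.0), (0.6, 0.2, 0.5), (0.2, 0.6, -0.5)]
    )
    def test_contrast_values(self, ap, an, expected):
        assert learning_rate_contrast(ap, an) == pytest.approx(expected)

    @given(ap=st.floats(0.01, 0.99), an=st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_contrast_antisymmetric(self, ap, an):
        assert learning_rate_contrast(ap, an) == pytest.approx(
            -learning_rate_contrast(an, ap)
        )
        assert -1 < learning_rate_contrast(ap, an) < 1

    def test_contrast_undefined_at_zero(self):
        with pytest.raises(ValueError):
            learning_rate_contrast(0.0, 0.0)

    @pytest.mark.parametrize(
        "gain, loss, expected", [(0.365, 0.488, 0.123), (0.4, 0.4, 0.0), (1, 0, -1)]
    )
    def test_reflection_values(self, gain, loss, expected):
        assert reflection_effect(gain, loss) == pytest.approx(expected)

    def test_reflection_composes_with_summary(self, hybrid, hybrid_params, schedules):
        data = simulate_subject(hybrid_params, hybrid, schedules, seed=9)
        summary = summarize_behavior([data])
        composed = reflection_effect(
            summary.risk_proportion(GAIN).iloc[0],
            summary.risk_proportion(LOSS).iloc[0],
        )
        assert summary.reflection.iloc[0] == pytest.approx(composed)


class TestParameterBehaviorRegression:
    def test_noiseless_linear_system(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["kappa", "contrast"])
        y = 0.7 * X["kappa"] - 0.2 * X["contrast"]
        res = parameter_behavior_regression(X, y)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        # standardized weights: b_j * sd(x_j) / sd(y)
        expect = np.array([0.7, -0.2]) * X.std(ddof=1).to_numpy() / y.std(ddof=1)
        np.testing.assert_allclose(res.coefficients.to_numpy(), expect, atol=1e-8)

    def test_null_predictors_match_permutation_distribution(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["kappa", "contrast"])
        y = rng.normal(size=200)
        r2 = parameter_behavior_regression(X, y).r2
        null = []
        for _ in range(300):
            null.append(
                parameter_behavior_regression(X, rng.permutation(y)).r2
            )
        assert r2 < np.quantile(null, 0.99)

    def test_recovers_generative_signs(self):
        """Cohorts varying in kappa and contrast: regression signs follow
        the generative directions (kappa +gain/-loss, contrast + both)."""
        model = get_model("hybrid")
        rng = np.random.default_rng(5)
        rows = []
        for i in range(120):
            kappa = float(np.exp(rng.normal(0, 0.4)))
            ap = float(1 / (1 + np.exp(-rng.normal(-0.7, 0.7))))
            an = float(1 / (1 + np.exp(-rng.normal(-0.7, 0.7))))
            pv = ParameterVector.from_natural(
                model, dict(alpha_p=ap, alpha_n=an, beta=3.0, kappa=kappa)
            )
            sch = (build_schedule(GAIN, 3 * i), build_schedule(LOSS, 3 * i + 1))
            data = simulate_subject(pv, model, sch, seed=50_000 + i,
                                    subject_id=f"s{i}")
            summary = summarize_behavior([data])
            rows.append({
                "kappa": kappa,
                "contrast": learning_rate_contrast(ap, an),
                "risk_gain": summary.risk_proportion(GAIN).iloc[0],
                "risk_loss": summary.risk_proportion(LOSS).iloc[0],
            })
        table = pd.DataFrame(rows)
        gain = parameter_behavior_regression(
            table[["kappa", "contrast"]], table["risk_gain"]
        )
        loss = parameter_behavior_regression(
            table[["kappa", "contrast"]], table["risk_loss"]
        )
        assert gain.coefficients["kappa"] > 0
        assert loss.coefficients["kappa"] < 0
        assert gain.coefficients["contrast"] > 0
        assert loss.coefficients["contrast"] > 0

    def test_too_few_observations_rejected(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError):
            parameter_behavior_regression(X, np.arange(3.0))


def _traits_frame(rng, n):
    return pd.DataFrame(
        {"pp": rng.normal(34, 5, n), "sp": rng.normal(21, 4, n),
         "ta": rng.normal(49, 11, n)}
    )


class TestHierarchicalTraitRegression:
    def test_simple_slopes_match_closed_form(self):
        """+/-1 SD recoding equals main slope +/- interaction slope."""
        rng = np.random.default_rng(2)
        traits = _traits_frame(rng, 80)
        z = traits.apply(lambda c: (c - c.mean()) / c.std(ddof=1))
        y = 0.3 * z["pp"] - 0.4 * z["pp"] * z["ta"] + rng.normal(0, 0.5, 80)
        res = hierarchical_trait_regression(
            traits, y, simple_slope_pairs=[("pp", "ta")]
        )
        b_main = res.coefficients["pp"]
        b_int = res.coefficients["pp:ta"]
        slopes = res.simple_slopes["pp|ta"]
        assert slopes["slope_high"] == pytest.approx(b_main + b_int, abs=1e-8)
        assert slopes["slope_low"] == pytest.approx(b_main - b_int, abs=1e-8)

    def test_null_interaction_type_i_rate(self):
        """With no interaction effect the step-2 F test at alpha = 0.01
        stays non-significant in >= 95% of 200 null simulations."""
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(200):
            traits = _traits_frame(rng, 60)
            y = rng.normal(size=60)
            res = hierarchical_trait_regression(traits, y, simple_slope_pairs=[])
            hits += res.delta_p < 0.01
        assert hits / 200 <= 0.05

    def test_crossover_interaction_power(self):
        """Imprinted pattern (negative slope at low anxiety, flat at high):
        simple-slope signs recovered in >= 90% of 100 runs at n = 300."""
        rng = np.random.default_rng(4)
        good = 0
        for _ in range(100):
            traits = _traits_frame(rng, 300)
            z = traits.apply(lambda c: (c - c.mean()) / c.std(ddof=1))
            # slope of pp: -0.25 at mean ta, 0 at +1 SD, -0.5 at -1 SD
            y = -0.25 * z["pp"] + 0.25 * z["pp"] * z["ta"] \
                + rng.normal(0, 0.8, 300)
            res = hierarchical_trait_regression(
                traits, y, simple_slope_pairs=[("pp", "ta")]
            )
            s = res.simple_slopes["pp|ta"]
            good += (s["slope_low"] < 0) and (s["slope_low"] < s["slope_high"])
        assert good >= 90

    def test_constant_outcome_all_zero(self):
        rng = np.random.default_rng(5)
        traits = _traits_frame(rng, 40)
        res = hierarchical_trait_regression(traits, np.full(40, 3.3))
        assert res.r2 == 0.0
        assert (res.coefficients == 0).all()

    def test_correlation_screen_shape_and_bonferroni(self):
        rng = np.random.default_rng(6)
        traits = _traits_frame(rng, 50)
        params = pd.DataFrame(rng.normal(size=(50, 4)),
                              columns=["alpha_p", "alpha_n", "beta", "kappa"])
        screen = trait_correlation_screen(traits, params)
        assert len(screen) == 12
        assert (screen["p_bonferroni"] >= screen["p"]).all()
        assert (screen["p_bonferroni"] <= 1.0).all()
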