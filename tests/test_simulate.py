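"""Synthetic generator: determinism, constraints, and aggregate calibration."""

import numpy as np
import pytest

from walletrdd import OutcomeParams, SimulationConfig, simulate_panel
from walletrdd.simulate import DEFAULT_OUTCOME_PARAMS, write_transaction_log


class TestConfig:
    def test_defaults_are_published_parameters(self):
        cfg = SimulationConfig()
        assert cfg.n_users == 3416 and cfg.study_days == 240 and cfg.cutoff_day == 82
        assert cfg.outcomes["saving"] == OutcomeParams(0.0090, 1.0124, 0.4152, 1.0113)
        assert cfg.outcomes["payment"] == OutcomeParams(0.0026, 1.0111, 0.5412, 1.0054)
        assert cfg.outcomes["voucher"] == OutcomeParams(0.0051, 1.0034, 0.5047, 1.0067)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            OutcomeParams(1.5, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            OutcomeParams(0.01, -1.0, 1.0, 1.0)

    def test_cutoff_must_be_inside_window(self):
        with pytest.raises(ValueError):
            SimulationConfig(study_days=80, cutoff_day=82)

    def test_non_integer_seed_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            SimulationConfig(seed="zero")

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "sim.yaml"
        p.write_text(
            "n_users: 50\nstudy_days: 60\ncutoff_day: 20\nseed: 7\n"
            "outcomes:\n  saving:\n    baseline_rate: 0.01\n    pre_trend_irr: 1.0\n"
            "    jump_irr: 0.5\n    post_trend_irr: 1.0\n"
        )
        cfg = SimulationConfig.from_yaml(p)
        assert cfg.n_users == 50 and cfg.outcomes["saving"].jump_irr == 0.5

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_dict({"n_user": 10})


class TestSimulatePanel:
    def test_person_day_accounting(self):
        cfg = SimulationConfig(n_users=40, study_days=50, cutoff_day=20, seed=1)
        panels, _ = simulate_panel(cfg)
        for p in panels.values():
            assert p.n_person_days == 40 * 50

    def test_identical_seed_identical_panel(self):
        a, _ = simulate_panel(SimulationConfig(n_users=80, seed=5))
        b, _ = simulate_panel(SimulationConfig(n_users=80, seed=5))
        for k in a:
            assert np.array_equal(a[k].y, b[k].y)
        c, _ = simulate_panel(SimulationConfig(n_users=80, seed=6))
        assert any(not np.array_equal(a[k].y, c[k].y) for k in a)

    def test_constraint_compliance(self, small_sim):
        _, panels, _ = small_sim
        assert panels["payment"].y.sum(axis=1).max() <= 1
        assert panels["voucher"].y.max() <= 1  # binary cells = <=1 voucher/day

    def test_flat_rate_total_within_four_sd(self):
        """Binomial oracle: constant p=0.005 over 10,000 x 100 person-days."""
        cfg = SimulationConfig(
            n_users=10_000,
            study_days=100,
            cutoff_day=50,
            outcomes={"saving": OutcomeParams(0.005, 1.0, 1.0, 1.0)},
            seed=2024,
        )
        panels, _ = simulate_panel(cfg)
        total = panels["saving"].y.sum()
        mean, sd = 5000.0, np.sqrt(10_000 * 100 * 0.005 * 0.995)
        assert abs(total - mean) < 4 * sd

    def test_no_discontinuity_when_jump_is_one(self):
        """With jump 1 and equal slopes the aggregate mean curve is one
        smooth exponential: compare mean rates just left/right of the cutoff
        over 200 replicates."""
        params = OutcomeParams(0.01, 1.002, 1.0, 1.002)
        left, right = [], []
        for r in range(200):
            cfg = SimulationConfig(
                n_users=150, study_days=60, cutoff_day=30,
                outcomes={"saving": params}, seed=30_000 + r,
            )
            panels, _ = simulate_panel(cfg)
            daily = panels["saving"].daily_counts() / 150
            left.append(daily[27:30].mean())
            right.append(daily[30:33].mean())
        gap = np.mean(right) - np.mean(left)
        expected_gap = params.rate_curve(60, 30)[30:33].mean() - params.rate_curve(60, 30)[27:30].mean()
        se = np.sqrt(np.var(right, ddof=1) / 200 + np.var(left, ddof=1) / 200)
        assert abs(gap - expected_gap) < 4 * se

    def test_probability_above_one_names_day(self):
        cfg_kwargs = dict(
            n_users=10, study_days=200, cutoff_day=50,
            outcomes={"saving": OutcomeParams(0.5, 1.01, 1.2, 1.01)}, seed=0,
        )
        with pytest.raises(ValueError, match="day"):
            simulate_panel(SimulationConfig(**cfg_kwargs))

    def test_truth_is_exact_log_of_config(self):
        cfg = SimulationConfig(n_users=20, seed=3)
        _, truth = simulate_panel(cfg)
        for k, p in cfg.outcomes.items():
            b = truth.block(k)
            assert b.log_jump == np.log(p.jump_irr)
            assert b.pre_slope == np.log(p.pre_trend_irr)
            assert b.post_slope == np.log(p.post_trend_irr)
            assert b.intercept == np.log(p.baseline_rate)

    def test_age_overrides_change_group_rates(self):
        cfg = SimulationConfig(
            n_users=2000, study_days=120, cutoff_day=60,
            outcomes={"saving": OutcomeParams(0.02, 1.0, 1.0, 1.0)},
            age_group_overrides={"<25": {"jump_irr": 0.2}},
            seed=9,
        )
        panels, truth = simulate_panel(cfg)
        assert truth.block("saving", "<25").log_jump == pytest.approx(np.log(0.2))
        p = panels["saving"]
        young = p.y[(p.users["age_group"] == "<25").to_numpy()]
        old = p.y[(p.users["age_group"] == ">30").to_numpy()]
        assert young[:, 60:].mean() < 0.5 * old[:, 60:].mean()

    def test_age_distribution_calibration(self):
        cfg = SimulationConfig(n_users=4000, seed=77)
        panels, _ = simulate_panel(cfg)
        ages = panels["saving"].users["age_years"]
        assert abs(ages.median() - 26) <= 1
        iqr = ages.quantile(0.75) - ages.quantile(0.25)
        assert abs(iqr - 9) <= 2

    def test_mean_rate_converges_to_configured_curve(self):
        """Replicate-mean daily rates track p(t) at the 1/sqrt(reps) scale."""
        params = OutcomeParams(0.02, 1.005, 0.6, 1.004)
        reps, acc = 60, None
        for r in range(reps):
            cfg = SimulationConfig(n_users=200, study_days=80, cutoff_day=40,
                                   outcomes={"saving": params}, seed=40_000 + r)
            panels, _ = simulate_panel(cfg)
            daily = panels["saving"].daily_counts() / 200
            acc = daily if acc is None else acc + daily
        mean_curve = acc / reps
        expected = params.rate_curve(80, 40)
        se = np.sqrt(expected * (1 - expected) / (200 * reps))
        assert np.all(np.abs(mean_curve - expected) < 5 * se)


def test_transaction_log_roundtrip(tmp_path):
    """Write events + registry, re-ingest through the panel pipeline, and
    recover the exact panels."""
    from walletrdd import binarize, load_events, validate_constraints
    from walletrdd.panel import load_registry
    from walletrdd.simulate import write_registry

    cfg = SimulationConfig(n_users=60, study_days=90, cutoff_day=40, seed=8)
    panels, _ = simulate_panel(cfg)
    tx, reg = tmp_path / "tx.csv", tmp_path / "reg.csv"
    write_transaction_log(panels, tx)
    write_registry(panels, reg)
    events = load_events(tx, start_date=cfg.start_date, study_days=90)
    events, violations = validate_constraints(events)
    assert not violations  # generator already enforces the rules
    users = load_registry(reg)
    for outcome, panel in panels.items():
        rebuilt = binarize(events, users, study_days=90, outcome=outcome, cutoff_day=40)
        assert np.array_equal(rebuilt.y, panel.y)
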