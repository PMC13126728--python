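"""Engine unit tests: initialization, tick cycle, invariants, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from openwindow import (
    DecisionContext,
    SimulationConfig,
    decide_action,
    initialize_from_baseline,
    run_simulation,
)
from openwindow.engine import (
    CD4,
    CD8,
    EXHAUSTED,
    Environment,
    _batch_decide,
    init_state,
    step,
)


class TestInitialization:
    def test_baseline_scaling(self):
        agents, pathogens, env, cfg = initialize_from_baseline(scale=0.1, seed=0)
        assert cfg.initial_cd4 == 81 and cfg.initial_cd8 == 61
        assert agents.count(CD4) / agents.count(CD8) == pytest.approx(1.33, abs=0.01)
        assert env.lactate == 0.0
        assert np.all(env.glucose == cfg.glucose_init)

    def test_same_seed_same_placement(self):
        a1, *_ = initialize_from_baseline(scale=0.1, seed=5)
        a2, *_ = initialize_from_baseline(scale=0.1, seed=5)
        np.testing.assert_array_equal(a1.x, a2.x)
        np.testing.assert_array_equal(a1.y, a2.y)

    def test_tiny_scale_rejected(self):
        with pytest.raises(ValueError):
            initialize_from_baseline(scale=1e-4)


class TestStepLimits:
    def test_omnipotent_killers_clear_in_one_step(self, fast_config):
        cfg = dataclasses.replace(
            fast_config,
            kill_prob=1.0,
            kill_prob_cd4=1.0,
            detect_radius=21,  # beyond the grid diagonal
            attack_cost=0.0,
        )
        rng = np.random.default_rng(cfg.seed)
        agents, pathogens, env = init_state(cfg, rng)
        # suppressive lactate rules out proliferation, so every T cell's
        # decision is to attack
        env.lactate = 10.0
        tallies = step(agents, pathogens, env, cfg, rng)
        assert len(pathogens) == 0
        assert tallies["killed_pathogen"] == cfg.initial_pathogen

    def test_zero_suppression_threshold_blocks_proliferation(self, fast_config):
        cfg = dataclasses.replace(fast_config, suppression_threshold=0.0)
        rng = np.random.default_rng(1)
        agents, pathogens, env = init_state(cfg, rng)
        env.lactate = 3.0
        total = 0
        for _ in range(30):
            t = step(agents, pathogens, env, cfg, rng)
            total += t["prolif_cd4"] + t["prolif_cd8"]
            env.lactate = max(env.lactate, 0.5)  # keep it positive
        assert total == 0

    def test_homeostasis_without_stress_or_pathogens(self):
        cfg = SimulationConfig(initial_pathogen=0, stress_multiplier=0.0, ticks=500, seed=3)
        trace = run_simulation(cfg).frame
        initial = trace["total_immune"].iloc[0]
        assert trace["total_immune"].min() >= 0.95 * initial
        assert trace["total_immune"].max() <= 1.05 * initial

    def test_no_proliferation_no_pathogens_is_non_increasing(self):
        cfg = SimulationConfig(
            initial_pathogen=0, proliferation_prob=0.0, ticks=200, seed=4
        )
        trace = run_simulation(cfg).frame
        assert (trace["total_immune"].diff().iloc[1:] <= 0).all()

    def test_lactate_geometric_decay_without_input(self, fast_config):
        rng = np.random.default_rng(0)
        agents, pathogens, env = init_state(fast_config, rng)
        pathogens.keep(np.zeros(len(pathogens), dtype=bool))
        env.lactate = 5.0
        for t in range(1, 11):
            step(agents, pathogens, env, fast_config, rng)
            assert env.lactate == pytest.approx(5.0 * 0.8**t)

    def test_glucose_never_negative(self):
        trace = run_simulation(SimulationConfig(ticks=120, seed=2)).frame
        assert (trace["total_glucose"] >= 0).all()


class TestTraceContracts:
    def test_zero_tick_run_is_initial_state_only(self):
        trace = run_simulation(SimulationConfig(ticks=0, seed=0))
        assert len(trace) == 1
        assert trace.frame["cd4"].iloc[0] == 81

    def test_seeded_determinism_byte_identical(self):
        cfg = SimulationConfig(ticks=100, seed=11)
        a = run_simulation(cfg).frame.to_csv(index=False)
        b = run_simulation(cfg).frame.to_csv(index=False)
        assert a == b

    def test_bookkeeping_conservation(self):
        f = run_simulation(SimulationConfig(ticks=150, seed=6)).frame
        for kind in ("cd4", "cd8"):
            delta = f[kind].diff().iloc[1:]
            net = (
                f[f"prolif_{kind}"] - f[f"apoptosis_{kind}"] - f[f"exhaustion_{kind}"]
            ).iloc[1:]
            assert (delta == net).all()
        apc_delta = f["apc"].diff().iloc[1:]
        assert (apc_delta == (-f["apoptosis_apc"] - f["exhaustion_apc"]).iloc[1:]).all()
        p_delta = f["pathogen"].diff().iloc[1:]
        assert (p_delta == (f["pathogen_replication"] - f["killed_pathogen"]).iloc[1:]).all()

    def test_stress_monotonically_suppresses_immunity(self):
        medians = []
        for mult in (0.0, 1.0, 4.0):
            terminals = [
                run_simulation(
                    SimulationConfig(stress_multiplier=mult, seed=s, ticks=280)
                ).frame["total_immune"].iloc[-1]
                for s in range(3)
            ]
            medians.append(np.median(terminals))
        assert medians[0] >= medians[1] >= medians[2]


class TestBatchDecisionAgreement:
    def test_batch_matches_scalar_decision_layer(self):
        """The engine's vectorized chooser equals decide_action pointwise."""
        cfg = SimulationConfig()
        rng = np.random.default_rng(42)
        names = ["rest", "migrate", "attack", "proliferate"]
        for _ in range(1500):
            kind = int(rng.choice([CD4, CD8]))
            k = int(rng.integers(0, 7))
            glu = float(rng.uniform(0, 11))
            lac = float(rng.uniform(0, 15))
            drive = float(rng.choice([0.0, 0.3, 0.6]))
            batch = _batch_decide(
                np.array([kind]), np.array([k]), np.array([glu]), lac, cfg, drive
            )[0]
            ctx = DecisionContext(
                pathogens_in_radius=k,
                local_glucose=glu,
                lactate=lac,
                energy=5.0,
                kill_weight=cfg.kill_prob if kind == CD8 else cfg.kill_prob_cd4,
                suppression_threshold=cfg.suppression_threshold,
                attack_cost=cfg.attack_cost,
                move_cost=cfg.move_cost,
                proliferation_cost=cfg.proliferation_cost,
                proliferation_horizon=cfg.mop.proliferation_horizon,
            )
            scalar = decide_action(
                ctx, np.random.default_rng(0), proliferation_drive=drive
            ).action
            assert names[batch] == scalar

    def test_exhausted_agents_never_act(self, fast_config):
        rng = np.random.default_rng(9)
        agents, pathogens, env = init_state(fast_config, rng)
        agents.activation[:] = EXHAUSTED
        x0, y0 = agents.x.copy(), agents.y.copy()
        tallies = step(agents, pathogens, env, fast_config, rng)
        alive = len(agents)
        np.testing.assert_array_equal(agents.x, x0[:alive])
        assert tallies["prolif_cd4"] + tallies["prolif_cd8"] == 0
        assert tallies["killed_pathogen"] == 0
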