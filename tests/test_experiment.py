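"""Run orchestration: reproducibility, kernel/reference equivalence, yoking, IO."""

import numpy as np
import pandas as pd
import pytest

from babblesim import plasticity
from babblesim._kernels import run_trial_kernel
from babblesim.experiment import (RunConfig, _neuron_param_arrays, load_run_log,
                                  run_simulation, run_sweep)
from babblesim.network import build_network, init_state, step_network
from conftest import SMALL_CONFIG


class TestReproducibility:
    def test_same_seed_bit_identical_logs(self, small_run):
        again = run_simulation(RunConfig(seed=3, n_trials=5, **SMALL_CONFIG))
        pd.testing.assert_frame_equal(small_run.log, again.log)
        np.testing.assert_array_equal(small_run.s_final, again.s_final)

    def test_different_seed_differs(self, small_run):
        other = run_simulation(RunConfig(seed=4, n_trials=5, **SMALL_CONFIG))
        assert not np.array_equal(small_run.s_final, other.s_final)

    def test_reservoir_weights_never_change(self, small_run):
        assert small_run.diagnostics["reservoir_weights_unchanged"]

    def test_one_record_per_trial(self, small_run):
        assert len(small_run.log) == 5
        assert small_run.log["trial_index"].tolist() == list(range(5))
        assert np.isfinite(small_run.log.drop(columns="theta").to_numpy(float)).all()


class TestKernelEquivalence:
    def test_fused_kernel_matches_reference_composition(self):
        """The numba fast path reproduces step_network + per_ms_update exactly."""
        cfg = RunConfig(seed=11, n_trials=1, n_reservoir=60, n_motor=10, fanout=8)
        net_cfg = cfg.network_config()
        topo = build_network(5, net_cfg)
        pl = plasticity.init_plasticity(6, net_cfg.n_output, net_cfg.n_motor)
        params = plasticity.PlasticityParams()
        n_ms = 300
        noise_res = np.random.default_rng(7).uniform(-6.5, 6.5, (n_ms, topo.n_reservoir))
        noise_mot = np.random.default_rng(8).uniform(-6.5, 6.5, (n_ms, topo.n_motor))

        # reference path
        state = init_state(topo)
        pl_ref = pl.copy()
        ag_ref = np.zeros(n_ms)
        ant_ref = np.zeros(n_ms)
        half = topo.n_motor // 2
        for t in range(n_ms):
            state = step_network(state, topo, pl_ref.s, noise_res[t], noise_mot[t])
            ag_ref[t] = state.spikes_mot[:half].sum()
            ant_ref[t] = state.spikes_mot[half:].sum()
            pl_ref = plasticity.per_ms_update(
                pl_ref, state.spikes_res[topo.output_ids], state.spikes_mot,
                t_ms=t + 1, params=params)
            if t == 0:
                pl_ref = plasticity.deliver_reward(pl_ref, params)

        # fused kernel
        out_map = np.full(topo.n_reservoir, -1, dtype=np.int64)
        out_map[topo.output_ids] = np.arange(net_cfg.n_output)
        arrs = _neuron_param_arrays(topo)
        v_res = np.full(topo.n_reservoir, -65.0)
        u_res = 0.2 * v_res.copy()
        v_mot = np.full(topo.n_motor, -65.0)
        u_mot = 0.2 * v_mot.copy()
        s, e, ctr = pl.s.copy(), pl.e.copy(), pl.c.copy()
        ag, ant, d_end, _, _, _, _ = run_trial_kernel(
            v_res, u_res, v_mot, u_mot,
            topo.fan_targets, topo.fan_weights, *arrs,
            out_map, topo.output_ids.astype(np.int64),
            s, e, ctr, 0.0, noise_res, noise_mot, 1, True,
            params.da_decay, params.trace_bump, params.trace_decay,
            params.elig_decay, params.weight_cap, params.da_bump,
            params.update_interval, False)

        np.testing.assert_array_equal(ag, ag_ref)
        np.testing.assert_array_equal(ant, ant_ref)
        np.testing.assert_allclose(v_res, state.v_res, atol=1e-9, rtol=0)
        np.testing.assert_allclose(s, pl_ref.s, atol=1e-12, rtol=0)
        np.testing.assert_allclose(e, pl_ref.e, atol=1e-12, rtol=0)
        np.testing.assert_allclose(ctr, pl_ref.c, atol=1e-12, rtol=0)
        assert d_end == pytest.approx(pl_ref.d, abs=1e-15)


class TestYokedRuns:
    def test_yoked_consumes_reference_rewards(self):
        ref = run_simulation(RunConfig(seed=21, n_trials=8, **SMALL_CONFIG))
        yoked = run_simulation(RunConfig(seed=22, n_trials=8,
                                         yoked_reward_trials=tuple(ref.reward_trials),
                                         **SMALL_CONFIG))
        assert yoked.reward_trials == ref.reward_trials
        assert int(yoked.log["r"].sum()) == int(ref.log["r"].sum())

    def test_empty_yoked_schedule_keeps_dopamine_on_decay(self):
        res = run_simulation(RunConfig(seed=23, n_trials=5,
                                       yoked_reward_trials=(), **SMALL_CONFIG))
        assert int(res.log["r"].sum()) == 0
        assert (res.log["dopamine_at_trial_end"] == 0.0).all()

    def test_replay_identical_across_seeds(self):
        ref = run_simulation(RunConfig(seed=24, n_trials=8, **SMALL_CONFIG))
        schedules = []
        logs = []
        for seed in (31, 32):
            yoked = run_simulation(RunConfig(seed=seed, n_trials=8,
                                             yoked_reward_trials=tuple(ref.reward_trials),
                                             **SMALL_CONFIG))
            schedules.append(yoked.reward_trials)
            logs.append(yoked.log["S"].to_numpy())
        assert schedules[0] == schedules[1]
        assert not np.array_equal(logs[0], logs[1]), "dynamics must differ by seed"


class TestRunDirectory:
    def test_outputs_written(self, tmp_path):
        out = tmp_path / "run"
        run_simulation(RunConfig(seed=3, n_trials=3, output_dir=str(out),
                                 snapshot_every=2, **SMALL_CONFIG))
        assert (out / "trials.csv").exists()
        assert (out / "config.json").exists()
        assert (out / "weights_initial.csv").exists()
        assert (out / "weights_final.csv").exists()
        assert (out / "vocalization_00000.wav").exists()
        log = load_run_log(out)
        assert len(log) == 3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(n_trials=0)
        with pytest.raises(ValueError):
            RunConfig(backend="nonsense")
        with pytest.raises(ValueError):
            RunConfig(n_motor=7)


class TestSweep:
    def test_single_cell_summary(self):
        summary = run_sweep([(20, 2.0)], seeds=[3, 4], n_trials=4, window=2,
                            n_reservoir=200, fanout=20)
        assert len(summary) == 1
        row = summary.iloc[0]
        assert row["n_motor"] == 20 and row["m"] == 2.0 and row["n_seeds"] == 2

    def test_start_end_recomputable_from_log(self):
        cfg = RunConfig(seed=3, n_trials=5, **SMALL_CONFIG)
        res = run_simulation(cfg)
        S = res.log["S"].to_numpy()
        summary = run_sweep([(SMALL_CONFIG["n_motor"], 2.0)], seeds=[3],
                            n_trials=5, window=2, n_reservoir=200, fanout=20)
        assert summary.iloc[0]["start_mean"] == pytest.approx(S[:2].mean())
        assert summary.iloc[0]["end_mean"] == pytest.approx(S[-2:].mean())
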