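"""Trial/run/sweep orchestration, logging and checkpointing.

One *trial* is 1 s of simulated time: 1000 ms of network dynamics with
per-ms plasticity bookkeeping, then smoothing of the motor rasters into
the 900-ms muscle series, synthesis of the 0.9-s vocalization, salience
scoring, reward evaluation (adaptive threshold or yoked replay) and
logging.  The reward earned by trial k bumps dopamine at the first ms of
trial k+1 (the distal-reward delay), and neural state is continuous
across trial boundaries -- a run is one uninterrupted simulation.

A full run is 7200 trials (2 simulated hours); scaled runs are a
configuration choice, not a code path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import motor_interface, plasticity, reward, salience, syllables, vocal_tract
from ._kernels import run_trial_kernel
from .network import (FAST_SPIKING, REGULAR_SPIKING, NetworkConfig,
                      NetworkTopology, build_network)

__all__ = ["RunConfig", "RunResult", "run_simulation", "run_sweep", "load_run_log"]

TRIAL_MS = 1000
WAV_SAMPLE_INTERVAL_TRIALS = 300   # one vocalization kept every 5 simulated minutes


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_trials: int = 7200
    n_motor: int = 200
    m: float = 2.0
    backend: str = "surrogate"            # or "praat-script-export"
    yoked_reward_trials: tuple | None = None   # replayed reward trial indices
    snapshot_every: int | None = None     # trials between weight snapshots
    output_dir: str | None = None
    n_reservoir: int = 1000
    fanout: int = 100
    normalize_by: str = "mean"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_motor % 2 != 0:
            raise ValueError("n_motor must be even")
        if self.backend not in ("surrogate", "praat-script-export"):
            raise ValueError(f"unknown backend {self.backend!r}")

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(n_reservoir=self.n_reservoir,
                             n_inhibitory=self.n_reservoir // 5,
                             n_motor=self.n_motor, fanout=self.fanout)


@dataclass
class RunResult:
    config: RunConfig
    log: pd.DataFrame               # one TrialRecord row per trial
    topology: NetworkTopology
    s_initial: np.ndarray           # plastic weights before any update
    s_final: np.ndarray
    theta_final: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def reward_trials(self) -> list[int]:
        return [int(t) for t in self.log.loc[self.log["r"] == 1, "trial_index"]]


def _neuron_param_arrays(topology: NetworkTopology):
    n = topology.n_reservoir
    a = np.full(n, REGULAR_SPIKING.a)
    b = np.full(n, REGULAR_SPIKING.b)
    c = np.full(n, REGULAR_SPIKING.c)
    dr = np.full(n, REGULAR_SPIKING.d_reset)
    inh = topology.inhibitory_ids
    a[inh], b[inh], c[inh], dr[inh] = (FAST_SPIKING.a, FAST_SPIKING.b,
                                       FAST_SPIKING.c, FAST_SPIKING.d_reset)
    nm = topology.n_motor
    return (a, b, c, dr,
            np.full(nm, REGULAR_SPIKING.a), np.full(nm, REGULAR_SPIKING.b),
            np.full(nm, REGULAR_SPIKING.c), np.full(nm, REGULAR_SPIKING.d_reset))


def run_simulation(config: RunConfig, progress: bool = False) -> RunResult:
    """Run one full simulation; (seed, config) fully determines every output."""
    # independent named substreams so topology is reproducible regardless of
    # run length: (topology, initial plastic weights, per-ms noise)
    topo_seed, weight_seed, noise_seed = (
        int(x) for x in np.random.SeedSequence(config.seed).generate_state(3))
    net_cfg = config.network_config()
    topology = build_network(topo_seed % (2 ** 31), net_cfg)
    plast_params = plasticity.PlasticityParams(normalize_by=config.normalize_by)
    plast = plasticity.init_plasticity(weight_seed % (2 ** 31),
                                       net_cfg.n_output, net_cfg.n_motor)
    noise_rng = np.random.default_rng(noise_seed)

    reservoir_hash_start = hashlib.sha256(
        topology.reservoir_weights.tobytes()).hexdigest()

    out_map = np.full(topology.n_reservoir, -1, dtype=np.int64)
    out_map[topology.output_ids] = np.arange(net_cfg.n_output)
    (a_res, b_res, c_res, dr_res,
     a_mot, b_mot, c_mot, dr_mot) = _neuron_param_arrays(topology)

    v_res = np.full(topology.n_reservoir, -65.0)
    u_res = REGULAR_SPIKING.b * v_res.copy()
    v_mot = np.full(topology.n_motor, -65.0)
    u_mot = REGULAR_SPIKING.b * v_mot.copy()

    s_initial = plast.s.copy()
    d = plast.d
    s, e, ctr = plast.s, plast.e, plast.c

    threshold_state = reward.ThresholdState()
    yoked = None
    if config.yoked_reward_trials is not None:
        yoked = reward.YokedReplayer(sorted(config.yoked_reward_trials),
                                     n_trials=config.n_trials)

    motor_cfg = motor_interface.MotorConfig(m=config.m)
    synth_cfg = vocal_tract.SynthConfig()
    sal_cfg = salience.SalienceConfig()
    nuc_params = syllables.NucleiParams()

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_config_sidecar(out_dir, config)
        _write_weights(out_dir / "weights_initial.csv", s_initial)

    records = []
    reward_pending = False
    min_s_run = np.inf
    max_s_postcap_run = -np.inf
    max_mean_dev_run = 0.0

    for trial in range(config.n_trials):
        noise_res = noise_rng.uniform(-6.5, 6.5, size=(TRIAL_MS, topology.n_reservoir))
        noise_mot = noise_rng.uniform(-6.5, 6.5, size=(TRIAL_MS, topology.n_motor))
        (ag_counts, ant_counts, d, res_spikes, min_s, max_s_postcap,
         max_mean_dev) = run_trial_kernel(
            v_res, u_res, v_mot, u_mot,
            topology.fan_targets, topology.fan_weights,
            a_res, b_res, c_res, dr_res,
            a_mot, b_mot, c_mot, dr_mot,
            out_map, topology.output_ids.astype(np.int64),
            s, e, ctr, d,
            noise_res, noise_mot,
            trial * TRIAL_MS + 1, reward_pending,
            plast_params.da_decay, plast_params.trace_bump,
            plast_params.trace_decay, plast_params.elig_decay,
            plast_params.weight_cap, plast_params.da_bump,
            plast_params.update_interval, plast_params.normalize_by == "sum")
        min_s_run = min(min_s_run, min_s)
        max_s_postcap_run = max(max_s_postcap_run, max_s_postcap)
        max_mean_dev_run = max(max_mean_dev_run, max_mean_dev)

        ag_smoothed = motor_interface.smooth_spikes(ag_counts, motor_cfg.window_ms)
        ant_smoothed = motor_interface.smooth_spikes(ant_counts, motor_cfg.window_ms)
        muscle = motor_interface.net_muscle(ag_smoothed, ant_smoothed,
                                            config.m, trial_index=trial)
        waveform = vocal_tract.synthesize_surrogate(muscle, synth_cfg)
        if config.backend == "praat-script-export" and out_dir is not None:
            vocal_tract.export_praat_script(
                muscle, synth_cfg, out_dir / f"trial_{trial:05d}.praat")

        S = salience.score_waveform(waveform, sal_cfg)
        nuclei = syllables.count_nuclei(waveform, nuc_params)

        if yoked is not None:
            r = yoked(trial)
            theta_at_eval = float("nan")
        else:
            event, threshold_state = reward.evaluate_trial(S, threshold_state,
                                                           trial_index=trial)
            r = event.r
            theta_at_eval = event.theta_at_eval
        reward_pending = bool(r)

        records.append({
            "trial_index": trial, "S": S, "r": r, "theta": theta_at_eval,
            "syllable_count": nuclei,
            "muscle_mean": float(muscle.values.mean()),
            "muscle_sd": float(muscle.values.std()),
            "dopamine_at_trial_end": d,
        })

        if out_dir is not None:
            if trial % WAV_SAMPLE_INTERVAL_TRIALS == 0:
                vocal_tract.write_wav(out_dir / f"vocalization_{trial:05d}.wav",
                                      waveform)
            if config.snapshot_every and (trial + 1) % config.snapshot_every == 0:
                _write_weights(out_dir / f"weights_{trial + 1:05d}.csv", s)
        if progress and (trial + 1) % 100 == 0:
            print(f"trial {trial + 1}/{config.n_trials}")

    reservoir_hash_end = hashlib.sha256(
        topology.reservoir_weights.tobytes()).hexdigest()

    log = pd.DataFrame.from_records(records)
    result = RunResult(
        config=config, log=log, topology=topology,
        s_initial=s_initial, s_final=s.copy(),
        theta_final=threshold_state.theta,
        diagnostics={
            "min_weight": float(min_s_run),
            "max_weight_post_cap": float(max_s_postcap_run),
            "max_norm_mean_deviation": float(max_mean_dev_run),
            "reservoir_weights_unchanged": reservoir_hash_start == reservoir_hash_end,
        },
    )
    if out_dir is not None:
        log.to_csv(out_dir / "trials.csv", index=False)
        _write_weights(out_dir / "weights_final.csv", s)
        with open(out_dir / "diagnostics.json", "w") as fh:
            json.dump(result.diagnostics, fh, indent=2)
    return result


def _write_config_sidecar(out_dir: Path, config: RunConfig) -> None:
    payload = dataclasses.asdict(config)
    payload["yoked_reward_trials"] = (
        None if config.yoked_reward_trials is None
        else list(config.yoked_reward_trials))
    with open(out_dir / "config.json", "w") as fh:
        json.dump(payload, fh, indent=2)


def _write_weights(path: Path, s: np.ndarray) -> None:
    pd.DataFrame(s).to_csv(path, index=False)


def load_run_log(run_dir) -> pd.DataFrame:
    return pd.read_csv(Path(run_dir) / "trials.csv")


def run_sweep(grid, seeds, n_trials: int, window: int = 60,
              **config_kwargs) -> pd.DataFrame:
    """Parameter sweep over (n_motor, m) combinations.

    For each combination and seed, reports the mean salience over the
    first and last ``window`` vocalizations, plus a paired t-test of the
    start/end difference across seeds.
    """
    from scipy import stats

    rows = []
    for n_motor, m in grid:
        starts, ends = [], []
        for seed in seeds:
            cfg = RunConfig(seed=seed, n_trials=n_trials, n_motor=n_motor, m=m,
                            **config_kwargs)
            result = run_simulation(cfg)
            S = result.log["S"].to_numpy()
            starts.append(S[:window].mean())
            ends.append(S[-window:].mean())
        starts, ends = np.array(starts), np.array(ends)
        if len(seeds) > 1:
            t_stat, p_value = stats.ttest_rel(ends, starts)
        else:
            t_stat, p_value = float("nan"), float("nan")
        rows.append({
            "n_motor": n_motor, "m": m, "n_seeds": len(seeds),
            "start_mean": starts.mean(), "start_sd": starts.std(ddof=1) if len(seeds) > 1 else 0.0,
            "end_mean": ends.mean(), "end_sd": ends.std(ddof=1) if len(seeds) > 1 else 0.0,
            "t_stat": float(t_stat), "p_value": float(p_value),
        })
    return pd.DataFrame(rows)
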