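"""Izhikevich spiking reservoir and agonist/antagonist motor pools.

The network has two parts.  A fixed recurrent *reservoir* of (by default)
1000 Izhikevich neurons, 80% excitatory (regular spiking) and 20%
inhibitory (fast spiking), each with exactly ``fanout`` outgoing synapses;
inhibitory neurons may only target excitatory neurons, and reservoir
weights never change.  A subset of the excitatory neurons are *output*
neurons that project, all-to-all through plastic synapses, onto a motor
population split into equal agonist and antagonist pools.  Agonist spikes
promote jaw/lip closure, antagonist spikes oppose it.

Dynamics run in 1-ms increments.  Every reservoir and motor neuron
receives independent input current drawn uniformly from [-6.5, 6.5] pA at
each step, plus synaptic current from presynaptic neurons that fired on
the previous step (spike propagation delay is exactly 1 ms).

The membrane equations are the standard two-variable Izhikevich form::

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)

with a spike emitted when v reaches 30 mV, after which v <- c and
u <- u + d_reset.  The membrane potential is integrated with two 0.5-ms
sub-steps per ms for numerical stability, the recovery variable with one
full step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SPIKE_THRESHOLD_MV = 30.0
NOISE_AMPLITUDE_PA = 6.5

__all__ = [
    "NeuronParams",
    "NetworkConfig",
    "NetworkTopology",
    "NetworkState",
    "REGULAR_SPIKING",
    "FAST_SPIKING",
    "build_network",
    "sample_noise",
    "init_state",
    "step_network",
    "save_topology",
    "load_topology",
]


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich neuron parameters.

    ``d_reset`` is the post-spike recovery increment (named to avoid any
    confusion with the dopamine concentration, which is also called *d*
    in the plasticity rule).
    """

    a: float
    b: float
    c: float
    d_reset: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"recovery time-scale a must be positive, got {self.a}")
        if not self.c < SPIKE_THRESHOLD_MV:
            raise ValueError(
                f"reset potential c={self.c} must lie below the spike threshold "
                f"({SPIKE_THRESHOLD_MV} mV)"
            )


#: Regular-spiking (excitatory) parameter set.
REGULAR_SPIKING = NeuronParams(a=0.02, b=0.2, c=-65.0, d_reset=8.0)
#: Fast-spiking (inhibitory) parameter set.
FAST_SPIKING = NeuronParams(a=0.1, b=0.2, c=-65.0, d_reset=2.0)


class ConfigurationError(ValueError):
    """Raised when a network configuration violates its preconditions."""


@dataclass(frozen=True)
class NetworkConfig:
    n_reservoir: int = 1000
    n_inhibitory: int = 200
    n_motor: int = 200          # split half agonist / half antagonist
    fanout: int = 100

    def __post_init__(self) -> None:
        if self.n_inhibitory >= self.n_reservoir:
            raise ConfigurationError("n_inhibitory must be < n_reservoir")
        if self.fanout >= self.n_reservoir:
            raise ConfigurationError("fanout must be < n_reservoir")
        if self.n_motor % 2 != 0:
            raise ConfigurationError("n_motor must be even (equal agonist/antagonist pools)")
        n_excitatory = self.n_reservoir - self.n_inhibitory
        if self.n_motor > n_excitatory:
            raise ConfigurationError(
                "n_output (= n_motor) cannot exceed the number of excitatory neurons"
            )

    @property
    def n_excitatory(self) -> int:
        return self.n_reservoir - self.n_inhibitory

    @property
    def n_output(self) -> int:
        # one reservoir output neuron per motor neuron
        return self.n_motor


@dataclass(frozen=True)
class NetworkTopology:
    """Fixed wiring of the reservoir plus index bookkeeping for the motor side.

    ``reservoir_weights[pre, post]`` holds the synaptic strength from
    reservoir neuron ``pre`` onto ``post`` (0 where no synapse exists).
    Excitatory rows lie in [0, 1], inhibitory rows in [-1, 0].  The
    output->motor synapses are *not* stored here -- they are plastic and
    live in :class:`babblesim.plasticity.PlasticityState`.
    """

    config: NetworkConfig
    reservoir_weights: np.ndarray          # (n_reservoir, n_reservoir), read-only
    inhibitory_ids: np.ndarray             # sorted indices of inhibitory neurons
    output_ids: np.ndarray                 # sorted excitatory indices projecting to motor pool
    agonist_ids: np.ndarray                # indices into the motor pool
    antagonist_ids: np.ndarray
    fan_targets: np.ndarray = None         # (n_reservoir, fanout) adjacency list
    fan_weights: np.ndarray = None         # weights aligned with fan_targets

    @property
    def n_reservoir(self) -> int:
        return self.config.n_reservoir

    @property
    def n_motor(self) -> int:
        return self.config.n_motor

    @property
    def excitatory_mask(self) -> np.ndarray:
        mask = np.ones(self.n_reservoir, dtype=bool)
        mask[self.inhibitory_ids] = False
        return mask


@dataclass
class NetworkState:
    """Membrane/recovery variables for reservoir + motor pool and the spike record."""

    v_res: np.ndarray
    u_res: np.ndarray
    v_mot: np.ndarray
    u_mot: np.ndarray
    spikes_res: np.ndarray = field(default=None)   # bool, spikes emitted this ms
    spikes_mot: np.ndarray = field(default=None)
    t_ms: int = 0                                  # global millisecond counter

    def copy(self) -> "NetworkState":
        return NetworkState(
            v_res=self.v_res.copy(), u_res=self.u_res.copy(),
            v_mot=self.v_mot.copy(), u_mot=self.u_mot.copy(),
            spikes_res=None if self.spikes_res is None else self.spikes_res.copy(),
            spikes_mot=None if self.spikes_mot is None else self.spikes_mot.copy(),
            t_ms=self.t_ms,
        )


def build_network(seed: int, config: NetworkConfig | None = None) -> NetworkTopology:
    """Build the fixed reservoir wiring and the motor-side index sets.

    Every reservoir neuron gets exactly ``config.fanout`` outgoing synapses
    to distinct other neurons (no self-connections); inhibitory neurons may
    target only excitatory neurons.  Excitatory outgoing weights are drawn
    from U(0, 1), inhibitory ones from U(-1, 0).  Identical seeds produce
    identical topologies.
    """
    config = config or NetworkConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    n = config.n_reservoir
    inhibitory_ids = np.sort(rng.choice(n, size=config.n_inhibitory, replace=False))
    excitatory_mask = np.ones(n, dtype=bool)
    excitatory_mask[inhibitory_ids] = False
    excitatory_ids = np.flatnonzero(excitatory_mask)

    weights = np.zeros((n, n))
    fan_targets = np.empty((n, config.fanout), dtype=np.int64)
    fan_weights = np.empty((n, config.fanout))
    for pre in range(n):
        if excitatory_mask[pre]:
            candidates = np.delete(np.arange(n), pre)
            draws = rng.uniform(0.0, 1.0, size=config.fanout)
        else:
            candidates = excitatory_ids  # inhibitory -> excitatory only
            draws = rng.uniform(-1.0, 0.0, size=config.fanout)
        targets = rng.choice(candidates, size=config.fanout, replace=False)
        weights[pre, targets] = draws
        fan_targets[pre] = targets
        fan_weights[pre] = draws
    weights.setflags(write=False)
    fan_targets.setflags(write=False)
    fan_weights.setflags(write=False)

    output_ids = np.sort(rng.choice(excitatory_ids, size=config.n_output, replace=False))
    half = config.n_motor // 2
    agonist_ids = np.arange(half)
    antagonist_ids = np.arange(half, config.n_motor)

    return NetworkTopology(
        config=config,
        reservoir_weights=weights,
        inhibitory_ids=inhibitory_ids,
        output_ids=output_ids,
        agonist_ids=agonist_ids,
        antagonist_ids=antagonist_ids,
        fan_targets=fan_targets,
        fan_weights=fan_weights,
    )


def sample_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-neuron input currents drawn uniformly from [-6.5, 6.5] pA."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.uniform(-NOISE_AMPLITUDE_PA, NOISE_AMPLITUDE_PA, size=n)


def init_state(topology: NetworkTopology) -> NetworkState:
    """All neurons at rest: v = -65 mV, u = b*v."""
    n, nm = topology.n_reservoir, topology.n_motor
    v_res = np.full(n, -65.0)
    u_res = REGULAR_SPIKING.b * v_res.copy()
    v_mot = np.full(nm, -65.0)
    u_mot = REGULAR_SPIKING.b * v_mot.copy()
    return NetworkState(v_res=v_res, u_res=u_res, v_mot=v_mot, u_mot=u_mot,
                        spikes_res=np.zeros(n, dtype=bool),
                        spikes_mot=np.zeros(nm, dtype=bool), t_ms=0)


def _izhikevich_update(v: np.ndarray, u: np.ndarray, current: np.ndarray,
                       a: np.ndarray, b: np.ndarray) -> None:
    """In-place Izhikevich integration: two 0.5-ms sub-steps for v, one for u."""
    for _ in range(2):
        v += 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
    u += a * (b * v - u)


def step_network(
    state: NetworkState,
    topology: NetworkTopology,
    plastic_weights: np.ndarray,
    noise_res: np.ndarray,
    noise_mot: np.ndarray,
    params_exc: NeuronParams = REGULAR_SPIKING,
    params_inh: NeuronParams = FAST_SPIKING,
) -> NetworkState:
    """Advance the whole network by one millisecond (pure-numpy reference path).

    Neurons at or above 30 mV on entry emit a spike, are reset, and their
    synaptic weights are delivered as input current during this step (they
    crossed threshold during the previous step's integration, so this
    realises the 1-ms propagation delay).  Motor neurons receive current
    only from reservoir output neurons, through ``plastic_weights``
    (shape n_output x n_motor), plus their own noise.
    """
    st = state.copy()
    n = topology.n_reservoir
    inh = topology.inhibitory_ids

    fired_res = st.v_res >= SPIKE_THRESHOLD_MV
    fired_mot = st.v_mot >= SPIKE_THRESHOLD_MV

    # reset spiking neurons
    d_res = np.full(n, params_exc.d_reset)
    d_res[inh] = params_inh.d_reset
    st.v_res[fired_res] = np.where(np.isin(np.flatnonzero(fired_res), inh),
                                   params_inh.c, params_exc.c)
    st.u_res[fired_res] += d_res[fired_res]
    st.v_mot[fired_mot] = params_exc.c
    st.u_mot[fired_mot] += params_exc.d_reset

    # synaptic currents from the spikes just registered
    current_res = noise_res.astype(float).copy()
    for pre in np.flatnonzero(fired_res):
        current_res += topology.reservoir_weights[pre]
    current_mot = noise_mot.astype(float).copy()
    fired_out = fired_res[topology.output_ids]
    for k in np.flatnonzero(fired_out):
        current_mot += plastic_weights[k]

    # integrate
    a_res = np.full(n, params_exc.a)
    a_res[inh] = params_inh.a
    b_res = np.full(n, params_exc.b)
    b_res[inh] = params_inh.b
    _izhikevich_update(st.v_res, st.u_res, current_res, a_res, b_res)
    _izhikevich_update(st.v_mot, st.u_mot, current_mot,
                       np.full(topology.n_motor, params_exc.a),
                       np.full(topology.n_motor, params_exc.b))

    if not (np.isfinite(st.v_res).all() and np.isfinite(st.u_res).all()
            and np.isfinite(st.v_mot).all() and np.isfinite(st.u_mot).all()):
        raise FloatingPointError("non-finite membrane state encountered")

    st.spikes_res = fired_res
    st.spikes_mot = fired_mot
    st.t_ms = state.t_ms + 1
    return st


def save_topology(topology: NetworkTopology, path) -> None:
    """Serialize the topology to a portable .npz-free text container (CSV bundle)."""
    import pandas as pd

    pre, post = np.nonzero(topology.reservoir_weights)
    pd.DataFrame({
        "pre": pre, "post": post,
        "weight": topology.reservoir_weights[pre, post],
    }).to_csv(path, index=False)


def load_topology(path, config: NetworkConfig, inhibitory_ids, output_ids) -> NetworkTopology:
    import pandas as pd

    df = pd.read_csv(path).sort_values(["pre", "post"], kind="stable")
    pre = df["pre"].to_numpy()
    post = df["post"].to_numpy()
    w = df["weight"].to_numpy()
    weights = np.zeros((config.n_reservoir, config.n_reservoir))
    weights[pre, post] = w
    weights.setflags(write=False)
    fan_targets = post.reshape(config.n_reservoir, config.fanout).astype(np.int64)
    fan_weights = w.reshape(config.n_reservoir, config.fanout)
    half = config.n_motor // 2
    return NetworkTopology(
        config=config, reservoir_weights=weights,
        inhibitory_ids=np.asarray(inhibitory_ids), output_ids=np.asarray(output_ids),
        agonist_ids=np.arange(half), antagonist_ids=np.arange(half, config.n_motor),
        fan_targets=fan_targets, fan_weights=fan_weights,
    )
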