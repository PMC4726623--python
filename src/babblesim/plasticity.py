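"""Dopamine-modulated, LTP-only STDP on the output->motor synapses.

Credit assignment across the ~1-s gap between behaviour and reward is
solved with eligibility traces.  Each output neuron carries a presynaptic
firing trace ``c`` (set to 0.1 on a spike, decaying by 0.95 per ms).
Whenever a motor neuron spikes, the eligibility ``e`` of each of its
incoming synapses grows by the presynaptic trace.  Every 10 ms the
synapse strengths are potentiated by ``e * d`` (``d`` the global dopamine
level, decaying by 0.995 per ms and bumped by +1 on reward), capped at 4,
then normalized by their mean; eligibility decays by 0.99 at the same
boundary.  There is no spike-timing depression: normalization alone keeps
the total drive bounded.

The per-ms statement order matters and is fixed:

1. dopamine decay
2. eligibility increment for motor spikes (using presynaptic traces from
   *before* this ms's presynaptic spikes are registered -- a presynaptic
   and postsynaptic spike in the same ms do not pair)
3. on 10-ms boundaries: weight potentiation with cap
4. presynaptic trace set (0.1) for output spikes, then trace decay
5. on 10-ms boundaries: weight normalization and eligibility decay

A reward bump (``deliver_reward``) is applied after these steps, at the
first ms of the trial following the evaluated vocalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlasticityParams",
    "PlasticityState",
    "init_plasticity",
    "per_ms_update",
    "apply_weight_update",
    "normalize_weights",
    "deliver_reward",
    "eligibility_oracle",
]


@dataclass(frozen=True)
class PlasticityParams:
    da_decay: float = 0.995        # dopamine decay per ms
    trace_bump: float = 0.1        # presynaptic trace value on a spike
    trace_decay: float = 0.95      # presynaptic trace decay per ms
    elig_decay: float = 0.99       # eligibility decay per 10-ms boundary
    weight_cap: float = 4.0
    da_bump: float = 1.0           # dopamine added per reward
    update_interval: int = 10      # ms between weight updates
    normalize_by: str = "mean"     # "mean" (default) or "sum"

    def __post_init__(self) -> None:
        for name in ("da_decay", "trace_decay", "elig_decay"):
            val = getattr(self, name)
            if not 0.0 < val < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {val}")
        if not self.weight_cap > 0:
            raise ValueError("weight_cap must be positive")
        if self.normalize_by not in ("mean", "sum"):
            raise ValueError("normalize_by must be 'mean' or 'sum'")


@dataclass
class PlasticityState:
    """Dopamine d, presynaptic traces c, eligibility e and plastic weights s."""

    d: float                 # global dopamine concentration, >= 0
    c: np.ndarray            # (n_output,) presynaptic firing traces
    e: np.ndarray            # (n_output, n_motor) eligibility traces
    s: np.ndarray            # (n_output, n_motor) synapse strengths, >= 0

    def copy(self) -> "PlasticityState":
        return PlasticityState(d=self.d, c=self.c.copy(), e=self.e.copy(), s=self.s.copy())


def init_plasticity(seed: int, n_output: int, n_motor: int) -> PlasticityState:
    """Fresh state: d = 0, traces zero, weights drawn elementwise from U(0, 1)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    return PlasticityState(
        d=0.0,
        c=np.zeros(n_output),
        e=np.zeros((n_output, n_motor)),
        s=rng.uniform(0.0, 1.0, size=(n_output, n_motor)),
    )


def apply_weight_update(state: PlasticityState,
                        params: PlasticityParams = PlasticityParams()) -> PlasticityState:
    """Potentiate (capped), normalize, and decay eligibility -- one 10-ms boundary."""
    st = state.copy()
    np.minimum(st.s + st.e * st.d, params.weight_cap, out=st.s)
    normalize_weights(st, params)
    st.e *= params.elig_decay
    return st


def normalize_weights(state: PlasticityState, params: PlasticityParams) -> None:
    divisor = state.s.mean() if params.normalize_by == "mean" else state.s.sum()
    if divisor == 0.0:
        raise FloatingPointError("weight normalization divisor is zero")
    state.s /= divisor


def per_ms_update(state: PlasticityState,
                  output_spikes: np.ndarray,
                  motor_spikes: np.ndarray,
                  t_ms: int,
                  params: PlasticityParams = PlasticityParams()) -> PlasticityState:
    """One millisecond of plasticity bookkeeping (pure-numpy reference path).

    ``t_ms`` is the 1-based global millisecond; weight updates and
    normalization fire when it is divisible by ``params.update_interval``.
    """
    st = state.copy()
    output_spikes = np.asarray(output_spikes, dtype=bool)
    motor_spikes = np.asarray(motor_spikes, dtype=bool)
    boundary = t_ms % params.update_interval == 0

    # 1. dopamine decay
    st.d *= params.da_decay
    # 2. eligibility grows on postsynaptic (motor) spikes, from pre-update traces
    if motor_spikes.any():
        st.e[:, motor_spikes] += st.c[:, None]
    # 3. potentiation with cap
    if boundary:
        np.minimum(st.s + st.e * st.d, params.weight_cap, out=st.s)
    # 4. presynaptic trace set-then-decay
    st.c[output_spikes] = params.trace_bump
    st.c *= params.trace_decay
    # 5. normalization and eligibility decay
    if boundary:
        normalize_weights(st, params)
        st.e *= params.elig_decay
    return st


def deliver_reward(state: PlasticityState,
                   params: PlasticityParams = PlasticityParams()) -> PlasticityState:
    """Reward receipt: d <- d + 1.  Nothing else changes."""
    st = state.copy()
    st.d += params.da_bump
    return st


def eligibility_oracle(pre_spike_times, post_spike_times, query_ms: int,
                       params: PlasticityParams = PlasticityParams()) -> float:
    """Closed-form eligibility of one synapse, independent of the incremental path.

    Each presynaptic spike at ``t_p`` pairing with a later postsynaptic
    spike at ``t_q > t_p`` contributes ``0.1 * 0.95**(t_q - t_p)``, then
    decays by 0.99 for every 10-ms boundary in [t_q, query_ms] (the
    boundary of ``t_q`` itself counts: the eligibility decay runs after
    the increment within the same ms).  Same-ms pairs contribute nothing.
    """
    pre = list(pre_spike_times)
    post = list(post_spike_times)
    if sorted(pre) != pre or sorted(post) != post:
        raise ValueError("spike-time lists must be sorted")
    if any(t > query_ms for t in pre + post):
        raise ValueError("query_ms must be at or after every spike time")

    interval = params.update_interval
    total = 0.0
    for t_q in post:
        # trace value seen by the postsynaptic spike: most recent pre < t_q wins
        # (the trace is *set*, not accumulated, on each presynaptic spike)
        prior = [t_p for t_p in pre if t_p < t_q]
        if not prior:
            continue
        t_p = prior[-1]
        contribution = params.trace_bump * params.trace_decay ** (t_q - t_p)
        n_boundaries = query_ms // interval - (t_q - 1) // interval
        total += contribution * params.elig_decay ** n_boundaries
    return total
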