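"""Adaptive reward thresholding and yoked-control reward replay.

A vocalization is rewarded when its salience score strictly exceeds the
current threshold theta.  Theta starts at 4.5 and ratchets upward: when
at least 3 of the last 10 trials were rewarded (a 30% recent reward
rate), theta increases by 0.1 and the reward history is reset, so each
further increment requires three new rewards.  Theta never decreases.

Yoked controls replay the reward *times* of a reference run, decoupling
reward from the control run's own behaviour; they isolate reward
contingency as the cause of learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ThresholdState", "RewardEvent", "evaluate_trial", "YokedReplayer"]

THETA_INIT = 4.5
THETA_INCREMENT = 0.1
HISTORY_LEN = 10
CRITERION_COUNT = 3   # 30% of the last 10 trials


@dataclass(frozen=True)
class ThresholdState:
    theta: float = THETA_INIT
    history: tuple = (0,) * HISTORY_LEN    # last-10 reward indicators
    increment: float = THETA_INCREMENT
    criterion_count: int = CRITERION_COUNT

    def __post_init__(self) -> None:
        if len(self.history) != HISTORY_LEN:
            raise ValueError(f"history must hold exactly {HISTORY_LEN} entries")


@dataclass(frozen=True)
class RewardEvent:
    trial_index: int
    r: int                  # 0/1 reward indicator
    S: float                # salience score that was evaluated
    theta_at_eval: float    # threshold the score was compared against


def evaluate_trial(S: float, state: ThresholdState,
                   trial_index: int = 0) -> tuple[RewardEvent, ThresholdState]:
    """One step of the threshold state machine.

    r = 1 iff S > theta (strict).  The indicator is appended to the
    10-long history; if the history then holds >= 3 rewards, theta grows
    by the increment and the history is zeroed.
    """
    r = 1 if S > state.theta else 0
    event = RewardEvent(trial_index=trial_index, r=r, S=float(S),
                        theta_at_eval=state.theta)
    history = state.history[1:] + (r,)
    if sum(history) >= state.criterion_count:
        new_state = ThresholdState(theta=state.theta + state.increment,
                                   history=(0,) * HISTORY_LEN,
                                   increment=state.increment,
                                   criterion_count=state.criterion_count)
    else:
        new_state = ThresholdState(theta=state.theta, history=history,
                                   increment=state.increment,
                                   criterion_count=state.criterion_count)
    return event, new_state


class YokedReplayer:
    """Reward source replaying the reward trial indices of a reference run.

    ``r = 1`` exactly at the listed trial indices, regardless of the
    yoked run's own salience (which is still logged for analysis).
    """

    def __init__(self, reward_trials, n_trials: int | None = None):
        trials = [int(t) for t in reward_trials]
        if trials != sorted(trials):
            raise ValueError("reward trial indices must be sorted")
        if any(t < 0 for t in trials):
            raise ValueError("reward trial indices must be non-negative")
        if n_trials is not None and any(t >= n_trials for t in trials):
            raise ValueError("reward trial index beyond run length")
        self._trials = frozenset(trials)

    @classmethod
    def from_log(cls, log, n_trials: int | None = None) -> "YokedReplayer":
        """Build from a run log DataFrame (columns trial_index, r)."""
        rewarded = log.loc[log["r"] == 1, "trial_index"].to_numpy()
        return cls(sorted(int(t) for t in rewarded), n_trials=n_trials)

    def __call__(self, trial_index: int) -> int:
        return 1 if trial_index in self._trials else 0

    @property
    def reward_trials(self) -> frozenset:
        return self._trials
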