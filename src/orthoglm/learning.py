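"""Rescorla-Wagner learning traces.

The Rescorla-Wagner rule models trial-by-trial reward learning: on each
trial the agent holds a predicted value ``V_t`` for the conditional
stimulus, observes the reward ``R_t``, computes the reward prediction
error

.. math::

    \\delta_t = R_t - V_t

and updates its expectation for the next trial with a learning rate
``alpha``:

.. math::

    V_{t+1} = V_t + \\alpha \\, \\delta_t

The prediction-error sequence ``delta`` is what model-based fMRI analyses
use as a parametric modulation at feedback time, where it competes with the
raw reward-outcome indicator ``R`` as an explanation of the BOLD signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["TrialSequence", "LearningTrace", "rw_trace"]


@dataclass(frozen=True)
class TrialSequence:
    """An ordered sequence of per-trial reward receipts.

    Parameters
    ----------
    rewards
        One real number per trial. In the classic conditioning setting the
        values are 1 (reward delivered) and 0 (reward omitted), but any
        real-valued reward magnitude is allowed.
    trial_types
        Optional per-trial stimulus labels. Only needed when a per-stimulus
        learning rate is used: each label then tracks its own predicted
        value.
    """

    rewards: np.ndarray
    trial_types: tuple[str, ...] | None = None

    def __init__(
        self,
        rewards: Sequence[float],
        trial_types: Sequence[str] | None = None,
    ) -> None:
        arr = np.asarray(rewards, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("rewards must be a non-empty 1-D sequence")
        object.__setattr__(self, "rewards", arr)
        if trial_types is not None:
            tt = tuple(str(t) for t in trial_types)
            if len(tt) != arr.size:
                raise ValueError(
                    f"trial_types has length {len(tt)}, expected {arr.size}"
                )
            object.__setattr__(self, "trial_types", tt)
        else:
            object.__setattr__(self, "trial_types", None)

    @property
    def n_trials(self) -> int:
        return int(self.rewards.size)


@dataclass(frozen=True)
class LearningTrace:
    """Predicted values and prediction errors under the Rescorla-Wagner rule.

    Attributes
    ----------
    alpha
        Learning rate in [0, 1], or a mapping from trial type to rate.
    v0
        Initial predicted value ``V_1`` (shared by all trial types).
    values
        ``V_t`` for each trial, with ``values[0] == v0``.
    deltas
        ``delta_t = rewards[t] - values[t]`` for each trial.
    """

    alpha: float | Mapping[str, float]
    v0: float
    values: np.ndarray = field(repr=False)
    deltas: np.ndarray = field(repr=False)

    @property
    def n_trials(self) -> int:
        return int(self.values.size)


def _check_alpha(alpha: float) -> float:
    a = float(alpha)
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"learning rate alpha must lie in [0, 1], got {a}")
    return a


def rw_trace(
    seq: TrialSequence | Sequence[float],
    alpha: float | Mapping[str, float],
    v0: float = 0.0,
) -> LearningTrace:
    """Run the Rescorla-Wagner recurrence over a reward sequence.

    Parameters
    ----------
    seq
        Trial sequence (or a plain sequence of rewards).
    alpha
        Learning rate in [0, 1]. May also be a mapping from trial type to
        learning rate, in which case ``seq`` must carry ``trial_types`` and
        each trial type maintains its own predicted value (starting at
        ``v0``) updated with its own rate.
    v0
        Initial predicted value, default 0.

    Returns
    -------
    LearningTrace
        Satisfies ``deltas[t] = rewards[t] - values[t]`` and
        ``values[t+1] = values[t] + alpha * deltas[t]`` exactly (no rounding
        is applied internally).

    Examples
    --------
    The seven-trial reward schedule [1, 0, 0, 1, 1, 1, 0] with
    ``alpha = 0.5`` yields prediction errors
    [1, -0.5, -0.25, 0.875, 0.4375, 0.21875, -0.890625].
    """
    if not isinstance(seq, TrialSequence):
        seq = TrialSequence(seq)
    rewards = seq.rewards
    n = seq.n_trials
    values = np.empty(n, dtype=float)
    deltas = np.empty(n, dtype=float)

    if isinstance(alpha, Mapping):
        if seq.trial_types is None:
            raise ValueError(
                "per-trial-type alpha mapping requires a TrialSequence "
                "with trial_types"
            )
        rates = {k: _check_alpha(v) for k, v in alpha.items()}
        missing = sorted(set(seq.trial_types) - set(rates))
        if missing:
            raise ValueError(f"no learning rate given for trial types {missing}")
        state = {k: float(v0) for k in rates}
        for t, (r, tt) in enumerate(zip(rewards, seq.trial_types)):
            v = state[tt]
            values[t] = v
            deltas[t] = r - v
            state[tt] = v + rates[tt] * deltas[t]
        return LearningTrace(alpha=dict(rates), v0=float(v0), values=values, deltas=deltas)

    a = _check_alpha(alpha)
    v = float(v0)
    for t, r in enumerate(rewards):
        values[t] = v
        deltas[t] = r - v
        v = v + a * deltas[t]
    return LearningTrace(alpha=a, v0=float(v0), values=values, deltas=deltas)
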