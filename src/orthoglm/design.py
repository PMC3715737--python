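"""Regressor construction for event-related GLM designs.

Events (onset, duration, per-event modulation) are rendered as stick or
boxcar stimulus functions on a fine internal time grid, convolved with a
canonical double-gamma hemodynamic response function (HRF), and decimated
to the output sampling interval. Regressors can then be z-standardized and
serially orthogonalized, and assembled into the four design matrices used
for model comparison: two "full" designs containing both candidate
regressors with reversed orthogonalization order, and two "reduced"
designs containing one candidate each.

Conventions
-----------
* Standard deviations are population (divide by n) throughout, so the
  z-score of a length-3 ramp is exactly ``[-1.2247, 0, 1.2247]``.
* Orthogonalization projects out the mean as well as the bases, so a zero
  dot product is the same thing as a zero Pearson correlation.
* Orthogonalized regressors are *not* re-standardized; this preserves the
  identity between the orthogonalized regressor's beta and its beta in the
  corresponding non-orthogonalized joint model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

__all__ = [
    "EventSpec",
    "Regressor",
    "DesignMatrix",
    "canonical_hrf",
    "build_regressor",
    "center_modulations",
    "zscore",
    "orthogonalize",
    "build_designs",
]

#: fine grid used for convolution before decimating to the output interval
INTERNAL_DT = 0.1

#: length of the sampled HRF window in seconds
HRF_DURATION = 32.0


@dataclass(frozen=True)
class EventSpec:
    """A set of events of one trial type with per-event modulations.

    Onsets and durations are in seconds from the start of the series;
    modulations are the per-event amplitudes (e.g. reward indicators or
    prediction errors) that scale each event's stick/boxcar.
    """

    onsets: np.ndarray
    durations: np.ndarray
    modulations: np.ndarray
    label: str = "events"

    def __init__(
        self,
        onsets: Sequence[float],
        durations: Sequence[float],
        modulations: Sequence[float],
        label: str = "events",
    ) -> None:
        on = np.asarray(onsets, dtype=float)
        du = np.asarray(durations, dtype=float)
        mo = np.asarray(modulations, dtype=float)
        if not (on.shape == du.shape == mo.shape) or on.ndim != 1:
            raise ValueError("onsets, durations and modulations must be equal-length 1-D")
        if on.size < 1:
            raise ValueError("at least one event is required")
        if np.any(np.diff(on) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(du < 0):
            raise ValueError("durations must be non-negative")
        object.__setattr__(self, "onsets", on)
        object.__setattr__(self, "durations", du)
        object.__setattr__(self, "modulations", mo)
        object.__setattr__(self, "label", str(label))

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)


@dataclass(frozen=True)
class Regressor:
    """A named, sampled time series with provenance flags."""

    name: str
    samples: np.ndarray = field(repr=False)
    dt: float
    standardized: bool = False
    orthogonalized_against: tuple[str, ...] = ()

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def same_grid(self, other: "Regressor") -> bool:
        return self.n_samples == other.n_samples and np.isclose(self.dt, other.dt)


@dataclass(frozen=True)
class DesignMatrix:
    """Ordered regressors plus an optional intercept column.

    ``ortho_order`` is a human-readable record of which regressor was
    serially orthogonalized against which, e.g. ``"RPE orthogonalized
    against RO"``; empty for designs without orthogonalization.
    """

    regressors: tuple[Regressor, ...]
    include_intercept: bool = True
    ortho_order: str = ""

    def __init__(
        self,
        regressors: Sequence[Regressor],
        include_intercept: bool = True,
        ortho_order: str = "",
    ) -> None:
        regs = tuple(regressors)
        if not regs:
            raise ValueError("a design needs at least one regressor")
        for r in regs[1:]:
            if not regs[0].same_grid(r):
                raise ValueError(
                    f"regressor {r.name!r} is not on the grid of {regs[0].name!r}"
                )
        object.__setattr__(self, "regressors", regs)
        object.__setattr__(self, "include_intercept", bool(include_intercept))
        object.__setattr__(self, "ortho_order", str(ortho_order))

    @property
    def n_samples(self) -> int:
        return self.regressors[0].n_samples

    @property
    def n_columns(self) -> int:
        return len(self.regressors) + (1 if self.include_intercept else 0)

    @property
    def column_names(self) -> tuple[str, ...]:
        names = tuple(r.name for r in self.regressors)
        return names + ("intercept",) if self.include_intercept else names

    def matrix(self) -> np.ndarray:
        cols = [r.samples for r in self.regressors]
        if self.include_intercept:
            cols.append(np.ones(self.n_samples))
        return np.column_stack(cols)


def canonical_hrf(dt: float, duration: float = HRF_DURATION) -> np.ndarray:
    """Sample the canonical double-gamma HRF on ``[0, duration]`` seconds.

    The response is the difference of two gamma densities — peak at ~5 s
    (shape 6, unit dispersion) minus an undershoot at ~15 s (shape 16,
    unit dispersion) weighted 1/6 — rescaled to unit peak so that event
    modulations carry the amplitude.

    Parameters
    ----------
    dt
        Sampling interval in seconds, ``0 < dt <= 2``.
    duration
        Window length in seconds (default 32).
    """
    if not 0 < dt <= 2:
        raise ValueError(f"dt must lie in (0, 2] seconds, got {dt}")
    t = np.arange(0.0, duration + dt / 2, dt)
    h = stats.gamma.pdf(t, a=6.0) - stats.gamma.pdf(t, a=16.0) / 6.0
    return h / h.max()


def build_regressor(
    events: EventSpec,
    total_duration: float,
    dt: float,
    hrf: np.ndarray | None = None,
    internal_dt: float = INTERNAL_DT,
) -> Regressor:
    """Convolve an event stimulus function with the HRF and sample it.

    Zero-duration events become unit impulses scaled by their modulation
    ("sticks"); positive durations become boxcars of that height. The
    stimulus function is built on the fine ``internal_dt`` grid (0.1 s by
    default) to avoid onset-quantization artifacts, convolved, truncated to
    ``total_duration``, and decimated to the output interval ``dt``.

    Parameters
    ----------
    events
        Event specification; onsets are snapped to the nearest internal
        sample.
    total_duration
        Length of the output series in seconds.
    dt
        Output sampling interval; must be an integer multiple of
        ``internal_dt`` (or equal to it).
    hrf
        Optional pre-sampled HRF on the ``internal_dt`` grid; defaults to
        :func:`canonical_hrf`.
    """
    if total_duration <= 0:
        raise ValueError("total_duration must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt < internal_dt:
        internal_dt = dt
    factor = int(round(dt / internal_dt))
    if abs(factor * internal_dt - dt) > 1e-9:
        raise ValueError(
            f"dt={dt} must be an integer multiple of internal_dt={internal_dt}"
        )

    n_hi = int(round(total_duration / internal_dt))
    stim = np.zeros(n_hi)
    for onset, dur, mod in zip(events.onsets, events.durations, events.modulations):
        if onset > total_duration or onset + dur > total_duration:
            raise ValueError(
                f"event at {onset:g}s (duration {dur:g}s) extends beyond the "
                f"{total_duration:g}s series"
            )
        i0 = int(round(onset / internal_dt))
        if dur == 0:
            stim[min(i0, n_hi - 1)] += mod
        else:
            i1 = max(i0 + 1, int(round((onset + dur) / internal_dt)))
            stim[i0:i1] += mod

    if hrf is None:
        hrf = canonical_hrf(internal_dt)
    samples_hi = np.convolve(stim, np.asarray(hrf, dtype=float))[:n_hi]
    n_out = int(round(total_duration / dt))
    samples = samples_hi[::factor][:n_out]
    return Regressor(name=events.label, samples=samples, dt=float(dt))


def center_modulations(events: EventSpec) -> EventSpec:
    """Mean-center the per-event modulation vector (parametric-modulator
    convention).

    With centered modulations, the Pearson correlation between two
    convolved regressors built on the same well-separated onsets equals
    the Pearson correlation of the modulation vectors themselves; without
    centering, the shared onset-locked response inflates or deflates it
    toward the uncentered cosine. Constant modulation vectors (a plain
    onset regressor) are returned unchanged — centering them would zero
    the regressor.
    """
    if np.std(events.modulations) < 1e-15:
        return events
    return EventSpec(
        events.onsets,
        events.durations,
        events.modulations - events.modulations.mean(),
        label=events.label,
    )


def _pop_sd(x: np.ndarray) -> float:
    return float(np.std(x))


def zscore(reg: Regressor) -> Regressor:
    """Standardize to mean 0, population sd 1. Idempotent."""
    sd = _pop_sd(reg.samples)
    if sd < 1e-15:
        raise DegenerateInputError(
            f"regressor {reg.name!r} is constant and cannot be z-scored"
        )
    samples = (reg.samples - reg.samples.mean()) / sd
    return replace(reg, samples=samples, standardized=True)


def orthogonalize(target: Regressor, bases: Sequence[Regressor]) -> Regressor:
    """Residualize ``target`` against ``bases`` (and the mean).

    Returns the least-squares residual of the mean-centered target after
    projection onto the span of the mean-centered bases; the result has a
    zero dot product (hence zero Pearson correlation) with every base. The
    output keeps the target's name, records the base names in
    ``orthogonalized_against``, and is *not* re-standardized.

    Raises
    ------
    DegenerateInputError
        If the target lies in the span of the bases (residual sd < 1e-12).
    """
    bases = list(bases)
    if not bases:
        return target
    for b in bases:
        if not target.same_grid(b):
            raise ValueError(f"base {b.name!r} is not on the target's grid")
    tc = target.samples - target.samples.mean()
    B = np.column_stack([b.samples - b.samples.mean() for b in bases])
    coef, *_ = np.linalg.lstsq(B, tc, rcond=None)
    resid = tc - B @ coef
    if _pop_sd(resid) < 1e-12:
        raise DegenerateInputError(
            f"regressor {target.name!r} lies in the span of "
            f"{[b.name for b in bases]}; orthogonalization is degenerate"
        )
    return replace(
        target,
        samples=resid,
        standardized=False,
        orthogonalized_against=tuple(b.name for b in bases),
    )


def build_designs(regA: Regressor, regB: Regressor) -> dict[str, DesignMatrix]:
    """Assemble the four model-comparison designs for two candidates.

    Returns
    -------
    dict
        ``full_1``: ``[A, B orthogonalized against A, intercept]``;
        ``full_2``: ``[B, A orthogonalized against B, intercept]``;
        ``reduced_A``: ``[A, intercept]``; ``reduced_B``: ``[B, intercept]``.
        The two full designs span the same fitted-value space; they differ
        only in which regressor's beta measures uniquely explained
        variance.
    """
    if not (regA.standardized and regB.standardized):
        raise ValueError("both regressors must be z-standardized first")
    if not regA.same_grid(regB):
        raise ValueError("regressors are on different sampling grids")
    b_perp = orthogonalize(regB, [regA])
    a_perp = orthogonalize(regA, [regB])
    return {
        "full_1": DesignMatrix(
            [regA, b_perp],
            ortho_order=f"{regB.name} orthogonalized against {regA.name}",
        ),
        "full_2": DesignMatrix(
            [regB, a_perp],
            ortho_order=f"{regA.name} orthogonalized against {regB.name}",
        ),
        "reduced_A": DesignMatrix([regA]),
        "reduced_B": DesignMatrix([regB]),
    }
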