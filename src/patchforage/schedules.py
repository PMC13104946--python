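"""Reward-availability schedules for the three-patch foraging task.

Each patch delivers reward on a variable-interval (VI) schedule: after every
button press a fresh reward-availability interval (RAI) ``lambda_i`` is drawn,
and a press is rewarded iff the time elapsed since the previous press at that
patch is at least ``lambda_i``.  Two interval laws are supported:

* ``exponential`` — rate ``mu_j = 1/mean_interval``; constant hazard, so
  elapsed time carries no information about impending reward and a premature
  reset is statistically free (memorylessness).
* ``gamma`` — shape ``a = 10`` and rate ``b_j = a/mean_interval``; the hazard
  increases with elapsed time, so premature presses discard accumulated
  progress and are costly.

The visual cue variable ``X(t) in [0, 1]`` differs between variants: under the
exponential schedule it is the cumulative probability that reward has become
available since the last press, ``1 - exp(-mu_j * (t - t_i))``; under the
gamma schedule it is the normalized progression through the active interval,
``min((t - t_i)/lambda_i, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "Variant",
    "PatchId",
    "PATCH_MEAN_INTERVALS",
    "GAMMA_SHAPE",
    "ScheduleSpec",
    "PatchProcess",
    "PressOutcome",
    "sample_interval",
    "hazard",
    "cue_value",
    "press",
    "time_to_availability_after_reset",
    "mean_interval_check",
]


class Variant(str, Enum):
    """Interval law of the task variant."""

    EXPONENTIAL = "exponential"
    GAMMA = "gamma"


class PatchId(str, Enum):
    """Patch identity by quality (mean RAI 7 / 14 / 21 s)."""

    FAST = "fast"
    MED = "med"
    SLOW = "slow"


#: Mean reward-availability interval per patch, seconds.
PATCH_MEAN_INTERVALS: dict[PatchId, float] = {
    PatchId.FAST: 7.0,
    PatchId.MED: 14.0,
    PatchId.SLOW: 21.0,
}

#: Fixed gamma shape parameter ``a``.
GAMMA_SHAPE: float = 10.0


@dataclass(frozen=True)
class ScheduleSpec:
    """Interval law of one patch.

    Parameters
    ----------
    variant
        ``Variant.EXPONENTIAL`` or ``Variant.GAMMA``.
    mean_interval
        Mean reward-availability interval, seconds; must be positive.
    shape
        Gamma shape ``a`` (ignored for the exponential variant).
    """

    variant: Variant
    mean_interval: float
    shape: float = GAMMA_SHAPE

    def __post_init__(self) -> None:
        if not self.mean_interval > 0:
            raise ValueError(
                f"mean_interval must be positive, got {self.mean_interval!r}"
            )
        if self.variant is Variant.GAMMA and not self.shape > 0:
            raise ValueError(f"gamma shape must be positive, got {self.shape!r}")

    @property
    def rate(self) -> float:
        """Exponential rate ``mu_j = 1/mean_interval`` (1/s)."""
        return 1.0 / self.mean_interval

    @property
    def gamma_rate(self) -> float:
        """Gamma rate ``b_j = a/mean_interval`` (1/s), so ``a/b_j`` is the mean."""
        return self.shape / self.mean_interval

    def distribution(self):
        """The interval law as a frozen ``scipy.stats`` distribution."""
        if self.variant is Variant.EXPONENTIAL:
            return stats.expon(scale=self.mean_interval)
        return stats.gamma(a=self.shape, scale=1.0 / self.gamma_rate)


@dataclass
class PatchProcess:
    """Evolving VI state of one patch.

    ``t_last_press`` is the time of the most recent press (``t_i``) and
    ``current_interval`` the active sampled RAI (``lambda_i``).  Reward is
    available iff ``now - t_last_press >= current_interval``.
    """

    patch_id: PatchId
    spec: ScheduleSpec
    t_last_press: float
    current_interval: float

    @classmethod
    def start(
        cls, patch_id: PatchId, spec: ScheduleSpec, t0: float, rng: np.random.Generator
    ) -> "PatchProcess":
        """Initialize at ``t0`` with a freshly sampled interval."""
        return cls(patch_id, spec, t0, sample_interval(spec, rng))

    def available(self, now: float) -> bool:
        return (now - self.t_last_press) >= self.current_interval


@dataclass(frozen=True)
class PressOutcome:
    """One press event: rewarded iff the active interval had elapsed."""

    time: float
    patch_id: PatchId
    rewarded: bool


def sample_interval(spec: ScheduleSpec, rng: np.random.Generator) -> float:
    """Draw one reward-availability interval from ``spec``'s law."""
    if spec.variant is Variant.EXPONENTIAL:
        return float(rng.exponential(spec.mean_interval))
    return float(rng.gamma(spec.shape, 1.0 / spec.gamma_rate))


def hazard(spec: ScheduleSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Hazard rate of reward becoming available at elapsed time ``t``.

    Constant ``mu_j`` for exponential intervals; ``f(t)/(1 - F(t))`` of the
    gamma law otherwise, which increases with ``t`` for shape > 1.  Computed
    in log space so the ratio stays finite far into the upper tail.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("hazard requires t >= 0")
    if spec.variant is Variant.EXPONENTIAL:
        out = np.full_like(t_arr, spec.rate)
    else:
        dist = spec.distribution()
        with np.errstate(divide="ignore"):
            out = np.exp(dist.logpdf(t_arr) - dist.logsf(t_arr))
    return float(out) if np.isscalar(t) else out


def cue_value(process: PatchProcess, now: float) -> float:
    """Cue variable ``X(t) in [0, 1]`` for the patch at time ``now``.

    Exponential variant: cumulative probability of availability,
    ``1 - exp(-mu_j * elapsed)``.  Gamma variant: normalized progression
    ``min(elapsed / lambda_i, 1)`` through the active interval.
    """
    elapsed = now - process.t_last_press
    if elapsed < 0:
        raise ValueError(f"now={now} precedes last press at {process.t_last_press}")
    if process.spec.variant is Variant.EXPONENTIAL:
        return float(-np.expm1(-process.spec.rate * elapsed))
    return float(min(elapsed / process.current_interval, 1.0))


def press(
    process: PatchProcess, now: float, rng: np.random.Generator
) -> tuple[PressOutcome, PatchProcess]:
    """Press the patch's button at time ``now``.

    Rewarded iff the active interval has elapsed.  In all cases a new
    interval is sampled and the press clock resets, so availability restarts
    from zero (for exponential intervals this reset is statistically
    equivalent to keeping the original interval).
    """
    if now < process.t_last_press:
        raise ValueError(
            f"press at {now} precedes previous press at {process.t_last_press}"
        )
    rewarded = process.available(now)
    updated = replace(
        process,
        t_last_press=now,
        current_interval=sample_interval(process.spec, rng),
    )
    return PressOutcome(now, process.patch_id, rewarded), updated


def time_to_availability_after_reset(
    spec: ScheduleSpec,
    reset_times: np.ndarray,
    rng: np.random.Generator,
    n_draws: int = 1,
) -> np.ndarray:
    """Waiting time from process start until reward availability, under a
    schedule of premature resets (exponential variant only).

    At each reset time the active interval is discarded and resampled, as an
    unrewarded press would do.  By memorylessness the resulting waiting-time
    distribution is identical to the reset-free exponential law — the property
    this function exists to demonstrate.

    Parameters
    ----------
    reset_times
        Strictly increasing times (seconds from start) at which resets occur;
        may be empty.
    n_draws
        Number of independent waiting times to return.
    """
    if spec.variant is not Variant.EXPONENTIAL:
        raise ValueError("reset-invariance is an exponential-schedule property")
    resets = np.asarray(reset_times, dtype=float)
    if resets.ndim != 1 or (resets.size > 1 and np.any(np.diff(resets) <= 0)):
        raise ValueError("reset_times must be a strictly increasing 1-D array")
    out = np.empty(n_draws)
    for k in range(n_draws):
        seg_start = 0.0
        lam = sample_interval(spec, rng)
        for r in resets:
            if seg_start + lam <= r:
                break
            seg_start = r
            lam = sample_interval(spec, rng)
        out[k] = seg_start + lam
    return out


def mean_interval_check(
    spec: ScheduleSpec, n: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo estimate ``(mean, standard error)`` of the interval mean.

    Requires ``n >= 1000`` so the normal-approximation SE is meaningful.
    """
    if n < 1000:
        raise ValueError("mean_interval_check requires n >= 1000")
    if spec.variant is Variant.EXPONENTIAL:
        draws = rng.exponential(spec.mean_interval, size=n)
    else:
        draws = rng.gamma(spec.shape, 1.0 / spec.gamma_rate, size=n)
    return float(draws.mean()), float(draws.std(ddof=1) / np.sqrt(n))
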