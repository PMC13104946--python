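"""Synthetic forager agents.

Stand-ins for the animal: each agent interacts with the three VI patches
through the same information set a subject has — noisy cue values and binary
reward outcomes, never the latent interval or availability state — and emits
a press-event log with the statistical structure the analysis pipeline
expects (quality-graded allocation, bimodal inter-push intervals,
reliability-dependent precision).

Three policies:

* ``random`` — Poisson pressing at ``base_push_rate`` with uniform patch
  choice; by construction it matches the rate-matched null model, so its
  normalized stay/return times calibrate the analysis at 1.
* ``cue_threshold`` — presses a patch when its belief that the press will be
  rewarded exceeds ``cue_threshold``.  The belief is formed from the noisy
  cue according to the variant's cue semantics: under the exponential
  schedule the cue *is* the reward probability, so the belief is the clipped
  observation; under the gamma schedule reward requires full progression, so
  the belief is ``Phi((A_hat - 1)/sigma)``.  Observation noise is zero-mean
  Gaussian with sd ``cue_noise_sd / sqrt(kappa)``, mirroring how the stimulus
  concentration controls decodability without rendering frames in the loop.
* ``rate_matching`` — exponentially weighted per-patch reward estimates with
  softmax patch choice and Poisson press timing; reproduces matching-law
  style allocation without using the cue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedules import (
    PATCH_MEAN_INTERVALS,
    PatchId,
    PatchProcess,
    ScheduleSpec,
    Variant,
    cue_value,
    press,
)

__all__ = [
    "AgentSpec",
    "SessionConfig",
    "SessionLog",
    "run_session",
    "random_agent_policy",
    "rate_matching_policy",
    "cue_threshold_policy",
    "perceived_reward_probability",
]

PATCH_ORDER = (PatchId.FAST, PatchId.MED, PatchId.SLOW)

EVENT_COLUMNS = ["t_s", "patch", "rewarded"]


@dataclass(frozen=True)
class AgentSpec:
    """Parameters of a synthetic forager.

    ``cue_noise_sd`` is the observation-noise scale at kappa = 1; the
    effective sd is ``cue_noise_sd / sqrt(kappa)``.  ``travel_time`` is the
    locomotion cost (s) incurred when pressing a different patch than the
    previous one.
    """

    kind: str  # "random" | "cue_threshold" | "rate_matching"
    base_push_rate: float = 0.5  # presses per second (Poisson policies)
    cue_threshold: float = 0.5
    cue_noise_sd: float = 0.4
    switch_cost: float = 0.3  # belief discount applied to non-current patches
    learning_rate: float = 0.1
    softmax_temperature: float = 0.2
    travel_time: float = 3.0
    tick: float = 0.25  # cue-sampling resolution of the threshold policy, s

    def __post_init__(self) -> None:
        if self.kind not in ("random", "cue_threshold", "rate_matching"):
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if self.base_push_rate <= 0 or self.travel_time < 0 or self.tick <= 0:
            raise ValueError("rates and times must be positive")
        if not 0.0 <= self.cue_threshold <= 1.0:
            raise ValueError("cue_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class SessionConfig:
    """One ~15-minute block of the task."""

    variant: Variant
    kappa: float
    seed: int
    duration: float = 900.0
    block_id: str = "block0"
    mean_intervals: dict[PatchId, float] = field(
        default_factory=lambda: dict(PATCH_MEAN_INTERVALS)
    )

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be nonnegative")
        if set(self.mean_intervals) != set(PATCH_ORDER):
            raise ValueError("exactly three patches (fast/med/slow) required")

    def specs(self) -> dict[PatchId, ScheduleSpec]:
        return {
            p: ScheduleSpec(self.variant, self.mean_intervals[p]) for p in PATCH_ORDER
        }


@dataclass
class SessionLog:
    """Ordered press events of one block plus its configuration."""

    config: SessionConfig
    events: pd.DataFrame  # columns t_s (float), patch (str), rewarded (bool)

    def __post_init__(self) -> None:
        ev = self.events
        missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise ValueError(f"event log missing columns: {missing}")
        t = ev["t_s"].to_numpy(float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")
        bad = set(ev["patch"]) - {p.value for p in PatchId}
        if bad:
            raise ValueError(f"unknown patch labels: {sorted(bad)}")


def _phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def perceived_reward_probability(
    variant: Variant, cue_obs: float, sigma: float
) -> float:
    """Agent's belief that a press now would be rewarded, from a noisy cue.

    Exponential variant: the cue encodes the availability probability
    directly, so the belief is the observation clipped to [0, 1].  Gamma
    variant: reward requires progression >= 1, so the belief is the posterior
    ``Phi((A_hat - 1)/sigma)`` (a step at 1 when sigma = 0).
    """
    if variant is Variant.EXPONENTIAL:
        return min(max(cue_obs, 0.0), 1.0)
    if sigma <= 0:
        return 1.0 if cue_obs >= 1.0 else 0.0
    return _phi((cue_obs - 1.0) / sigma)


def cue_threshold_policy(
    beliefs: dict[PatchId, float],
    current: PatchId | None,
    agent: AgentSpec,
) -> PatchId | None:
    """Target patch whose travel-discounted belief exceeds the threshold.

    The belief of every patch other than the current one is discounted by
    ``switch_cost`` (the locomotion penalty), so switching requires a belief
    advantage; the discounted maximum above ``cue_threshold`` wins.  Ties
    favor the current patch, then fast > med > slow order.  Returns None when
    no patch qualifies (keep waiting).
    """
    value = {
        p: beliefs[p] - (agent.switch_cost if current is not None and p is not current else 0.0)
        for p in PATCH_ORDER
    }
    above = [p for p in PATCH_ORDER if value[p] >= agent.cue_threshold]
    if not above:
        return None
    best = max(value[p] for p in above)
    if current in above and value[current] >= best:
        return current
    return next(p for p in PATCH_ORDER if p in above and value[p] >= best)


def random_agent_policy(
    agent: AgentSpec, rng: np.random.Generator
) -> tuple[float, PatchId]:
    """Exponential waiting time at ``base_push_rate``, uniform patch choice."""
    wait = float(rng.exponential(1.0 / agent.base_push_rate))
    patch = PATCH_ORDER[rng.integers(3)]
    return wait, patch


def rate_matching_policy(
    values: dict[PatchId, float], agent: AgentSpec, rng: np.random.Generator
) -> tuple[float, PatchId]:
    """Poisson press timing; patch by softmax over reward-rate estimates."""
    wait = float(rng.exponential(1.0 / agent.base_push_rate))
    v = np.array([values[p] for p in PATCH_ORDER])
    z = v / agent.softmax_temperature
    z -= z.max()
    prob = np.exp(z)
    prob /= prob.sum()
    patch = PATCH_ORDER[rng.choice(3, p=prob)]
    return wait, patch


def run_session(config: SessionConfig, agent: AgentSpec) -> SessionLog:
    """Simulate one block; same config + agent always yields the same log."""
    rng = np.random.default_rng(config.seed)
    procs = {
        p: PatchProcess.start(p, spec, 0.0, rng)
        for p, spec in config.specs().items()
    }
    rows: list[tuple[float, str, bool]] = []

    def do_press(patch: PatchId, t: float) -> None:
        outcome, procs[patch] = press(procs[patch], t, rng)
        rows.append((t, patch.value, outcome.rewarded))

    if agent.kind in ("random", "rate_matching"):
        values = {p: 0.5 for p in PATCH_ORDER}
        t = 0.0
        while True:
            if agent.kind == "random":
                wait, patch = random_agent_policy(agent, rng)
            else:
                wait, patch = rate_matching_policy(values, agent, rng)
            t += wait
            if t >= config.duration:
                break
            do_press(patch, t)
            if agent.kind == "rate_matching":
                lr = agent.learning_rate
                values[patch] = (1 - lr) * values[patch] + lr * float(rows[-1][2])
    else:  # cue_threshold
        if config.kappa <= 0:
            raise ValueError("cue_threshold agent requires kappa > 0")
        sigma = agent.cue_noise_sd / math.sqrt(config.kappa)
        current: PatchId | None = None
        t = 0.0
        while t < config.duration:
            noise = rng.standard_normal(3)
            beliefs = {
                p: perceived_reward_probability(
                    config.variant, cue_value(procs[p], t) + sigma * noise[i], sigma
                )
                for i, p in enumerate(PATCH_ORDER)
            }
            target = cue_threshold_policy(beliefs, current, agent)
            if target is None:
                t += agent.tick
                continue
            t_press = t if (current is None or target is current) else t + agent.travel_time
            if t_press >= config.duration:
                break
            do_press(target, t_press)
            current = target
            t = t_press + agent.tick

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events["rewarded"] = events["rewarded"].astype(bool)
    return SessionLog(config, events)
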