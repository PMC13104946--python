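"""Behavioral analysis pipeline for press-event logs.

Implements the allocation, timing, and dynamics statistics used to
characterize three-patch VI foraging: push fractions and their Spearman
correlation with patch quality rank, per-patch inter-push-interval (IPI)
distributions, patch-transition matrices, visit segmentation with stay and
return times normalized by a rate-matched null model, the continuous
(piecewise-constant) push-rate series, and time-resolved windowed allocation
within a session.

All functions accept either a :class:`~patchforage.agents.SessionLog` or a
bare DataFrame with columns ``t_s``, ``patch``, ``rewarded``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .agents import PATCH_ORDER, SessionLog
from .schedules import PatchId

__all__ = [
    "QUALITY_RANK",
    "Visit",
    "TransitionMatrix",
    "BlockMetrics",
    "push_fraction",
    "quality_rank_spearman",
    "perblock_spearman",
    "ipi_distribution",
    "ipi_bimodality_separation",
    "transition_matrix",
    "segment_visits",
    "stay_times",
    "return_times",
    "null_model",
    "pooled_normalized_stay_return",
    "normalize_metric",
    "block_metrics",
    "continuous_push_rate",
    "windowed_push_fraction",
    "timeresolved_spearman",
]

#: Quality rank used in rank correlations: slow=1, med=2, fast=3.
QUALITY_RANK: dict[PatchId, int] = {PatchId.SLOW: 1, PatchId.MED: 2, PatchId.FAST: 3}

_PATCH_VALUES = [p.value for p in PATCH_ORDER]


def _events(log) -> pd.DataFrame:
    if isinstance(log, SessionLog):
        return log.events
    return log


def push_fraction(log) -> dict[PatchId, float]:
    """Fraction of presses at each patch; fractions sum to 1."""
    ev = _events(log)
    if len(ev) == 0:
        raise ValueError("push fraction undefined for an empty log")
    counts = ev["patch"].value_counts()
    total = len(ev)
    return {p: float(counts.get(p.value, 0)) / total for p in PATCH_ORDER}


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int


def quality_rank_spearman(fraction_sets: list[dict[PatchId, float]]) -> SpearmanResult:
    """Pooled Spearman correlation of push fraction vs quality rank.

    Each block contributes three (fraction, rank) observations, pooled into a
    single correlation over ``n = 3 * n_blocks`` points with a two-sided
    asymptotic p-value.  Returns ``rho = nan`` (flagged) when all fractions
    are identical.
    """
    if len(fraction_sets) < 2:
        raise ValueError("pooled correlation needs at least 2 blocks")
    fr = np.array([[fs[p] for p in PATCH_ORDER] for fs in fraction_sets]).ravel()
    rk = np.array([[QUALITY_RANK[p] for p in PATCH_ORDER]] * len(fraction_sets)).ravel()
    if np.allclose(fr, fr[0]):
        return SpearmanResult(float("nan"), float("nan"), fr.size)
    res = stats.spearmanr(fr, rk)
    return SpearmanResult(float(res.statistic), float(res.pvalue), fr.size)


def perblock_spearman(fractions: dict[PatchId, float]) -> tuple[float, float]:
    """Spearman rho and exact permutation p for a single block (3 points).

    With only three observations the asymptotic p is invalid; the exact
    two-sided permutation p over the 6 rank orderings is returned instead
    (its smallest attainable value is 1/3).
    """
    fr = np.array([fractions[p] for p in PATCH_ORDER])
    rk = np.array([QUALITY_RANK[p] for p in PATCH_ORDER])
    if np.allclose(fr, fr[0]):
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(fr, rk).statistic)
    from itertools import permutations

    perm_rhos = [
        stats.spearmanr(fr, np.array(perm)).statistic for perm in permutations(rk)
    ]
    p = float(np.mean([abs(r) >= abs(rho) - 1e-12 for r in perm_rhos]))
    return rho, p


@dataclass(frozen=True)
class IPISummary:
    """Per-patch inter-push intervals (s) and their median."""

    intervals: np.ndarray
    median: float


def ipi_distribution(log, patch: PatchId | None = None, per_patch: bool = True):
    """Inter-push intervals, per patch or globally.

    Per-patch IPIs are successive differences between presses at that patch;
    intervening presses elsewhere do not break the pairing.  With ``patch``
    given, returns one :class:`IPISummary`; otherwise a dict over patches
    (or, with ``per_patch=False``, a single global summary).
    """
    ev = _events(log)
    t = ev["t_s"].to_numpy(float)
    if patch is None and not per_patch:
        iv = np.diff(t)
        return IPISummary(iv, float(np.median(iv)) if iv.size else float("nan"))
    if patch is not None:
        tp = t[ev["patch"].to_numpy() == patch.value]
        iv = np.diff(tp)
        return IPISummary(iv, float(np.median(iv)) if iv.size else float("nan"))
    return {p: ipi_distribution(log, p) for p in PATCH_ORDER}


def ipi_bimodality_separation(intervals: np.ndarray) -> float:
    """Two-component separation score of log-IPIs.

    Fits a 2-component Gaussian mixture to log intervals and returns the
    component-mean separation in units of the pooled within-component sd
    (> 2 indicates clear bimodality).
    """
    from sklearn.mixture import GaussianMixture

    x = np.log(np.asarray(intervals, float)[np.asarray(intervals) > 0]).reshape(-1, 1)
    if len(x) < 10:
        raise ValueError("need at least 10 positive intervals")
    gm = GaussianMixture(n_components=2, random_state=0).fit(x)
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    return float(abs(mu[0] - mu[1]) / np.sqrt(0.5 * (sd[0] ** 2 + sd[1] ** 2)))


@dataclass(frozen=True)
class TransitionMatrix:
    """Patch-to-patch transition counts and row-normalized probabilities.

    Rows index the current patch, columns the next, in fast/med/slow order.
    ``p_to_fast_given_not_fast`` is the probability of switching to the fast
    patch conditional on the current press being at medium or slow.
    """

    counts: np.ndarray
    probs: np.ndarray
    p_to_fast_given_not_fast: float

    def prob(self, frm: PatchId, to: PatchId) -> float:
        return float(self.probs[PATCH_ORDER.index(frm), PATCH_ORDER.index(to)])

    @property
    def self_transitions(self) -> dict[PatchId, float]:
        return {p: float(self.probs[i, i]) for i, p in enumerate(PATCH_ORDER)}


def transition_matrix(log) -> TransitionMatrix:
    """Transitions counted over consecutive press pairs."""
    ev = _events(log)
    if len(ev) < 2:
        raise ValueError("transition matrix needs at least 2 presses")
    idx = pd.Categorical(ev["patch"], categories=_PATCH_VALUES).codes
    counts = np.zeros((3, 3))
    np.add.at(counts, (idx[:-1], idx[1:]), 1)
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(rowsum > 0, counts / rowsum, np.nan)
    out_of_notfast = counts[1:, :].sum()
    p_cond = counts[1:, 0].sum() / out_of_notfast if out_of_notfast > 0 else float("nan")
    return TransitionMatrix(counts, probs, float(p_cond))


@dataclass(frozen=True)
class Visit:
    """Maximal run of consecutive presses at one patch."""

    patch: PatchId
    t_first: float
    t_last: float
    n_pushes: int


def segment_visits(log) -> list[Visit]:
    """Split the log into maximal same-patch runs (first/last runs included)."""
    ev = _events(log)
    if len(ev) == 0:
        raise ValueError("cannot segment an empty log")
    t = ev["t_s"].to_numpy(float)
    labels = ev["patch"].to_numpy()
    breaks = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(labels)]])
    return [
        Visit(PatchId(labels[s]), float(t[s]), float(t[e - 1]), int(e - s))
        for s, e in zip(starts, ends)
    ]


def stay_times(visits: list[Visit]) -> dict[PatchId, np.ndarray]:
    """Stay time per visit (t_last - t_first), pooled by patch.

    Single-push visits contribute a stay of 0 s (retained by default).
    """
    out = {p: [] for p in PATCH_ORDER}
    for v in visits:
        out[v.patch].append(v.t_last - v.t_first)
    return {p: np.asarray(d, float) for p, d in out.items()}


def return_times(visits: list[Visit]) -> dict[PatchId, np.ndarray]:
    """Gap between leaving a patch and the first press upon returning."""
    out = {p: [] for p in PATCH_ORDER}
    last_leave: dict[PatchId, float] = {}
    for v in visits:
        if v.patch in last_leave:
            out[v.patch].append(v.t_first - last_leave[v.patch])
        last_leave[v.patch] = v.t_last
    return {p: np.asarray(d, float) for p, d in out.items()}


def _runs_mean_stay_return(
    t: np.ndarray, labels: np.ndarray, stay_sum, stay_n, ret_sum, ret_n
) -> None:
    """Accumulate per-patch stay/return sums for one (surrogate) sequence."""
    breaks = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(labels)]])
    lab = labels[starts]
    stay = t[ends - 1] - t[starts]
    for k in range(3):
        sel = lab == k
        stay_sum[k] += stay[sel].sum()
        stay_n[k] += int(sel.sum())
        pos = np.flatnonzero(sel)
        if pos.size > 1:
            gaps = t[starts[pos[1:]]] - t[ends[pos[:-1]] - 1]
            ret_sum[k] += gaps.sum()
            ret_n[k] += gaps.size


@dataclass(frozen=True)
class NullStats:
    """Null-model mean stay/return per patch (nan where never revisited).

    ``stay_n``/``return_n`` are total visit/return counts pooled over all
    surrogate repetitions, for visit-weighted pooling across blocks.
    """

    mean_stay: dict[PatchId, float]
    mean_return: dict[PatchId, float]
    stay_n: dict[PatchId, int]
    return_n: dict[PatchId, int]
    n_reps: int


def null_model(log, n_reps: int, rng: np.random.Generator) -> NullStats:
    """Rate-matched surrogate stay/return times.

    Surrogates keep the real event count and draw inter-push intervals from
    an exponential law at the empirical mean push rate ``(n-1)/(t_n - t_1)``,
    with uniformly random patch labels, destroying structured switching while
    preserving overall tempo.  Stay/return are computed exactly as for real
    data and pooled across repetitions.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ev = _events(log)
    n = len(ev)
    if n < 2:
        raise ValueError("null model needs at least 2 presses")
    t = ev["t_s"].to_numpy(float)
    rate = (n - 1) / (t[-1] - t[0])
    stay_sum = np.zeros(3)
    stay_n = np.zeros(3, int)
    ret_sum = np.zeros(3)
    ret_n = np.zeros(3, int)
    for _ in range(n_reps):
        tt = np.cumsum(rng.exponential(1.0 / rate, size=n))
        labels = rng.integers(0, 3, size=n)
        _runs_mean_stay_return(tt, labels, stay_sum, stay_n, ret_sum, ret_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        ms = stay_sum / stay_n
        mr = np.where(ret_n > 0, ret_sum / np.maximum(ret_n, 1), np.nan)
    return NullStats(
        {p: float(ms[i]) for i, p in enumerate(PATCH_ORDER)},
        {p: float(mr[i]) for i, p in enumerate(PATCH_ORDER)},
        {p: int(stay_n[i]) for i, p in enumerate(PATCH_ORDER)},
        {p: int(ret_n[i]) for i, p in enumerate(PATCH_ORDER)},
        n_reps,
    )


def pooled_normalized_stay_return(
    logs: list, n_reps: int, rng: np.random.Generator
) -> tuple[dict[PatchId, float], dict[PatchId, float]]:
    """Condition-level normalized stay/return, pooling visits across blocks.

    Real stay/return values are pooled across all blocks' visits per patch
    (the within-condition pooling of the stay/return procedure); the null
    mean is pooled over every block's surrogate visits weighted by count.
    Returns ``(normalized_stay, normalized_return)`` dicts.
    """
    real_stay = {p: 0.0 for p in PATCH_ORDER}
    real_stay_n = {p: 0 for p in PATCH_ORDER}
    real_ret = {p: 0.0 for p in PATCH_ORDER}
    real_ret_n = {p: 0 for p in PATCH_ORDER}
    null_stay = {p: 0.0 for p in PATCH_ORDER}
    null_stay_n = {p: 0 for p in PATCH_ORDER}
    null_ret = {p: 0.0 for p in PATCH_ORDER}
    null_ret_n = {p: 0 for p in PATCH_ORDER}
    for lg in logs:
        visits = segment_visits(lg)
        st = stay_times(visits)
        rt = return_times(visits)
        null = null_model(lg, n_reps, rng)
        for p in PATCH_ORDER:
            real_stay[p] += st[p].sum()
            real_stay_n[p] += st[p].size
            real_ret[p] += rt[p].sum()
            real_ret_n[p] += rt[p].size
            if null.stay_n[p]:
                null_stay[p] += null.mean_stay[p] * null.stay_n[p]
                null_stay_n[p] += null.stay_n[p]
            if null.return_n[p]:
                null_ret[p] += null.mean_return[p] * null.return_n[p]
                null_ret_n[p] += null.return_n[p]

    def _ratio(rsum, rn, nsum, nn):
        out = {}
        for p in PATCH_ORDER:
            if rn[p] and nn[p] and nsum[p] > 0:
                out[p] = (rsum[p] / rn[p]) / (nsum[p] / nn[p])
            else:
                out[p] = float("nan")
        return out

    return (
        _ratio(real_stay, real_stay_n, null_stay, null_stay_n),
        _ratio(real_ret, real_ret_n, null_ret, null_ret_n),
    )


def normalize_metric(
    real: dict[PatchId, float], null: dict[PatchId, float]
) -> dict[PatchId, float]:
    """Elementwise real/null ratio; nan (flagged) where the null mean is 0."""
    out = {}
    for p in PATCH_ORDER:
        if null[p] and null[p] > 0:
            out[p] = real[p] / null[p]
        else:
            warnings.warn(f"null mean for {p.value} is zero/undefined; ratio flagged")
            out[p] = float("nan")
    return out


@dataclass
class BlockMetrics:
    """All per-block analysis outputs."""

    push_fractions: dict[PatchId, float]
    ipi: dict[PatchId, IPISummary]
    transitions: TransitionMatrix
    mean_stay: dict[PatchId, float]
    mean_return: dict[PatchId, float]
    null: NullStats
    norm_stay: dict[PatchId, float]
    norm_return: dict[PatchId, float]
    spearman_rho: float
    spearman_p_exact: float
    block_id: str = ""


def block_metrics(log, n_null: int = 1000, rng: np.random.Generator | None = None) -> BlockMetrics:
    """Full per-block analysis (deterministic given the log and rng state)."""
    if rng is None:
        rng = np.random.default_rng(0)
    fr = push_fraction(log)
    visits = segment_visits(log)
    st = stay_times(visits)
    rt = return_times(visits)
    mean_stay = {
        p: float(np.mean(st[p])) if st[p].size else float("nan") for p in PATCH_ORDER
    }
    mean_return = {
        p: float(np.mean(rt[p])) if rt[p].size else float("nan") for p in PATCH_ORDER
    }
    null = null_model(log, n_null, rng)
    rho, p_exact = perblock_spearman(fr)
    cfg = log.config if isinstance(log, SessionLog) else None
    return BlockMetrics(
        push_fractions=fr,
        ipi=ipi_distribution(log),
        transitions=transition_matrix(log),
        mean_stay=mean_stay,
        mean_return=mean_return,
        null=null,
        norm_stay=normalize_metric(mean_stay, null.mean_stay),
        norm_return=normalize_metric(mean_return, null.mean_return),
        spearman_rho=rho,
        spearman_p_exact=p_exact,
        block_id=cfg.block_id if cfg is not None else "",
    )


def continuous_push_rate(
    log, window: float = 60.0, grid_step: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized, smoothed instantaneous push-rate time series.

    The rate on each inter-press interval is its inverse, held
    piecewise-constant between presses; the series is rescaled by the
    session's time-averaged rate and smoothed with a centered moving-average
    window.  Returns ``(times, normalized_rate)`` on a uniform grid.
    """
    ev = _events(log)
    t = ev["t_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("continuous push rate needs at least 2 presses")
    dt = np.diff(t)
    if np.any(dt <= 0):
        pos = dt[dt > 0]
        if pos.size == 0:
            raise ValueError("all press timestamps coincide")
        warnings.warn("duplicate timestamps: clipping infinite rates")
        dt = np.maximum(dt, pos.min())
    r = 1.0 / dt
    mean_rate = (len(t) - 1) / (t[-1] - t[0])
    grid = np.arange(t[0], t[-1], grid_step)
    seg = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, len(r) - 1)
    series = r[seg] / mean_rate
    k = max(1, int(round(window / grid_step)))
    kernel = np.ones(k)
    smoothed = np.convolve(series, kernel, mode="same") / np.convolve(
        np.ones_like(series), kernel, mode="same"
    )
    return grid, smoothed


def _window_centers(duration: float, window: float, step: float) -> np.ndarray:
    return np.arange(window / 2.0, duration - window / 2.0 + 1e-9, step)


def _block_windowed_fractions(
    ev: pd.DataFrame, centers: np.ndarray, window: float
) -> np.ndarray:
    """(n_centers, 3) windowed fractions; nan rows where the window is empty."""
    t = ev["t_s"].to_numpy(float)
    codes = pd.Categorical(ev["patch"], categories=_PATCH_VALUES).codes
    out = np.full((centers.size, 3), np.nan)
    for i, c in enumerate(centers):
        sel = (t >= c - window / 2.0) & (t < c + window / 2.0)
        tot = int(sel.sum())
        if tot:
            out[i] = np.bincount(codes[sel], minlength=3) / tot
    return out


@dataclass
class TimeCourse:
    """Across-block mean and SEM of a windowed quantity on a common grid.

    For fractions, ``mean``/``sem`` have shape (n_times, 3) in fast/med/slow
    order; for scalar series (time-resolved rho) they are 1-D.
    """

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray


def _nan_mean_sem(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        n = np.sum(~np.isnan(stack), axis=0)
        sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    return mean, sem


def windowed_push_fraction(
    logs: list, window: float = 60.0, step: float = 10.0
) -> TimeCourse:
    """Sliding-window push fraction per patch, averaged across blocks.

    Windows with no presses are masked (nan) and excluded from the
    across-block mean/SEM.
    """
    if not logs:
        raise ValueError("need at least one block")
    duration = min(
        lg.config.duration if isinstance(lg, SessionLog) else _events(lg)["t_s"].max()
        for lg in logs
    )
    centers = _window_centers(duration, window, step)
    stack = np.stack(
        [_block_windowed_fractions(_events(lg), centers, window) for lg in logs]
    )
    mean, sem = _nan_mean_sem(stack)
    return TimeCourse(centers, mean, sem)


def timeresolved_spearman(
    logs: list, window: float = 60.0, step: float = 10.0
) -> TimeCourse:
    """Time-resolved Spearman rho between windowed fraction and quality rank.

    Per block and time point the correlation uses the three patch
    observations (rho in {-1, -0.5, 0, 0.5, 1} when untied); block
    values are then averaged with SEM.  Masked windows propagate as nan.
    """
    if len(logs) < 2:
        raise ValueError("time-resolved correlation needs at least 2 blocks")
    duration = min(
        lg.config.duration if isinstance(lg, SessionLog) else _events(lg)["t_s"].max()
        for lg in logs
    )
    centers = _window_centers(duration, window, step)
    ranks = np.array([QUALITY_RANK[p] for p in PATCH_ORDER], float)
    per_block = np.full((len(logs), centers.size), np.nan)
    for b, lg in enumerate(logs):
        fr = _block_windowed_fractions(_events(lg), centers, window)
        for i in range(centers.size):
            row = fr[i]
            if np.any(np.isnan(row)) or np.allclose(row, row[0]):
                continue
            per_block[b, i] = stats.spearmanr(row, ranks).statistic
    mean, sem = _nan_mean_sem(per_block)
    return TimeCourse(centers, mean, sem)
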