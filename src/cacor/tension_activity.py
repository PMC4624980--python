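"""Group analysis of continuous tension ratings.

A set of listeners continuously rates perceived tension with a
spring-loaded joystick (nonnegative deflection, 50 Hz).  The module
quantifies how strongly a stimulus coordinates those ratings:

* pairwise inter-rater correlations with a surrogate significance test;
* the stimulus lag of the mean rating relative to sound intensity
  (ratings trail the sound; the lag is found on a 0-3 s / 10 ms
  cross-correlation grid, falling back to 1.0 s when no clear peak
  exists, e.g. for non-musical sounds);
* activity analysis: per 1 s window (50 % overlap) the percentage of
  raters whose rating rises / falls, tested against a circular-shift
  permutation null, summarised as a Coordination Score (the fraction of
  windows with significantly coordinated movement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .audio_features import FeatureSeries
from .cacor_stats import phase_randomize
from .data_io import RatingSet

logger = logging.getLogger("cacor")

__all__ = [
    "ActivityResult",
    "pairwise_rating_correlation",
    "optimal_lag",
    "align_and_resample",
    "activity_index",
    "activity_significance",
]


@dataclass
class ActivityResult:
    """Windowed rise/fall percentages with permutation significance."""

    rise_pct: np.ndarray
    fall_pct: np.ndarray
    sig_mask: np.ndarray | None
    coordination_score: float   # fraction of significant windows
    n_significant: int
    window_len: float = 1.0
    overlap: float = 0.5
    rate: float = 2.0           # windows per second (1 / step)

    def __post_init__(self):
        self.rise_pct = np.asarray(self.rise_pct, dtype=float)
        self.fall_pct = np.asarray(self.fall_pct, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.rise_pct)) / self.rate


def _pair_r(x, y):
    xc = x - x.mean()
    yc = y - y.mean()
    d = np.linalg.norm(xc) * np.linalg.norm(yc)
    return float(xc @ yc / d) if d > 0 else np.nan


def pairwise_rating_correlation(
    rs: RatingSet,
    n_surr: int = 199,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
):
    """All pairwise Pearson correlations and the share of significant pairs.

    Significance of each pair is assessed against phase-randomised
    surrogates of one member (two-sided).  Constant rating rows produce
    NaN pairs that are excluded from the percentage.  Returns
    ``(correlation matrix, pct_significant)``.
    """
    if rs.n_raters < 2:
        raise ValueError("need at least 2 raters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = rs.ratings
    n = rs.n_raters
    corr = np.full((n, n), np.nan)
    np.fill_diagonal(corr, 1.0)
    sig, total = 0, 0
    stds = R.std(axis=1)
    for j in range(n):
        surr = phase_randomize(R[j], rng, n_surr) if stds[j] > 0 else None
        for i in range(j):
            r = _pair_r(R[i], R[j]) if stds[i] > 0 and stds[j] > 0 else np.nan
            corr[i, j] = corr[j, i] = r
            if not np.isfinite(r):
                continue
            total += 1
            xc = R[i] - R[i].mean()
            sc = surr - surr.mean(axis=1, keepdims=True)
            denom = np.linalg.norm(xc) * np.linalg.norm(sc, axis=1)
            r_surr = np.where(denom > 0, (sc @ xc) / np.where(denom > 0, denom, 1), 0.0)
            p = (1 + int(np.sum(np.abs(r_surr) >= abs(r)))) / (n_surr + 1)
            sig += int(p <= alpha)
    pct = 100.0 * sig / total if total else float("nan")
    return corr, pct


def _common_grid(x, x_rate, y, y_rate, grid_rate=100.0):
    tx = np.arange(len(x)) / x_rate
    ty = np.arange(len(y)) / y_rate
    t_end = min(tx[-1], ty[-1])
    t = np.arange(0.0, t_end, 1.0 / grid_rate)
    return np.interp(t, tx, x), np.interp(t, ty, y), grid_rate


def optimal_lag(
    mean_rating,
    intensity,
    rating_rate: float = 50.0,
    max_lag: float = 3.0,
    step: float = 0.01,
    fallback: float = 1.0,
    prominence: float = 0.01,
) -> float:
    """Lag (s) of the mean rating behind sound intensity.

    Both series are z-scored and cross-correlated for lags 0..``max_lag``
    in ``step`` increments; the argmax lag is returned.  When the best
    nonzero lag does not beat the zero-lag correlation by ``prominence``
    (no clear peak) or the intensity is constant, ``fallback`` is
    returned.
    """
    if isinstance(intensity, FeatureSeries):
        ival, irate = intensity.values, intensity.rate
    else:
        ival, irate = np.asarray(intensity, dtype=float), rating_rate
    mean_rating = np.asarray(mean_rating, dtype=float)
    if np.std(ival) == 0 or np.std(mean_rating) == 0:
        return float(fallback)
    grid_rate = 1.0 / step
    r, s, rate = _common_grid(mean_rating, rating_rate, ival, irate, grid_rate)
    if len(r) < int(10 * rate):
        raise ValueError("series overlap must be at least 10 s")
    r = (r - r.mean()) / r.std()
    s = (s - s.mean()) / s.std()
    lags = np.arange(0, int(round(max_lag * rate)) + 1)
    c = np.empty(len(lags))
    for k, lag in enumerate(lags):
        a = r[lag:]
        b = s[: len(s) - lag] if lag else s
        c[k] = _pair_r(a, b)
    best = int(np.nanargmax(c))
    if best > 0 and c[best] - c[0] < prominence:
        return float(fallback)
    return float(lags[best] / rate)


def align_and_resample(
    rs: RatingSet, lag: float, target_rate: float = 10 / 3
) -> RatingSet:
    """Advance ratings by ``lag`` seconds and resample to ``target_rate``.

    Trailing samples are dropped; resampling is linear interpolation.
    """
    if lag < 0:
        raise ValueError("lag must be nonnegative")
    k = int(round(lag * rs.rate))
    shifted = rs.ratings[:, k:] if k else rs.ratings
    if shifted.shape[1] < 2:
        raise ValueError("lag removes the entire recording")
    if np.isclose(target_rate, rs.rate) :
        out = shifted.copy()
    else:
        t_in = np.arange(shifted.shape[1]) / rs.rate
        n_out = int(np.floor(t_in[-1] * target_rate)) + 1
        t_out = np.arange(n_out) / target_rate
        out = np.stack([np.interp(t_out, t_in, row) for row in shifted])
    return RatingSet(
        ratings=out,
        rate=target_rate if not np.isclose(target_rate, rs.rate) else rs.rate,
        stimulus_id=rs.stimulus_id,
        rater_ids=list(rs.rater_ids),
    )


def _window_starts(n, wlen, step):
    if wlen > n:
        raise ValueError("window longer than the recording")
    return np.arange(0, n - wlen + 1, step)


def _net_change(R, starts, wlen):
    # raters x windows net change (last minus first sample of the window)
    return R[:, starts + wlen - 1] - R[:, starts]


def activity_index(
    rs: RatingSet, window_len: float = 1.0, overlap: float = 0.5
) -> ActivityResult:
    """Percentage of raters rising / falling per 50 %-overlapping window.

    A rater counts as rising (falling) in a window when the net change
    over the window is positive (negative); zero net change counts as
    neither, so rise + fall <= 100.
    """
    wlen = int(round(window_len * rs.rate))
    step = max(1, int(round(window_len * (1 - overlap) * rs.rate)))
    starts = _window_starts(rs.n_samples, wlen, step)
    net = _net_change(rs.ratings, starts, wlen)
    rise = 100.0 * (net > 0).sum(axis=0) / rs.n_raters
    fall = 100.0 * (net < 0).sum(axis=0) / rs.n_raters
    return ActivityResult(
        rise_pct=rise,
        fall_pct=fall,
        sig_mask=None,
        coordination_score=float("nan"),
        n_significant=0,
        window_len=window_len,
        overlap=overlap,
        rate=rs.rate / step,
    )


def activity_significance(
    rs: RatingSet,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    window_len: float = 1.0,
    overlap: float = 0.5,
) -> ActivityResult:
    """Permutation test of coordinated rating movement per window.

    The null preserves each rater's own dynamics but destroys alignment:
    every permutation circularly shifts each rater by an independent
    uniform offset.  A window is significant when the observed
    max(rise, fall) proportion strictly exceeds the ``1 - alpha``
    quantile of its own null distribution.  The Coordination Score is
    the fraction of significant windows (the raw count is kept
    alongside).
    """
    if rs.n_raters < 2:
        raise ValueError("coordination is undefined for a single rater")
    if n_perm < 199:
        raise ValueError("use at least 199 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = activity_index(rs, window_len, overlap)
    wlen = int(round(window_len * rs.rate))
    step = max(1, int(round(window_len * (1 - overlap) * rs.rate)))
    starts = _window_starts(rs.n_samples, wlen, step)
    obs = np.maximum(base.rise_pct, base.fall_pct)
    n = rs.n_samples
    R = rs.ratings
    nulls = np.empty((n_perm, len(starts)))
    for k in range(n_perm):
        offsets = rng.integers(1, n, size=rs.n_raters)
        idx_last = (starts[None, :] + wlen - 1 + offsets[:, None]) % n
        idx_first = (starts[None, :] + offsets[:, None]) % n
        net = np.take_along_axis(R, idx_last, axis=1) - np.take_along_axis(
            R, idx_first, axis=1
        )
        nulls[k] = (
            100.0
            * np.maximum((net > 0).sum(axis=0), (net < 0).sum(axis=0))
            / rs.n_raters
        )
    sig = obs > np.quantile(nulls, 1.0 - alpha, axis=0)
    return ActivityResult(
        rise_pct=base.rise_pct,
        fall_pct=base.fall_pct,
        sig_mask=sig,
        coordination_score=float(sig.mean()),
        n_significant=int(sig.sum()),
        window_len=window_len,
        overlap=overlap,
        rate=base.rate,
    )
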