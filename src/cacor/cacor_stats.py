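"""Correlation statistics for autocorrelated EEG/audio time series.

The cortico-acoustic correlation (CACor) is the Pearson correlation
between a reconstructed EEG projection and the audio power slope.  Both
series are strongly autocorrelated, so naive correlation tests are
anti-conservative; two complementary routes are provided:

* a surrogate test against Fourier phase-randomised versions of the
  power slope (amplitude spectrum preserved, phases scrambled), and
* Pyper & Peterman's effective-degrees-of-freedom correction
  ``1/N* = 1/N + (2/N) sum_j ((N-j)/N) rho_xx(j) rho_yy(j)``,
  with the corrected sample count ``N*`` feeding a t-test.

Presentation-level p-values are Bonferroni-corrected within a stimulus;
the CACor score of a stimulus counts its significant presentations.
Feature relationships use partial correlations (controls residualised
out) with the Pyper correction at a 10 s autocorrelation horizon and
Benjamini-Hochberg FDR across cells.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .eeg_regression import Projection

logger = logging.getLogger("cacor")

__all__ = [
    "CACorResult",
    "TimeResolvedCACor",
    "cacor",
    "surrogate_test",
    "phase_randomize",
    "pyper_effective_df",
    "correct_presentations",
    "cacor_score",
    "grand_average_cacor",
    "time_resolved_cacor",
    "partial_correlation",
    "fdr_correct",
    "profile_correlation",
]


@dataclass
class CACorResult:
    r: float
    p_perm: float
    p_pyper: float
    n_eff: float
    n: int
    significant: bool = False
    subject_id: str = ""
    stimulus_id: str = ""
    presentation_index: int = 0


@dataclass
class TimeResolvedCACor:
    """Windowed correlation: 3 s windows, 90 % overlap -> 3.33 Hz series."""

    values: np.ndarray
    rate: float
    window_len: float
    overlap: float
    stimulus_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self):
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Window start times: exactly k * step."""
        return np.arange(len(self.values)) / self.rate


def _as_pair(p, y):
    x = p.values if isinstance(p, Projection) else np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    if isinstance(p, Projection) and p.n_pad > 0:
        x, y = x[: n - p.n_pad], y[: n - p.n_pad]  # drop zero-padded tail
    return x, y


def _pearson(x, y):
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx <= 0.0 or sy <= 0.0:
        raise ValueError("zero-variance input to correlation")
    return float(xc @ yc / np.sqrt(sx * sy))


def cacor(p, y) -> float:
    """Pearson correlation between an EEG projection and the power slope.

    Samples relying on the embedding's zero padding are excluded.
    """
    x, yy = _as_pair(p, y)
    return _pearson(x, yy)


def phase_randomize(y: np.ndarray, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Fourier surrogates of ``y``: amplitude spectrum kept, phases drawn
    uniformly.  Returns an ``n x len(y)`` array."""
    y = np.asarray(y, dtype=float)
    N = len(y)
    spec = np.fft.rfft(y)
    n_bins = len(spec)
    phases = rng.uniform(0.0, 2 * np.pi, size=(n, n_bins))
    phases[:, 0] = 0.0
    if N % 2 == 0:
        phases[:, -1] = 0.0  # Nyquist bin stays real
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=N, axis=1)


def surrogate_test(
    p,
    y,
    n_surr: int = 999,
    seed: int | np.random.Generator = 0,
    alternative: str = "greater",
) -> float:
    """Permutation p-value of the CACor against phase-randomised slopes.

    The stimulus side is randomised (the EEG projection keeps all its
    properties); ``p = (1 + #{r_surr >= r_obs}) / (n_surr + 1)`` for the
    default one-sided positive alternative, with ``two-sided`` comparing
    absolute values.  The smallest attainable p is ``1/(n_surr + 1)``.
    """
    if n_surr < 99:
        raise ValueError("use at least 99 surrogates")
    x, yy = _as_pair(p, y)
    r_obs = _pearson(x, yy)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    surr = phase_randomize(yy, rng, n_surr)
    xc = x - x.mean()
    sc = surr - surr.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xc) * np.linalg.norm(sc, axis=1)
    ok = denom > 0
    r_surr = np.zeros(n_surr)
    r_surr[ok] = (sc[ok] @ xc) / denom[ok]
    if alternative == "greater":
        exceed = int(np.sum(r_surr >= r_obs))
    elif alternative == "two-sided":
        exceed = int(np.sum(np.abs(r_surr) >= abs(r_obs)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + exceed) / (n_surr + 1)


def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    xc = x - x.mean()
    denom = float(xc @ xc)
    full = np.correlate(xc, xc, mode="full")[len(xc) - 1 :]
    return full[1 : max_lag + 1] / denom  # biased estimator, lags 1..J


def pyper_effective_df(
    x,
    y,
    rate: float = 1.0,
    max_lag: float = 2.0,
    r: float | None = None,
    alternative: str = "greater",
):
    """Effective sample count ``N*`` and autocorrelation-corrected p-value.

    ``1/N* = 1/N + (2/N) sum_{j=1}^{J} ((N-j)/N) rho_xx(j) rho_yy(j)``
    with ``J = max_lag * rate``; ``N*`` is clipped to ``[2, N]`` and the
    t-statistic ``r sqrt((N*-2)/(1-r^2))`` is referred to ``N*-2``
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    N = min(len(x), len(y))
    x, y = x[:N], y[:N]
    J = int(np.floor(max_lag * rate))
    if J >= N // 2:
        raise ValueError(
            f"autocorrelation horizon ({J} lags) must stay below half the "
            f"series length ({N})"
        )
    if r is None:
        r = _pearson(x, y)
    j = np.arange(1, J + 1)
    corr_sum = float((((N - j) / N) * _acf(x, J) * _acf(y, J)).sum())
    inv = 1.0 / N + (2.0 / N) * corr_sum
    n_eff = 1.0 / inv if inv > 0 else float(N)
    n_eff = float(np.clip(n_eff, 2.0, N))
    if n_eff <= 2.0:
        warnings.warn("effective sample count collapsed to 2; p set to 1")
        return n_eff, 1.0
    t = r * np.sqrt((n_eff - 2.0) / max(1.0 - r**2, 1e-300))
    if alternative == "greater":
        p = float(sps.t.sf(t, df=n_eff - 2.0))
    elif alternative == "two-sided":
        p = float(2.0 * sps.t.sf(abs(t), df=n_eff - 2.0))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return n_eff, min(max(p, np.finfo(float).tiny), 1.0)


def correct_presentations(p_values, n: int | None = None, alpha: float = 0.05):
    """Bonferroni significance flags: ``p <= alpha / n`` per presentation."""
    p_values = np.asarray(p_values, dtype=float)
    if n is None:
        n = len(p_values)
    if n != len(p_values):
        raise ValueError("n must equal the number of p-values")
    return p_values <= alpha / n


def cacor_score(flags) -> int:
    """Number of presentations with significant CACor."""
    return int(np.sum(np.asarray(flags, dtype=bool)))


def grand_average_cacor(
    projections,
    y,
    n_surr: int = 999,
    seed: int | np.random.Generator = 0,
    rate: float | None = None,
    max_lag: float = 2.0,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> CACorResult:
    """Group-level CACor of the element-wise mean of all projections."""
    vals = [
        p.values if isinstance(p, Projection) else np.asarray(p, float)
        for p in projections
    ]
    n = min(len(v) for v in vals)
    ga = np.mean([v[:n] for v in vals], axis=0)
    pads = [p.n_pad for p in projections if isinstance(p, Projection)]
    proj = Projection(
        values=ga,
        rate=rate
        or next(
            (p.rate for p in projections if isinstance(p, Projection)), 1.0
        ),
        n_pad=max(pads) if pads else 0,
        stimulus_id=next(
            (p.stimulus_id for p in projections if isinstance(p, Projection)), ""
        ),
    )
    x, yy = _as_pair(proj, y)
    r = _pearson(x, yy)
    p_perm = surrogate_test(proj, y, n_surr=n_surr, seed=seed, alternative=alternative)
    n_eff, p_pyper = pyper_effective_df(
        x, yy, rate=proj.rate, max_lag=max_lag, r=r, alternative=alternative
    )
    return CACorResult(
        r=r,
        p_perm=p_perm,
        p_pyper=p_pyper,
        n_eff=n_eff,
        n=len(x),
        significant=bool(p_perm <= alpha),
        subject_id="GA",
        stimulus_id=proj.stimulus_id,
    )


def time_resolved_cacor(
    ga,
    y,
    rate: float | None = None,
    window_len: float = 3.0,
    overlap: float = 0.9,
    min_pairs: int = 10,
    stimulus_id: str = "",
) -> TimeResolvedCACor:
    """Pearson correlation per 3 s window stepped by 0.3 s (3.33 Hz series).

    Windows with fewer than ``min_pairs`` finite sample pairs yield NaN.
    """
    if isinstance(ga, Projection):
        rate = rate or ga.rate
        x = ga.values
    else:
        x = np.asarray(ga, dtype=float)
    if rate is None:
        raise ValueError("rate is required for plain-array input")
    y = np.asarray(y, dtype=float)
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    wlen = int(round(window_len * rate))
    step = int(round(window_len * (1 - overlap) * rate))
    if wlen > n:
        raise ValueError("input shorter than one window")
    starts = np.arange(0, n - wlen + 1, step)
    vals = np.full(len(starts), np.nan)
    for i, s in enumerate(starts):
        xs, ys = x[s : s + wlen], y[s : s + wlen]
        m = np.isfinite(xs) & np.isfinite(ys)
        if m.sum() < min_pairs:
            continue
        try:
            vals[i] = _pearson(xs[m], ys[m])
        except ValueError:
            pass  # zero-variance window stays NaN
    return TimeResolvedCACor(
        values=vals,
        rate=1.0 / (window_len * (1 - overlap)),
        window_len=window_len,
        overlap=overlap,
        stimulus_id=stimulus_id,
    )


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(C, v, rcond=None)
    return v - C @ beta


def partial_correlation(
    target,
    feature,
    controls=(),
    rate: float = 10 / 3,
    max_lag: float = 10.0,
    alternative: str = "two-sided",
):
    """Partial Pearson correlation of ``target`` and ``feature`` given
    ``controls``, with a Pyper-corrected p-value on the residual series.

    NaN frames are dropped listwise; linearly dependent control columns
    are tolerated (minimum-norm residualisation) with a warning.
    """
    target = np.asarray(target, dtype=float)
    feature = np.asarray(feature, dtype=float)
    controls = [np.asarray(c, dtype=float) for c in controls]
    n = min([len(target), len(feature)] + [len(c) for c in controls])
    cols = [target[:n], feature[:n]] + [c[:n] for c in controls]
    M = np.column_stack(cols)
    keep = np.all(np.isfinite(M), axis=1)
    M = M[keep]
    if len(M) < 10:
        raise ValueError("fewer than 10 complete observations")
    C = np.column_stack([np.ones(len(M))] + [M[:, 2 + i] for i in range(len(controls))])
    if len(controls) and np.linalg.matrix_rank(C) < C.shape[1]:
        warnings.warn("collinear control set; using minimum-norm residualisation")
    rt = _residualize(M[:, 0], C)
    rf = _residualize(M[:, 1], C)
    r = _pearson(rt, rf)
    # a short residual series cannot support the full horizon: clip it
    usable = (len(rt) // 2 - 1) / rate
    if usable < max_lag:
        warnings.warn(
            f"autocorrelation horizon clipped from {max_lag:g} to {usable:g} s "
            "for a short series"
        )
        max_lag = usable
    _, p = pyper_effective_df(
        rt, rf, rate=rate, max_lag=max_lag, r=r, alternative=alternative
    )
    return r, p


def fdr_correct(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up flags at rate ``q`` (NaNs excluded)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    flags = np.zeros(p.shape, dtype=bool)
    m = np.isfinite(p)
    if m.any():
        flags[m] = multipletests(p[m], alpha=q, method="fdr_bh")[0]
    return flags


def profile_correlation(a, b, exact_max: int = 9):
    """Spearman correlation between two per-stimulus profiles.

    Profiles are mappings stimulus -> value; only shared stimuli enter.
    Ties are mid-ranked.  For ``n <= exact_max`` the two-sided p-value is
    exact over all n! rank permutations, otherwise the t approximation
    is used.
    """
    a = dict(a)
    b = dict(b)
    shared = [k for k in a if k in b]
    n = len(shared)
    if n < 4:
        raise ValueError("need at least 4 shared stimuli")
    ra = sps.rankdata([a[k] for k in shared])
    rb = sps.rankdata([b[k] for k in shared])
    rho = _pearson(ra, rb)
    if n <= exact_max:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.int16)
        rho_perm = _rank_corr_batch(ra[perms], rb)
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return float(rho), p


def _rank_corr_batch(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    denom = np.linalg.norm(Ac, axis=1) * np.linalg.norm(bc)
    return (Ac @ bc) / denom
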