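"""From regression filters to interpretable source components.

A backward-model filter mixes signal and noise directions and cannot be
read as a scalp topography.  The activation-pattern transform
``A = Cov(X) w / Var(X w)`` recovers how the tracked source projects
onto the scalp, per latency.  The channels x latencies pattern is then
factorised by SVD, truncated at a fixed variance fraction (98 % by
default), and the retained spatial subspace is decomposed into
dipole-related, generally non-orthogonal components with a recursive
(RAP-style) MUSIC scan over a single-sphere head model.  One component
per subject/stimulus is finally selected by similarity to a reference
topography derived from onset ERPs.

The head model is a homogeneous unit sphere: dipole potentials are
evaluated with the classical Legendre series expansion, dipoles sit on
concentric shells (radii 0.30-0.85), and the gain matrix is
average-referenced.  The model is deliberately generic — the analysis
needs a self-consistent forward model, not an individual head.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .eeg_regression import EmbeddedDesign, SpatioTemporalFilter

logger = logging.getLogger("cacor")

__all__ = [
    "SpatioTemporalPattern",
    "SVDFactors",
    "HeadModel",
    "MusicComponent",
    "filter_to_pattern",
    "svd_reduce",
    "build_leadfield",
    "music_decompose",
    "reference_pattern",
    "match_component",
]


@dataclass
class SpatioTemporalPattern:
    """Activation pattern over channels x latencies (same shape as its filter)."""

    pattern: np.ndarray
    channel_labels: list
    source_rate: float = 100.0

    def __post_init__(self):
        self.pattern = np.asarray(self.pattern, dtype=float)
        if not np.all(np.isfinite(self.pattern)):
            raise ValueError("pattern must be finite")
        if self.pattern.shape[0] != len(self.channel_labels):
            raise ValueError("pattern rows must match the channel labels")


@dataclass
class SVDFactors:
    """Truncated SVD of a spatio-temporal pattern."""

    spatial: np.ndarray    # channels x k, orthonormal columns
    values: np.ndarray     # k singular values
    temporal: np.ndarray   # (L+1) x k, orthonormal columns
    total_sq: float        # total squared singular mass before truncation

    @property
    def k(self) -> int:
        return len(self.values)

    @property
    def retained_fraction(self) -> float:
        return float((self.values**2).sum() / self.total_sq)

    def reconstruct(self) -> np.ndarray:
        return self.spatial @ np.diag(self.values) @ self.temporal.T


@dataclass
class HeadModel:
    """Single-sphere forward model: electrodes, dipole grid, gain matrix."""

    electrodes: np.ndarray      # n_el x 3, unit sphere
    channel_labels: list
    grid: np.ndarray            # n_grid x 3, radii <= 0.85
    gain: np.ndarray            # n_el x (3 * n_grid), average-referenced
    grid_spacing: float

    def gain_at(self, i: int) -> np.ndarray:
        """n_el x 3 gain block of grid point ``i``."""
        return self.gain[:, 3 * i : 3 * i + 3]


@dataclass
class MusicComponent:
    spatial_map: np.ndarray        # channels, unit norm
    time_course: np.ndarray        # L+1 weights in the SVD temporal basis
    dipole_location: np.ndarray
    dipole_orientation: np.ndarray
    explained_variance: float      # fraction of retained pattern mass
    subspace_correlation: float


# ---------------------------------------------------------------------------
# pattern transform and SVD truncation


def filter_to_pattern(
    f: SpatioTemporalFilter, X: EmbeddedDesign
) -> SpatioTemporalPattern:
    """Activation pattern ``A = Cov(X) w / Var(X w)`` of a trained filter.

    ``X`` must be the training design of ``f``.  The product is evaluated
    as ``X_c^T (X_c w)`` so the full covariance matrix is never formed.
    """
    M = X.matrix[X.valid]
    Mc = M - M.mean(axis=0)
    z = Mc @ f.flat
    var = float(z @ z) / (len(z) - 1)
    if var <= 0.0:
        raise ValueError("filter output has zero variance on the training design")
    a = (Mc.T @ z) / (len(z) - 1) / var
    return SpatioTemporalPattern(
        pattern=a.reshape(X.n_channels, X.n_lags + 1),
        channel_labels=list(X.channel_labels),
        source_rate=X.source_rate,
    )


def pattern_to_filter(P: SpatioTemporalPattern, X: EmbeddedDesign) -> np.ndarray:
    """Inverse transform ``w ~ Cov(X)^-1 A`` (direction only, full-rank designs)."""
    M = X.matrix[X.valid]
    Mc = M - M.mean(axis=0)
    S = (Mc.T @ Mc) / (len(Mc) - 1)
    w = np.linalg.solve(S, P.pattern.reshape(-1))
    return w.reshape(P.pattern.shape)


def svd_reduce(P: SpatioTemporalPattern, var_frac: float = 0.98) -> SVDFactors:
    """Smallest-rank SVD truncation covering ``var_frac`` of the squared mass."""
    if not 0.0 < var_frac <= 1.0:
        raise ValueError("var_frac must lie in (0, 1]")
    U, s, Vt = np.linalg.svd(P.pattern, full_matrices=False)
    total = float((s**2).sum())
    if total <= 0.0:
        raise ValueError("cannot factorise an all-zero pattern")
    cum = np.cumsum(s**2) / total
    k = int(np.searchsorted(cum, var_frac - 1e-12) + 1)
    k = min(k, len(s))
    return SVDFactors(
        spatial=U[:, :k], values=s[:k], temporal=Vt[:k].T, total_sq=total
    )


# ---------------------------------------------------------------------------
# spherical head model


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _dipole_potential_sums(cosg: np.ndarray, f: float, n_terms: int = 80):
    """Legendre series sums for a dipole at fractional radius ``f``.

    Returns ``(R, T)`` with ``R = sum (2n+1) f^(n-1) P_n`` (radial moment)
    and ``T = sum ((2n+1)/n) f^(n-1) P_n^1`` (tangential moment, positive
    convention), the classical expansion of the surface potential of a
    current dipole inside a homogeneous conducting unit sphere.
    """
    c = cosg
    s = np.sqrt(np.clip(1.0 - c**2, 0.0, None))
    Pnm1 = np.ones_like(c)   # P_0
    Pn = c.copy()            # P_1
    P1nm1 = np.zeros_like(c)  # P_0^1
    P1n = s.copy()            # P_1^1
    R = 3.0 * Pn.copy()       # n = 1 term: (2n+1) f^0 P_1
    T = 3.0 * P1n.copy()      # n = 1 term: 3/1 * P_1^1
    fpow = 1.0
    for n in range(1, n_terms):
        fpow *= f
        Pnp1 = ((2 * n + 1) * c * Pn - n * Pnm1) / (n + 1)
        P1np1 = ((2 * n + 1) * c * P1n - (n + 1) * P1nm1) / n
        Pnm1, Pn = Pn, Pnp1
        P1nm1, P1n = P1n, P1np1
        m = n + 1
        R += (2 * m + 1) * fpow * Pn
        T += (2 * m + 1) / m * fpow * P1n
    return R, T


def dipole_field(
    electrodes: np.ndarray, location, moment, n_terms: int = 80
) -> np.ndarray:
    """Average-referenced scalp field of one dipole in the unit sphere."""
    electrodes = np.asarray(electrodes, dtype=float)
    location = np.asarray(location, dtype=float)
    moment = np.asarray(moment, dtype=float)
    f = np.linalg.norm(location)
    if not 0 < f < 1:
        raise ValueError("dipole must lie strictly inside the unit sphere")
    bhat = location / f
    cosg = electrodes @ bhat
    R, T = _dipole_potential_sums(cosg, f, n_terms)
    sing = np.sqrt(np.clip(1.0 - cosg**2, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = (electrodes - cosg[:, None] * bhat) / np.where(
            sing[:, None] > 1e-12, sing[:, None], 1.0
        )
    u[sing <= 1e-12] = 0.0
    v = ((moment @ bhat) * R + (u @ (moment - (moment @ bhat) * bhat)) * T) / (
        4 * np.pi
    )
    return v - v.mean()


def build_leadfield(
    electrodes: np.ndarray,
    grid_spacing: float = 0.15,
    radii=None,
    channel_labels=None,
    n_terms: int = 80,
) -> HeadModel:
    """Gain matrix of a dipole grid inside a homogeneous unit sphere.

    Dipoles sit on concentric shells (default radii 0.30-0.85 spaced by
    ``grid_spacing``) with quasi-uniform in-shell spacing; each grid
    point contributes three orthogonal unit moments.  Rows are
    average-referenced so every gain column sums to zero.
    """
    electrodes = np.asarray(electrodes, dtype=float)
    if len(electrodes) < 8:
        raise ValueError("need at least 8 electrodes with positions")
    norms = np.linalg.norm(electrodes, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("electrode positions must lie on the unit sphere")
    if radii is None:
        radii = np.arange(0.30, 0.85 + 1e-9, grid_spacing)
        if radii[-1] < 0.85 - 1e-9:
            radii = np.append(radii, 0.85)
    grid_parts = []
    for r in radii:
        n_pts = max(16, int(round(4 * np.pi * r**2 / grid_spacing**2)))
        grid_parts.append(r * _fibonacci_sphere(n_pts))
    grid = np.vstack(grid_parts)
    n_el, n_grid = len(electrodes), len(grid)
    gain = np.empty((n_el, 3 * n_grid))
    for i, pos in enumerate(grid):
        f = np.linalg.norm(pos)
        bhat = pos / f
        cosg = electrodes @ bhat
        R, T = _dipole_potential_sums(cosg, f, n_terms)
        sing = np.sqrt(np.clip(1.0 - cosg**2, 0.0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            u = (electrodes - cosg[:, None] * bhat) / np.where(
                sing[:, None] > 1e-12, sing[:, None], 1.0
            )
        u[sing <= 1e-12] = 0.0
        # basis moment e_k: radial part (e_k . bhat) R + tangential (e_k . u) T
        block = (np.outer(R, bhat) + T[:, None] * u) / (4 * np.pi)
        gain[:, 3 * i : 3 * i + 3] = block
    gain -= gain.mean(axis=0, keepdims=True)  # average reference
    if not np.all(np.isfinite(gain)):
        raise ValueError("non-finite leadfield gain")
    return HeadModel(
        electrodes=electrodes,
        channel_labels=list(channel_labels) if channel_labels is not None else [],
        grid=grid,
        gain=gain,
        grid_spacing=float(grid_spacing),
    )


# ---------------------------------------------------------------------------
# MUSIC decomposition


def _best_orientation(A: np.ndarray, B: np.ndarray):
    """Max subspace correlation of ``A o`` (o in R^3) with orthonormal ``B``."""
    AtA = A.T @ A
    AtB = A.T @ B
    M = AtB @ AtB.T
    reg = 1e-12 * max(np.trace(AtA), 1e-300)
    try:
        vals, vecs = linalg.eigh(M, AtA + reg * np.eye(3))
    except linalg.LinAlgError:
        return 0.0, np.array([0.0, 0.0, 1.0])
    corr2 = float(np.clip(vals[-1], 0.0, 1.0))
    return np.sqrt(corr2), vecs[:, -1]


def music_decompose(
    factors: SVDFactors,
    H: HeadModel,
    n_max: int = 4,
    min_corr: float = 0.8,
) -> list:
    """Sequential (RAP-style) MUSIC scan of the retained spatial subspace.

    Each round finds the grid dipole whose best-oriented field has
    maximal subspace correlation with the (recursively projected)
    retained subspace, emits its unit-norm field as a component, then
    projects the found field out of both subspace and gains.  The scan
    stops after ``n_max`` components or when the correlation drops below
    ``min_corr``; the first component is always emitted.  Components are
    generally non-orthogonal.
    """
    if factors.k < 1:
        raise ValueError("empty spatial subspace")
    n_el = factors.spatial.shape[0]
    if H.gain.shape[0] != n_el:
        raise ValueError("head model electrode count does not match the pattern")
    pattern_k = factors.reconstruct()
    total_sq = float((factors.values**2).sum())
    found_fields = []
    comps = []
    proj = np.eye(n_el)
    B = factors.spatial.copy()
    n_grid = len(H.grid)
    for _ in range(n_max):
        best = (-1.0, None, None)  # corr, grid index, orientation
        for g in range(n_grid):
            A = proj @ H.gain_at(g)
            corr, o = _best_orientation(A, B)
            if corr > best[0]:
                best = (corr, g, o)
        corr, g, o = best
        if comps and corr < min_corr:
            break
        field = H.gain_at(g) @ o
        nrm = np.linalg.norm(field)
        if nrm <= 0.0:
            break
        a = field / nrm
        tc = pattern_k.T @ a  # least-squares weights of the map over latencies
        comps.append(
            MusicComponent(
                spatial_map=a,
                time_course=tc,
                dipole_location=H.grid[g].copy(),
                dipole_orientation=o / np.linalg.norm(o),
                explained_variance=float((tc @ tc) / total_sq),
                subspace_correlation=float(corr),
            )
        )
        found_fields.append(a)
        Q = linalg.orth(np.column_stack(found_fields))
        proj = np.eye(n_el) - Q @ Q.T
        Bp = proj @ factors.spatial
        # re-orthonormalize; directions reduced to numerical residue are gone
        U, s, _ = np.linalg.svd(Bp, full_matrices=False)
        keep = s > 1e-6
        if not keep.any():
            break
        B = U[:, keep]
    return comps


# ---------------------------------------------------------------------------
# reference-pattern selection


def reference_pattern(
    erps: dict,
    channel_labels,
    rate: float,
    channel: str = "Fz",
    search_window: tuple = (0.13, 0.28),
    halfwidth: float = 0.01,
) -> np.ndarray:
    """Cross-subject onset-ERP reference topography, unit-normalised.

    For each subject's average epoch the latency of maximal absolute
    amplitude at ``channel`` inside ``search_window`` is located and the
    topography averaged over +-``halfwidth`` seconds around it; the
    per-subject topographies are then averaged and normalised.
    """
    labels = list(channel_labels)
    if channel not in labels:
        raise ValueError(f"channel {channel!r} not in the montage")
    ci = labels.index(channel)
    lo = int(np.floor(search_window[0] * rate))
    hi = int(np.ceil(search_window[1] * rate))
    hw = int(round(halfwidth * rate))
    topos = []
    for subject, epoch in erps.items():
        epoch = np.asarray(epoch, dtype=float)
        seg = epoch[ci, lo : hi + 1]
        if seg.size == 0:
            raise ValueError(f"search window outside the epoch for subject {subject}")
        peak = lo + int(np.argmax(np.abs(seg)))
        a = max(0, peak - hw)
        b = min(epoch.shape[1], peak + hw + 1)
        topos.append(epoch[:, a:b].mean(axis=1))
    ref = np.mean(topos, axis=0)
    nrm = np.linalg.norm(ref)
    if nrm <= 0.0:
        raise ValueError("reference topography is identically zero")
    return ref / nrm


def match_component(comps, ref: np.ndarray):
    """Select the component most similar to a reference topography.

    Similarity is the absolute cosine between unit-normalised maps
    (sign-invariant).  Ties break toward larger explained variance, then
    lower component index.  Returns ``(component, similarity)``.
    """
    if not comps:
        raise ValueError("no components to match")
    ref = np.asarray(ref, dtype=float)
    ref = ref / np.linalg.norm(ref)
    sims = np.array([abs(float(c.spatial_map @ ref)) for c in comps])
    order = sorted(
        range(len(comps)),
        key=lambda i: (-round(sims[i], 12), -comps[i].explained_variance, i),
    )
    best = order[0]
    if sims[best] < 0.1:
        logger.warning(
            "reference match is weak (|cos| = %.3f); selected the "
            "highest-variance component",
            sims[best],
        )
    return comps[best], float(sims[best])
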