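"""Joint-distribution-entropy (JDistEn) coupling between channel pairs.

JDistEn quantifies nonlinear coupling between two short series without
needing long recordings. Each unit-range channel is delay-embedded (dimension
``m``, delay ``tau``); a per-channel distance matrix over the embedded columns
is combined entrywise into a joint distance matrix

    JD = 1 - sqrt((1 - D1) * (1 - D2)),

and the normalized Shannon entropy of the histogram of JD's off-diagonal
entries (bin count from Doane's rule) is the coupling value in [0, 1].
When the channels carry the same dynamics, D1 = D2 and JD keeps the full
spread of the single-channel distances (high entropy, coupling near 1);
independent channels average each other's structure away, concentrating the
histogram (low entropy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DomainError,
    NormalizationError,
    TooFewObservationsError,
    TooShortSeriesError,
)
from .preprocess import RescaledRecording

__all__ = [
    "EmbeddingConfig",
    "JointHistogram",
    "embed",
    "channel_distance_matrix",
    "joint_distance_matrix",
    "off_diagonal",
    "doane_bins",
    "joint_histogram",
    "jdisten_from_histogram",
    "pair_jdisten",
    "coupling_matrix",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding parameters shared by all channels.

    ``m=2, tau=1`` are the defaults used throughout EEG entropy work at
    these record lengths. ``norm`` selects the inter-column distance:
    ``"range"`` is the operational definition used here,
    ``max[max(X(i)) - min(X(j)), max(X(j)) - min(X(i))]``; ``"chebyshev"``
    is the textbook maximum norm ``max_k |x_k(i) - x_k(j)|`` (the two
    differ; "range" is the default).
    """

    m: int = 2
    tau: int = 1
    norm: str = "range"

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("embedding dimension and delay must be >= 1")
        if self.norm not in ("range", "chebyshev"):
            raise ValueError("norm must be 'range' or 'chebyshev'")

    @property
    def margin(self) -> int:
        """Trailing margin n = m * tau; embedded columns number N - n."""
        return self.m * self.tau


@dataclass
class JointHistogram:
    """Doane-binned histogram of off-diagonal joint-distance values."""

    bins: int
    b_raw: float
    g1: float
    sigma_g1: float
    n_obv: int
    counts: np.ndarray | None = None
    edges: np.ndarray | None = None
    rho: np.ndarray | None = field(default=None)


def embed(u_bar: np.ndarray, cfg: EmbeddingConfig = EmbeddingConfig()) -> np.ndarray:
    """Delay-embed one rescaled channel into an ``m x (N - n)`` state space.

    Column ``i`` (0-based) holds ``[u(i), u(i+tau), ..., u(i+(m-1)tau)]``.
    The index range runs to ``N - n`` with ``n = m * tau``.
    """
    u_bar = np.asarray(u_bar, dtype=float)
    n_samples = u_bar.shape[0]
    n = cfg.margin
    cols = n_samples - n
    if cols < 1:
        raise TooShortSeriesError(
            f"series of length {n_samples} too short for m={cfg.m}, tau={cfg.tau}"
        )
    return np.stack([u_bar[k * cfg.tau : k * cfg.tau + cols] for k in range(cfg.m)])


def channel_distance_matrix(X: np.ndarray, norm: str = "range") -> np.ndarray:
    """Pairwise distances between embedded columns.

    The "range" norm compares column extrema:
    ``max[max(X(i)) - min(X(j)), max(X(j)) - min(X(i))]``. It is symmetric
    and non-negative but gives a column's own range on the diagonal; the
    diagonal is never used downstream. ``"chebyshev"`` gives the ordinary
    maximum norm with a zero diagonal.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("state space must be m x (N - n) with >= 1 column")
    if norm == "range":
        cmax = X.max(axis=0)
        cmin = X.min(axis=0)
        a = cmax[:, None] - cmin[None, :]
        return np.maximum(a, a.T)
    if norm == "chebyshev":
        d = np.abs(X[0][:, None] - X[0][None, :])
        for row in X[1:]:
            np.maximum(d, np.abs(row[:, None] - row[None, :]), out=d)
        return d
    raise ValueError(f"unknown norm {norm!r}")


def joint_distance_matrix(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Combine two channels' distance matrices: ``1 - sqrt((1-d1)(1-d2))``.

    Requires entries in [0, 1] (guaranteed for unit-range channels); equals
    ``d1`` exactly when ``d1 == d2``.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("distance matrices must have the same shape")
    if d1.max(initial=0.0) > 1.0 + 1e-12 or d2.max(initial=0.0) > 1.0 + 1e-12:
        raise DomainError("distance entries above 1: negative value under sqrt")
    if np.array_equal(d1, d2):
        return d1.copy()  # sqrt of a square: the identity holds exactly
    prod = (1.0 - d1) * (1.0 - d2)
    np.clip(prod, 0.0, None, out=prod)
    return 1.0 - np.sqrt(prod)


def off_diagonal(mat: np.ndarray) -> np.ndarray:
    """All entries with i != j (both triangles), row-major order."""
    mat = np.asarray(mat)
    mask = ~np.eye(mat.shape[0], dtype=bool)
    return mat[mask]


def _population_skewness(values: np.ndarray) -> float:
    """Biased (population) skewness m3 / m2^1.5; defined as 0 for constants."""
    if np.ptp(values) == 0:
        return 0.0
    mu = values.mean()
    d = values - mu
    m2 = np.mean(d * d)
    if m2 == 0.0:
        return 0.0
    m3 = np.mean(d * d * d)
    return float(m3 / m2 ** 1.5)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def doane_bins(values: np.ndarray) -> JointHistogram:
    """Doane's bin-count rule applied to the joint-distance values.

    ``B = 1 + log2(n_obv) + log2(1 + |g1| / sigma_g1)`` with
    ``sigma_g1 = sqrt(6 (n_obv - 2) / ((n_obv + 1)(n_obv + 3)))``; B is
    rounded half-away-from-zero to the integer bin count, floored at 2.
    """
    values = np.asarray(values, dtype=float)
    n_obv = values.size
    if n_obv < 4:
        raise TooFewObservationsError(
            f"Doane binning needs >= 4 observations, got {n_obv}"
        )
    g1 = _population_skewness(values)
    sigma_g1 = math.sqrt(6.0 * (n_obv - 2) / ((n_obv + 1) * (n_obv + 3)))
    b = 1.0 + math.log2(n_obv) + math.log2(1.0 + abs(g1) / sigma_g1)
    bins = max(2, _round_half_away(b))
    return JointHistogram(bins=bins, b_raw=b, g1=g1, sigma_g1=sigma_g1, n_obv=n_obv)


def joint_histogram(values: np.ndarray) -> JointHistogram:
    """Equal-width histogram over [min, max] with the Doane bin count.

    The rightmost bin is closed, so the maximum lands in the last bin;
    masses ``rho`` are normalized to sum to 1.
    """
    values = np.asarray(values, dtype=float)
    h = doane_bins(values)
    counts, edges = np.histogram(values, bins=h.bins)
    h.counts = counts
    h.edges = edges
    h.rho = counts / counts.sum()
    return h


def jdisten_from_histogram(h: JointHistogram) -> float:
    """Normalized Shannon entropy ``-(1/log2 Bins) * sum rho log2 rho``.

    Zero-mass bins are excluded from the sum. 0 means uncoupled, 1 fully
    coupled (uniform histogram).
    """
    if h.bins < 2:
        raise NormalizationError("entropy normalization needs >= 2 bins")
    if h.rho is None:
        raise ValueError("histogram masses not populated")
    p = h.rho[h.rho > 0]
    value = float(-(p * np.log2(p)).sum() / math.log2(h.bins))
    return min(max(value, 0.0), 1.0)


def pair_jdisten(d1: np.ndarray, d2: np.ndarray) -> float:
    """JDistEn of one channel pair from their distance matrices."""
    jd = joint_distance_matrix(d1, d2)
    return jdisten_from_histogram(joint_histogram(off_diagonal(jd)))


def coupling_matrix(
    rec: RescaledRecording | np.ndarray,
    cfg: EmbeddingConfig = EmbeddingConfig(),
) -> np.ndarray:
    """Symmetric channels x channels matrix of pairwise JDistEn values.

    Per-channel distance matrices are computed once and reused across pairs.
    The diagonal (self-coupling) is set to 0 and excluded from downstream
    thresholding.
    """
    data = rec.data if isinstance(rec, RescaledRecording) else np.asarray(rec, float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a channels x samples matrix with >= 2 channels")
    n_ch = data.shape[0]
    # store 1 - D per channel: the pair step is then 1 - sqrt(G_a * G_b)
    comp = [
        1.0 - channel_distance_matrix(embed(data[c], cfg), cfg.norm)
        for c in range(n_ch)
    ]
    size = comp[0].shape[0]
    offdiag = ~np.eye(size, dtype=bool)
    out = np.zeros((n_ch, n_ch))
    for a in range(n_ch):
        for b in range(a + 1, n_ch):
            prod = comp[a] * comp[b]
            np.clip(prod, 0.0, None, out=prod)
            values = (1.0 - np.sqrt(prod))[offdiag]
            val = jdisten_from_histogram(joint_histogram(values))
            out[a, b] = out[b, a] = val
    return out
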