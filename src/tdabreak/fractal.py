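"""Fractal dimension estimators.

Two estimators are provided:

* The **Higuchi fractal dimension** (HFD) of a univariate series.  For a
  series ``X(1..T)`` the normalized curve length at lag ``k`` and offset
  ``m`` is

      L_m(k) = (T-1) / (floor((T-m)/k) * k^2)
               * sum_{i=1..floor((T-m)/k)} |X(m+ik) - X(m+(i-1)k)|

  and ``L(k)`` is the mean of ``L_m(k)`` over ``m = 1..k``.  The length
  scales as ``L(k) ~ k^(-HFD)``; the HFD is the OLS slope of ``log L(k)``
  on ``log(1/k)`` for ``k = 1..kmax``.  Smooth curves give HFD near 1,
  Brownian motion 1.5, white noise near 2; for fractional Brownian motion
  with Hurst index H, HFD = 2 - H.

* The **box-counting dimension** of a planar point set: the number of
  occupied cells ``N_r`` of an axis-aligned grid of mesh ``r`` scales as
  ``N_r ~ r^(-D)``; D is the OLS slope of ``log N_r`` on ``log(1/r)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HiguchiConfig",
    "HFDEstimate",
    "BoxCountEstimate",
    "higuchi_length_m",
    "higuchi_length",
    "estimate_hfd",
    "box_counting_dim",
]


@dataclass(frozen=True)
class HiguchiConfig:
    """Largest lag ``kmax`` used in the length-scale fit (default 10)."""

    kmax: int = 10

    def __post_init__(self) -> None:
        if self.kmax < 2:
            raise ValueError("kmax must be >= 2")


@dataclass(frozen=True)
class HFDEstimate:
    """HFD with its per-scale lengths and log-log fit quality."""

    hfd: float
    scales: np.ndarray  # k = 1..kmax
    lengths: np.ndarray  # L(k)
    fit_r2: float


@dataclass(frozen=True)
class BoxCountEstimate:
    """Box-counting dimension with per-scale occupied-box counts."""

    dim: float
    scales: np.ndarray  # box sizes r, decreasing
    counts: np.ndarray  # N_r
    fit_r2: float


def higuchi_length_m(x: np.ndarray, m: int, k: int) -> float:
    """Normalized lag-``k`` curve length starting at offset ``m`` (1-based).

    Direct evaluation of the Higuchi length definition; raises if fewer
    than one lag-``k`` increment fits after offset ``m``.
    """
    x = np.asarray(x, dtype=float)
    T = x.size
    if not 1 <= m <= k:
        raise ValueError(f"offset m={m} must satisfy 1 <= m <= k={k}")
    n_inc = (T - m) // k
    if n_inc < 1:
        raise ValueError(f"lag k={k} too large for series of length {T} at offset {m}")
    idx = m - 1 + k * np.arange(n_inc + 1)
    total = np.abs(np.diff(x[idx])).sum()
    return total * (T - 1) / (n_inc * k * k)


def higuchi_length(x: np.ndarray, k: int) -> float:
    """Mean of ``L_m(k)`` over offsets ``m = 1..k``."""
    return float(np.mean([higuchi_length_m(x, m, k) for m in range(1, k + 1)]))


def _length_curve(x: np.ndarray, kmax: int) -> np.ndarray:
    """L(k) for k = 1..kmax, vectorized over offsets."""
    T = x.size
    out = np.empty(kmax)
    # k = 1 has a single offset and is just the total variation, normalized
    out[0] = np.abs(np.diff(x)).sum() * (T - 1) / (T - 1)
    for k in range(2, kmax + 1):
        acc = 0.0
        for m in range(1, k + 1):
            n_inc = (T - m) // k
            seg = x[m - 1 : m - 1 + n_inc * k + 1 : k]
            acc += np.abs(np.diff(seg)).sum() * (T - 1) / (n_inc * k * k)
        out[k - 1] = acc / k
    return out


def estimate_hfd(x: np.ndarray, cfg: HiguchiConfig | None = None) -> HFDEstimate:
    """Estimate the Higuchi fractal dimension of a univariate series.

    OLS fit of ``log L(k)`` against ``log(1/k)`` over ``k = 1..kmax``
    (natural logs; the slope is base-invariant).  Raises ``ValueError``
    for constant series or series too short for ``kmax``.
    """
    if cfg is None:
        cfg = HiguchiConfig()
    x = np.asarray(x, dtype=float).ravel()
    T = x.size
    if T < 2 * cfg.kmax + 1:
        raise ValueError(
            f"series of length {T} too short for kmax={cfg.kmax} "
            f"(need at least {2 * cfg.kmax + 1})"
        )
    lengths = _length_curve(x, cfg.kmax)
    if np.any(lengths <= 0):
        raise ValueError("degenerate (locally constant) series: zero curve length")
    ks = np.arange(1, cfg.kmax + 1)
    lx = np.log(1.0 / ks)
    ly = np.log(lengths)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return HFDEstimate(hfd=float(slope), scales=ks, lengths=lengths, fit_r2=float(r2))


def box_counting_dim(points: np.ndarray, scales) -> BoxCountEstimate:
    """Box-counting dimension of a finite planar point set.

    The grid at each scale ``r`` is axis-aligned and anchored at the
    bounding-box minimum; ``N_r`` is the number of occupied cells.
    ``scales`` must be a decreasing sequence of at least 3 box sizes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an N x 2 array")
    scales = np.asarray(scales, dtype=float)
    if scales.size < 3:
        raise ValueError("need at least 3 scales")
    if np.any(np.diff(scales) >= 0):
        raise ValueError("scales must be strictly decreasing")
    lo = pts.min(axis=0)
    if np.all(pts.max(axis=0) == lo):
        raise ValueError("all points identical: box-counting dimension undefined")
    extent = pts.max(axis=0) - lo
    counts = np.empty(scales.size, dtype=int)
    for i, r in enumerate(scales):
        cells = np.floor((pts - lo) / r).astype(np.int64)
        # points on the far bounding-box edge belong to the last box
        last = np.maximum(np.ceil(extent / r) - 1, 0).astype(np.int64)
        cells = np.minimum(cells, last)
        counts[i] = np.unique(cells, axis=0).shape[0]
    lx = np.log(1.0 / scales)
    ly = np.log(counts.astype(float))
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return BoxCountEstimate(
        dim=float(slope), scales=scales, counts=counts, fit_r2=float(r2)
    )
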