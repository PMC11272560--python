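"""Vietoris-Rips persistence and time-varying total persistence.

For each windowed point cloud the Rips filtration ``X_eps`` (all simplices
whose vertices are pairwise within distance ``eps``) is swept over
increasing ``eps`` and the birth/death scales of k-dimensional holes are
recorded in a persistence diagram.  The per-window summary is the *total
persistence*

    TP_k = sum over finite bars [b, d] in dimension k of (d - b),

and stringing windows together yields the time-varying curves ``TP_k(t)``
for k = 0 (components), 1 (loops), 2 (cavities).  Infinite bars (the one
essential connected component, and any class still alive at the filtration
cutoff) are excluded from the sum; an optional mode caps them at the
cutoff instead.

The default cutoff ``eps_max="auto"`` is the maximum pairwise distance of
each cloud, at which the complex is complete, so every loop and cavity has
a finite death and the essential component is the only infinite bar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._reduction import rips_pairs
from .embedding import PointCloud, SignalMatrix, WindowConfig, make_point_clouds

__all__ = [
    "FiltrationParams",
    "PersistenceDiagram",
    "TPCurveSet",
    "rips_diagram",
    "total_persistence",
    "tv_total_persistence",
]


@dataclass(frozen=True)
class FiltrationParams:
    """Rips filtration settings.

    ``max_homology_dim`` in {0, 1, 2} (default 2). ``eps_max`` is the
    filtration cutoff: ``"auto"`` resolves per window to the cloud's
    maximum pairwise distance.  ``cap_infinite`` replaces infinite deaths
    by the cutoff in total-persistence sums instead of dropping them.
    """

    max_homology_dim: int = 2
    eps_max: float | str = "auto"
    cap_infinite: bool = False

    def __post_init__(self) -> None:
        if self.max_homology_dim not in (0, 1, 2):
            raise ValueError("max_homology_dim must be 0, 1 or 2")
        if self.eps_max != "auto":
            if not (isinstance(self.eps_max, (int, float)) and self.eps_max > 0):
                raise ValueError('eps_max must be "auto" or a positive number')


@dataclass(frozen=True)
class PersistenceDiagram:
    """Birth/death pairs per homology dimension, one cloud's Rips diagram.

    ``births``/``deaths``/``dims`` are parallel arrays; deaths may be
    ``inf`` for essential classes.  Zero-persistence pairs are omitted.
    ``eps_max`` records the filtration cutoff actually used.
    """

    births: np.ndarray
    deaths: np.ndarray
    dims: np.ndarray
    max_homology_dim: int
    eps_max: float

    def features(self, k: int | None = None):
        """(birth, death, dim) triples, optionally restricted to dim k."""
        sel = slice(None) if k is None else self.dims == k
        return list(zip(self.births[sel], self.deaths[sel], self.dims[sel]))


@dataclass(frozen=True)
class TPCurveSet:
    """Time-varying total persistence: one series per homology dimension."""

    times: np.ndarray
    tp: dict  # k -> series aligned with times

    def __getitem__(self, k: int) -> np.ndarray:
        return self.tp[k]


def rips_diagram(
    cloud: PointCloud | np.ndarray, params: FiltrationParams | None = None
) -> PersistenceDiagram:
    """Persistence diagram of one point cloud's Rips filtration.

    Accepts a :class:`PointCloud` or a plain ``n x p`` array; Euclidean
    metric.  Deterministic for fixed input.
    """
    if params is None:
        params = FiltrationParams()
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("point cloud must be a 2-D array with at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point cloud contains non-finite coordinates")
    dm = squareform(pdist(pts))
    eps = float(dm.max()) if params.eps_max == "auto" else float(params.eps_max)
    births, deaths, dims = rips_pairs(dm, params.max_homology_dim, eps)
    order = np.lexsort((births, dims))
    return PersistenceDiagram(
        births=births[order],
        deaths=deaths[order],
        dims=dims[order],
        max_homology_dim=params.max_homology_dim,
        eps_max=eps,
    )


def total_persistence(
    diagram: PersistenceDiagram, k: int, cap_infinite: bool = False
) -> float:
    """Sum of (death - birth) over dimension-k bars of the diagram.

    Infinite bars are excluded (default) or capped at the filtration
    cutoff when ``cap_infinite`` is set.  An empty dimension gives 0.
    """
    if k > diagram.max_homology_dim:
        raise ValueError(
            f"k={k} exceeds the diagram's max homology dimension "
            f"{diagram.max_homology_dim}"
        )
    sel = diagram.dims == k
    births = diagram.births[sel]
    deaths = diagram.deaths[sel]
    finite = np.isfinite(deaths)
    tp = float(np.sum(deaths[finite] - births[finite]))
    if cap_infinite:
        tp += float(np.sum(diagram.eps_max - births[~finite]))
    return tp


def tv_total_persistence(
    signal: SignalMatrix,
    win: WindowConfig,
    params: FiltrationParams | None = None,
) -> TPCurveSet:
    """Total-persistence curves ``TP_k(t)`` over non-overlapping windows.

    Slices the signal into point clouds, computes each cloud's Rips
    diagram and reduces it to TP_k for every k up to
    ``params.max_homology_dim``; values are time-stamped at the window
    end.
    """
    if params is None:
        params = FiltrationParams()
    clouds = make_point_clouds(signal, win)
    ks = range(params.max_homology_dim + 1)
    times = np.array([c.end_time for c in clouds])
    tp = {k: np.empty(len(clouds)) for k in ks}
    for i, cloud in enumerate(clouds):
        diag = rips_diagram(cloud, params)
        for k in ks:
            tp[k][i] = total_persistence(diag, k, cap_infinite=params.cap_infinite)
    return TPCurveSet(times=times, tp=tp)
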