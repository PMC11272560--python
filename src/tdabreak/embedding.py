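"""Localized point-cloud embedding of a multivariate time series.

A multivariate series ``X(t) in R^P`` observed at ``T`` time samples is
sliced into windows of ``w`` consecutive samples; each window is treated as
a point cloud of ``w`` points in ``R^P``.  The topology of that cloud (holes,
cavities) reflects the instantaneous dependence structure among the
components, and tracking it over windows gives a dynamic picture of the
signal.  Windows are non-overlapping by default (stride = width), which
avoids the autocorrelation that overlapping windows induce in downstream
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SignalMatrix", "WindowConfig", "PointCloud", "make_point_clouds"]


@dataclass(frozen=True)
class SignalMatrix:
    """A multivariate time series: rows are time samples, columns channels.

    Parameters
    ----------
    values
        T x P array of finite floats.
    sampling_rate
        Samples per second; used only to convert window indices into
        time stamps. Defaults to 1 (time measured in samples).
    """

    values: np.ndarray
    sampling_rate: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ValueError(f"signal must be 2-D (T x P), got ndim={arr.ndim}")
        if arr.shape[0] < 2 or arr.shape[1] < 1:
            raise ValueError(f"signal needs T >= 2 and P >= 1, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("signal contains non-finite entries")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: width ``w`` and stride (default ``w``)."""

    width: int
    stride: int | None = None

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError("window width must be >= 2")
        stride = self.width if self.stride is None else self.stride
        if stride < 1:
            raise ValueError("stride must be >= 1")
        object.__setattr__(self, "stride", stride)


@dataclass(frozen=True)
class PointCloud:
    """One window's samples viewed as ``w`` points in ``R^P``.

    ``end_time`` is the time stamp of the window's last sample; total
    persistence computed from this cloud is plotted at that time.
    """

    points: np.ndarray
    window_index: int
    end_time: float


def make_point_clouds(signal: SignalMatrix, cfg: WindowConfig) -> list[PointCloud]:
    """Slice ``signal`` into point clouds of ``cfg.width`` consecutive samples.

    Windows cover samples ``[i*stride, i*stride + width)`` (0-based,
    half-open); a trailing window with fewer than ``width`` samples is
    dropped.  No centering or rescaling is applied: row ``j`` of each cloud
    is the raw sample at the corresponding time index.

    Returns the clouds in time order.  With the default stride the number
    of clouds is ``floor(T / width)`` and concatenating their rows
    reproduces the first ``floor(T/width)*width`` rows of the input.
    """
    T = signal.n_samples
    if cfg.width > T:
        raise ValueError(f"window width {cfg.width} exceeds series length {T}")
    clouds: list[PointCloud] = []
    stride = cfg.stride
    assert stride is not None
    n_windows = (T - cfg.width) // stride + 1
    for i in range(n_windows):
        lo = i * stride
        hi = lo + cfg.width
        end_time = (hi - 1) / signal.sampling_rate
        clouds.append(
            PointCloud(points=signal.values[lo:hi], window_index=i, end_time=end_time)
        )
    return clouds
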