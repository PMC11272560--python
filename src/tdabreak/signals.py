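"""Synthetic signal generators.

Two families live here:

* **Epoch/scenario generators** — 3-dimensional point-process signals whose
  samples are drawn from geometric patterns (Gaussian blob, circle, sphere,
  lemniscate, torus, spiral).  Concatenating epochs with different patterns
  yields a multivariate series whose windowed point clouds change topology
  at known times, which is exactly what the structural-break test is meant
  to detect.  Two presets are provided: ``example1`` (Gaussian / circle /
  Gaussian / sphere / Gaussian, 3,000 samples each at 100 Hz, window 50)
  and ``example2`` (infinity / torus / spiral, 5,000 samples each at
  100 Hz, window 150).

* **Univariate calibration processes** — Brownian motion, fractional
  Brownian motion (fBm), Gaussian white noise and a smooth deterministic
  chirp ``x(t) = t cos(t^2/10)``.  These have known Higuchi fractal
  dimensions (1.5, 2 - H, 2 and ~1 respectively) and are used to calibrate
  and validate the fractal-dimension estimator.

All stochastic generators take a :class:`numpy.random.Generator`; a fixed
generator state yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import SignalMatrix, WindowConfig

__all__ = [
    "EpochSpec",
    "ScenarioPreset",
    "FBMConfig",
    "generate_epoch",
    "build_scenario",
    "generate_brownian",
    "generate_white_noise",
    "generate_smooth_curve",
    "generate_fbm",
    "SCENARIO_NAMES",
]

_PATTERNS = ("gaussian", "circle", "sphere", "infinity", "torus", "spiral")


@dataclass(frozen=True)
class EpochSpec:
    """One epoch of a scenario: a pattern, its parameters, and noise level.

    ``params`` are pattern-specific: ``sd`` (gaussian), ``radius`` (circle,
    sphere), ``scale`` (infinity), ``major_radius``/``minor_radius``
    (torus), ``r_start``/``r_end``/``turns``/``height`` (spiral).
    ``noise_sd`` is additive isotropic Gaussian observation noise applied
    to the manifold patterns (it is ignored for ``gaussian``, whose spread
    is the pattern itself).
    """

    pattern: str
    n_samples: int
    params: dict = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(
                f"unknown pattern {self.pattern!r}; expected one of {_PATTERNS}"
            )
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for key, val in self.params.items():
            if key in {"sd", "radius", "scale", "major_radius", "minor_radius",
                       "r_start", "r_end", "height"} and val <= 0:
                raise ValueError(f"parameter {key} must be > 0, got {val}")


@dataclass(frozen=True)
class ScenarioPreset:
    """Ordered epochs plus the sampling rate and window width they imply."""

    name: str
    epochs: tuple
    sampling_rate: float
    window_width: int

    @property
    def n_samples(self) -> int:
        return sum(e.n_samples for e in self.epochs)

    @property
    def window_config(self) -> WindowConfig:
        return WindowConfig(width=self.window_width)


@dataclass(frozen=True)
class FBMConfig:
    """Fractional Brownian motion with Hurst index ``hurst`` in (0, 1).

    ``hurst = 0.5`` reduces to standard Brownian motion (independent
    increments of variance ``dt``).  On the unit-``dt`` scale the process
    satisfies ``Var[B_H(t)] = t^(2H)``.
    """

    hurst: float
    n_samples: int
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"hurst must lie in (0, 1), got {self.hurst}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


def _pattern_points(spec: EpochSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_samples
    p = spec.params
    if spec.pattern == "gaussian":
        sd = p.get("sd", 1.0)
        dim = int(p.get("dim", 3))
        return rng.normal(0.0, sd, size=(n, dim))
    if spec.pattern == "circle":
        r = p.get("radius", 1.0)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(n)])
    if spec.pattern == "sphere":
        r = p.get("radius", 1.0)
        g = rng.normal(size=(n, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        return r * g
    if spec.pattern == "infinity":
        # Gerono lemniscate in the xy-plane: a figure-eight with one loop
        # on each side of the origin, hence two 1-dimensional holes.
        a = p.get("scale", 4.0)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.column_stack(
            [a * np.cos(theta), a * np.sin(theta) * np.cos(theta), np.zeros(n)]
        )
    if spec.pattern == "torus":
        R = p.get("major_radius", 3.0)
        r = p.get("minor_radius", 1.0)
        if R <= r:
            raise ValueError(f"torus needs major_radius > minor_radius, got {R} <= {r}")
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)  # around the hole
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)  # around the tube
        return np.column_stack(
            [
                (R + r * np.cos(phi)) * np.cos(theta),
                (R + r * np.cos(phi)) * np.sin(theta),
                r * np.sin(phi),
            ]
        )
    if spec.pattern == "spiral":
        # Conical spiral: radius grows linearly while the curve winds and
        # drifts vertically; topologically an arc (no holes or cavities).
        r0 = p.get("r_start", 0.5)
        r1 = p.get("r_end", 4.0)
        turns = p.get("turns", 3.0)
        height = p.get("height", 2.0)
        u = rng.uniform(0.0, 1.0, size=n)
        rho = r0 + (r1 - r0) * u
        ang = 2.0 * np.pi * turns * u
        return np.column_stack([rho * np.cos(ang), rho * np.sin(ang), height * u])
    raise ValueError(f"unknown pattern {spec.pattern!r}")


def generate_epoch(spec: EpochSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw ``spec.n_samples`` points from the epoch's pattern.

    Returns an ``n_samples x 3`` array (``n_samples x dim`` for a gaussian
    epoch with a ``dim`` override).  Manifold patterns receive additive
    isotropic N(0, noise_sd^2) observation noise; with ``noise_sd = 0`` the
    points satisfy the pattern's defining equation to machine precision.
    """
    pts = _pattern_points(spec, rng)
    if spec.noise_sd > 0 and spec.pattern != "gaussian":
        pts = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)
    return pts


def _example1_epochs(noise_sd: float) -> tuple:
    g = EpochSpec("gaussian", 3000, {"sd": 1.0})
    return (
        g,
        EpochSpec("circle", 3000, {"radius": 4.0}, noise_sd=noise_sd),
        g,
        EpochSpec("sphere", 3000, {"radius": 2.5}, noise_sd=noise_sd),
        g,
    )


def _example2_epochs(noise_sd: float) -> tuple:
    return (
        EpochSpec("infinity", 5000, {"scale": 4.0}, noise_sd=noise_sd),
        EpochSpec(
            "torus", 5000, {"major_radius": 3.0, "minor_radius": 1.0}, noise_sd=noise_sd
        ),
        EpochSpec(
            "spiral",
            5000,
            {"r_start": 0.5, "r_end": 4.0, "turns": 3.0, "height": 2.0},
            noise_sd=noise_sd,
        ),
    )


SCENARIO_NAMES = ("example1", "example2")


def build_scenario(
    name: str, noise_sd: float = 0.1, rng: np.random.Generator | None = None
) -> tuple[SignalMatrix, ScenarioPreset]:
    """Generate one of the two preset scenarios.

    ``example1``: five 30 s epochs of 3,000 samples at 100 Hz —
    Gaussian(sd 1), circle(radius 4), Gaussian, sphere(radius 2.5),
    Gaussian — analysed with window width 50.

    ``example2``: three 50 s epochs of 5,000 samples at 100 Hz —
    infinity, torus, spiral — analysed with window width 150.

    ``noise_sd`` is the observation noise added to the manifold epochs
    (default 0.1, so the point clouds are full-dimensional).
    """
    if rng is None:
        rng = np.random.default_rng()
    if name == "example1":
        epochs = _example1_epochs(noise_sd)
        preset = ScenarioPreset(name, epochs, sampling_rate=100.0, window_width=50)
    elif name == "example2":
        epochs = _example2_epochs(noise_sd)
        preset = ScenarioPreset(name, epochs, sampling_rate=100.0, window_width=150)
    else:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    segments = [generate_epoch(e, rng) for e in preset.epochs]
    values = np.concatenate(segments, axis=0)
    return SignalMatrix(values, sampling_rate=preset.sampling_rate), preset


def generate_brownian(
    n_samples: int, dt: float = 1.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Standard Brownian path: cumulative sum of N(0, dt) increments, B(0)=0."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    inc = rng.normal(0.0, np.sqrt(dt), size=n_samples - 1)
    out = np.empty(n_samples)
    out[0] = 0.0
    np.cumsum(inc, out=out[1:])
    return out


def generate_white_noise(
    n_samples: int, sd: float = 1.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """I.i.d. N(0, sd^2) series."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    return rng.normal(0.0, sd, size=n_samples)


def generate_smooth_curve(n_samples: int, t_max: float = 30.0) -> np.ndarray:
    """The smooth chirp ``x(t) = t cos(t^2/10)`` on an even grid over [0, t_max]."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    t = np.linspace(0.0, t_max, n_samples)
    return t * np.cos(t**2 / 10.0)


def generate_fbm(cfg: FBMConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Fractional Brownian motion by Davies-Harte circulant embedding.

    Exact-covariance simulation: the fractional Gaussian noise (increment)
    autocovariance ``gamma(h) = (|h+1|^{2H} - 2|h|^{2H} + |h-1|^{2H}) / 2``
    is embedded in a circulant matrix whose eigenvalues (computed by FFT)
    are non-negative for all H in (0, 1); sampling in the spectral domain
    then gives increments with exactly the fGn covariance.  The returned
    path starts at 0 and has ``Var[B_H(t_k)] = (k * dt)^{2H} * dt^{... }``
    — on the unit-``dt`` scale, ``Var[B_H(k)] = k^{2H}``; for general
    ``dt`` increments are scaled by ``dt^H`` (self-similarity).
    """
    if rng is None:
        rng = np.random.default_rng()
    H = cfg.hurst
    n = cfg.n_samples - 1  # number of increments
    # fGn autocovariance on lags 0..n-1
    h = np.arange(n, dtype=float)
    gamma = 0.5 * (
        np.abs(h + 1) ** (2 * H) - 2 * np.abs(h) ** (2 * H) + np.abs(h - 1) ** (2 * H)
    )
    # first row of the 2n-circulant embedding
    row = np.concatenate([gamma, [0.0], gamma[1:][::-1]])
    eig = np.fft.fft(row).real
    # eigenvalues are >= 0 in exact arithmetic; clip round-off negatives
    eig = np.clip(eig, 0.0, None)
    m = 2 * n
    z = rng.normal(size=m) + 1j * rng.normal(size=m)
    w = np.fft.fft(np.sqrt(eig / m) * z)
    # real and imaginary parts are two independent fGn draws; use the real one
    fgn = w[:n].real * cfg.dt**H
    out = np.empty(cfg.n_samples)
    out[0] = 0.0
    np.cumsum(fgn, out=out[1:])
    return out
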