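"""Structural-break test for total-persistence curves.

The test asks whether the mean of a total-persistence curve ``TP_k(t)``
changes over time.  Under the null hypothesis ``E[D_k(t)] = 0`` for all
``t``, where ``D_k(t) = TP_k(t) - mean(TP_k)`` are the deviations from
the global sample mean, the CUSUM path

    S_k(0) = 0,  S_k(t) = S_k(t-1) + D_k(t)

behaves like a random walk and therefore has Higuchi fractal dimension
close to 1.5.  A sustained mean shift makes the CUSUM drift smoothly,
pulling its fractal dimension toward 1.  The deviations are exchangeable
under the null, so a permutation reference distribution is built by
shuffling them, re-accumulating, and re-estimating the HFD; the p-value
is the add-one permutation tail probability.  By default the lower tail
is used (break => smoother CUSUM => smaller HFD); a two-sided variant
measures extremeness by ``|HFD - 1.5|``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import SignalMatrix, WindowConfig
from .fractal import HiguchiConfig, estimate_hfd
from .persistence import FiltrationParams, TPCurveSet, tv_total_persistence

__all__ = [
    "DeviationSeries",
    "CusumSeries",
    "BreakTestResult",
    "deviations",
    "cusum",
    "hfd_break_test",
    "run_full_test",
]


@dataclass(frozen=True)
class DeviationSeries:
    """Deviations of a TP curve from its global sample mean (sum to 0)."""

    d: np.ndarray
    mean_tp: float


@dataclass(frozen=True)
class CusumSeries:
    """Prefix sums of deviations including the leading S(0) = 0.

    Because the deviations are mean-centered the path also returns to 0
    at its last point (up to round-off).
    """

    s: np.ndarray


@dataclass(frozen=True)
class BreakTestResult:
    """Observed and permuted CUSUM fractal dimensions and the p-value."""

    observed_hfd: float
    permuted_hfds: np.ndarray
    p_value: float
    alternative: str
    n_permutations: int
    observed_cusum: np.ndarray
    mean_permuted_hfd: float


def deviations(tp: np.ndarray) -> DeviationSeries:
    """Mean-center a TP curve; raises on constant input (test undefined)."""
    tp = np.asarray(tp, dtype=float).ravel()
    if tp.size < 3:
        raise ValueError("need at least 3 values to form deviations")
    if np.all(tp == tp[0]):
        raise ValueError("constant series: deviations are degenerate")
    mean = float(tp.mean())
    return DeviationSeries(d=tp - mean, mean_tp=mean)


def cusum(dev: DeviationSeries) -> CusumSeries:
    """CUSUM path of the deviations, with the leading zero included."""
    s = np.empty(dev.d.size + 1)
    s[0] = 0.0
    np.cumsum(dev.d, out=s[1:])
    return CusumSeries(s=s)


def _cusum_hfd(d: np.ndarray, hcfg: HiguchiConfig) -> float:
    s = np.empty(d.size + 1)
    s[0] = 0.0
    np.cumsum(d, out=s[1:])
    return estimate_hfd(s, hcfg).hfd


def hfd_break_test(
    tp: np.ndarray,
    n_permutations: int = 999,
    hcfg: HiguchiConfig | None = None,
    alternative: str = "lower",
    rng: np.random.Generator | None = None,
) -> BreakTestResult:
    """Permutation test for a structural break in one TP curve.

    Parameters
    ----------
    tp
        The total-persistence curve (one value per window).
    n_permutations
        Number of random permutations B (>= 19); the p-value floor is
        ``1/(B+1)``.
    hcfg
        Higuchi settings for the CUSUM fractal dimension (kmax 10).
    alternative
        ``"lower"`` (default): a break smooths the CUSUM, so permuted
        HFDs at or below the observed one count as extreme.
        ``"two_sided"``: extremeness by distance from 1.5.
    rng
        Seeded generator; fixed state gives identical p-values.
    """
    if hcfg is None:
        hcfg = HiguchiConfig()
    if alternative not in ("lower", "two_sided"):
        raise ValueError('alternative must be "lower" or "two_sided"')
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations")
    if rng is None:
        rng = np.random.default_rng()
    tp = np.asarray(tp, dtype=float).ravel()
    if tp.size < 2 * hcfg.kmax + 2:
        raise ValueError(
            f"TP curve of length {tp.size} too short for kmax={hcfg.kmax}"
        )
    dev = deviations(tp)
    s_obs = cusum(dev)
    observed = estimate_hfd(s_obs.s, hcfg).hfd
    permuted = np.empty(n_permutations)
    for b in range(n_permutations):
        permuted[b] = _cusum_hfd(rng.permutation(dev.d), hcfg)
    if alternative == "lower":
        extreme = permuted <= observed
    else:
        extreme = np.abs(permuted - 1.5) >= abs(observed - 1.5)
    p = (1.0 + int(extreme.sum())) / (n_permutations + 1.0)
    return BreakTestResult(
        observed_hfd=float(observed),
        permuted_hfds=permuted,
        p_value=float(p),
        alternative=alternative,
        n_permutations=n_permutations,
        observed_cusum=s_obs.s,
        mean_permuted_hfd=float(permuted.mean()),
    )


def run_full_test(
    signal: SignalMatrix,
    win: WindowConfig,
    params: FiltrationParams | None = None,
    n_permutations: int = 999,
    hcfg: HiguchiConfig | None = None,
    alternative: str = "lower",
    rng: np.random.Generator | None = None,
    bonferroni: bool = False,
) -> tuple[dict, TPCurveSet]:
    """Full pipeline: TP curves then one break test per homology dimension.

    Each dimension's permutations come from an independent stream spawned
    from ``rng`` so that results per k are individually reproducible.
    Returns ``(results, curves)`` where ``results[k]`` is a
    :class:`BreakTestResult` (p-values Bonferroni-adjusted across the
    tested dimensions when ``bonferroni`` is set).
    """
    if params is None:
        params = FiltrationParams()
    if rng is None:
        rng = np.random.default_rng()
    curves = tv_total_persistence(signal, win, params)
    ks = list(range(params.max_homology_dim + 1))
    streams = rng.spawn(len(ks))
    results: dict[int, BreakTestResult] = {}
    for k, stream in zip(ks, streams):
        res = hfd_break_test(
            curves[k], n_permutations, hcfg, alternative, stream
        )
        if bonferroni:
            res = BreakTestResult(
                observed_hfd=res.observed_hfd,
                permuted_hfds=res.permuted_hfds,
                p_value=min(1.0, res.p_value * len(ks)),
                alternative=res.alternative,
                n_permutations=res.n_permutations,
                observed_cusum=res.observed_cusum,
                mean_permuted_hfd=res.mean_permuted_hfd,
            )
        results[k] = res
    return results, curves
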