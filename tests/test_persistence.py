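import numpy as np
import pytest

from tdabreak.embedding import SignalMatrix, WindowConfig
from tdabreak.persistence import (
    FiltrationParams,
    PersistenceDiagram,
    rips_diagram,
    total_persistence,
    tv_total_persistence,
)
from tdabreak.signals import EpochSpec, generate_epoch

from oracles import brute_rips_bars, mst_total_weight


def _bars(diag, k=None):
    return sorted(
        (b, d, int(dim)) for b, d, dim in zip(diag.births, diag.deaths, diag.dims)
        if k is None or dim == k
    )


class TestRipsDiagram:
    def test_two_points(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        diag = rips_diagram(pts)
        h0 = _bars(diag, 0)
        assert len(h0) == 2
        assert h0[0] == (0.0, 5.0, 0)
        assert np.isinf(h0[1][1])
        assert not _bars(diag, 1) and not _bars(diag, 2)

    def test_circle_has_one_dominant_loop(self, rng):
        cloud = generate_epoch(EpochSpec("circle", 50, {"radius": 4.0}), rng)
        diag = rips_diagram(cloud)
        pers = np.sort(
            [d - b for b, d, k in _bars(diag, 1)]
        )
        assert pers[-1] > 3 * (pers[-2] if len(pers) > 1 else 1e-12)
        # the loop of a dense circle dies near sqrt(3) * radius
        top = max(_bars(diag, 1), key=lambda bar: bar[1] - bar[0])
        assert top[1] == pytest.approx(np.sqrt(3) * 4.0, rel=0.1)

    def test_sphere_cavity_beats_matched_gaussian(self, rng):
        sphere = generate_epoch(EpochSpec("sphere", 150, {"radius": 2.5}), rng)
        gauss = rng.normal(size=(150, 3))
        h2 = lambda pts: max(
            (d - b for b, d, k in _bars(rips_diagram(pts), 2)), default=0.0
        )
        assert h2(sphere) > h2(gauss)

    def test_point_order_invariance(self, rng):
        pts = rng.normal(size=(20, 3))
        a = _bars(rips_diagram(pts))
        b = _bars(rips_diagram(pts[rng.permutation(20)]))
        np.testing.assert_allclose(
            [x[:2] for x in a], [x[:2] for x in b], atol=1e-12
        )

    def test_scale_equivariance(self, rng):
        pts = rng.normal(size=(15, 3))
        c = 2.7
        base = _bars(rips_diagram(pts))
        scaled = _bars(rips_diagram(c * pts))
        for (b1, d1, k1), (b2, d2, k2) in zip(base, scaled):
            assert k1 == k2
            assert b2 == pytest.approx(c * b1, abs=1e-10)
            if np.isfinite(d1):
                assert d2 == pytest.approx(c * d1, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rips_diagram(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            rips_diagram(np.array([[0.0, np.inf], [1.0, 2.0]]))


class TestOracleEquivalence:
    """The numba engine against textbook boundary-matrix reduction."""

    @pytest.mark.parametrize("seed", range(8))
    def test_small_cloud_diagrams_match(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        pts = rng.normal(size=(n, int(rng.integers(2, 4))))
        if seed % 3 == 0:
            pts = np.round(pts)  # force distance ties and duplicates
        mine = _bars(rips_diagram(pts, FiltrationParams(max_homology_dim=2)))
        oracle = [
            (b, d, k)
            for b, d, k in brute_rips_bars(pts, maxdim=2)
        ]
        oracle = sorted(oracle)
        assert len(mine) == len(oracle)
        for a, b in zip(mine, oracle):
            assert a[2] == b[2]
            assert a[0] == pytest.approx(b[0], abs=1e-12)
            assert np.isinf(a[1]) == np.isinf(b[1])
            if np.isfinite(a[1]):
                assert a[1] == pytest.approx(b[1], abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_tp0_equals_mst_weight(self, seed):
        rng = np.random.default_rng(100 + seed)
        pts = rng.normal(size=(int(rng.integers(3, 13)), 3))
        diag = rips_diagram(pts)
        assert total_persistence(diag, 0) == pytest.approx(
            mst_total_weight(pts), abs=1e-9
        )


class TestTotalPersistence:
    def _diag(self, features):
        b, d, k = (np.array(v, dtype=float) for v in zip(*features))
        return PersistenceDiagram(
            births=b, deaths=d, dims=k.astype(int), max_homology_dim=2, eps_max=5.0
        )

    def test_sum_of_finite_lifetimes(self):
        diag = self._diag([(0, 1, 1), (0.5, 2, 1)])
        assert total_persistence(diag, 1) == pytest.approx(2.5)

    def test_empty_dimension_is_zero(self):
        diag = self._diag([(0, 1, 0)])
        assert total_persistence(diag, 2) == 0.0

    def test_infinite_bars_excluded_or_capped(self):
        diag = self._diag([(0, np.inf, 0), (0, 0.7, 0)])
        assert total_persistence(diag, 0) == pytest.approx(0.7)
        # capped mode adds eps_max - birth for the essential bar
        assert total_persistence(diag, 0, cap_infinite=True) == pytest.approx(5.7)

    def test_k_beyond_diagram_rejected(self):
        diag = self._diag([(0, 1, 0)])
        object.__setattr__(diag, "max_homology_dim", 1)
        with pytest.raises(ValueError):
            total_persistence(diag, 2)


class TestTimeVaryingTP:
    def test_constant_signal_gives_zero_curves(self):
        s = SignalMatrix(np.ones((40, 3)) * 2.5)
        curves = tv_total_persistence(s, WindowConfig(10))
        for k in (0, 1, 2):
            np.testing.assert_array_equal(curves[k], 0.0)

    def test_epoch_peaks_in_example1(self, example1_curves):
        """Loops peak in the circle epoch, cavities in the sphere epoch."""
        t = example1_curves.times
        gauss = ((t < 30) | ((t >= 60) & (t < 90)) | (t >= 120))
        circle = (t >= 30) & (t < 60)
        sphere = (t >= 90) & (t < 120)
        tp1, tp2 = example1_curves[1], example1_curves[2]
        assert tp1[circle].mean() > tp1[gauss].mean()
        assert tp2[sphere].mean() > tp2[gauss].mean()

    def test_torus_epoch_dominates_example2_windows(self, rng):
        """One window per epoch of the lemniscate/torus/spiral design:
        the torus window carries the most loop and cavity persistence."""
        from tdabreak.signals import build_scenario

        signal, preset = build_scenario("example2", rng=rng)
        tp = {}
        for i, name in enumerate(["infinity", "torus", "spiral"]):
            cloud = signal.values[i * 5000 : i * 5000 + 150]
            diag = rips_diagram(cloud)
            tp[name] = (total_persistence(diag, 1), total_persistence(diag, 2))
        assert tp["torus"][0] > max(tp["infinity"][0], tp["spiral"][0])
        assert tp["torus"][1] > max(tp["infinity"][1], tp["spiral"][1])

    def test_times_are_window_ends(self, example1_curves):
        assert example1_curves.times[0] == pytest.approx(49 / 100.0)
        assert example1_curves.times[-1] == pytest.approx(14999 / 100.0)
        assert example1_curves.times.size == 300
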