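import numpy as np
import pytest

from tdabreak.signals import (
    EpochSpec,
    FBMConfig,
    build_scenario,
    generate_brownian,
    generate_epoch,
    generate_fbm,
    generate_smooth_curve,
    generate_white_noise,
)


class TestEpochPatterns:
    def test_gaussian_moments(self, rng):
        seg = generate_epoch(EpochSpec("gaussian", 3000, {"sd": 1.0}), rng)
        assert seg.shape == (3000, 3)
        tol = 4 / np.sqrt(3000)
        assert np.all(np.abs(seg.mean(axis=0)) < tol)
        assert np.all(np.abs(seg.std(axis=0) - 1.0) < tol)

    def test_noise_free_circle_on_circle(self, rng):
        seg = generate_epoch(EpochSpec("circle", 200, {"radius": 4.0}), rng)
        assert np.allclose(np.linalg.norm(seg, axis=1), 4.0, atol=1e-12)
        assert np.all(seg[:, 2] == 0.0)

    def test_noise_free_sphere_on_sphere(self, rng):
        seg = generate_epoch(EpochSpec("sphere", 200, {"radius": 2.5}), rng)
        assert np.allclose(np.linalg.norm(seg, axis=1), 2.5, atol=1e-12)

    def test_noise_free_torus_on_torus(self, rng):
        R, r = 3.0, 1.0
        seg = generate_epoch(
            EpochSpec("torus", 200, {"major_radius": R, "minor_radius": r}), rng
        )
        rho = np.hypot(seg[:, 0], seg[:, 1])
        assert np.allclose((rho - R) ** 2 + seg[:, 2] ** 2, r**2, atol=1e-12)

    def test_noise_free_infinity_on_lemniscate(self, rng):
        a = 4.0
        seg = generate_epoch(EpochSpec("infinity", 200, {"scale": a}), rng)
        x, y = seg[:, 0], seg[:, 1]
        # Gerono lemniscate: a^2 y^2 = x^2 (a^2 - x^2)
        assert np.allclose(a**2 * y**2, x**2 * (a**2 - x**2), atol=1e-9)
        assert np.all(seg[:, 2] == 0.0)

    def test_noise_perturbs_off_manifold(self, rng):
        spec = EpochSpec("circle", 500, {"radius": 4.0}, noise_sd=0.1)
        seg = generate_epoch(spec, rng)
        norms = np.linalg.norm(seg[:, :2], axis=1)
        assert norms.std() > 0.01  # no longer exactly on the circle
        assert abs(norms.mean() - 4.0) < 0.1

    @pytest.mark.parametrize(
        "bad",
        [
            dict(pattern="helix", n_samples=10),
            dict(pattern="gaussian", n_samples=0),
            dict(pattern="circle", n_samples=5, noise_sd=-1.0),
            dict(pattern="circle", n_samples=5, params={"radius": -2.0}),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            EpochSpec(**bad)

    def test_torus_radius_ordering_enforced(self, rng):
        spec = EpochSpec("torus", 5, {"major_radius": 1.0, "minor_radius": 2.0})
        with pytest.raises(ValueError, match="major_radius > minor_radius"):
            generate_epoch(spec, rng)


class TestScenarios:
    @pytest.mark.parametrize(
        "name, n_epochs, window", [("example1", 5, 50), ("example2", 3, 150)]
    )
    def test_preset_geometry(self, name, n_epochs, window, rng):
        signal, preset = build_scenario(name, rng=rng)
        assert signal.values.shape == (15000, 3)
        assert signal.sampling_rate == 100.0
        assert len(preset.epochs) == n_epochs
        assert preset.window_width == window
        assert preset.n_samples == 15000

    def test_example1_epoch_order(self, rng):
        _, preset = build_scenario("example1", rng=rng)
        assert [e.pattern for e in preset.epochs] == [
            "gaussian", "circle", "gaussian", "sphere", "gaussian",
        ]
        assert preset.epochs[1].params["radius"] == 4.0
        assert preset.epochs[3].params["radius"] == 2.5

    def test_fixed_seed_bit_identical(self):
        a, _ = build_scenario("example1", rng=np.random.default_rng(11))
        b, _ = build_scenario("example1", rng=np.random.default_rng(11))
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            build_scenario("example3")


class TestUnivariateProcesses:
    def test_brownian_starts_at_zero_and_scales(self, rng):
        x = generate_brownian(10_000, dt=0.25, rng=rng)
        assert x[0] == 0.0
        inc = np.diff(x)
        assert abs(inc.var() - 0.25) < 0.02

    def test_white_noise_sd(self, rng):
        x = generate_white_noise(10_000, sd=3.0, rng=rng)
        assert abs(x.std() - 3.0) < 0.15

    def test_smooth_curve_closed_form(self):
        x = generate_smooth_curve(101, t_max=30.0)
        t = np.linspace(0, 30, 101)
        np.testing.assert_allclose(x, t * np.cos(t**2 / 10))

    def test_fbm_half_is_brownian(self):
        # H = 0.5: increments uncorrelated at lag 1
        x = generate_fbm(FBMConfig(0.5, 4097), np.random.default_rng(1))
        d = np.diff(x)
        rho = np.corrcoef(d[:-1], d[1:])[0, 1]
        assert abs(rho) < 3 / np.sqrt(d.size)
        assert x[0] == 0.0

    @pytest.mark.parametrize("hurst", [0.3, 0.7])
    def test_fbm_increment_variance_scaling(self, hurst):
        # Var[B_H(t+s) - B_H(t)] ~ s^{2H}, checked at two lags
        n = 2**12
        rng = np.random.default_rng(42)
        paths = np.array(
            [generate_fbm(FBMConfig(hurst, n), rng) for _ in range(40)]
        )
        for lag in (4, 32):
            v = np.concatenate(
                [p[lag:] - p[:-lag] for p in paths]
            ).var()
            assert abs(v / lag ** (2 * hurst) - 1.0) < 0.15

    def test_fbm_hurst_validation(self):
        with pytest.raises(ValueError, match="hurst"):
            FBMConfig(1.2, 100)
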