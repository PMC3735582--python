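"""Penetration profiling: extraction, normalization, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stain3d import diffusion, synthetic
from stain3d.diffusion import (
    DegenerateProfileError,
    average_ensemble,
    extract_profiles,
    find_edge,
    normalize_amplitude,
    normalize_distance,
)
from stain3d.synthetic import DiffusionSpec, simulate_diffusion_profile
from stain3d.types import ChannelVolume, LineProfile


def analytic_profiles(times, n_samples=2000, depth=2.0, noise_sd=0.0, seed=0, normalize=True):
    spec = DiffusionSpec(noise_sd=noise_sd)
    x = np.linspace(0, depth, n_samples)
    out = []
    for i, t in enumerate(times):
        y = simulate_diffusion_profile(spec, t, x, seed=seed * 1000 + i)
        p = normalize_distance(LineProfile(x, y, incubation_time=t))
        out.append(normalize_amplitude(p) if normalize else p)
    return out


class TestExtractProfiles:
    def test_half_plane_gradient_recovered_in_each_of_20_lines(self):
        # intensity depends on column only; edge = left image border
        ncol = 80
        ramp = np.linspace(5.0, 1.0, ncol)
        img = ChannelVolume(np.tile(ramp, (100, 1)), pixel_size=0.01)
        edge = np.column_stack([np.linspace(10, 89, 50), np.zeros(50)])
        profiles = extract_profiles(img, edge=edge, n_lines=20, depth=0.5)
        assert len(profiles) == 20
        expected = ramp[:51]
        for p in profiles:
            np.testing.assert_allclose(p.intensity, expected, rtol=1e-9)

    def test_constant_image_gives_constant_profiles(self):
        img = ChannelVolume(np.full((64, 64), 4.2), pixel_size=0.02)
        edge = np.column_stack([np.linspace(5, 58, 30), np.full(30, 2.0)])
        for p in extract_profiles(img, edge=edge, n_lines=10, depth=0.6):
            np.testing.assert_allclose(p.intensity, 4.2)

    def test_rendered_erfc_front_roundtrips_to_simulated_profile(self):
        spec = DiffusionSpec(D=0.02, noise_sd=0.0)
        t = 24.0
        px = 0.005
        ncol = 300
        x = np.arange(ncol) * px
        truth = simulate_diffusion_profile(spec, t, x)
        img = ChannelVolume(np.tile(truth, (120, 1)), pixel_size=px, incubation_time=t)
        edge = np.column_stack([np.linspace(20, 99, 40), np.zeros(40)])
        profiles = extract_profiles(img, edge=edge, n_lines=5, depth=1.0)
        n = len(profiles[0].distance)
        for p in profiles:
            np.testing.assert_allclose(p.intensity, truth[:n], rtol=1e-3)

    def test_normal_exiting_image_truncates_and_flags(self):
        img = ChannelVolume(np.ones((40, 40)), pixel_size=0.1)
        edge = np.column_stack([np.linspace(5, 35, 20), np.full(20, 30.0)])
        profiles = extract_profiles(img, edge=edge, n_lines=5, depth=10.0)
        assert profiles and all(p.truncated for p in profiles)

    def test_edge_outside_image_rejected(self):
        img = ChannelVolume(np.ones((40, 40)), pixel_size=0.1)
        with pytest.raises(ValueError, match="within the image"):
            extract_profiles(img, edge=np.array([[0.0, 0.0], [50.0, 50.0]]))

    def test_otsu_edge_detection_finds_tissue_contour(self):
        img = np.zeros((128, 128))
        rr, cc = np.mgrid[0:128, 0:128]
        img[(rr - 64) ** 2 + (cc - 64) ** 2 < 40**2] = 100.0
        edge = find_edge(ChannelVolume(img, 0.02))
        radii = np.hypot(edge[:, 0] - 64, edge[:, 1] - 64)
        assert np.all(np.abs(radii - 40) < 4)


class TestNormalizeDistance:
    def test_sqrt_four_hours_halves_the_axis(self):
        p = LineProfile([0.0, 1.0, 2.0], [3.0, 2.0, 1.0], incubation_time=4.0)
        np.testing.assert_allclose(normalize_distance(p).distance, [0.0, 0.5, 1.0])

    def test_one_hour_is_identity(self):
        p = LineProfile([0.0, 1.0, 2.0], [3.0, 2.0, 1.0], incubation_time=1.0)
        np.testing.assert_array_equal(normalize_distance(p).distance, p.distance)

    def test_free_profiles_at_5_and_45_hours_coincide_after_scaling(self):
        # sample each time at x = s * sqrt(t) so scaled grids match exactly
        spec = DiffusionSpec(noise_sd=0.0, times=(5.0, 45.0))
        s = np.linspace(0, 0.5, 400)
        scaled = []
        for t in spec.times:
            y = simulate_diffusion_profile(spec, t, s * np.sqrt(t))
            scaled.append(normalize_distance(LineProfile(s * np.sqrt(t), y, incubation_time=t)))
        np.testing.assert_allclose(scaled[0].distance, scaled[1].distance, atol=1e-12)
        assert np.max(np.abs(scaled[0].intensity - scaled[1].intensity)) < 1e-9

    def test_missing_time_raises(self):
        with pytest.raises(ValueError, match="incubation_time"):
            normalize_distance(LineProfile([0.0, 1.0], [1.0, 0.5]))


class TestNormalizeAmplitude:
    def test_exact_cubic_normalizes_origin_exactly(self):
        x = np.linspace(0, 1, 50)
        cubic = 2.0 - 0.5 * x + 0.3 * x**2 - 0.1 * x**3
        out = normalize_amplitude(LineProfile(x, cubic, incubation_time=1.0))
        assert out.intensity[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(out.intensity, cubic / 2.0, rtol=1e-10)

    def test_constant_profile_becomes_unity(self):
        x = np.linspace(0, 1, 20)
        out = normalize_amplitude(LineProfile(x, np.full(20, 3.3), incubation_time=1.0))
        np.testing.assert_allclose(out.intensity, 1.0, atol=1e-12)

    def test_noisy_erfc_origin_estimate_within_5pct(self):
        errs = []
        spec = DiffusionSpec(noise_sd=0.02)
        x = np.linspace(0, 2, 200)
        for seed in range(100):
            y = simulate_diffusion_profile(spec, 24.0, x, seed=seed)
            normed = normalize_amplitude(LineProfile(x, y, incubation_time=24.0))
            # fitted amplitude = raw / normalized at any sample
            a_hat = y[10] / normed.intensity[10]
            errs.append(abs(a_hat - spec.C0))
        assert max(errs) < 0.05 * spec.C0

    def test_negative_origin_raises_degenerate_error(self):
        x = np.linspace(0, 1, 30)
        with pytest.raises(DegenerateProfileError):
            normalize_amplitude(LineProfile(x, x - 1.0, incubation_time=1.0))

    def test_idempotent_to_machine_precision(self):
        spec = DiffusionSpec(noise_sd=0.02)
        x = np.linspace(0, 2, 150)
        y = simulate_diffusion_profile(spec, 10.0, x, seed=1)
        once = normalize_amplitude(LineProfile(x, y, incubation_time=10.0))
        twice = normalize_amplitude(once)
        np.testing.assert_allclose(twice.intensity, once.intensity, atol=1e-12)


class TestAverageEnsemble:
    def test_identical_profiles_have_zero_width_band(self):
        p = analytic_profiles([24.0])[0]
        ens = average_ensemble([p, p, p])
        np.testing.assert_allclose(ens.mean_intensity, np.interp(
            ens.scaled_distance, p.distance, p.intensity))
        np.testing.assert_allclose(ens.ci90_high - ens.ci90_low, 0.0, atol=1e-12)

    def test_two_profiles_average_pointwise(self):
        x = np.linspace(0, 1, 40)
        a = LineProfile(x, np.linspace(1, 0, 40), incubation_time=1.0)
        b = LineProfile(x, np.linspace(3, 1, 40), incubation_time=1.0)
        ens = average_ensemble([a, b])
        np.testing.assert_allclose(
            ens.mean_intensity, (a.intensity + b.intensity) / 2.0, rtol=1e-12
        )
        assert ens.n_profiles == 2

    def test_band_ordering_invariant(self):
        profs = analytic_profiles([5.0, 10.0, 24.0], noise_sd=0.02, seed=3)
        ens = average_ensemble(profs, allow_mixed_conditions=True)
        assert np.all(ens.ci90_low <= ens.mean_intensity + 1e-12)
        assert np.all(ens.mean_intensity <= ens.ci90_high + 1e-12)
        assert 0.9 <= ens.mean_intensity[0] <= 1.1

    def test_permutation_invariance(self):
        profs = analytic_profiles([5.0, 10.0, 24.0, 48.0], noise_sd=0.05, seed=7)
        a = average_ensemble(profs)
        b = average_ensemble(profs[::-1])
        np.testing.assert_allclose(a.mean_intensity, b.mean_intensity, rtol=1e-12)
        np.testing.assert_allclose(a.ci90_low, b.ci90_low, rtol=1e-12, atol=1e-12)

    def test_mixed_conditions_require_explicit_opt_in(self):
        x = np.linspace(0, 1, 10)
        a = LineProfile(x, np.ones(10), incubation_time=1.0, condition="4C")
        b = LineProfile(x, np.ones(10), incubation_time=1.0, condition="37C")
        with pytest.raises(ValueError, match="mixed condition"):
            average_ensemble([a, b])
        assert average_ensemble([a, b], allow_mixed_conditions=True).condition == "mixed"


def test_sqrt_time_collapse_of_free_diffusion():
    """Noiseless free-diffusion profiles at 5/10/24/48 h collapse to one
    curve on the x/sqrt(t) axis."""
    profs = analytic_profiles([5.0, 10.0, 24.0, 48.0], normalize=False)
    grid = np.linspace(0, min(p.distance[-1] for p in profs), 500)
    stack = np.vstack([np.interp(grid, p.distance, p.intensity) for p in profs])
    assert stack.std(axis=0, ddof=1).max() < 1e-6  # amplitude C0 = 1


@settings(max_examples=20, deadline=None)
@given(t=st.floats(min_value=0.5, max_value=100.0))
def test_distance_scaling_preserves_intensity(t):
    x = np.linspace(0, 1, 50)
    y = np.exp(-x)
    p = LineProfile(x, y, incubation_time=t)
    out = normalize_distance(p)
    np.testing.assert_array_equal(out.intensity, y)
    np.testing.assert_allclose(out.distance * np.sqrt(t), x, atol=1e-12)
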