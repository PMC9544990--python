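"""Phantom simulator: geometry rendering, correlated noise, dose scaling."""

import numpy as np
import pytest

import ctqa
from ctqa.phantom import (
    AcquisitionPlan,
    Insert,
    NoiseSpectrum,
    PhantomGeometry,
    ReconPreset,
    correlated_noise_field,
    noise_sd_at_dose,
    render_truth,
    simulate_stack,
)

PIX = 250.0 / 512.0


def interior_mask(n, pixel_mm, center_mm, radius_mm, margin_mm=1.5):
    coords = (np.arange(n) + 0.5) * pixel_mm - n * pixel_mm / 2
    x, y = coords[None, :], coords[:, None]
    return (x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2 <= (radius_mm - margin_mm) ** 2


class TestRenderTruth:
    def test_uniform_phantom(self):
        g = PhantomGeometry()
        img = render_truth(g, 256, 1.0)
        coords = (np.arange(256) + 0.5) - 128
        r = np.hypot(coords[None, :], coords[:, None])
        assert np.all(img[r <= 98] == 0.0)
        assert np.all(img[r >= 102] == -1000.0)

    def test_polyethylene_insert_mean(self):
        g = PhantomGeometry(inserts=(Insert("poly", (-45, 0), 25.0, -95.0),))
        img = render_truth(g, 512, PIX)
        inner = interior_mask(512, PIX, (-45, 0), 12.5)
        assert img[inner].mean() == pytest.approx(-95.0, abs=0.5)

    def test_resolution_refinement(self):
        g = PhantomGeometry(inserts=(Insert("poly", (-45, 0), 25.0, -95.0),))
        means = []
        for n in (256, 512):
            img = render_truth(g, n, 250.0 / n)
            inner = interior_mask(n, 250.0 / n, (-45, 0), 12.5, margin_mm=2.0)
            means.append(img[inner].mean())
        assert abs(means[1] - means[0]) < 0.1

    def test_insert_outside_body_rejected(self):
        with pytest.raises(ValueError, match="inside the body"):
            PhantomGeometry(inserts=(Insert("far", (95, 0), 25.0, -95.0),))

    def test_duplicate_labels_rejected(self):
        ins = Insert("a", (0, 0), 10.0, -95.0)
        with pytest.raises(ValueError, match="unique"):
            PhantomGeometry(inserts=(ins, Insert("a", (30, 0), 10.0, -1000.0)))

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            render_truth(PhantomGeometry(), 64, 1.0)


class TestCorrelatedNoise:
    def test_white_noise_sd(self):
        f = correlated_noise_field((512, 512), PIX, 10.0, NoiseSpectrum(0), seed=1)
        assert f.std() == pytest.approx(10.0, rel=0.02)
        assert abs(f.mean()) < 1e-9

    def test_determinism(self):
        a = correlated_noise_field((128, 128), PIX, 10.0, NoiseSpectrum(0.5), seed=42)
        b = correlated_noise_field((128, 128), PIX, 10.0, NoiseSpectrum(0.5), seed=42)
        assert np.array_equal(a, b)

    def test_colored_sd_rescaled_exactly(self):
        f = correlated_noise_field((128, 128), PIX, 7.5, NoiseSpectrum(1.0), seed=3)
        assert f.std() == pytest.approx(7.5, rel=1e-6)

    def test_texture_ordering(self, rng):
        """Higher f_peak shifts the ensemble spectrum to higher frequencies."""
        centroids = []
        for f_peak in (0.5, 2.0):
            fields = correlated_noise_field(
                (64, 64), PIX, 10.0, NoiseSpectrum(f_peak), seed=5, n_fields=100
            )
            spec = (np.abs(np.fft.fft2(fields)) ** 2).mean(axis=0)
            fr = np.hypot(*np.meshgrid(np.fft.fftfreq(64, PIX), np.fft.fftfreq(64, PIX)))
            centroids.append((fr * spec).sum() / spec.sum())
        assert centroids[1] > centroids[0]

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            correlated_noise_field((64, 64), PIX, 0.0, seed=1)


class TestSimulateStack:
    plan = AcquisitionPlan(
        ctdivol_levels=(9.5, 2.375),
        reference_dose=9.5,
        reference_noise_sd=10.0,
        n_slices_per_acquisition=25,
        n_acquisitions=2,
        seed=9,
        n_pixels=128,
        pixel_mm=1.0,
    )
    geometry = PhantomGeometry(body_diameter=100.0)
    preset = ReconPreset("p", psf_sigma=0.8, noise_scale=1.0, nps_shape=NoiseSpectrum(0.2))

    def background_sds(self, stack):
        inner = interior_mask(128, 1.0, (0, 0), 50.0, margin_mm=15.0)
        return stack.pixels[:, inner].std(axis=1)

    def test_reference_dose_sd(self):
        stack = simulate_stack(self.geometry, self.preset, self.plan, 9.5)
        sds = self.background_sds(stack)
        assert sds.mean() == pytest.approx(10.0, rel=0.05)

    def test_quarter_dose_doubles_sd(self):
        hi = simulate_stack(self.geometry, self.preset, self.plan, 9.5)
        lo = simulate_stack(self.geometry, self.preset, self.plan, 9.5 / 4)
        ratio = self.background_sds(lo).mean() / self.background_sds(hi).mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_dose_sqrt_law_across_plan(self):
        doses = (9.5, 7.5, 6.0, 2.5, 0.4)
        plan = AcquisitionPlan(
            ctdivol_levels=doses, reference_dose=9.5, reference_noise_sd=10.0,
            n_slices_per_acquisition=25, n_acquisitions=2, seed=2,
            n_pixels=128, pixel_mm=1.0,
        )
        for dose in doses:
            stack = simulate_stack(self.geometry, self.preset, plan, dose)
            expected = noise_sd_at_dose(plan, self.preset, dose)
            assert self.background_sds(stack).mean() == pytest.approx(expected, rel=0.05)

    def test_determinism_and_module_separation(self):
        a = simulate_stack(self.geometry, self.preset, self.plan, 9.5, module="nps")
        b = simulate_stack(self.geometry, self.preset, self.plan, 9.5, module="nps")
        c = simulate_stack(self.geometry, self.preset, self.plan, 9.5, module="ttf")
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_truth_metadata_attached(self):
        stack = simulate_stack(self.geometry, self.preset, self.plan, 2.375)
        assert stack.dose_mgy == 2.375
        assert stack.truth["psf_sigma_mm"] == 0.8
        assert stack.truth["noise_sd"] == pytest.approx(20.0)
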