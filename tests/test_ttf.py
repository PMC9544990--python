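"""Circular-edge TTF: composites, CNR gate, ESF binning and conditioning."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.special import erf

import ctqa
from ctqa.phantom import (
    AcquisitionPlan,
    Insert,
    PhantomGeometry,
    ReconPreset,
    render_truth,
    simulate_stack,
)
from ctqa.stack import ImageStack
from ctqa.ttf import (
    ESFProfile,
    bin_esf,
    composite_image,
    condition_esf,
    esf_to_ttf,
    estimate_center,
    measure_cnr_total,
    measure_ttf,
    ttf50_of,
)

PIX = 250.0 / 512.0
GEOM = PhantomGeometry(inserts=(Insert("poly", (-45, 0), 25.0, -95.0),))
CENTER = (256 - 0.5, 256 - 0.5 - 45 / PIX)  # pixel coords of the insert axis


def gaussian_truth(sigma_mm, geometry=GEOM, n=512, pixel_mm=PIX):
    truth = render_truth(geometry, n, pixel_mm)
    return ndimage.gaussian_filter(truth, sigma_mm / pixel_mm, mode="nearest")


class TestComposite:
    def test_single_slice_identity(self, rng):
        pix = rng.normal(size=(1, 32, 32)).astype(np.float32)
        stack = ImageStack(pix, 1.0)
        assert np.array_equal(composite_image(stack), pix[0])

    def test_noise_reduction_sqrt_n(self, rng):
        pix = rng.normal(0, 30.0, size=(150, 64, 64)).astype(np.float32)
        stack = ImageStack(pix, 1.0)
        comp = composite_image(stack)
        assert comp.std() == pytest.approx(30.0 / np.sqrt(150), rel=0.10)

    def test_noiseless_mean_preserved(self):
        truth = gaussian_truth(0.8)
        stack = ImageStack(np.repeat(truth[None], 5, axis=0), PIX)
        assert np.allclose(composite_image(stack), truth, atol=1e-4)

    def test_empty_selection_rejected(self):
        stack = ImageStack(np.zeros((3, 8, 8)), 1.0)
        with pytest.raises(ValueError, match="empty"):
            composite_image(stack, [])


class TestCnrTotal:
    def test_direct_arithmetic(self, rng):
        comp = np.zeros((64, 64))
        insert = np.zeros_like(comp, dtype=bool)
        background = np.zeros_like(comp, dtype=bool)
        insert[:16] = True
        background[32:] = True
        noise = rng.normal(size=background.sum())
        comp[background] = 5.0 * (noise - noise.mean()) / noise.std()
        comp[insert] = -95.0
        assert measure_cnr_total(comp, insert, background) == pytest.approx(19.0)

    def test_zero_contrast(self):
        comp = np.zeros((16, 16))
        comp[8:] = 1e-12
        m1 = np.zeros_like(comp, dtype=bool); m1[:4] = True
        m2 = np.zeros_like(comp, dtype=bool); m2[12:] = True
        comp[m2] += np.linspace(-1, 1, comp[m2].size).reshape(-1)
        assert measure_cnr_total(comp, m1, m2) < 0.1

    def test_zero_background_sd_is_infinite(self):
        comp = np.zeros((16, 16)); comp[:4] = -95.0
        m1 = np.zeros_like(comp, dtype=bool); m1[:4] = True
        m2 = np.zeros_like(comp, dtype=bool); m2[12:] = True
        assert measure_cnr_total(comp, m1, m2) == np.inf

    def test_overlapping_rois_rejected(self):
        comp = np.zeros((16, 16))
        m = np.ones_like(comp, dtype=bool)
        with pytest.raises(ValueError, match="disjoint"):
            measure_cnr_total(comp, m, m)


class TestEstimateCenter:
    def test_symmetric_disc_exact(self):
        truth = gaussian_truth(0.8)
        cy, cx = estimate_center(truth, CENTER, 12.5 / PIX, background_hu=0.0)
        assert cy == pytest.approx(CENTER[0], abs=0.05)
        assert cx == pytest.approx(CENTER[1], abs=0.05)

    def test_subpixel_offset_recovered(self):
        g = PhantomGeometry(inserts=(Insert("poly", (-45.17, 0.23), 25.0, -95.0),))
        truth = gaussian_truth(0.8, geometry=g)
        approx = (256 - 0.5 + 0.23 / PIX, 256 - 0.5 - 45.17 / PIX)
        cy, cx = estimate_center(truth, (approx[0] - 1, approx[1] + 1), 12.5 / PIX,
                                 background_hu=0.0)
        assert cy == pytest.approx(approx[0], abs=0.2)
        assert cx == pytest.approx(approx[1], abs=0.2)

    def test_noisy_composite_within_half_pixel(self):
        plan = AcquisitionPlan(reference_noise_sd=10.0, seed=21)
        preset = ReconPreset("p", psf_sigma=0.8)
        stack = simulate_stack(GEOM, preset, plan, 9.5, n_slices=150, module="ttf")
        comp = composite_image(stack)
        cy, cx = estimate_center(comp, CENTER, 12.5 / PIX, background_hu=0.0)
        assert np.hypot(cy - CENTER[0], cx - CENTER[1]) < 0.5

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            estimate_center(np.zeros((64, 64)), (32, 32), 10.0, background_hu=0.0)


class TestBinEsf:
    def test_sharp_disc_step_position(self):
        truth = render_truth(GEOM, 512, PIX)
        esf = bin_esf(truth, CENTER, 12.5, PIX)
        mid = -95.0 / 2.0
        crossing = esf.radii[np.argmax(esf.values >= mid)]
        assert abs(crossing) <= 2 * esf.bin_width

    def test_gaussian_edge_matches_erf(self):
        sigma = 0.8
        blurred = gaussian_truth(sigma)
        esf = bin_esf(blurred, CENTER, 12.5, PIX)
        oracle = -95.0 * 0.5 * (1.0 - erf(esf.radii / (sigma * np.sqrt(2))))
        rms = np.sqrt(((esf.values - oracle) ** 2).mean())
        assert rms < 1.0

    def test_bin_refinement_consistent(self):
        sigma = 0.8
        blurred = gaussian_truth(sigma)
        rms = []
        for bw in (0.2, 0.1, 0.05):
            esf = bin_esf(blurred, CENTER, 12.5, PIX, bin_width_px=bw)
            oracle = -95.0 * 0.5 * (1.0 - erf(esf.radii / (sigma * np.sqrt(2))))
            rms.append(np.sqrt(((esf.values - oracle) ** 2).mean()))
        assert rms[2] < 2 * rms[0] + 0.2  # refining bins does not blow up error


class TestConditioning:
    def noisy_esf(self, seed=3, sd=1.0):
        rng = np.random.default_rng(seed)
        radii = np.linspace(-6, 12, 360)
        clean = -95.0 * 0.5 * (1.0 - erf(radii / (0.8 * np.sqrt(2))))
        return clean, ESFProfile(radii=radii, values=clean + rng.normal(0, sd, 360),
                                 bin_width=radii[1] - radii[0])

    def test_gate_threshold_boundary(self):
        _, esf = self.noisy_esf()
        assert condition_esf(esf, 15.001).conditioned is False
        assert condition_esf(esf, 15.0).conditioned is False
        assert condition_esf(esf, 14.999).conditioned is True

    def test_gate_off_returns_unchanged(self):
        _, esf = self.noisy_esf()
        out = condition_esf(esf, 20.0)
        assert np.array_equal(out.values, esf.values)

    def test_monotone_input_unchanged(self):
        radii = np.linspace(-6, 12, 360)
        clean = -95.0 * 0.5 * (1.0 - erf(radii / (0.8 * np.sqrt(2))))
        esf = ESFProfile(radii=radii, values=clean, bin_width=radii[1] - radii[0])
        out = condition_esf(esf, 5.0)
        assert out.conditioned is True
        assert np.allclose(out.values, clean)

    def test_conditioned_profile_monotone_and_accurate(self):
        clean, esf = self.noisy_esf(sd=1.2)
        out = condition_esf(esf, 10.0)
        assert np.all(np.diff(out.values) >= 0)
        rms = np.sqrt(((out.values - clean) ** 2).mean())
        assert rms < 2.0
        n20 = out.values.size // 5
        assert out.values[:n20].mean() == pytest.approx(-95.0, abs=1.0)


class TestEsfToTtf:
    def esf_of(self, sigma):
        blurred = gaussian_truth(sigma)
        return bin_esf(blurred, CENTER, 12.5, PIX)

    def test_gaussian_transfer_recovered(self):
        sigma = 0.8
        freqs, ttf = esf_to_ttf(self.esf_of(sigma))
        assert ttf[0] == pytest.approx(1.0)
        expected50 = np.sqrt(np.log(2) / (2 * np.pi**2 * sigma**2))
        assert ttf50_of(freqs, ttf) == pytest.approx(expected50, rel=0.05)
        f10 = np.sqrt(np.log(10) / (2 * np.pi**2 * sigma**2))
        band = freqs <= f10
        oracle = np.exp(-2 * np.pi**2 * sigma**2 * freqs[band] ** 2)
        assert np.abs(ttf[band] - oracle).max() < 0.03

    def test_sigma_doubling_halves_ttf50(self):
        f1, t1 = esf_to_ttf(self.esf_of(0.8))
        f2, t2 = esf_to_ttf(self.esf_of(1.6))
        assert ttf50_of(f2, t2) / ttf50_of(f1, t1) == pytest.approx(0.5, rel=0.05)

    def test_step_edge_near_bin_nyquist(self):
        radii = np.arange(-5, 10, 0.05)
        values = np.where(radii < 0.013, -95.0, 0.0)
        esf = ESFProfile(radii=radii, values=values, bin_width=0.05)
        freqs, ttf = esf_to_ttf(esf)
        assert ttf50_of(freqs, ttf) >= 0.8 * (1 / (2 * 0.05))

    def test_flat_profile_rejected(self):
        esf = ESFProfile(radii=np.linspace(0, 1, 50), values=np.zeros(50),
                         bin_width=0.02)
        with pytest.raises(ValueError, match="flat ESF"):
            esf_to_ttf(esf)


class TestMeasureTtf:
    def test_contrast_sign_invariance(self):
        """Air (-1000) and polyethylene (-95) inserts with equal blur give equal TTF."""
        g = PhantomGeometry(inserts=(
            Insert("poly", (-45, 0), 25.0, -95.0),
            Insert("air", (45, 0), 25.0, -1000.0),
        ))
        truth = gaussian_truth(0.8, geometry=g)
        stack = ImageStack(truth[None].astype(np.float32), PIX,
                           truth={"geometry": g})
        a = measure_ttf(stack, "poly")
        b = measure_ttf(stack, "air")
        assert a.ttf50 == pytest.approx(b.ttf50, rel=0.02)
        assert a.contrast == pytest.approx(-95.0, abs=1.5)
        assert b.contrast == pytest.approx(-1000.0, abs=3.0)

    def test_pooling_reduces_ttf50_spread(self):
        """150-slice composites give tighter ttf50 estimates than 30-slice ones."""
        g = PhantomGeometry(
            body_diameter=120.0,
            inserts=(Insert("poly", (-25, 0), 25.0, -95.0),),
        )
        preset = ReconPreset("p", psf_sigma=1.2)
        est = {30: [], 150: []}
        for seed in range(8):
            plan = AcquisitionPlan(reference_noise_sd=25.0, seed=seed,
                                   n_pixels=128, pixel_mm=1.0)
            stack = simulate_stack(g, preset, plan, 9.5, n_slices=150, module="ttf")
            est[150].append(measure_ttf(stack, "poly").ttf50)
            sub = ImageStack(stack.pixels[:30], stack.pixel_mm, truth=stack.truth)
            est[30].append(measure_ttf(sub, "poly").ttf50)
        assert np.var(est[150]) < np.var(est[30])

    def test_conditioning_triggers_at_low_dose(self):
        """High noise drives CNR below 15; conditioned ttf50 stays accurate."""
        plan = AcquisitionPlan(reference_noise_sd=85.0, seed=7)
        preset = ReconPreset("noisy", psf_sigma=0.8)
        stack = simulate_stack(GEOM, preset, plan, 9.5, n_slices=150, module="ttf")
        res = measure_ttf(stack, "poly")
        assert res.cnr_total < 15
        assert res.conditioning_applied
        expected50 = np.sqrt(np.log(2) / (2 * np.pi**2 * 0.8**2))
        assert res.ttf50 == pytest.approx(expected50, rel=0.07)
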