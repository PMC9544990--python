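"""Synthetic ACR-like phantom simulator.

Generates seeded stacks of axial slices of a cylindrical quality-assurance
phantom (uniform water-equivalent body, optional circular inserts such as
air at -1000 HU and polyethylene at -95 HU).  A reconstruction preset is
emulated by a Gaussian in-plane point-spread function plus stationary
correlated noise whose power spectrum follows a band-pass shape, and the
noise standard deviation scales with dose as 1/sqrt(CTDIvol).

Every stack carries its generating ground truth (noiseless image, PSF
width, noise spectrum) so the downstream NPS/TTF/detectability estimators
can be validated against known answers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .stack import ImageStack

AIR_HU = -1000.0

__all__ = [
    "AIR_HU",
    "Insert",
    "PhantomGeometry",
    "NoiseSpectrum",
    "ReconPreset",
    "AcquisitionPlan",
    "render_truth",
    "correlated_noise_field",
    "noise_sd_at_dose",
    "simulate_stack",
    "gaussian_mtf",
]


@dataclass(frozen=True)
class Insert:
    """A circular insert: ``center_offset`` is (x, y) mm from the body axis."""

    label: str
    center_offset: tuple[float, float]
    diameter: float
    hu: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"insert {self.label!r}: diameter must be > 0")


@dataclass(frozen=True)
class PhantomGeometry:
    """Cylindrical body phantom with circular inserts.

    Defaults emulate a 20-cm QA phantom with a water-equivalent
    (0 HU) background; everything outside the body disc is air.
    """

    body_diameter: float = 200.0
    background_hu: float = 0.0
    inserts: tuple[Insert, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "inserts", tuple(self.inserts))
        labels = [ins.label for ins in self.inserts]
        if len(set(labels)) != len(labels):
            raise ValueError("insert labels must be unique")
        r_body = self.body_diameter / 2.0
        for ins in self.inserts:
            cx, cy = ins.center_offset
            if np.hypot(cx, cy) + ins.diameter / 2.0 > r_body:
                raise ValueError(
                    f"insert {ins.label!r} does not lie fully inside the body disc"
                )

    def insert(self, label: str) -> Insert:
        for ins in self.inserts:
            if ins.label == label:
                return ins
        raise KeyError(label)


@dataclass(frozen=True)
class NoiseSpectrum:
    """Radially symmetric noise-power shape.

    ``f_peak == 0`` gives white noise.  For ``f_peak > 0`` the shape is the
    band-pass ``S(f) = f * exp(-f / f_peak)`` whose maximum sits at
    ``f_peak`` (cyc/mm).  An optional ``bandwidth`` adds a Gaussian
    high-frequency roll-off ``exp(-(f / bandwidth)**2)``.
    """

    f_peak: float = 0.0
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.f_peak < 0:
            raise ValueError("f_peak must be >= 0")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")

    def value(self, f: np.ndarray) -> np.ndarray:
        """Unnormalized spectral shape sampled at frequencies ``f`` (cyc/mm)."""
        f = np.asarray(f, dtype=float)
        if self.f_peak == 0:
            out = np.ones_like(f)
        else:
            out = f * np.exp(-f / self.f_peak)
        if self.bandwidth is not None:
            out = out * np.exp(-((f / self.bandwidth) ** 2))
        return out


@dataclass(frozen=True)
class ReconPreset:
    """Emulated reconstruction behaviour: blur, noise level, noise texture.

    ``psf_sigma`` is the Gaussian PSF width in mm, ``noise_scale`` a
    dimensionless multiplier on the plan's reference noise SD, and
    ``nps_shape`` the correlated-noise texture.
    """

    name: str
    psf_sigma: float
    noise_scale: float = 1.0
    nps_shape: NoiseSpectrum = field(default_factory=NoiseSpectrum)

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")


@dataclass(frozen=True)
class AcquisitionPlan:
    """Dose series and repetition structure of the simulated study."""

    ctdivol_levels: tuple[float, ...] = (9.5, 7.5, 6.0, 2.5, 0.4)
    reference_dose: float = 9.5
    reference_noise_sd: float = 10.0
    n_slices_per_acquisition: int = 50
    n_acquisitions: int = 5
    seed: int = 0
    n_pixels: int = 512
    pixel_mm: float = 250.0 / 512.0  # 250 mm FOV on a 512 matrix

    def __post_init__(self) -> None:
        object.__setattr__(self, "ctdivol_levels", tuple(self.ctdivol_levels))
        if any(d <= 0 for d in self.ctdivol_levels):
            raise ValueError("all doses must be > 0")
        if self.reference_dose <= 0 or self.reference_noise_sd <= 0:
            raise ValueError("reference dose and noise SD must be > 0")
        if self.n_slices_per_acquisition < 1 or self.n_acquisitions < 1:
            raise ValueError("slice and acquisition counts must be >= 1")

    @property
    def n_slices_total(self) -> int:
        return self.n_slices_per_acquisition * self.n_acquisitions


def noise_sd_at_dose(plan: AcquisitionPlan, preset: ReconPreset, dose: float) -> float:
    """Per-slice noise SD (HU): quantum-noise 1/sqrt(dose) scaling."""
    if dose <= 0:
        raise ValueError("dose must be > 0")
    return plan.reference_noise_sd * np.sqrt(plan.reference_dose / dose) * preset.noise_scale


def _label_key(text: str) -> int:
    # stable 32-bit key for seeding, independent of PYTHONHASHSEED
    return zlib.crc32(text.encode("utf8"))


def render_truth(
    geometry: PhantomGeometry,
    n_pixels: int,
    pixel_mm: float,
    supersample: int = 4,
) -> np.ndarray:
    """Noiseless HU image of the phantom on an ``n_pixels`` square grid.

    Pixels straddling a disc edge take area-weighted partial-volume values,
    approximated by ``supersample`` x ``supersample`` sub-pixel averaging.
    The grid is centered on the body axis.
    """
    if pixel_mm <= 0:
        raise ValueError("pixel_mm must be > 0")
    if n_pixels * pixel_mm < geometry.body_diameter:
        raise ValueError("grid does not cover the body disc")
    r_grid = n_pixels * pixel_mm / 2.0
    for ins in geometry.inserts:
        cx, cy = ins.center_offset
        if max(abs(cx), abs(cy)) + ins.diameter / 2.0 > r_grid:
            raise ValueError(f"insert {ins.label!r} outside grid")

    s = int(supersample)
    n_fine = n_pixels * s
    # sub-pixel centers, mm, origin at grid center
    coords = (np.arange(n_fine) + 0.5) * (pixel_mm / s) - r_grid
    x = coords[None, :]
    y = coords[:, None]
    r2 = x * x + y * y
    img = np.where(r2 <= (geometry.body_diameter / 2.0) ** 2,
                   geometry.background_hu, AIR_HU)
    for ins in geometry.inserts:
        cx, cy = ins.center_offset
        mask = (x - cx) ** 2 + (y - cy) ** 2 <= (ins.diameter / 2.0) ** 2
        img = np.where(mask, ins.hu, img)
    # block-average back to the target grid
    img = img.reshape(n_pixels, s, n_pixels, s).mean(axis=(1, 3))
    return img


def correlated_noise_field(
    shape: tuple[int, int],
    pixel_mm: float,
    target_sd: float,
    nps_shape: NoiseSpectrum | None = None,
    seed=None,
    n_fields: int | None = None,
) -> np.ndarray:
    """Zero-mean stationary noise with the requested power-spectrum shape.

    White Gaussian noise is colored in the frequency domain by
    ``sqrt(S(f))``; fields are synthesized at twice the requested size and
    center-cropped to suppress periodic-boundary artifacts, then demeaned
    and rescaled so the sample SD equals ``target_sd`` exactly.

    With ``n_fields`` set, returns a ``(n_fields, ny, nx)`` array (each
    field independently rescaled); otherwise a single ``(ny, nx)`` field.
    """
    if target_sd <= 0:
        raise ValueError("target_sd must be > 0")
    if nps_shape is None:
        nps_shape = NoiseSpectrum()
    ny, nx = shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    squeeze = n_fields is None
    count = 1 if n_fields is None else int(n_fields)

    if nps_shape.f_peak == 0 and nps_shape.bandwidth is None:
        fields = rng.standard_normal((count, ny, nx))
    else:
        oy, ox = 2 * ny, 2 * nx
        fu = np.fft.rfftfreq(ox, d=pixel_mm)
        fv = np.fft.fftfreq(oy, d=pixel_mm)
        fr = np.hypot(fv[:, None], fu[None, :])
        h = np.sqrt(nps_shape.value(fr)).astype(np.float32)
        fields = np.empty((count, ny, nx))
        batch = max(1, int(2.0e8 // (oy * ox * 8)))  # keep FFT workspace modest
        for start in range(0, count, batch):
            stop = min(count, start + batch)
            # single precision is ample for noise synthesis and much faster
            white = rng.standard_normal((stop - start, oy, ox), dtype=np.float32)
            spec = sp_fft.rfft2(white) * h
            colored = sp_fft.irfft2(spec, s=(oy, ox))
            fields[start:stop] = colored[:, ny // 2:ny // 2 + ny, nx // 2:nx // 2 + nx]

    fields -= fields.mean(axis=(1, 2), keepdims=True)
    sd = fields.std(axis=(1, 2), keepdims=True)
    fields *= target_sd / sd
    return fields[0] if squeeze else fields


def simulate_stack(
    geometry: PhantomGeometry,
    preset: ReconPreset,
    plan: AcquisitionPlan,
    dose: float,
    n_slices: int | None = None,
    module: str = "",
) -> ImageStack:
    """Simulate one reconstructed stack at the given dose.

    Each slice is the PSF-blurred truth plus an independent correlated
    noise field with SD ``reference_noise_sd * sqrt(reference_dose/dose) *
    noise_scale``.  Reproducible: the slice seeds derive deterministically
    from ``(plan.seed, preset.name, dose, module)``.

    ``module`` distinguishes stacks of different phantom sections (e.g. the
    uniform noise section vs. the insert section) within one plan.
    """
    n_pixels, pixel_mm = plan.n_pixels, plan.pixel_mm
    if n_slices is None:
        n_slices = plan.n_slices_total
    truth = render_truth(geometry, n_pixels, pixel_mm)
    sigma_px = preset.psf_sigma / pixel_mm
    blurred = ndimage.gaussian_filter(truth, sigma_px, mode="nearest")
    sd = noise_sd_at_dose(plan, preset, dose)

    ss = np.random.SeedSequence(
        entropy=plan.seed,
        spawn_key=(_label_key(preset.name), int(round(dose * 1000)), _label_key(module)),
    )
    rng = np.random.default_rng(ss)
    noise = correlated_noise_field(
        (n_pixels, n_pixels), pixel_mm, sd, preset.nps_shape, rng, n_fields=n_slices
    )
    pixels = (blurred[None, :, :] + noise).astype(np.float32)
    return ImageStack(
        pixels=pixels,
        pixel_mm=pixel_mm,
        dose_mgy=dose,
        preset=preset.name,
        truth={
            "image": blurred,
            "unblurred": truth,
            "psf_sigma_mm": preset.psf_sigma,
            "noise_sd": sd,
            "nps_shape": preset.nps_shape,
            "geometry": geometry,
            "module": module,
        },
    )


def gaussian_mtf(f, sigma_mm: float):
    """Modulation transfer of a Gaussian PSF: exp(-2 pi^2 sigma^2 f^2)."""
    f = np.asarray(f, dtype=float)
    return np.exp(-2.0 * np.pi**2 * sigma_mm**2 * f**2)
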