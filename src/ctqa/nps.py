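"""Noise power spectrum estimation from ROI ensembles.

The 2-D NPS is the ensemble mean periodogram of detrended square ROIs
taken in the uniform section of the phantom,

    NPS(u, v) = (dx * dy) / (Nx * Ny) * < |DFT2(roi - plane)|^2 >,

in HU^2 mm^2.  The radially averaged 1-D profile is the mean of the 2-D
NPS over annular frequency bins one DFT bin wide (zero-frequency bin
excluded); summary metrics are the noise magnitude (square root of the
2-D NPS integral), the spectral centroid f_av of the raw 1-D profile, and
the peak frequency of an 11th-order polynomial fit to the profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import ImageStack

__all__ = ["RoiSpec", "NPSResult", "extract_rois", "detrend_roi", "compute_nps"]


@dataclass(frozen=True)
class RoiSpec:
    """Square ROI placement for NPS measurement (pixel units)."""

    centers: tuple[tuple[int, int], ...]
    size: int = 128

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", tuple(tuple(c) for c in self.centers))
        if self.size < 8:
            raise ValueError("ROI size must be >= 8")

    @property
    def count_per_slice(self) -> int:
        return len(self.centers)


@dataclass
class NPSResult:
    """2-D and radially averaged noise power spectrum with summary metrics."""

    nps2d: np.ndarray            # HU^2 mm^2, fftshifted grid
    freqs_2d: np.ndarray         # radial frequency of each 2-D sample, cyc/mm
    freqs: np.ndarray            # 1-D bin centers, cyc/mm
    nps1d: np.ndarray            # raw radial average, HU^2 mm^2
    nps1d_fit: np.ndarray        # 11th-order polynomial fit evaluated at freqs
    noise_magnitude: float       # HU
    f_av: float                  # cyc/mm
    f_peak: float                # cyc/mm, argmax of the fitted curve
    n_rois: int
    pixel_mm: float

    def interp(self, f: np.ndarray) -> np.ndarray:
        """Radial NPS at arbitrary frequencies, flat beyond the measured band."""
        return np.interp(np.asarray(f, dtype=float), self.freqs, self.nps1d)


def extract_rois(stack: ImageStack, spec: RoiSpec) -> np.ndarray:
    """Pull ``count_per_slice * n_slices`` square ROIs out of a stack.

    ROIs must lie inside the image and, when the stack carries its
    generating geometry, inside the uniform background (not the air margin,
    not overlapping any insert).
    """
    ny, nx = stack.shape
    half = spec.size // 2
    geometry = stack.truth.get("geometry")
    rois = []
    for cy, cx in spec.centers:
        y0, x0 = cy - half, cx - half
        y1, x1 = y0 + spec.size, x0 + spec.size
        if y0 < 0 or x0 < 0 or y1 > ny or x1 > nx:
            raise ValueError(f"ROI at ({cy}, {cx}) exceeds the image bounds")
        if geometry is not None:
            _check_uniform(geometry, (cy, cx), spec.size, (ny, nx), stack.pixel_mm)
        rois.append(stack.pixels[:, y0:y1, x0:x1])
    out = np.concatenate(rois, axis=0).astype(float)
    return out


def _check_uniform(geometry, center_px, size, shape, pixel_mm) -> None:
    cy, cx = center_px
    ny, nx = shape
    # ROI corner coordinates in mm, origin on the body axis
    ys = (np.array([cy - size / 2, cy + size / 2]) - ny / 2) * pixel_mm
    xs = (np.array([cx - size / 2, cx + size / 2]) - nx / 2) * pixel_mm
    corners = [(x, y) for x in xs for y in ys]
    r_body = geometry.body_diameter / 2.0
    if any(np.hypot(x, y) > r_body for x, y in corners):
        raise ValueError("ROI extends outside the uniform body region")
    for ins in geometry.inserts:
        icx, icy = ins.center_offset
        r = ins.diameter / 2.0
        # distance from insert center to ROI rectangle
        dx = max(xs[0] - icx, 0.0, icx - xs[1])
        dy = max(ys[0] - icy, 0.0, icy - ys[1])
        if np.hypot(dx, dy) <= r:
            raise ValueError(f"ROI overlaps insert {ins.label!r}")


def detrend_roi(roi: np.ndarray) -> np.ndarray:
    """Subtract a least-squares plane (first-order 2-D polynomial)."""
    roi = np.asarray(roi, dtype=float)
    ny, nx = roi.shape[-2:]
    y = np.arange(ny) - (ny - 1) / 2.0
    x = np.arange(nx) - (nx - 1) / 2.0
    xg, yg = np.meshgrid(x, y)
    # orthogonal basis on the grid: 1, x, y (zero-mean, so coefficients decouple)
    flat = roi.reshape(*roi.shape[:-2], ny * nx)
    xf = xg.ravel()
    yf = yg.ravel()
    cx = flat @ xf / (xf @ xf)
    cy_ = flat @ yf / (yf @ yf)
    mean = flat.mean(axis=-1)
    fit = (
        mean[..., None]
        + cx[..., None] * xf
        + cy_[..., None] * yf
    )
    return (flat - fit).reshape(roi.shape)


def radial_bin_index(shape: tuple[int, int], pixel_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Annular bin index (width one DFT bin) and bin-center frequencies."""
    ny, nx = shape
    fu = np.fft.fftshift(np.fft.fftfreq(nx, d=pixel_mm))
    fv = np.fft.fftshift(np.fft.fftfreq(ny, d=pixel_mm))
    fr = np.hypot(fv[:, None], fu[None, :])
    df = 1.0 / (nx * pixel_mm)
    idx = np.floor(fr / df).astype(int)
    n_bins = idx.max() + 1
    centers = (np.arange(n_bins) + 0.5) * df
    return idx, centers


def compute_nps(rois: np.ndarray, pixel_mm: float, fit_order: int = 11) -> NPSResult:
    """Ensemble NPS of a set of same-sized square ROIs."""
    rois = np.asarray(rois, dtype=float)
    if rois.ndim == 2:
        rois = rois[None]
    if rois.shape[0] < 2:
        raise ValueError("need at least 2 ROIs")
    n, ny, nx = rois.shape
    if ny != nx:
        raise ValueError("ROIs must be square")

    detrended = detrend_roi(rois)
    spectra = np.abs(np.fft.fft2(detrended)) ** 2
    nps2d = np.fft.fftshift(spectra.mean(axis=0)) * (pixel_mm * pixel_mm) / (nx * ny)

    idx, centers = radial_bin_index((ny, nx), pixel_mm)
    fr = None
    counts = np.bincount(idx.ravel(), minlength=centers.size)
    sums = np.bincount(idx.ravel(), weights=nps2d.ravel(), minlength=centers.size)
    with np.errstate(invalid="ignore"):
        prof = sums / counts
    # drop the zero-frequency bin and any empty bins
    keep = (np.arange(centers.size) >= 1) & (counts > 0)
    freqs = centers[keep]
    nps1d = prof[keep]

    df_u = 1.0 / (nx * pixel_mm)
    noise_magnitude = float(np.sqrt(nps2d.sum() * df_u * df_u))
    f_av = float((freqs * nps1d).sum() / nps1d.sum())

    # polynomial fit on a normalized abscissa for conditioning
    order = min(fit_order, len(freqs) - 1)
    t = freqs / freqs.max()
    coeffs = np.polynomial.polynomial.polyfit(t, nps1d, order)
    nps1d_fit = np.polynomial.polynomial.polyval(t, coeffs)
    t_fine = np.linspace(t.min(), t.max(), 4096)
    fit_fine = np.polynomial.polynomial.polyval(t_fine, coeffs)
    f_peak = float(t_fine[np.argmax(fit_fine)] * freqs.max())

    fu = np.fft.fftshift(np.fft.fftfreq(nx, d=pixel_mm))
    fv = np.fft.fftshift(np.fft.fftfreq(ny, d=pixel_mm))
    fr = np.hypot(fv[:, None], fu[None, :])

    return NPSResult(
        nps2d=nps2d,
        freqs_2d=fr,
        freqs=freqs,
        nps1d=nps1d,
        nps1d_fit=nps1d_fit,
        noise_magnitude=noise_magnitude,
        f_av=f_av,
        f_peak=f_peak,
        n_rois=n,
        pixel_mm=pixel_mm,
    )
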