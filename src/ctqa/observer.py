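"""NPWE model-observer detectability index.

The task is a radially symmetric "designer" lesion profile (flat core,
raised-cosine edge) defined in the frequency domain on a fixed task grid.
The non-prewhitening observer with an eye filter scores it against the
measured system TTF and noise power spectrum:

    d'^2 = [ sum W^2 TTF^2 E^2 du dv ]^2
           / sum W^2 TTF^2 NPS E^4 du dv

with W the task function (HU mm^2), TTF the task transfer function, NPS
the noise power spectrum (HU^2 mm^2) and E the visual response (eye)
filter mapped from cycles/degree to object-plane cycles/mm through the
display zoom and viewing distance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .nps import NPSResult
from .ttf import TTFResult

__all__ = [
    "TaskFunction",
    "ViewingConditions",
    "DetectabilityPoint",
    "designer_task_function",
    "eye_filter",
    "dprime_npwe",
    "chest_tasks",
]


@dataclass
class TaskFunction:
    """Frequency-domain representation of one detection task."""

    label: str
    contrast: float              # HU
    diameter: float              # mm
    matrix: int
    pixel_mm: float
    transition_fraction: float
    w2d: np.ndarray              # |W(u,v)|, HU mm^2, unshifted DFT layout
    freqs_2d: np.ndarray         # radial frequency of each sample, cyc/mm

    @property
    def delta_f(self) -> float:
        return 1.0 / (self.matrix * self.pixel_mm)


@dataclass(frozen=True)
class ViewingConditions:
    """Display conditions and eye-filter parameters.

    The visual response function is ``E(rho) = rho**gamma * exp(-c*rho)``
    in cycles/degree, normalized to unit maximum; object-plane frequencies
    map to angular ones via the zoom factor and viewing distance.
    """

    zoom: float = 1.5
    distance_mm: float = 500.0
    gamma: float = 1.3
    c: float = 0.325  # per cyc/deg; peak response at gamma/c = 4 cyc/deg

    def __post_init__(self) -> None:
        if self.zoom <= 0 or self.distance_mm <= 0:
            raise ValueError("zoom and distance must be positive")


@dataclass
class DetectabilityPoint:
    d_prime: float
    task: str
    dose_mgy: float | None = None
    preset: str | None = None
    inputs_hash: str = ""
    extras: dict = field(default_factory=dict)


def _render_disc_profile(
    contrast: float,
    diameter: float,
    matrix: int,
    pixel_mm: float,
    transition_fraction: float,
    supersample: int = 4,
) -> np.ndarray:
    radius = diameter / 2.0
    t = transition_fraction
    s = int(supersample)
    n_fine = matrix * s
    coords = (np.arange(n_fine) + 0.5) * (pixel_mm / s) - matrix * pixel_mm / 2.0
    r = np.hypot(coords[None, :], coords[:, None])
    r0, r1 = radius * (1.0 - t), radius * (1.0 + t)
    if t == 0:
        prof = np.where(r <= radius, contrast, 0.0)
    else:
        prof = np.zeros_like(r)
        prof[r <= r0] = contrast
        mid = (r > r0) & (r < r1)
        prof[mid] = contrast * 0.5 * (1.0 + np.cos(np.pi * (r[mid] - r0) / (r1 - r0)))
    return prof.reshape(matrix, s, matrix, s).mean(axis=(1, 3))


def designer_task_function(
    contrast: float,
    diameter: float = 5.0,
    matrix: int = 300,
    pixel_mm: float = 0.05,
    transition_fraction: float = 0.1,
    label: str = "",
) -> TaskFunction:
    """Designer lesion task: flat core of radius R(1-t), raised-cosine edge.

    ``w2d`` approximates the continuous 2-D Fourier magnitude of the
    profile (DFT scaled by the pixel area), so Parseval's identity links
    its squared integral to the spatial energy of the lesion.
    """
    if not 0 <= transition_fraction < 1:
        raise ValueError("transition_fraction must be in [0, 1)")
    if diameter * (1 + transition_fraction) >= matrix * pixel_mm:
        raise ValueError("lesion larger than the task grid")
    profile = _render_disc_profile(contrast, diameter, matrix, pixel_mm,
                                   transition_fraction)
    w2d = np.abs(np.fft.fft2(profile)) * pixel_mm * pixel_mm
    f1d = np.fft.fftfreq(matrix, d=pixel_mm)
    freqs_2d = np.hypot(f1d[:, None], f1d[None, :])
    return TaskFunction(
        label=label,
        contrast=contrast,
        diameter=diameter,
        matrix=matrix,
        pixel_mm=pixel_mm,
        transition_fraction=transition_fraction,
        w2d=w2d,
        freqs_2d=freqs_2d,
    )


def eye_filter(freqs: np.ndarray, viewing: ViewingConditions) -> np.ndarray:
    """Visual response at object-plane frequencies ``freqs`` (cyc/mm).

    rho [cyc/deg] = f [cyc/mm] * (distance / zoom) * (pi / 180); the filter
    ``rho**gamma * exp(-c * rho)`` is normalized to unit peak analytically
    (maximum at rho = gamma / c), so E(0) = 0 and max E = 1.
    """
    f = np.asarray(freqs, dtype=float)
    rho = f * (viewing.distance_mm / viewing.zoom) * (np.pi / 180.0)
    peak = (viewing.gamma / viewing.c) ** viewing.gamma * np.exp(-viewing.gamma)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(rho > 0, rho**viewing.gamma * np.exp(-viewing.c * rho) / peak, 0.0)
    return e


def _as_radial_fn(obj, kind: str):
    """Accept result objects, callables, or scalars as radial curves."""
    if obj is None:
        return lambda f: np.ones_like(np.asarray(f, dtype=float))
    if isinstance(obj, (TTFResult, NPSResult)):
        return obj.interp
    if np.isscalar(obj):
        val = float(obj)
        if kind == "nps" and val <= 0:
            raise ValueError("white NPS level must be positive")
        return lambda f: np.full_like(np.asarray(f, dtype=float), val)
    if callable(obj):
        return obj
    raise TypeError(f"cannot interpret {kind} input of type {type(obj)!r}")


def _provenance(task, ttf, nps) -> str:
    bits = [task.label, f"{task.contrast}", f"{task.diameter}"]
    if isinstance(ttf, TTFResult):
        bits += ["ttf", ttf.insert_label, f"{ttf.ttf50:.6g}", f"{ttf.cnr_total:.6g}"]
    if isinstance(nps, NPSResult):
        bits += ["nps", f"{nps.noise_magnitude:.6g}", f"{nps.f_av:.6g}", f"{nps.n_rois}"]
    return hashlib.sha1("|".join(bits).encode()).hexdigest()[:16]


def dprime_npwe(
    task: TaskFunction,
    ttf=None,
    nps=1.0,
    viewing: ViewingConditions | None = None,
    dose_mgy: float | None = None,
    preset: str | None = None,
) -> DetectabilityPoint:
    """NPWE detectability index for one (task, TTF, NPS) combination.

    ``ttf`` and ``nps`` may be measurement results (interpolated radially
    onto the task grid, flat beyond the measured band), plain callables of
    frequency, or scalars; ``ttf=None`` means an ideal system (TTF = 1) and
    ``viewing=None`` disables the eye filter (E = 1).
    """
    fr = task.freqs_2d
    t2 = _as_radial_fn(ttf, "ttf")(fr) ** 2
    n = _as_radial_fn(nps, "nps")(fr)
    if np.all(n == 0):
        raise ValueError("NPS is identically zero: d' is undefined")
    e2 = eye_filter(fr, viewing) ** 2 if viewing is not None else np.ones_like(fr)

    w2 = task.w2d**2
    df2 = task.delta_f**2
    numerator = (w2 * t2 * e2).sum() * df2
    denominator = (w2 * t2 * n * e2 * e2).sum() * df2
    if denominator <= 0:
        raise ValueError("noise term vanished: d' is undefined")
    d_prime = float(numerator / np.sqrt(denominator))
    return DetectabilityPoint(
        d_prime=d_prime,
        task=task.label,
        dose_mgy=dose_mgy,
        preset=preset,
        inputs_hash=_provenance(task, ttf, nps),
    )


def chest_tasks() -> dict[str, TaskFunction]:
    """The three 5-mm chest detection tasks on the standard 300 x 0.05 mm grid.

    LCN: low-contrast soft-tissue nodule, 50 HU; GGO: ground-glass opacity,
    200 HU; HCP: high-contrast pulmonary lesion, 950 HU.  d' is invariant
    to the contrast sign, so magnitudes are used.
    """
    spec = {"LCN": 50.0, "GGO": 200.0, "HCP": 950.0}
    return {
        name: designer_task_function(contrast, diameter=5.0, matrix=300,
                                     pixel_mm=0.05, transition_fraction=0.1,
                                     label=name)
        for name, contrast in spec.items()
    }
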