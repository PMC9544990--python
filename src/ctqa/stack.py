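"""In-memory container for a stack of axial CT slices in Hounsfield units."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class ImageStack:
    """A set of axial slices in HU with acquisition metadata.

    Parameters
    ----------
    pixels : ndarray, shape (n_slices, ny, nx)
        Slice data in Hounsfield units.
    pixel_mm : float
        In-plane pixel spacing (square pixels assumed).
    slice_mm : float
        Spacing between consecutive slices.
    dose_mgy : float or None
        CTDIvol label of the acquisition, mGy.
    preset : str or None
        Reconstruction-preset label.
    truth : dict
        Optional ground-truth record attached by the simulator
        (noiseless image, PSF sigma, generating noise spectrum, ...)
        so downstream estimators can be tested against known answers.
    """

    pixels: np.ndarray
    pixel_mm: float
    slice_mm: float = 1.0
    dose_mgy: float | None = None
    preset: str | None = None
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (n_slices, ny, nx)")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def __len__(self) -> int:
        return self.n_slices
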