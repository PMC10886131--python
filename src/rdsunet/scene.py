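"""The universal sample unit: an RGB field image with a per-pixel mask."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, ShapeError

CLASS_NAMES = ("background", "corn", "weed")
N_CLASSES = len(CLASS_NAMES)
BACKGROUND, CORN, WEED = 0, 1, 2

# palette convention: black background, green corn, red weed
PALETTE = [0, 0, 0, 0, 255, 0, 255, 0, 0] + [0] * (256 * 3 - 9)


@dataclass
class LabeledScene:
    """One RGB image (H x W x 3 uint8) with its class-index mask (H x W)."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        self.validate()

    def validate(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ShapeError(f"image must be H x W x 3, got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ShapeError(
                f"mask shape {self.mask.shape} does not match image "
                f"{self.image.shape[:2]}")
        bad = np.setdiff1d(np.unique(self.mask), np.arange(N_CLASSES))
        if bad.size:
            raise FormatError(
                f"mask contains out-of-range class indices {bad.tolist()}; "
                f"allowed 0..{N_CLASSES - 1}")

    @property
    def size(self) -> int:
        return self.image.shape[0]
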