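"""Core in-memory containers for complex en face OCT data.

An *en face* plane is a transverse slice of an OCT volume at fixed depth.
Because OCT is interferometric, each pixel carries a complex value
(magnitude and phase of the backscattered field); phase is what makes
coherent averaging and computational bandwidth expansion possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np

__all__ = ["EnFaceField", "StackContainer"]


@dataclass
class EnFaceField:
    """A single complex-valued en face field image with physical pixel pitch.

    Parameters
    ----------
    data:
        Complex 2D array, shape (H, W). Rows are y, columns are x.
    pitch_x, pitch_y:
        Transverse sampling interval in µm/pixel; both must be positive.
        ``pitch_y`` defaults to ``pitch_x`` (square pixels).
    """

    data: np.ndarray
    pitch_x: float
    pitch_y: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"field must be 2D, got shape {self.data.shape}")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if self.pitch_y is None:
            self.pitch_y = self.pitch_x
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def intensity(self) -> np.ndarray:
        """OCT scattering intensity, the squared magnitude."""
        return np.abs(self.data) ** 2


@dataclass
class StackContainer:
    """N co-registered complex en face frames on a shared grid.

    This is the unit of coherent/incoherent averaging: ``frames`` has shape
    (N, H, W) and every frame shares the same pixel pitch. ``provenance``
    is a free-form metadata record (generator seed and parameters, source
    file, ...) that rides along through I/O round-trips.
    """

    frames: np.ndarray
    pitch_x: float
    pitch_y: float | None = None
    wavelength_um: float | None = None
    depth_index: int | None = None
    provenance: dict[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must have shape (N, H, W), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if not np.iscomplexobj(self.frames):
            self.frames = self.frames.astype(np.complex128)
        if self.pitch_y is None:
            self.pitch_y = self.pitch_x
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    def field(self, index: int) -> EnFaceField:
        """Return frame ``index`` as an :class:`EnFaceField`."""
        return EnFaceField(self.frames[index], self.pitch_x, self.pitch_y)
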