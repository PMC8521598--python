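"""Inter-frame bulk-shift and global-phase registration.

Coherent averaging only suppresses noise if the backscattered signal adds
in phase, which fails when the sample drifts between acquisitions. This
module corrects the two perturbations relevant for stack averaging: a
rigid subpixel translation and a global phase rotation per frame.
Rotation, warping and per-line phase errors are out of scope.

Shift is estimated from the cross-correlation of the complex fields with
upsampled-DFT subpixel refinement — the correlation magnitude is
insensitive to a global phase rotation, and complex fields (unlike their
magnitudes) are band-limited, which keeps the subpixel estimate unbiased.
The global phase is then the angle of the complex inner product between
the reference and the shifted frame; quality is the normalized magnitude
cross-correlation after alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

from .containers import EnFaceField, StackContainer

__all__ = [
    "FrameCorrection",
    "estimate_correction",
    "apply_correction",
    "register_stack",
]


@dataclass
class FrameCorrection:
    """Per-frame rigid correction: subpixel shift, global phase, quality."""

    dx_um: float
    dy_um: float
    phi: float  # radians, wrapped to (-pi, pi]
    quality: float  # normalized magnitude cross-correlation at the peak, [0, 1]

    def __neg__(self) -> "FrameCorrection":
        return FrameCorrection(-self.dx_um, -self.dy_um, -self.phi, self.quality)


def _shift_complex(data: np.ndarray, dy_px: float, dx_px: float) -> np.ndarray:
    """Translate by (+dy, +dx) pixels via a spectral phase ramp."""
    h, w = data.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    ramp = np.exp(-2j * np.pi * (fy * dy_px + fx * dx_px))
    return np.fft.ifft2(np.fft.fft2(data) * ramp)


def estimate_correction(
    frame: EnFaceField,
    reference: EnFaceField,
    upsample_factor: int = 100,
    quality_threshold: float = 0.5,
) -> FrameCorrection:
    """Estimate the correction aligning ``frame`` to ``reference``.

    A quality below ``quality_threshold`` is flagged (returned, not
    raised): the caller decides whether to drop or keep the frame.
    """
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must share the same grid")
    ref_mag = reference.magnitude
    shift, _, _ = phase_cross_correlation(
        reference.data, frame.data, upsample_factor=upsample_factor, normalization=None
    )
    dy_px, dx_px = float(shift[0]), float(shift[1])
    shifted = _shift_complex(frame.data, dy_px, dx_px)
    inner = np.vdot(reference.data, shifted)  # sum conj(ref) * shifted
    phi = float(np.angle(inner)) if inner != 0 else 0.0

    a = ref_mag - ref_mag.mean()
    b = np.abs(shifted) - np.abs(shifted).mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    quality = float(np.clip(np.sum(a * b) / denom, 0.0, 1.0)) if denom > 0 else 0.0
    corr = FrameCorrection(
        dx_um=dx_px * frame.pitch_x,
        dy_um=dy_px * frame.pitch_y,
        phi=phi,
        quality=quality,
    )
    corr.low_quality = quality < quality_threshold  # type: ignore[attr-defined]
    return corr


def apply_correction(frame: EnFaceField, corr: FrameCorrection) -> EnFaceField:
    """Apply a subpixel shift (spectral phase ramp) and remove the phase drift."""
    data = _shift_complex(
        frame.data, corr.dy_um / frame.pitch_y, corr.dx_um / frame.pitch_x
    )
    data = data * np.exp(-1j * corr.phi)
    return EnFaceField(data, frame.pitch_x, frame.pitch_y)


def register_stack(
    stack: StackContainer,
    reference_index: int = 0,
    upsample_factor: int = 100,
) -> tuple[StackContainer, pd.DataFrame]:
    """Register every frame to a reference frame (first frame by default).

    Returns the corrected stack and a per-frame table of
    (dx_um, dy_um, phi, quality).
    """
    reference = stack.field(reference_index)
    frames = np.empty_like(stack.frames)
    rows = []
    for i in range(stack.n_frames):
        corr = estimate_correction(stack.field(i), reference, upsample_factor)
        frames[i] = apply_correction(stack.field(i), corr).data
        rows.append(
            {"frame": i, "dx_um": corr.dx_um, "dy_um": corr.dy_um,
             "phi": corr.phi, "quality": corr.quality}
        )
    registered = StackContainer(
        frames,
        pitch_x=stack.pitch_x,
        pitch_y=stack.pitch_y,
        wavelength_um=stack.wavelength_um,
        depth_index=stack.depth_index,
        provenance={**stack.provenance, "registered": True},
    )
    return registered, pd.DataFrame(rows)
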