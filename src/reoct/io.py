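"""HDF5 I/O for complex field stacks and TIFF export for inspection.

Layout: one group ``/stack`` per file with datasets ``real`` and ``imag``
of shape (N, H, W) and attributes ``pitch_x_um``, ``pitch_y_um``,
``wavelength_um`` (optional), ``depth_index`` (optional) and
``provenance_json``. Complex values are stored as paired real/imag planes
(not interleaved, not magnitude/phase) to avoid dialect ambiguity; the
frame index is the explicit leading axis, so reading never reorders
frames. The round-trip is lossless at float64.

TIFF export is for human inspection only; quantitative I/O goes through
HDF5/CSV/JSON.
"""

from __future__ import annotations

import json
from os import PathLike

import h5py
import numpy as np
import tifffile

from .containers import StackContainer

__all__ = ["read_stack", "write_stack", "export_magnitude_tiff", "StackFormatError"]

_GROUP = "stack"


class StackFormatError(ValueError):
    """Raised when an HDF5 container does not match the expected layout."""


def write_stack(stack: StackContainer, path: str | PathLike) -> None:
    """Write a :class:`StackContainer` to an HDF5 file (lossless)."""
    if stack.frames.shape[0] < 1:
        raise ValueError("cannot write an empty stack")
    with h5py.File(path, "w") as f:
        g = f.create_group(_GROUP)
        g.create_dataset("real", data=np.ascontiguousarray(stack.frames.real))
        g.create_dataset("imag", data=np.ascontiguousarray(stack.frames.imag))
        g.attrs["pitch_x_um"] = float(stack.pitch_x)
        g.attrs["pitch_y_um"] = float(stack.pitch_y)
        if stack.wavelength_um is not None:
            g.attrs["wavelength_um"] = float(stack.wavelength_um)
        if stack.depth_index is not None:
            g.attrs["depth_index"] = int(stack.depth_index)
        g.attrs["provenance_json"] = json.dumps(stack.provenance)


def read_stack(path: str | PathLike) -> StackContainer:
    """Read a stack written by :func:`write_stack`.

    Raises
    ------
    StackFormatError
        If the ``real``/``imag`` datasets are missing or shape-mismatched,
        naming the offending dataset, or if the pitch attributes are absent.
    """
    with h5py.File(path, "r") as f:
        if _GROUP not in f:
            raise StackFormatError(f"missing group '/{_GROUP}' in {path}")
        g = f[_GROUP]
        for name in ("real", "imag"):
            if name not in g:
                raise StackFormatError(f"missing dataset '{name}' in {path}")
        real = g["real"][...]
        imag = g["imag"][...]
        if real.shape != imag.shape:
            raise StackFormatError(
                f"dataset 'imag' shape {imag.shape} does not match "
                f"'real' shape {real.shape}"
            )
        if "pitch_x_um" not in g.attrs or "pitch_y_um" not in g.attrs:
            raise StackFormatError(f"missing pitch metadata in {path}")
        provenance = {}
        if "provenance_json" in g.attrs:
            provenance = json.loads(g.attrs["provenance_json"])
        return StackContainer(
            frames=real + 1j * imag,
            pitch_x=float(g.attrs["pitch_x_um"]),
            pitch_y=float(g.attrs["pitch_y_um"]),
            wavelength_um=float(g.attrs["wavelength_um"])
            if "wavelength_um" in g.attrs
            else None,
            depth_index=int(g.attrs["depth_index"])
            if "depth_index" in g.attrs
            else None,
            provenance=provenance,
        )


def export_magnitude_tiff(
    field: np.ndarray,
    path: str | PathLike,
    log_scale: bool = True,
    db_floor: float = -40.0,
) -> None:
    """Export |field| as a 16-bit grayscale TIFF.

    In log mode, values are dB relative to the image maximum, clipped at
    ``db_floor`` and mapped linearly to [0, 65535]. An all-zero field is
    written as all zeros (no NaN propagation).
    """
    mag = np.abs(np.asarray(field))
    if not np.all(np.isfinite(mag)):
        raise ValueError("field contains non-finite values")
    peak = mag.max()
    if peak == 0:
        out = np.zeros(mag.shape, dtype=np.uint16)
    elif log_scale:
        if db_floor >= 0:
            raise ValueError("db_floor must be negative")
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(mag / peak)
        db = np.clip(db, db_floor, 0.0)
        out = np.round((db - db_floor) / (-db_floor) * 65535).astype(np.uint16)
    else:
        out = np.round(mag / peak * 65535).astype(np.uint16)
    tifffile.imwrite(path, out)
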