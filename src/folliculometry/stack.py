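"""Image stacks with physical voxel spacing, TIFF I/O, reslicing and projections.

A light-sheet acquisition produces one camera frame per sample position along
the translation axis.  The stack is stored ``(z, y, x)`` with ``z`` the
translation (axial) direction; the spacing tuple ``(dz, dy, dx)`` is in
micrometres and is typically strongly anisotropic (e.g. a 16 um z-step against
a 4 um camera pixel).  Every downstream measurement is in physical units, so a
stack without spacing is treated as an error, not a default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "reslice",
    "max_intensity_projection",
]

#: axis name -> transpose permutation; each permutation is an involution so that
#: reslicing twice along the same axis restores the original orientation.
_RESLICE_PERMS = {"z": (0, 1, 2), "y": (1, 0, 2), "x": (2, 1, 0)}


@dataclass
class ImageStack:
    """A 3D grayscale volume with anisotropic voxel spacing in micrometres.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative intensities.
    spacing : tuple of float
        ``(dz, dy, dx)`` voxel pitch in micrometres; all components positive.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got ndim={self.voxels.ndim}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.spacing = sp
        if np.issubdtype(self.voxels.dtype, np.floating):
            if not np.isfinite(self.voxels).all():
                raise ValueError("stack intensities must be finite")
            if float(self.voxels.min()) < 0:
                raise ValueError("stack intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def physical_extent_um(self) -> tuple[float, float, float]:
        """Physical size of the volume along (z, y, x), micrometres."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page grayscale TIFF plus a spacing sidecar.

    Spacing is recorded three ways: an ImageJ-style ``spacing`` (z-step) tag,
    the TIFF X/Y resolution tags, and a sidecar JSON ``{"spacing_um": [dz, dy,
    dx]}`` next to the file.  The sidecar is authoritative on read-back.
    """
    path = Path(path)
    dz, dy, dx = stack.spacing
    tifffile.imwrite(
        path,
        stack.voxels,
        imagej=stack.voxels.dtype in (np.dtype(np.uint8), np.dtype(np.uint16)),
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    _sidecar_path(path).write_text(json.dumps({"spacing_um": [dz, dy, dx]}))


def _spacing_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Best-effort spacing recovery from ImageJ metadata + resolution tags."""
    meta = tif.imagej_metadata
    if not meta or "spacing" not in meta:
        return None
    dz = float(meta["spacing"])
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
    except KeyError:
        return None
    dx = xres[1] / xres[0]
    dy = yres[1] / yres[0]
    return (dz, float(dy), float(dx))


def read_stack(
    path: str | Path,
    spacing: tuple[float, float, float] | None = None,
    memmap: bool = False,
) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    Spacing precedence is ``spacing`` argument > sidecar JSON > TIFF tags; if
    all three are missing this is an error, because measurements downstream are
    meaningless without physical units.  With ``memmap=True`` the pixel data is
    memory-mapped rather than loaded, which lets full-size acquisitions (600
    planes of 2,560x2,160) be opened without holding them in RAM.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        tag_spacing = _spacing_from_tiff(tif)
    voxels = tifffile.memmap(path, mode="r") if memmap else tifffile.imread(path)
    voxels = np.asarray(voxels) if not memmap else voxels
    if voxels.ndim == 2:
        voxels = voxels[None]
    if voxels.ndim != 3:
        raise ValueError(
            f"{path}: expected multi-page grayscale TIFF, got shape {voxels.shape}"
        )
    if spacing is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            spacing = tuple(json.loads(sidecar.read_text())["spacing_um"])
        elif tag_spacing is not None:
            spacing = tag_spacing
        else:
            raise ValueError(
                f"{path}: no voxel spacing found (argument, sidecar JSON, or TIFF "
                "tags); pass spacing=(dz, dy, dx) in micrometres"
            )
    return ImageStack(voxels, spacing)  # type: ignore[arg-type]


def reslice(stack: ImageStack, axis: str) -> ImageStack:
    """Reorient the stack so that viewing planes are orthogonal to ``axis``.

    Axes are permuted together with their spacings, so the physical coordinate
    of every voxel is unchanged; applying the same reslice twice restores the
    original orientation.
    """
    if axis not in _RESLICE_PERMS:
        raise ValueError(f"axis must be one of 'x', 'y', 'z', got {axis!r}")
    perm = _RESLICE_PERMS[axis]
    voxels = np.transpose(stack.voxels, perm)
    spacing = tuple(stack.spacing[p] for p in perm)
    return ImageStack(voxels.copy(), spacing)  # type: ignore[arg-type]


def max_intensity_projection(stack: ImageStack, axis: str = "z") -> np.ndarray:
    """Maximum intensity projection along the named axis."""
    if axis not in _RESLICE_PERMS:
        raise ValueError(f"axis must be one of 'x', 'y', 'z', got {axis!r}")
    iaxis = {"z": 0, "y": 1, "x": 2}[axis]
    return stack.voxels.max(axis=iaxis)
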