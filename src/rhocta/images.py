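"""Core image containers and TIFF I/O.

All in-memory images are float arrays with intensities in [0, 1]; on disk
they are stored as grayscale 16-bit TIFF (full scale = 1.0). Physical scale
is carried explicitly as a pixel pitch in micrometers, so metrics such as
vascular-network length per mm^2 are unit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile

#: Valid perfusion-state labels for an en-face image.
STATES = ("baseline", "compressed", "hyperemia", "histology")

_U16_MAX = np.float64(65535.0)


@dataclass
class EnFaceImage:
    """A 2D top-down angiographic (or projected histology) image.

    Parameters
    ----------
    pixels
        2D non-negative intensity grid, values nominally in [0, 1].
    pixel_pitch_um
        Physical size of one pixel in micrometers (isotropic).
    state
        Perfusion-state label: baseline, compressed, hyperemia or histology.
    site
        Optional anatomical site label ("inner" / "outer" forearm).
    """

    pixels: np.ndarray
    pixel_pitch_um: float
    state: str = "baseline"
    site: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("EnFaceImage requires a 2D pixel grid")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def field_area_mm2(self) -> float:
        """Physical image area in mm^2."""
        h, w = self.pixels.shape
        return h * w * (self.pixel_pitch_um / 1000.0) ** 2

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        """Copy of this image with replaced pixel data (metadata kept)."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))


@dataclass
class AngioVolume:
    """A 3D angiographic volume, axes ordered (depth, y, x).

    ``spacing_um`` is (x, y, z) voxel spacing in micrometers; the depth axis
    is always axis 0 of ``voxels``, with depth 0 at the first slice.
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float] = (6.5, 6.5, 3.5)
    depth_axis: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("AngioVolume requires a 3D voxel grid")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("voxel spacing must be positive")
        if self.depth_axis != 0:
            raise ValueError("depth axis must be axis 0 (depth, y, x ordering)")
        if np.any(self.voxels < 0) or not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite and non-negative")

    @property
    def lateral_pitch_um(self) -> float:
        sx, sy, _ = self.spacing_um
        if not np.isclose(sx, sy):
            raise ValueError("anisotropic lateral spacing is not supported")
        return sx


@dataclass
class HistologyStack:
    """Serial horizontal histology sections spanning a dermal depth range.

    ``true_offsets`` holds the per-section (dy, dx) pixel translations that
    were applied when the stack is synthetic, enabling registration tests;
    ``applied_shifts`` records the corrections from registration.
    """

    sections: np.ndarray  # (n_sections, H, W)
    depths_um: np.ndarray
    pixel_pitch_um: float
    true_offsets: Optional[np.ndarray] = None  # (n_sections, 2) as (dy, dx)
    applied_shifts: Optional[np.ndarray] = None
    site: Optional[str] = None

    def __post_init__(self) -> None:
        self.sections = np.asarray(self.sections, dtype=np.float64)
        self.depths_um = np.asarray(self.depths_um, dtype=np.float64)
        if self.sections.ndim != 3:
            raise ValueError("sections must be a (n, H, W) array")
        if len(self.depths_um) != self.sections.shape[0]:
            raise ValueError("one depth per section required")
        if np.any(np.diff(self.depths_um) <= 0):
            raise ValueError("section depths must be strictly increasing")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def n_sections(self) -> int:
        return self.sections.shape[0]


# ---------------------------------------------------------------------------
# TIFF I/O


def _to_u16(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.round(pixels * _U16_MAX), 0, _U16_MAX).astype(np.uint16)


def write_enface_tiff(image: EnFaceImage, path: str | Path) -> None:
    """Write an en-face image as grayscale 16-bit TIFF (full scale = 1.0)."""
    tifffile.imwrite(str(path), _to_u16(image.pixels))


def read_enface_tiff(
    path: str | Path,
    pixel_pitch_um: float = 6.5,
    state: str = "baseline",
    site: Optional[str] = None,
) -> EnFaceImage:
    """Read a grayscale TIFF into an EnFaceImage, rescaling to [0, 1]."""
    raw = tifffile.imread(str(path))
    if raw.ndim != 2:
        raise ValueError(f"{path}: expected a single-page grayscale TIFF")
    if raw.dtype == np.uint16:
        pixels = raw.astype(np.float64) / float(_U16_MAX)
    elif raw.dtype == np.uint8:
        pixels = raw.astype(np.float64) / 255.0
    else:
        pixels = raw.astype(np.float64)
    return EnFaceImage(pixels, pixel_pitch_um=pixel_pitch_um, state=state, site=site)


def write_stack_tiff(stack: HistologyStack, path: str | Path) -> None:
    """Write a histology stack as a multi-page 16-bit TIFF."""
    tifffile.imwrite(str(path), _to_u16(stack.sections))


def read_stack_tiff(
    path: str | Path,
    depths_um: Optional[Sequence[float]] = None,
    pixel_pitch_um: float = 6.5,
) -> HistologyStack:
    """Read a multi-page TIFF into a HistologyStack.

    If depths are not given, sections are placed evenly over 40-440 um,
    the conventional dermal depth range for horizontal sectioning.
    """
    raw = tifffile.imread(str(path))
    if raw.ndim == 2:
        raw = raw[None, ...]
    if raw.dtype == np.uint16:
        sections = raw.astype(np.float64) / float(_U16_MAX)
    elif raw.dtype == np.uint8:
        sections = raw.astype(np.float64) / 255.0
    else:
        sections = raw.astype(np.float64)
    if depths_um is None:
        depths_um = np.linspace(40.0, 440.0, sections.shape[0])
    return HistologyStack(sections, np.asarray(depths_um, float), pixel_pitch_um)


def read_volume_tiff(
    path: str | Path, spacing_um: tuple[float, float, float] = (6.5, 6.5, 3.5)
) -> AngioVolume:
    """Read a multi-page TIFF as an angiographic volume (pages = depth)."""
    raw = tifffile.imread(str(path))
    if raw.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page TIFF volume")
    if raw.dtype == np.uint16:
        voxels = raw.astype(np.float64) / float(_U16_MAX)
    else:
        voxels = raw.astype(np.float64)
    return AngioVolume(voxels, spacing_um=spacing_um)
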