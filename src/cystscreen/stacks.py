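"""Z-stack container shared by the generator and the segmentation code."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """One well, one fluorescence channel: ordered focal planes along z.

    Parameters
    ----------
    planes : ndarray, shape (n_planes, height, width)
        Pixel intensities in acquisition order along z.
    z_interval_um : float
        Spacing between consecutive focal planes, in microns.
    channel : str
        ``"actin"`` or ``"nuclei"``.
    well_id : str
        Plate coordinate in letter + two-digit form (``"A01"``).
    """

    planes: np.ndarray
    z_interval_um: float = 50.0
    channel: str = "actin"
    well_id: str = ""

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise ValueError("planes must be a (n_planes, height, width) array")
        if self.planes.shape[0] < 1:
            raise ValueError("an ImageStack needs at least one plane")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every plane."""
        return self.planes.shape[1:]

    def max_projection(self) -> np.ndarray:
        """Per-pixel maximum over all focal planes."""
        return self.planes.max(axis=0)


def max_projection(stack: ImageStack | np.ndarray) -> np.ndarray:
    """Maximum intensity projection of a stack (per-pixel max over z)."""
    planes = stack.planes if isinstance(stack, ImageStack) else np.asarray(stack)
    if planes.ndim != 3 or planes.shape[0] < 1:
        raise ValueError("expected a non-empty (n_planes, h, w) stack")
    return planes.max(axis=0)


def write_stack(path, stack: ImageStack, dtype=np.uint16) -> None:
    """Write a stack as a multi-page TIFF, rounding to the given integer dtype."""
    info = np.iinfo(dtype)
    data = np.clip(np.rint(stack.planes), info.min, info.max).astype(dtype)
    tifffile.imwrite(path, data, metadata={"axes": "ZYX"})


def read_stack(path, z_interval_um: float = 50.0, channel: str = "actin",
               well_id: str = "") -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    data = tifffile.imread(path)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[None, ...]
    return ImageStack(data, z_interval_um=z_interval_um, channel=channel,
                      well_id=well_id)
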