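"""In-memory containers for multi-channel 3D stacks and label volumes.

Stacks are stored channel-first ``(c, z, y, x)`` in memory and written to
TIFF as ``(z, c, y, x)`` 16-bit planes, the axis order confocal software
typically exports. Label volumes are written as 32-bit integer TIFF.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import FormatError

#: Channel order used throughout the package.
DEFAULT_CHANNELS = ("nuclei", "CD90", "CD19", "CD3", "CAR")

#: z-step from the study's confocal stacks (um); lateral size assumed isotropic.
DEFAULT_VOXEL_SIZE = (1.04, 1.0, 1.0)


@dataclass
class ImageStack:
    """A named multi-channel 3D voxel grid with physical voxel spacing.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, z, y, x)``; non-negative intensities.
    channel_names:
        Unique channel labels, one per leading-axis plane of ``data``.
    voxel_size:
        Physical voxel extent in micrometres, ordered ``(z, y, x)``.
    """

    data: np.ndarray
    channel_names: tuple = DEFAULT_CHANNELS
    voxel_size: tuple = DEFAULT_VOXEL_SIZE

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 4:
            raise FormatError(f"stack data must be 4D (c, z, y, x); got {self.data.ndim}D")
        if len(self.channel_names) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError("channel names must be unique")

    @property
    def shape(self) -> tuple:
        """Spatial shape ``(z, y, x)``."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D grid for one named channel."""
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None

    def write_tiff(self, path) -> None:
        """Write as a ``(z, c, y, x)`` uint16 TIFF; intensities are clipped."""
        arr = np.clip(np.rint(self.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(
            path,
            arr.transpose(1, 0, 2, 3),
            metadata={
                "axes": "ZCYX",
                "channel_names": list(self.channel_names),
                "voxel_size_um_zyx": list(map(float, self.voxel_size)),
            },
        )

    @classmethod
    def read_tiff(cls, path, channel_names=None, voxel_size=None) -> "ImageStack":
        """Read a ``(z, c, y, x)`` TIFF written by :meth:`write_tiff`."""
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        if arr.ndim != 4:
            raise FormatError(f"expected a 4D (z, c, y, x) TIFF; got {arr.ndim}D in {path}")
        if channel_names is None:
            channel_names = meta.get("channel_names")
        if channel_names is None:
            channel_names = [f"ch{i}" for i in range(arr.shape[1])]
        if voxel_size is None:
            voxel_size = tuple(meta.get("voxel_size_um_zyx", DEFAULT_VOXEL_SIZE))
        return cls(
            data=arr.transpose(1, 0, 2, 3).astype(np.float64),
            channel_names=tuple(channel_names),
            voxel_size=tuple(voxel_size),
        )


@dataclass
class LabelVolume:
    """Integer-labeled 3D segmentation; 0 is background, each id one cell mask."""

    labels: np.ndarray
    voxel_size: tuple = DEFAULT_VOXEL_SIZE
    id_map: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"label volume must be 3D; got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(f"labels must be integer-valued; got dtype {self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise FormatError("labels must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted nonzero label ids present in the volume."""
        ids = np.unique(self.labels)
        return ids[ids != 0]

    @property
    def n_cells(self) -> int:
        return int(self.ids.size)

    def write_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            self.labels.astype(np.int32),
            metadata={"axes": "ZYX", "voxel_size_um_zyx": list(map(float, self.voxel_size))},
        )
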