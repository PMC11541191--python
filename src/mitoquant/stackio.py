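"""ImageStack container and (OME-)TIFF reading/writing.

The pipeline's universal currency is a 5-D grey-value array in TCZYX order
(time, channel, z, y, x) with voxel-size metadata in micrometres.  Arrays
of lower dimensionality are promoted by inserting singleton axes on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["ImageStack", "read_stack", "write_stack"]

_AXES = "TCZYX"


@dataclass
class ImageStack:
    """n-D grey-value stack with voxel-size metadata.

    data : array in (t, c, z, y, x) order.
    voxel_size : (z, y, x) voxel edge lengths in um.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.130, 0.0425, 0.0425)
    channel_names: Optional[list[str]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim > 5:
            raise ValueError(f"at most 5 dimensions supported, got {arr.ndim}")
        while arr.ndim < 5:
            arr = arr[np.newaxis]
        self.data = arr
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def volume(self, t: int = 0, c: int = 0) -> np.ndarray:
        """The (z, y, x) volume for one timepoint and channel."""
        return self.data[t, c]

    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


def _normalise_axes(arr: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/pad an array with tifffile axis labels into TCZYX."""
    axes = axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if any(a not in _AXES for a in axes):
        raise ValueError(f"cannot interpret axes {axes!r}")
    for i, a in enumerate(_AXES):
        if a not in axes:
            arr = np.expand_dims(arr, i)
            axes = axes[:i] + a + axes[i:]
    order = [axes.index(a) for a in _AXES]
    return arr.transpose(order)


def read_stack(
    path: Union[str, Path],
    voxel_size: Optional[tuple[float, float, float]] = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Axes are normalised to TCZYX using the file's axis metadata; missing
    axes become singletons.  Voxel size is read from OME metadata when
    available; an explicit ``voxel_size`` argument always wins (a notice is
    logged when it overrides file metadata).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes
        meta_vs = None
        if tf.ome_metadata:
            try:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tf.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                px = root.find(".//ome:Pixels", ns)
                if px is not None:
                    sx = px.get("PhysicalSizeX")
                    sy = px.get("PhysicalSizeY")
                    sz = px.get("PhysicalSizeZ")
                    if sx and sy and sz:
                        meta_vs = (float(sz), float(sy), float(sx))
            except Exception:  # malformed OME block: fall back to override
                meta_vs = None
    data = _normalise_axes(arr, axes)
    if voxel_size is not None:
        if meta_vs is not None and tuple(voxel_size) != meta_vs:
            logger.info(
                "voxel-size override %s takes precedence over file metadata %s",
                voxel_size,
                meta_vs,
            )
        vs = tuple(voxel_size)
    elif meta_vs is not None:
        vs = meta_vs
    else:
        raise ValueError(
            f"{path}: no voxel-size metadata found and no override given"
        )
    return ImageStack(data=data, voxel_size=vs)


def write_stack(stack: ImageStack, path: Union[str, Path]) -> Path:
    """Write an :class:`ImageStack` as OME-TIFF with voxel-size metadata."""
    path = Path(path)
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        metadata={
            "axes": _AXES,
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
        },
    )
    return path
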