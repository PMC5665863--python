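"""Multi-channel 3D intensity stacks with physical voxel sizes.

The package works in physical micrometres throughout: confocal stacks of
the germarium are strongly anisotropic (0.43 um z step vs 0.14 um in xy),
so distances computed in voxel index space would be wrong.  Axis order is
(channel, z, y, x); coordinates are right-handed with the origin at the
centre of the corner voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile


class StackError(ValueError):
    """Raised for malformed stacks or missing metadata."""


@dataclass
class VoxelStack:
    """A (channel, z, y, x) intensity grid with voxel sizes in micrometres.

    Parameters
    ----------
    data:
        Non-negative intensity array of shape ``(n_channels, nz, ny, nx)``.
    voxel_size:
        ``(z, y, x)`` voxel edge lengths in um, all positive.
    channel_names:
        One unique name per channel, same length as the channel axis.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 4:
            raise StackError(f"expected 3-D or 4-D data, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise StackError(f"voxel sizes must be three positive floats, got {self.voxel_size}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise StackError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise StackError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical (z, y, x) extent in um (voxel count times voxel size)."""
        return tuple(n * v for n, v in zip(self.shape_zyx, self.voxel_size))

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise StackError(f"no channel named {name!r}; have {self.channel_names}") from None

    def um_to_voxel(self, pos_um: np.ndarray) -> np.ndarray:
        """Convert (z, y, x) um coordinates to fractional voxel indices."""
        return np.asarray(pos_um, dtype=float) / np.asarray(self.voxel_size)

    def voxel_to_um(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * np.asarray(self.voxel_size)


def write_stack(path, stack: VoxelStack) -> None:
    """Write a stack as OME-TIFF with voxel size and channel-name metadata."""
    vz, vy, vx = stack.voxel_size
    metadata = {
        "axes": "CZYX",
        "PhysicalSizeZ": vz,
        "PhysicalSizeY": vy,
        "PhysicalSizeX": vx,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
        "Channel": {"Name": list(stack.channel_names)},
    }
    tifffile.imwrite(str(path), stack.data, metadata=metadata, ome=True)


def read_stack(path, voxel_size=None, channel_names=None) -> VoxelStack:
    """Read a TIFF / OME-TIFF stack.

    Voxel size and channel names are taken from OME metadata when present;
    otherwise they must be supplied.  Integer data round-trips losslessly.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta_vs, meta_names = _parse_ome(tf)
    if data.ndim == 3:
        data = data[np.newaxis]
    if data.ndim != 4:
        raise StackError(f"unsupported TIFF dimensionality {data.ndim}")
    vs = voxel_size or meta_vs
    if vs is None:
        raise StackError("no voxel size in metadata and none supplied")
    names = channel_names or meta_names
    if names is not None and len(names) != data.shape[0]:
        raise StackError(f"{len(names)} channel names supplied for {data.shape[0]} channels")
    return VoxelStack(data=data, voxel_size=vs, channel_names=list(names) if names else [])


def _parse_ome(tf: tifffile.TiffFile):
    """Extract ((z,y,x) voxel size, channel names) from OME-XML, if present."""
    if not tf.is_ome or tf.ome_metadata is None:
        return None, None
    import xml.etree.ElementTree as ET

    root = ET.fromstring(tf.ome_metadata)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        return None, None
    try:
        vs = tuple(
            float(pixels.attrib[k]) for k in ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX")
        )
    except KeyError:
        vs = None
    names = [c.attrib.get("Name", f"ch{i}") for i, c in enumerate(pixels.findall("ome:Channel", ns))]
    return vs, (names or None)
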