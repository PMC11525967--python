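"""Reading and writing multi-channel stacks (OME-TIFF) and tabular outputs.

Stacks are written as OME-TIFF with voxel-size metadata and channel names.
Plain multi-page TIFFs without usable metadata are accepted when a YAML
sidecar supplies voxel sizes (and optionally channel names); the sidecar, when
present, always wins over embedded metadata.
"""

from __future__ import annotations

import hashlib
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .geometry import VoxelGrid
from .stack import ImageStack

__all__ = ["write_image", "read_image"]


def _make_deterministic_uuid(path: Path, data: np.ndarray) -> None:
    """Replace the writer's time-based OME UUID with one derived from the
    pixel data, so identical stacks produce byte-identical files."""
    raw = path.read_bytes()
    marker = b"urn:uuid:"
    i = raw.find(marker)
    if i < 0:
        return
    digest = hashlib.sha256(data.tobytes()).hexdigest()
    det = f"{digest[:8]}-{digest[8:12]}-{digest[12:16]}-{digest[16:20]}-{digest[20:32]}"
    j = i + len(marker)
    path.write_bytes(raw[:j] + det.encode() + raw[j + 36:])


def write_image(stack: ImageStack, path) -> None:
    """Write a stack as OME-TIFF (axes CZYX) with physical voxel sizes in µm."""
    path = Path(path)
    names = stack.channel_names
    data = np.stack([np.asarray(stack[c], dtype=np.float32) for c in names])
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.grid.dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.grid.dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.grid.dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": names},
        },
    )
    _make_deterministic_uuid(path, data)


def _parse_ome(xml_text: str):
    """Extract (dx, dy, dz, channel names) from OME-XML; None where absent."""
    root = ET.fromstring(xml_text)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        return None, None, None, []
    def _get(attr):
        v = pixels.get(attr)
        return float(v) if v is not None else None
    names = [
        ch.get("Name") or f"channel_{i}"
        for i, ch in enumerate(pixels.findall("ome:Channel", ns))
    ]
    return _get("PhysicalSizeX"), _get("PhysicalSizeY"), _get("PhysicalSizeZ"), names


def read_image(path, sidecar=None) -> ImageStack:
    """Read a multi-channel TIFF/OME-TIFF into an :class:`ImageStack`.

    Voxel sizes come from the OME metadata or, failing that, from a YAML
    sidecar (``dx_um``, ``dy_um``, ``dz_um``, optional ``channels`` list).
    Missing voxel sizes with no sidecar is an error, as is an unreadable file.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            ome_xml = tf.ome_metadata
    except Exception as exc:
        raise ValueError(f"cannot read image file {path}: {exc}") from exc

    dx = dy = dz = None
    names: list[str] = []
    if ome_xml:
        dx, dy, dz, names = _parse_ome(ome_xml)

    side = {}
    if sidecar is not None:
        side = yaml.safe_load(Path(sidecar).read_text()) or {}
    dx = side.get("dx_um", dx)
    dy = side.get("dy_um", dy)
    dz = side.get("dz_um", dz)
    if side.get("channels"):
        names = list(side["channels"])
    if dx is None or dy is None or dz is None:
        raise ValueError(
            f"{path}: no voxel-size metadata found and no sidecar provided "
            "(need dx_um, dy_um, dz_um)"
        )

    data = np.asarray(data)
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"{path}: expected CZYX or ZYX data, got {data.shape}")
    if not names or len(names) != data.shape[0]:
        names = [f"channel_{i}" for i in range(data.shape[0])]
    grid = VoxelGrid(dx=float(dx), dy=float(dy), dz=float(dz),
                     shape=tuple(data.shape[1:]))
    return ImageStack(
        channels={n: data[i].astype(np.float64) for i, n in enumerate(names)},
        grid=grid,
    )
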