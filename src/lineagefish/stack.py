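"""Multi-channel 3D image stacks with physical voxel sizes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import VoxelGrid

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A set of same-shape 3D channels sampled on one voxel grid.

    Channels are ``(nz, ny, nx)`` float arrays keyed by name (e.g. ``"dapi"``,
    ``"egl-1"``, ``"ced-3"``).
    """

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    grid: VoxelGrid = field(default_factory=VoxelGrid)

    def __post_init__(self) -> None:
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"channel {name!r} has shape {arr.shape}, "
                    f"grid expects {self.grid.shape}"
                )
            self.channels[name] = arr

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def scaled(self, factor: float) -> "ImageStack":
        """A copy with every channel multiplied by ``factor``."""
        return ImageStack(
            channels={k: v * factor for k, v in self.channels.items()},
            grid=self.grid,
        )
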