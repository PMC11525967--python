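"""Display helpers: time-course bands and maximum-intensity projections.

Numeric outputs are the contract of the analysis modules; everything here is
presentation only.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np
from scipy import ndimage

from .stack import ImageStack

__all__ = ["plot_timecourse", "max_projection"]


def plot_timecourse(tc, ax=None, landmark: bool = True):
    """Smoothed concentration vs nuclei count with shaded SEM bands.

    ``tc`` is the output of :func:`lineagefish.timecourse.build_timecourse`;
    one line per (cell, channel), with a dotted vertical line at the division
    landmark (e.g. ~180 nuclei, when MSpaap divides).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for (cell, channel), g in tc.groupby(["cell_name", "channel"]):
        ax.plot(g["smoothed_stage"], g["smoothed_value"],
                label=f"{cell} {channel}")
        ax.fill_between(
            g["smoothed_stage"],
            g["smoothed_value"] - g["sem"],
            g["smoothed_value"] + g["sem"],
            alpha=0.3,
        )
    if landmark and len(tc):
        ax.axvline(float(tc["division_landmark"].iloc[0]),
                   linestyle=":", color="k", linewidth=1)
    ax.set_xlabel("embryonic nuclei count")
    ax.set_ylabel("mRNA concentration [copies/µm³]")
    ax.legend(fontsize=8)
    return ax


def max_projection(stack: ImageStack, channel: str,
                   blur_radius_px: float = 1.5) -> np.ndarray:
    """Gaussian-smoothed maximum-intensity z-projection, for display only."""
    img = stack[channel]
    proj = np.asarray(img).max(axis=0)
    if blur_radius_px > 0:
        proj = ndimage.gaussian_filter(proj, blur_radius_px)
    return proj
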