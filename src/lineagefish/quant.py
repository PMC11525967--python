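"""Absolute mRNA copy numbers from smFISH stacks, and nuclei-count staging.

The estimator is intensity-based, not spot-counting-based: the total signal
``SI_Total`` integrated over a cell's spherical ROI, minus the mean signal
``SI_Bkgd`` of equally sized neighbouring regions free of mRNA signal, divided
by the integrated intensity of a single diffraction-limited spot ``SI_Spot``:

    copies = (SI_Total − SI_Bkgd) / SI_Spot

This remains accurate when spots overlap and cannot be counted individually.
Cell volumes assume sphericality, V = (π/6)·d³, so concentrations are
copies/µm³; embryos are staged by counting DAPI nuclei with a
difference-of-Gaussian blob detector.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import SphericalROI, VoxelGrid, sphere_volume
from .stack import ImageStack

__all__ = [
    "SpotDetectionParams",
    "NucleiDetectionParams",
    "CopyNumberEstimate",
    "StagePoint",
    "detect_spots",
    "integrate_roi_signal",
    "estimate_background",
    "calibrate_spot_intensity",
    "copy_number",
    "concentration",
    "count_nuclei",
    "fallback_positional_average",
    "quantify_stack",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpotDetectionParams:
    """Difference-of-Gaussian settings for diffraction-limited spots."""

    sigma_xy: float = 0.13  # µm
    sigma_z: float = 0.30  # µm
    threshold_mads: float = 10.0  # robust threshold above the DoG median
    min_separation_um: float = 0.4
    # a calibration spot counts as isolated only when no other candidate lies
    # within this many sigmas (per axis); 6 keeps neighbours out of the
    # integration box and its background shell
    isolation_sigmas: float = 6.0


@dataclass(frozen=True)
class NucleiDetectionParams:
    """Blob-detection settings for ~1 µm-sigma nuclei.

    Detection runs at ``detection_scale`` times the nuclear sigma: filtering
    at the full nuclear scale blurs neighbouring nuclei (≥ 2.5 µm apart) into
    single maxima, while half-scale filtering keeps them separable and is
    still far above the noise.
    """

    sigma_um: float = 1.0
    min_separation_um: float = 2.5
    detection_scale: float = 0.5
    threshold_rel: float = 0.25  # fraction of the peak DoG response
    threshold_mads: float = 6.0  # significance gate for any detection at all


@dataclass(frozen=True)
class CopyNumberEstimate:
    """One cell × channel intensity-based copy-number estimate."""

    cell_name: str
    channel: str
    si_total: float
    si_bkgd: float
    si_spot: float
    copies: float
    fallback: bool = False

    @classmethod
    def from_signals(
        cls, cell_name: str, channel: str,
        si_total: float, si_bkgd: float, si_spot: float,
    ) -> "CopyNumberEstimate":
        return cls(cell_name, channel, si_total, si_bkgd, si_spot,
                   copy_number(si_total, si_bkgd, si_spot))


@dataclass
class StagePoint:
    """One embryo's staged measurement: nuclei count + per-cell estimates."""

    embryo_id: str
    nuclei_count: int
    estimates: list[CopyNumberEstimate]
    diameters_um: dict[str, float]

    def __post_init__(self) -> None:
        if self.nuclei_count < 0:
            raise ValueError("nuclei_count must be non-negative")

    def concentration_of(self, cell_name: str, channel: str) -> float:
        for est in self.estimates:
            if est.cell_name == cell_name and est.channel == channel:
                return concentration(
                    est.copies, sphere_volume(self.diameters_um[cell_name])
                )
        raise KeyError(f"no estimate for {cell_name!r}/{channel!r}")


# ---------------------------------------------------------------------------
# detection primitives
# ---------------------------------------------------------------------------

def _resolve_channel(stack: ImageStack, channel: Optional[str]) -> np.ndarray:
    if channel is not None:
        return stack[channel]
    non_dapi = [c for c in stack.channel_names if c != "dapi"]
    if len(non_dapi) == 1:
        return stack[non_dapi[0]]
    raise ValueError(
        f"channel must be named explicitly; stack has {stack.channel_names}"
    )


def _dog_maxima(
    img: np.ndarray,
    grid: VoxelGrid,
    sigma_um: tuple[float, float, float],
    min_separation_um: float | tuple[float, float, float],
    threshold_rel: float,
    threshold_mads: float,
    mad_is_gate: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Difference-of-Gaussian local maxima.

    Returns ``(centers_um, responses)`` where centers are (x, y, z) in µm.
    The robust noise level (median + ``threshold_mads``·MAD of the DoG
    response) is used either as a per-voxel floor combined with
    ``threshold_rel`` of the peak response (sparse bright spots), or — with
    ``mad_is_gate`` — only as a global significance gate, after which the
    relative threshold alone applies (dense blobs, whose signal inflates the
    MAD itself).
    """
    img = np.asarray(img, dtype=float)
    sz, sy, sx = sigma_um[2] / grid.dz, sigma_um[1] / grid.dy, sigma_um[0] / grid.dx
    s1 = (sz, sy, sx)
    s2 = tuple(1.6 * s for s in s1)
    dog = ndimage.gaussian_filter(img, s1) - ndimage.gaussian_filter(img, s2)
    if not np.any(dog > 0):
        return np.empty((0, 3)), np.empty(0)

    med = float(np.median(dog))
    mad = float(np.median(np.abs(dog - med)))
    noise_level = med + threshold_mads * 1.4826 * mad
    if mad_is_gate:
        if float(dog.max()) <= noise_level:
            return np.empty((0, 3)), np.empty(0)
        thresh = threshold_rel * float(dog.max())
    else:
        thresh = max(threshold_rel * float(dog.max()), noise_level)

    if isinstance(min_separation_um, (int, float)):
        sep = (min_separation_um,) * 3
    else:
        sep = tuple(min_separation_um)
    # stage 1: local maxima over a half-separation box
    size = (
        max(3, 2 * int(math.ceil(sep[2] / (2 * grid.dz))) + 1),
        max(3, 2 * int(math.ceil(sep[1] / (2 * grid.dy))) + 1),
        max(3, 2 * int(math.ceil(sep[0] / (2 * grid.dx))) + 1),
    )
    is_max = dog == ndimage.maximum_filter(dog, size=size, mode="nearest")
    kz, jy, ix = np.nonzero(is_max & (dog > thresh))
    centers = np.column_stack([
        (ix + 0.5) * grid.dx,
        (jy + 0.5) * grid.dy,
        (kz + 0.5) * grid.dz,
    ])
    responses = dog[kz, jy, ix]
    if len(centers) <= 1:
        return centers, responses
    # stage 2: greedy anisotropic suppression at the full separation
    order = np.argsort(responses)[::-1]
    sep_xy2, sep_z2 = sep[0] * sep[1], sep[2] ** 2
    kept: list[int] = []
    kept_pts = np.empty((0, 3))
    for i in order:
        c = centers[i]
        if len(kept):
            dxy2 = ((kept_pts[:, :2] - c[:2]) ** 2).sum(axis=1)
            dz2 = (kept_pts[:, 2] - c[2]) ** 2
            if np.any(dxy2 / sep_xy2 + dz2 / sep_z2 < 1.0):
                continue
        kept.append(i)
        kept_pts = np.vstack([kept_pts, c[None]])
    kept_arr = np.sort(np.array(kept))
    return centers[kept_arr], responses[kept_arr]


def detect_spots(
    stack: ImageStack,
    params: SpotDetectionParams | None = None,
    channel: Optional[str] = None,
) -> np.ndarray:
    """Candidate spot centres ``(x, y, z)`` in µm (difference-of-Gaussian)."""
    params = params or SpotDetectionParams()
    img = _resolve_channel(stack, channel)
    centers, _ = _dog_maxima(
        img, stack.grid,
        (params.sigma_xy, params.sigma_xy, params.sigma_z),
        (params.min_separation_um, params.min_separation_um,
         max(params.min_separation_um, 2.0 * params.sigma_z)),
        threshold_rel=0.05,
        threshold_mads=params.threshold_mads,
    )
    return centers


# ---------------------------------------------------------------------------
# ROI integration and background
# ---------------------------------------------------------------------------

def integrate_roi_signal(
    stack: ImageStack,
    roi: SphericalROI,
    channel: Optional[str] = None,
) -> float:
    """SI_Total: summed intensity over the ROI disk in the z-slab sum-projection.

    The slab comprises every slice whose centre lies in [z−r, z+r]; the disk
    has the cell's diameter, centred on the cell, in the projection.
    """
    img = _resolve_channel(stack, channel)
    grid = stack.grid
    roi.check_within(grid)
    cx, cy, cz = roi.center
    slab = grid.z_slab(cz - roi.radius, cz + roi.radius)
    proj = img[slab].sum(axis=0)
    mask = grid.disk_mask(cx, cy, roi.radius)
    return float(proj[mask].sum())


def _compass_candidates(
    roi: SphericalROI, grid: VoxelGrid, distance_factor: float = 1.5
) -> list[SphericalROI]:
    """Up to 8 same-size disks around the ROI at 1.5 diameters, in-bounds only."""
    cx, cy, cz = roi.center
    d = distance_factor * roi.diameter
    out = []
    for ang in range(8):
        theta = ang * math.pi / 4.0
        cand = SphericalROI(
            (cx + d * math.cos(theta), cy + d * math.sin(theta), cz),
            roi.diameter,
        )
        if cand.within(grid):
            out.append(cand)
    return out


def _region_median(img: np.ndarray, grid: VoxelGrid, roi: SphericalROI) -> float:
    cx, cy, cz = roi.center
    slab = grid.z_slab(cz - roi.radius, cz + roi.radius)
    mask = grid.disk_mask(cx, cy, roi.radius)
    return float(np.median(img[np.ix_(slab, *np.nonzero(mask))]))


def _region_voxels(grid: VoxelGrid, roi: SphericalROI) -> int:
    slab = grid.z_slab(roi.center[2] - roi.radius, roi.center[2] + roi.radius)
    return int(len(slab) * grid.disk_mask(roi.center[0], roi.center[1],
                                          roi.radius).sum())


def estimate_background(
    stack: ImageStack,
    roi: SphericalROI,
    n_regions: int = 3,
    params: SpotDetectionParams | None = None,
    channel: Optional[str] = None,
    spots: Optional[np.ndarray] = None,
) -> float:
    """SI_Bkgd: mean integrated intensity of neighbouring signal-free regions.

    Candidate regions are eight same-size disks at 1.5 diameters from the ROI
    centre (compass directions in-plane); regions containing detected spots
    are dropped ("no visible mRNA signal").  Among the remaining candidates,
    the ``n_regions`` whose mean is closest to the spot-free consensus
    (median) are used, which keeps the estimate unbiased under slowly varying
    background.  With fewer than ``n_regions`` spot-free candidates, the
    lowest-intensity candidates fill in and a warning is logged.
    """
    img = _resolve_channel(stack, channel)
    grid = stack.grid
    params = params or SpotDetectionParams()
    candidates = _compass_candidates(roi, grid)
    if len(candidates) < n_regions:
        raise ValueError(
            f"only {len(candidates)} candidate background regions fit in the "
            f"image; {n_regions} required"
        )
    if spots is None:
        spots = detect_spots(stack, params, channel)

    def _contains_spot(cand: SphericalROI) -> bool:
        if len(spots) == 0:
            return False
        cx, cy, cz = cand.center
        inxy = ((spots[:, 0] - cx) ** 2 + (spots[:, 1] - cy) ** 2) <= cand.radius**2
        inz = np.abs(spots[:, 2] - cz) <= cand.radius
        return bool(np.any(inxy & inz))

    # normalise each candidate integral to the ROI's voxel count: sub-voxel
    # alignment makes equal-diameter disks cover slightly different numbers of
    # voxel centres, which would otherwise bias the background by a fraction
    # of a spot
    roi_voxels = _region_voxels(grid, roi)
    integrals = {
        i: integrate_roi_signal(stack, cand, channel)
        * roi_voxels / _region_voxels(grid, cand)
        for i, cand in enumerate(candidates)
    }
    free = [i for i, cand in enumerate(candidates) if not _contains_spot(cand)]

    if len(free) >= n_regions:
        consensus = float(np.median([integrals[i] for i in free]))
        best = min(
            itertools.combinations(free, n_regions),
            key=lambda combo: abs(
                np.mean([integrals[i] for i in combo]) - consensus
            ),
        )
        chosen = list(best)
    else:
        logger.warning(
            "only %d spot-free background regions near ROI at %s; "
            "falling back to lowest-intensity candidates",
            len(free), roi.center,
        )
        ranked = sorted(integrals, key=lambda i: _region_median(img, grid,
                                                                candidates[i]))
        chosen = list(free)
        for i in ranked:
            if len(chosen) >= n_regions:
                break
            if i not in chosen:
                chosen.append(i)
    return float(np.mean([integrals[i] for i in chosen]))


# ---------------------------------------------------------------------------
# single-spot calibration
# ---------------------------------------------------------------------------

def _spot_box_geometry(grid: VoxelGrid, sigma_xy: float, sigma_z: float):
    """Half-extents (voxels) of the 3σ integration box and its background
    shell, plus the per-axis isolation radii (µm) outside which another spot
    cannot touch the shell."""
    hx = max(2, int(math.ceil(3 * sigma_xy / grid.dx)))
    hy = max(2, int(math.ceil(3 * sigma_xy / grid.dy)))
    hz = max(1, int(math.ceil(3 * sigma_z / grid.dz)))
    sx = hx + max(2, int(math.ceil(2 * sigma_xy / grid.dx)))
    sy = hy + max(2, int(math.ceil(2 * sigma_xy / grid.dy)))
    sz = hz + 1
    iso = (
        (sx + 1) * grid.dx + 3 * sigma_xy,
        (sy + 1) * grid.dy + 3 * sigma_xy,
        (sz + 1) * grid.dz + 3 * sigma_z,
    )
    return (hx, hy, hz), (sx, sy, sz), iso


def _integrate_spot(
    img: np.ndarray, grid: VoxelGrid, center: np.ndarray,
    sigma_xy: float, sigma_z: float,
) -> float:
    """Integrated intensity of one spot above its local background shell."""
    cx, cy, cz = center
    (hx, hy, hz), (sx, sy, sz), _ = _spot_box_geometry(grid, sigma_xy, sigma_z)
    ix, iy, iz = int(cx / grid.dx), int(cy / grid.dy), int(cz / grid.dz)

    def _clip_box(h0, h1, h2):
        return (
            slice(max(0, iz - h2), min(grid.nz, iz + h2 + 1)),
            slice(max(0, iy - h1), min(grid.ny, iy + h1 + 1)),
            slice(max(0, ix - h0), min(grid.nx, ix + h0 + 1)),
        )

    inner = img[_clip_box(hx, hy, hz)]
    outer = img[_clip_box(sx, sy, sz)]
    shell_sum = outer.sum() - inner.sum()
    shell_n = outer.size - inner.size
    local_bg = shell_sum / shell_n if shell_n > 0 else 0.0
    return float(inner.sum() - local_bg * inner.size)


def calibrate_spot_intensity(
    stack: ImageStack,
    params: SpotDetectionParams | None = None,
    channel: Optional[str] = None,
    min_spots: int = 5,
) -> float:
    """SI_Spot: robust (median) integrated intensity of isolated single spots.

    Spots are difference-of-Gaussian candidates kept only if no other
    candidate lies within the isolation radius; each is integrated above its
    local background shell.  Raises when fewer than ``min_spots`` isolated
    spots are found — enter SI_Spot manually via the run configuration in
    that case.
    """
    params = params or SpotDetectionParams()
    img = _resolve_channel(stack, channel)
    centers = detect_spots(stack, params, channel)
    if len(centers) == 0:
        raise ValueError(
            "no diffraction-limited spots detected; supply SI_Spot manually "
            "via the configuration"
        )
    # anisotropic box isolation matching the integration box + background
    # shell: a neighbour contaminates only if it is close on *every* axis
    grid = stack.grid
    _, _, (rx, ry, rz) = _spot_box_geometry(grid, params.sigma_xy,
                                            params.sigma_z)
    rx = max(rx, params.isolation_sigmas * params.sigma_xy)
    keep = []
    for i, c in enumerate(centers):
        d = np.abs(centers - c)
        inside = (d[:, 0] < rx) & (d[:, 1] < ry) & (d[:, 2] < rz)
        inside[i] = False
        if not inside.any():
            keep.append(i)
    if len(keep) < min_spots:
        raise ValueError(
            f"only {len(keep)} isolated spots found (need ≥ {min_spots}); "
            "supply SI_Spot manually via the configuration"
        )
    vals = [
        _integrate_spot(img, stack.grid, centers[i],
                        params.sigma_xy, params.sigma_z)
        for i in keep
    ]
    return float(np.median(vals))


# ---------------------------------------------------------------------------
# arithmetic of the estimator
# ---------------------------------------------------------------------------

def copy_number(si_total: float, si_bkgd: float, si_spot: float) -> float:
    """(SI_Total − SI_Bkgd) / SI_Spot, clipped at zero (clipping is logged)."""
    if si_spot <= 0:
        raise ValueError("SI_Spot must be positive")
    raw = (si_total - si_bkgd) / si_spot
    if raw < 0:
        logger.info("negative copy number %.3f clipped to 0", raw)
        return 0.0
    return raw


def concentration(copies: float, volume: float) -> float:
    """mRNA concentration in copies/µm³."""
    if volume <= 0:
        raise ValueError("cell volume must be positive")
    return copies / volume


def count_nuclei(
    dapi_stack: ImageStack | np.ndarray,
    params: NucleiDetectionParams | None = None,
    grid: VoxelGrid | None = None,
) -> int:
    """Number of nuclei in the DAPI channel (3D blob maxima after NMS).

    Zero is a valid answer (empty or signal-free stack).
    """
    params = params or NucleiDetectionParams()
    if isinstance(dapi_stack, ImageStack):
        img = dapi_stack["dapi"] if "dapi" in dapi_stack else _resolve_channel(
            dapi_stack, None)
        grid = dapi_stack.grid
    else:
        img = np.asarray(dapi_stack)
        if grid is None:
            raise ValueError("grid required when passing a bare array")
    if img.size == 0:
        return 0
    s = params.detection_scale * params.sigma_um
    centers, _ = _dog_maxima(
        img, grid,
        (s, s, s),
        0.8 * params.min_separation_um,
        threshold_rel=params.threshold_rel,
        threshold_mads=params.threshold_mads,
        mad_is_gate=True,
    )
    return int(len(centers))


def fallback_positional_average(estimates: Sequence) -> float:
    """Positional fallback: mean copy number of the four cells at the
    expected position of an undetectable cell of interest.

    Accepts exactly four :class:`CopyNumberEstimate` objects or numbers.
    Outputs using this value must be flagged as a positional fallback.
    """
    if len(estimates) != 4:
        raise ValueError(f"expected exactly 4 estimates, got {len(estimates)}")
    vals = [
        e.copies if isinstance(e, CopyNumberEstimate) else float(e)
        for e in estimates
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def quantify_stack(
    stack: ImageStack,
    rois: pd.DataFrame,
    embryo_id: str = "embryo_001",
    spot_params: SpotDetectionParams | None = None,
    nuclei_params: NucleiDetectionParams | None = None,
    si_spot_override: Optional[float] = None,
) -> pd.DataFrame:
    """Quantify every ROI row against a stack; returns the tidy estimate table.

    ``rois`` columns: cell_name, x_um, y_um, z_um, diameter_um, channel.
    SI_Spot is calibrated per image and channel (median over isolated spots)
    unless ``si_spot_override`` is given.  The DAPI channel, when present,
    provides the embryonic nuclei count used as the developmental stage.
    """
    spot_params = spot_params or SpotDetectionParams()
    required = {"cell_name", "x_um", "y_um", "z_um", "diameter_um", "channel"}
    missing = required - set(rois.columns)
    if missing:
        raise ValueError(f"ROI table missing columns {sorted(missing)}")

    nuclei = (
        count_nuclei(stack, nuclei_params) if "dapi" in stack else 0
    )
    rows = []
    for channel, group in rois.groupby("channel", sort=False):
        channel = str(channel)
        si_spot = (
            si_spot_override
            if si_spot_override is not None
            else calibrate_spot_intensity(stack, spot_params, channel)
        )
        spots = detect_spots(stack, spot_params, channel)
        for _, r in group.iterrows():
            roi = SphericalROI(
                (float(r.x_um), float(r.y_um), float(r.z_um)),
                float(r.diameter_um),
            )
            si_total = integrate_roi_signal(stack, roi, channel)
            si_bkgd = estimate_background(stack, roi, params=spot_params,
                                          channel=channel, spots=spots)
            copies = copy_number(si_total, si_bkgd, si_spot)
            vol = sphere_volume(roi.diameter)
            rows.append({
                "embryo_id": embryo_id,
                "cell_name": r.cell_name,
                "channel": channel,
                "si_total": si_total,
                "si_bkgd": si_bkgd,
                "si_spot": si_spot,
                "copies": copies,
                "volume_um3": vol,
                "concentration": concentration(copies, vol),
                "nuclei_count": nuclei,
                "fallback_flag": False,
            })
    return pd.DataFrame(rows)
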