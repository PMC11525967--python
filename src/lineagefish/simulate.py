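"""Synthetic smFISH stacks and 4D lineage records with known ground truth.

Everything downstream (copy-number quantification, nuclei staging, fate
classification, time-courses) is validated against this generator, so it is a
first-class, fully specified component rather than a test fixture.

Images
------
mRNAs appear as diffraction-limited spots: 3D Gaussians with lateral sigma
``sigma_xy`` and axial sigma ``sigma_z``, sampled on 500-nm-spaced z-slices.
Each spot's *integrated* intensity (its total voxel sum) is drawn from a
Gamma distribution with mean ``unit_integrated_intensity`` and coefficient of
variation ``intensity_cv``, mimicking probe-set labelling variability.  Spots
are placed uniformly inside the cell sphere, inset by 2.5 sigmas per axis so
the rendered point-spread mass stays inside the cell.  The DAPI channel
contains a configurable number of non-overlapping nuclear blobs (sigma 1 µm,
centres ≥ 2.5 µm apart) so a blob detector of that resolution can recover the
embryonic nuclei count.  Noise: flat or linearly tilted background, optional
Poisson shot noise, Gaussian read noise.

Lineages
--------
Named regimes bundle the lineage statistics of a genotype: mother cell-cycle
means, per-round cycle lengthening along a reference path (e.g. ABarp →
ABarpppppp), probabilities that a programmed death or a sister/mother division
is blocked, and time-to-corpse distributions.  The built-in regimes are
calibrated to a wild-type embryo, a CMG-helicase-compromised mutant
(``psf2_like``), a thymidylate-synthase mutant (``tyms1_like``, long cycles
but intact deaths) and a caspase-null (``ced3_like``, all deaths blocked).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .geometry import VoxelGrid, sphere_volume
from .lineage import LineageNode, LineageRecord, mother_name, sister_name
from .stack import ImageStack

__all__ = [
    "SpotModel",
    "NoiseModel",
    "SyntheticCell",
    "Regime",
    "GroundTruth",
    "REGIMES",
    "get_regime",
    "DEFAULT_AB_CANDIDATES",
    "simulate_embryo_image",
    "simulate_lineage",
    "simulate_stage_series",
]


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotModel:
    """Rendering model for one diffraction-limited mRNA spot.

    ``unit_integrated_intensity`` is the true single-molecule integrated
    intensity (the quantity a calibration step estimates); ``probe_count`` is
    bookkeeping for the oligo probe set (23 for the egl-1 set, 48 for ced-3).
    """

    sigma_xy: float = 0.13
    sigma_z: float = 0.30
    unit_integrated_intensity: float = 500.0
    intensity_cv: float = 0.2
    probe_count: int = 23

    def __post_init__(self) -> None:
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ValueError("spot sigmas must be positive")
        if self.unit_integrated_intensity <= 0:
            raise ValueError("unit_integrated_intensity must be positive")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Camera/background model: tilted background + shot + read noise."""

    background_level: float = 5.0
    background_gradient: float = 0.0  # units per µm along x
    shot_noise: bool = True
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")

    @staticmethod
    def none() -> "NoiseModel":
        """Zero-noise, zero-background model for oracle tests."""
        return NoiseModel(0.0, 0.0, False, 0.0)


@dataclass(frozen=True)
class SyntheticCell:
    """A spherical cell with known per-channel transcript counts."""

    name: str
    center: tuple[float, float, float]  # µm
    diameter: float  # µm
    true_mrna_count: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("cell diameter must be positive")
        for ch, n in self.true_mrna_count.items():
            if n < 0:
                raise ValueError(f"negative transcript count for channel {ch!r}")


@dataclass(frozen=True)
class Regime:
    """Named parameter bundle for lineage simulation.

    Cycle parameters are minutes.  ``mother_cycle_mean`` applies to mothers
    whose daughter goes on to die; ``mother_cycle_blocked_mean`` (when set) to
    mothers whose daughter's death is blocked — the two populations have
    distinct printed means in the helicase-mutant regime (108 vs 101 min).
    Death-block probabilities are looked up by the candidate's founder: AB
    descendants, MS descendants, and postembryonic Q-lineage deaths.
    ``cycle_round_start_mean`` and ``cycle_lengthening_factor`` describe the
    per-round cycle ramp along a reference non-death lineage path.
    """

    name: str
    mother_cycle_mean: float = 42.0
    mother_cycle_sd: float = 8.0
    mother_cycle_blocked_mean: Optional[float] = None
    cycle_round_start_mean: float = 22.0
    cycle_lengthening_factor: float = (40.0 / 22.0) ** 0.25
    death_block_probability: float = 0.0
    ms_death_block_probability: float = 0.0
    larval_death_block_probability: float = 0.0
    division_block_probability: float = 0.0
    sister_inappropriate_death_probability: float = 0.0
    mother_death_probability: float = 0.0
    time_to_corpse_mean: float = 23.6
    time_to_corpse_sd: Optional[float] = None  # default: 30% of the mean

    def __post_init__(self) -> None:
        for p in (
            self.death_block_probability,
            self.ms_death_block_probability,
            self.larval_death_block_probability,
            self.division_block_probability,
            self.sister_inappropriate_death_probability,
            self.mother_death_probability,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.mother_cycle_mean, self.cycle_round_start_mean,
               self.time_to_corpse_mean) <= 0:
            raise ValueError("means must be positive")

    @property
    def corpse_sd(self) -> float:
        return (
            self.time_to_corpse_sd
            if self.time_to_corpse_sd is not None
            else 0.3 * self.time_to_corpse_mean
        )

    def block_probability_for(self, candidate: str) -> float:
        if candidate.startswith("MS"):
            return self.ms_death_block_probability
        if candidate.startswith("Q"):
            return self.larval_death_block_probability
        return self.death_block_probability


REGIMES: dict[str, Regime] = {
    "wild_type": Regime(
        name="wild_type",
        mother_cycle_mean=42.0,
        mother_cycle_sd=8.0,
        cycle_round_start_mean=22.0,
        cycle_lengthening_factor=(40.0 / 22.0) ** 0.25,
        time_to_corpse_mean=23.6,
    ),
    "psf2_like": Regime(
        name="psf2_like",
        mother_cycle_mean=108.0,
        mother_cycle_sd=30.0,
        mother_cycle_blocked_mean=101.0,
        cycle_round_start_mean=39.0,
        cycle_lengthening_factor=(144.0 / 39.0) ** 0.25,
        death_block_probability=0.63,
        ms_death_block_probability=0.67,
        larval_death_block_probability=0.29,
        division_block_probability=0.342,
        time_to_corpse_mean=49.7,
    ),
    "tyms1_like": Regime(
        name="tyms1_like",
        mother_cycle_mean=125.0,
        mother_cycle_sd=30.0,
        cycle_round_start_mean=39.0,
        cycle_lengthening_factor=(144.0 / 39.0) ** 0.25,
        time_to_corpse_mean=23.6,
    ),
    "ced3_like": Regime(
        name="ced3_like",
        mother_cycle_mean=42.0,
        mother_cycle_sd=8.0,
        cycle_round_start_mean=22.0,
        cycle_lengthening_factor=(40.0 / 22.0) ** 0.25,
        death_block_probability=1.0,
        ms_death_block_probability=1.0,
        larval_death_block_probability=1.0,
        time_to_corpse_mean=23.6,
    ),
}


def get_regime(name: str, **overrides) -> Regime:
    """Fetch a built-in regime, optionally overriding fields (name ``custom``)."""
    if name in REGIMES:
        base = REGIMES[name]
        return replace(base, **overrides) if overrides else base
    if name == "custom":
        return Regime(name="custom", **overrides)
    raise KeyError(f"unknown regime {name!r}; known: {sorted(REGIMES)} or 'custom'")


# The first wave of cell death comprises 13 AB-derived cells (dying after the
# 9th division round).  Only two of them are fixed here by name; the remaining
# eleven are synthetic placeholder names (valid Sulston strings) since the
# full canonical list lives in the classic lineage literature.  Override with
# your own list when the real names matter.
DEFAULT_AB_CANDIDATES: tuple[str, ...] = (
    "ABalaapapa",
    "ABalaappaa",
    # synthetic placeholders:
    "ABalapaapa",
    "ABalappapa",
    "ABalpaapaa",
    "ABalppapaa",
    "ABaraapapa",
    "ABarapppaa",
    "ABarppapaa",
    "ABplaapapa",
    "ABplpapapa",
    "ABpraapppa",
    "ABprpappaa",
)


@dataclass
class GroundTruth:
    """What the generator actually did, keyed for downstream comparison."""

    # imaging
    true_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    spot_intensities: dict[tuple[str, str], list[float]] = field(default_factory=dict)
    nuclei_count: Optional[int] = None
    nuclei_centers: list[tuple[float, float, float]] = field(default_factory=list)
    # lineaging: (embryo_id, cell_name) -> label
    fate_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    sister_labels: dict[tuple[str, str], str] = field(default_factory=dict)

    def mean_spot_intensity(self, cell: str, channel: str) -> float:
        vals = self.spot_intensities[(cell, channel)]
        return float(np.mean(vals)) if vals else math.nan

    def to_jsonable(self) -> dict:
        return {
            "true_counts": {f"{c}|{ch}": n for (c, ch), n in self.true_counts.items()},
            "nuclei_count": self.nuclei_count,
            "nuclei_centers": [list(c) for c in self.nuclei_centers],
            "fate_labels": {f"{e}|{c}": v for (e, c), v in self.fate_labels.items()},
            "sister_labels": {f"{e}|{c}": v
                              for (e, c), v in self.sister_labels.items()},
        }


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------

def _erf_kernel_1d(coords: np.ndarray, center: float, sigma: float,
                   step: float) -> np.ndarray:
    """Per-voxel integral of a unit Gaussian over voxel extents.

    ``coords`` are voxel-centre coordinates; the kernel entry is the Gaussian
    mass falling inside each voxel, so the full-axis sum is 1 up to tail
    truncation.
    """
    a = (coords - step / 2.0 - center) / (sigma * math.sqrt(2.0))
    b = (coords + step / 2.0 - center) / (sigma * math.sqrt(2.0))
    return 0.5 * (special.erf(b) - special.erf(a))


def _render_gaussian(
    img: np.ndarray,
    grid: VoxelGrid,
    center: tuple[float, float, float],
    sigma_xy: float,
    sigma_z: float,
    integrated: float,
    halfwidth_sigmas: float = 5.0,
) -> None:
    """Add a 3D Gaussian of the given integrated (voxel-sum) intensity in place."""
    cx, cy, cz = center
    hx = max(1, int(math.ceil(halfwidth_sigmas * sigma_xy / grid.dx)))
    hy = max(1, int(math.ceil(halfwidth_sigmas * sigma_xy / grid.dy)))
    hz = max(1, int(math.ceil(halfwidth_sigmas * sigma_z / grid.dz)))
    ix = int(cx / grid.dx)
    iy = int(cy / grid.dy)
    iz = int(cz / grid.dz)
    x0, x1 = max(0, ix - hx), min(grid.nx, ix + hx + 1)
    y0, y1 = max(0, iy - hy), min(grid.ny, iy + hy + 1)
    z0, z1 = max(0, iz - hz), min(grid.nz, iz + hz + 1)
    xs = (np.arange(x0, x1) + 0.5) * grid.dx
    ys = (np.arange(y0, y1) + 0.5) * grid.dy
    zs = (np.arange(z0, z1) + 0.5) * grid.dz
    kx = _erf_kernel_1d(xs, cx, sigma_xy, grid.dx)
    ky = _erf_kernel_1d(ys, cy, sigma_xy, grid.dy)
    kz = _erf_kernel_1d(zs, cz, sigma_z, grid.dz)
    img[z0:z1, y0:y1, x0:x1] += (
        integrated * kz[:, None, None] * ky[None, :, None] * kx[None, None, :]
    )


def _uniform_in_inset_sphere(
    rng: np.random.Generator,
    center: tuple[float, float, float],
    radius: float,
    margin_xy: float,
    margin_z: float,
    n: int,
) -> np.ndarray:
    """Uniform points in the ellipsoid obtained by insetting the sphere per axis."""
    ax = max(radius - margin_xy, 0.2 * radius)
    az = max(radius - margin_z, 0.2 * radius)
    pts = np.empty((n, 3))
    semi = np.array([ax, ax, az])
    got = 0
    while got < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - got) + 8, 3))
        keep = (cand**2).sum(axis=1) <= 1.0
        cand = cand[keep][: n - got]
        pts[got:got + len(cand)] = cand * semi + np.asarray(center)
        got += len(cand)
    return pts


def _sample_spot_intensities(
    rng: np.random.Generator, model: SpotModel, n: int
) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    u, cv = model.unit_integrated_intensity, model.intensity_cv
    if cv == 0:
        return np.full(n, u)
    shape = 1.0 / cv**2
    return rng.gamma(shape, u / shape, size=n)


def _nuclei_positions(
    rng: np.random.Generator,
    grid: VoxelGrid,
    n: int,
    min_separation: float,
    margin: float,
) -> np.ndarray:
    """Jittered-grid nucleus centres with guaranteed minimum separation."""
    if n == 0:
        return np.empty((0, 3))
    ex, ey, ez = grid.extent
    spacing = min_separation + 0.5
    jitter = 0.2
    axes = []
    for ext in (ex, ey, ez):
        lo, hi = margin, ext - margin
        if hi <= lo:
            raise ValueError("image volume too small for nuclei placement")
        k = max(1, int((hi - lo) / spacing) + 1)
        axes.append(lo + np.arange(k) * spacing)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    sites = sites[(sites[:, 0] <= ex - margin)
                  & (sites[:, 1] <= ey - margin)
                  & (sites[:, 2] <= ez - margin)]
    if len(sites) < n:
        raise ValueError(
            f"cannot place {n} nuclei at ≥{min_separation} µm separation in a "
            f"{ex:.0f}×{ey:.0f}×{ez:.0f} µm volume ({len(sites)} sites)"
        )
    idx = rng.choice(len(sites), size=n, replace=False)
    chosen = sites[idx]
    chosen = chosen + rng.uniform(-jitter, jitter, size=chosen.shape)
    return chosen


def simulate_embryo_image(
    cells: Sequence[SyntheticCell],
    spot_model: SpotModel | None = None,
    noise: NoiseModel | None = None,
    nuclei_count: int = 0,
    voxel_grid: VoxelGrid | None = None,
    seed: int = 0,
    nuclei_sigma: float = 1.0,
    nuclei_min_separation: float = 2.5,
    nuclei_intensity: float = 20000.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render an embryo stack: one channel per probed mRNA plus ``dapi``.

    Each cell receives exactly its ``true_mrna_count`` spots, placed uniformly
    inside its sphere (inset by 2.5 sigmas so the spot mass stays inside the
    cell); spot integrated intensities are Gamma-distributed around the unit
    intensity.  Identical seeds give bit-identical stacks.

    Raises if cells overlap or leave the volume; warns (does not fail) when
    the spot density is too high for isolated-spot calibration.
    """
    spot_model = spot_model or SpotModel()
    noise = noise or NoiseModel()
    grid = voxel_grid or VoxelGrid()
    if nuclei_count < 0:
        raise ValueError("nuclei_count must be non-negative")

    ex, ey, ez = grid.extent
    for cell in cells:
        x, y, z = cell.center
        r = cell.diameter / 2.0
        if not (r <= x <= ex - r and r <= y <= ey - r and r <= z <= ez - r):
            raise ValueError(f"cell {cell.name!r} does not fit inside the volume")
    for i, a in enumerate(cells):
        for b in cells[i + 1:]:
            d = math.dist(a.center, b.center)
            if d < (a.diameter + b.diameter) / 2.0:
                raise ValueError(f"cells {a.name!r} and {b.name!r} overlap")

    channel_names: list[str] = []
    for cell in cells:
        for ch in cell.true_mrna_count:
            if ch not in channel_names:
                channel_names.append(ch)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    truth = GroundTruth()
    channels = {ch: np.zeros(grid.shape) for ch in channel_names}

    margin_xy = 2.5 * spot_model.sigma_xy
    margin_z = 2.5 * spot_model.sigma_z
    spot_footprint = (4 * spot_model.sigma_xy) ** 2 * (4 * spot_model.sigma_z)
    for cell in cells:
        r = cell.diameter / 2.0
        placement_vol = sphere_volume(cell.diameter)
        for ch in channel_names:
            n = int(cell.true_mrna_count.get(ch, 0))
            truth.true_counts[(cell.name, ch)] = n
            if n == 0:
                truth.spot_intensities[(cell.name, ch)] = []
                continue
            if n * spot_footprint > placement_vol:
                warnings.warn(
                    f"cell {cell.name!r}, channel {ch!r}: {n} spots are dense "
                    "enough that isolated-spot calibration may fail",
                    stacklevel=2,
                )
            pts = _uniform_in_inset_sphere(rng, cell.center, r, margin_xy,
                                           margin_z, n)
            intensities = _sample_spot_intensities(rng, spot_model, n)
            truth.spot_intensities[(cell.name, ch)] = [float(v) for v in intensities]
            for p, inten in zip(pts, intensities):
                _render_gaussian(channels[ch], grid, tuple(p),
                                 spot_model.sigma_xy, spot_model.sigma_z,
                                 float(inten))

    # DAPI nuclei
    dapi = np.zeros(grid.shape)
    centers = _nuclei_positions(rng, grid, nuclei_count, nuclei_min_separation,
                                margin=max(2.0, 2.0 * nuclei_sigma))
    for c in centers:
        inten = nuclei_intensity * (1.0 + 0.1 * rng.standard_normal())
        _render_gaussian(dapi, grid, tuple(c), nuclei_sigma, nuclei_sigma,
                         max(inten, 0.1 * nuclei_intensity))
    truth.nuclei_count = int(nuclei_count)
    truth.nuclei_centers = [tuple(map(float, c)) for c in centers]
    channels["dapi"] = dapi

    # noise, applied channel by channel in a fixed order
    xs = (np.arange(grid.nx) + 0.5) * grid.dx
    background = noise.background_level + noise.background_gradient * xs
    for ch in list(channels):
        img = channels[ch] + background[None, None, :]
        if noise.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
        channels[ch] = img.astype(np.float32)

    return ImageStack(channels=channels, grid=grid), truth


# ---------------------------------------------------------------------------
# lineage simulation
# ---------------------------------------------------------------------------

def _truncnorm(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float,
    high: float = math.inf,
) -> float:
    if sd <= 0:
        return float(min(max(mean, low), high))
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _reference_path_nodes(
    rng: np.random.Generator,
    regime: Regime,
    start: str = "ABarp",
    rounds: int = 5,
    t0: float = 60.0,
) -> list[LineageNode]:
    """A control (non-death) lineage path, e.g. ABarp followed to ABarpppppp.

    Cycle means ramp from ``cycle_round_start_mean`` by the lengthening factor
    per round; each division also emits the anterior sibling as a leaf.
    """
    nodes: list[LineageNode] = []
    name, birth, parent = start, t0, None
    for k in range(rounds):
        mean = regime.cycle_round_start_mean * regime.cycle_lengthening_factor**k
        cycle = _truncnorm(rng, mean, 0.15 * mean, low=1.0)
        div = birth + cycle
        nodes.append(LineageNode(name, birth, division_min=div, parent=parent))
        nodes.append(LineageNode(name + "a", div,
                                 last_observed_min=div + 60.0, parent=name))
        parent, name, birth = name, name + "p", div
    nodes.append(LineageNode(name, birth, last_observed_min=birth + 90.0,
                             parent=parent))
    return nodes


def simulate_lineage(
    regime: Regime | str,
    candidate_death_names: Sequence[str] = DEFAULT_AB_CANDIDATES,
    n_embryos: int = 1,
    seed: int = 0,
    include_reference_path: bool = True,
) -> tuple[list[LineageRecord], GroundTruth]:
    """Simulate timed lineage records with ground-truth fate labels.

    Per embryo and per candidate, the mother is born around t = 150 min; she
    may die precociously or fail to divide (regime probabilities), otherwise
    her cycle length is drawn from the regime's mother-cycle distribution
    (separate means for mothers of dying vs. death-blocked daughters when
    configured).  A non-blocked candidate forms a corpse at birth plus a
    truncated-normal time-to-corpse bounded by twice the mother's cycle; a
    blocked candidate never does and is observed for three mother cycles.
    Sister cells divide, are division-blocked, or (rarely) die
    inappropriately; divisions of the cohort are scheduled strictly after the
    embryo's last candidate corpse so that ground-truth labels are exactly
    recoverable by the fate classifier.

    One random substream per embryo, spawned from the master seed, keeps each
    embryo independently reproducible.
    """
    if isinstance(regime, str):
        regime = get_regime(regime)
    if n_embryos < 1:
        raise ValueError("n_embryos must be ≥ 1")
    if not candidate_death_names:
        raise ValueError("candidate_death_names must be non-empty")

    truth = GroundTruth()
    records: list[LineageRecord] = []
    master = np.random.SeedSequence(seed)
    streams = master.spawn(n_embryos)

    for e in range(n_embryos):
        rng = np.random.default_rng(streams[e])
        embryo_id = f"embryo_{e + 1:03d}"
        nodes: list[LineageNode] = []
        if include_reference_path:
            nodes.extend(_reference_path_nodes(rng, regime))

        pending_sisters: list[tuple[str, float, float]] = []  # name, birth, mother cycle
        latest_corpse = -math.inf

        for cand in candidate_death_names:
            mname = mother_name(cand)
            sname = sister_name(cand)
            tb = 150.0 + rng.normal(0.0, 5.0)

            if rng.random() < regime.mother_death_probability:
                ttc = _truncnorm(rng, regime.time_to_corpse_mean,
                                 regime.corpse_sd, low=1.0)
                nodes.append(LineageNode(mname, tb, corpse_min=tb + ttc,
                                         last_observed_min=tb + ttc + 30.0))
                truth.fate_labels[(embryo_id, cand)] = "mother_dies"
                truth.sister_labels[(embryo_id, sname)] = "not_applicable"
                continue

            if rng.random() < regime.division_block_probability:
                nodes.append(LineageNode(
                    mname, tb,
                    last_observed_min=tb + 4.0 * regime.mother_cycle_mean,
                ))
                truth.fate_labels[(embryo_id, cand)] = "mother_division_blocked"
                truth.sister_labels[(embryo_id, sname)] = "not_applicable"
                continue

            blocked = rng.random() < regime.block_probability_for(cand)
            cycle_mean = (
                regime.mother_cycle_blocked_mean
                if blocked and regime.mother_cycle_blocked_mean is not None
                else regime.mother_cycle_mean
            )
            cycle = _truncnorm(rng, cycle_mean, regime.mother_cycle_sd, low=5.0)
            div = tb + cycle
            nodes.append(LineageNode(mname, tb, division_min=div))

            if blocked:
                nodes.append(LineageNode(
                    cand, div, last_observed_min=div + 3.0 * cycle, parent=mname
                ))
                truth.fate_labels[(embryo_id, cand)] = "cell_death_blocked"
            else:
                ttc = _truncnorm(rng, regime.time_to_corpse_mean,
                                 regime.corpse_sd, low=0.5,
                                 high=2.0 * cycle - 0.5)
                nodes.append(LineageNode(
                    cand, div, corpse_min=div + ttc,
                    last_observed_min=div + ttc + 30.0, parent=mname,
                ))
                truth.fate_labels[(embryo_id, cand)] = "cell_death"
                latest_corpse = max(latest_corpse, div + ttc)

            u = rng.random()
            if u < regime.sister_inappropriate_death_probability:
                sttc = _truncnorm(rng, regime.time_to_corpse_mean,
                                  regime.corpse_sd, low=0.5)
                nodes.append(LineageNode(
                    sname, div, corpse_min=div + sttc,
                    last_observed_min=div + sttc + 30.0, parent=mname,
                ))
                truth.sister_labels[(embryo_id, sname)] = "inappropriate_death"
            elif u < (regime.sister_inappropriate_death_probability
                      + regime.division_block_probability):
                nodes.append(LineageNode(
                    sname, div, last_observed_min=div + 3.0 * cycle, parent=mname
                ))
                truth.sister_labels[(embryo_id, sname)] = "division_blocked"
            else:
                pending_sisters.append((sname, div, cycle))
                truth.sister_labels[(embryo_id, sname)] = "divided"

        # schedule cohort (next-round) divisions strictly after the last corpse
        for sname, birth, mcycle in pending_sisters:
            mean = mcycle * regime.cycle_lengthening_factor
            low = max(5.0, latest_corpse - birth + 1.0)
            scycle = _truncnorm(rng, mean, 0.15 * mean, low=low)
            sdiv = birth + scycle
            mname = mother_name(sname)
            nodes.append(LineageNode(sname, birth, division_min=sdiv,
                                     parent=mname))
            for suffix in ("a", "p"):
                nodes.append(LineageNode(sname + suffix, sdiv,
                                         last_observed_min=sdiv + 30.0,
                                         parent=sname))

        records.append(LineageRecord(embryo_id, nodes))

    return records, truth


# ---------------------------------------------------------------------------
# staged concentration series (for time-course demos and tests)
# ---------------------------------------------------------------------------

def simulate_stage_series(
    cell_name: str,
    channel: str,
    diameter_um: float,
    stage_range: tuple[int, int],
    conc_start: float,
    conc_end: float,
    n_embryos: int = 20,
    noise_cv: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-embryo staged copy-number measurements with a linear concentration trend.

    Emulates a cross-sectional developmental series: each simulated embryo is
    fixed at a random nuclei-count stage in ``stage_range``; the cell's true
    concentration interpolates linearly from ``conc_start`` to ``conc_end``
    (copies/µm³) across that range, with multiplicative measurement noise.
    Columns mirror the quantification output so the time-course stage can
    consume either source.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lo, hi = stage_range
    vol = sphere_volume(diameter_um)
    stages = np.sort(rng.integers(lo, hi + 1, size=n_embryos))
    frac = (stages - lo) / max(hi - lo, 1)
    conc = conc_start + (conc_end - conc_start) * frac
    noisy = conc * np.clip(rng.normal(1.0, noise_cv, size=n_embryos), 0.05, None)
    rows = pd.DataFrame({
        "embryo_id": [f"embryo_{i + 1:03d}" for i in range(n_embryos)],
        "cell_name": cell_name,
        "channel": channel,
        "nuclei_count": stages.astype(int),
        "copies": noisy * vol,
        "volume_um3": vol,
        "concentration": noisy,
    })
    return rows
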