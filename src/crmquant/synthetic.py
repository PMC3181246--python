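"""Synthetic collagen networks and confocal-style rendering.

Ground-truth 3D fiber networks (straight cylinders in a box), remodeling
operators (deposition, degradation, alignment), and renderers that turn a
network into a reflection-channel image stack (with the reflection blind
spot for axis-parallel fibers) or a cell-fluorescence stack. Everything is
deterministic given its seed, so downstream structural metrics can be
validated against known geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from ._geometry import (
    align_directions,
    clip_segment_to_box,
    segment_voxel_mask,
    sphere_voxel_mask,
    unit_vectors_uniform,
)

__all__ = [
    "FiberSegment",
    "FiberNetwork",
    "RemodelingRates",
    "RenderConfig",
    "ImageStack",
    "generate_network",
    "remodel_step",
    "render_crm",
    "render_cells",
    "rasterize_network",
    "network_occupancy",
]

#: default sampling geometry: 60x60 µm field, 30 µm deep, 60x lens pixels
DEFAULT_BOX = (60.0, 60.0, 30.0)
DEFAULT_VOXEL = (0.23, 0.23, 0.5)


@dataclass(frozen=True)
class FiberSegment:
    """A straight cylindrical fibril: endpoints (µm, xyz) and radius (µm)."""

    a: tuple[float, float, float]
    b: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"fiber radius must be > 0, got {self.radius}")
        if self.length <= 0:
            raise ValueError("fiber endpoints must be distinct")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.b, self.a)))

    @property
    def direction(self) -> np.ndarray:
        d = np.subtract(self.b, self.a)
        return d / np.linalg.norm(d)

    @property
    def volume(self) -> float:
        """Cylinder volume πr²L, ignoring overlap with other fibers."""
        return float(np.pi * self.radius**2 * self.length)


@dataclass
class FiberNetwork:
    """A set of fiber segments inside the box [0, box] (µm).

    ``nominal_concentration`` is a mg/ml label only; the quantitative ground
    truth is the geometry itself (see :func:`network_occupancy`).
    """

    segments: list[FiberSegment]
    box: tuple[float, float, float] = DEFAULT_BOX
    nominal_concentration: float | None = None
    #: sampling parameters remembered for deposition during remodeling
    mean_fiber_length: float = 10.0
    mean_radius: float = 0.4

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.box):
            raise ValueError(f"box extents must be > 0, got {self.box}")

    @property
    def n_fibers(self) -> int:
        return len(self.segments)

    def naive_volume_fraction(self) -> float:
        """Σ cylinder volumes / box volume (no overlap correction)."""
        return sum(s.volume for s in self.segments) / float(np.prod(self.box))


@dataclass(frozen=True)
class RemodelingRates:
    """Per-step remodeling intensities.

    deposition_rate
        expected number of newly deposited fibers per step (Poisson).
    degradation_prob
        independent removal probability per existing fiber per step.
    alignment_strength
        [0, 1] nematic pull of fiber directions toward a preferred axis;
        1 makes every fiber exactly axis-parallel.
    """

    deposition_rate: float = 0.0
    degradation_prob: float = 0.0
    alignment_strength: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.degradation_prob <= 1.0:
            raise ValueError("degradation_prob must be in [0, 1]")
        if not 0.0 <= self.alignment_strength <= 1.0:
            raise ValueError("alignment_strength must be in [0, 1]")
        if self.deposition_rate < 0:
            raise ValueError("deposition_rate must be >= 0")


@dataclass(frozen=True)
class RenderConfig:
    """Imaging model for the synthetic confocal renderers.

    Defaults mirror a 60x water-immersion acquisition: 0.23 µm lateral
    pixels, 30 µm stacks of 0.5 µm slices. ``blind_spot_half_angle`` is the
    cone half-angle (degrees) around the optical (z) axis inside which a
    fiber reflects nothing; outside the cone reflectance falls off as
    cos^p of the fiber's elevation out of the transverse plane.
    """

    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL
    stack_depth: float = 30.0
    psf_sigma: tuple[float, float] = (0.25, 0.75)  # (lateral, axial) µm
    noise_sd: float = 0.0
    blind_spot_half_angle: float = 0.0
    seed: int = 0
    base_intensity: float = 100.0
    blind_spot_power: float = 2.0
    lateral_extent: tuple[float, float] = (DEFAULT_BOX[0], DEFAULT_BOX[1])

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")
        if not 0.0 <= self.blind_spot_half_angle <= 90.0:
            raise ValueError("blind_spot_half_angle must be in [0, 90] degrees")
        if self.stack_depth <= 0:
            raise ValueError("stack_depth must be > 0")


@dataclass
class ImageStack:
    """A 3D intensity stack with physical voxel sizes.

    ``voxels`` is indexed [z, y, x]; ``voxel_size`` is (x, y, z) in µm.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = "reflection"  # or "fluorescence"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D [z, y, x] array")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        if self.channel not in ("reflection", "fluorescence"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """(x, y, z) extent in µm."""
        nz, ny, nx = self.voxels.shape
        vx, vy, vz = self.voxel_size
        return (nx * vx, ny * vy, nz * vz)


def _grid_shape(box_xyz: np.ndarray, voxel_size: np.ndarray) -> tuple[int, int, int]:
    nx, ny, nz = (int(round(box_xyz[i] / voxel_size[i])) for i in range(3))
    return (max(nz, 1), max(ny, 1), max(nx, 1))


def rasterize_network(
    network: FiberNetwork,
    voxel_size: tuple[float, float, float],
    depth: float | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Voxelise the union of the network's cylinders.

    Returns a boolean [z, y, x] grid (or, when per-segment ``weights`` are
    given, a float grid combined by maximum). A voxel is foreground iff its
    center lies inside at least one cylinder — the same membership rule the
    independent point-in-cylinder test uses.
    """
    vs = np.asarray(voxel_size, dtype=float)
    box = np.asarray(network.box, dtype=float)
    if depth is not None:
        box = box.copy()
        box[2] = depth
    shape = _grid_shape(box, vs)
    if weights is None:
        grid = np.zeros(shape, dtype=bool)
        for seg in network.segments:
            block, mask = segment_voxel_mask(
                np.asarray(seg.a), np.asarray(seg.b), seg.radius, shape, vs
            )
            if mask.size:
                grid[block] |= mask
    else:
        grid = np.zeros(shape, dtype=float)
        for seg, w in zip(network.segments, weights):
            if w <= 0.0:
                continue
            block, mask = segment_voxel_mask(
                np.asarray(seg.a), np.asarray(seg.b), seg.radius, shape, vs
            )
            if mask.size:
                sub = grid[block]
                np.maximum(sub, np.where(mask, w, 0.0), out=sub)
    return grid


def network_occupancy(
    network: FiberNetwork, grid_spacing: float = 0.2
) -> float:
    """Overlap-corrected volume fraction: voxelised union count / box volume."""
    grid = rasterize_network(network, (grid_spacing,) * 3)
    return float(grid.mean())


def _sample_segments(
    rng: np.random.Generator,
    n: int,
    box: np.ndarray,
    mean_length: float,
    mean_radius: float,
    alignment_strength: float = 0.0,
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> list[FiberSegment]:
    """Draw fibers: uniform centers, (optionally aligned) directions,
    lognormal lengths (CV 0.35) and radii (CV 0.15), clipped to the box."""
    centers = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    dirs = unit_vectors_uniform(rng, n)
    dirs = align_directions(dirs, np.asarray(axis), alignment_strength)
    sigma_l = np.sqrt(np.log(1 + 0.35**2))
    lengths = rng.lognormal(np.log(mean_length) - 0.5 * sigma_l**2, sigma_l, n)
    sigma_r = np.sqrt(np.log(1 + 0.15**2))
    radii = rng.lognormal(np.log(mean_radius) - 0.5 * sigma_r**2, sigma_r, n)
    out: list[FiberSegment] = []
    for c, u, length, r in zip(centers, dirs, lengths, radii):
        a = c - 0.5 * length * u
        b = c + 0.5 * length * u
        clipped = clip_segment_to_box(a, b, box)
        if clipped is None:
            continue
        pa, pb = clipped
        out.append(FiberSegment(tuple(pa), tuple(pb), float(r)))
    return out


def generate_network(
    concentration_label: float | None = None,
    target_volume_fraction: float = 0.15,
    mean_fiber_length: float = 10.0,
    mean_radius: float = 0.4,
    box: tuple[float, float, float] = DEFAULT_BOX,
    seed: int = 0,
    grid_spacing: float = 0.2,
    max_segments: int = 200_000,
) -> FiberNetwork:
    """Grow a random fiber network until its voxelised union occupancy
    reaches ``target_volume_fraction``.

    Occupancy is tracked on an internal grid of ``grid_spacing`` µm, which
    corrects for cylinder overlap. Raises RuntimeError if the target is not
    reachable within ``max_segments`` fibers (never silently undershoots).
    """
    if not 0.0 <= target_volume_fraction < 0.5:
        raise ValueError("target_volume_fraction must be in [0, 0.5)")
    box_arr = np.asarray(box, dtype=float)
    net = FiberNetwork(
        [],
        box=tuple(box_arr),
        nominal_concentration=concentration_label,
        mean_fiber_length=mean_fiber_length,
        mean_radius=mean_radius,
    )
    if target_volume_fraction == 0.0:
        return net

    rng = np.random.default_rng(seed)
    vs = np.full(3, grid_spacing)
    shape = _grid_shape(box_arr, vs)
    grid = np.zeros(shape, dtype=bool)
    n_total = grid.size
    # batch size scaled so each batch adds ~1% occupancy
    fiber_vol = np.pi * mean_radius**2 * mean_fiber_length
    batch = max(4, int(0.01 * np.prod(box_arr) / fiber_vol))
    segments: list[FiberSegment] = []
    occ = 0.0
    n_set = 0
    while occ < target_volume_fraction:
        if len(segments) >= max_segments:
            raise RuntimeError(
                f"occupancy {occ:.4f} after {len(segments)} fibers; "
                f"target {target_volume_fraction} unreachable"
            )
        new = _sample_segments(
            rng, batch, box_arr, mean_fiber_length, mean_radius
        )
        for seg in new:
            block, mask = segment_voxel_mask(
                np.asarray(seg.a), np.asarray(seg.b), seg.radius, shape, vs
            )
            if mask.size:
                sub = grid[block]
                n_set += int(np.count_nonzero(mask & ~sub))
                sub |= mask
            segments.append(seg)
            occ = n_set / n_total
            if occ >= target_volume_fraction:
                break
    if abs(occ - target_volume_fraction) > 0.1 * target_volume_fraction:
        raise RuntimeError(
            f"overshot target fraction: reached {occ:.4f} for "
            f"target {target_volume_fraction} (fibers too coarse for box)"
        )
    net.segments = segments
    return net


def remodel_step(
    network: FiberNetwork,
    rates: RemodelingRates,
    seed: int = 0,
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> FiberNetwork:
    """One remodeling step: degrade, align, then deposit.

    Each existing fiber survives with probability 1 − degradation_prob;
    survivors are rotated about their centers toward ±axis by
    alignment_strength; Poisson(deposition_rate) new fibers are deposited
    with the same alignment bias. Expected fiber count afterwards is
    n·(1 − degradation_prob) + deposition_rate.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(network.box, dtype=float)
    survivors: list[FiberSegment] = []
    if network.segments:
        keep = rng.random(len(network.segments)) >= rates.degradation_prob
        kept = [s for s, k in zip(network.segments, keep) if k]
        if kept and rates.alignment_strength > 0.0:
            dirs = np.array([s.direction for s in kept])
            new_dirs = align_directions(
                dirs, np.asarray(axis, dtype=float), rates.alignment_strength
            )
            for seg, u in zip(kept, new_dirs):
                c = 0.5 * (np.asarray(seg.a) + np.asarray(seg.b))
                half = 0.5 * seg.length * u
                clipped = clip_segment_to_box(c - half, c + half, box)
                if clipped is None:
                    continue
                pa, pb = clipped
                survivors.append(FiberSegment(tuple(pa), tuple(pb), seg.radius))
        else:
            survivors = kept

    n_new = int(rng.poisson(rates.deposition_rate)) if rates.deposition_rate else 0
    if n_new:
        survivors = survivors + _sample_segments(
            rng,
            n_new,
            box,
            network.mean_fiber_length,
            network.mean_radius,
            alignment_strength=rates.alignment_strength,
            axis=axis,
        )
    return replace(network, segments=survivors)


def _reflectance_factors(network: FiberNetwork, cfg: RenderConfig) -> np.ndarray:
    """Per-fiber reflectance in [0, 1] from the blind-spot model.

    Elevation φ is the fiber's angle out of the transverse (xy) plane;
    reflectance = cos(φ)^p, hard-zeroed for fibers within the blind-spot
    half-angle of the optical (z) axis, i.e. φ > 90° − half_angle.
    """
    if not network.segments:
        return np.zeros(0)
    dirs = np.array([s.direction for s in network.segments])
    cos_elev = np.sqrt(np.clip(dirs[:, 0] ** 2 + dirs[:, 1] ** 2, 0.0, 1.0))
    factors = cos_elev**cfg.blind_spot_power
    if cfg.blind_spot_half_angle > 0.0:
        elev_deg = np.degrees(np.arccos(np.clip(cos_elev, -1.0, 1.0)))
        factors[elev_deg > 90.0 - cfg.blind_spot_half_angle] = 0.0
    return factors


def render_crm(network: FiberNetwork, cfg: RenderConfig) -> ImageStack:
    """Render a reflection-channel stack of the network.

    Voxels whose centers fall inside a fiber get the base intensity scaled
    by that fiber's orientation reflectance (max over overlapping fibers);
    the stack is then blurred with the Gaussian PSF and Gaussian read noise
    (clipped at 0) is added. Deterministic under ``cfg.seed``.
    """
    if network.box[2] < cfg.stack_depth - 1e-9:
        raise ValueError(
            f"network depth {network.box[2]} µm shallower than requested "
            f"stack depth {cfg.stack_depth} µm"
        )
    min_d = min((2 * s.radius for s in network.segments), default=np.inf)
    if min_d < max(cfg.voxel_size[:2]):
        warnings.warn(
            "thinnest fiber is narrower than one voxel; it will render at "
            "least one voxel wide (diameter bias)",
            stacklevel=2,
        )
    factors = _reflectance_factors(network, cfg)
    grid = rasterize_network(
        network, cfg.voxel_size, depth=cfg.stack_depth,
        weights=cfg.base_intensity * factors,
    )
    sigma_lat, sigma_ax = cfg.psf_sigma
    if sigma_lat > 0.0 or sigma_ax > 0.0:
        sigma_vox = (
            sigma_ax / cfg.voxel_size[2],
            sigma_lat / cfg.voxel_size[1],
            sigma_lat / cfg.voxel_size[0],
        )
        grid = gaussian_filter(grid, sigma=sigma_vox)
    if cfg.noise_sd > 0.0:
        rng = np.random.default_rng(cfg.seed)
        grid = grid + rng.normal(0.0, cfg.noise_sd, size=grid.shape)
    np.clip(grid, 0.0, None, out=grid)
    return ImageStack(grid, cfg.voxel_size, channel="reflection")


def render_cells(
    cell_centers: list[tuple[float, float, float]],
    cell_radius: float,
    cfg: RenderConfig,
) -> ImageStack:
    """Render the fluorescence cell channel: spherical blobs at the given
    centers (µm), blurred by the PSF, with optional noise.

    Centers outside the render volume are dropped with a warning.
    """
    if cell_radius <= 0:
        raise ValueError("cell_radius must be > 0")
    vs = np.asarray(cfg.voxel_size, dtype=float)
    box = np.array([cfg.lateral_extent[0], cfg.lateral_extent[1], cfg.stack_depth])
    shape = _grid_shape(box, vs)
    grid = np.zeros(shape, dtype=float)
    for c in cell_centers:
        c = np.asarray(c, dtype=float)
        if np.any(c < 0.0) or np.any(c > box):
            warnings.warn(
                f"cell center {tuple(c)} outside render volume; skipped",
                stacklevel=2,
            )
            continue
        block, mask = sphere_voxel_mask(c, cell_radius, shape, vs)
        if mask.size:
            sub = grid[block]
            np.maximum(sub, np.where(mask, cfg.base_intensity, 0.0), out=sub)
    sigma_lat, sigma_ax = cfg.psf_sigma
    if sigma_lat > 0.0 or sigma_ax > 0.0:
        grid = gaussian_filter(
            grid, sigma=(sigma_ax / vs[2], sigma_lat / vs[1], sigma_lat / vs[0])
        )
    if cfg.noise_sd > 0.0:
        rng = np.random.default_rng(cfg.seed)
        grid = grid + rng.normal(0.0, cfg.noise_sd, size=grid.shape)
    np.clip(grid, 0.0, None, out=grid)
    return ImageStack(grid, cfg.voxel_size, channel="fluorescence")
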