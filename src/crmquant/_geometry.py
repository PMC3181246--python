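"""Shared voxel/segment geometry.

Conventions used throughout the package:

* physical coordinates are in micrometres (µm), axis order (x, y, z);
* voxel arrays are indexed ``[z, y, x]`` (the plane order of a TIFF stack);
* the centre of voxel ``(k, j, i)`` sits at ``((i + 0.5) vx, (j + 0.5) vy,
  (k + 0.5) vz)``;
* a fiber is a finite straight cylinder with flat caps: a point is inside
  iff its axial projection falls between the endpoints and its radial
  distance from the axis is at most the radius.
"""

from __future__ import annotations

import numpy as np


def voxel_centers_subgrid(
    lo_idx: np.ndarray, hi_idx: np.ndarray, voxel_size: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Physical (x, y, z) center coordinates of an index sub-box.

    ``lo_idx``/``hi_idx`` are inclusive/exclusive (x, y, z) index bounds.
    Returns broadcastable arrays shaped for a ``[z, y, x]`` block.
    """
    xs = (np.arange(lo_idx[0], hi_idx[0]) + 0.5) * voxel_size[0]
    ys = (np.arange(lo_idx[1], hi_idx[1]) + 0.5) * voxel_size[1]
    zs = (np.arange(lo_idx[2], hi_idx[2]) + 0.5) * voxel_size[2]
    return (
        xs[np.newaxis, np.newaxis, :],
        ys[np.newaxis, :, np.newaxis],
        zs[:, np.newaxis, np.newaxis],
    )


def segment_voxel_mask(
    a: np.ndarray,
    b: np.ndarray,
    radius: float,
    grid_shape_zyx: tuple[int, int, int],
    voxel_size: np.ndarray,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Voxels whose centers lie inside the finite cylinder ``(a, b, radius)``.

    Returns a ``[z, y, x]`` slice triple locating the cylinder's bounding
    block in the full grid plus the boolean in-cylinder mask of that block.
    The block is empty when the cylinder misses the grid entirely.
    """
    nz, ny, nx = grid_shape_zyx
    n_xyz = np.array([nx, ny, nz])
    lo = np.minimum(a, b) - radius
    hi = np.maximum(a, b) + radius
    lo_idx = np.clip(np.floor(lo / voxel_size).astype(int), 0, n_xyz)
    hi_idx = np.clip(np.ceil(hi / voxel_size).astype(int) + 1, 0, n_xyz)
    if np.any(hi_idx <= lo_idx):
        empty = (slice(0, 0), slice(0, 0), slice(0, 0))
        return empty, np.zeros((0, 0, 0), dtype=bool)

    x, y, z = voxel_centers_subgrid(lo_idx, hi_idx, voxel_size)
    d = b - a
    dd = float(d @ d)
    px, py, pz = x - a[0], y - a[1], z - a[2]
    if dd == 0.0:  # degenerate: sphere of given radius
        r2 = px**2 + py**2 + pz**2
        mask = r2 <= radius**2
    else:
        t = (px * d[0] + py * d[1] + pz * d[2]) / dd
        r2 = (
            (px - t * d[0]) ** 2
            + (py - t * d[1]) ** 2
            + (pz - t * d[2]) ** 2
        )
        mask = (t >= 0.0) & (t <= 1.0) & (r2 <= radius**2)
    block = (
        slice(lo_idx[2], hi_idx[2]),
        slice(lo_idx[1], hi_idx[1]),
        slice(lo_idx[0], hi_idx[0]),
    )
    return block, mask


def sphere_voxel_mask(
    center: np.ndarray,
    radius: float,
    grid_shape_zyx: tuple[int, int, int],
    voxel_size: np.ndarray,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Voxels whose centers lie inside a sphere; same return layout as above."""
    return segment_voxel_mask(center, center, radius, grid_shape_zyx, voxel_size)


def clip_segment_to_box(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    """Clip segment a→b to the axis-aligned box [0, box] (slab method).

    Returns the clipped endpoints, or None when the segment misses the box
    or the clipped piece has zero length.
    """
    d = b - a
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if d[ax] == 0.0:
            if a[ax] < 0.0 or a[ax] > box[ax]:
                return None
            continue
        ta = (0.0 - a[ax]) / d[ax]
        tb = (box[ax] - a[ax]) / d[ax]
        ta, tb = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 >= t1:
            return None
    pa, pb = a + t0 * d, a + t1 * d
    if not np.any(np.abs(pb - pa) > 1e-12):
        return None
    return pa, pb


def unit_vectors_uniform(rng: np.random.Generator, n: int) -> np.ndarray:
    """n unit vectors uniform on the sphere, shape (n, 3)."""
    v = rng.standard_normal((n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # resample the (measure-zero) chance of a zero vector
    bad = norm[:, 0] < 1e-12
    while np.any(bad):
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        bad = norm[:, 0] < 1e-12
    return v / norm


def align_directions(
    u: np.ndarray, axis: np.ndarray, strength: float
) -> np.ndarray:
    """Pull unit directions toward ±axis by linear mixing and renormalising.

    strength 0 leaves directions untouched; strength 1 makes every output
    exactly parallel to the axis. Each direction is pulled toward the axis
    hemisphere it already points into, so alignment is nematic (fibers have
    no head/tail).
    """
    if strength == 0.0:
        return u
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    sign = np.where(u @ axis >= 0.0, 1.0, -1.0)[:, np.newaxis]
    mixed = (1.0 - strength) * u + strength * sign * axis
    norm = np.linalg.norm(mixed, axis=1, keepdims=True)
    # (1-s)u exactly antipodal to s*axis cannot occur for |u|=1 unless s=0.5
    # and u = -axis; fall back to the axis itself there.
    out = np.where(norm > 1e-12, mixed / np.maximum(norm, 1e-300), axis)
    return out
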