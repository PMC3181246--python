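"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities with the simplest
possible code (explicit loops, no shared helpers) so they stay independent
of the implementation paths they check.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from crmquant.synthetic import (
    FiberNetwork,
    FiberSegment,
    RenderConfig,
    generate_network,
    render_crm,
)


# ---------------------------------------------------------------- oracles


def brute_force_gap_scan(profile, excluded=None, step=1.0):
    """Reference pore-run scanner: walk the profile and record each maximal
    background gap, classifying it as interior (fiber on both sides) or
    censored (cut by the border or an excluded pixel).

    Returns (interior_lengths, censored_lengths).
    """
    n = len(profile)
    if excluded is None:
        excluded = [False] * n
    interior, censored = [], []
    i = 0
    while i < n:
        if profile[i] or excluded[i]:
            i += 1
            continue
        j = i
        while j < n and not profile[j] and not excluded[j]:
            j += 1
        gap = (j - i) * step
        left_fiber = i > 0 and profile[i - 1] and not excluded[i - 1]
        right_fiber = j < n and profile[j] and not excluded[j]
        if left_fiber and right_fiber:
            interior.append(gap)
        else:
            censored.append(gap)
        i = j
    return interior, censored


def point_in_cylinder_oracle(segments, grid_shape_zyx, voxel_size_xyz):
    """Reference voxelisation: for every voxel center, test membership in
    every cylinder from the defining inequalities. Vectorised over the full
    grid (no bounding boxes), independent of the package's rasteriser."""
    nz, ny, nx = grid_shape_zyx
    vx, vy, vz = voxel_size_xyz
    xs = (np.arange(nx) + 0.5) * vx
    ys = (np.arange(ny) + 0.5) * vy
    zs = (np.arange(nz) + 0.5) * vz
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    occupied = np.zeros(grid_shape_zyx, dtype=bool)
    for seg in segments:
        a = np.asarray(seg.a)
        b = np.asarray(seg.b)
        d = b - a
        dd = d @ d
        px, py, pz = X - a[0], Y - a[1], Z - a[2]
        t = (px * d[0] + py * d[1] + pz * d[2]) / dd
        closest_x = px - t * d[0]
        closest_y = py - t * d[1]
        closest_z = pz - t * d[2]
        r2 = closest_x**2 + closest_y**2 + closest_z**2
        occupied |= (t >= 0) & (t <= 1) & (r2 <= seg.radius**2)
    return occupied


# ---------------------------------------------------------------- fixtures


SWEEP_TARGETS = (0.05, 0.10, 0.20, 0.30)
SWEEP_SEEDS = 20
SWEEP_BOX = (40.0, 40.0, 20.0)
SWEEP_VOXEL = (0.25, 0.25, 0.5)


@pytest.fixture(scope="session")
def density_sweep():
    """Blur-free renders over 4 generator densities x 20 seeds.

    For each run: the generated network, its rendered-grid occupancy, the
    measured fibril fraction and the mean pore size. Shared by the
    fraction-recovery and monotonicity checks so the stacks are rendered
    once.
    """
    from crmquant.metrics import (
        binarize,
        fibril_fraction,
        pore_runs_center_slice,
        pore_size_summary,
    )
    from crmquant.synthetic import rasterize_network

    records = []
    for target in SWEEP_TARGETS:
        for i in range(SWEEP_SEEDS):
            seed = 1000 * int(target * 100) + i
            net = generate_network(
                target_volume_fraction=target,
                box=SWEEP_BOX,
                seed=seed,
            )
            rendered_occ = float(
                rasterize_network(net, SWEEP_VOXEL, depth=SWEEP_BOX[2]).mean()
            )
            cfg = RenderConfig(
                voxel_size=SWEEP_VOXEL,
                stack_depth=SWEEP_BOX[2],
                psf_sigma=(0.0, 0.0),
                noise_sd=0.0,
                seed=seed,
                lateral_extent=SWEEP_BOX[:2],
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                stack = render_crm(net, cfg)
            binary = binarize(stack, method="fixed", fixed_value=0.5)
            measured = fibril_fraction(binary)
            mean_pore, _ = pore_size_summary(pore_runs_center_slice(binary))
            records.append(
                {
                    "target": target,
                    "seed": seed,
                    "network": net,
                    "rendered_occupancy": rendered_occ,
                    "measured_fraction": measured,
                    "mean_pore_um": mean_pore,
                }
            )
    return records


@pytest.fixture()
def single_cylinder_stack():
    """One transverse cylinder rendered blur- and noise-free."""
    box = (20.0, 20.0, 10.0)
    seg = FiberSegment((4.0, 10.0, 5.0), (16.0, 10.0, 5.0), 0.4)
    net = FiberNetwork([seg], box=box)
    cfg = RenderConfig(
        voxel_size=(0.2, 0.2, 0.2),
        stack_depth=box[2],
        psf_sigma=(0.0, 0.0),
        noise_sd=0.0,
        seed=0,
        lateral_extent=box[:2],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        stack = render_crm(net, cfg)
    return net, cfg, stack
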