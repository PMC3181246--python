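"""End-to-end experiment orchestration.

Reproduces the design of the imaging study on synthetic ground truth:
per condition (collagen concentration x cell line), replicate gels are
generated as fiber networks, evolved day by day under remodeling, rendered
to reflection (and cell-channel) stacks, measured with the structural
metrics, and assembled into a long-format experiment table with BCa
confidence-interval comparisons. Everything is reproducible from the
config plus one master seed, which is split hierarchically into per-stack
and per-bootstrap sub-seeds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as sm
from .io import read_stack, write_network_json, write_stack
from .stats import ComparisonReport, ExperimentTable, compare_conditions
from .synthetic import (
    FiberNetwork,
    ImageStack,
    RemodelingRates,
    RenderConfig,
    generate_network,
    rasterize_network,
    remodel_step,
    render_cells,
    render_crm,
)

__all__ = [
    "run_experiment",
    "default_config",
    "rates_toward_fraction",
    "calibrate_threshold",
]


def default_config() -> dict:
    """The default synthetic study design: the imaging geometry of the
    source protocol (30 µm stacks, 0.5 µm slices, 3 replicate gels x 3
    stacks, days 1/3/5/7) over three collagen concentrations without cells.
    """
    return {
        "seed": 0,
        "days": [1, 3, 5, 7],
        "n_replicates": 3,
        "n_stacks": 3,
        "box": [60.0, 60.0, 30.0],
        "voxel_size": [0.23, 0.23, 0.5],
        "psf_sigma": [0.15, 0.35],
        "noise_sd": 2.0,
        "blind_spot_half_angle": 0.0,
        "base_intensity": 100.0,
        "steps_per_day": 1,
        # one threshold per experiment, frozen after calibration on a
        # phantom of known occupancy (the cross-image consistency rule)
        "threshold": {"method": "calibrated"},
        "n_boot": 5000,
        "level": 0.95,
        "measure_fibers": False,
        "min_voxels": 8,
        "cell_radius": 8.0,
        "n_cells": 2,
        "conditions": [
            # 2/3/4 mg/ml acellular gels; initial fractions rise with
            # concentration as in reflection imaging of collagen gels
            {"name": "control-2mgml", "concentration": 2, "cell_line": "none",
             "initial_fraction": 0.10, "remodeling": None},
            {"name": "control-3mgml", "concentration": 3, "cell_line": "none",
             "initial_fraction": 0.15, "remodeling": None},
            {"name": "control-4mgml", "concentration": 4, "cell_line": "none",
             "initial_fraction": 0.20, "remodeling": None},
        ],
        "comparisons": [
            {"metric": "fibril_fraction",
             "grouping": ["concentration", "cell_line", "day"]},
            {"metric": "pore_size",
             "grouping": ["concentration", "cell_line", "day"]},
        ],
    }


def rates_toward_fraction(
    network: FiberNetwork, target_fraction: float, rate: float = 0.5
) -> RemodelingRates:
    """Remodeling rates that move a network's occupancy toward a target.

    Uses the Boolean-model relation occ = 1 − exp(−Σv/V) between the naive
    (overlap-ignoring) cylinder volume fraction and the union occupancy to
    compute how many fibers to degrade or deposit; ``rate`` in (0, 1] is
    the fraction of the gap closed per step.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    naive = network.naive_volume_fraction()
    naive_target = -np.log(1.0 - target_fraction)
    if naive <= naive_target:
        deficit = (naive_target - naive) * rate
        fiber_vol = np.pi * network.mean_radius**2 * network.mean_fiber_length
        k = deficit * float(np.prod(network.box)) / fiber_vol
        return RemodelingRates(deposition_rate=float(k))
    frac_remove = rate * (1.0 - naive_target / naive)
    return RemodelingRates(degradation_prob=float(frac_remove))


def calibrate_threshold(
    cfg: dict, reference_fraction: float, seed: int
) -> float:
    """Solve for the fixed binarization threshold on a reference phantom.

    A network of known occupancy is generated and rendered with the
    experiment's imaging settings; the threshold is the intensity at which
    the binarized fibril fraction equals the phantom's true (voxelised)
    occupancy. The value is frozen for every stack of the experiment,
    mirroring the rule that one processing setting is applied to all
    images. Bisection to 0.01 intensity units; deterministic under seed.
    """
    from scipy.optimize import brentq

    box = tuple(cfg["box"])
    net = generate_network(
        target_volume_fraction=reference_fraction, box=box, seed=seed
    )
    truth = float(
        rasterize_network(net, tuple(cfg["voxel_size"]), depth=box[2]).mean()
    )
    rcfg = RenderConfig(
        voxel_size=tuple(cfg["voxel_size"]),
        stack_depth=box[2],
        psf_sigma=tuple(cfg["psf_sigma"]),
        noise_sd=cfg["noise_sd"],
        blind_spot_half_angle=cfg["blind_spot_half_angle"],
        base_intensity=cfg["base_intensity"],
        seed=seed,
        lateral_extent=(box[0], box[1]),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        stack = render_crm(net, rcfg)

    def gap(thr: float) -> float:
        binary = sm.binarize(stack, method="fixed", fixed_value=thr)
        return sm.fibril_fraction(binary) - truth

    lo, hi = 0.5, 0.99 * cfg["base_intensity"]
    if gap(lo) <= 0:  # already below truth at the lowest threshold
        return lo
    if gap(hi) >= 0:
        return hi
    return float(brentq(gap, lo, hi, xtol=0.01))


def _condition_rates(cond: dict, network: FiberNetwork) -> RemodelingRates:
    spec = cond.get("remodeling")
    if spec is None:
        return RemodelingRates()
    if "toward_fraction" in spec:
        return rates_toward_fraction(
            network, spec["toward_fraction"], spec.get("rate", 0.5)
        )
    return RemodelingRates(
        deposition_rate=spec.get("deposition_rate", 0.0),
        degradation_prob=spec.get("degradation_prob", 0.0),
        alignment_strength=spec.get("alignment_strength", 0.0),
    )


def _sub_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _measure_stack(
    stack: ImageStack,
    cfg: dict,
    region: str,
    exclusion: np.ndarray | None,
) -> tuple[float, list[float], list[sm.FiberMeasure]]:
    thr = cfg["threshold"]
    binary = sm.binarize(
        stack, method=thr.get("method", "otsu"), fixed_value=thr.get("value")
    )
    frac = sm.fibril_fraction(binary)
    runs = sm.pore_runs_center_slice(binary, exclusion_mask=exclusion)
    _, pooled = sm.pore_size_summary(runs)
    fibers: list[sm.FiberMeasure] = []
    if cfg.get("measure_fibers"):
        fibers = sm.measure_fibers(binary, min_voxels=cfg.get("min_voxels", 8))
    return frac, pooled, fibers


def _simulate_condition(
    cond: dict, cfg: dict, cond_ss: np.random.SeedSequence, out_dir: Path | None
) -> list[dict]:
    """All measurement rows for one condition across replicates/days."""
    rows: list[dict] = []
    days = list(cfg["days"])
    regions = ["control"] if cond["cell_line"] == "none" else ["cellular", "acellular"]
    box = tuple(cfg["box"])
    rep_seeds = cond_ss.spawn(cfg["n_replicates"])
    for rep, rep_ss in enumerate(rep_seeds, start=1):
        stack_seeds = rep_ss.spawn(len(regions) * cfg["n_stacks"])
        i_stack = 0
        for region in regions:
            for s in range(cfg["n_stacks"]):
                ss = stack_seeds[i_stack]
                i_stack += 1
                net_seed, cell_seed, *day_seeds = (
                    _sub_seed(child) for child in ss.spawn(2 + len(days))
                )
                network = generate_network(
                    concentration_label=cond.get("concentration"),
                    target_volume_fraction=cond["initial_fraction"],
                    mean_fiber_length=cond.get("mean_fiber_length", 10.0),
                    mean_radius=cond.get("mean_radius", 0.4),
                    box=box,
                    seed=net_seed,
                )
                prev_day = 0
                for day, day_seed in zip(days, day_seeds):
                    for step in range(
                        (day - prev_day) * cfg.get("steps_per_day", 1)
                    ):
                        rates = _condition_rates(cond, network)
                        network = remodel_step(
                            network, rates, seed=day_seed + step + 1
                        )
                    prev_day = day
                    rcfg = RenderConfig(
                        voxel_size=tuple(cfg["voxel_size"]),
                        stack_depth=box[2],
                        psf_sigma=tuple(cfg["psf_sigma"]),
                        noise_sd=cfg["noise_sd"],
                        blind_spot_half_angle=cfg["blind_spot_half_angle"],
                        base_intensity=cfg["base_intensity"],
                        seed=day_seed,
                        lateral_extent=(box[0], box[1]),
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", UserWarning)
                        stack = render_crm(network, rcfg)
                    exclusion = None
                    region_label = region
                    if region == "cellular":
                        rng = np.random.default_rng(cell_seed)
                        r = cfg["cell_radius"]
                        b_arr = np.asarray(box)
                        lo = np.minimum(r, b_arr / 2)
                        hi = np.maximum(b_arr - r, b_arr / 2)
                        centers = [
                            tuple(rng.uniform(lo, hi))
                            for _ in range(cfg["n_cells"])
                        ]
                        cell_stack = render_cells(centers, r, rcfg)
                        region_label, cell_mask = sm.classify_region(
                            cell_stack, cell_threshold=cfg["base_intensity"] / 2
                        )
                        exclusion = cell_mask[cell_mask.shape[0] // 2]
                    frac, pooled_runs, fibers = _measure_stack(
                        stack, cfg, region_label, exclusion
                    )
                    stack_id = f"{cond['name']}/rep{rep}/{region}{s}"
                    key = {
                        "concentration": cond.get("concentration"),
                        "cell_line": cond["cell_line"],
                        "region": region_label,
                        "day": day,
                        "replicate": rep,
                        "stack_id": stack_id,
                    }
                    rows.append(key | {"metric": "fibril_fraction", "value": frac})
                    rows.append(key | {
                        "metric": "rendered_occupancy",
                        "value": float(
                            rasterize_network(
                                network, tuple(cfg["voxel_size"]), depth=box[2]
                            ).mean()
                        ),
                    })
                    for run in pooled_runs:
                        rows.append(key | {"metric": "pore_size", "value": run})
                    for f in fibers:
                        rows.append(key | {"metric": "fiber_length", "value": f.length})
                        rows.append(key | {"metric": "fiber_diameter", "value": f.diameter})
                    if out_dir is not None:
                        stack_dir = out_dir / "stacks"
                        stack_dir.mkdir(parents=True, exist_ok=True)
                        base = stack_id.replace("/", "_") + f"_day{day}"
                        write_stack(stack, stack_dir / f"{base}.ome.tif")
                        write_network_json(network, stack_dir / f"{base}.json")
    return rows


def _ingest_condition(cond: dict, cfg: dict) -> list[dict]:
    """Rows measured from stacks already on disk (one path list per day)."""
    rows: list[dict] = []
    declared = {int(d) for d in cfg["days"]}
    stacks = cond["stacks"]
    missing = [str(d) for d in sorted(declared) if str(d) not in
               {str(k) for k in stacks}]
    absent_files = [
        p for paths in stacks.values() for p in paths if not Path(p).exists()
    ]
    if missing or absent_files:
        raise FileNotFoundError(
            f"condition {cond['name']!r}: missing days {missing}, "
            f"missing files {absent_files}"
        )
    for day_key, paths in stacks.items():
        for i, p in enumerate(paths):
            stack = read_stack(p, voxel_size=cond.get("voxel_size"))
            frac, pooled_runs, fibers = _measure_stack(
                stack, cfg, cond.get("region", "control"), None
            )
            key = {
                "concentration": cond.get("concentration"),
                "cell_line": cond["cell_line"],
                "region": cond.get("region", "control"),
                "day": int(day_key),
                "replicate": 1,
                "stack_id": f"{cond['name']}/{Path(p).stem}",
            }
            rows.append(key | {"metric": "fibril_fraction", "value": frac})
            for run in pooled_runs:
                rows.append(key | {"metric": "pore_size", "value": run})
            for f in fibers:
                rows.append(key | {"metric": "fiber_length", "value": f.length})
                rows.append(key | {"metric": "fiber_diameter", "value": f.diameter})
    return rows


def run_experiment(
    config: dict, out_dir: str | Path | None = None, save_stacks: bool = False
) -> tuple[ExperimentTable, dict[str, ComparisonReport]]:
    """Run the full synthetic (or ingested) experiment described by config.

    Returns the long-format experiment table and one comparison report per
    configured comparison; when ``out_dir`` is given, writes
    ``measurements.csv`` (long), ``metrics.csv`` (per-stack summary),
    ``comparisons.csv`` and a JSON manifest of all settings and seeds.
    """
    cfg = default_config() | dict(config)
    names = [c["name"] for c in cfg["conditions"]]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate condition names in config: {names}")
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    thr = dict(cfg["threshold"])
    if thr.get("method") == "calibrated":
        if any("stacks" in c for c in cfg["conditions"]):
            raise ValueError(
                "calibrated thresholding needs synthetic ground truth; use "
                "threshold method 'fixed' or 'otsu' when ingesting stacks"
            )
        ref_fraction = thr.get(
            "reference_fraction",
            float(np.mean([c["initial_fraction"] for c in cfg["conditions"]])),
        )
        cal_seed = _sub_seed(np.random.SeedSequence((cfg["seed"], 2)))
        value = calibrate_threshold(cfg, ref_fraction, cal_seed)
        cfg["threshold"] = {
            "method": "fixed",
            "value": value,
            "calibrated": True,
            "reference_fraction": ref_fraction,
        }

    master = np.random.SeedSequence(cfg["seed"])
    cond_seeds = master.spawn(len(cfg["conditions"]))
    rows: list[dict] = []
    for cond, cond_ss in zip(cfg["conditions"], cond_seeds):
        if "stacks" in cond:
            rows.extend(_ingest_condition(cond, cfg))
        else:
            rows.extend(
                _simulate_condition(
                    cond, cfg, cond_ss, out_path if save_stacks else None
                )
            )
    table = ExperimentTable(pd.DataFrame(rows), days=tuple(cfg["days"]))

    comp_seed_root = np.random.SeedSequence((cfg["seed"], 1))
    reports: dict[str, ComparisonReport] = {}
    comparisons = cfg.get("comparisons") or []
    comp_seeds = comp_seed_root.spawn(max(len(comparisons), 1))
    for comp, comp_ss in zip(comparisons, comp_seeds):
        metric = comp["metric"]
        subset = comp.get("conditions")
        tbl = table
        if subset:
            undefined = [s for s in subset if s not in names]
            if undefined:
                raise ValueError(
                    f"comparison references undefined condition(s): {undefined}"
                )
            keep = table.records["stack_id"].str.split("/").str[0].isin(subset)
            tbl = ExperimentTable(table.records[keep], days=table.days)
        reports[metric] = compare_conditions(
            tbl,
            metric,
            grouping=comp.get("grouping", ["concentration", "cell_line", "day"]),
            statistic=comp.get("statistic", "mean"),
            level=cfg["level"],
            n_boot=cfg["n_boot"],
            seed=_sub_seed(comp_ss),
        )

    if out_path is not None:
        _write_outputs(table, reports, cfg, out_path)
    return table, reports


def _write_outputs(
    table: ExperimentTable,
    reports: dict[str, ComparisonReport],
    cfg: dict,
    out_path: Path,
) -> None:
    long_df = table.records.sort_values(
        ["stack_id", "day", "metric", "value"], kind="mergesort"
    ).reset_index(drop=True)
    long_df.to_csv(out_path / "measurements.csv", index=False)

    per_stack = (
        long_df.pivot_table(
            index=["concentration", "cell_line", "region", "day",
                   "replicate", "stack_id"],
            columns="metric",
            values="value",
            aggfunc="mean",
        )
        .rename(columns={"pore_size": "mean_pore_um"})
        .reset_index()
        .sort_values(["stack_id", "day"], kind="mergesort")
    )
    n_pores = (
        long_df[long_df["metric"] == "pore_size"]
        .groupby(["stack_id", "day"])["value"].size().rename("n_pores")
    )
    per_stack = per_stack.merge(n_pores, on=["stack_id", "day"], how="left")
    per_stack["n_pores"] = per_stack["n_pores"].fillna(0).astype(int)
    per_stack.to_csv(out_path / "metrics.csv", index=False)

    comp_frames = []
    for metric, rep in reports.items():
        pairs = rep.pairs.copy()
        pairs.insert(0, "metric", metric)
        comp_frames.append(pairs)
    if comp_frames:
        pd.concat(comp_frames, ignore_index=True).to_csv(
            out_path / "comparisons.csv", index=False
        )
        group_frames = []
        for metric, rep in reports.items():
            g = rep.groups.copy()
            g.insert(0, "metric", metric)
            group_frames.append(g)
        pd.concat(group_frames, ignore_index=True).to_csv(
            out_path / "group_cis.csv", index=False
        )

    manifest = {k: v for k, v in cfg.items()}
    (out_path / "manifest.json").write_text(json.dumps(manifest, indent=1))
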