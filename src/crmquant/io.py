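"""Reading and writing stacks, ground truth and tabular assay data.

Stacks travel as multi-page TIFF (plain or OME, with PhysicalSizeX/Y/Z
voxel metadata); fiber-network ground truth as a JSON sidecar; rheology
sweeps as 2-column CSV; fit records as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .assays import PowerLawFit, RheologySweep
from .synthetic import FiberNetwork, FiberSegment, ImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_network_json",
    "read_network_json",
    "read_rheology_csv",
    "write_power_law_json",
]


def write_stack(stack: ImageStack, path: str | Path, ome: bool | None = None) -> Path:
    """Write a stack as multi-page TIFF; OME metadata carries voxel sizes.

    OME is used when the filename ends in .ome.tif(f) or ``ome=True``.
    """
    path = Path(path)
    vx, vy, vz = stack.voxel_size
    if ome is None:
        ome = path.name.endswith((".ome.tif", ".ome.tiff"))
    data = stack.voxels.astype(np.float32)
    if ome:
        tifffile.imwrite(
            path,
            data,
            ome=True,
            metadata={
                "axes": "ZYX",
                "PhysicalSizeX": vx, "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": vy, "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZ": vz, "PhysicalSizeZUnit": "µm",
                "Channel": {"Name": stack.channel},
            },
        )
    else:
        tifffile.imwrite(
            path, data,
            metadata={"voxel_size_um": [vx, vy, vz], "channel": stack.channel},
        )
    return path


def _voxel_from_ome(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    if not tf.is_ome:
        return None
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tf.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is None:
            return None
        return tuple(
            float(px.attrib[f"PhysicalSize{ax}"]) for ax in "XYZ"
        )
    except (KeyError, ValueError, ET.ParseError):
        return None


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    channel: str = "reflection",
) -> ImageStack:
    """Read a 3D stack; voxel sizes from OME/ImageJ/shaped metadata unless
    overridden. Raises when no voxel size can be determined."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_channel = channel
        if voxel_size is None:
            voxel_size = _voxel_from_ome(tf)
        if voxel_size is None and tf.shaped_metadata:
            meta = tf.shaped_metadata[0]
            if "voxel_size_um" in meta:
                voxel_size = tuple(meta["voxel_size_um"])
            meta_channel = meta.get("channel", channel)
        if voxel_size is None and tf.imagej_metadata:
            ij = tf.imagej_metadata
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is not None and "spacing" in ij:
                num, den = res.value
                voxel_size = (den / num, den / num, float(ij["spacing"]))
    if data.ndim == 2:
        data = data[np.newaxis]
    if voxel_size is None:
        raise ValueError(
            f"{path}: no voxel-size metadata found; pass voxel_size explicitly"
        )
    return ImageStack(np.asarray(data, dtype=float), tuple(voxel_size), meta_channel)


def write_network_json(
    network: FiberNetwork, path: str | Path, extra: dict | None = None
) -> Path:
    """Ground-truth sidecar: all segments, box, labels and any extras."""
    path = Path(path)
    payload = {
        "box_um": list(network.box),
        "nominal_concentration_mg_ml": network.nominal_concentration,
        "mean_fiber_length_um": network.mean_fiber_length,
        "mean_radius_um": network.mean_radius,
        "segments": [
            {"a_um": list(s.a), "b_um": list(s.b), "radius_um": s.radius}
            for s in network.segments
        ],
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_network_json(path: str | Path) -> FiberNetwork:
    payload = json.loads(Path(path).read_text())
    return FiberNetwork(
        segments=[
            FiberSegment(tuple(s["a_um"]), tuple(s["b_um"]), s["radius_um"])
            for s in payload["segments"]
        ],
        box=tuple(payload["box_um"]),
        nominal_concentration=payload.get("nominal_concentration_mg_ml"),
        mean_fiber_length=payload.get("mean_fiber_length_um", 10.0),
        mean_radius=payload.get("mean_radius_um", 0.4),
    )


def read_rheology_csv(path: str | Path) -> RheologySweep:
    """Read a frequency sweep: columns frequency_hz, storage_modulus_pa."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        f = df[cols["frequency_hz"]].to_numpy(dtype=float)
        g = df[cols["storage_modulus_pa"]].to_numpy(dtype=float)
    except KeyError as e:
        raise ValueError(
            f"{path}: need columns frequency_hz, storage_modulus_pa"
        ) from e
    order = np.argsort(f)
    return RheologySweep(tuple(f[order]), tuple(g[order]))


def write_power_law_json(fit: PowerLawFit, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "prefactor_pa": fit.prefactor,
        "exponent": fit.exponent,
        "modulus_at_10hz_pa": fit.modulus_at_10Hz,
        "r_squared": fit.r_squared,
    }, indent=1))
    return path
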