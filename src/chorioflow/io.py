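"""Reading and writing the tool's standard file formats.

Masks travel as 8-bit single-channel PNG/TIFF (nonzero = lumen), junction
maps as CSV (``id,kind,x_um,y_um,radius_um``) or an equivalent JSON list,
occupancy grids and field solutions as NPZ archives, and run configuration
as YAML/JSON.  A manifest (config hash, seed, package version) accompanies
every output for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import BinaryCapillaryMask, Junction, JunctionMap, OccupancyGrid

__all__ = [
    "load_mask", "save_mask",
    "load_junctions", "save_junctions",
    "save_occupancy", "load_occupancy",
    "save_fields", "load_config", "write_manifest",
]


def load_mask(path: str | Path, pixel_size_um: float) -> BinaryCapillaryMask:
    """Read a binary capillary mask image (nonzero pixels = lumen)."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return BinaryCapillaryMask((img > 0).astype(np.uint8), pixel_size_um)


def save_mask(mask: BinaryCapillaryMask, path: str | Path) -> None:
    path = Path(path)
    data = (mask.pixels * 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        res = 1e4 / mask.pixel_size_um  # pixels per cm
        tifffile.imwrite(path, data, resolution=(res, res),
                         resolutionunit="CENTIMETER")
    else:
        iio.imwrite(path, data)


def load_junctions(path: str | Path) -> JunctionMap:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    juncs = tuple(Junction(int(r["id"]), str(r["kind"]),
                           (float(r["x_um"]), float(r["y_um"])),
                           float(r["radius_um"])) for r in rows)
    return JunctionMap(juncs)


def save_junctions(jmap: JunctionMap, path: str | Path) -> None:
    rows = [{"id": j.id, "kind": j.kind, "x_um": j.center_um[0],
             "y_um": j.center_um[1], "radius_um": j.radius_um}
            for j in jmap.junctions]
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows).to_csv(path, index=False)


def save_occupancy(grid: OccupancyGrid, path: str | Path) -> None:
    labels = {}
    for name, cells in (("inlet", grid.inlet_cells),
                        ("outlet", grid.outlet_cells)):
        for jid, arr in cells.items():
            labels[f"{name}_{jid}"] = np.asarray(arr)
    np.savez_compressed(path, P=grid.P, spacing_um=grid.spacing_um,
                        layer_index=grid.layer_index,
                        top_cap_z=grid._top_cap_index(), **labels)


def load_occupancy(path: str | Path) -> OccupancyGrid:
    d = np.load(path)
    inlet, outlet = {}, {}
    for key in d.files:
        if key.startswith("inlet_"):
            inlet[int(key[6:])] = d[key]
        elif key.startswith("outlet_"):
            outlet[int(key[7:])] = d[key]
    grid = OccupancyGrid(P=d["P"], spacing_um=float(d["spacing_um"]),
                         layer_index=int(d["layer_index"]),
                         inlet_cells=inlet, outlet_cells=outlet)
    grid.top_cap_z = int(d["top_cap_z"])
    return grid


def save_fields(macro, path: str | Path) -> None:
    """Write the macroscopic solution (SI and lattice units) as NPZ."""
    np.savez_compressed(
        path, velocity=macro.velocity, pressure=macro.pressure,
        rho_lattice=macro.rho, u_lattice=macro.u_lat, P=macro.P,
        dx=macro.units.dx, dt=macro.units.dt, tau=macro.units.tau,
        layer_index=macro.layer_index)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_manifest(out_dir: str | Path, config: dict | None = None,
                   seed: int | None = None, **extra) -> Path:
    from . import __version__

    payload = {"version": __version__, "seed": seed, **extra}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        payload["config_sha256"] = hashlib.sha256(blob).hexdigest()
        payload["config"] = config
    out = Path(out_dir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(payload, indent=1, default=str))
    return out
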