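"""File formats: tagged-mesh text, voltage traces, structured-grid
snapshots (legacy ASCII VTK) and run manifests.

The tagged-mesh format is one line per cell,

    x y z tag atp_i k_o f_gcal f_gna sigma

with x/y/z the cell-centre positions in um (position = (index + 0.5) * h),
tag one of HEALTHY|PZ|SCAR_MYO|NONCOND, concentrations in model units, and
a header carrying dims/spacing.  Floats are written with repr precision so
a write/read round trip is bit-exact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np

from .tissue_solver import Tag, TissueGrid

__all__ = ["write_tagged_mesh", "read_tagged_mesh", "write_trace",
           "read_trace", "write_snapshot_series", "RunManifest"]

NONCOND_SENTINEL = -1.0e3  # mV value encoding NONCOND cells in snapshots


def write_tagged_mesh(grid: TissueGrid, path) -> None:
    h = grid.spacing
    with open(path, "w") as fh:
        fh.write("# cardiomaze tagged mesh v1\n")
        fh.write(f"# dims {grid.dims[0]} {grid.dims[1]} {grid.dims[2]}\n")
        fh.write(f"# spacing_um {h!r}\n")
        fh.write(f"# beta_per_cm {grid.beta!r} cm_uF_cm2 {grid.cm!r}\n")
        fh.write("# columns: x_um y_um z_um tag atp_mM ko_mM fgcal fgna "
                 "sigma_mS_cm\n")
        tags = grid.tags
        for ix in range(grid.dims[0]):
            for iy in range(grid.dims[1]):
                for iz in range(grid.dims[2]):
                    c = (ix, iy, iz)
                    fh.write(
                        f"{(ix + 0.5) * h!r} {(iy + 0.5) * h!r} "
                        f"{(iz + 0.5) * h!r} {Tag(tags[c]).name} "
                        f"{float(grid.atp[c])!r} {float(grid.k_o[c])!r} "
                        f"{float(grid.f_gcal[c])!r} "
                        f"{float(grid.f_gna[c])!r} "
                        f"{float(grid.sigma[c])!r}\n")


def read_tagged_mesh(path) -> TissueGrid:
    dims = None
    spacing = beta = cm = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["dims"]:
                    dims = tuple(int(x) for x in parts[1:4])
                elif parts[:1] == ["spacing_um"]:
                    spacing = float(parts[1])
                elif parts[:1] == ["beta_per_cm"]:
                    beta = float(parts[1])
                    cm = float(parts[3])
                continue
            rows.append(line.split())
    if dims is None or spacing is None:
        raise ValueError("tagged-mesh header missing dims/spacing")
    if len(rows) != dims[0] * dims[1] * dims[2]:
        raise ValueError("tagged-mesh row count does not match dims")
    grid = TissueGrid(dims=dims, spacing=spacing,
                      beta=beta if beta is not None else 1400.0,
                      cm=cm if cm is not None else 1.0)
    k = 0
    for ix in range(dims[0]):
        for iy in range(dims[1]):
            for iz in range(dims[2]):
                r = rows[k]
                k += 1
                grid.tags[ix, iy, iz] = int(Tag[r[3]])
                grid.atp[ix, iy, iz] = float(r[4])
                grid.k_o[ix, iy, iz] = float(r[5])
                grid.f_gcal[ix, iy, iz] = float(r[6])
                grid.f_gna[ix, iy, iz] = float(r[7])
                grid.sigma[ix, iy, iz] = float(r[8])
    return grid


def write_trace(path, t_ms, v_mv) -> None:
    """Two-column delimited text voltage trace (t_ms, V_mV)."""
    with open(path, "w") as fh:
        fh.write("# t_ms\tV_mV\n")
        for t, v in zip(np.asarray(t_ms), np.asarray(v_mv)):
            fh.write(f"{float(t)!r}\t{float(v)!r}\n")


def read_trace(path):
    data = np.loadtxt(path)
    return data[:, 0], data[:, 1]


def _write_vtk_field(path, grid: TissueGrid, values: np.ndarray,
                     name: str = "V") -> None:
    """Legacy ASCII VTK STRUCTURED_POINTS scalar field; NONCOND cells hold
    the documented sentinel value."""
    full = np.full(grid.dims, NONCOND_SENTINEL, dtype=float)
    full[grid.conducting_mask()] = values
    nx, ny, nz = grid.dims
    h_mm = grid.spacing * 1e-3
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"cardiomaze {name} field "
                 f"(NONCOND sentinel {NONCOND_SENTINEL})\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {0.5 * h_mm} {0.5 * h_mm} {0.5 * h_mm}\n")
        fh.write(f"SPACING {h_mm} {h_mm} {h_mm}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        # VTK expects x varying fastest
        for val in full.transpose(2, 1, 0).ravel():
            fh.write(f"{val:.4f}\n")


def write_snapshot_series(record, grid: TissueGrid, out_dir) -> list:
    """One VTK file per snapshot plus an index file; returns the inventory
    (list of file names)."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    inventory = []
    for k, t in enumerate(record.times):
        name = f"v_{k:05d}.vtk"
        _write_vtk_field(os.path.join(out_dir, name), grid,
                         record.v_fields[k].astype(float))
        inventory.append({"file": name, "t_ms": float(t)})
    index_path = os.path.join(out_dir, "index.json")
    with open(index_path, "w") as fh:
        json.dump({"noncond_sentinel_mV": NONCOND_SENTINEL,
                   "snapshots": inventory}, fh, indent=1)
    return [e["file"] for e in inventory] + ["index.json"]


@dataclass
class RunManifest:
    """Provenance of one pipeline run: configuration hash, seeds, package
    version, stage timings and produced files."""

    config_hash: str = ""
    seeds: dict = field(default_factory=dict)
    code_version: str = ""
    timings_s: dict = field(default_factory=dict)
    files: list = field(default_factory=list)

    @staticmethod
    def hash_config(config: dict) -> str:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def start(cls, config: dict, seeds: dict) -> "RunManifest":
        from . import __version__
        return cls(config_hash=cls.hash_config(config), seeds=dict(seeds),
                   code_version=__version__)

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.timings_s[name] = time.perf_counter() - self.t0
                return False

        return _Timer()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
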