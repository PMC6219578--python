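"""Synthetic infarct geometries and stochastic diffuse fibrosis.

Builds slab/wedge grids with a spherical (disc, for one-cell-thick slabs)
scar core surrounded by a peri-infarct zone (PZ) and a healthy rim, applies
the PZ gradients -- [ATP]i and the fibrosis fraction phi change linearly
with distance from the scar boundary, from their scar values to the healthy
values (6.8 mM and zero) -- and generates diffuse-fibrosis mazes by
independently removing lesion cells (-> NONCOND) with their local
probability phi at (100 um)^3 resolution.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import ionic_model as im
from .tissue_solver import Tag, TissueGrid

__all__ = ["LesionSpec", "MazeRealization", "build_wedge", "pz_gradient",
           "apply_diffuse_fibrosis"]

ATP_HEALTHY = 6.8  # mM
FIBROSIS_SPACING_UM = 100.0


@dataclass(frozen=True)
class LesionSpec:
    """Spherical scar + PZ shell lesion.

    Distances in um from ``scar_center`` (grid coordinates, cell units):
    r <= scar_radius -> SCAR_MYO, scar_radius < r <= pz_outer_radius -> PZ,
    else HEALTHY.  ``phi_scar``/``atp_scar`` hold inside the scar and ramp
    linearly across the PZ to (0, 6.8 mM) at its outer edge.
    """

    scar_center: tuple
    scar_radius: float          # um
    pz_outer_radius: float      # um
    phi_scar: float = 0.66
    atp_scar: float = 2.0       # mM
    k_o_scar: float = im.KO_NORMAL
    f_gcal_scar: float = 1.0
    f_gna_scar: float = 1.0
    transmural_axis: int | None = 2  # cylinder axis; None -> spherical

    def __post_init__(self) -> None:
        if not (self.pz_outer_radius > self.scar_radius >= 0):
            raise ValueError("need pz_outer_radius > scar_radius >= 0")
        if not (0.0 <= self.phi_scar <= 1.0):
            raise ValueError("phi_scar must lie in [0, 1]")


@dataclass
class MazeRealization:
    """One stochastic fibrosis pattern; reproducible from (grid spec, seed)."""

    seed: int
    removed_mask: np.ndarray   # True where the cell became NONCOND
    phi_field: np.ndarray      # per-cell removal probability actually used

    def mask_hash(self) -> str:
        return hashlib.sha256(np.packbits(self.removed_mask).tobytes()
                              ).hexdigest()


def _radius_field(dims, spacing, center, transmural_axis=None) -> np.ndarray:
    nx, ny, nz = dims
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    d2 = 0.0
    for ax, idx in enumerate((ix, iy, iz)):
        if ax == transmural_axis:
            continue  # lesion spans the wall thickness (transmural cut)
        d2 = d2 + (idx - center[ax]) ** 2
    return spacing * np.sqrt(d2)


def build_wedge(dims, spacing: float, lesion: LesionSpec,
                **grid_kw) -> TissueGrid:
    """Healthy grid with SCAR_MYO / PZ / HEALTHY tags assigned by distance
    to the scar centre.  The lesion must sit strictly inside the domain with
    a healthy margin of at least one cell on every face (so the paced wave
    can reach it from any side)."""
    dims = tuple(int(d) for d in dims)
    grid = TissueGrid.uniform(dims, spacing, **grid_kw)
    r = _radius_field(dims, spacing, lesion.scar_center,
                      lesion.transmural_axis)
    tags = np.full(dims, int(Tag.HEALTHY), dtype=np.int8)
    tags[r <= lesion.pz_outer_radius] = int(Tag.PZ)
    tags[r <= lesion.scar_radius] = int(Tag.SCAR_MYO)

    for ax in range(3):
        if dims[ax] == 1 or ax == lesion.transmural_axis:
            continue  # the lesion spans the wall along this axis
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[ax] = face
            if np.any(tags[tuple(sl)] != int(Tag.HEALTHY)):
                raise ValueError("lesion touches the domain boundary; "
                                 "enlarge the domain or shrink the lesion")
    grid.tags = tags
    return grid


def pz_gradient(grid: TissueGrid, lesion: LesionSpec):
    """Per-cell ([ATP]i, phi) fields with the linear PZ ramp.

    Scar: (atp_scar, phi_scar).  PZ at normalized distance
    u = (r - scar_radius)/(pz_outer - scar_radius):
    atp = atp_scar + u*(6.8 - atp_scar), phi = phi_scar*(1 - u).
    Healthy: (6.8, 0).  Continuous at both interfaces.  The grid's
    ischemia fields are updated in place and (atp, phi) returned.
    """
    r = _radius_field(grid.dims, grid.spacing, lesion.scar_center,
                      lesion.transmural_axis)
    u = (r - lesion.scar_radius) / (lesion.pz_outer_radius
                                    - lesion.scar_radius)
    u = np.clip(u, 0.0, 1.0)
    atp = lesion.atp_scar + u * (ATP_HEALTHY - lesion.atp_scar)
    phi = lesion.phi_scar * (1.0 - u)
    healthy = grid.tags == int(Tag.HEALTHY)
    atp[healthy] = ATP_HEALTHY
    phi[healthy] = 0.0

    grid.atp = atp
    grid.k_o = np.where(healthy, im.KO_NORMAL,
                        im.KO_NORMAL + (1.0 - u) * (lesion.k_o_scar
                                                    - im.KO_NORMAL))
    grid.f_gcal = np.where(healthy, 1.0,
                           1.0 + (1.0 - u) * (lesion.f_gcal_scar - 1.0))
    grid.f_gna = np.where(healthy, 1.0,
                          1.0 + (1.0 - u) * (lesion.f_gna_scar - 1.0))
    return atp, phi


def apply_diffuse_fibrosis(grid: TissueGrid, phi_field: np.ndarray,
                           seed: int) -> MazeRealization:
    """Independently set each cell NONCOND with its local probability phi.

    Diffuse fibrosis is modelled at (100 um)^3 block resolution; grids with
    a different spacing refuse fibrosis generation rather than rescaling,
    because percolation behaviour is lattice-resolution dependent.  The grid
    tags are updated in place; identical inputs and seed give an identical
    maze.
    """
    if grid.spacing != FIBROSIS_SPACING_UM:
        raise ValueError(
            f"diffuse fibrosis is defined at {FIBROSIS_SPACING_UM} um "
            f"spacing, got {grid.spacing} um")
    phi_field = np.asarray(phi_field, dtype=float)
    if phi_field.shape != tuple(grid.dims):
        raise ValueError("phi_field shape does not match grid dims")
    if np.any((phi_field < 0) | (phi_field > 1)):
        raise ValueError("phi_field values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    draw = rng.random(phi_field.shape)
    removed = draw < phi_field
    grid.tags[removed] = int(Tag.NONCOND)
    return MazeRealization(seed=seed, removed_mask=removed,
                           phi_field=phi_field)
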