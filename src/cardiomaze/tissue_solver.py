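"""Monodomain reaction-diffusion solver on a regular hexahedral grid.

The transmembrane potential obeys

    beta * Cm * dV/dt + beta * I_ion(V, eta) = div(sigma grad V) + I_stim,
    d(eta)/dt = f(V, eta),

with no-flux boundaries on the active domain: non-conducting (fibrotic)
cells carry no state and exchange no current with their neighbours.  The
diffusion term is discretized with a cell-centred finite-volume 6-face
stencil (harmonic-mean face conductivities), and time integration uses
operator splitting: a Rush-Larsen/Euler reaction update of every conducting
cell at dt = 0.02 ms, followed by an explicit diffusion update of V.  The
diffusion half-step is automatically sub-stepped when the explicit stability
bound dt <= h^2 beta Cm / (2 d sigma) is tighter than the reaction step.

Conventions: cell-centred 0-based indices, physical position
(index + 0.5) * h; V in mV, t in ms, sigma in mS/cm, beta in 1/cm, Cm in
uF/cm^2; stimulus amplitudes are per-capacitance currents (uA/uF), negative
= depolarizing.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _kernel
from . import ionic_model as im

__all__ = [
    "Tag",
    "TissueGrid",
    "StimulusSite",
    "StimulusProtocol",
    "SimulationRecord",
    "StabilityError",
    "assemble_diffusion_operator",
    "step",
    "run",
    "DEFAULT_SIGMA",
    "DEFAULT_BETA",
    "DEFAULT_CM",
]

# Conductivity calibrated so a healthy planar wave propagates at ~68 cm/s
# (typical human ventricular CV); see scripts/calibrate.py and docs.
DEFAULT_SIGMA = 1.85   # mS/cm (isotropic monodomain effective conductivity)
DEFAULT_BETA = 1400.0  # 1/cm surface-to-volume ratio
DEFAULT_CM = 1.0       # uF/cm^2


class Tag(enum.IntEnum):
    HEALTHY = 0
    PZ = 1
    SCAR_MYO = 2
    NONCOND = 3


class StabilityError(RuntimeError):
    pass


@dataclass
class TissueGrid:
    """Regular hexahedral lattice of myocytes with per-cell region tags and
    ischemia parameters.

    Arrays are shaped ``dims = (nx, ny, nz)``; ``spacing`` is the isotropic
    cell size in um.  NONCOND cells are excluded from the active domain.
    """

    dims: tuple[int, int, int]
    spacing: float = 100.0  # um
    tags: np.ndarray = None
    atp: np.ndarray = None
    k_o: np.ndarray = None
    f_gcal: np.ndarray = None
    f_gna: np.ndarray = None
    sigma: np.ndarray = None
    beta: float = DEFAULT_BETA
    cm: float = DEFAULT_CM
    katp: im.KatpConstants = field(default_factory=im.KatpConstants)

    def __post_init__(self) -> None:
        shape = tuple(self.dims)
        if self.tags is None:
            self.tags = np.full(shape, int(Tag.HEALTHY), dtype=np.int8)
        if self.atp is None:
            self.atp = np.full(shape, im.HEALTHY_ISCHEMIA.atp_i)
        if self.k_o is None:
            self.k_o = np.full(shape, im.KO_NORMAL)
        if self.f_gcal is None:
            self.f_gcal = np.ones(shape)
        if self.f_gna is None:
            self.f_gna = np.ones(shape)
        if self.sigma is None:
            self.sigma = np.full(shape, DEFAULT_SIGMA)

    @classmethod
    def uniform(cls, dims, spacing: float = 100.0, *,
                isch: im.IschemiaParams = im.HEALTHY_ISCHEMIA,
                sigma: float = DEFAULT_SIGMA, **kw) -> "TissueGrid":
        g = cls(dims=tuple(dims), spacing=spacing, **kw)
        g.atp[:] = isch.atp_i
        g.k_o[:] = isch.k_o
        g.f_gcal[:] = isch.f_gcal
        g.f_gna[:] = isch.f_gna
        g.sigma[:] = sigma
        return g

    def conducting_mask(self) -> np.ndarray:
        return self.tags != int(Tag.NONCOND)

    @property
    def n_conducting(self) -> int:
        return int(self.conducting_mask().sum())

    def positions_cm(self) -> np.ndarray:
        """(nx*ny*nz, 3) physical cell-centre positions in cm."""
        nx, ny, nz = self.dims
        ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny),
                                 np.arange(nz), indexing="ij")
        h_cm = self.spacing * 1e-4
        return np.stack([(ix + 0.5) * h_cm, (iy + 0.5) * h_cm,
                         (iz + 0.5) * h_cm], axis=-1).reshape(-1, 3)

    def validate(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.n_conducting < 1:
            raise ValueError("grid has no conducting cells")
        for name in ("tags", "atp", "k_o", "f_gcal", "f_gna", "sigma"):
            if getattr(self, name).shape != tuple(self.dims):
                raise ValueError(f"{name} shape does not match dims")


@dataclass(frozen=True)
class StimulusSite:
    """One stimulated cell set: flat grid indices (C-order over dims),
    per-capacitance amplitude (uA/uF, negative = depolarizing), start and
    duration in ms."""

    indices: np.ndarray
    amplitude: float = -52.0
    start: float = 0.0
    duration: float = 2.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")


@dataclass
class StimulusProtocol:
    sites: list
    mode: str = "single_point"  # or "multi_site"

    @property
    def end_time(self) -> float:
        return max((s.start + s.duration for s in self.sites), default=0.0)

    @classmethod
    def point(cls, grid: TissueGrid, center, radius_cells: float = 2.5,
              amplitude: float = -52.0, start: float = 5.0,
              duration: float = 2.0) -> "StimulusProtocol":
        """Point-like stimulus: conducting cells within ``radius_cells`` of
        ``center`` (grid coordinates)."""
        nx, ny, nz = grid.dims
        ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny),
                                 np.arange(nz), indexing="ij")
        r2 = ((ix - center[0]) ** 2 + (iy - center[1]) ** 2
              + (iz - center[2]) ** 2)
        mask = (r2 <= radius_cells ** 2) & grid.conducting_mask()
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            raise ValueError("point stimulus addresses no conducting cells")
        return cls(sites=[StimulusSite(idx, amplitude, start, duration)])

    @classmethod
    def plane(cls, grid: TissueGrid, axis: int = 0, thickness: int = 2,
              amplitude: float = -52.0, start: float = 5.0,
              duration: float = 2.0) -> "StimulusProtocol":
        """Planar stimulus: the first ``thickness`` conducting layers along
        ``axis`` (for CV measurement runs)."""
        sel = [slice(None)] * 3
        sel[axis] = slice(0, thickness)
        mask = np.zeros(grid.dims, dtype=bool)
        mask[tuple(sel)] = True
        idx = np.flatnonzero((mask & grid.conducting_mask()).ravel())
        return cls(sites=[StimulusSite(idx, amplitude, start, duration)])

    @classmethod
    def multi_site(cls, grid: TissueGrid, centers, **kw) -> "StimulusProtocol":
        sites = []
        for c in centers:
            sites.extend(cls.point(grid, c, **kw).sites)
        return cls(sites=sites, mode="multi_site")


@dataclass
class SimulationRecord:
    """Snapshotted potential field plus per-cell event lists.

    ``v_fields[k]`` holds V (mV) of every conducting cell at ``times[k]``;
    ``activations``/``repolarizations`` are per-conducting-cell sorted time
    lists; ``quiescent_from`` is set when the run was truncated because all
    activity died out (no further events are possible)."""

    times: np.ndarray
    v_fields: np.ndarray
    activations: list
    repolarizations: list
    positions: np.ndarray  # (n_conducting, 3) cm
    dt: float
    quiescent_from: float | None = None

    def probe_distance_cm(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.positions[a] - self.positions[b]))

    @property
    def n_cells(self) -> int:
        return len(self.activations)


def assemble_diffusion_operator(grid: TissueGrid) -> sp.csr_matrix:
    """Finite-volume diffusion operator on conducting cells (mS/cm^3).

    dV/dt|diffusion = (L @ V) / (beta * Cm).  Faces between conducting
    cells carry the harmonic-mean conductivity divided by h^2; faces to
    NONCOND cells or the outer boundary carry zero flux, so every row sums
    to zero and the matrix is symmetric.
    """
    grid.validate()
    cond = grid.conducting_mask()
    n_total = cond.size
    index = -np.ones(n_total, dtype=np.int64)
    flat_cond = cond.ravel()
    index[flat_cond] = np.arange(flat_cond.sum())
    h_cm = grid.spacing * 1e-4
    inv_h2 = 1.0 / h_cm ** 2
    sigma = grid.sigma

    rows, cols, vals = [], [], []
    for ax in range(3):
        if grid.dims[ax] < 2:
            continue
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        a_mask = cond[tuple(sl_a)] & cond[tuple(sl_b)]
        ia = _flat_indices(grid.dims, ax, 0)[a_mask.ravel()]
        ib = _flat_indices(grid.dims, ax, 1)[a_mask.ravel()]
        sa = sigma[tuple(sl_a)].ravel()[a_mask.ravel()]
        sb = sigma[tuple(sl_b)].ravel()[a_mask.ravel()]
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(sa + sb > 0, 2.0 * sa * sb / (sa + sb), 0.0)
        g = g * inv_h2
        ca, cb = index[ia], index[ib]
        rows.extend([ca, cb, ca, cb])
        cols.extend([cb, ca, ca, cb])
        vals.extend([g, g, -g, -g])
    n = int(flat_cond.sum())
    if not rows:
        return sp.csr_matrix((n, n))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _flat_indices(dims, ax, side):
    """Flat C-order indices of the lower (side=0) / upper (side=1) cells of
    every interior face along ``ax``."""
    nx, ny, nz = dims
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    flat = (ix * ny + iy) * nz + iz
    sl = [slice(None)] * 3
    sl[ax] = slice(0, -1) if side == 0 else slice(1, None)
    return flat[tuple(sl)].ravel()


def diffusion_substeps(grid: TissueGrid, L: sp.csr_matrix, dt: float,
                       max_substeps: int = 64) -> int:
    """Number of explicit diffusion sub-steps needed for stability."""
    if L.nnz == 0:
        return 1
    max_diag = float(np.abs(L.diagonal()).max())
    if max_diag == 0:
        return 1
    bound = 0.9 * grid.beta * grid.cm / max_diag  # Gershgorin: dt_sub <= b*cm/|Lii|
    n_sub = max(int(math.ceil(dt / bound)), 1)
    if n_sub > max_substeps:
        h = grid.spacing
        raise StabilityError(
            f"explicit diffusion unstable: dt = {dt} ms at h = {h} um "
            f"needs {n_sub} sub-steps (> {max_substeps}); reduce dt or "
            "increase h")
    return n_sub


class _TissueStepper:
    """Mutable integration state shared by step() and run()."""

    def __init__(self, grid: TissueGrid, dt: float = 0.02):
        if dt <= 0:
            raise ValueError("dt must be positive")
        grid.validate()
        self.grid = grid
        self.dt = dt
        cond = grid.conducting_mask().ravel()
        self.cond = cond
        self.n = int(cond.sum())
        self.Y = _kernel.initial_states(self.n)
        self.P = _kernel.cell_params(
            grid.atp.ravel()[cond], grid.k_o.ravel()[cond],
            grid.f_gcal.ravel()[cond], grid.f_gna.ravel()[cond], grid.katp)
        self.L = assemble_diffusion_operator(grid)
        self.n_sub = diffusion_substeps(grid, self.L, dt)
        self.scale = dt / self.n_sub / (grid.beta * grid.cm)
        self.istim = np.zeros(self.n)
        self.t = 0.0

    def advance(self) -> None:
        _kernel.react_step(self.Y, self.P, self.dt, self.istim)
        v = self.Y[0]
        if self.L.nnz:
            for _ in range(self.n_sub):
                v += self.scale * (self.L @ v)
        self.t += self.dt


def step(grid: TissueGrid, Y: np.ndarray, dt: float,
         istim: np.ndarray | None = None) -> np.ndarray:
    """One operator-split step of the full state array (N_VARS, n_cond);
    returns the updated array (in place).  Convenience wrapper used by tests;
    long runs should use :func:`run`."""
    st = _TissueStepper(grid, dt)
    st.Y = Y
    if istim is not None:
        st.istim = istim
    st.advance()
    return Y


def run(grid: TissueGrid, protocol: StimulusProtocol, duration: float,
        snapshot_every: float = 5.0, dt: float = 0.02,
        early_stop_quiescent: bool = True) -> SimulationRecord:
    """Integrate the monodomain model and extract activation/repolarization
    events.

    Activation = upward crossing of -20 mV (10 ms refractory guard);
    repolarization = downward crossing of the per-cell 90%-repolarization
    level.  Reproducible given (grid, protocol, dt).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    st = _TissueStepper(grid, dt)
    n = st.n
    cond = st.cond

    # map stimulus sites (flat grid indices) onto conducting-cell indices
    index = -np.ones(cond.size, dtype=np.int64)
    index[cond] = np.arange(n)
    cells_list, amps, t0s, t1s = [], [], [], []
    for s in protocol.sites:
        ci = index[np.asarray(s.indices, dtype=np.int64)]
        ci = ci[ci >= 0]
        if ci.size == 0:
            raise ValueError("stimulus site addresses no conducting cells")
        cells_list.append(ci.astype(np.int64))
        amps.append(s.amplitude)
        t0s.append(s.start)
        t1s.append(s.start + s.duration)
    site_cells = (np.concatenate(cells_list) if cells_list
                  else np.zeros(0, dtype=np.int64))
    site_off = np.zeros(len(cells_list) + 1, dtype=np.int64)
    np.cumsum([c.size for c in cells_list], out=site_off[1:])
    site_amp = np.asarray(amps)
    site_t0 = np.asarray(t0s)
    site_t1 = np.asarray(t1s)
    stim_end = protocol.end_time

    L = st.L.tocsr()
    Ldata, Lind, Lptr = L.data, L.indices, L.indptr
    T, TK1 = _kernel.build_tables(dt)

    n_steps = int(round(duration / dt))
    snap_stride = max(int(round(snapshot_every / dt)), 1)
    times, fields = [], []
    activations: list[list[float]] = [[] for _ in range(n)]
    repolarizations: list[list[float]] = [[] for _ in range(n)]
    last_act = np.full(n, -1e18)
    peak = np.full(n, -1e18)
    rest_ref = st.Y[0].copy()
    active = np.zeros(n, dtype=np.uint8)
    buf = max(4 * n, 1024)
    act_cell = np.empty(buf, dtype=np.int64)
    act_time = np.empty(buf)
    rep_cell = np.empty(buf, dtype=np.int64)
    rep_time = np.empty(buf)
    quiescent_ms = 0.0
    quiescent_from = None

    done = 0
    while done < n_steps:
        if done % snap_stride == 0:
            times.append(done * dt)
            fields.append(st.Y[0].astype(np.float32).copy())
        chunk = min(snap_stride - (done % snap_stride), n_steps - done)
        steps, n_act, n_rep, status, quiescent_ms = _kernel._integrate_chunk(
            st.Y, st.P, T, TK1, dt, chunk, done * dt,
            site_cells, site_off, site_amp, site_t0, site_t1,
            Ldata, Lind, Lptr, st.n_sub, st.scale,
            last_act, peak, rest_ref, active,
            act_cell, act_time, rep_cell, rep_time,
            stim_end, early_stop_quiescent, quiescent_ms)
        for k in range(n_act):
            activations[act_cell[k]].append(round(act_time[k], 6))
        for k in range(n_rep):
            repolarizations[rep_cell[k]].append(round(rep_time[k], 6))
        done += steps
        if status == 2:
            raise FloatingPointError(
                f"numerical blow-up at t = {done * dt:.2f} ms (step {done})")
        if status == 3:
            quiescent_from = done * dt
            break

    pos = grid.positions_cm()[cond]
    return SimulationRecord(
        times=np.asarray(times), v_fields=np.asarray(fields),
        activations=activations, repolarizations=repolarizations,
        positions=pos, dt=dt, quiescent_from=quiescent_from)
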