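"""Monte-Carlo sweep of (phi, [ATP]i) over stochastic fibrosis mazes.

For each pair (fibrosis fraction phi, scar [ATP]i) a number of independent
maze realizations is generated on the same wedge geometry; each realization
is simulated end-to-end (wedge -> PZ gradients -> maze -> single point
stimulus in the healthy rim -> >= 1 s past the stimulus) and classified for
sustained reentry and ectopic beats.  Aggregation yields the per-pair
probability that the infarct region behaves as an ectopic pacemaker, with
Wilson binomial confidence intervals.

The default design mirrors the study protocol -- phi = 0.64..0.69 step
0.01, scar [ATP]i in {2, 3} mM, 20 realizations per pair (240 runs) -- on
a desk-scale synthetic wedge: a one-cell-thick 6 x 6 mm slab at 100 um
spacing with a 2 mm-radius scar, simulated 1.5 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tissue_solver as ts
from .activity_metrics import classify_sustained_reentry, detect_ectopic_beats
from .geometry_fibrosis import LesionSpec, apply_diffuse_fibrosis, \
    build_wedge, pz_gradient

__all__ = ["SweepDesign", "run_sweep", "run_realization", "aggregate",
           "realization_seed"]

DEFAULT_PHI = tuple(round(0.64 + 0.01 * i, 2) for i in range(6))
DEFAULT_ATP = (2.0, 3.0)


@dataclass(frozen=True)
class SweepDesign:
    """Full specification of a Monte-Carlo sweep; total runs =
    len(phi_values) * len(atp_values) * n_realizations."""

    phi_values: tuple = DEFAULT_PHI
    atp_values: tuple = DEFAULT_ATP
    n_realizations: int = 20
    base_seed: int = 0
    dims: tuple = (60, 60, 1)
    spacing: float = 100.0           # um
    scar_radius: float = 2000.0      # um
    pz_outer_radius: float = 2600.0  # um
    duration: float = 1500.0         # ms
    stim_start: float = 5.0          # ms
    horizon: float = 1000.0          # ms after stimulus end
    snapshot_every: float = 10.0     # ms

    @property
    def n_runs(self) -> int:
        return (len(self.phi_values) * len(self.atp_values)
                * self.n_realizations)

    def lesion(self, phi: float, atp: float) -> LesionSpec:
        center = tuple((d - 1) / 2.0 for d in self.dims)
        return LesionSpec(scar_center=center, scar_radius=self.scar_radius,
                          pz_outer_radius=self.pz_outer_radius,
                          phi_scar=phi, atp_scar=atp)


def realization_seed(base_seed: int, i_phi: int, i_atp: int,
                     i_real: int) -> int:
    """Deterministic per-run maze seed (counter scheme; < 2^31)."""
    ss = np.random.SeedSequence([base_seed, i_phi, i_atp, i_real])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_realization(design: SweepDesign, phi: float, atp: float,
                    seed: int) -> dict:
    """One end-to-end Monte-Carlo realization -> result row dict."""
    import time
    t_wall = time.perf_counter()
    lesion = design.lesion(phi, atp)
    grid = build_wedge(design.dims, design.spacing, lesion)
    _, phi_field = pz_gradient(grid, lesion)
    apply_diffuse_fibrosis(grid, phi_field, seed)

    # single point-like stimulus in the healthy rim corner
    protocol = ts.StimulusProtocol.point(
        grid, center=(1.5, 1.5, (design.dims[2] - 1) / 2.0),
        radius_cells=4.0, start=design.stim_start, duration=3.0)
    duration = max(design.duration, protocol.end_time + design.horizon + 60.0)
    record = ts.run(grid, protocol, duration,
                    snapshot_every=design.snapshot_every)
    verdict = classify_sustained_reentry(record, protocol.end_time,
                                         design.horizon)
    beats = detect_ectopic_beats(record, grid)
    return {
        "phi": phi, "atp": atp, "seed": seed,
        "sustained": bool(verdict.sustained),
        "n_ectopic_beats": len(beats),
        "last_activation_time": verdict.last_activation_time,
        "runtime_s": time.perf_counter() - t_wall,
    }


def run_sweep(design: SweepDesign, out_csv=None,
              progress: bool = False) -> pd.DataFrame:
    """Execute the full sweep; resumable via ``out_csv`` (completed
    (phi, atp, seed) rows are skipped) and fully reproducible from
    ``design.base_seed``.  Individual run failures are recorded as failed
    rows and the sweep continues."""
    done: dict[tuple, dict] = {}
    if out_csv is not None:
        import os
        if os.path.exists(out_csv):
            prev = pd.read_csv(out_csv)
            done = {(r.phi, r.atp, int(r.seed)): r._asdict()
                    for r in prev.itertuples(index=False)}
    rows = []
    for i_phi, phi in enumerate(design.phi_values):
        for i_atp, atp in enumerate(design.atp_values):
            for i_real in range(design.n_realizations):
                seed = realization_seed(design.base_seed, i_phi, i_atp,
                                        i_real)
                key = (phi, atp, seed)
                if key in done:
                    rows.append(done[key])
                    continue
                try:
                    row = run_realization(design, phi, atp, seed)
                except (FloatingPointError, ts.StabilityError) as err:
                    row = {"phi": phi, "atp": atp, "seed": seed,
                           "sustained": False, "n_ectopic_beats": 0,
                           "last_activation_time": np.nan,
                           "runtime_s": np.nan, "failed": str(err)}
                rows.append(row)
                if progress:
                    print(f"phi={phi} atp={atp} seed={seed} -> "
                          f"{row.get('sustained')}", flush=True)
                if out_csv is not None:
                    pd.DataFrame(rows).to_csv(out_csv, index=False)
    table = pd.DataFrame(rows)
    if "failed" not in table.columns:
        table["failed"] = np.nan
    return table


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Reentry fraction per (phi, atp) with a 95% Wilson interval.

    Failed runs are excluded from the denominators and counted in
    ``n_failed``."""
    if table.empty:
        raise ValueError("empty sweep table")
    from statsmodels.stats.proportion import proportion_confint

    table = table.copy()
    if "failed" not in table.columns:
        table["failed"] = np.nan
    ok = table[table["failed"].isna()]
    out = []
    for (phi, atp), grp in table.groupby(["phi", "atp"], sort=True):
        g = ok[(ok.phi == phi) & (ok.atp == atp)]
        n = len(g)
        k = int(g.sustained.sum())
        lo, hi = (proportion_confint(k, n, method="wilson") if n
                  else (np.nan, np.nan))
        out.append({"phi": phi, "atp": atp, "n": n, "n_sustained": k,
                    "fraction": k / n if n else np.nan,
                    "ci_low": lo, "ci_high": hi,
                    "n_failed": int(len(grp) - n)})
    return pd.DataFrame(out)


def summary_figure(agg: pd.DataFrame, path) -> None:
    """Bar chart of reentry percentage vs phi, one bar group per [ATP]i."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    atps = sorted(agg.atp.unique())
    phis = sorted(agg.phi.unique())
    width = 0.8 / max(len(atps), 1)
    for k, atp in enumerate(atps):
        sub = agg[agg.atp == atp].set_index("phi").reindex(phis)
        x = np.arange(len(phis)) + k * width
        ax.bar(x, 100 * sub.fraction.values, width,
               label=f"[ATP]$_i$ = {atp} mM")
    ax.set_xticks(np.arange(len(phis)) + 0.4 - width / 2)
    ax.set_xticklabels([f"{p:.2f}" for p in phis])
    ax.set_xlabel(r"fibrosis fraction $\phi$")
    ax.set_ylabel("sustained reentries (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
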