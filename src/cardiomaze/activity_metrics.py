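"""Quantification of simulations: APD90, conduction velocity, wavelength,
sustained-reentry classification and ectopic-beat detection.

Definitions used throughout the package:

* activation -- upward crossing of -20 mV, with a 10 ms refractory guard
  between distinct activations of the same cell;
* APD90 -- time from the activation crossing to 90% repolarization toward
  the pre-upstroke diastolic potential;
* wavelength -- APD90 x CV (cm), the spatial extent of depolarized tissue
  behind a planar wavefront;
* sustained reentry -- activity still present ~1 s after the end of a single
  stimulus: an activation event inside [t_stim_end + 950, t_stim_end + 1050]
  ms, or any conducting cell above -70 mV at t_stim_end + 1000 ms;
* ectopic beat -- activation of healthy tissue at the peri-infarct interface
  that is not attributable to the paced primary wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ACTIVATION_THRESHOLD_MV = -20.0
REFRACTORY_GUARD_MS = 10.0
QUIESCENT_MV = -70.0

__all__ = [
    "WaveMetrics",
    "ReentryVerdict",
    "measure_apd90",
    "measure_cv",
    "wavelength_cm",
    "classify_sustained_reentry",
    "detect_ectopic_beats",
    "activation_map",
]


@dataclass(frozen=True)
class WaveMetrics:
    """APD90 (ms), conduction velocity (cm/s) and wavelength (cm) of a
    planar wave; wavelength = apd90 * cv by construction."""

    apd90: float
    cv: float

    @property
    def wavelength(self) -> float:
        return self.apd90 * 1e-3 * self.cv  # ms * cm/s -> cm


@dataclass
class ReentryVerdict:
    sustained: bool
    last_activation_time: float  # ms, -inf when no activation at all
    n_ectopic_beats: int = 0
    ectopic_exit_times: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.n_ectopic_beats = len(self.ectopic_exit_times) \
            if self.ectopic_exit_times else self.n_ectopic_beats


def measure_apd90(t: np.ndarray, v: np.ndarray, *, which: str = "last"):
    """APD90 of a voltage trace, or None when no complete AP is present.

    ``which`` selects the first or last complete action potential.  The
    diastolic reference is the minimum V over the 100 ms preceding the
    upstroke (the pre-stimulus diastolic potential).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size < 3:
        return None
    thr = ACTIVATION_THRESHOLD_MV
    ups = np.where((v[:-1] < thr) & (v[1:] >= thr))[0] + 1
    if ups.size == 0:
        return None
    order = ups if which == "first" else ups[::-1]
    dt_samp = t[1] - t[0]
    pre_n = max(int(round(100.0 / dt_samp)), 1)
    for u in order:
        end = ups[ups > u]
        seg_end = end[0] if end.size else v.size
        seg = v[u:seg_end]
        if seg.size < 2:
            continue
        base = v[max(0, u - pre_n):u].min() if u > 0 else v[0]
        ipk = int(np.argmax(seg))
        peak = seg[ipk]
        v90 = peak - 0.9 * (peak - base)
        below = np.where(seg[ipk:] <= v90)[0]
        if below.size == 0:
            continue  # AP not complete within the trace
        k = ipk + below[0]
        # linear interpolation of the crossing time
        if k > 0 and seg[k - 1] > seg[k]:
            frac = (seg[k - 1] - v90) / (seg[k - 1] - seg[k])
        else:
            frac = 0.0
        return float(t[u + k - 1] + frac * dt_samp - t[u]) if k > 0 \
            else float(t[u] - t[u])
    return None


def measure_cv(record, probe_a: int, probe_b: int) -> float:
    """Conduction velocity (cm/s) between two probes of a planar-wave run.

    Probes are conducting-cell indices into the record; each must have been
    activated exactly once (use a planar stimulus protocol and colinear
    probes along the propagation axis).
    """
    acts_a = record.activations[probe_a]
    acts_b = record.activations[probe_b]
    if len(acts_a) != 1 or len(acts_b) != 1:
        raise ValueError(
            "each probe must activate exactly once; run a planar-wave "
            f"protocol (probe activations: {len(acts_a)}, {len(acts_b)})")
    dt_ms = acts_b[0] - acts_a[0]
    if dt_ms == 0:
        raise ValueError("probes activated simultaneously; move them apart "
                         "along the propagation axis")
    dist_cm = record.probe_distance_cm(probe_a, probe_b)
    return float(dist_cm / (abs(dt_ms) * 1e-3))


def wavelength_cm(apd90_ms: float, cv_cm_s: float) -> float:
    """Wavelength = APD x CV, in cm."""
    return apd90_ms * 1e-3 * cv_cm_s


def classify_sustained_reentry(record, stimulus_end: float,
                               horizon: float = 1000.0,
                               window: float = 50.0) -> ReentryVerdict:
    """Decide whether activity is self-sustained ``horizon`` ms after the
    stimulus ended.

    Sustained when (a) any activation event falls inside
    [stimulus_end + horizon - window, stimulus_end + horizon + window], or
    (b) some conducting cell is above -70 mV at the snapshot nearest to
    stimulus_end + horizon.  A record truncated earlier because the tissue
    went (and stayed) quiescent is classified not sustained; otherwise the
    record must cover the horizon.
    """
    t_probe = stimulus_end + horizon
    covered = record.times.size and record.times[-1] >= t_probe - window
    if not covered and not getattr(record, "quiescent_from", None):
        raise ValueError("record too short to classify sustained reentry")

    all_acts = [a for acts in record.activations for a in acts]
    last_act = max(all_acts) if all_acts else float("-inf")

    sustained = False
    lo, hi = t_probe - window, t_probe + window
    if any(lo <= a <= hi for a in all_acts):
        sustained = True
    elif covered:
        k = int(np.argmin(np.abs(record.times - t_probe)))
        if record.v_fields[k].max() > QUIESCENT_MV:
            sustained = True
    return ReentryVerdict(sustained=sustained, last_activation_time=last_act)


def detect_ectopic_beats(record, grid, *, guard: float = 50.0,
                         merge_window: float = 40.0) -> list[float]:
    """Times (ms) of ectopic beats: activations of healthy cells adjacent to
    the peri-infarct zone that occur after the paced primary wave.

    The paced wave is attributed as every healthy-cell activation up to
    T_paced + guard, where T_paced is the latest first-activation over the
    healthy domain.  Later interface activations are merged into beats when
    closer than ``merge_window`` ms.
    """
    from .tissue_solver import Tag

    tags = grid.tags
    cond = grid.conducting_mask()
    healthy = tags == Tag.HEALTHY
    pz = tags == Tag.PZ
    # healthy cells with a face neighbour in the PZ
    interface = np.zeros_like(healthy)
    for ax in range(3):
        for sh in (1, -1):
            interface |= healthy & np.roll(pz, sh, axis=ax)
    # np.roll wraps around the boundary; lesions never touch it by invariant
    iface_idx = set(np.flatnonzero(interface[cond]))
    healthy_idx = np.flatnonzero(healthy[cond])

    firsts = [record.activations[i][0] for i in healthy_idx
              if record.activations[i]]
    if not firsts:
        return []
    t_paced = max(firsts)

    exits = sorted(
        a for i in iface_idx for a in record.activations[i]
        if a > t_paced + guard)
    beats: list[float] = []
    for e in exits:
        if not beats or e - beats[-1] > merge_window:
            beats.append(e)
    return beats


def activation_map(record, *, which: str = "first") -> np.ndarray:
    """Per-conducting-cell first (or last) activation time; NaN where the
    cell never activated."""
    n = len(record.activations)
    out = np.full(n, np.nan)
    for i, acts in enumerate(record.activations):
        if acts:
            out[i] = acts[0] if which == "first" else acts[-1]
    return out
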