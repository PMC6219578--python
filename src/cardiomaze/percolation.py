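"""Percolation analysis of diffuse-fibrosis mazes.

Connectivity is 6-neighbour (face) adjacency, matching the finite-volume
flux stencil, so "electrically connected" and "same cluster" coincide.  A
lattice spans when one conducting cluster touches two opposite outer faces
along any axis.  For i.i.d. site removal on the 3D cubic lattice the
spanning probability drops through 0.5 near a removed fraction of ~0.69
(the site-percolation threshold: occupied fraction p_c ~ 0.3116); the
reentry-prone fibrosis band sits just below this threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["ClusterLabeling", "label_clusters", "spans",
           "spanning_probability", "estimate_threshold"]

_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class ClusterLabeling:
    """Connected components of the conducting cells.

    ``labels`` assigns 0 to non-conducting cells and 1..n_clusters to
    conducting cells; ``sizes[k]`` is the cell count of cluster k+1;
    ``spanning`` is True when any cluster touches two opposite faces of the
    domain along some axis.
    """

    labels: np.ndarray
    sizes: np.ndarray
    spanning: bool

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def label_clusters(mask: np.ndarray, axes=None) -> ClusterLabeling:
    """Label 6-connected clusters of True (conducting) cells.

    ``axes`` restricts the spanning check to the given axes (default: every
    axis of extent >= 2; pass e.g. (0, 1) for thin slabs where spanning the
    thickness is trivial)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-dimensional")
    labels, n = ndimage.label(mask, structure=_STRUCTURE)
    sizes = (np.bincount(labels.ravel(), minlength=n + 1)[1:]
             if n else np.zeros(0, dtype=np.int64))
    return ClusterLabeling(labels=labels, sizes=sizes,
                           spanning=_spanning(labels, axes))


def _spanning(labels: np.ndarray, axes=None) -> bool:
    for ax in (range(3) if axes is None else axes):
        if labels.shape[ax] < 2:
            continue
        lo = labels.take(0, axis=ax)
        hi = labels.take(-1, axis=ax)
        common = np.intersect1d(lo[lo > 0], hi[hi > 0])
        if common.size:
            return True
    return False


def spans(mask: np.ndarray, axes=None) -> bool:
    """True when a conducting cluster connects two opposite domain faces."""
    return label_clusters(mask, axes).spanning


def spanning_probability(phi: float, lattice_size, n_trials: int,
                         seed: int, axes=None) -> float:
    """Monte-Carlo Pr[spanning] for i.i.d. removal at fraction ``phi``."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    shape = (tuple(lattice_size) if np.iterable(lattice_size)
             else (lattice_size,) * 3)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_trials):
        conducting = rng.random(shape) >= phi
        if spans(conducting, axes):
            hits += 1
    return hits / n_trials


def estimate_threshold(lattice_size=32, n_trials: int = 200, seed: int = 0,
                       phi_grid=None, axes=None):
    """Removed-fraction threshold phi_c where Pr[spanning] crosses 0.5.

    Scans ``phi_grid`` (default 0.60..0.76 step 0.01), enforces
    monotonicity with a decreasing isotonic fit, and interpolates the 0.5
    crossing.  Returns (phi_c, standard_error); the SE combines the binomial
    noise of the two bracketing grid points.  Finite-size caveat: on small
    lattices the crossing is shifted and broadened relative to the
    infinite-lattice threshold.
    """
    if n_trials < 50:
        raise ValueError("n_trials must be >= 50 for a threshold estimate")
    if phi_grid is None:
        phi_grid = np.arange(0.60, 0.7601, 0.01)
    phi_grid = np.asarray(phi_grid, dtype=float)
    rng = np.random.default_rng(seed)
    probs = np.array([
        spanning_probability(p, lattice_size, n_trials,
                             int(rng.integers(2 ** 31)), axes)
        for p in phi_grid])

    from sklearn.isotonic import IsotonicRegression
    iso = IsotonicRegression(increasing=False)
    fit = iso.fit_transform(phi_grid, probs)

    below = np.where(fit <= 0.5)[0]
    above = np.where(fit >= 0.5)[0]
    if below.size == 0 or above.size == 0:
        raise RuntimeError(
            "spanning probability does not cross 0.5 on the phi grid; "
            "widen the grid")
    j = below[0]           # first phi with fit <= 0.5
    i = max(j - 1, 0)      # last phi with fit > 0.5 (or j itself)
    if fit[i] == fit[j]:
        phi_c = 0.5 * (phi_grid[i] + phi_grid[j])
    else:
        phi_c = phi_grid[i] + (fit[i] - 0.5) / (fit[i] - fit[j]) \
            * (phi_grid[j] - phi_grid[i])
    p_se = np.sqrt(np.clip(fit * (1 - fit), 0.25 / n_trials, None)
                   / n_trials)
    slope = abs(fit[i] - fit[j]) / abs(phi_grid[j] - phi_grid[i]) \
        if fit[i] != fit[j] else 1.0
    se = float(0.5 * (p_se[i] + p_se[j]) / max(slope, 1e-9))
    return float(phi_c), se
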