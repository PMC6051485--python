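"""Uncertainty sets and the three-valued loss weight map.

During image-specific fine-tuning the network is refitted to its own
current segmentation, so pixels the estimate is unsure about must not
drive the update.  Two uncertainty sets are used:

* network-based: ``U_p = {i | t0 < p_i < t1}`` — pixels whose foreground
  probability falls strictly between two thresholds;
* scribble-based: ``U_s = U_s^f | U_s^b`` with
  ``U_s^f = {i | i not in S, G(i, S^f) < eps, y_i = 0}`` (and symmetrically
  for background), where ``G`` is the intensity-aware geodesic distance
  from the scribbles.  Scribbles mark mis-segmented areas, so nearby
  pixels carrying the opposite label are suspect.

The weight map is ``omega`` on scribbles (highest precedence), 0 on
``(U_p | U_s) \\ S`` and 1 elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .crf import ScribbleSet, _grid_edges
from .errors import InputError

GEODESIC_GAMMA = 1.0  # intensity weighting of the geodesic step cost


@dataclass(frozen=True)
class UncertaintyParams:
    """Thresholds for the uncertainty sets and the scribble loss weight."""

    t0: float = 0.2
    t1: float = 0.7
    epsilon: float = 0.2
    omega: float = 5.0

    def __post_init__(self):
        if not (0.0 <= self.t0 < self.t1 <= 1.0):
            raise InputError("thresholds must satisfy 0 <= t0 < t1 <= 1")
        if self.epsilon <= 0:
            raise InputError("epsilon must be positive")
        if self.omega < 1:
            raise InputError("omega must be >= 1")


@dataclass
class WeightMap:
    """Per-pixel loss weights taking values in {0, 1, omega}."""

    w: np.ndarray
    omega: float


def network_uncertainty(prob, t0: float, t1: float) -> np.ndarray:
    """Boolean mask of pixels with ``t0 < p < t1`` (strict on both sides)."""
    p = np.asarray(prob.p if hasattr(prob, "p") else prob)
    return (p > t0) & (p < t1)


def geodesic_distance(region, seeds: np.ndarray, gamma: float = GEODESIC_GAMMA) -> np.ndarray:
    """Geodesic distance from every pixel to the nearest seed.

    Shortest-path distance on the axis-neighbor pixel graph with step cost
    ``sqrt(1 + gamma^2 * (I_i - I_j)^2)`` (unit spacing, normalized
    intensities).  On a constant image this is the pure spatial graph
    distance; seeds are at distance 0.
    """
    intens = region.intensities if hasattr(region, "intensities") else np.asarray(region)
    seeds = np.asarray(seeds, dtype=bool)
    if seeds.shape != intens.shape:
        raise InputError("seed mask must match the region shape")
    if not seeds.any():
        raise InputError("geodesic distance requires a nonempty seed set")
    x = np.asarray(intens, dtype=np.float64).ravel()
    a, b = _grid_edges(intens.shape)
    cost = np.sqrt(1.0 + (gamma * (x[a] - x[b])) ** 2)
    n = x.size
    graph = csr_matrix((np.concatenate([cost, cost]),
                        (np.concatenate([a, b]), np.concatenate([b, a]))), shape=(n, n))
    seed_idx = np.flatnonzero(seeds.ravel())
    dist = dijkstra(graph, directed=False, indices=seed_idx, min_only=True)
    return dist.reshape(intens.shape)


def scribble_uncertainty(region, scribbles: ScribbleSet, labeling,
                         epsilon: float, gamma: float = GEODESIC_GAMMA) -> np.ndarray:
    """Unscribbled pixels geodesically close to a scribble but labeled
    opposite to it; empty when there are no scribbles (unsupervised mode)."""
    intens = region.intensities if hasattr(region, "intensities") else np.asarray(region)
    y = np.asarray(labeling)
    if y.shape != intens.shape:
        raise InputError("labeling shape must match the region")
    out = np.zeros(intens.shape, dtype=bool)
    in_s = scribbles.any_mask
    if scribbles.fg.any():
        gf = geodesic_distance(intens, scribbles.fg, gamma)
        out |= (~in_s) & (gf < epsilon) & (y == 0)
    if scribbles.bg.any():
        gb = geodesic_distance(intens, scribbles.bg, gamma)
        out |= (~in_s) & (gb < epsilon) & (y == 1)
    return out


def build_weight_map(scribbles: ScribbleSet, u_p: np.ndarray, u_s: np.ndarray,
                     omega: float) -> WeightMap:
    """Three-valued weights with precedence S > (U_p | U_s) > default 1."""
    u_p = np.asarray(u_p, dtype=bool)
    u_s = np.asarray(u_s, dtype=bool)
    if u_p.shape != scribbles.fg.shape or u_s.shape != scribbles.fg.shape:
        raise InputError("uncertainty sets must match the scribble mask shape")
    w = np.ones(u_p.shape, dtype=np.float64)
    w[u_p | u_s] = 0.0
    w[scribbles.any_mask] = omega
    return WeightMap(w, omega)
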