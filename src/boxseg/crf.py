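"""Binary CRF over a cropped region, solved exactly with graph cuts.

The energy is the usual foreground-extraction objective

    E(Y) = sum_i phi(y_i) + lambda * sum_{(i,j)} psi(y_i, y_j)

with a negative-log-softmax unary ``phi(y_i) = -(y_i log p_i +
(1-y_i) log(1-p_i))`` and a contrast-sensitive Potts pairwise
``psi = [y_i != y_j] exp(-(I_i - I_j)^2 / (2 sigma^2)) / d_ij`` over a
4-neighborhood (2D) or 6-neighborhood (3D), where d_ij = 1.  User
scribbles are hard constraints: a scribbled pixel pays nothing for its own
label and an effectively infinite cost for the opposite one, so any
finite-energy labeling agrees with every scribble.

Since the pairwise term is submodular the global minimizer is found with a
single max-flow/min-cut on the pixel grid.  Capacities are scaled to
fixed-point integers (up to 2^20 per unit energy, lowered adaptively so the
worst finite cut fits scipy's int32 max-flow arithmetic);
``brute_force_solve`` provides an exhaustive reference for tiny regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .errors import InputError

PROB_EPS = 1e-6
_FIXED_POINT = 2 ** 20


@dataclass(frozen=True)
class CRFParams:
    """Pairwise weight, contrast scale (in normalized-intensity units) and
    connectivity ("4/6" means 4-neighborhood in 2D, 6 in 3D)."""

    lam: float = 3.0
    sigma: float = 0.1
    neighborhood: str = "4/6"

    def __post_init__(self):
        if self.lam < 0:
            raise InputError("lambda must be nonnegative")
        if self.sigma <= 0:
            raise InputError("sigma must be positive")


@dataclass
class ScribbleSet:
    """Foreground/background scribble masks over a region."""

    fg: np.ndarray
    bg: np.ndarray

    def __post_init__(self):
        self.fg = np.asarray(self.fg, dtype=bool)
        self.bg = np.asarray(self.bg, dtype=bool)
        if self.fg.shape != self.bg.shape:
            raise InputError("scribble mask shapes differ")
        if np.any(self.fg & self.bg):
            raise InputError("a pixel cannot be both foreground and background scribble")

    @staticmethod
    def empty(shape) -> "ScribbleSet":
        return ScribbleSet(np.zeros(shape, bool), np.zeros(shape, bool))

    @property
    def any_mask(self) -> np.ndarray:
        return self.fg | self.bg

    @property
    def is_empty(self) -> bool:
        return not (self.fg.any() or self.bg.any())


# ---------------------------------------------------------------------------
# Energy terms


def pairwise_term(xi, xj, yi, yj, dij, sigma) -> float:
    """Contrast-sensitive Potts potential between one pixel pair."""
    if dij <= 0:
        raise InputError("pairwise distance must be positive")
    if sigma <= 0:
        raise InputError("sigma must be positive")
    if yi == yj:
        return 0.0
    return float(np.exp(-((xi - xj) ** 2) / (2.0 * sigma ** 2)) / dij)


def unary_term(p_i, y_i) -> float:
    """Negative log softmax probability of the assigned label (clamped)."""
    p = np.clip(p_i, PROB_EPS, 1.0 - PROB_EPS)
    return float(-np.log(p) if y_i == 1 else -np.log(1.0 - p))


def constrained_unary(p_i, y_i, scribbles: ScribbleSet, index) -> float:
    """Unary with scribble hard constraints.

    On a scribbled pixel the agreeing label is free and the disagreeing one
    costs ``large_constant`` (finite stand-in for infinity, guaranteed to
    exceed any achievable finite energy); elsewhere it is the plain unary.
    """
    if scribbles.fg[index]:
        return 0.0 if y_i == 1 else _large_for(scribbles.fg.shape)
    if scribbles.bg[index]:
        return 0.0 if y_i == 0 else _large_for(scribbles.bg.shape)
    return unary_term(p_i, y_i)


def large_constant(prob: np.ndarray, lam: float, n_edges: int) -> float:
    """A finite 'infinity': above the sum of all clamped unaries plus the
    maximal pairwise total."""
    pc = np.clip(np.asarray(prob, dtype=np.float64), PROB_EPS, 1.0 - PROB_EPS)
    worst_unary = np.maximum(-np.log(pc), -np.log(1.0 - pc)).sum()
    return float(worst_unary + lam * n_edges + 1.0)


def _large_for(shape) -> float:
    n = int(np.prod(shape))
    return float(n * -np.log(PROB_EPS) + 1.0) * 10.0


# ---------------------------------------------------------------------------
# Neighborhood plumbing


def _grid_edges(shape) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j), i < j, of axis-aligned neighbors on the grid."""
    idx = np.arange(int(np.prod(shape))).reshape(shape)
    pairs_a, pairs_b = [], []
    for ax in range(len(shape)):
        sl_a = [slice(None)] * len(shape)
        sl_b = [slice(None)] * len(shape)
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        pairs_a.append(idx[tuple(sl_a)].ravel())
        pairs_b.append(idx[tuple(sl_b)].ravel())
    return np.concatenate(pairs_a), np.concatenate(pairs_b)


def _edge_weights(intensities: np.ndarray, edges, sigma: float) -> np.ndarray:
    x = np.asarray(intensities, dtype=np.float64).ravel()
    a, b = edges
    return np.exp(-((x[a] - x[b]) ** 2) / (2.0 * sigma ** 2))  # d_ij = 1


def _unary_tables(prob, scribbles: ScribbleSet, large: float):
    p = np.clip(np.asarray(prob, dtype=np.float64).ravel(), PROB_EPS, 1.0 - PROB_EPS)
    u0 = -np.log(1.0 - p)
    u1 = -np.log(p)
    fg = scribbles.fg.ravel()
    bg = scribbles.bg.ravel()
    u0[fg] = large
    u1[fg] = 0.0
    u0[bg] = 0.0
    u1[bg] = large
    return u0, u1


# ---------------------------------------------------------------------------
# Energy and solvers


def energy(labeling, prob, region, scribbles: ScribbleSet | None, params: CRFParams) -> float:
    """Total CRF energy of ``labeling`` (scribble violations cost LARGE each)."""
    y = np.asarray(labeling).ravel().astype(np.int8)
    intens = region.intensities if hasattr(region, "intensities") else np.asarray(region)
    if scribbles is None:
        scribbles = ScribbleSet.empty(intens.shape)
    edges = _grid_edges(intens.shape)
    w = _edge_weights(intens, edges, params.sigma)
    large = large_constant(prob, params.lam, len(w))
    u0, u1 = _unary_tables(prob, scribbles, large)
    e = float(np.where(y == 1, u1, u0).sum())
    a, b = edges
    e += params.lam * float(w[y[a] != y[b]].sum())
    return e


def solve_labels(prob, region, scribbles: ScribbleSet | None, params: CRFParams) -> np.ndarray:
    """Exact global minimizer of the scribble-constrained CRF energy.

    Returns a binary array of the region's shape.  With ``lam == 0`` and no
    scribbles this reduces to thresholding p at 0.5 (ties to background).
    """
    intens = region.intensities if hasattr(region, "intensities") else np.asarray(region)
    p = np.asarray(prob.p if hasattr(prob, "p") else prob, dtype=np.float64)
    if p.shape != intens.shape:
        raise InputError("probability map and region shapes differ")
    if scribbles is None:
        scribbles = ScribbleSet.empty(intens.shape)
    if scribbles.fg.shape != intens.shape:
        raise InputError("scribble masks must match the region shape")
    n = p.size
    edges = _grid_edges(intens.shape)
    w = params.lam * _edge_weights(intens, edges, params.sigma)
    u0, u1 = _unary_tables(p, scribbles, np.inf)
    # t-link simplification: subtracting min(u0, u1) per pixel shifts the
    # energy by a labeling-independent constant
    base = np.minimum(u0, u1)
    cap_s = u0 - base  # paid when the pixel ends up background (sink side)
    cap_t = u1 - base  # paid when it ends up foreground (source side)
    # scipy's max-flow works in int32, so pick a fixed-point scale such that
    # the worst finite cut (every pixel pays its larger shifted t-link, every
    # pairwise edge is cut) plus rounding slack stays below 2^31; scribble
    # "infinity" capacities sit just above that bound and are never cut
    scribbled = scribbles.any_mask.ravel()
    finite_bound = float(np.maximum(cap_s, cap_t)[~scribbled].sum() + w.sum() + 1.0)
    n_terms = n + 2 * len(w)
    scale = min(_FIXED_POINT, int((2 ** 31 - 4 - n_terms) / max(finite_bound, 1e-9)))
    if scale < 1:
        raise InputError("region too large for fixed-point graph construction")
    large_int = int(round(finite_bound * scale)) + n_terms + 2

    def fx(v):
        out = np.rint(np.where(np.isfinite(v), v, 0.0) * scale).astype(np.int64)
        return np.where(np.isfinite(v), out, large_int)

    a, b = edges
    src, snk = n, n + 1
    rows = np.concatenate([np.full(n, src), np.arange(n), a, b])
    cols = np.concatenate([np.arange(n), np.full(n, snk), b, a])
    caps = np.concatenate([fx(cap_s), fx(cap_t), fx(w), fx(w)])
    keep = caps > 0
    graph = csr_matrix((caps[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2))
    result = maximum_flow(graph, src, snk)
    residual = graph - result.flow
    residual.data = np.where(residual.data > 0, residual.data, 0)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, src, directed=True, return_predecessors=False)
    labels = np.zeros(n, dtype=np.uint8)
    labels[reach[reach < n]] = 1
    return labels.reshape(intens.shape)


def brute_force_solve(prob, region, scribbles: ScribbleSet | None, params: CRFParams) -> np.ndarray:
    """Exhaustive minimizer for regions of at most 16 pixels (test oracle)."""
    intens = region.intensities if hasattr(region, "intensities") else np.asarray(region)
    p = np.asarray(prob.p if hasattr(prob, "p") else prob, dtype=np.float64)
    n = p.size
    if n > 16:
        raise InputError("brute force refused: region larger than 16 pixels")
    if scribbles is None:
        scribbles = ScribbleSet.empty(intens.shape)
    edges = _grid_edges(intens.shape)
    w = _edge_weights(intens, edges, params.sigma)
    large = large_constant(p, params.lam, len(w))
    u0, u1 = _unary_tables(p, scribbles, large)
    all_labels = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(np.int8)
    e = all_labels @ u1 + (1 - all_labels) @ u0
    a, b = edges
    e += params.lam * ((all_labels[:, a] != all_labels[:, b]) * w).sum(axis=1)
    best = int(np.argmin(e))  # first minimum: deterministic tie-break
    return all_labels[best].astype(np.uint8).reshape(intens.shape)
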