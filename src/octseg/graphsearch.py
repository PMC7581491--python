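"""Graph-search boundary delineation from class probability maps.

Each boundary (ILM, RPE) gets its own boundary-probability ("edge") map:
the positive part of the row-wise increase of the probability of lying
at or below that boundary.  A directed acyclic graph is built with one
vertex per pixel, each connected to its three rightmost neighbours
(horizontal, diagonally up, diagonally down) with weight
``w(s, d) = 2 - (p_s + p_d)``; a dummy column of probability-1,
vertically connected vertices on each side lets a corner-to-corner path
enter and leave at any row.  The minimum-cost left-to-right path -- the
predicted boundary -- is found by column-sweep relaxation, which on this
acyclic graph returns exactly the Dijkstra shortest path; the dummy
columns contribute the analytic entry cost ``1 - p`` at the first column
and exit cost ``1 - p`` at the last.

Tie-breaking is deterministic: among equal-cost predecessors the
horizontal one is preferred, then diagonal-up, then diagonal-down, and
the topmost end row is chosen among equal-cost paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import BoundarySet
from .preprocess import PAD_ROWS_DEFAULT, onehot_regions

BOUNDARIES = ("ILM", "RPE")


@dataclass
class PathResult:
    rows: np.ndarray   # (W,) int row per column
    cost: float
    boundary: str = ""

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.int64)
        if self.rows.size > 1 and np.abs(np.diff(self.rows)).max() > 1:
            raise ValueError("path violates 3-neighbour connectivity")


def _as_probmap(probmap_or_labels) -> np.ndarray:
    """Accept (3, H, W) probabilities or (H, W) hard labels (-> one-hot)."""
    arr = np.asarray(probmap_or_labels)
    if arr.ndim == 2:
        return onehot_regions(arr.astype(np.int64))
    if arr.ndim == 3 and arr.shape[0] == 3:
        return arr.astype(np.float32, copy=False)
    raise ValueError("expected (3, H, W) probabilities or (H, W) labels")


def boundary_edge_map(probmap_or_labels, boundary: str) -> np.ndarray:
    """Boundary probability map for "ILM" or "RPE".

    ILM: positive part of the row-wise increase of P(class >= 1), the
    vitreous -> retina transition (identical to the rise of the retina
    probability on clean maps, and placing coincident ILM/RPE paths when
    the retina class is empty).  RPE: positive part of the row-wise
    increase of P(class = 2), the retina -> choroid transition.  Values
    are clipped to [0, 1].
    """
    probs = _as_probmap(probmap_or_labels)
    if boundary == "ILM":
        below = probs[1] + probs[2]
    elif boundary == "RPE":
        below = probs[2]
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    rise = np.diff(below, axis=0, prepend=below[:1])  # first row has no rise
    return np.clip(rise, 0.0, 1.0)


def shortest_boundary_path(edge: np.ndarray, boundary: str = "",
                           weight_form: str = "sum") -> PathResult:
    """Minimum-cost left-to-right path through a boundary probability map.

    ``weight_form``: "sum" uses ``w = 2 - (p_s + p_d)`` (non-negative,
    rewards both endpoints); "literal" uses ``w = 2 - p_s + p_d`` (kept
    for auditability -- it penalizes high-probability destinations).
    """
    p = np.asarray(edge, dtype=np.float64)
    if p.ndim != 2 or p.size == 0:
        raise ValueError("edge map must be a non-empty 2-D array")
    if not np.all(np.isfinite(p)):
        raise ValueError("edge map contains non-finite probabilities")
    H, W = p.shape
    if weight_form == "sum":
        src_term, dst_term = 1.0 - p, 1.0 - p
        exit_term = 1.0 - p[:, -1]
    elif weight_form == "literal":
        src_term, dst_term = 1.0 - p, 1.0 + p
        exit_term = 3.0 - p[:, -1]  # edge into the probability-1 dummy column
    else:
        raise ValueError("weight_form must be 'sum' or 'literal'")

    # D[r, c]: cost of the best path from the top-left dummy corner to (r, c);
    # entering from the dummy column costs src(dummy)=1-1=0 plus dst(r, 0).
    dist = dst_term[:, 0].copy()
    pred = np.zeros((H, W), dtype=np.int8)  # -1: from r-1, 0: from r, 1: from r+1
    inf = np.inf
    for c in range(1, W):
        leave = dist + src_term[:, c - 1]
        up = np.concatenate([leave[1:], [inf]])    # predecessor r+1 (diag-up)
        down = np.concatenate([[inf], leave[:-1]])  # predecessor r-1 (diag-down)
        stacked = np.stack([leave, up, down])       # tie preference order
        choice = stacked.argmin(axis=0)
        dist = stacked[choice, np.arange(H)] + dst_term[:, c]
        pred[:, c] = np.where(choice == 0, 0, np.where(choice == 1, 1, -1))

    # leave through the right dummy column
    total = dist + exit_term
    r = int(np.argmin(total))  # topmost row among ties
    cost = float(total[r])
    rows = np.empty(W, dtype=np.int64)
    rows[W - 1] = r
    for c in range(W - 1, 0, -1):
        r = r + pred[r, c]
        rows[c - 1] = r
    return PathResult(rows=rows, cost=cost, boundary=boundary)


def extract_boundaries(probmap_or_labels, pad_rows: int = PAD_ROWS_DEFAULT,
                       weight_form: str = "sum") -> BoundarySet:
    """Delineate ILM and RPE independently and remove the top padding offset.

    Predictions are defined at every column of the scan.  Rows are
    clipped so the returned BoundarySet stays inside the unpadded image
    and keeps ILM at or above the RPE.
    """
    probs = _as_probmap(probmap_or_labels)
    H = probs.shape[1]
    paths = {}
    for b in BOUNDARIES:
        edge = boundary_edge_map(probs, b)
        paths[b] = shortest_boundary_path(edge, boundary=b,
                                          weight_form=weight_form)
    ilm = np.clip(paths["ILM"].rows - pad_rows, 0, H - 1 - pad_rows)
    rpe = np.clip(paths["RPE"].rows - pad_rows, 0, H - 1 - pad_rows)
    rpe = np.maximum(ilm, rpe)
    return BoundarySet(ilm.astype(np.float64), rpe.astype(np.float64))


def build_sparse_graph(edge: np.ndarray, weight_form: str = "sum"):
    """Explicit sparse graph with dummy end columns, for cross-checking.

    Vertices are (row, col) with col in [0, W+1]; columns 0 and W+1 are
    the dummy columns (probability 1, vertically connected in both
    directions).  Returns (scipy CSR matrix, start index, end index).
    """
    from scipy.sparse import csr_matrix

    p = np.asarray(edge, dtype=np.float64)
    H, W = p.shape
    paug = np.hstack([np.ones((H, 1)), p, np.ones((H, 1))])
    Wa = W + 2

    def idx(r, c):
        return r * Wa + c

    rows_i, cols_i, w = [], [], []

    def add(r1, c1, r2, c2):
        ps, pd = paug[r1, c1], paug[r2, c2]
        if weight_form == "sum":
            wt = 2.0 - (ps + pd)
        else:
            wt = 2.0 - ps + pd
        rows_i.append(idx(r1, c1))
        cols_i.append(idx(r2, c2))
        w.append(wt)

    for c in range(Wa - 1):
        for r in range(H):
            for dr in (0, -1, 1):
                r2 = r + dr
                if 0 <= r2 < H:
                    add(r, c, r2, c + 1)
    for c in (0, Wa - 1):  # vertical edges inside dummy columns
        for r in range(H - 1):
            add(r, c, r + 1, c)
            add(r + 1, c, r, c)

    g = csr_matrix((w, (rows_i, cols_i)), shape=(H * Wa, H * Wa))
    return g, idx(0, 0), idx(H - 1, Wa - 1)
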