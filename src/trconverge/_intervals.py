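"""Low-level interval arithmetic on sorted numpy arrays.

All coordinates are 0-based half-open (BED convention). Intervals of a
"merged" target are pairwise non-overlapping and sorted by start; bookended
intervals (end == next start) are kept distinct and never treated as
overlapping, matching bedtools' strict ``-f`` overlap semantics.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping intervals on one chromosome (single linkage, >=1 bp).

    Bookended intervals are NOT merged. Returns sorted, disjoint (starts, ends).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    # running maximum of ends defines the current merged block
    run_end = np.maximum.accumulate(e)
    # a new block starts where start >= max end of everything before it
    new_block = np.empty(s.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] >= run_end[:-1]
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    out_s = s[new_block]
    out_e = np.zeros(n_blocks, dtype=np.int64)
    np.maximum.at(out_e, block_id, e)
    return out_s, out_e


def merge_labels(
    starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Like :func:`merge_intervals` but also return, for each input interval
    (in input order), the index of the merged block it belongs to."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends, np.empty(0, dtype=np.int64)
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    run_end = np.maximum.accumulate(e)
    new_block = np.empty(s.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] >= run_end[:-1]
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    out_s = s[new_block]
    out_e = np.zeros(n_blocks, dtype=np.int64)
    np.maximum.at(out_e, block_id, e)
    labels = np.empty(starts.size, dtype=np.int64)
    labels[order] = block_id
    return out_s, out_e, labels


def overlaps_any(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    t_starts: np.ndarray,
    t_ends: np.ndarray,
) -> np.ndarray:
    """Boolean per query interval: >=1 bp overlap with a *merged* target set."""
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    if t_starts.size == 0:
        return np.zeros(q_starts.size, dtype=bool)
    # first target whose end is strictly greater than the query start
    idx = np.searchsorted(t_ends, q_starts, side="right")
    hit = idx < t_starts.size
    res = np.zeros(q_starts.size, dtype=bool)
    res[hit] = t_starts[idx[hit]] < q_ends[hit]
    return res


def coverage_below(t_starts: np.ndarray, t_ends: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Total bp of a merged target set strictly below position x (vectorized)."""
    cum = np.concatenate([[0], np.cumsum(t_ends - t_starts)])
    x = np.asarray(x, dtype=np.int64)
    j = np.searchsorted(t_starts, x, side="right")  # intervals starting before x
    full = cum[np.maximum(j - 1, 0)]
    partial = np.zeros(x.shape, dtype=np.int64)
    has = j > 0
    if np.any(has):
        last_s = t_starts[j[has] - 1]
        last_e = t_ends[j[has] - 1]
        partial[has] = np.clip(np.minimum(x[has], last_e) - last_s, 0, None)
    return full + partial


def overlap_bp(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    t_starts: np.ndarray,
    t_ends: np.ndarray,
) -> np.ndarray:
    """bp of intersection of each query interval with a merged target set."""
    if t_starts.size == 0:
        return np.zeros(np.asarray(q_starts).size, dtype=np.int64)
    return coverage_below(t_starts, t_ends, q_ends) - coverage_below(
        t_starts, t_ends, q_starts
    )


def nearest_position(
    q_starts: np.ndarray, q_ends: np.ndarray, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each interval to the nearest of ``positions`` (sorted),
    plus the index of that position.

    A position p inside [start, end) gives distance 0; otherwise the distance
    is min over both edges, the end edge being end-1 (last covered base).
    Ties between an equally near left and right neighbour are broken toward
    the lower index (caller refines ties with its own rules).
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    n = positions.size
    if n == 0:
        raise ValueError("no positions to search")
    idx_right = np.searchsorted(positions, q_starts, side="left")
    # candidates: positions[idx_right-1] (left of start) and positions[idx_right:]
    best_d = np.full(q_starts.size, np.iinfo(np.int64).max)
    best_i = np.zeros(q_starts.size, dtype=np.int64)
    for shift in (-1, 0, 1):
        cand = np.clip(idx_right + shift, 0, n - 1)
        p = positions[cand]
        inside = (p >= q_starts) & (p < q_ends)
        d = np.where(
            inside, 0, np.minimum(np.abs(p - q_starts), np.abs(p - (q_ends - 1)))
        )
        better = d < best_d
        best_d[better] = d[better]
        best_i[better] = cand[better]
    return best_d, best_i
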