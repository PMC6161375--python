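"""Half-open interval arithmetic on numpy arrays.

All functions take and return ``(starts, ends)`` pairs of int arrays that
describe half-open intervals ``[start, end)`` on a single chromosome.
Inputs need not be sorted; outputs are sorted and non-overlapping.
"""

from __future__ import annotations

import numpy as np


def merge(starts: np.ndarray, ends: np.ndarray, gap: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals; intervals separated by < ``gap`` bp are also fused."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - out_e[-1] < gap or s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def intersect(
    a_starts: np.ndarray, a_ends: np.ndarray, b_starts: np.ndarray, b_ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Intersection of two interval sets (each first merged)."""
    a_starts, a_ends = merge(a_starts, a_ends)
    b_starts, b_ends = merge(b_starts, b_ends)
    out_s, out_e = [], []
    i = j = 0
    while i < len(a_starts) and j < len(b_starts):
        s = max(a_starts[i], b_starts[j])
        e = min(a_ends[i], b_ends[j])
        if s < e:
            out_s.append(s)
            out_e.append(e)
        if a_ends[i] < b_ends[j]:
            i += 1
        else:
            j += 1
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def subtract(
    a_starts: np.ndarray, a_ends: np.ndarray, b_starts: np.ndarray, b_ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Parts of A not covered by B."""
    a_starts, a_ends = merge(a_starts, a_ends)
    b_starts, b_ends = merge(b_starts, b_ends)
    out_s, out_e = [], []
    j = 0
    for s, e in zip(a_starts, a_ends):
        cur = s
        while j < len(b_starts) and b_ends[j] <= cur:
            j += 1
        k = j
        while k < len(b_starts) and b_starts[k] < e:
            if b_starts[k] > cur:
                out_s.append(cur)
                out_e.append(b_starts[k])
            cur = max(cur, b_ends[k])
            if cur >= e:
                break
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def total_bp(starts: np.ndarray, ends: np.ndarray) -> int:
    starts, ends = merge(starts, ends)
    return int(np.sum(ends - starts))


def overlap_per_interval(
    q_starts: np.ndarray, q_ends: np.ndarray, r_starts: np.ndarray, r_ends: np.ndarray
) -> np.ndarray:
    """Overlap bp of each query interval with the (merged) reference set.

    Uses the cumulative-coverage trick: overlap with [s, e) is C(e) - C(s)
    where C is the running bp covered by the reference up to a position.
    """
    r_starts, r_ends = merge(r_starts, r_ends)
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    if r_starts.size == 0:
        return np.zeros(q_starts.size, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(r_ends - r_starts)])

    def cov_at(pos: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(r_starts, pos, side="right")
        full = cum[idx]
        # subtract the part of interval idx-1 that lies beyond pos
        prev_end = np.where(idx > 0, r_ends[np.maximum(idx - 1, 0)], 0)
        trim = np.clip(prev_end - pos, 0, None)
        trim = np.where(idx > 0, np.minimum(trim, np.where(idx > 0, r_ends[np.maximum(idx - 1, 0)] - r_starts[np.maximum(idx - 1, 0)], 0)), 0)
        return full - trim

    return cov_at(q_ends) - cov_at(q_starts)
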