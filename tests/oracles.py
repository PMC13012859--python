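"""Independent brute-force reference implementations used only by tests.

Every function here enumerates pixels/pairs/runs/zones with explicit
Python loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np

DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
EIGHT = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def glcm_bruteforce(q, mask, n_levels):
    """Direction-averaged symmetric co-occurrence counts by pair enumeration."""
    h, w = q.shape
    acc = np.zeros((n_levels, n_levels))
    for dr, dc in DIRECTIONS:
        m = np.zeros((n_levels, n_levels))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    m[q[r, c] - 1, q[r2, c2] - 1] += 1
        acc += m + m.T
    return acc / len(DIRECTIONS)


def glrlm_bruteforce(q, mask, n_levels):
    """Run enumeration: walk from every run start in each direction."""
    h, w = q.shape
    runs = []
    for dr, dc in DIRECTIONS:
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    continue
                pr, pc = r - dr, c - dc
                if 0 <= pr < h and 0 <= pc < w and mask[pr, pc] and q[pr, pc] == q[r, c]:
                    continue  # not a run start
                length = 1
                nr, nc = r + dr, c + dc
                while 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and q[nr, nc] == q[r, c]:
                    length += 1
                    nr, nc = nr + dr, nc + dc
                runs.append((q[r, c], length))
    max_len = max(length for _, length in runs)
    acc = np.zeros((n_levels, max_len))
    for lev, length in runs:
        acc[lev - 1, length - 1] += 1
    return acc


def glszm_bruteforce(q, mask, n_levels):
    """Zone enumeration by breadth-first flood fill (8-connectivity)."""
    h, w = q.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            lev = q[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in EIGHT:
                    nr, nc = rr + dr, cc + dc
                    if (0 <= nr < h and 0 <= nc < w and mask[nr, nc]
                            and not seen[nr, nc] and q[nr, nc] == lev):
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            zones.append((lev, size))
    max_size = max(s for _, s in zones)
    acc = np.zeros((n_levels, max_size))
    for lev, s in zones:
        acc[lev - 1, s - 1] += 1
    return acc


def gldm_bruteforce(q, mask, n_levels, alpha=0):
    deps = []
    h, w = q.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            d = 0
            for dr, dc in EIGHT:
                nr, nc = r + dr, c + dc
                if (0 <= nr < h and 0 <= nc < w and mask[nr, nc]
                        and abs(int(q[nr, nc]) - int(q[r, c])) <= alpha):
                    d += 1
            deps.append((q[r, c], d + 1))
    max_dep = max(d for _, d in deps)
    acc = np.zeros((n_levels, max_dep))
    for lev, d in deps:
        acc[lev - 1, d - 1] += 1
    return acc


def ngtdm_bruteforce(q, mask, n_levels):
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    h, w = q.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nbrs = [q[r + dr, c + dc] for dr, dc in EIGHT
                    if 0 <= r + dr < h and 0 <= c + dc < w and mask[r + dr, c + dc]]
            if not nbrs:
                continue
            s[q[r, c] - 1] += abs(q[r, c] - sum(nbrs) / len(nbrs))
            n[q[r, c] - 1] += 1
    return s, n


def attention_bruteforce(a, bm, cm, dm, alpha):
    """Double-loop position attention: S_ji = softmax_i(B_i . C_j),
    E_j = alpha * sum_i S_ji D_i + A_j.  Inputs are (C, N) arrays."""
    c, n = a.shape
    e = np.zeros_like(a)
    for j in range(n):
        scores = np.array([bm[:, i] @ cm[:, j] for i in range(n)])
        scores = np.exp(scores - scores.max())
        s_j = scores / scores.sum()
        ctx = sum(s_j[i] * dm[:, i] for i in range(n))
        e[:, j] = alpha * ctx + a[:, j]
    return e


def hausdorff_bruteforce(mask_a, mask_b):
    """All-pairs symmetric Hausdorff distance between 4-boundary sets."""

    def boundary(m):
        h, w = m.shape
        pts = []
        for r in range(h):
            for c in range(w):
                if not m[r, c]:
                    continue
                for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                    nr, nc = r + dr, c + dc
                    if not (0 <= nr < h and 0 <= nc < w) or not m[nr, nc]:
                        pts.append((r, c))
                        break
        return pts

    pa, pb = boundary(mask_a), boundary(mask_b)

    def directed(xs, ys):
        return max(
            min(((x[0] - y[0]) ** 2 + (x[1] - y[1]) ** 2) ** 0.5 for y in ys)
            for x in xs
        )

    return max(directed(pa, pb), directed(pb, pa))


def early_stop_bruteforce(history, patience, min_delta):
    """Window-scan early stopping: stop iff none of the last ``patience``
    values beats the pre-window best by at least ``min_delta``."""
    if len(history) <= patience:
        return False
    pre_best = max(history[:len(history) - patience])
    return max(history[len(history) - patience:]) < pre_best + min_delta
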