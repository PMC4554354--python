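"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the vectorized code paths of the package: the
maxima oracle is a pure-Python flood fill per local maximum, the perimeter
oracle walks the object boundary pixel by pixel, the matching oracle
enumerates all one-to-one matchings, and the threshold oracle runs the
classic intermeans recursion directly on pixel values.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def prominence_maxima_oracle(raster, roi_mask, noise_level):
    """Set of accepted maxima (x, y, value) under the pinned contract.

    A plateau (8-connected equal-value set with no brighter in-ROI
    neighbor, and at least one lower in-ROI neighbor) is accepted iff the
    flood region reachable through in-ROI pixels of value > v - tol holds
    no pixel brighter than v.  Equal-valued plateaus sharing one region
    collapse to the representative with the smallest (y, x); a plateau's
    own representative is its pixel nearest the plateau centroid (ties by
    smallest (y, x)).
    """
    raster = np.asarray(raster)
    h, w = raster.shape
    inroi = np.asarray(roi_mask, dtype=bool)
    pix = {(y, x) for y, x in zip(*np.nonzero(inroi))}

    def nbrs(p):
        y, x = p
        for dy, dx in _NBRS:
            q = (y + dy, x + dx)
            if q in pix:
                yield q

    val = {p: int(raster[p]) for p in pix}

    # plateaus: connected components of equal value
    seen = set()
    plateaus = []
    for p in sorted(pix):
        if p in seen:
            continue
        v = val[p]
        comp = {p}
        stack = [p]
        seen.add(p)
        while stack:
            q = stack.pop()
            for r in nbrs(q):
                if r not in comp and val[r] == v:
                    comp.add(r)
                    seen.add(r)
                    stack.append(r)
        plateaus.append((v, comp))

    def representative(comp):
        ys = [p[0] for p in comp]
        xs = [p[1] for p in comp]
        cy, cx = sum(ys) / len(ys), sum(xs) / len(xs)
        return min(comp, key=lambda p: ((p[0] - cy) ** 2 + (p[1] - cx) ** 2,
                                        p[0], p[1]))

    accepted = []  # (v, rep, region_key)
    for v, comp in plateaus:
        ring = {r for p in comp for r in nbrs(p)} - comp
        if any(val[r] > v for r in ring):
            continue  # not a local maximum
        if not ring:
            continue  # plateau spans the whole ROI: no peak
        if noise_level <= 0:
            accepted.append((v, representative(comp), ("self", min(comp))))
            continue
        region = set(comp)
        stack = list(comp)
        reject = False
        while stack:
            q = stack.pop()
            for r in nbrs(q):
                if r in region or not (val[r] > v - noise_level):
                    continue
                if val[r] > v:
                    reject = True
                    stack = []
                    break
                region.add(r)
                stack.append(r)
        if not reject:
            accepted.append((v, representative(comp), (v, min(region))))

    # merge equal-valued plateaus sharing one flood region
    groups = {}
    for v, rep, key in accepted:
        groups.setdefault(key, []).append((v, rep))
    out = set()
    for members in groups.values():
        v, rep = min(members, key=lambda t: t[1])
        out.add((rep[1], rep[0], v))  # (x, y, value)
    return out


def boundary_walk_perimeter(mask):
    """Perimeter by Moore boundary tracing through pixel centers, summing
    unit and diagonal step lengths.  Valid for a single 8-connected,
    simply-connected object of more than one pixel."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    ys, xs = np.nonzero(padded)
    start = (ys.min(), xs[ys == ys.min()].min())
    # Moore neighborhood in clockwise order starting from west
    ring = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]

    def trace():
        cur = start
        backtrack = (start[0], start[1] - 1)
        path = [cur]
        while True:
            i = ring.index((backtrack[0] - cur[0], backtrack[1] - cur[1]))
            for k in range(1, 9):
                cand = ring[(i + k) % 8]
                nxt = (cur[0] + cand[0], cur[1] + cand[1])
                if padded[nxt]:
                    backtrack = (cur[0] + ring[(i + k - 1) % 8][0],
                                 cur[1] + ring[(i + k - 1) % 8][1])
                    cur = nxt
                    path.append(cur)
                    break
            else:
                return path  # isolated pixel
            if cur == start and len(path) > 2:
                return path
        return path

    path = trace()
    if len(path) < 3:
        return 4.0  # single pixel: unit square
    length = 0.0
    for a, b in zip(path, path[1:]):
        length += math.hypot(a[0] - b[0], a[1] - b[1])
    return length


def max_cardinality_matching(points1, points2, tolerance):
    """Exhaustive maximum-cardinality, then minimum-total-distance
    one-to-one matching between two small point sets (<= ~7 each)."""
    n1, n2 = len(points1), len(points2)
    if n1 > n2:
        best_n, best_d = max_cardinality_matching(points2, points1, tolerance)
        return best_n, best_d
    dist = [[math.hypot(a[0] - b[0], a[1] - b[1]) for b in points2]
            for a in points1]
    best_n, best_d = 0, 0.0
    for perm in permutations(range(n2), n1):
        n, d = 0, 0.0
        for i, j in enumerate(perm):
            if dist[i][j] <= tolerance:
                n += 1
                d += dist[i][j]
        if n > best_n or (n == best_n and (best_n == 0 or d < best_d)):
            best_n, best_d = n, d
    return best_n, best_d


def isodata_recursion(raster):
    """Classic intermeans iteration on raw pixel values: t converges to
    (mean below-or-at t + mean above t) / 2."""
    vals = np.asarray(raster, dtype=np.float64).ravel()
    t = vals.mean()
    for _ in range(500):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            return t
        tn = (lo.mean() + hi.mean()) / 2.0
        if abs(tn - t) < 0.25:
            return tn
        t = tn
    return t


def roi_stats_bruteforce(raster, ys, xs):
    """Per-pixel area/mean/min/max recomputation."""
    total, mn, mx, n = 0.0, float("inf"), float("-inf"), 0
    for y, x in zip(ys, xs):
        v = float(raster[y, x])
        total += v
        mn = min(mn, v)
        mx = max(mx, v)
        n += 1
    return n, total / n, mn, mx
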