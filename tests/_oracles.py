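"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (O(n^2) scans, exhaustive floods and
enumerations) and shares no code with the package.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def brute_nnd(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    out = np.empty(n)
    for i in range(n):
        d = np.sqrt(np.sum((pts - pts[i]) ** 2, axis=1))
        d[i] = np.inf
        out[i] = d.min()
    return out


def brute_nn_index(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    out = np.empty(n, dtype=int)
    for i in range(n):
        d = np.sqrt(np.sum((pts - pts[i]) ** 2, axis=1))
        d[i] = np.inf
        out[i] = int(np.argmin(d))
    return out


def brute_density(points: np.ndarray, r: float) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    out = np.empty(len(pts), dtype=int)
    for i in range(len(pts)):
        d = np.sqrt(np.sum((pts - pts[i]) ** 2, axis=1))
        out[i] = int(np.sum(d <= r))
    return out


def brute_local_intensity(points: np.ndarray, intensities: np.ndarray,
                          r: float) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(intensities, dtype=float)
    out = np.empty(len(pts))
    for i in range(len(pts)):
        d = np.sqrt(np.sum((pts - pts[i]) ** 2, axis=1))
        out[i] = vals[d <= r].mean()
    return out


def flood_maxima(data: np.ndarray, threshold: float,
                 noise_tolerance: float) -> list[tuple[int, int, int]]:
    """Literal prominence rule: candidates (>= all 26 in-bounds neighbours,
    > at least one, >= threshold) descending by (intensity, lex); accept iff
    the 26-connected region of voxels >= candidate - tolerance holds no
    previously accepted seed."""
    data = np.asarray(data, dtype=float)
    nz, ny, nx = data.shape
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]

    candidates = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = data[z, y, x]
                if v < threshold:
                    continue
                ge_all, gt_some = True, False
                for dz, dy, dx in offsets:
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                        if data[zz, yy, xx] > v:
                            ge_all = False
                            break
                        if data[zz, yy, xx] < v:
                            gt_some = True
                if ge_all and gt_some:
                    candidates.append((z, y, x))
    candidates.sort(key=lambda p: (-data[p], p))

    accepted: list[tuple[int, int, int]] = []
    accepted_set = set()
    for c in candidates:
        level = data[c] - noise_tolerance
        seen = {c}
        queue = deque([c])
        hit = False
        while queue and not hit:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                zz, yy, xx = z + dz, y + dy, x + dx
                if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                    p = (zz, yy, xx)
                    if p in seen or data[p] < level:
                        continue
                    if p in accepted_set:
                        hit = True
                        break
                    seen.add(p)
                    queue.append(p)
        if not hit:
            accepted.append(c)
            accepted_set.add(c)
    return accepted


def greedy_match_bruteforce(det: np.ndarray, tru: np.ndarray,
                            tolerance: float) -> list[tuple[int, int, float]]:
    """Literal greedy matching contract: all pairs within tolerance sorted by
    (distance, detected id, truth id), accepted when both endpoints free."""
    det = np.asarray(det, dtype=float)
    tru = np.asarray(tru, dtype=float)
    pairs = []
    for i in range(len(det)):
        for j in range(len(tru)):
            d = float(np.linalg.norm(det[i] - tru[j]))
            if d <= tolerance:
                pairs.append((d, i, j))
    pairs.sort()
    used_d, used_t, out = set(), set(), []
    for d, i, j in pairs:
        if i not in used_d and j not in used_t:
            used_d.add(i)
            used_t.add(j)
            out.append((i, j, d))
    return out


def max_bipartite_matching_size(dist: np.ndarray, tolerance: float) -> int:
    """Maximum-cardinality matching by exhaustive enumeration (tiny inputs)."""
    n, m = dist.shape
    edges = [(i, j) for i in range(n) for j in range(m) if dist[i, j] <= tolerance]
    best = 0
    for k in range(len(edges), 0, -1):
        if k <= best:
            break
        for combo in itertools.combinations(edges, k):
            if (len({i for i, _ in combo}) == k and len({j for _, j in combo}) == k):
                best = max(best, k)
                break
    return best


def bh_stepup(p_values, q):
    """Textbook Benjamini-Hochberg: rejection flags in input order."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    if k_star:
        reject[order[:k_star]] = True
    return reject


def bh_adjusted(p_values):
    """Textbook BH adjusted p-values (step-up with running minimum)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def mw_exact_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments
    (ties-free samples only)."""
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    combined = sorted(a + b)
    assert len(set(combined)) == n + m, "oracle requires ties-free data"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_of = lambda sample: sum(ranks[v] for v in sample) - len(sample) * (len(sample) + 1) / 2

    u_obs = u_of(a)
    mean_u = n * m / 2.0
    dev = abs(u_obs - mean_u)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = sum(i + 1 for i in combo) - n * (n + 1) / 2
        total += 1
        if abs(u - mean_u) >= dev - 1e-12:
            count += 1
    return count / total
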