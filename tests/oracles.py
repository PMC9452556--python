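"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (exhaustive
enumeration, direct definitions) rather than calling the code paths they
check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_detect(x: np.ndarray, threshold: float, frame_rate_hz: float = 1.0,
                       min_separation_s: float = 3.0, prominence_fraction: float = 0.2):
    """Enumerate every sample and apply the three event rules directly.

    Local maximum: strictly greater than both neighbours.  Topographic
    prominence: height above the higher of the two base minima, where each
    base is the minimum between the peak and the nearest strictly higher
    sample (or the signal edge).  Separation: greedy keep-largest with
    earlier-index tie-break.  Returns peak indices.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    candidates = [i for i in range(1, n - 1) if x[i - 1] < x[i] > x[i + 1]]

    def prominence(i: int) -> float:
        left = x[:i][::-1]
        higher = np.nonzero(left > x[i])[0]
        lo_l = left[: higher[0]].min() if higher.size else left.min() if left.size else x[i]
        right = x[i + 1:]
        higher = np.nonzero(right > x[i])[0]
        lo_r = right[: higher[0]].min() if higher.size else right.min() if right.size else x[i]
        return x[i] - max(lo_l, lo_r)

    kept = [
        i
        for i in candidates
        if x[i] > threshold and prominence(i) >= prominence_fraction * threshold
    ]
    min_sep = min_separation_s * frame_rate_hz
    chosen: list[int] = []
    for i in sorted(kept, key=lambda i: (-x[i], i)):
        if all(abs(i - j) >= min_sep for j in chosen):
            chosen.append(i)
    return sorted(chosen)


def brute_force_kmeans_threshold(values: np.ndarray, k: int) -> float:
    """Optimal 1-D k-means threshold by enumerating every contiguous
    partition of the sorted values (feasible for small n)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    best_sse, best_th = np.inf, None
    for cuts in combinations(range(1, n), k - 1):
        edges = (0, *cuts, n)
        sse = sum(
            float(((x[a:b] - x[a:b].mean()) ** 2).sum())
            for a, b in zip(edges[:-1], edges[1:])
        )
        if sse < best_sse - 1e-12:
            best_sse, best_th = sse, float(x[edges[-2]])
    return best_th


def dp_kmeans_threshold(values: np.ndarray, k: int) -> float:
    """Optimal 1-D k-means threshold by an independently written
    dynamic program (plain Python loops, scalar prefix sums)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    p1 = [0.0]
    p2 = [0.0]
    for v in x:
        p1.append(p1[-1] + v)
        p2.append(p2[-1] + v * v)

    def sse(i: int, j: int) -> float:  # x[i:j]
        m = j - i
        s = p1[j] - p1[i]
        return (p2[j] - p2[i]) - s * s / m

    INF = float("inf")
    D = [[INF] * (n + 1) for _ in range(k + 1)]
    back = [[0] * (n + 1) for _ in range(k + 1)]
    D[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, bi = INF, 0
            for i in range(c - 1, j):
                v = D[c - 1][i] + sse(i, j)
                if v < best - 1e-12:
                    best, bi = v, i
            D[c][j] = best
            back[c][j] = bi
    j = n
    start_last = back[k][n]
    return float(x[start_last])


def match_events(true_times, detected_times, window_s: float = 2.0):
    """Greedy 1-1 matching of detected peaks to ground-truth peak times.

    Returns (n_matched, n_true, n_detected).  Each truth matches the
    closest unused detection within the window.
    """
    used: set[int] = set()
    matched = 0
    detected_times = list(detected_times)
    for tt in true_times:
        best = None
        for j, d in enumerate(detected_times):
            if j in used or abs(d - tt) > window_s:
                continue
            if best is None or abs(d - tt) < abs(detected_times[best] - tt):
                best = j
        if best is not None:
            used.add(best)
            matched += 1
    return matched, len(list(true_times)), len(detected_times)
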