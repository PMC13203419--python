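"""Independent brute-force oracles used by unit and acceptance tests.

Written as explicit loops over grid points so they share no code path
with the vectorized implementations they check.
"""

import math


def oi_bruteforce(freqs, power, df_hz, k=0.375, wl=0.0, wh=20.0,
                  harmonic_search=0.5):
    """Organization Index by direct band summation over the grid.

    Centers: the DF, plus for each integer multiple m*DF <= wh the local
    maximum within +-harmonic_search (or the multiple itself when the
    maximum there is not a local maximum). Equal-power candidates resolve
    to the frequency closest to the exact multiple, then the lower one.
    Frequencies within k of any center (and inside [wl, wh]) contribute
    to the numerator exactly once.
    """
    tol = 1e-9
    centers = [df_hz]
    m = 2
    while m * df_hz <= wh + tol:
        target = m * df_hz
        best_i, best_key = None, None
        for i, f in enumerate(freqs):
            if abs(f - target) <= harmonic_search + tol:
                key = (-power[i], abs(f - target), f)
                if best_key is None or key < best_key:
                    best_i, best_key = i, key
        center = target
        if best_i is not None and 0 < best_i < len(freqs) - 1:
            if power[best_i] >= power[best_i - 1] and power[best_i] >= power[best_i + 1]:
                center = freqs[best_i]
        centers.append(center)
        m += 1
    num = 0.0
    den = 0.0
    for i, f in enumerate(freqs):
        if wl - tol <= f <= wh + tol:
            den += power[i]
            if any(abs(f - c) <= k + tol for c in centers):
                num += power[i]
    if den <= 0:
        return None
    return num / den


def trimmed_mean_bruteforce(values, alpha):
    """Sort, slice off floor(alpha*n) from each end, average the rest."""
    x = sorted(values)
    n = len(x)
    k = math.floor(alpha * n)
    kept = x[k : n - k]
    return sum(kept) / len(kept)


def knn_bruteforce(points, voxel_indices, query, k):
    """Exhaustive k-NN under the (distance, lexicographic index) order."""
    cands = []
    for i, p in enumerate(points):
        if i == query:
            continue
        d2 = sum((a - b) ** 2 for a, b in zip(p, points[query]))
        cands.append((d2, voxel_indices[i], i))
    cands.sort()
    return [i for _, _, i in cands[: min(k, len(cands))]]
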