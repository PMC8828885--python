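"""Independent brute-force oracles used to check the pipeline's fast paths.

Everything here is deliberately naive — direct scans, per-pixel loops,
textbook algorithm statements — and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def otsu_variance_curve(image: np.ndarray, nbins: int = 256):
    """Between-class variance of every single-threshold split of a histogram."""
    hist, edges = np.histogram(np.asarray(image).ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    variances = np.full(nbins, -np.inf)
    for i in range(1, nbins):
        w0, w1 = w[:i].sum(), w[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (w[:i] * centers[:i]).sum() / w0
        m1 = (w[i:] * centers[i:]).sum() / w1
        variances[i] = w0 * w1 * (m0 - m1) ** 2
    return variances, centers


def otsu_threshold_bruteforce(image: np.ndarray, nbins: int = 256) -> float:
    variances, centers = otsu_variance_curve(image, nbins)
    return float(centers[int(np.argmax(variances)) - 1])


def otsu_variance_at(image: np.ndarray, threshold: float, nbins: int = 256) -> float:
    """Histogram between-class variance achieved by a given threshold."""
    variances, centers = otsu_variance_curve(image, nbins)
    i = int(np.searchsorted(centers, threshold)) + 1
    return float(variances[min(i, nbins - 1)])


def multiotsu_bruteforce(image: np.ndarray, nbins: int = 256):
    """Exhaustive 2-threshold scan maximising 3-class between-class variance."""
    hist, edges = np.histogram(np.asarray(image).ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cm = np.concatenate([[0.0], np.cumsum(w * centers)])
    total_w, total_m = cw[-1], cm[-1]
    mu = total_m / total_w
    best, best_ts = -np.inf, None
    for i in range(1, nbins - 1):
        for j in range(i + 1, nbins):
            w0, w1, w2 = cw[i], cw[j] - cw[i], total_w - cw[j]
            if w0 == 0 or w1 == 0 or w2 == 0:
                continue
            m0 = cm[i] / w0
            m1 = (cm[j] - cm[i]) / w1
            m2 = (total_m - cm[j]) / w2
            v = w0 * (m0 - mu) ** 2 + w1 * (m1 - mu) ** 2 + w2 * (m2 - mu) ** 2
            if v > best:
                best, best_ts = v, (float(centers[i - 1]), float(centers[j - 1]))
    return best_ts, best


def multiotsu_variance_at(image: np.ndarray, thresholds, nbins: int = 256) -> float:
    hist, edges = np.histogram(np.asarray(image).ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    mu = (w * centers).sum() / w.sum()
    t1, t2 = thresholds
    sel0 = centers <= t1
    sel1 = (centers > t1) & (centers <= t2)
    sel2 = centers > t2
    v = 0.0
    for sel in (sel0, sel1, sel2):
        wk = w[sel].sum()
        if wk == 0:
            return -np.inf
        mk = (w[sel] * centers[sel]).sum() / wk
        v += wk * (mk - mu) ** 2
    return float(v)


def disk_pixels(radius: float) -> int:
    """Pixel count of a rasterised disk (centre distance <= radius)."""
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return int((dy * dy + dx * dx <= radius * radius).sum())


def dilate_bruteforce(mask: np.ndarray, radius: float) -> np.ndarray:
    """Dilation by explicit disk stamping at every foreground pixel."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    offs = list(zip(dy[keep], dx[keep]))
    for y, x in np.argwhere(mask):
        for oy, ox in offs:
            yy, xx = y + oy, x + ox
            if 0 <= yy < h and 0 <= xx < w:
                out[yy, xx] = True
    return out


def erode_bruteforce(mask: np.ndarray, radius: float) -> np.ndarray:
    h, w = mask.shape
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    offs = list(zip(dy[keep], dx[keep]))
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            ok = True
            for oy, ox in offs:
                yy, xx = y + oy, x + ox
                if not (0 <= yy < h and 0 <= xx < w) or not mask[yy, xx]:
                    ok = False
                    break
            out[y, x] = ok
    return out


def gaussian_convolve_bruteforce(image: np.ndarray, sigma: float) -> np.ndarray:
    """Dense separable Gaussian convolution with reflective boundary."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(image.astype(np.float64), radius, mode="symmetric")
    h, w = image.shape
    out = np.zeros((h, w))
    size = 2 * radius + 1
    for y in range(h):
        for x_ in range(w):
            block = padded[y : y + size, x_ : x_ + size]
            out[y, x_] = (block * np.outer(kernel, kernel)).sum()
    return out


def nearest_seed_bruteforce(
    nuclei: np.ndarray, allowed: np.ndarray, max_dist: float
) -> np.ndarray:
    """Nearest-nucleus expansion: per-pixel scan over all seed pixels.

    Exact integer squared distances; ties go to the lower label.
    """
    out = nuclei.astype(np.int64).copy()
    seeds = np.argwhere(nuclei > 0)
    seed_labels = nuclei[seeds[:, 0], seeds[:, 1]]
    max_d2 = max_dist * max_dist
    for y, x in np.argwhere(allowed & (nuclei == 0)):
        d2 = (seeds[:, 0] - y) ** 2 + (seeds[:, 1] - x) ** 2
        best = d2.min()
        if best <= max_d2:
            out[y, x] = seed_labels[d2 == best].min()
    return out


def features_bruteforce(labels: np.ndarray, stack_pixels: np.ndarray):
    """Per-cell area, centroid and channel means by per-pixel accumulation."""
    n = labels.max()
    results = {}
    for k in range(1, n + 1):
        ys, xs = np.where(labels == k)
        means = [float(stack_pixels[ys, xs, c].mean()) for c in range(stack_pixels.shape[2])]
        results[k] = {
            "area": len(ys),
            "centroid_x": float(xs.mean()),
            "centroid_y": float(ys.mean()),
            "means": means,
        }
    return results


def nearest_distances_bruteforce(src_xy, src_ids, tgt_xy, tgt_ids):
    """O(n*m) nearest-target scan with self-exclusion by id."""
    out = []
    for i in range(len(src_xy)):
        best, best_j = np.inf, -1
        for j in range(len(tgt_xy)):
            if tgt_ids[j] == src_ids[i]:
                continue
            d = float(np.hypot(src_xy[i, 0] - tgt_xy[j, 0], src_xy[i, 1] - tgt_xy[j, 1]))
            if d < best:
                best, best_j = d, j
        out.append((best, best_j))
    return out


def dbscan_bruteforce(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Textbook DBSCAN: neighbourhood counting and seed-set expansion.

    Returns labels with -1 for noise and clusters numbered from 0 in order
    of discovery (points processed in index order, seed sets expanded
    first-in-first-out).
    """
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbours = [set(np.nonzero(d[i] <= eps)[0]) for i in range(n)]
    core = [len(neighbours[i]) >= min_pts for i in range(n)]
    labels = np.full(n, -1, dtype=np.int64)
    visited = np.zeros(n, dtype=bool)
    cluster = -1
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        cluster += 1
        queue = [i]
        visited[i] = True
        labels[i] = cluster
        while queue:
            j = queue.pop(0)
            if not core[j]:
                continue
            for k in sorted(neighbours[j]):
                if labels[k] == -1:
                    labels[k] = cluster
                if not visited[k]:
                    visited[k] = True
                    queue.append(k)
    return labels


def overlap_typing_bruteforce(fractions: np.ndarray, minimums: np.ndarray):
    """Eligibility-then-argmax cell typing over a fraction matrix.

    Returns the winning rule index per cell, or -1 when no rule is eligible;
    ties go to the earlier rule.
    """
    n_cells, n_rules = fractions.shape
    out = np.full(n_cells, -1, dtype=np.int64)
    for i in range(n_cells):
        best, best_j = -1.0, -1
        for j in range(n_rules):
            if fractions[i, j] >= minimums[j] and fractions[i, j] > best:
                best, best_j = fractions[i, j], j
        out[i] = best_j
    return out


def ranksum_enumeration(a: np.ndarray, b: np.ndarray):
    """Exact two-sided rank-sum test by enumerating all group assignments."""
    from itertools import combinations
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    observed = ranks[:n_a].sum()
    total = 0
    as_extreme = 0
    mean_w = ranks.sum() * n_a / len(pooled)
    for combo in combinations(range(len(pooled)), n_a):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= abs(observed - mean_w) - 1e-12:
            as_extreme += 1
    return float(observed), as_extreme / total
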