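"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: thresholding criteria
are evaluated exhaustively over every candidate split of a 256-bin
histogram, and connected components are found by an explicit stack-based
flood fill.
"""

from __future__ import annotations

import numpy as np


def histogram_like_impl(gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gray = np.asarray(gray, dtype=float)
    counts, edges = np.histogram(gray.ravel(), bins=256, range=(gray.min(), gray.max()))
    return counts.astype(float), 0.5 * (edges[:-1] + edges[1:])


def otsu_criterion(counts: np.ndarray, centers: np.ndarray, k: int) -> float:
    """Between-class variance for the split low = bins 0..k, high = rest."""
    n = counts.sum()
    n0, n1 = counts[: k + 1].sum(), counts[k + 1 :].sum()
    if n0 == 0 or n1 == 0:
        return -np.inf
    mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / n0
    mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / n1
    return (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2


def brute_force_otsu(gray: np.ndarray) -> float:
    counts, centers = histogram_like_impl(gray)
    crits = [otsu_criterion(counts, centers, k) for k in range(256)]
    return float(centers[int(np.argmax(crits))])


def isodata_is_fixed_point(gray: np.ndarray, t: float, tol: float = 1e-6) -> bool:
    """Mean-of-means fixed-point check, evaluated from raw pixels."""
    g = np.asarray(gray, dtype=float).ravel()
    low, high = g[g <= t], g[g > t]
    if low.size == 0 or high.size == 0:
        return False
    return abs(t - 0.5 * (low.mean() + high.mean())) <= tol


def brute_force_mean(gray: np.ndarray) -> float:
    counts, centers = histogram_like_impl(gray)
    return float((counts * centers).sum() / counts.sum())


def triangle_criterion(counts: np.ndarray, k: int, p: int, end: int) -> float:
    """Perpendicular distance of histogram point k to the peak-tail chord.

    Heights normalized by the peak count and positions by the tail length,
    distance computed via the 2D cross-product formula.
    """
    h = counts / counts.max()
    lo, hi = (p, end) if end > p else (end, p)
    if not (lo <= k <= hi) or p == end:
        return -np.inf
    a = np.array([0.0, h[p]])
    b = np.array([1.0, h[end]])
    q = np.array([(k - p) / (end - p), h[k]])
    ab, aq = b - a, q - a
    return float(abs(ab[0] * aq[1] - ab[1] * aq[0]) / np.linalg.norm(ab))


def brute_force_triangle(gray: np.ndarray) -> float:
    counts, centers = histogram_like_impl(gray)
    nz = np.nonzero(counts)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    p = int(np.argmax(counts))
    end = lo if (p - lo) > (hi - p) else hi
    crits = [triangle_criterion(counts, k, p, end) for k in range(256)]
    return float(centers[int(np.argmax(crits))])


def yen_criterion(counts: np.ndarray, k: int) -> float:
    p = counts / counts.sum()
    w = p[: k + 1].sum()
    lowsq = (p[: k + 1] ** 2).sum()
    highsq = (p[k + 1 :] ** 2).sum()
    if w <= 0 or w >= 1 or lowsq <= 0 or highsq <= 0:
        return -np.inf
    return float(-np.log(lowsq * highsq) + 2.0 * np.log(w * (1.0 - w)))


def brute_force_yen(gray: np.ndarray) -> float:
    counts, centers = histogram_like_impl(gray)
    crits = [yen_criterion(counts, k) for k in range(256)]
    return float(centers[int(np.argmax(crits))])


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """Stack-based flood fill; returns the pixel set of each component."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    seen = np.zeros_like(mask)
    components = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                comp = set()
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr, dc in offsets:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                components.append(comp)
    return components


def component_summary(components: list[set[tuple[int, int]]]) -> list[tuple[int, float, float]]:
    """(area, centroid_x, centroid_y) per component, sorted for comparison."""
    out = []
    for comp in components:
        rc = np.asarray(sorted(comp), dtype=float)
        out.append((len(comp), float(rc[:, 1].mean()), float(rc[:, 0].mean())))
    return sorted(out)
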