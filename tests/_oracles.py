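"""Independent brute-force oracles for the segmentation primitives.

Everything here is written as plain set/loop arithmetic, deliberately
avoiding the code paths (separable convolution, scipy.ndimage, cumsum
algebra) used by the implementation, so the two can be compared
bit-exactly on small images.
"""

from __future__ import annotations

from collections import deque

import numpy as np

CROSS_OFFSETS = [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]
N4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
N8 = N4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def gaussian_window_kernel(window: int, sigma: float) -> np.ndarray:
    half = window // 2
    k = np.empty((window, window))
    for i in range(window):
        for j in range(window):
            k[i, j] = np.exp(-((i - half) ** 2 + (j - half) ** 2) / (2 * sigma**2))
    return k / k.sum()


def adaptive_mask_oracle(img: np.ndarray, window: int, offset_c: float,
                         sigma: float) -> np.ndarray:
    """Per-pixel windowed weighted mean on an edge-replicated pad."""
    half = window // 2
    pad = np.pad(np.asarray(img, float), half, mode="edge")
    kern = gaussian_window_kernel(window, sigma)
    h, w = img.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            win = pad[i:i + window, j:j + window]
            out[i, j] = img[i, j] > float((win * kern).sum()) - offset_c
    return out


def otsu_oracle(img: np.ndarray) -> tuple[np.ndarray, int]:
    """Exhaustive search of the 256 candidate thresholds."""
    q = np.clip(np.round(np.asarray(img, float)), 0, 255).astype(int).ravel()
    best_t, best_v = 0, -1.0
    n = q.size
    for t in range(256):
        lo = q[q <= t]
        hi = q[q > t]
        if lo.size == 0 or hi.size == 0:
            v = 0.0
        else:
            w0, w1 = lo.size / n, hi.size / n
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return np.asarray(img, float) > best_t, best_t


def erode_oracle(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    out = np.asarray(mask, bool).copy()
    h, w = out.shape
    for _ in range(iterations):
        nxt = np.zeros_like(out)
        for i in range(h):
            for j in range(w):
                nxt[i, j] = all(
                    0 <= i + di < h and 0 <= j + dj < w and out[i + di, j + dj]
                    for di, dj in CROSS_OFFSETS
                )
        out = nxt
    return out


def dilate_oracle(mask: np.ndarray) -> np.ndarray:
    out = np.asarray(mask, bool)
    h, w = out.shape
    nxt = np.zeros_like(out)
    for i in range(h):
        for j in range(w):
            nxt[i, j] = any(
                0 <= i + di < h and 0 <= j + dj < w and out[i + di, j + dj]
                for di, dj in CROSS_OFFSETS
            )
    return nxt


def open_oracle(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    out = np.asarray(mask, bool).copy()
    for _ in range(iterations):
        out = dilate_oracle(erode_oracle(out))
    return out


def _flood(mask: np.ndarray, seeds: list[tuple[int, int]],
           neighbours: list[tuple[int, int]]) -> np.ndarray:
    """Pixels of ``mask`` reachable from ``seeds`` (which must lie in mask)."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    dq = deque(s for s in seeds if mask[s])
    for s in dq:
        seen[s] = True
    while dq:
        i, j = dq.popleft()
        for di, dj in neighbours:
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] and not seen[ni, nj]:
                seen[ni, nj] = True
                dq.append((ni, nj))
    return seen


def _border_pixels(shape: tuple[int, int]) -> list[tuple[int, int]]:
    h, w = shape
    out = [(0, j) for j in range(w)] + [(h - 1, j) for j in range(w)]
    out += [(i, 0) for i in range(h)] + [(i, w - 1) for i in range(h)]
    return out


def clear_border_oracle(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    mask = np.asarray(mask, bool)
    nb = N8 if connectivity == 8 else N4
    touching = _flood(mask, _border_pixels(mask.shape), nb)
    return mask & ~touching


def fill_holes_oracle(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    mask = np.asarray(mask, bool)
    nb = N4 if connectivity == 8 else N8  # complementary connectivity
    outside = _flood(~mask, _border_pixels(mask.shape), nb)
    return mask | (~mask & ~outside)


def reconstruct_oracle(marker: np.ndarray, reference: np.ndarray,
                       connectivity: int = 8) -> np.ndarray:
    marker = np.asarray(marker, bool) & np.asarray(reference, bool)
    nb = N8 if connectivity == 8 else N4
    seeds = [tuple(p) for p in np.argwhere(marker)]
    return _flood(np.asarray(reference, bool), seeds, nb)
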