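"""Independent brute-force reference implementations.

Every oracle here is a direct loop transcription of the defining formula,
kept deliberately separate from the vectorized/library-backed paths in the
package so that agreement between the two is a meaningful check.
"""

from __future__ import annotations

import numpy as np


def local_stats_loops(img: np.ndarray, n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood mean/variance by explicit summation with zero padding."""
    h, w = img.shape
    mu = np.zeros((h, w))
    var = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            s = 0.0
            s2 = 0.0
            for dy in range(-(n // 2), n // 2 + 1):
                for dx in range(-(m // 2), m // 2 + 1):
                    yy, xx = y + dy, x + dx
                    v = img[yy, xx] if 0 <= yy < h and 0 <= xx < w else 0.0
                    s += v
                    s2 += v * v
            mu[y, x] = s / (n * m)
            var[y, x] = max(s2 / (n * m) - mu[y, x] ** 2, 0.0)
    return mu, var


def wiener_loops(img: np.ndarray, n: int, m: int, nu2: float) -> np.ndarray:
    """Per-pixel Wiener estimate b = mu + max(var - nu2, 0)/var * (a - mu)."""
    mu, var = local_stats_loops(img, n, m)
    out = np.zeros_like(img, dtype=float)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            if var[y, x] <= 1e-12:
                out[y, x] = mu[y, x]
            else:
                gain = max(var[y, x] - nu2, 0.0) / var[y, x]
                out[y, x] = mu[y, x] + gain * (img[y, x] - mu[y, x])
    return out


def se_probe_loops(f: np.ndarray, s: np.ndarray, origin: tuple[int, int],
                   y: int, x: int) -> int:
    """Coincident 1-count of a structuring element placed with origin at (y, x)."""
    h, w = f.shape
    oy, ox = origin
    total = 0
    for j in range(s.shape[0]):
        for k in range(s.shape[1]):
            if not s[j, k]:
                continue
            yy, xx = y + j - oy, x + k - ox
            if 0 <= yy < h and 0 <= xx < w:
                total += int(f[yy, xx])
    return total


def erode_loops(f: np.ndarray, s: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    need = int(s.sum())
    out = np.zeros_like(f)
    for y in range(f.shape[0]):
        for x in range(f.shape[1]):
            out[y, x] = 1 if se_probe_loops(f, s, origin, y, x) == need else 0
    return out


def dilate_loops(f: np.ndarray, s: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    out = np.zeros_like(f)
    for y in range(f.shape[0]):
        for x in range(f.shape[1]):
            out[y, x] = 1 if se_probe_loops(f, s, origin, y, x) > 0 else 0
    return out


def adaptive_threshold_loops(img: np.ndarray, window: int, c: float,
                             plus: bool = False) -> np.ndarray:
    mu, _ = local_stats_loops(img, window, window)
    t = mu + c if plus else mu - c
    return (img > t).astype(np.uint8)


def conv_loops(x: np.ndarray, kernels: np.ndarray, stride: int = 1,
               pad: int = 0) -> np.ndarray:
    """Quadruple-loop valid cross-correlation; x is H x W x D."""
    h, w, d = x.shape
    kh, kw, din, dout = kernels.shape
    assert din == d
    xp = np.zeros((h + 2 * pad, w + 2 * pad, d))
    xp[pad:pad + h, pad:pad + w] = x
    h3 = (h + 2 * pad - kh) // stride + 1
    w3 = (w + 2 * pad - kw) // stride + 1
    out = np.zeros((h3, w3, dout))
    for o in range(dout):
        for y in range(h3):
            for x2 in range(w3):
                acc = 0.0
                for j in range(kh):
                    for k in range(kw):
                        for dd in range(d):
                            acc += xp[y * stride + j, x2 * stride + k, dd] \
                                * kernels[j, k, dd, o]
                out[y, x2, o] = acc
    return out


def maxpool_loops(x: np.ndarray, window: int = 2) -> np.ndarray:
    h, w, d = x.shape
    out = np.zeros((h // window, w // window, d))
    for c in range(d):
        for y in range(h // window):
            for x2 in range(w // window):
                out[y, x2, c] = x[y * window:(y + 1) * window,
                                  x2 * window:(x2 + 1) * window, c].max()
    return out


def ellipse_pixel_count(cy: float, cx: float, a: float, b: float,
                        h: int, w: int) -> int:
    """Count grid pixels inside ((y-cy)/a)^2 + ((x-cx)/b)^2 <= 1 by loops."""
    n = 0
    for y in range(h):
        for x in range(w):
            if ((y - cy) / a) ** 2 + ((x - cx) / b) ** 2 <= 1.0:
                n += 1
    return n
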