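"""Independent brute-force oracles used to check the vectorized operations.

Everything here is written as plain Python loops, deliberately sharing no
code with the package implementations.
"""

import math

import numpy as np


def mse_loop(a, b):
    total = 0.0
    h, w, c = a.shape
    for i in range(h):
        for j in range(w):
            for k in range(c):
                d = float(a[i, j, k]) - float(b[i, j, k])
                total += d * d
    return total / (h * w * c)


def psnr_from_mse(mse):
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(255.0**2 / mse)


def luma_mean_loop(img):
    h, w, _ = img.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            r, g, b = (float(v) for v in img[i, j])
            total += 0.299 * r + 0.587 * g + 0.114 * b
    return total / (h * w)


def median_filter_loop(img, side):
    """Per-channel sorted median with edge-replicating (reflect) padding."""
    pad = side // 2
    padded = np.pad(img, ((pad, pad), (pad, pad), (0, 0)), mode="symmetric")
    h, w, c = img.shape
    out = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            for k in range(c):
                window = sorted(
                    int(padded[i + di, j + dj, k])
                    for di in range(side)
                    for dj in range(side)
                )
                out[i, j, k] = window[len(window) // 2]
    return out


def masked_mean_luma_loop(img, mask):
    total = 0.0
    count = 0
    h, w, _ = img.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                r, g, b = (float(v) for v in img[i, j])
                total += 0.299 * r + 0.587 * g + 0.114 * b
                count += 1
    return total / count
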