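"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's vectorized code paths: moments are
plain python sums and the co-occurrence matrix is an explicit loop over all
pixel pairs.
"""

import math

import numpy as np


def naive_moments(values):
    """Sum-based mean / skewness / non-excess kurtosis."""
    v = [float(x) for x in values]
    n = len(v)
    mean = sum(v) / n
    m2 = sum((x - mean) ** 2 for x in v) / n
    if m2 < 1e-12:
        return mean, 0.0, 3.0
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    return mean, m3 / m2**1.5, m4 / m2**2


def brute_force_glcm(gray, mask, Ng, offset=(0, 1), symmetric=True):
    """Pair enumeration over every pixel; both orders when symmetric."""
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    h, w = gray.shape
    dr, dc = offset
    counts = np.zeros((Ng, Ng))
    total = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i = min(int(gray[r, c] * Ng // 256), Ng - 1)
                j = min(int(gray[r2, c2] * Ng // 256), Ng - 1)
                counts[i, j] += 1
                total += 1
                if symmetric:
                    counts[j, i] += 1
                    total += 1
    if total == 0:
        return None
    return counts / total


def brute_force_glcm_metrics(p, gray_roi):
    """Closed-form metric sums written as explicit loops."""
    Ng = p.shape[0]
    contrast = sum(
        (i - j) ** 2 * p[i, j] for i in range(Ng) for j in range(Ng)
    )
    pi = [sum(p[i, j] for j in range(Ng)) for i in range(Ng)]
    pj = [sum(p[i, j] for i in range(Ng)) for j in range(Ng)]
    mu_i = sum(i * pi[i] for i in range(Ng))
    mu_j = sum(j * pj[j] for j in range(Ng))
    sd_i = math.sqrt(sum((i - mu_i) ** 2 * pi[i] for i in range(Ng)))
    sd_j = math.sqrt(sum((j - mu_j) ** 2 * pj[j] for j in range(Ng)))
    if sd_i * sd_j < 1e-12:
        corr = 1.0
    else:
        corr = sum(
            (i - mu_i) * (j - mu_j) * p[i, j]
            for i in range(Ng)
            for j in range(Ng)
        ) / (sd_i * sd_j)
    energy = sum(p[i, j] ** 2 for i in range(Ng) for j in range(Ng))
    homog = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(Ng) for j in range(Ng)
    )
    entropy = -sum(
        p[i, j] * math.log2(p[i, j])
        for i in range(Ng)
        for j in range(Ng)
        if p[i, j] > 0
    )
    intensity = float(np.mean(gray_roi))
    return contrast, corr, energy, homog, entropy, intensity
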