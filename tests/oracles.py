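"""Independent brute-force reference implementations used only by tests.

These follow the textbook definition formulas with explicit Python loops and
are deliberately written without reference to the package's optimised code.
"""

import math

import numpy as np


def moments_oracle(x):
    """(mean, population variance, skewness g1) by direct summation."""
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    skew = m3 / m2**1.5 if m2 > 0 else float("nan")
    return mean, m2, skew


def cov_corr_oracle(x, y):
    """(population covariance, correlation) by direct summation."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    corr = cov / math.sqrt(vx * vy) if vx > 0 and vy > 0 else float("nan")
    return cov, corr


def vi_oracle(blue, green, red, rededge, nir, nir2, L=0.5, gamma=1.0):
    """All nine vegetation indices for one pixel, straight from the formulas."""

    def div(a, b):
        return a / b if b != 0 else float("nan")

    rrb = red - gamma * (blue - red)
    disc = (2 * nir + 1) ** 2 - 8 * (nir - red)
    return {
        "ndvi": div(nir - red, nir + red),
        "gndvi": div(nir - green, nir + green),
        "evi": div(2.5 * (nir - red), nir + 6 * red - 7.5 * blue + 1),
        "tcari": 3 * ((rededge - red) - 0.2 * (rededge - green) * div(rededge, red)),
        "simple_ratio": div(nir, red),
        "sarvi": div((1 + L) * (nir - rrb), nir + rrb + L),
        "savi": div((1 + L) * (nir - red), nir + red + L),
        "msavi2": (2 * nir + 1 - math.sqrt(disc)) / 2 if disc >= 0 else float("nan"),
        "ndvi_nir2": div(nir2 - red, nir2 + red),
    }


_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_oracle(levels, G, angle_deg, distance=1, symmetric=True):
    """Co-occurrence counts by looping over every pixel pair."""
    levels = np.asarray(levels)
    h, w = levels.shape
    dr, dc = _OFFSETS[angle_deg]
    dr, dc = dr * distance, dc * distance
    P = np.zeros((G, G))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and levels[r, c] >= 0 and levels[r2, c2] >= 0:
                P[levels[r, c], levels[r2, c2]] += 1
    if symmetric:
        P = P + P.T
    return P / P.sum() if P.sum() else P


def haralick_oracle(P):
    """The thirteen descriptors by explicit double loops (0-based, log2)."""
    P = np.asarray(P, dtype=float)
    G = P.shape[0]
    px = [sum(P[i, j] for j in range(G)) for i in range(G)]
    py = [sum(P[i, j] for i in range(G)) for j in range(G)]
    mu_x = sum(i * px[i] for i in range(G))
    mu_y = sum(j * py[j] for j in range(G))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(G))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(G))

    f_asm = sum(P[i, j] ** 2 for i in range(G) for j in range(G))
    f_contrast = sum((i - j) ** 2 * P[i, j] for i in range(G) for j in range(G))
    if var_x > 0 and var_y > 0:
        f_corr = (
            sum(i * j * P[i, j] for i in range(G) for j in range(G)) - mu_x * mu_y
        ) / math.sqrt(var_x * var_y)
    else:
        f_corr = float("nan")
    f_var = sum((i - mu_x) ** 2 * P[i, j] for i in range(G) for j in range(G))
    f_hom = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G))

    p_sum = [0.0] * (2 * G - 1)
    p_diff = [0.0] * G
    for i in range(G):
        for j in range(G):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]
    f_sum_avg = sum(k * p_sum[k] for k in range(2 * G - 1))
    f_sum_var = sum((k - f_sum_avg) ** 2 * p_sum[k] for k in range(2 * G - 1))

    def ent(ps):
        return -sum(p * math.log2(p) for p in ps if p > 0)

    f_sum_entropy = ent(p_sum)
    f_entropy = ent(P.ravel())
    mu_d = sum(k * p_diff[k] for k in range(G))
    f_diff_var = sum((k - mu_d) ** 2 * p_diff[k] for k in range(G))
    f_diff_entropy = ent(p_diff)

    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * py[j])
        for i in range(G)
        for j in range(G)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    denom = max(hx, hy)
    f_imc = (f_entropy - hxy1) / denom if denom > 0 else float("nan")

    rows = [i for i in range(G) if px[i] > 0]
    cols = [j for j in range(G) if py[j] > 0]
    if len(rows) >= 2 and len(cols) >= 2:
        Q = np.zeros((len(rows), len(rows)))
        for a, i in enumerate(rows):
            for b, j in enumerate(rows):
                Q[a, b] = sum(
                    P[i, k] * P[j, k] / (px[i] * py[k]) for k in cols
                )
        ev = sorted(np.real(np.linalg.eigvals(Q)))
        f_mcc = math.sqrt(max(0.0, min(1.0, ev[-2])))
    else:
        f_mcc = float("nan")

    return {
        "f_asm": f_asm,
        "f_contrast": f_contrast,
        "f_correlation": f_corr,
        "f_variance": f_var,
        "f_homogeneity": f_hom,
        "f_sum_avg": f_sum_avg,
        "f_sum_var": f_sum_var,
        "f_sum_entropy": f_sum_entropy,
        "f_entropy": f_entropy,
        "f_diff_var": f_diff_var,
        "f_diff_entropy": f_diff_entropy,
        "f_imc": f_imc,
        "f_max_corr_coeff": f_mcc,
    }


def control_stats_oracle(scene_pts, control_pts):
    """Table-style residual statistics by definition formulas."""
    dx = [s[0] - c[0] for s, c in zip(scene_pts, control_pts)]
    dy = [s[1] - c[1] for s, c in zip(scene_pts, control_pts)]
    n = len(dx)

    def mean(v):
        return sum(v) / n

    def sd(v):
        m = mean(v)
        return math.sqrt(sum((x - m) ** 2 for x in v) / n)

    adx, ady = [abs(v) for v in dx], [abs(v) for v in dy]
    return {
        "mean_abs_x": mean(adx),
        "sd_abs_x": sd(adx),
        "mean_abs_y": mean(ady),
        "sd_abs_y": sd(ady),
        "min_x": min(dx),
        "max_x": max(dx),
        "min_y": min(dy),
        "max_y": max(dy),
        "rmse_x": math.sqrt(mean([v**2 for v in dx])),
        "rmse_y": math.sqrt(mean([v**2 for v in dy])),
    }
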