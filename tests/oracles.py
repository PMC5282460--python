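"""Independent brute-force oracles used by the test suite.

These transcribe the definitions literally (explicit loops over voxel pairs
and matrix entries) and deliberately share no code with the package
implementations they check.
"""

import numpy as np


def brute_force_glcm(levels, mask, dx, dy, dz, n_levels):
    """Count in-mask level pairs by looping over every voxel pair."""
    nb, h, w = levels.shape
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for z in range(nb):
        for y in range(h):
            for x in range(w):
                z2, y2, x2 = z + dz, y + dy, x + dx
                if not (0 <= z2 < nb and 0 <= y2 < h and 0 <= x2 < w):
                    continue
                if mask[y, x] and mask[y2, x2]:
                    counts[levels[z, y, x], levels[z2, y2, x2]] += 1
    return counts


def literal_haralick(p):
    """The 12 texture functions transcribed term by term (1-based levels).

    Contrast (f4) is evaluated through its n-sum form and the inverse
    difference moment (f12) independently of homogeneity, so the pairwise
    formula identities are genuinely tested, not assumed.
    """
    ng = p.shape[0]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sigma_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)) ** 0.5
    sigma_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)) ** 0.5

    f1 = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    f2 = -sum(
        p[i][j] * np.log(p[i][j])
        for i in range(ng)
        for j in range(ng)
        if p[i][j] > 0
    )
    if sigma_x == 0 or sigma_y == 0:
        f3 = 0.0
    else:
        f3 = (
            sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
            - mu_x * mu_y
        ) / (sigma_x * sigma_y)
    f4 = sum(
        n**2 * sum(
            p[i][j]
            for i in range(ng)
            for j in range(ng)
            if abs((i + 1) - (j + 1)) == n
        )
        for n in range(ng)
    )
    f5 = sum(
        p[i][j] / (1 + ((i + 1) - (j + 1)) ** 2) for i in range(ng) for j in range(ng)
    )
    f6 = sum(
        (i + 1 - mu_x) ** 2 * p[i][j] + (j + 1 - mu_y) ** 2 * p[i][j]
        for i in range(ng)
        for j in range(ng)
    )
    f7 = sum(
        n * sum(
            p[i][j]
            for i in range(ng)
            for j in range(ng)
            if (i + 1) + (j + 1) == n
        )
        for n in range(2, 2 * ng + 1)
    )
    f8 = sum(
        ((i + 1) - (j + 1)) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
    )
    f9 = sum(
        ((i + 1) + (j + 1) - mu_x - mu_y) ** 3 * p[i][j]
        for i in range(ng)
        for j in range(ng)
    )
    f10 = sum(
        ((i + 1) + (j + 1) - mu_x - mu_y) ** 2 * p[i][j]
        for i in range(ng)
        for j in range(ng)
    )
    f11 = max(p[i][j] for i in range(ng) for j in range(ng))
    f12 = sum(
        p[i][j] / (1 + ((i + 1) - (j + 1)) ** 2) for i in range(ng) for j in range(ng)
    )
    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12])


def anova_f_pvalue(groups):
    """One-way fixed-effects ANOVA from first principles (scalar feature)."""
    from scipy.stats import f as f_dist

    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    k = len(groups)
    n = len(all_vals)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    f_stat = ms_between / ms_within
    return f_stat, float(f_dist.sf(f_stat, k - 1, n - k))
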