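"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain triple loops over voxels, deliberately
ignoring the vectorised code paths in the package, so that agreement between
the two routes is meaningful.  Only usable on small ROIs.
"""

import numpy as np

DIRECTIONS_13 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]


def naive_dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = 0
    na = nb = 0
    for idx in np.ndindex(a.shape):
        if a[idx]:
            na += 1
        if b[idx]:
            nb += 1
        if a[idx] and b[idx]:
            inter += 1
    if na + nb == 0:
        return 1.0
    return 2 * inter / (na + nb)


def _surface_points(mask: np.ndarray, spacing) -> list:
    pts = []
    padded = np.pad(mask, 1)
    for idx in np.ndindex(mask.shape):
        if not mask[idx]:
            continue
        z, y, x = idx
        exposed = False
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            if not padded[z + 1 + dz, y + 1 + dy, x + 1 + dx]:
                exposed = True
        if exposed:
            pts.append((z * spacing[0], y * spacing[1], x * spacing[2]))
    return pts


def naive_hausdorff(a: np.ndarray, b: np.ndarray, spacing=(1, 1, 1)) -> float:
    pa = _surface_points(a, spacing)
    pb = _surface_points(b, spacing)
    def directed(p, q):
        worst = 0.0
        for x in p:
            best = min(sum((xi - yi) ** 2 for xi, yi in zip(x, y)) ** 0.5
                       for y in q)
            worst = max(worst, best)
        return worst
    return max(directed(pa, pb), directed(pb, pa))


def naive_auc(scores, labels) -> float:
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_icc_1_1(m: np.ndarray) -> float:
    n, k = m.shape
    grand = m.mean()
    row_means = [m[i].mean() for i in range(n)]
    ss_r = sum(k * (rm - grand) ** 2 for rm in row_means)
    ss_w = sum((m[i, j] - row_means[i]) ** 2
               for i in range(n) for j in range(k))
    ms_r = ss_r / (n - 1)
    ms_w = ss_w / (n * (k - 1))
    return (ms_r - ms_w) / (ms_r + (k - 1) * ms_w)


# ---------------------------------------------------------------------------
# texture matrices, naive route

def naive_glcm(binned, roi, n_levels, direction):
    p = np.zeros((n_levels, n_levels))
    shape = roi.shape
    for idx in np.ndindex(shape):
        if not roi[idx]:
            continue
        nb = tuple(i + d for i, d in zip(idx, direction))
        if all(0 <= c < s for c, s in zip(nb, shape)) and roi[nb]:
            p[binned[idx] - 1, binned[nb] - 1] += 1
            p[binned[nb] - 1, binned[idx] - 1] += 1
    return p


def naive_glcm_features(binned, roi, n_levels):
    feats = {}
    per_dir = []
    for d in DIRECTIONS_13:
        p = naive_glcm(binned, roi, n_levels, d)
        if p.sum() == 0:
            continue
        p = p / p.sum()
        i = np.arange(1, n_levels + 1)
        px = p.sum(axis=1)
        mu = (i * px).sum()
        sig = np.sqrt(((i - mu) ** 2 * px).sum())
        f = {}
        f["joint_energy"] = (p ** 2).sum()
        f["contrast"] = sum((a - b) ** 2 * p[a - 1, b - 1]
                            for a in i for b in i)
        num = sum((a - mu) * (b - mu) * p[a - 1, b - 1] for a in i for b in i)
        f["correlation"] = num / sig ** 2 if sig > 0 else 1.0
        f["joint_entropy"] = -sum(v * np.log2(v) for v in p.ravel() if v > 0)
        f["inverse_difference"] = sum(p[a - 1, b - 1] / (1 + abs(a - b))
                                      for a in i for b in i)
        f["inverse_difference_moment"] = sum(
            p[a - 1, b - 1] / (1 + (a - b) ** 2) for a in i for b in i)
        f["dissimilarity"] = sum(abs(a - b) * p[a - 1, b - 1]
                                 for a in i for b in i)
        f["sum_average"] = sum((a + b) * p[a - 1, b - 1] for a in i for b in i)
        f["cluster_tendency"] = sum(((a - mu) + (b - mu)) ** 2 * p[a - 1, b - 1]
                                    for a in i for b in i)
        f["maximum_probability"] = p.max()
        per_dir.append(f)
    for key in per_dir[0]:
        feats[key] = float(np.mean([f[key] for f in per_dir]))
    return feats


def naive_glrlm(binned, roi, n_levels, direction):
    runs = []
    shape = roi.shape
    d = direction
    for idx in np.ndindex(shape):
        if not roi[idx]:
            continue
        prev = tuple(i - s for i, s in zip(idx, d))
        inside = all(0 <= c < s for c, s in zip(prev, shape))
        if inside and roi[prev] and binned[prev] == binned[idx]:
            continue
        level = binned[idx]
        length = 1
        nxt = tuple(i + s for i, s in zip(idx, d))
        while (all(0 <= c < s for c, s in zip(nxt, shape)) and roi[nxt]
               and binned[nxt] == level):
            length += 1
            nxt = tuple(i + s for i, s in zip(nxt, d))
        runs.append((level, length))
    max_len = max(l for _, l in runs)
    p = np.zeros((n_levels, max_len))
    for level, length in runs:
        p[level - 1, length - 1] += 1
    return p


def naive_glszm(binned, roi, n_levels):
    # flood fill with 26-connectivity, pure python
    visited = np.zeros(roi.shape, dtype=bool)
    zones = []
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    for idx in np.ndindex(roi.shape):
        if not roi[idx] or visited[idx]:
            continue
        level = binned[idx]
        stack = [idx]
        visited[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if not all(0 <= c < s for c, s in zip(nb, roi.shape)):
                    continue
                if roi[nb] and not visited[nb] and binned[nb] == level:
                    visited[nb] = True
                    stack.append(nb)
        zones.append((level, size))
    max_size = max(s for _, s in zones)
    p = np.zeros((n_levels, max_size))
    for level, size in zones:
        p[level - 1, size - 1] += 1
    return p


def naive_rl_features(p, n_voxels, names):
    n_runs = p.sum()
    n_lev, n_len = p.shape
    i = np.arange(1, n_lev + 1)
    l = np.arange(1, n_len + 1)
    pn = p / n_runs
    p_i = p.sum(axis=1)
    p_l = p.sum(axis=0)
    mu_i = sum(ii * p_i[ii - 1] for ii in i) / n_runs
    mu_l = sum(ll * p_l[ll - 1] for ll in l) / n_runs
    vals = {
        "sre": sum(p[a - 1, b - 1] / b ** 2 for a in i for b in l) / n_runs,
        "lre": sum(p[a - 1, b - 1] * b ** 2 for a in i for b in l) / n_runs,
        "gln": sum(v ** 2 for v in p_i) / n_runs,
        "glnn": sum(v ** 2 for v in p_i) / n_runs ** 2,
        "rln": sum(v ** 2 for v in p_l) / n_runs,
        "rlnn": sum(v ** 2 for v in p_l) / n_runs ** 2,
        "rp": n_runs / n_voxels,
        "glv": sum(pn[a - 1, b - 1] * (a - mu_i) ** 2 for a in i for b in l),
        "rv": sum(pn[a - 1, b - 1] * (b - mu_l) ** 2 for a in i for b in l),
        "re": -sum(v * np.log2(v) for v in pn.ravel() if v > 0),
        "lglre": sum(p[a - 1, b - 1] / a ** 2 for a in i for b in l) / n_runs,
        "hglre": sum(p[a - 1, b - 1] * a ** 2 for a in i for b in l) / n_runs,
        "srlgle": sum(p[a - 1, b - 1] / (a ** 2 * b ** 2)
                      for a in i for b in l) / n_runs,
        "srhgle": sum(p[a - 1, b - 1] * a ** 2 / b ** 2
                      for a in i for b in l) / n_runs,
        "lrlgle": sum(p[a - 1, b - 1] * b ** 2 / a ** 2
                      for a in i for b in l) / n_runs,
        "lrhgle": sum(p[a - 1, b - 1] * a ** 2 * b ** 2
                      for a in i for b in l) / n_runs,
    }
    return {names[k]: float(v) for k, v in vals.items()}


def naive_glrlm_features(binned, roi, n_levels, names):
    n_vox = int(roi.sum())
    per_dir = [naive_rl_features(naive_glrlm(binned, roi, n_levels, d),
                                 n_vox, names) for d in DIRECTIONS_13]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def naive_glszm_features(binned, roi, n_levels, names):
    return naive_rl_features(naive_glszm(binned, roi, n_levels),
                             int(roi.sum()), names)
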