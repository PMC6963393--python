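"""Independent brute-force reference implementations used only by the tests.

Everything here is deliberately naive (explicit loops, BFS flood fill,
textbook sums of squares) so that it shares no code path with the package.
"""

from collections import deque

import numpy as np


def ellipsoid_voxel_count(grid_shape, spacing, center_mm, semi_axes_mm):
    """Count voxels whose centres fall inside an ellipsoid, by triple loop."""
    a, b, c = semi_axes_mm
    cx, cy, cz = center_mm
    dx, dy, dz = spacing
    count = 0
    for i in range(grid_shape[0]):
        for j in range(grid_shape[1]):
            for k in range(grid_shape[2]):
                x, y, z = i * dx, j * dy, k * dz
                if ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 < 1.0:
                    count += 1
    return count


def threshold_loop(data, plaque, cutoff, strict=True):
    """Voxel-by-voxel threshold scan."""
    out = np.zeros(data.shape, bool)
    for idx in np.ndindex(data.shape):
        if plaque[idx]:
            v = data[idx]
            out[idx] = v > cutoff if strict else v >= cutoff
    return out


def _neighbours(idx, shape, connectivity):
    i, j, k = idx
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                ni, nj, nk = i + di, j + dj, k + dk
                if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                    yield ni, nj, nk


def flood_fill_components(mask, connectivity=26):
    """BFS connected-component labelling; returns a list of voxel-index lists."""
    mask = np.asarray(mask, bool)
    seen = np.zeros(mask.shape, bool)
    components = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = []
        queue = deque([start])
        seen[start] = True
        while queue:
            cur = queue.popleft()
            comp.append(cur)
            for nb in _neighbours(cur, mask.shape, connectivity):
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        components.append(comp)
    return components


def has_consecutive_run(slice_indices, min_slices):
    ks = sorted(set(slice_indices))
    run = 1
    best = 1 if ks else 0
    for prev, cur in zip(ks, ks[1:]):
        run = run + 1 if cur == prev + 1 else 1
        best = max(best, run)
    return best >= min_slices


def segment_iph_naive(data, plaque, ref_mean, ratio, min_slices=2, connectivity=26):
    """Threshold + flood fill + consecutive-slice rule, all brute force."""
    candidate = threshold_loop(data, plaque, ratio * ref_mean)
    out = np.zeros(data.shape, bool)
    for comp in flood_fill_components(candidate, connectivity):
        if has_consecutive_run([k for _, _, k in comp], min_slices):
            for idx in comp:
                out[idx] = True
    return out


def icc_anova_loops(values_a, values_b, model):
    """Textbook two-way ANOVA sums of squares with explicit loops."""
    n = len(values_a)
    k = 2
    table = [[float(values_a[i]), float(values_b[i])] for i in range(n)]
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_total = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_total - ss_rows) / (n * (k - 1))
    if model == "oneway":
        return (msr - msw) / (msr + (k - 1) * msw)
    if model == "twoway-consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def rician_mean(a, sigma):
    """Closed-form Rician mean sigma·sqrt(pi/2)·L_{1/2}(−a²/(2σ²)),
    evaluated with exponentially scaled Bessel functions for stability."""
    from scipy.special import ive
    t = a ** 2 / (2 * sigma ** 2)
    laguerre = (1 + t) * ive(0, t / 2) + t * ive(1, t / 2)
    return sigma * np.sqrt(np.pi / 2) * laguerre
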