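"""Independent brute-force re-implementations used as oracles.

Everything here is deliberately written as plain Python loops over scalars,
sharing no code path with the package, so that agreement with the package
is a meaningful check.
"""

from __future__ import annotations

import math


def max_speed(positions, dt) -> float:
    best = 0.0
    for i in range(len(positions) - 1):
        (x0, y0), (x1, y1) = positions[i], positions[i + 1]
        best = max(best, math.hypot(x1 - x0, y1 - y0))
    return best / dt


def avg_speed(positions, dt) -> float:
    total = 0.0
    for i in range(len(positions) - 1):
        (x0, y0), (x1, y1) = positions[i], positions[i + 1]
        total += math.hypot(x1 - x0, y1 - y0)
    return total / (len(positions) - 1) / dt


def bias(positions) -> float:
    steps = []
    for i in range(len(positions) - 1):
        dx = positions[i + 1][0] - positions[i][0]
        dy = positions[i + 1][1] - positions[i][1]
        if dx != 0.0 or dy != 0.0:
            steps.append((dx, dy))
    if len(steps) < 2:
        return float("nan")
    total = 0.0
    for (ax, ay), (bx, by) in zip(steps, steps[1:]):
        cosv = (ax * bx + ay * by) / (math.hypot(ax, ay) * math.hypot(bx, by))
        total += min(1.0, max(-1.0, cosv))
    return total / (len(steps) - 1)


def bbox_area(positions, dt, window_s) -> float:
    n_win = round(window_s / dt)
    areas = []
    start = 0
    while start + n_win <= len(positions) - 1:
        xs = [p[0] for p in positions[start : start + n_win + 1]]
        ys = [p[1] for p in positions[start : start + n_win + 1]]
        areas.append((max(xs) - min(xs)) * (max(ys) - min(ys)))
        start += n_win
    return sum(areas) / len(areas)


def centroid(volume, voxel_size_zyx):
    """Intensity-weighted centroid of a 3D array by triple loop."""
    sz, sy, sx = voxel_size_zyx
    total = 0.0
    cz = cy = cx = 0.0
    nz, ny, nx = len(volume), len(volume[0]), len(volume[0][0])
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                w = float(volume[iz][iy][ix])
                total += w
                cz += w * iz * sz
                cy += w * iy * sy
                cx += w * ix * sx
    return (cz / total, cy / total, cx / total)


def variance_trace(volume, voxel_size_zyx) -> float:
    """Trace of the intensity-weighted coordinate covariance, µm²."""
    cz, cy, cx = centroid(volume, voxel_size_zyx)
    sz, sy, sx = voxel_size_zyx
    total = 0.0
    acc = 0.0
    nz, ny, nx = len(volume), len(volume[0]), len(volume[0][0])
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                w = float(volume[iz][iy][ix])
                total += w
                acc += w * (
                    (iz * sz - cz) ** 2 + (iy * sy - cy) ** 2 + (ix * sx - cx) ** 2
                )
    return acc / total


def ks_statistic(a, b) -> float:
    """sup |ECDF_a - ECDF_b| by sweeping the pooled sorted values."""
    a, b = sorted(a), sorted(b)
    best = 0.0
    for v in a + b:
        fa = sum(1 for x in a if x <= v) / len(a)
        fb = sum(1 for x in b if x <= v) / len(b)
        best = max(best, abs(fa - fb))
    return best


def mwu_statistic(a, b) -> float:
    """min(U_a, U_b) by O(n²) count of pairwise wins plus half-ties."""
    u_a = 0.0
    for x in a:
        for y in b:
            if x > y:
                u_a += 1.0
            elif x == y:
                u_a += 0.5
    return min(u_a, len(a) * len(b) - u_a)


def yates_chi2(a, b, c, d) -> float:
    """Yates-corrected chi-square via expected counts (independent route)."""
    n = a + b + c + d
    chi2 = 0.0
    for obs, row, col in (
        (a, a + b, a + c),
        (b, a + b, b + d),
        (c, c + d, a + c),
        (d, c + d, b + d),
    ):
        expect = row * col / n
        chi2 += max(abs(obs - expect) - 0.5, 0.0) ** 2 / expect
    return chi2


def welch_statistic(a, b) -> tuple[float, float]:
    """Welch t and Welch-Satterthwaite df by textbook formulas."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
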