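"""Independent brute-force reference implementations used by the tests.

Everything here evaluates the defining formulas and procedures naively —
explicit loops over points, lags and regions — without reusing the
package's vectorized/FFT/union-find code paths.
"""

import math

import numpy as np


# ---------------------------------------------------------------------------
# Height parameters (double loop over the grid)


def bf_height_params(z: np.ndarray) -> dict:
    nr, nc = z.shape
    n = nr * nc
    s_abs = s2 = s3 = s4 = 0.0
    zmax = -math.inf
    zmin = math.inf
    for i in range(nr):
        for j in range(nc):
            v = z[i, j]
            s_abs += abs(v)
            s2 += v * v
            s3 += v ** 3
            s4 += v ** 4
            zmax = max(zmax, v)
            zmin = min(zmin, v)
    sq = math.sqrt(s2 / n)
    return {
        "Sa": s_abs / n,
        "Sq": sq,
        "Ssk": (s3 / n) / sq ** 3,
        "Sku": (s4 / n) / sq ** 4,
        "Sp": zmax,
        "Sv": -zmin,
        "Sz": zmax - zmin,
    }


def bf_smr(z: np.ndarray) -> float:
    m = z.mean()
    count = 0
    for v in z.ravel():
        if v >= m:
            count += 1
    return 100.0 * count / z.size


def bf_material_ratio(z: np.ndarray, c: float) -> float:
    count = 0
    for v in z.ravel():
        if v >= c:
            count += 1
    return 100.0 * count / z.size


def bf_height_at(z: np.ndarray, p: float) -> float:
    """Inverse material ratio by explicit interpolation on the sorted heights."""
    zs = sorted(z.ravel(), reverse=True)
    n = len(zs)
    mr = [100.0 * (k + 1) / n for k in range(n)]
    if p <= mr[0]:
        return zs[0]
    if p >= mr[-1]:
        return zs[-1]
    for k in range(n - 1):
        if mr[k] <= p <= mr[k + 1]:
            t = (p - mr[k]) / (mr[k + 1] - mr[k])
            return zs[k] + t * (zs[k + 1] - zs[k])
    return zs[-1]


def bf_volume_params(z: np.ndarray, p: float = 10.0, q: float = 80.0) -> dict:
    def vm(pp):
        c = bf_height_at(z, pp)
        tot = 0.0
        for v in z.ravel():
            if v > c:
                tot += v - c
        return tot / z.size

    def vv(pp):
        c = bf_height_at(z, pp)
        tot = 0.0
        for v in z.ravel():
            if v < c:
                tot += c - v
        return tot / z.size

    vmp, vmq = vm(p), vm(q)
    vvp, vvq = vv(p), vv(q)
    return {"Vm": vmp, "Vv": vvp, "Vmp": vmp, "Vmc": vmq - vmp,
            "Vvc": vvp - vvq, "Vvv": vvq}


def bf_stratified(z: np.ndarray, window: float = 40.0, n_grid: int = 1001) -> dict:
    u = [100.0 * k / (n_grid - 1) for k in range(n_grid)]
    c = [bf_height_at(z, ui) for ui in u]
    if c[0] - c[-1] <= 0.0:
        return {"Sk": 0.0, "Spk": 0.0, "Svk": 0.0, "Smr1": 0.0, "Smr2": 100.0}
    w = round(window / 100.0 * (n_grid - 1))
    best, i0 = math.inf, 0
    for i in range(n_grid - w):
        drop = c[i] - c[i + w]
        if drop < best:
            best, i0 = drop, i
    slope = (c[i0 + w] - c[i0]) / (u[i0 + w] - u[i0])
    c_top = c[i0] + slope * (0.0 - u[i0])
    c_bot = c[i0] + slope * (100.0 - u[i0])
    sk = c_top - c_bot

    def crossing(target):
        if target >= c[0]:
            return 0.0
        if target <= c[-1]:
            return 100.0
        for k in range(n_grid - 1):
            if c[k] >= target >= c[k + 1]:
                if c[k] == c[k + 1]:
                    return u[k]
                t = (c[k] - target) / (c[k] - c[k + 1])
                return u[k] + t * (u[k + 1] - u[k])
        return 100.0

    smr1, smr2 = crossing(c_top), crossing(c_bot)
    a1 = a2 = 0.0  # trapezoid integration of the clipped areas
    for k in range(n_grid - 1):
        du = u[k + 1] - u[k]
        a1 += 0.5 * (max(c[k] - c_top, 0.0) + max(c[k + 1] - c_top, 0.0)) * du
        a2 += 0.5 * (max(c_bot - c[k], 0.0) + max(c_bot - c[k + 1], 0.0)) * du
    a1 /= 100.0
    a2 /= 100.0
    spk = 200.0 * a1 / smr1 if smr1 > 0 else 0.0
    svk = 200.0 * a2 / (100.0 - smr2) if smr2 < 100 else 0.0
    return {"Sk": sk, "Spk": spk, "Svk": svk, "Smr1": smr1, "Smr2": smr2}


# ---------------------------------------------------------------------------
# Spatial parameters (direct cyclic autocorrelation + plain radial walk)


def bf_autocorrelation(z: np.ndarray) -> np.ndarray:
    z = z - z.mean()
    nr, nc = z.shape
    var = (z ** 2).mean()
    acf = np.empty((nr, nc))
    for dy in range(nr):
        for dx in range(nc):
            acf[dy, dx] = (z * np.roll(np.roll(z, dy, axis=0), dx, axis=1)).mean() / var
    return np.fft.fftshift(acf)


def bf_radial_decay(acf, step_x, step_y, s, n_angles=360):
    nr, nc = acf.shape
    r0, c0 = nr // 2, nc // 2
    max_r = min((nr // 2) * step_y, (nc // 2) * step_x)
    dr = 0.5 * min(step_x, step_y)
    radii = np.arange(dr, max_r, dr)
    angles = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    first = [max_r] * n_angles
    for i, th in enumerate(angles):
        for r in radii:
            x = r * math.cos(th) / step_x + c0
            y = r * math.sin(th) / step_y + r0
            x0, y0 = int(math.floor(x)), int(math.floor(y))
            fx, fy = x - x0, y - y0
            x0 = min(max(x0, 0), nc - 2)
            y0 = min(max(y0, 0), nr - 2)
            val = ((1 - fx) * (1 - fy) * acf[y0, x0]
                   + fx * (1 - fy) * acf[y0, x0 + 1]
                   + (1 - fx) * fy * acf[y0 + 1, x0]
                   + fx * fy * acf[y0 + 1, x0 + 1])
            if val < s:
                first[i] = r
                break
    return min(first), max(first)


# ---------------------------------------------------------------------------
# Watershed by naive per-point descent and naive Wolf pruning


def _bf_neighbours(r, c, nr, nc, connectivity):
    if connectivity == 4:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1),
                (1, -1), (1, 0), (1, 1)]
    for dr, dc in offs:
        rr, cc = r + dr, c + dc
        if 0 <= rr < nr and 0 <= cc < nc:
            yield rr, cc


def bf_watershed(w: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Per-point steepest descent on the strict key (w, row, col)."""
    nr, nc = w.shape

    def key(r, c):
        return (w[r, c], r, c)

    def descend(r, c):
        while True:
            best = (r, c)
            for rr, cc in _bf_neighbours(r, c, nr, nc, connectivity):
                if key(rr, cc) < key(*best):
                    best = (rr, cc)
            if best == (r, c):
                return r * nc + c
            r, c = best

    sinks = np.empty((nr, nc), dtype=int)
    for r in range(nr):
        for c in range(nc):
            sinks[r, c] = descend(r, c)
    uniq = sorted(set(sinks.ravel().tolist()))
    lut = {s: i for i, s in enumerate(uniq)}
    return np.vectorize(lut.get)(sinks)


def bf_wolf_prune(labels: np.ndarray, w: np.ndarray, threshold: float,
                  connectivity: int = 8) -> np.ndarray:
    """Naive Wolf pruning: merge smallest Wolf height first (ties by label)
    into the neighbour across the lowest saddle (ties by label)."""
    labels = labels.copy()
    nr, nc = w.shape
    while True:
        ids = sorted(set(labels.ravel().tolist()))
        if len(ids) <= 1:
            break
        mins = {a: math.inf for a in ids}
        for r in range(nr):
            for c in range(nc):
                mins[labels[r, c]] = min(mins[labels[r, c]], w[r, c])
        saddle = {}
        for r in range(nr):
            for c in range(nc):
                for rr, cc in _bf_neighbours(r, c, nr, nc, connectivity):
                    a, b = labels[r, c], labels[rr, cc]
                    if a != b:
                        hgt = max(w[r, c], w[rr, cc])
                        k = (min(a, b), max(a, b))
                        saddle[k] = min(saddle.get(k, math.inf), hgt)
        best = None
        for a in ids:
            nb = {}
            for (x, y), h in saddle.items():
                if x == a:
                    nb[y] = min(nb.get(y, math.inf), h)
                elif y == a:
                    nb[x] = min(nb.get(x, math.inf), h)
            if not nb:
                continue
            lowest = min(nb.values())
            wolf = lowest - mins[a]
            target = min(b for b, h in nb.items() if h == lowest)
            cand = (wolf, a, target)
            if best is None or cand < best:
                best = cand
        if best is None or best[0] >= threshold:
            break
        _, a, target = best
        labels[labels == a] = target
    # compact
    ids = sorted(set(labels.ravel().tolist()))
    lut = {s: i for i, s in enumerate(ids)}
    return np.vectorize(lut.get)(labels)


def canonical_partition(labels: np.ndarray):
    """Partition as a frozenset of frozensets of flat indices (label-free)."""
    groups = {}
    for idx, lab in enumerate(labels.ravel().tolist()):
        groups.setdefault(lab, set()).add(idx)
    return frozenset(frozenset(g) for g in groups.values())
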