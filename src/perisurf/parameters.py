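"""Areal surface-texture parameters (ISO 25178-2 style) of a height map.

All operations assume a *preprocessed* height map: fully valid, levelled so
the mean plane is z = 0 (see :func:`perisurf.heightmap.preprocess`).

Conventions adopted here (stated because vendor software varies):

* Material at a section height c is counted where z >= c (ties included), so
  a flat surface has a material ratio of 100% at its mean height.
* Discrete integrals weight every point by one cell area (step_x × step_y);
  the only sub-sample interpolation is the linear inverse of the material
  ratio curve.
* S_td is the direction of the dominant periodic variation (the wavevector
  angle of the spectral maximum), measured counterclockwise from the +x
  (column) axis and reported modulo 180°.
* The S_k family uses the 40%-width minimum-slope secant construction on the
  material ratio curve.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .heightmap import HeightMap

__all__ = [
    "ParameterSet",
    "MaterialRatioCurve",
    "ZeroVarianceError",
    "height_params",
    "material_ratio_curve",
    "smr",
    "functional_params",
    "spatial_params",
    "volume_params",
    "stratified_params",
    "compute_all",
    "PARAMETER_NAMES",
    "PARAMETER_UNITS",
]


class ZeroVarianceError(ValueError):
    """Skewness/kurtosis are undefined on a zero-variance surface."""


@dataclass
class ParameterSet:
    """The twenty-six areal texture parameters screened in this pipeline.

    Height parameters are in μm except the dimensionless Ssk and Sku; Smr,
    Smr1, Smr2 are percentages; Sal in μm; Str dimensionless in [0, 1]; Std
    in degrees; the V-family is volume per unit area (μm³/μm² = μm).
    """

    Sq: float
    Ssk: float
    Sku: float
    Sp: float
    Sv: float
    Sz: float
    Sa: float
    Smr: float
    Smc: float
    Sxp: float
    Sal: float
    Str: float
    Std: float
    Vm: float
    Vv: float
    Vmp: float
    Vmc: float
    Vvc: float
    Vvv: float
    Sk: float
    Spk: float
    Svk: float
    Smr1: float
    Smr2: float
    S10z: float
    S5v: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


PARAMETER_NAMES = [f.name for f in fields(ParameterSet)]

PARAMETER_UNITS = {
    "Sq": "um", "Ssk": "-", "Sku": "-", "Sp": "um", "Sv": "um", "Sz": "um",
    "Sa": "um", "Smr": "%", "Smc": "um", "Sxp": "um", "Sal": "um", "Str": "-",
    "Std": "deg", "Vm": "um", "Vv": "um", "Vmp": "um", "Vmc": "um",
    "Vvc": "um", "Vvv": "um", "Sk": "um", "Spk": "um", "Svk": "um",
    "Smr1": "%", "Smr2": "%", "S10z": "um", "S5v": "um",
}


# ---------------------------------------------------------------------------
# Height parameters


def height_params(hm: HeightMap) -> dict:
    """Moment and extreme-value height parameters.

    Sa is the discrete form of the areal mean of |z| over the evaluation
    area; Sq the RMS height; Ssk/Sku the standardized third and fourth
    moments (Sku non-excess, so a Gaussian surface has Sku = 3); Sp the
    highest peak, Sv the deepest pit depth (positive), Sz = Sp + Sv.
    """
    z = hm.heights.ravel()
    sa = np.abs(z).mean()
    sq = np.sqrt((z ** 2).mean())
    if sq == 0:
        raise ZeroVarianceError("flat surface: Ssk and Sku are undefined")
    ssk = (z ** 3).mean() / sq ** 3
    sku = (z ** 4).mean() / sq ** 4
    sp = z.max()
    sv = -z.min()
    return {"Sq": sq, "Ssk": ssk, "Sku": sku, "Sp": sp, "Sv": sv,
            "Sz": sp + sv, "Sa": sa}


# ---------------------------------------------------------------------------
# Material ratio (Abbott-Firestone) curve and the parameters on it


@dataclass
class MaterialRatioCurve:
    """Areal material ratio curve mr(c): % of points with z >= c.

    `levels`/`ratios` are a sampled version of the curve for display; the
    exact empirical curve (every sorted height) is kept in `heights_sorted`
    (descending) and drives all parameter computations, so results do not
    depend on the display sampling.
    """

    levels: np.ndarray          # section heights c, μm (descending)
    ratios: np.ndarray          # mr(c), %
    mean_height: float          # m (0 after levelling), μm
    area_at_mean: float         # A(m), μm²
    eval_area: float            # A(N), μm²
    heights_sorted: np.ndarray  # all heights, descending, μm

    @property
    def smr(self) -> float:
        """S_mr = 100 · A(m) / A(N)."""
        return 100.0 * self.area_at_mean / self.eval_area

    def ratio_at(self, c: float) -> float:
        """Exact mr(c) from the empirical distribution."""
        return 100.0 * np.mean(self.heights_sorted >= c)

    def height_at(self, p: float) -> float:
        """Inverse material ratio c(p): section height at material ratio p%.

        Linear interpolation on the empirical curve; c(0) is the highest
        point and c(100) the lowest.
        """
        if not 0.0 <= p <= 100.0:
            raise ValueError("material ratio must be in [0, 100] %")
        zs = self.heights_sorted
        n = zs.size
        mr_grid = 100.0 * np.arange(1, n + 1) / n
        return float(np.interp(p, mr_grid, zs, left=zs[0], right=zs[-1]))

    def material_volume(self, p: float) -> float:
        """Vm(p): material volume per unit area above the section at p%. μm."""
        c = self.height_at(p)
        return float(np.clip(self.heights_sorted - c, 0.0, None).mean())

    def void_volume(self, p: float) -> float:
        """Vv(p): void volume per unit area below the section at p%. μm."""
        c = self.height_at(p)
        return float(np.clip(c - self.heights_sorted, 0.0, None).mean())


def material_ratio_curve(hm: HeightMap, n_levels: int = 512) -> MaterialRatioCurve:
    """Sample the areal material ratio curve of a preprocessed height map."""
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    z = hm.heights.ravel()
    zs = np.sort(z)[::-1]
    m = z.mean()
    levels = np.linspace(zs[0], zs[-1], n_levels)
    ratios = np.array([100.0 * np.mean(z >= c) for c in levels])
    area_at_mean = np.count_nonzero(z >= m) * hm.cell_area
    return MaterialRatioCurve(levels=levels, ratios=ratios, mean_height=m,
                              area_at_mean=area_at_mean, eval_area=hm.eval_area,
                              heights_sorted=zs)


def smr(hm: HeightMap) -> float:
    """Areal material ratio at the mean height, S_mr = 100·A(m)/A(N) (%)."""
    z = hm.heights
    m = z.mean()
    return 100.0 * np.count_nonzero(z >= m) / z.size


def functional_params(curve: MaterialRatioCurve, p: float = 2.5,
                      q: float = 50.0, mc_ratio: float = 10.0) -> dict:
    """Inverse-material-ratio parameters.

    Smc is the section height at material ratio `mc_ratio` (default 10%),
    relative to the mean plane; Sxp = c(p%) − c(q%) is the peak-extreme
    height between the 2.5% and 50% sections.
    """
    if p >= q:
        raise ValueError("require p < q for Sxp")
    smc = curve.height_at(mc_ratio)
    sxp = curve.height_at(p) - curve.height_at(q)
    return {"Smc": smc, "Sxp": sxp}


def volume_params(curve: MaterialRatioCurve, p: float = 10.0,
                  q: float = 80.0) -> dict:
    """Material/void volume parameters from the material ratio curve.

    Vm/Vv are evaluated at p (default 10%); Vmp = Vm(p), Vvv = Vv(q),
    Vmc = Vm(q) − Vm(p) (core material), Vvc = Vv(p) − Vv(q) (core void).
    Units: volume per unit area, μm.
    """
    if p >= q:
        raise ValueError("require p < q")
    vm_p, vm_q = curve.material_volume(p), curve.material_volume(q)
    vv_p, vv_q = curve.void_volume(p), curve.void_volume(q)
    return {"Vm": vm_p, "Vv": vv_p, "Vmp": vm_p, "Vmc": vm_q - vm_p,
            "Vvc": vv_p - vv_q, "Vvv": vv_q}


def stratified_params(curve: MaterialRatioCurve, window: float = 40.0,
                      n_grid: int = 1001) -> dict:
    """Core/peak/valley decomposition (Sk family) by the secant construction.

    The equivalent straight line is the secant over the `window`%-wide
    stretch of the material ratio curve with minimum |slope|; its heights at
    mr = 0 and 100% bound the core (Sk).  Smr1/Smr2 are the material ratios
    where the curve crosses the core bounds; Spk/Svk are the heights of
    right triangles whose areas equal the peak/valley areas outside the
    core.  A flat (degenerate) curve yields all zeros with Smr1 = 0 and
    Smr2 = 100.
    """
    u = np.linspace(0.0, 100.0, n_grid)
    c = np.array([curve.height_at(ui) for ui in u])
    if c[0] - c[-1] <= 0.0:  # flat surface
        return {"Sk": 0.0, "Spk": 0.0, "Svk": 0.0, "Smr1": 0.0, "Smr2": 100.0}
    w = int(round(window / 100.0 * (n_grid - 1)))
    drops = c[:n_grid - w] - c[w:]          # >= 0, c is non-increasing
    i0 = int(np.argmin(drops))              # ties: first window
    slope = (c[i0 + w] - c[i0]) / (u[i0 + w] - u[i0])
    c_top = c[i0] + slope * (0.0 - u[i0])
    c_bot = c[i0] + slope * (100.0 - u[i0])
    sk = c_top - c_bot

    # crossings of the empirical curve with the core bounds
    smr1 = 0.0 if c_top >= c[0] else float(np.interp(-c_top, -c, u))
    smr2 = 100.0 if c_bot <= c[-1] else float(np.interp(-c_bot, -c, u))

    a1 = np.trapezoid(np.clip(c - c_top, 0.0, None), u) / 100.0
    a2 = np.trapezoid(np.clip(c_bot - c, 0.0, None), u) / 100.0
    spk = 200.0 * a1 / smr1 if smr1 > 0 else 0.0
    svk = 200.0 * a2 / (100.0 - smr2) if smr2 < 100 else 0.0
    return {"Sk": sk, "Spk": spk, "Svk": svk, "Smr1": smr1, "Smr2": smr2}


# ---------------------------------------------------------------------------
# Spatial parameters


def autocorrelation(hm: HeightMap) -> np.ndarray:
    """Normalized cyclic areal autocorrelation, zero lag at the centre."""
    z = hm.heights - hm.heights.mean()
    var = (z ** 2).mean()
    if var == 0:
        raise ZeroVarianceError("flat surface: autocorrelation undefined")
    F = np.fft.fft2(z)
    acf = np.fft.ifft2(F * np.conj(F)).real / (z.size * var)
    return np.fft.fftshift(acf)


def _radial_decay(acf: np.ndarray, step_x: float, step_y: float, s: float,
                  n_angles: int = 360) -> tuple[float, float]:
    """Min/max radius at which the ACF first decays below s, by direction.

    Walks outward from the zero lag along `n_angles` directions with
    bilinear interpolation; a direction that never decays within the map
    contributes its maximum reachable radius.
    """
    nr, nc = acf.shape
    r0, c0 = nr // 2, nc // 2
    max_r = min((nr // 2) * step_y, (nc // 2) * step_x)
    dr = 0.5 * min(step_x, step_y)
    radii = np.arange(dr, max_r, dr)
    angles = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    first = np.full(n_angles, max_r)
    for i, th in enumerate(angles):
        xs = radii * np.cos(th) / step_x + c0
        ys = radii * np.sin(th) / step_y + r0
        x0f, y0f = np.floor(xs).astype(int), np.floor(ys).astype(int)
        fx, fy = xs - x0f, ys - y0f
        x0f = np.clip(x0f, 0, nc - 2)
        y0f = np.clip(y0f, 0, nr - 2)
        vals = ((1 - fx) * (1 - fy) * acf[y0f, x0f]
                + fx * (1 - fy) * acf[y0f, x0f + 1]
                + (1 - fx) * fy * acf[y0f + 1, x0f]
                + fx * fy * acf[y0f + 1, x0f + 1])
        below = np.nonzero(vals < s)[0]
        if below.size:
            first[i] = radii[below[0]]
    return float(first.min()), float(first.max())


def spatial_params(hm: HeightMap, s: float = 0.2) -> dict:
    """Autocorrelation length, texture aspect ratio, and texture direction.

    Sal is the shortest lag (μm) at which the normalized autocorrelation
    decays to `s`; Str = Sal / (longest such lag) ∈ [0, 1]; Std is the
    wavevector angle of the dominant spectral component, degrees from the
    +x axis, counterclockwise, modulo 180.
    """
    nr, nc = hm.shape
    if nr < 3 or nc < 3:
        raise ValueError("grid too small for spatial parameters (< 3x3)")
    acf = autocorrelation(hm)
    sal, rmax = _radial_decay(acf, hm.step_x, hm.step_y, s)
    s_tr = sal / rmax if rmax > 0 else 1.0

    z = hm.heights - hm.heights.mean()
    P = np.abs(np.fft.fft2(z)) ** 2
    P[0, 0] = 0.0  # exclude DC
    fy = np.fft.fftfreq(nr, d=hm.step_y)
    fx = np.fft.fftfreq(nc, d=hm.step_x)
    iy, ix = np.unravel_index(int(np.argmax(P)), P.shape)
    std = np.degrees(np.arctan2(fy[iy], fx[ix])) % 180.0
    return {"Sal": sal, "Str": s_tr, "Std": std}


# ---------------------------------------------------------------------------
# Aggregate


def compute_all(hm: HeightMap, *, prune_fraction: float = 0.10,
                n_levels: int = 512) -> ParameterSet:
    """Compute all 26 areal parameters of a preprocessed height map.

    The two feature parameters (S10z, S5v) are delegated to the watershed
    segmentation module with Wolf pruning at `prune_fraction` of Sz.
    """
    from . import segmentation

    vals = height_params(hm)
    curve = material_ratio_curve(hm, n_levels=n_levels)
    vals["Smr"] = curve.smr
    vals.update(functional_params(curve))
    vals.update(spatial_params(hm))
    vals.update(volume_params(curve))
    vals.update(stratified_params(curve))
    feat = segmentation.feature_params(
        hm, segmentation.SegmentationConfig(prune_fraction=prune_fraction))
    vals["S10z"] = feat["S10z"]
    vals["S5v"] = feat["S5v"]
    return ParameterSet(**{k: vals[k] for k in PARAMETER_NAMES})
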