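"""Pseudo-random surface synthesis with targeted Sa, Sv, Smr.

The generator reverse-engineers rough substrata: heights are drawn from the
Pearson-system member matching a prescribed skewness/kurtosis pair (the
rock-derived defaults are -0.3 and 3.0), given mm-scale spatial structure
by low-pass filtering with rank re-mapping (which restores the drawn
marginal exactly, so the four moments survive filtering), and calibrated to
hit three areal parameter targets:

* Sa  — by scaling the overall standard deviation;
* Sv  — by a constant h multiplying deviations below a low height quantile
        (the pit tail), stretching the deepest pits while leaving the bulk
        of the marginal — and hence Sa and the material ratio — nearly
        untouched;
* Smr — by a regular micro-pattern of flat-bottomed depressions whose area
        fraction is adjusted until the material ratio at the mean plane
        matches.

Achieved values are always re-measured through the areal-parameter module
on the re-levelled surface — never read back from the generator's knobs —
and reported as targeted/actual/percent-error, the same layout used to
validate fabricated tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .heightmap import HeightMap
from .pearson import PearsonSpec, sample_pearson
from . import parameters

__all__ = [
    "SynthesisTarget",
    "ValidationReport",
    "SmrInfeasibleError",
    "correlated_pearson_field",
    "apply_depressions",
    "synthesize_surface",
    "validate_surface",
]

MM = 1000.0  # μm per mm


class SmrInfeasibleError(ValueError):
    """Raised when the Smr target cannot be reached by depression patterning."""


@dataclass
class SynthesisTarget:
    """Targets and knobs for one synthesized substratum surface.

    Targets are in the units used for tile design: Sa and Sv in mm, Smr in
    percent.  `h` is the initial pit-stretching constant (calibrated);
    `corr_mm` the low-pass correlation length; depression patterning uses
    square cells on `depression_pitch_mm` centres with depth
    `depression_depth_mm` (default 0.25 × the Sv target).
    """

    sa_mm: float
    sv_mm: float
    smr_pct: float
    skewness: float = -0.3
    kurtosis: float = 3.0
    rows: int = 128
    cols: int = 128
    step_mm: float = 0.4
    corr_mm: float = 2.0
    h: float = 1.0
    depression_pitch_mm: float = 5.0
    depression_depth_mm: float = None
    pit_tail_q: float = 0.02
    rel_tolerance: float = 0.05
    max_iter: int = 50
    seed: int = 0

    def __post_init__(self):
        if min(self.sa_mm, self.sv_mm, self.smr_pct) <= 0:
            raise ValueError("targets must be positive")
        if self.rel_tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.depression_depth_mm is None:
            self.depression_depth_mm = 0.25 * self.sv_mm


@dataclass
class ValidationReport:
    """Targeted vs achieved parameter values with percent errors.

    `table` has one row per parameter: targeted, actual, error_pct
    (= 100·|actual − targeted| / targeted; NaN-flagged for a zero target).
    """

    table: pd.DataFrame
    converged: bool = True

    @property
    def mean_error_pct(self) -> float:
        return float(self.table["error_pct"].mean())

    def __str__(self):
        head = "" if self.converged else "NOT CONVERGED\n"
        return head + self.table.to_string(index=False,
                                           float_format=lambda v: f"{v:.3f}")


def percent_error(actual: float, targeted: float) -> float:
    """100·|actual − targeted|/targeted; NaN for a zero target (flagged)."""
    if targeted == 0:
        return float("nan")
    return 100.0 * abs(actual - targeted) / abs(targeted)


def validate_surface(achieved: dict, target) -> ValidationReport:
    """Build a targeted/actual/percent-error report.

    `achieved` maps parameter names to measured values; `target` is a
    SynthesisTarget or a plain mapping of the same parameter names to
    targeted values.  Units must already agree.
    """
    if isinstance(target, SynthesisTarget):
        targets = {"Sa": target.sa_mm, "Sv": target.sv_mm, "Smr": target.smr_pct}
    else:
        targets = dict(target)
    rows = []
    for name, t in targets.items():
        a = achieved[name]
        rows.append({"parameter": name, "targeted": t, "actual": a,
                     "error_pct": percent_error(a, t)})
    return ValidationReport(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Building blocks


def correlated_pearson_field(rows: int, cols: int, spec: PearsonSpec,
                             corr_px: float, seed=None) -> np.ndarray:
    """Spatially correlated field with an exact Pearson marginal.

    Draws rows×cols values from the Pearson sampler, Gaussian low-pass
    filters the grid (periodic boundaries, sigma = `corr_px` samples), and
    rank re-maps the filtered field onto the sorted draws.  The output is
    therefore a spatial rearrangement of the original sample: its marginal
    (and all sample moments) are exactly those of the draws.
    """
    draws = sample_pearson(rows * cols, spec, seed=seed)
    grid = draws.reshape(rows, cols)
    smooth = ndimage.gaussian_filter(grid, sigma=corr_px, mode="wrap")
    out = np.empty(rows * cols)
    out[np.argsort(smooth.ravel(), kind="stable")] = np.sort(draws)
    return out.reshape(rows, cols)


def _depression_mask(rows: int, cols: int, step: float, pitch: float,
                     area_fraction: float, seed: int = 0) -> np.ndarray:
    """Boolean mask of a regular grid of square depressions.

    Cells of `pitch` × `pitch` each contain one centred square patch of
    side pitch·sqrt(area_fraction); patch centres get a deterministic
    sub-sample jitter (hashed from the cell index and seed) so the achieved
    fraction varies smoothly with `area_fraction` on coarse grids.
    """
    if not 0.0 <= area_fraction <= 1.0:
        raise ValueError("area_fraction must be in [0, 1]")
    if area_fraction == 0.0:
        return np.zeros((rows, cols), dtype=bool)
    pitch_px = pitch / step
    if pitch_px < 2.0:
        raise ValueError("pitch must span at least 2 samples")
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = np.floor(y / pitch_px), np.floor(x / pitch_px)
    rng_jit = np.random.default_rng(seed)
    ncy = int(np.ceil(rows / pitch_px))
    ncx = int(np.ceil(cols / pitch_px))
    jy = rng_jit.uniform(-0.5, 0.5, size=(ncy, ncx))
    jx = rng_jit.uniform(-0.5, 0.5, size=(ncy, ncx))
    oy = (y / pitch_px - cy) - 0.5 - jy[cy.astype(int), cx.astype(int)] / pitch_px
    ox = (x / pitch_px - cx) - 0.5 - jx[cy.astype(int), cx.astype(int)] / pitch_px
    half = 0.5 * np.sqrt(area_fraction)
    return (np.abs(oy) <= half) & (np.abs(ox) <= half)


def apply_depressions(hm: HeightMap, pitch: float, depth: float,
                      area_fraction: float, seed: int = 0) -> HeightMap:
    """Cut a regular micro-pattern of flat-bottomed depressions.

    Points inside the pattern are lowered to `depth` below the current mean
    plane (material above that floor is removed; material already lower is
    untouched).  With area_fraction = 0 the map is returned unchanged.
    Increasing the area fraction removes more at/above-mean material, so
    the material ratio at the mean plane decreases monotonically.

    `pitch`, `depth` are in the height map's units (μm).
    """
    mask = _depression_mask(*hm.shape, step=hm.step_x, pitch=pitch,
                            area_fraction=area_fraction, seed=seed)
    if not mask.any():
        return hm
    z = hm.heights.copy()
    floor = z.mean() - depth
    z[mask] = np.minimum(z[mask], floor)
    return hm.copy_with(heights=z)


def _measure(z: np.ndarray, step: float) -> dict:
    """Re-level and measure Sa, Sv, Smr (μm / %) through areal_parameters."""
    hm = HeightMap(z - z.mean(), step, step)
    hp = parameters.height_params(hm)
    return {"Sa": hp["Sa"], "Sv": hp["Sv"], "Smr": parameters.smr(hm), "hm": hm}


# ---------------------------------------------------------------------------
# Main pipeline


def synthesize_surface(target: SynthesisTarget):
    """Generate a surface hitting the Sa/Sv/Smr targets.

    Returns (HeightMap, ValidationReport, PearsonSpec).  The height map is
    in μm on the target's lateral step (converted from mm).  Replicates
    from different seeds differ point-by-point but share the targeted
    parameter values ("self-similar" replicates).

    Raises SmrInfeasibleError when the Smr target exceeds what the marginal
    distribution allows (depressions can only lower the material ratio).
    The report's `converged` flag is False if the fixed-point calibration
    exhausts `max_iter` without meeting every tolerance — never a silent
    success.
    """
    step = target.step_mm * MM
    spec = PearsonSpec(0.0, 1.0, target.skewness, target.kurtosis)
    corr_px = max(target.corr_mm / target.step_mm, 0.5)
    base = correlated_pearson_field(target.rows, target.cols, spec,
                                    corr_px, seed=target.seed)
    base = base - base.mean()
    q_pit = np.quantile(base, target.pit_tail_q)
    tail = base < q_pit

    sa_t, sv_t, smr_t = target.sa_mm * MM, target.sv_mm * MM, target.smr_pct
    pitch = target.depression_pitch_mm * MM
    depth = target.depression_depth_mm * MM
    tol = target.rel_tolerance

    # Smr feasibility: depressions only remove at/above-mean material
    smr_max = _measure(base, step)["Smr"]
    if smr_t > smr_max * (1.0 + tol):
        raise SmrInfeasibleError(
            f"Smr target {smr_t:.1f}% exceeds the {smr_max:.1f}% the marginal "
            "distribution allows (depressions only lower the material ratio)")

    sigma = sa_t / max(np.abs(base).mean(), 1e-30)
    h = target.h
    f_lo, f_hi = 0.0, 0.95
    f = 0.0
    converged = False
    meas = None
    for _ in range(target.max_iter):
        u = np.where(tail, q_pit + h * (base - q_pit), base)
        z = sigma * u
        z = z - z.mean()
        hm_i = HeightMap(z, step, step)
        hm_i = apply_depressions(hm_i, pitch, depth, f, seed=target.seed)
        meas = _measure(hm_i.heights, step)
        ok_sa = abs(meas["Sa"] - sa_t) <= tol * sa_t
        ok_sv = abs(meas["Sv"] - sv_t) <= tol * sv_t
        ok_smr = abs(meas["Smr"] - smr_t) <= tol * smr_t
        if ok_sa and ok_sv and ok_smr:
            converged = True
            break
        sigma *= sa_t / meas["Sa"]
        h = min(max(h * sv_t / meas["Sv"], 1e-3), 1e3)
        if not ok_smr:
            if meas["Smr"] > smr_t:
                f_lo = f
            else:
                f_hi = f
            f = 0.5 * (f_lo + f_hi)

    hm = meas["hm"].copy_with(origin_note=f"synthesized seed={target.seed}")
    achieved = {"Sa": meas["Sa"] / MM, "Sv": meas["Sv"] / MM, "Smr": meas["Smr"]}
    report = validate_surface(achieved, target)
    report.converged = converged
    return hm, report, spec
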