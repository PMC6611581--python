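"""Synthetic-data generators emulating every input the pipeline consumes.

Each generator is a pure function of (configuration, seed): rock-like
surfaces with registered dale populations, per-feature parameter tables
with group structure for the screening stage, biomass datasets with the
lane/trial layout of the floway experiment, and early-colonization site
maps biased to hills.

Distributional choices: quantities that are physically non-negative
(biomass, depths, most texture parameters) are drawn from normals
truncated at zero with the configured group moments; the signed skewness
column is left untruncated.  The group means/SDs default to the observed
rock and biomass statistics (see StudyConfig) so that pushing generated
data through the pipeline reproduces the study's effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .heightmap import HeightMap
from .segmentation import SiteClassificationConfig

__all__ = [
    "StudyConfig",
    "gen_feature_table",
    "gen_rock_surface",
    "gen_biomass",
    "gen_colonization_map",
]

# Parameters with no colonized/bare group difference by default, so the
# screen's specificity is testable.  (mean, sd) in the units of
# parameters.PARAMETER_UNITS; magnitudes loosely rock-like.
NULL_PARAM_STATS = {
    "Sq": (58.0, 15.0), "Ssk": (-0.3, 0.2), "Sku": (3.0, 0.5),
    "Sp": (210.0, 50.0), "Sz": (410.0, 90.0), "Smc": (70.0, 20.0),
    "Sxp": (120.0, 30.0), "Sal": (250.0, 60.0), "Str": (0.5, 0.15),
    "Std": (90.0, 45.0), "Vm": (2.0, 0.8), "Vv": (60.0, 15.0),
    "Vmp": (2.0, 0.8), "Vmc": (50.0, 12.0), "Vvc": (55.0, 14.0),
    "Vvv": (7.0, 2.0), "Sk": (110.0, 25.0), "Spk": (45.0, 15.0),
    "Svk": (60.0, 18.0), "Smr1": (10.0, 3.0), "Smr2": (88.0, 4.0),
    "S10z": (380.0, 80.0), "S5v": (180.0, 40.0),
}

UNTRUNCATED = {"Ssk"}  # physically signed


@dataclass
class StudyConfig:
    """Group statistics driving all generators.

    Defaults are the observed study conditions: dale screening statistics
    (S_v 203.94±49.14 vs 163.63±55.86 μm; S_a 46.63±12.09 vs 38.24±10.94 μm;
    S_mr 0.001±0.001 vs 0.004±0.002 %) over 21 colonized and 21 bare dales;
    biomass 1.86±0.40 vs 0.50±0.16 mg/cm² over 12 replicates × 3 trials per
    level on 4 flow lanes; per-level hill/dale magnitudes (hills 8.29 vs
    2.58 mm, dales 8.35 vs 6.64 mm); and a 0.99 hill bias for early
    colonization sites.
    """

    colonized_sv: tuple = (203.94, 49.14)
    bare_sv: tuple = (163.63, 55.86)
    colonized_sa: tuple = (46.63, 12.09)
    bare_sa: tuple = (38.24, 10.94)
    colonized_smr: tuple = (0.001, 0.001)
    bare_smr: tuple = (0.004, 0.002)
    n_colonized: int = 21
    n_bare: int = 21

    biomass_level2: tuple = (1.86, 0.40)
    biomass_level1: tuple = (0.50, 0.16)
    replicates_per_level: int = 12
    n_trials: int = 3
    n_lanes: int = 4

    hill_height_level2_mm: float = 8.29
    hill_height_level1_mm: float = 2.58
    dale_depth_level2_mm: float = 8.35
    dale_depth_level1_mm: float = 6.64

    hill_bias: float = 0.99
    master_seed: int = 0

    def __post_init__(self):
        for nm in ("colonized_sv", "bare_sv", "colonized_sa", "bare_sa",
                   "colonized_smr", "bare_smr", "biomass_level2", "biomass_level1"):
            if getattr(self, nm)[1] <= 0:
                raise ValueError(f"{nm}: SD must be positive")
        if min(self.n_colonized, self.n_bare) < 2:
            raise ValueError("need at least 2 features per group")
        if not 0.0 <= self.hill_bias <= 1.0:
            raise ValueError("hill_bias must be a probability")


def _truncnorm0(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated at zero."""
    if mean < -5 * sd:
        raise ValueError("infeasible truncation: mean far below zero")
    a = (0.0 - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def gen_feature_table(cfg: StudyConfig = None, seed=None) -> pd.DataFrame:
    """Per-dale parameter table with the configured group structure.

    One row per dale, 26 parameter columns, and a 'group' label
    (colonized / bare).  Sv, Sa and Smr carry the configured group
    differences; the other 23 parameters are drawn identically in both
    groups.
    """
    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(cfg.master_seed if seed is None else seed)
    frames = []
    for group, n in (("colonized", cfg.n_colonized), ("bare", cfg.n_bare)):
        cols = {"group": [group] * n}
        sv = getattr(cfg, f"{group}_sv")
        sa = getattr(cfg, f"{group}_sa")
        smr_ = getattr(cfg, f"{group}_smr")
        cols["Sv"] = _truncnorm0(*sv, n, rng)
        cols["Sa"] = _truncnorm0(*sa, n, rng)
        cols["Smr"] = _truncnorm0(*smr_, n, rng)
        for name, (m, s) in NULL_PARAM_STATS.items():
            if name in UNTRUNCATED:
                cols[name] = rng.normal(m, s, size=n)
            else:
                cols[name] = _truncnorm0(m, s, n, rng)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def gen_rock_surface(cfg: StudyConfig = None, n_dales: int = 8,
                     depth_mean: float = 203.94, depth_sd: float = 49.14,
                     seed=None, rows: int = 96, cols: int = 96,
                     step: float = 5.0, noise_sd: float = 2.0,
                     dale_radius_px: int = 8):
    """Rock-like surface: noisy plane with registered cosine-bell dales.

    Pits are smooth cosine bells of drawn depth at non-overlapping random
    centres; the returned registry (true count, centres, depths) is the
    ground truth for segmentation oracle tests.  Depth defaults are the
    colonized-dale statistics (203.94 ± 49.14 μm).

    Returns (HeightMap, registry DataFrame).
    """
    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(cfg.master_seed if seed is None else seed)
    z = rng.normal(0.0, noise_sd, size=(rows, cols))
    margin = dale_radius_px + 1
    centres = []
    depths = []
    tries = 0
    while len(centres) < n_dales:
        tries += 1
        if tries > 200 * max(n_dales, 1):
            raise RuntimeError("overcrowded placement: dales do not fit the grid")
        r = rng.integers(margin, rows - margin)
        c = rng.integers(margin, cols - margin)
        if any(abs(r - r0) <= 2 * dale_radius_px and abs(c - c0) <= 2 * dale_radius_px
               for r0, c0 in centres):
            continue
        centres.append((r, c))
        depths.append(_truncnorm0(depth_mean, depth_sd, 1, rng)[0])
    yy, xx = np.mgrid[0:rows, 0:cols]
    for (r, c), d in zip(centres, depths):
        rr = np.hypot(yy - r, xx - c)
        bell = np.where(rr <= dale_radius_px,
                        0.5 * (1.0 + np.cos(np.pi * rr / dale_radius_px)), 0.0)
        z -= d * bell
    registry = pd.DataFrame({
        "row": [r for r, _ in centres],
        "col": [c for _, c in centres],
        "depth": depths,
    })
    hm = HeightMap(z - z.mean(), step, step, origin_note=f"gen_rock_surface seed={seed}")
    return hm, registry


def gen_biomass(cfg: StudyConfig = None, seed=None) -> pd.DataFrame:
    """Biomass dataset with the floway layout.

    Per trial, each of the 4 lanes holds 6 tiles, 3 of each treatment
    level, alternately placed; dry biomass per tile is drawn from the
    configured truncated normals (mg/cm²).  With the defaults this yields
    36 tiles per level across 3 trials.
    """
    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(cfg.master_seed if seed is None else seed)
    per_lane = 2 * cfg.replicates_per_level // cfg.n_lanes  # 6 tiles/lane/trial
    rows = []
    for trial in range(1, cfg.n_trials + 1):
        for lane in range(1, cfg.n_lanes + 1):
            for pos in range(per_lane):
                level = 2 if (pos + lane) % 2 == 0 else 1  # alternating layout
                rows.append({"trial": trial, "lane": lane, "position": pos + 1,
                             "level": level})
    df = pd.DataFrame(rows)
    df["biomass"] = 0.0
    for level, (m, s) in ((1, cfg.biomass_level1), (2, cfg.biomass_level2)):
        idx = df.index[df.level == level]
        df.loc[idx, "biomass"] = _truncnorm0(m, s, len(idx), rng)
    return df


def gen_colonization_map(hm: HeightMap, n_sites: int = 300,
                         hill_bias: float = 0.99,
                         cfg: SiteClassificationConfig = None,
                         seed=None) -> np.ndarray:
    """Early-colonization sites biased to hill-class points.

    Each site lands on a uniformly chosen hill-class point (height >=
    hill threshold) with probability `hill_bias`, else on a uniformly
    chosen non-hill point.  Returns an (n_sites, 2) array of (row, col).
    """
    cfg = cfg or SiteClassificationConfig()
    rng = np.random.default_rng(seed)
    hill_mask = hm.heights >= cfg.hill_height_min
    hills = np.argwhere(hill_mask)
    others = np.argwhere(~hill_mask)
    if hills.size == 0 and hill_bias > 0:
        raise ValueError("map has no hill-class points but hill_bias > 0")
    if others.size == 0:
        raise ValueError("map has no non-hill points")
    on_hill = rng.random(n_sites) < hill_bias
    sites = np.empty((n_sites, 2), dtype=int)
    if on_hill.any():
        sites[on_hill] = hills[rng.integers(0, len(hills), on_hill.sum())]
    if (~on_hill).any():
        sites[~on_hill] = others[rng.integers(0, len(others), (~on_hill).sum())]
    return sites
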