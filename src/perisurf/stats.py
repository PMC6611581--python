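"""Statistics for the colonization pipeline.

Three stages: (1) screening the 26 areal parameters between colonized and
bare dale populations with per-parameter one-way ANOVA; (2) comparing
biomass accrual between substratum treatment levels (one-way ANOVA on the
level main effect, Tukey HSD across flow lanes within each level, and an
Anderson-Darling normality check on the residuals); (3) quantifying how
strongly early colonization sites localize on hills.

Screening applies no multiple-testing correction by default, reporting
each parameter at its own alpha; Bonferroni or Benjamini-Hochberg
adjustment is available via `correction`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .heightmap import HeightMap
from .segmentation import SiteClassificationConfig, classify_sites, FeatureSet

__all__ = [
    "ScreeningResult",
    "ComparisonReport",
    "screen_parameters",
    "compare_biomass",
    "hill_localization",
]


@dataclass
class ScreeningResult:
    """Per-parameter screen between two feature groups.

    `table` columns: parameter, mean/sd per group, F, p, significant.
    """

    table: pd.DataFrame
    alpha: float
    groups: tuple

    @property
    def significant(self) -> list:
        return self.table.loc[self.table["significant"], "parameter"].tolist()


def screen_parameters(tbl: pd.DataFrame, alpha: float = 0.05,
                      group_col: str = "group",
                      correction: str = None) -> ScreeningResult:
    """One-way ANOVA per parameter between two feature groups.

    `tbl` holds one row per feature (dale), one column per parameter, and a
    group label column (e.g. colonized / bare).  With two groups the F
    statistic equals the square of the pooled two-sample t.  A parameter
    constant within both groups gets NaN F/p and is flagged undefined, not
    silently zero.

    correction: None (per-parameter alpha, the default), "bonferroni", or
    "fdr_bh".
    """
    groups = sorted(tbl[group_col].unique())
    if len(groups) != 2:
        raise ValueError("screening expects exactly two groups")
    g0 = tbl[tbl[group_col] == groups[0]]
    g1 = tbl[tbl[group_col] == groups[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("need at least 2 observations per group")
    params = [c for c in tbl.columns if c != group_col
              and np.issubdtype(tbl[c].dtype, np.number)]
    rows = []
    for pcol in params:
        a, b = g0[pcol].to_numpy(float), g1[pcol].to_numpy(float)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            F, p = np.nan, np.nan
        else:
            F, p = sps.f_oneway(a, b)
        rows.append({"parameter": pcol,
                     f"mean_{groups[0]}": a.mean(), f"sd_{groups[0]}": a.std(ddof=1),
                     f"mean_{groups[1]}": b.mean(), f"sd_{groups[1]}": b.std(ddof=1),
                     "F": F, "p": p})
    out = pd.DataFrame(rows)
    pvals = out["p"].to_numpy()
    if correction is None:
        sig = pvals < alpha
    else:
        from statsmodels.stats.multitest import multipletests
        finite = np.isfinite(pvals)
        sig = np.zeros(pvals.size, dtype=bool)
        if finite.any():
            sig[finite] = multipletests(pvals[finite], alpha=alpha,
                                        method=correction)[0]
    out["significant"] = np.where(np.isfinite(pvals), sig, False)
    return ScreeningResult(table=out, alpha=alpha, groups=tuple(groups))


@dataclass
class ComparisonReport:
    """Biomass comparison between substratum treatment levels.

    Holds level means ± SD, the ratio of level means (higher over lower
    treatment label), the one-way ANOVA F with its degrees of freedom and
    p-value, Tukey HSD across flow lanes within each level, and the
    Anderson-Darling statistic on the ANOVA residuals (reported, never used
    to gate the ANOVA).
    """

    level_stats: pd.DataFrame
    ratio: float
    F: float
    df: tuple
    p: float
    tukey_lanes: dict
    ad_statistic: float
    ad_critical: dict

    def summary(self) -> str:
        lines = [self.level_stats.to_string(),
                 f"ratio of level means = {self.ratio:.2f}",
                 f"ANOVA main effect: F[{self.df[0]}, {self.df[1]}] = "
                 f"{self.F:.2f}, p = {self.p:.3g}",
                 f"Anderson-Darling on residuals: A2 = {self.ad_statistic:.3f}"]
        for lvl, tk in self.tukey_lanes.items():
            any_sig = bool(np.asarray(tk.reject).any())
            lines.append(f"Tukey across lanes, level {lvl}: "
                         + ("some lanes differ" if any_sig
                            else "no significant lane differences"))
        return "\n".join(lines)


def compare_biomass(ds: pd.DataFrame, alpha: float = 0.05,
                    value_col: str = "biomass", level_col: str = "level",
                    lane_col: str = "lane",
                    diagnostics: bool = True) -> ComparisonReport:
    """One-way ANOVA of biomass on treatment level, with lane diagnostics.

    `ds` has one row per tile with dry biomass (mg/cm²), treatment level,
    and flow-lane id.  Degrees of freedom are (groups − 1, N − groups).
    `diagnostics=False` skips the Tukey and Anderson-Darling checks (useful
    in simulation loops that only need the main effect).
    """
    levels = sorted(ds[level_col].unique())
    if len(levels) < 2:
        raise ValueError("need at least two treatment levels")
    samples = [ds.loc[ds[level_col] == lv, value_col].to_numpy(float)
               for lv in levels]
    if any(s.size < 2 for s in samples):
        raise ValueError("every level needs at least 2 tiles")
    F, p = sps.f_oneway(*samples)
    df = (len(levels) - 1, sum(s.size for s in samples) - len(levels))

    means = np.array([s.mean() for s in samples])
    stats_tbl = pd.DataFrame({
        "level": levels,
        "n": [s.size for s in samples],
        "mean": means,
        "sd": [s.std(ddof=1) for s in samples],
    }).set_index("level")
    ratio = means.max() / means.min()

    tukey = {}
    ad_stat, ad_crit = float("nan"), {}
    if diagnostics:
        resid = np.concatenate([s - s.mean() for s in samples])
        import warnings
        with warnings.catch_warnings():
            # scipy >= 1.17 deprecates the critical-value interface in favour
            # of interpolated p-values; the critical-value table is what we
            # report
            warnings.simplefilter("ignore", FutureWarning)
            ad = sps.anderson(resid, dist="norm")
        ad_stat = float(ad.statistic)
        ad_crit = dict(zip(ad.significance_level, ad.critical_values))

        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        for lv in levels:
            sub = ds[ds[level_col] == lv]
            if lane_col in sub and sub[lane_col].nunique() > 1:
                tukey[lv] = pairwise_tukeyhsd(sub[value_col].to_numpy(float),
                                              sub[lane_col].to_numpy(),
                                              alpha=alpha)
    return ComparisonReport(level_stats=stats_tbl, ratio=float(ratio), F=float(F),
                            df=df, p=float(p), tukey_lanes=tukey,
                            ad_statistic=ad_stat, ad_critical=ad_crit)


def hill_localization(hm: HeightMap, sites,
                      cfg: SiteClassificationConfig = None,
                      feature_set: FeatureSet = None) -> dict:
    """Fraction of early-colonization sites that fall on hills.

    Sites are labelled hill / dale / neither by the height thresholds in
    `cfg` (default: hill at >= 3000 μm, dale at <= 0 μm).  Returns the
    percentage of sites on hills plus the per-site label table.

    If a pruned hill `feature_set` is supplied, the secondary per-hill
    ratio is also computed: hills containing at least one site ("attracting"
    hills) versus hills with none.
    """
    cfg = cfg or SiteClassificationConfig()
    labels = classify_sites(hm, sites, cfg)
    frac = 100.0 * (labels["label"] == "hill").mean()
    out = {"fraction_on_hills": float(frac), "labels": labels}
    if feature_set is not None:
        peaks = feature_set.extremes >= cfg.hill_height_min
        hill_ids = np.nonzero(peaks)[0]
        site_feats = feature_set.labels[labels["row"], labels["col"]]
        attracting = np.isin(hill_ids, site_feats)
        n_attr = int(attracting.sum())
        n_not = int(hill_ids.size - n_attr)
        out["hills_attracting"] = n_attr
        out["hills_not_attracting"] = n_not
        out["attract_ratio"] = n_attr / n_not if n_not else np.inf
    return out
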