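"""Genetic-proximity association, variance homogeneity, motion control,
and two-sample power.

Genetic proximity to illness is coded ordinally and treated as a linear
numeric regressor (0 = control twin, 1 = discordant-DZ cotwin,
2 = discordant-MZ cotwin); the phenotype is regressed on proximity plus
age, sex and mean FD, optionally with a cohort indicator when samples
are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .twin_models import intraclass_correlation, pairs_from_table

__all__ = [
    "RegressionResult",
    "LeveneResult",
    "MotionSimilarity",
    "proximity_regression",
    "levene_test",
    "motion_similarity_control",
    "power_two_sample",
]

PROXIMITY_LEVELS = {0: "control twin", 1: "discordant DZ cotwin", 2: "discordant MZ cotwin"}


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    stderr: float
    t_stat: float
    p_value: float
    one_sided: bool
    covariates: dict
    n: int


@dataclass(frozen=True)
class LeveneResult:
    w_stat: float
    p_value: float
    group_sizes: tuple


@dataclass(frozen=True)
class MotionSimilarity:
    icc_mz: float
    icc_dz: float
    difference: float


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    # incremental scan to name the first offending column
    kept: list[int] = []
    for j in range(x.shape[1]):
        sub = x[:, kept + [j]]
        if np.linalg.matrix_rank(sub) == len(kept) + 1:
            kept.append(j)
        else:
            raise ValueError(f"design is rank deficient: column {design.columns[j]!r} "
                             "is collinear with earlier columns")
    raise ValueError("design is rank deficient")


def proximity_regression(records: pd.DataFrame, include_cohort: bool = False,
                         one_sided: bool = False,
                         ordinal_contrast: bool = False) -> RegressionResult:
    """OLS of phenotype on genetic proximity with age/sex/FD covariates.

    ``records`` needs columns group (0/1/2 proximity), phenotype, age, sex,
    fd, and cohort when ``include_cohort``.  Proximity enters as an equally
    spaced numeric regressor by default; ``ordinal_contrast=True`` uses the
    orthogonal linear contrast over the observed levels instead (same test
    when all three levels are present and coding is equally spaced).

    The two-sided p is reported by default; ``one_sided=True`` halves it in
    the direction of a positive slope (the directional hypothesis that
    proximity increases the phenotype).
    """
    required = {"group", "phenotype", "age", "sex", "fd"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table is missing columns {sorted(missing)}")
    levels = np.sort(records["group"].unique())
    if levels.size < 2:
        raise ValueError("need >= 2 distinct proximity levels")
    prox = records["group"].to_numpy(dtype=float)
    if ordinal_contrast:
        centered = {lv: i - (levels.size - 1) / 2 for i, lv in enumerate(levels)}
        prox = np.array([centered[g] for g in records["group"]])
    design = pd.DataFrame({
        "proximity": prox,
        "age": records["age"].to_numpy(dtype=float),
        "sex": records["sex"].to_numpy(dtype=float),
        "fd": records["fd"].to_numpy(dtype=float),
    })
    if include_cohort:
        if "cohort" not in records.columns:
            raise ValueError("include_cohort=True but records has no cohort column")
        dummies = pd.get_dummies(records["cohort"].astype(str), prefix="cohort",
                                 drop_first=True, dtype=float)
        design = pd.concat([design, dummies.reset_index(drop=True)], axis=1)
    design.insert(0, "const", 1.0)
    _check_full_rank(design)
    fit = sm.OLS(records["phenotype"].to_numpy(dtype=float), design).fit()
    slope = float(fit.params["proximity"])
    t_stat = float(fit.tvalues["proximity"])
    p = float(fit.pvalues["proximity"])
    if one_sided:
        p = p / 2.0 if slope > 0 else 1.0 - p / 2.0
    covs = {k: float(v) for k, v in fit.params.items() if k != "proximity"}
    return RegressionResult(slope=slope, stderr=float(fit.bse["proximity"]),
                            t_stat=t_stat, p_value=p, one_sided=one_sided,
                            covariates=covs, n=int(fit.nobs))


def levene_test(groups: list) -> LeveneResult:
    """Levene's variance-homogeneity W using group-mean absolute deviations."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size < 3:
            raise ValueError(f"group {i} has fewer than 3 values")
    devs = [np.abs(a - a.mean()) for a in arrays]
    if all(np.all(d == 0.0) for d in devs):
        raise ValueError("all group deviations are zero; Levene W undefined")
    w, p = stats.levene(*arrays, center="mean")
    return LeveneResult(w_stat=float(w), p_value=float(p),
                        group_sizes=tuple(a.size for a in arrays))


def motion_similarity_control(table: pd.DataFrame) -> MotionSimilarity:
    """Twin-pair similarity of mean FD, by zygosity.

    If head motion itself were strongly heritable, motion similarity could
    masquerade as phenotype heritability; near-equal MZ and DZ FD ICCs
    argue against that confound.  Expects a long cohort table with
    pair_id, zygosity and fd columns.
    """
    pairs = pairs_from_table(table, phenotype="fd")
    icc_mz = intraclass_correlation(pairs, "MZ")
    icc_dz = intraclass_correlation(pairs, "DZ")
    return MotionSimilarity(icc_mz=icc_mz, icc_dz=icc_dz,
                            difference=icc_mz - icc_dz)


def power_two_sample(n1: int, n2: int, effect_size_d: float, alpha: float = 0.05,
                     tails: int = 2) -> float:
    """Power of a two-sample t test at standardized effect size d.

    Uses the noncentral t distribution with noncentrality
    ``d * sqrt(n1*n2/(n1+n2))`` and ``n1+n2-2`` degrees of freedom.
    At d = 0 the power equals alpha exactly.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if effect_size_d < 0:
        raise ValueError("effect_size_d must be nonnegative")
    if not 0.0 < alpha <= 0.5:
        raise ValueError("alpha must lie in (0, 0.5]")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n1 + n2 - 2
    ncp = effect_size_d * np.sqrt(n1 * n2 / (n1 + n2))
    if tails == 1:
        crit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
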