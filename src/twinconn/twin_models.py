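"""Biometric variance decomposition for twin pairs.

The classical twin design contrasts monozygotic (MZ) pairs, who share all
segregating genetic variation, with dizygotic (DZ) pairs, who share on
average half of the additive and a quarter of the dominance genetic
variation.  Under a multivariate-normal model the phenotype vector of a
pair is bivariate normal with a common variance and a zygosity-specific
within-pair covariance,

    cov_MZ = sigma2_A + sigma2_D + sigma2_C
    cov_DZ = 0.5 * sigma2_A + 0.25 * sigma2_D + sigma2_C

where A is additive genetic, D dominance genetic, C shared (common)
environment and E unique environment.  D and C are not jointly
identifiable from MZ/DZ data, so the supported models are ADE, ACE, AE,
CE, DE and E, plus a saturated reference model with free per-zygosity
means, variances and covariance.

Fitting maximizes the Gaussian log-likelihood over path coefficients
(variance components are squared paths, hence nonnegative by
construction) with deterministic multi-start quasi-Newton optimization.
Model fit is summarized by -2LL and an AIC on the degrees-of-freedom
convention ``-2LL - 2*(n_obs - n_params)``; nested models are compared
with naive chi-squared likelihood-ratio tests (no boundary mixture
correction).  Heritability confidence intervals come from the profile
likelihood of the standardized genetic fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TwinPairObservation",
    "VarianceComponents",
    "ModelFit",
    "ModelComparison",
    "ModelSelection",
    "GroupMomentTest",
    "HeritabilityEstimate",
    "pairs_from_table",
    "intraclass_correlation",
    "fit_biometric_model",
    "fit_saturated",
    "model_aic",
    "likelihood_ratio_test",
    "heritability",
    "select_model",
    "compare_group_moments",
]

logger = logging.getLogger(__name__)

ZYGOSITIES = ("MZ", "DZ")
MODELS = ("ADE", "ACE", "AE", "CE", "DE", "E")

# (MZ, DZ) within-pair sharing coefficient of each component's variance.
_SHARING = {"A": (1.0, 0.5), "D": (1.0, 0.25), "C": (1.0, 1.0), "E": (0.0, 0.0)}

_LN_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class TwinPairObservation:
    """One complete twin pair: both phenotypes present."""

    pair_id: str
    zygosity: str
    y1: float
    y2: float

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"zygosity must be one of {ZYGOSITIES}, got {self.zygosity!r}")
        if not (np.isfinite(self.y1) and np.isfinite(self.y2)):
            raise ValueError(f"pair {self.pair_id}: non-finite phenotype")


@dataclass(frozen=True)
class VarianceComponents:
    """Raw and standardized variance components of a fitted model."""

    model: str
    sigma2_a: float
    sigma2_d: float
    sigma2_c: float
    sigma2_e: float
    a2: float
    d2: float
    c2: float
    e2: float
    h2: float

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_d + self.sigma2_c + self.sigma2_e


@dataclass
class ModelFit:
    """A fitted biometric (or saturated) twin model."""

    model: str
    mean: float | None
    components: VarianceComponents | None
    minus2ll: float
    n_params: int
    n_obs: int
    aic: float
    converged: bool
    group_means: dict[str, tuple[float, float]] | None = None
    h2_ci: tuple[float, float] | None = None
    _stats: "_PairMoments | None" = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class ModelComparison:
    nested: str
    full: str
    delta_minus2ll: float
    delta_df: int
    p_value: float


@dataclass(frozen=True)
class ModelSelection:
    best: ModelFit
    table: pd.DataFrame


@dataclass(frozen=True)
class GroupMomentTest:
    t_stat: float
    p_mean: float
    w_stat: float
    p_var: float


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    ci_low: float
    ci_high: float
    level: float


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _ZygMoments:
    n: int
    sum1: float  # sum of y1
    sum2: float  # sum of y2
    ss11: float  # sum of y1^2
    ss22: float  # sum of y2^2
    ss12: float  # sum of y1*y2


@dataclass(frozen=True)
class _PairMoments:
    """Per-zygosity sufficient statistics of the bivariate Gaussian likelihood."""

    mz: _ZygMoments
    dz: _ZygMoments

    @property
    def n_pairs(self) -> int:
        return self.mz.n + self.dz.n

    @property
    def n_obs(self) -> int:
        return 2 * self.n_pairs

    def by_zyg(self, zyg: str) -> _ZygMoments:
        return self.mz if zyg == "MZ" else self.dz


def _moments(pairs: Sequence[TwinPairObservation]) -> _PairMoments:
    out = {}
    for zyg in ZYGOSITIES:
        y1 = np.array([p.y1 for p in pairs if p.zygosity == zyg], dtype=float)
        y2 = np.array([p.y2 for p in pairs if p.zygosity == zyg], dtype=float)
        out[zyg] = _ZygMoments(
            n=y1.size,
            sum1=float(y1.sum()),
            sum2=float(y2.sum()),
            ss11=float((y1 * y1).sum()),
            ss22=float((y2 * y2).sum()),
            ss12=float((y1 * y2).sum()),
        )
    return _PairMoments(mz=out["MZ"], dz=out["DZ"])


def _centered_cross_products(m: _ZygMoments, mu: float) -> tuple[float, float, float]:
    """S11, S22, S12 of sum_i (y_i - mu*1)(y_i - mu*1)^T."""
    s11 = m.ss11 - 2.0 * mu * m.sum1 + m.n * mu * mu
    s22 = m.ss22 - 2.0 * mu * m.sum2 + m.n * mu * mu
    s12 = m.ss12 - mu * (m.sum1 + m.sum2) + m.n * mu * mu
    return s11, s22, s12


def _m2ll_from_cov(stats_: _PairMoments, mu: float, var: float,
                   cov_mz: float, cov_dz: float) -> float:
    """-2 log-likelihood of the common-mean bivariate-normal twin model."""
    total = 0.0
    for zyg, cov in (("MZ", cov_mz), ("DZ", cov_dz)):
        m = stats_.by_zyg(zyg)
        if m.n == 0:
            continue
        det = var * var - cov * cov
        if det <= 0.0 or var <= 0.0:
            return float("inf")
        s11, s22, s12 = _centered_cross_products(m, mu)
        quad = (var * (s11 + s22) - 2.0 * cov * s12) / det
        total += 2.0 * m.n * _LN_2PI + m.n * math.log(det) + quad
    return total


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------


def pairs_from_table(table: pd.DataFrame, phenotype: str = "phenotype") -> list[TwinPairObservation]:
    """Build complete twin pairs from a long cohort table.

    Expects columns ``pair_id``, ``zygosity`` and the phenotype column, one
    row per twin.  Incomplete pairs (fewer or more than two rows, or missing
    phenotypes) are excluded with a logged count.
    """
    pairs: list[TwinPairObservation] = []
    dropped = 0
    for pid, grp in table.groupby("pair_id", sort=True):
        vals = grp[phenotype].to_numpy(dtype=float)
        if len(grp) != 2 or not np.all(np.isfinite(vals)):
            dropped += 1
            continue
        zyg = grp["zygosity"].iloc[0]
        pairs.append(TwinPairObservation(str(pid), str(zyg), float(vals[0]), float(vals[1])))
    if dropped:
        logger.warning("excluded %d incomplete twin pairs", dropped)
    return pairs


def intraclass_correlation(pairs: Iterable[TwinPairObservation],
                           zygosity: str | None = None) -> float:
    """Double-entry intraclass correlation.

    Each pair contributes both orderings (y1, y2) and (y2, y1), which makes
    the estimate invariant to the arbitrary within-pair labeling; the result
    is the Pearson correlation of the doubled sample.
    """
    sel = [p for p in pairs if zygosity is None or p.zygosity == zygosity]
    if len(sel) < 3:
        raise ValueError(f"need at least 3 pairs (got {len(sel)}) for zygosity {zygosity!r}")
    x = np.array([[p.y1, p.y2] for p in sel], dtype=float)
    a = np.concatenate([x[:, 0], x[:, 1]])
    b = np.concatenate([x[:, 1], x[:, 0]])
    if np.std(a) == 0.0:
        raise ValueError("zero phenotype variance; ICC undefined")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# structured model fitting
# ---------------------------------------------------------------------------


def _double_entry_var(stats_: _PairMoments) -> tuple[float, float]:
    """Double-entry mean and variance pooled over zygosity."""
    n = stats_.n_obs
    s = stats_.mz.sum1 + stats_.mz.sum2 + stats_.dz.sum1 + stats_.dz.sum2
    ss = stats_.mz.ss11 + stats_.mz.ss22 + stats_.dz.ss11 + stats_.dz.ss22
    mu = s / n
    var = ss / n - mu * mu
    return mu, var


def _double_entry_corr(m: _ZygMoments) -> float:
    if m.n < 2:
        return 0.0
    n = 2 * m.n
    s = m.sum1 + m.sum2
    ss = m.ss11 + m.ss22
    mu = s / n
    var = ss / n - mu * mu
    if var <= 0.0:
        return 0.0
    cov = m.ss12 / m.n - mu * mu
    return float(np.clip(cov / var, -0.99, 0.99))


def _moment_fractions(model: str, r_mz: float, r_dz: float) -> dict[str, float]:
    """Falconer-style moment estimates of standardized components, clipped
    to the admissible region (negative solutions pinned to the boundary)."""
    f: dict[str, float] = {}
    if model == "AE":
        f["A"] = np.clip(r_mz, 0.0, 0.95)
    elif model == "ADE":
        f["A"] = np.clip(4.0 * r_dz - r_mz, 0.0, 0.95)
        f["D"] = np.clip(2.0 * r_mz - 4.0 * r_dz, 0.0, 0.95 - f["A"])
    elif model == "ACE":
        f["A"] = np.clip(2.0 * (r_mz - r_dz), 0.0, 0.95)
        f["C"] = np.clip(2.0 * r_dz - r_mz, 0.0, 0.95 - f["A"])
    elif model == "DE":
        f["D"] = np.clip(r_mz, 0.0, 0.95)
    elif model == "CE":
        f["C"] = np.clip(0.5 * (r_mz + r_dz), 0.0, 0.95)
    elif model == "E":
        pass
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    f["E"] = max(1.0 - sum(f.values()), 0.05)
    return f


def _start_points(model: str, stats_: _PairMoments) -> list[np.ndarray]:
    """Eight deterministic starting vectors (mu, paths...)."""
    comps = list(model)
    mu0, var0 = _double_entry_var(stats_)
    var0 = max(var0, 1e-12)
    r_mz = _double_entry_corr(stats_.mz)
    r_dz = _double_entry_corr(stats_.dz)
    base = _moment_fractions(model, r_mz, r_dz)

    def fracs_to_x(fracs: dict[str, float]) -> np.ndarray:
        paths = [math.sqrt(max(fracs.get(c, 0.0), 0.0) * var0) for c in comps]
        return np.array([mu0] + paths, dtype=float)

    def scaled(factor: float) -> dict[str, float]:
        gen = {c: base.get(c, 0.0) * factor for c in comps if c != "E"}
        tot = sum(gen.values())
        if tot > 0.95:
            gen = {c: v * 0.95 / tot for c, v in gen.items()}
        gen["E"] = 1.0 - sum(gen.values())
        return gen

    k = len(comps)
    equal = {c: 1.0 / k for c in comps}
    mostly_e = {c: (0.05 if c != "E" else 0.0) for c in comps}
    mostly_e["E"] = 1.0 - sum(mostly_e.values())
    mostly_gen = {c: (0.8 / max(k - 1, 1) if c != "E" else 0.0) for c in comps}
    mostly_gen["E"] = 1.0 - sum(mostly_gen.values())

    candidates = [base, scaled(0.5), scaled(1.5), equal, mostly_e, mostly_gen,
                  scaled(0.25), scaled(0.8)]
    return [fracs_to_x(f) for f in candidates[:8]]


def _model_objective(model: str, stats_: _PairMoments):
    comps = list(model)
    coef_mz = np.array([_SHARING[c][0] for c in comps])
    coef_dz = np.array([_SHARING[c][1] for c in comps])

    def objective(x: np.ndarray) -> float:
        mu = x[0]
        variances = x[1:] ** 2
        var = float(variances.sum())
        cov_mz = float((variances * coef_mz).sum())
        cov_dz = float((variances * coef_dz).sum())
        val = _m2ll_from_cov(stats_, mu, var, cov_mz, cov_dz)
        if not np.isfinite(val):
            return 1e12
        return val

    return objective, comps


def fit_biometric_model(pairs: Sequence[TwinPairObservation], model: str = "ADE",
                        aic_convention: str = "df") -> ModelFit:
    """Maximum-likelihood fit of a structured biometric model.

    Parameters are one grand mean plus one path coefficient per component
    (variance components are the squared paths).  Optimization runs
    L-BFGS-B with finite-difference gradients from 8 deterministic starts
    (moment-based plus fixed perturbations), then a Nelder-Mead polish.
    Non-convergence after all restarts is flagged, never silent.
    """
    model = model.upper()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    stats_ = _moments(pairs)
    if stats_.mz.n < 2 or stats_.dz.n < 2:
        raise ValueError(
            f"need >= 2 pairs per zygosity (got MZ={stats_.mz.n}, DZ={stats_.dz.n})")
    _, var0 = _double_entry_var(stats_)
    if var0 <= 0.0:
        raise ValueError("zero phenotype variance")

    objective, comps = _model_objective(model, stats_)
    best_x, best_val, converged = None, float("inf"), False
    for x0 in _start_points(model, stats_):
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                options={"ftol": 1e-13, "gtol": 1e-10, "maxiter": 500})
        if res.fun < best_val:
            best_x, best_val, converged = res.x, float(res.fun), bool(res.success)
    # simplex polish tightens boundary solutions (e.g. d -> 0)
    res = optimize.minimize(objective, best_x, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000})
    if res.fun <= best_val:
        best_x, best_val = res.x, float(res.fun)
        converged = converged or bool(res.success)
    if not np.isfinite(best_val):
        raise RuntimeError(f"{model} fit failed to produce a finite likelihood")

    mu = float(best_x[0])
    variances = {c: float(v * v) for c, v in zip(comps, best_x[1:])}
    raw = {c: variances.get(c, 0.0) for c in "ADCE"}
    total = sum(raw.values())
    std = {c: raw[c] / total for c in "ADCE"}
    # genetic share of the fitted model (A plus D; zero for CE/E)
    h2 = std["A"] + std["D"]
    components = VarianceComponents(
        model=model,
        sigma2_a=raw["A"], sigma2_d=raw["D"], sigma2_c=raw["C"], sigma2_e=raw["E"],
        a2=std["A"], d2=std["D"], c2=std["C"], e2=std["E"], h2=h2,
    )
    n_params = 1 + len(comps)
    n_obs = stats_.n_obs
    fit = ModelFit(
        model=model, mean=mu, components=components, minus2ll=best_val,
        n_params=n_params, n_obs=n_obs,
        aic=model_aic(best_val, n_obs, n_params, convention=aic_convention),
        converged=converged, _stats=stats_,
    )
    if not converged:
        logger.warning("%s fit flagged as non-converged (-2LL=%.6f)", model, best_val)
    return fit


def fit_saturated(pairs: Sequence[TwinPairObservation],
                  aic_convention: str = "df") -> ModelFit:
    """Saturated reference model: free means, variances and covariance per
    zygosity (10 parameters).  The ML solution is closed form (sample
    moments with denominator n), and -2LL at the MLE is
    ``sum_z n_z * (2*ln(2*pi) + ln|Sigma_z| + 2)``.
    """
    stats_ = _moments(pairs)
    if stats_.mz.n < 3 or stats_.dz.n < 3:
        raise ValueError(
            f"need >= 3 pairs per zygosity (got MZ={stats_.mz.n}, DZ={stats_.dz.n})")
    minus2ll = 0.0
    group_means: dict[str, tuple[float, float]] = {}
    for zyg in ZYGOSITIES:
        m = stats_.by_zyg(zyg)
        m1, m2 = m.sum1 / m.n, m.sum2 / m.n
        v1 = m.ss11 / m.n - m1 * m1
        v2 = m.ss22 / m.n - m2 * m2
        c12 = m.ss12 / m.n - m1 * m2
        det = v1 * v2 - c12 * c12
        if det <= 0.0:
            raise ValueError(f"singular within-{zyg} covariance")
        minus2ll += m.n * (2.0 * _LN_2PI + math.log(det) + 2.0)
        group_means[zyg] = (m1, m2)
    n_obs = stats_.n_obs
    n_params = 10
    return ModelFit(
        model="saturated", mean=None, components=None, minus2ll=minus2ll,
        n_params=n_params, n_obs=n_obs,
        aic=model_aic(minus2ll, n_obs, n_params, convention=aic_convention),
        converged=True, group_means=group_means, _stats=stats_,
    )


def model_aic(minus2ll: float, n_obs: int, n_params: int,
              convention: str = "df") -> float:
    """Akaike Information Criterion.

    Default convention is ``-2LL - 2*(n_obs - n_params)`` (the
    degrees-of-freedom form used by SEM software); ``convention='classic'``
    gives the textbook ``-2LL + 2*n_params``.
    """
    if n_params < 1 or n_params >= n_obs:
        raise ValueError(f"need 1 <= n_params < n_obs (got k={n_params}, n={n_obs})")
    if convention == "df":
        return minus2ll - 2.0 * (n_obs - n_params)
    if convention == "classic":
        return minus2ll + 2.0 * n_params
    raise ValueError(f"unknown AIC convention {convention!r}")


def likelihood_ratio_test(nested: ModelFit, full: ModelFit) -> ModelComparison:
    """Naive chi-squared LRT between nested Gaussian fits on the same data.

    No 50:50 boundary mixture correction is applied; a component estimated
    on its boundary therefore yields the conservative p (up to p = 1 when
    the -2LL values coincide).
    """
    if nested.n_obs != full.n_obs:
        raise ValueError(f"fits are on different data (n_obs {nested.n_obs} vs {full.n_obs})")
    if nested.n_params >= full.n_params:
        raise ValueError("nested model must have fewer parameters than the full model")
    delta = max(nested.minus2ll - full.minus2ll, 0.0)
    ddf = full.n_params - nested.n_params
    p = float(stats.chi2.sf(delta, ddf))
    return ModelComparison(nested=nested.model, full=full.model,
                           delta_minus2ll=delta, delta_df=ddf, p_value=p)


# ---------------------------------------------------------------------------
# profile-likelihood heritability CI
# ---------------------------------------------------------------------------


def _concentrated_m2ll(stats_: _PairMoments, r_mz: float, r_dz: float) -> float:
    """-2LL maximized over the grand mean and total variance in closed form,
    for fixed standardized within-pair correlations (r_mz, r_dz).

    With Sigma_z = sigma2 * R_z and exchangeable R_z, the GLS mean is a
    weighted average with per-zygosity weight 1/(1+r_z) and the ML variance
    is the weighted mean square; both drop out analytically.
    """
    if not (-1.0 < r_mz < 1.0 and -1.0 < r_dz < 1.0):
        return float("inf")
    w = {"MZ": 1.0 / (1.0 + r_mz), "DZ": 1.0 / (1.0 + r_dz)}
    num = den = 0.0
    for zyg in ZYGOSITIES:
        m = stats_.by_zyg(zyg)
        num += w[zyg] * (m.sum1 + m.sum2)
        den += w[zyg] * 2.0 * m.n
    mu = num / den
    n_obs = stats_.n_obs
    quad = 0.0
    logdet = 0.0
    for zyg, r in (("MZ", r_mz), ("DZ", r_dz)):
        m = stats_.by_zyg(zyg)
        if m.n == 0:
            continue
        det = 1.0 - r * r
        s11, s22, s12 = _centered_cross_products(m, mu)
        quad += ((s11 + s22) - 2.0 * r * s12) / det
        logdet += m.n * math.log(det)
    sigma2 = quad / n_obs
    if sigma2 <= 0.0:
        return float("inf")
    return n_obs * _LN_2PI + n_obs * math.log(sigma2) + logdet + n_obs


def _profile_m2ll(model: str, stats_: _PairMoments, h2: float) -> float:
    """Profile -2LL at fixed total genetic fraction h2, minimizing over the
    model's remaining free standardized component."""
    eps = 1e-9
    if model == "AE":
        return _concentrated_m2ll(stats_, h2, 0.5 * h2)
    if model == "DE":
        return _concentrated_m2ll(stats_, h2, 0.25 * h2)
    if model == "ADE":
        # split h2 = a2 + d2; r_mz = h2 fixed, r_dz varies with the split
        def inner(a2: float) -> float:
            return _concentrated_m2ll(stats_, h2, 0.5 * a2 + 0.25 * (h2 - a2))
        if h2 <= eps:
            return inner(0.0)
        res = optimize.minimize_scalar(inner, bounds=(0.0, h2), method="bounded",
                                       options={"xatol": 1e-10})
        return float(res.fun)
    if model == "ACE":
        hi = max(1.0 - h2 - 1e-6, 0.0)

        def inner(c2: float) -> float:
            return _concentrated_m2ll(stats_, h2 + c2, 0.5 * h2 + c2)
        if hi <= eps:
            return inner(0.0)
        res = optimize.minimize_scalar(inner, bounds=(0.0, hi), method="bounded",
                                       options={"xatol": 1e-10})
        return float(res.fun)
    raise ValueError(f"profile CI not defined for model {model!r}")


def heritability(fit: ModelFit, ci_level: float = 0.95) -> HeritabilityEstimate:
    """Heritability (genetic fraction of phenotypic variance) with a
    profile-likelihood confidence interval.

    The interval collects h2 values whose profile -2LL lies within the
    chi-squared(1) quantile of the minimum (3.84 at 95%).  For CE/E models
    the genetic fraction is structurally zero and the interval degenerates.
    """
    if fit.components is None:
        raise ValueError("heritability is undefined for the saturated model")
    if not fit.converged:
        raise ValueError("refusing to profile a non-converged fit")
    if fit._stats is None:
        raise ValueError("fit carries no data summary; refit with fit_biometric_model")
    h2_hat = fit.components.h2
    if fit.model in ("CE", "E"):
        return HeritabilityEstimate(h2=0.0, ci_low=0.0, ci_high=0.0, level=ci_level)

    stats_ = fit._stats
    cutoff = float(stats.chi2.ppf(ci_level, 1))
    h_max = 1.0 - 1e-6

    def g(h2: float) -> float:
        return _profile_m2ll(fit.model, stats_, h2)

    # locate the profile minimum (matches the path fit up to tolerance)
    res = optimize.minimize_scalar(g, bounds=(0.0, h_max), method="bounded",
                                   options={"xatol": 1e-10})
    h2_min, m2ll_min = float(res.x), float(res.fun)
    if m2ll_min > fit.minus2ll + 1e-6:
        logger.warning("profile minimum %.6f above fit -2LL %.6f", m2ll_min, fit.minus2ll)
    m2ll_min = min(m2ll_min, fit.minus2ll)

    def crossing(h2: float) -> float:
        return g(h2) - m2ll_min - cutoff

    if crossing(0.0) <= 0.0:
        lo = 0.0
    else:
        lo = float(optimize.brentq(crossing, 0.0, h2_min, xtol=1e-8))
    if crossing(h_max) <= 0.0:
        hi = 1.0
    else:
        hi = float(optimize.brentq(crossing, h2_min, h_max, xtol=1e-8))
    return HeritabilityEstimate(h2=h2_hat, ci_low=lo, ci_high=hi, level=ci_level)


# ---------------------------------------------------------------------------
# model selection and group moments
# ---------------------------------------------------------------------------


def select_model(fits: Sequence[ModelFit]) -> ModelSelection:
    """Pick the most parsimonious structured model: smallest AIC, ties broken
    toward fewer parameters.  The returned table lists -2LL, AIC and LRTs of
    each structured model against the fullest structured model and against
    the saturated model when one is supplied in ``fits``."""
    structured = [f for f in fits if f.model != "saturated"]
    saturated = next((f for f in fits if f.model == "saturated"), None)
    if not structured:
        raise ValueError("need at least one structured fit")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError("fits are on different data")
    full = max(structured, key=lambda f: f.n_params)
    rows = []
    for f in sorted(structured, key=lambda f: (f.aic, f.n_params)):
        row = {"model": f.model, "minus2ll": f.minus2ll, "n_params": f.n_params,
               "aic": f.aic}
        if f is not full and f.n_params < full.n_params:
            row["p_vs_full"] = likelihood_ratio_test(f, full).p_value
        else:
            row["p_vs_full"] = np.nan
        if saturated is not None and f.n_params < saturated.n_params:
            row["p_vs_saturated"] = likelihood_ratio_test(f, saturated).p_value
        else:
            row["p_vs_saturated"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    best = min(structured, key=lambda f: (f.aic, f.n_params))
    return ModelSelection(best=best, table=table)


def compare_group_moments(mz_pairs: Sequence[TwinPairObservation],
                          dz_pairs: Sequence[TwinPairObservation]) -> GroupMomentTest:
    """Compare MZ vs DZ phenotype mean (two-sample t) and variance (Levene,
    mean-centered) on subject-level values.  Pair clustering is ignored, a
    known limitation of this screen."""
    if len(mz_pairs) < 3 or len(dz_pairs) < 3:
        raise ValueError("need >= 3 pairs per zygosity")
    mz = np.array([v for p in mz_pairs for v in (p.y1, p.y2)], dtype=float)
    dz = np.array([v for p in dz_pairs for v in (p.y1, p.y2)], dtype=float)
    if np.std(mz) == 0.0 and np.std(dz) == 0.0:
        raise ValueError("degenerate variance in both groups")
    t_stat, p_mean = stats.ttest_ind(mz, dz)
    w_stat, p_var = stats.levene(mz, dz, center="mean")
    return GroupMomentTest(t_stat=float(t_stat), p_mean=float(p_mean),
                           w_stat=float(w_stat), p_var=float(p_var))
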