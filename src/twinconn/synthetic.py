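"""Synthetic twin cohorts and multi-paradigm ROI time series.

Every downstream stage of the package is testable against ground truth
generated here: twin phenotypes drawn from the bivariate-normal ACE/ADE
covariance structure, node time series carrying a planted shared
connectivity pattern whose per-subject loading is an affine map of the
twin phenotype, and a three-group discordant cohort with an ordered
group-mean effect plus age/sex/FD covariates.

Demographic defaults emulate the two cohorts this pipeline targets: a
young-adult healthy twin sample (ages 22-36, mean FD ~0.17 mm) and a
middle-aged discordant-cotwin sample with group sizes (32, 30, 10) for
proximity levels control < discordant-DZ < discordant-MZ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import NuisanceSet

__all__ = [
    "VarianceComponentsSpec",
    "TwinCohortSpec",
    "ParadigmSimSpec",
    "DiscordantCohortSpec",
    "MultiParadigmSimulation",
    "simulate_twin_phenotypes",
    "simulate_multiparadigm_timeseries",
    "simulate_discordant_cohort",
]


@dataclass(frozen=True)
class VarianceComponentsSpec:
    """Standardized generative variance fractions of the twin phenotype."""

    a2: float = 0.0
    d2: float = 0.0
    c2: float = 0.0
    e2: float = 1.0
    total_var: float = 1.0
    mean: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a2", "d2", "c2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.e2 <= 1.0:
            raise ValueError(f"e2 must lie in (0, 1], got {self.e2}")
        total = self.a2 + self.d2 + self.c2 + self.e2
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {total})")
        if self.d2 > 0 and self.c2 > 0:
            raise ValueError("d2 and c2 cannot both be positive: the classical "
                             "twin design cannot identify D and C jointly")
        if self.total_var <= 0:
            raise ValueError("total_var must be positive")

    def pair_covariance(self, zygosity: str) -> float:
        """Within-pair phenotype covariance for MZ or DZ pairs."""
        if zygosity == "MZ":
            share = self.a2 + self.d2 + self.c2
        elif zygosity == "DZ":
            share = 0.5 * self.a2 + 0.25 * self.d2 + self.c2
        else:
            raise ValueError(f"unknown zygosity {zygosity!r}")
        return share * self.total_var


@dataclass(frozen=True)
class TwinCohortSpec:
    n_mz: int
    n_dz: int
    components: VarianceComponentsSpec
    seed: int
    age_range: tuple[float, float] = (22.0, 36.0)
    fd_mean: float = 0.17
    fd_sd: float = 0.05
    # within-pair FD correlation, equal for MZ and DZ (motion similarity is
    # familial but shows no extra MZ resemblance)
    fd_pair_corr: float = 0.36

    def __post_init__(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0 or self.n_mz + self.n_dz < 1:
            raise ValueError("need n_mz >= 0, n_dz >= 0 and at least one pair")
        if not -1.0 < self.fd_pair_corr < 1.0:
            raise ValueError("fd_pair_corr must lie in (-1, 1)")


@dataclass(frozen=True)
class ParadigmSimSpec:
    paradigm_id: str
    n_timepoints: int = 200
    tr_seconds: float = 0.72
    n_sessions: int = 2
    shared_weight: float = 1.0
    specific_weight: float = 0.3
    noise_sd: float = 0.5
    kind: str = "rest"  # "rest" or "task"; controls emitted task regressors

    def __post_init__(self) -> None:
        if self.n_timepoints < 16:
            raise ValueError("n_timepoints must be >= 16")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.shared_weight < 0 or self.specific_weight < 0:
            raise ValueError("pattern weights must be nonnegative")
        if self.kind not in ("rest", "task"):
            raise ValueError("kind must be 'rest' or 'task'")


@dataclass(frozen=True)
class DiscordantCohortSpec:
    """Three ordered groups g = 0 (control twin), 1 (discordant-DZ cotwin),
    2 (discordant-MZ cotwin) with an ordered mean effect and covariates."""

    n_per_group: tuple[int, int, int] = (32, 30, 10)
    # 0.5 residual-SD per proximity step: consistent with the one-tailed
    # powers of the design's pairwise group comparisons
    group_means: tuple[float, float, float] = (0.0, 0.5, 1.0)
    beta_age: float = 0.01
    beta_sex: float = 0.1
    beta_fd: float = 0.5
    residual_sd: float = 1.0
    seed: int = 0
    age_means: tuple[float, float, float] = (46.4, 51.1, 43.8)
    age_sds: tuple[float, float, float] = (6.9, 10.1, 11.9)
    male_fractions: tuple[float, float, float] = (0.44, 0.53, 0.70)
    fd_means: tuple[float, float, float] = (0.10, 0.13, 0.13)
    fd_sds: tuple[float, float, float] = (0.05, 0.07, 0.06)

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(n < 0 for n in self.n_per_group):
            raise ValueError("need three nonnegative group sizes")
        if self.residual_sd <= 0:
            raise ValueError("residual sd must be positive")


@dataclass
class MultiParadigmSimulation:
    """Simulated runs plus the ground truth needed for recovery tests.

    The planted shared pattern has two parts: a backbone common to all
    subjects and paradigms, and a circuit subcomponent whose amplitude is
    each subject's latent loading (an affine map of the phenotype).
    ``shared_pattern_edges`` is the population-mean shared pattern;
    ``circuit_pattern_edges`` is the circuit alone, whose top positive
    edges are the natural scoring mask.
    """

    series: dict  # (subject_id, paradigm_id, session) -> n_nodes x T array
    nuisance: dict  # same keys -> NuisanceSet
    shared_pattern_edges: np.ndarray  # population shared pattern, edge order
    circuit_pattern_edges: np.ndarray  # subject-modulated subcomponent
    paradigm_pattern_edges: dict  # paradigm_id -> edge vector
    subject_loadings: pd.Series  # latent circuit loading per subject
    n_nodes: int
    paradigms: tuple[ParadigmSimSpec, ...]
    tr_by_paradigm: dict
    seed: int
    circuit_weight: float = 0.4

    def circuit_mask(self, top_k: int = 50):
        """EdgeMask of the circuit's top-k strongest positive edges."""
        from .cpc import EdgeMask
        order = np.argsort(self.circuit_pattern_edges)[::-1][:top_k]
        iu = np.triu_indices(self.n_nodes, k=1)
        return EdgeMask.from_pairs(
            (int(iu[0][e]), int(iu[1][e])) for e in order)

    def expected_correlation_edges(self, subject_id: str, paradigm_id: str) -> np.ndarray:
        """Population correlation edge vector for one subject/paradigm."""
        p = next(q for q in self.paradigms if q.paradigm_id == paradigm_id)
        lam = float(self.subject_loadings[subject_id])
        num = (p.shared_weight * (self._backbone_edges + lam * self.circuit_weight
                                  * self.circuit_pattern_edges)
               + p.specific_weight * self.paradigm_pattern_edges[paradigm_id])
        den = (p.shared_weight * (1.0 + lam * self.circuit_weight)
               + p.specific_weight + p.noise_sd**2)
        return num / den

    _backbone_edges: np.ndarray | None = None


def _truncnorm_nonneg(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal draws with a floor at 0 (resampled, not clipped)."""
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out < 0
    return out


def simulate_twin_phenotypes(spec: TwinCohortSpec) -> pd.DataFrame:
    """Draw MZ and DZ twin pairs from the bivariate-normal twin model.

    MZ pairs share the full A, D and C variance; DZ pairs share half of A
    and a quarter of D.  Pairs are generated through the Cholesky factor
    of the 2x2 pair covariance — the latent components themselves are
    never materialized, only their implied covariance matters.

    Returns a long cohort table: one row per twin with columns
    subject_id, pair_id, zygosity, group, phenotype, age, sex, fd.
    """
    rng = np.random.default_rng(spec.seed)
    comp = spec.components
    rows = []
    for zyg, n_pairs in (("MZ", spec.n_mz), ("DZ", spec.n_dz)):
        if n_pairs == 0:
            continue
        cov = comp.pair_covariance(zyg)
        sigma = np.array([[comp.total_var, cov], [cov, comp.total_var]])
        chol = np.linalg.cholesky(sigma + 1e-15 * np.eye(2))
        z = rng.standard_normal((n_pairs, 2))
        y = comp.mean + z @ chol.T
        ages = rng.uniform(*spec.age_range, n_pairs)
        fd_cov = spec.fd_sd**2 * np.array([[1.0, spec.fd_pair_corr],
                                           [spec.fd_pair_corr, 1.0]])
        fd_pairs = spec.fd_mean + rng.standard_normal((n_pairs, 2)) @ \
            np.linalg.cholesky(fd_cov).T
        fd = np.clip(fd_pairs, 0.0, None).ravel()
        sexes_pair = rng.integers(0, 2, n_pairs)
        sexes_dz = rng.integers(0, 2, (n_pairs, 2))
        for p in range(n_pairs):
            pid = f"{zyg}{p:05d}"
            for t in range(2):
                # MZ twins are same-sex by definition; DZ twins may differ
                sex = int(sexes_pair[p]) if zyg == "MZ" else int(sexes_dz[p, t])
                rows.append({
                    "subject_id": f"{pid}_{t + 1}",
                    "pair_id": pid,
                    "zygosity": zyg,
                    "group": 0,
                    "phenotype": float(y[p, t]),
                    "age": float(ages[p]),
                    "sex": sex,
                    "fd": float(fd[2 * p + t]),
                })
    table = pd.DataFrame(rows)
    table.attrs["seed"] = spec.seed
    table.attrs["components"] = comp
    return table


def _unit_row_mixing(rng: np.random.Generator, n_nodes: int, q: int) -> np.ndarray:
    """Random node-by-factor mixing with unit-norm rows, so the implied
    covariance has a constant diagonal and correlation equals covariance."""
    w = rng.standard_normal((n_nodes, q))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return w


def _whiten_rows(f: np.ndarray) -> np.ndarray:
    """Demean and rotate/scale factor series so every row has exactly zero
    mean and F @ F.T / T = I.  Rows of the whitened matrix are linear
    combinations of demeaned rows, hence stay orthogonal to the constant."""
    q, t = f.shape
    f = f - f.mean(axis=1, keepdims=True)
    u, _, vt = np.linalg.svd(f, full_matrices=False)
    return math.sqrt(t) * (u @ vt)


def _edge_vector(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _simulate_nuisance(rng: np.random.Generator, n_tp: int, kind: str) -> NuisanceSet:
    motion = np.cumsum(rng.normal(0.0, 0.02, (n_tp, 6)), axis=0)
    fd = np.zeros(n_tp)
    fd[1:] = np.abs(np.diff(motion, axis=0)).sum(axis=1)
    ar = np.zeros(n_tp)
    wm = np.zeros(n_tp)
    csf = np.zeros(n_tp)
    e_wm = rng.standard_normal(n_tp)
    e_csf = rng.standard_normal(n_tp)
    for t in range(1, n_tp):
        wm[t] = 0.5 * wm[t - 1] + e_wm[t]
        csf[t] = 0.5 * csf[t - 1] + e_csf[t]
    task = None
    if kind == "task":
        # alternating 20-timepoint blocks as a single pre-convolved regressor
        task = (np.arange(n_tp) // 20 % 2).astype(float)[:, None]
    return NuisanceSet(task_regressors=task, wm_signal=wm, csf_signal=csf,
                       motion6=motion, fd=fd)


def simulate_multiparadigm_timeseries(
    cohort: pd.DataFrame,
    paradigms: Sequence[ParadigmSimSpec],
    n_nodes: int,
    shared_pattern_seed: int,
    loading_base: float = 1.0,
    loading_slope: float = 0.3,
    circuit_weight: float = 0.4,
    n_factors: int | None = None,
    n_circuit_factors: int = 3,
    emit_nuisance: bool = False,
) -> MultiParadigmSimulation:
    """Node time series carrying a planted shared connectivity pattern.

    Node signals are mixtures of latent edge-community factors.  The
    shared block — identical across paradigms — consists of a backbone
    (mixing ``W_b``, common to all subjects, emulating the stable
    connectome scaffold every paradigm expresses) plus a low-rank circuit
    (mixing ``W_c``) whose variance is scaled per subject by a latent
    loading; a paradigm-specific block and white observation noise
    complete the signal:

        x = sqrt(sw) * (W_b f_b + sqrt(lam * cw) * W_c f_c)
            + sqrt(spw) * W_p g + noise_sd * eps

    with sw/spw the paradigm's shared/specific weights and cw the circuit
    weight.  All mixing matrices have unit-norm rows, so the implied
    covariance has a node-constant diagonal and the correlation matrix is
    an affine image of the planted edge patterns.  Factor series are
    exactly whitened (zero mean, identity sample covariance), so at
    ``noise_sd=0`` the sample correlation reproduces the planted pattern
    exactly.

    The latent circuit loading is an affine map of the twin phenotype,
    ``lam = loading_base + loading_slope * z(phenotype)`` (floored at a
    small positive value), so network scores over circuit edges inherit
    the twin correlation structure.
    """
    if n_nodes < 3:
        raise ValueError("need n_nodes >= 3")
    if not len(paradigms):
        raise ValueError("need at least one paradigm spec")
    q = n_factors if n_factors is not None else max(2, n_nodes // 5)
    qc = n_circuit_factors
    q_total = 2 * q + qc
    min_tp = min(p.n_timepoints for p in paradigms)
    if min_tp <= q_total:
        raise ValueError(f"n_timepoints must exceed total factor count {q_total} "
                         "for exact factor whitening")

    ss = np.random.SeedSequence(shared_pattern_seed)
    w_backbone = _unit_row_mixing(np.random.default_rng(ss.spawn(1)[0]), n_nodes, q)
    backbone = _edge_vector(w_backbone @ w_backbone.T)
    w_circuit = _unit_row_mixing(np.random.default_rng(ss.spawn(1)[0]), n_nodes, qc)
    circuit = _edge_vector(w_circuit @ w_circuit.T)

    paradigm_w = {}
    paradigm_pattern = {}
    for p in paradigms:
        w = _unit_row_mixing(np.random.default_rng(ss.spawn(1)[0]), n_nodes, q)
        paradigm_w[p.paradigm_id] = w
        paradigm_pattern[p.paradigm_id] = _edge_vector(w @ w.T)

    pheno = cohort["phenotype"].to_numpy(dtype=float)
    sd = pheno.std()
    z = (pheno - pheno.mean()) / sd if sd > 0 else np.zeros_like(pheno)
    loadings = np.maximum(loading_base + loading_slope * z, 0.05)
    subject_loadings = pd.Series(loadings, index=cohort["subject_id"].to_numpy())

    series: dict = {}
    nuisance: dict = {}
    tr_by_paradigm = {p.paradigm_id: p.tr_seconds for p in paradigms}
    subj_rngs = {sid: np.random.default_rng(child)
                 for sid, child in zip(cohort["subject_id"], ss.spawn(len(cohort)))}
    for sid in cohort["subject_id"]:
        rng = subj_rngs[sid]
        lam = subject_loadings[sid]
        for p in paradigms:
            for sess in range(1, p.n_sessions + 1):
                f = _whiten_rows(rng.standard_normal((q_total, p.n_timepoints)))
                shared = (w_backbone @ f[:q]
                          + math.sqrt(lam * circuit_weight) * (w_circuit @ f[q:q + qc]))
                x = (math.sqrt(p.shared_weight) * shared
                     + math.sqrt(p.specific_weight) * (paradigm_w[p.paradigm_id] @ f[q + qc:]))
                if p.noise_sd > 0:
                    x = x + p.noise_sd * rng.standard_normal(x.shape)
                series[(sid, p.paradigm_id, sess)] = x
                if emit_nuisance:
                    nuisance[(sid, p.paradigm_id, sess)] = _simulate_nuisance(
                        rng, p.n_timepoints, p.kind)
    shared_pattern = backbone + loading_base * circuit_weight * circuit
    return MultiParadigmSimulation(
        series=series,
        nuisance=nuisance,
        shared_pattern_edges=shared_pattern,
        circuit_pattern_edges=circuit,
        paradigm_pattern_edges=paradigm_pattern,
        subject_loadings=subject_loadings,
        n_nodes=n_nodes,
        paradigms=tuple(paradigms),
        tr_by_paradigm=tr_by_paradigm,
        seed=shared_pattern_seed,
        circuit_weight=circuit_weight,
        _backbone_edges=backbone,
    )


def simulate_discordant_cohort(spec: DiscordantCohortSpec) -> pd.DataFrame:
    """Three-group cohort with an ordered group-mean phenotype effect.

    phenotype = group_mean[g] + beta_age*(age - 47) + beta_sex*sex
                + beta_fd*(fd - 0.12) + Normal(0, residual_sd).

    Age, sex and FD are drawn per group from the spec's demographic
    parameters (FD from a truncated normal with floor 0).
    """
    rng = np.random.default_rng(spec.seed)
    zyg_by_group = {0: None, 1: "DZ", 2: "MZ"}
    rows = []
    for g in (0, 1, 2):
        n = spec.n_per_group[g]
        if n == 0:
            continue
        ages = rng.normal(spec.age_means[g], spec.age_sds[g], n)
        sexes = (rng.random(n) < spec.male_fractions[g]).astype(int)
        fds = _truncnorm_nonneg(rng, spec.fd_means[g], spec.fd_sds[g], n)
        noise = rng.normal(0.0, spec.residual_sd, n)
        pheno = (spec.group_means[g]
                 + spec.beta_age * (ages - 47.0)
                 + spec.beta_sex * sexes
                 + spec.beta_fd * (fds - 0.12)
                 + noise)
        zyg = zyg_by_group[g]
        for i in range(n):
            rows.append({
                "subject_id": f"G{g}_{i:04d}",
                "pair_id": f"G{g}P{i:04d}",
                "zygosity": zyg if zyg is not None else ("MZ" if i % 2 == 0 else "DZ"),
                "group": g,
                "phenotype": float(pheno[i]),
                "age": float(ages[i]),
                "sex": int(sexes[i]),
                "fd": float(fds[i]),
            })
    table = pd.DataFrame(rows)
    table.attrs["seed"] = spec.seed
    return table
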