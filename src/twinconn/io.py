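"""File formats, configuration, QC and the end-to-end pipeline driver.

All tables are TSV with header rows; matrices and time series are
whitespace-delimited text with one ``#`` header line.  Node indices are
0-based everywhere (note: much of the atlas literature is 1-based).
Every output file carries the config hash and seed so a run can be
reproduced exactly from its own provenance header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cpc as cpc_mod
from . import twin_models as tm
from . import risk as risk_mod
from .connectivity import (ConnectivityMatrix, FilterSpec, NuisanceSet,
                           RoiTimeSeries, average_sessions, pearson_connectivity,
                           regress_nuisance, temporal_filter)
from .synthetic import (DiscordantCohortSpec, ParadigmSimSpec, TwinCohortSpec,
                        VarianceComponentsSpec, simulate_discordant_cohort,
                        simulate_multiparadigm_timeseries, simulate_twin_phenotypes)

__all__ = [
    "PipelineConfig",
    "PipelineData",
    "load_config",
    "config_hash",
    "read_inputs",
    "run_pipeline",
    "read_timeseries", "write_timeseries",
    "read_matrix", "write_matrix",
    "read_cohort_table", "write_cohort_table",
    "read_edge_mask", "write_edge_list", "read_edge_list",
    "read_scores", "write_scores",
    "read_nuisance",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["subject_id", "pair_id", "zygosity", "group", "phenotype",
                  "age", "sex", "fd"]
FD_EXCLUSION_MM = 0.5


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def _header_line(**kv) -> str:
    return "# " + " ".join(f"{k}={v}" for k, v in kv.items())


def _parse_header(line: str) -> dict:
    out = {}
    for tok in line.lstrip("#").split():
        k, _, v = tok.partition("=")
        out[k] = v
    return out


def write_timeseries(path: Path, ts: RoiTimeSeries) -> None:
    header = _header_line(subject=ts.subject_id, paradigm=ts.paradigm_id,
                          session=ts.session_id, tr=ts.tr_seconds)
    np.savetxt(path, ts.data, header=header.lstrip("# "), comments="# ")


def read_timeseries(path: Path) -> RoiTimeSeries:
    path = Path(path)
    with open(path) as fh:
        meta = _parse_header(fh.readline())
    data = np.loadtxt(path)
    return RoiTimeSeries(meta.get("subject", path.stem), meta.get("paradigm", "?"),
                         meta.get("session", "1"), data, float(meta.get("tr", 1.0)))


def write_matrix(path: Path, m: ConnectivityMatrix, **extra) -> None:
    header = _header_line(subject=m.subject_id, paradigm=m.paradigm_id, **extra)
    np.savetxt(path, m.values, header=header.lstrip("# "), comments="# ")


def read_matrix(path: Path) -> ConnectivityMatrix:
    path = Path(path)
    with open(path) as fh:
        meta = _parse_header(fh.readline())
    values = np.loadtxt(path)
    return ConnectivityMatrix(meta.get("subject", path.stem),
                              meta.get("paradigm", "?"), values)


def write_cohort_table(path: Path, table: pd.DataFrame, **extra) -> None:
    with open(path, "w") as fh:
        if extra:
            fh.write(_header_line(**extra) + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_cohort_table(path: Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    if table.empty:
        raise ValueError(f"{path}: empty metadata file")
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if (table["fd"] < 0).any():
        bad = table.index[table["fd"] < 0][0]
        raise ValueError(f"{path}: negative FD at row {bad}")
    if not table["zygosity"].isin(["MZ", "DZ"]).all():
        raise ValueError(f"{path}: zygosity must be MZ or DZ")
    return table


def write_edge_list(path: Path, edges: np.ndarray, n_nodes: int, **extra) -> None:
    """Edge vector in canonical order -> TSV (node_i, node_j, weight)."""
    iu = np.triu_indices(n_nodes, k=1)
    df = pd.DataFrame({"node_i": iu[0], "node_j": iu[1], "weight": edges})
    with open(path, "w") as fh:
        fh.write(_header_line(n_nodes=n_nodes, **extra) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_edge_list(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_edge_mask(path: Path) -> cpc_mod.EdgeMask:
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c for c in ("node_i", "node_j") if c in df.columns]
    if len(cols) != 2:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["node_i", "node_j"])
    return cpc_mod.EdgeMask.from_pairs(zip(df["node_i"], df["node_j"]))


def write_scores(path: Path, scores: pd.DataFrame, **extra) -> None:
    with open(path, "w") as fh:
        if extra:
            fh.write(_header_line(**extra) + "\n")
        scores.to_csv(fh, sep="\t", index=False)


def read_scores(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "subject_id" not in df.columns or "score" not in df.columns:
        raise ValueError(f"{path}: scores file needs subject_id and score columns")
    return df


def read_nuisance(path: Path) -> NuisanceSet:
    """Nuisance TSV: columns wm, csf, fd, motion1..motion6, task1..taskK."""
    df = pd.read_csv(path, sep="\t", comment="#")
    motion_cols = [c for c in df.columns if c.startswith("motion")]
    task_cols = [c for c in df.columns if c.startswith("task")]
    return NuisanceSet(
        task_regressors=df[task_cols].to_numpy() if task_cols else None,
        wm_signal=df["wm"].to_numpy() if "wm" in df else None,
        csf_signal=df["csf"].to_numpy() if "csf" in df else None,
        motion6=df[sorted(motion_cols)].to_numpy() if motion_cols else None,
        fd=df["fd"].to_numpy() if "fd" in df else None,
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Driver configuration; ``mode`` selects synthetic generation or files.

    In synthetic mode the generator parameters below define the cohort; in
    files mode the ``*_dir``/``*_path`` entries must exist at run start.
    """

    mode: str = "synthetic"
    seed: int = 0
    # synthetic cohort
    n_mz: int = 60
    n_dz: int = 40
    a2: float = 0.52
    d2: float = 0.0
    c2: float = 0.0
    n_nodes: int = 50
    n_paradigms: int = 4
    n_timepoints: int = 200
    n_sessions: int = 2
    tr_seconds: float = 0.72
    shared_weight: float = 1.0
    specific_weight: float = 0.3
    noise_sd: float = 0.5
    mask_top_k: int = 50
    # discordant branch
    discordant_sizes: tuple = (32, 30, 10)
    discordant_means: tuple = (0.0, 0.5, 1.0)
    # files mode
    ts_dir: str | None = None
    nuisance_dir: str | None = None
    mask_path: str | None = None
    metadata_path: str | None = None
    # analysis flags
    models: tuple = ("ADE", "ACE", "AE", "E")
    filter_task: str = "highpass:0.008"
    filter_rest: str = "bandpass:0.008-0.1"
    fisher_z: bool = False
    center_cpc: bool = False
    one_sided: bool = False
    aic_convention: str = "df"
    fd_threshold: float = FD_EXCLUSION_MM
    apply_filter: bool = False

    @property
    def e2(self) -> float:
        return 1.0 - self.a2 - self.d2 - self.c2


def load_config(path: Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("discordant_sizes", "discordant_means", "models"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# input reading and QC
# ---------------------------------------------------------------------------


@dataclass
class PipelineData:
    metadata: pd.DataFrame
    timeseries: dict  # (subject, paradigm, session) -> RoiTimeSeries
    nuisance: dict  # same keys -> NuisanceSet (may be empty)
    mask: cpc_mod.EdgeMask | None
    excluded_subjects: list


def read_inputs(config: PipelineConfig) -> PipelineData:
    """Read and schema-check files-mode inputs, applying the mean-FD QC rule.

    Subjects whose mean FD is at or above ``config.fd_threshold`` (default
    0.5 mm) are flagged and excluded from the returned metadata.
    """
    if config.metadata_path is None:
        raise ValueError("files mode requires metadata_path")
    metadata = read_cohort_table(Path(config.metadata_path))
    mean_fd = metadata.groupby("subject_id")["fd"].mean()
    excluded = sorted(mean_fd.index[mean_fd >= config.fd_threshold])
    if excluded:
        logger.warning("excluding %d subject(s) with mean FD >= %.2f mm: %s",
                       len(excluded), config.fd_threshold, excluded)
        metadata = metadata[~metadata["subject_id"].isin(excluded)]
    timeseries: dict = {}
    nuisance: dict = {}
    if config.ts_dir is not None:
        ts_dir = Path(config.ts_dir)
        if not ts_dir.is_dir():
            raise FileNotFoundError(f"ts_dir {ts_dir} does not exist")
        for path in sorted(ts_dir.glob("*.tsv")):
            ts = read_timeseries(path)
            if ts.subject_id in excluded:
                continue
            key = (ts.subject_id, ts.paradigm_id, ts.session_id)
            timeseries[key] = ts
            if config.nuisance_dir is not None:
                npath = Path(config.nuisance_dir) / path.name
                if npath.exists():
                    nuisance[key] = read_nuisance(npath)
    mask = read_edge_mask(Path(config.mask_path)) if config.mask_path else None
    return PipelineData(metadata=metadata, timeseries=timeseries,
                        nuisance=nuisance, mask=mask, excluded_subjects=excluded)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def _connectivity_stage(config: PipelineConfig, timeseries: dict,
                        nuisance: dict) -> dict:
    """(subject, paradigm, session) series -> session-averaged matrices."""
    by_sp: dict = {}
    for (sid, pid, sess), ts in timeseries.items():
        try:
            out = regress_nuisance(ts, nuisance.get((sid, pid, sess)))
            if config.apply_filter:
                spec = FilterSpec.parse(
                    config.filter_rest if "rest" in str(pid) else config.filter_task)
                out = temporal_filter(out, spec)
            mat = pearson_connectivity(out)
        except Exception as exc:
            raise RuntimeError(
                f"connectivity stage failed for subject {sid}, paradigm {pid}, "
                f"session {sess}: {exc}") from exc
        by_sp.setdefault((sid, pid), []).append(mat)
    return {key: average_sessions(mats, fisher_z=config.fisher_z)
            for key, mats in sorted(by_sp.items())}


def _cpc_stage(config: PipelineConfig, matrices: dict, mask: cpc_mod.EdgeMask) -> pd.DataFrame:
    """Per-subject CPC extraction and network scoring -> scores table."""
    by_subject: dict = {}
    for (sid, pid), mat in matrices.items():
        by_subject.setdefault(sid, []).append(cpc_mod.vectorize_edges(mat))
    rows = []
    for sid in sorted(by_subject):
        try:
            result = cpc_mod.compute_cpc(by_subject[sid], center=config.center_cpc)
            score = cpc_mod.network_score(result, mask)
        except Exception as exc:
            raise RuntimeError(f"cpc stage failed for subject {sid}: {exc}") from exc
        rows.append({"subject_id": sid, "score": score,
                     "pc1_variance_explained": float(result.variance_explained[0])})
    return pd.DataFrame(rows)


def _heritability_stage(config: PipelineConfig, cohort: pd.DataFrame,
                        phenotype: str = "phenotype") -> dict:
    pairs = tm.pairs_from_table(cohort, phenotype=phenotype)
    fits = [tm.fit_biometric_model(pairs, m, aic_convention=config.aic_convention)
            for m in config.models]
    fits.append(tm.fit_saturated(pairs, aic_convention=config.aic_convention))
    selection = tm.select_model(fits)
    best_h2 = tm.heritability(selection.best)
    mz = [p for p in pairs if p.zygosity == "MZ"]
    dz = [p for p in pairs if p.zygosity == "DZ"]
    return {
        "pairs": pairs,
        "icc_mz": tm.intraclass_correlation(pairs, "MZ"),
        "icc_dz": tm.intraclass_correlation(pairs, "DZ"),
        "fits": fits,
        "selection": selection,
        "heritability": best_h2,
        "moments": tm.compare_group_moments(mz, dz),
    }


def _fit_summary_table(fits: list) -> pd.DataFrame:
    rows = []
    for f in fits:
        c = f.components
        rows.append({
            "model": f.model,
            "mean": f.mean if f.mean is not None else np.nan,
            "a2": c.a2 if c else np.nan, "d2": c.d2 if c else np.nan,
            "c2": c.c2 if c else np.nan, "e2": c.e2 if c else np.nan,
            "h2": c.h2 if c else np.nan,
            "minus2ll": f.minus2ll, "n_params": f.n_params, "aic": f.aic,
            "converged": f.converged,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir: Path | None = None) -> dict:
    """Execute the full analysis and optionally write the output bundle.

    Synthetic mode runs both branches: a healthy-twin branch
    (simulate -> connectivity -> CPC -> network score -> biometric models)
    and a discordant-cohort branch (proximity regression, Levene variance
    test, motion-similarity control, power).  Deterministic given the
    config seed; every output carries the config hash and seed.
    """
    if config.mode == "synthetic":
        bundle = _run_synthetic(config)
    elif config.mode == "files":
        bundle = _run_files(config)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    if outdir is not None:
        _write_bundle(config, bundle, Path(outdir))
    return bundle


def _run_synthetic(config: PipelineConfig) -> dict:
    comp = VarianceComponentsSpec(a2=config.a2, d2=config.d2, c2=config.c2,
                                  e2=config.e2)
    cohort = simulate_twin_phenotypes(
        TwinCohortSpec(n_mz=config.n_mz, n_dz=config.n_dz, components=comp,
                       seed=config.seed))
    paradigms = [
        ParadigmSimSpec(paradigm_id=f"par{k}", n_timepoints=config.n_timepoints,
                        tr_seconds=config.tr_seconds, n_sessions=config.n_sessions,
                        shared_weight=config.shared_weight,
                        specific_weight=config.specific_weight,
                        noise_sd=config.noise_sd)
        for k in range(config.n_paradigms)]
    sim = simulate_multiparadigm_timeseries(
        cohort, paradigms, n_nodes=config.n_nodes,
        shared_pattern_seed=config.seed + 1)
    timeseries = {
        (sid, pid, str(sess)): RoiTimeSeries(sid, pid, str(sess), data,
                                             config.tr_seconds)
        for (sid, pid, sess), data in sim.series.items()}
    matrices = _connectivity_stage(config, timeseries, {})
    # score over the planted circuit's strongest positive edges
    mask = sim.circuit_mask(top_k=config.mask_top_k)
    scores = _cpc_stage(config, matrices, mask)
    scored = cohort.merge(scores, on="subject_id")
    herit = _heritability_stage(config, scored, phenotype="score")
    motion = risk_mod.motion_similarity_control(cohort)

    discordant = simulate_discordant_cohort(DiscordantCohortSpec(
        n_per_group=tuple(config.discordant_sizes),
        group_means=tuple(config.discordant_means),
        seed=config.seed + 2))
    regression = risk_mod.proximity_regression(discordant, one_sided=config.one_sided)
    levene = risk_mod.levene_test(
        [g["phenotype"].to_numpy() for _, g in discordant.groupby("group")])
    power = risk_mod.power_two_sample(
        n1=int(config.discordant_sizes[2]), n2=int(config.discordant_sizes[1]),
        effect_size_d=0.8, alpha=0.05, tails=1)
    return {
        "cohort": cohort, "scores": scored, "mask": mask,
        "shared_pattern": sim.shared_pattern_edges,
        "heritability": herit, "motion": motion,
        "discordant": discordant, "regression": regression,
        "levene": levene, "power": power,
    }


def _run_files(config: PipelineConfig) -> dict:
    data = read_inputs(config)
    bundle: dict = {"metadata": data.metadata,
                    "excluded_subjects": data.excluded_subjects}
    if data.timeseries:
        if data.mask is None:
            raise ValueError("files mode with time series requires mask_path")
        matrices = _connectivity_stage(config, data.timeseries, data.nuisance)
        scores = _cpc_stage(config, matrices, data.mask)
        scored = data.metadata.merge(scores, on="subject_id")
        bundle["scores"] = scored
        if set(scored["zygosity"]) >= {"MZ", "DZ"}:
            bundle["heritability"] = _heritability_stage(config, scored,
                                                         phenotype="score")
    if "group" in data.metadata.columns and data.metadata["group"].nunique() >= 2:
        pheno_col = "score" if "scores" in bundle else "phenotype"
        table = bundle.get("scores", data.metadata)
        bundle["regression"] = risk_mod.proximity_regression(
            table.rename(columns={pheno_col: "phenotype"})
            if pheno_col != "phenotype" else table,
            one_sided=config.one_sided)
    return bundle


def _write_bundle(config: PipelineConfig, bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"config_sha256": config_hash(config), "seed": config.seed}
    if "cohort" in bundle:
        write_cohort_table(outdir / "cohort.tsv", bundle["cohort"], **prov)
    if "scores" in bundle:
        write_scores(outdir / "scores.tsv", bundle["scores"], **prov)
    if "shared_pattern" in bundle:
        write_edge_list(outdir / "shared_pattern.tsv", bundle["shared_pattern"],
                        n_nodes=config.n_nodes, **prov)
    if "heritability" in bundle:
        herit = bundle["heritability"]
        with open(outdir / "fits.tsv", "w") as fh:
            fh.write(_header_line(**prov) + "\n")
            _fit_summary_table(herit["fits"]).to_csv(fh, sep="\t", index=False)
        with open(outdir / "comparison.tsv", "w") as fh:
            fh.write(_header_line(**prov) + "\n")
            herit["selection"].table.to_csv(fh, sep="\t", index=False)
    if "regression" in bundle:
        reg = bundle["regression"]
        with open(outdir / "risk.tsv", "w") as fh:
            fh.write(_header_line(**prov) + "\n")
            pd.DataFrame([{"slope": reg.slope, "stderr": reg.stderr,
                           "t": reg.t_stat, "p": reg.p_value, "n": reg.n,
                           "one_sided": reg.one_sided}]).to_csv(
                fh, sep="\t", index=False)
    if "discordant" in bundle:
        write_cohort_table(outdir / "discordant.tsv", bundle["discordant"], **prov)
    logger.info("pipeline outputs written to %s (config %s)", outdir,
                prov["config_sha256"])
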