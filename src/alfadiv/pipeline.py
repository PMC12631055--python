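"""Configuration-driven orchestration of the analysis stages.

A run is described by a YAML/dict config validated into ``RunConfig``
(unknown keys rejected).  Stages execute in dependency order; every
output file is recorded with a SHA-256 content hash in a JSON run
report.  Per-stage seeds derive deterministically from the single
global seed via ``numpy.random.SeedSequence([seed, stage_index])``, so
any stage can be re-run in isolation and reproduce its output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import concordance, fst, geno, selection, spatial, structure, synthetic

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "grm", "adjust", "structure", "mantel",
               "select", "fst_scan"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_groups: int = 6
    group_size: int = 30
    n_markers: int = 2000
    fst_neutral: float = 0.0625
    outlier_fraction: float = 0.02
    fst_outlier: float = 0.5
    pool_chromosomes: int | None = 400
    n_rows: int = 10
    n_cols: int = 44
    n_traits: int = 5
    mu: float = 10.0
    var_additive: float = 1.0
    var_spatial: float = 1.0
    var_residual: float = 1.0
    spatial_length_scale: float = 4.0


class GrmConfig(_Strict):
    freq: str | None = None
    marker_map: str | None = None
    n_scale: float = 16.0
    auto_scale: bool = False
    max_missing: float = 0.05
    maf_min: float = 0.01
    drop_unmapped: bool = True


class AdjustConfig(_Strict):
    plots: str | None = None
    grm: str | None = None
    knots: tuple[int, int] = (6, 8)
    knot_grid: list[tuple[int, int]] | None = None
    s_structure: str = "identity"


class StructureConfig(_Strict):
    traits: str | None = None
    k_min: int = 1
    k_max: int = 10
    n_restarts: int = 20
    variance_target: float = 0.9


class MantelConfig(_Strict):
    freq: str | None = None
    traits: str | None = None
    n_permutations: int = 999
    shrinkage: float | str = "auto"


class SelectConfig(_Strict):
    traits: str | None = None
    groups: str | None = None
    alpha: float = 0.05
    max_runs: int = 100
    n_trees: int = 500
    prefilter_threshold: float = 0.9


class FstScanConfig(_Strict):
    freq: str | None = None
    groups: str | None = None
    neutral_size: int = 5000
    q_threshold: float = 0.05
    min_group_size: int = 3
    gff: str | None = None
    window: int = 500


class RunConfig(_Strict):
    stages: list[str] = Field(default_factory=list)
    outdir: str = "alfadiv_run"
    seed: int = 1
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    grm: GrmConfig = Field(default_factory=GrmConfig)
    adjust: AdjustConfig = Field(default_factory=AdjustConfig)
    structure: StructureConfig = Field(default_factory=StructureConfig)
    mantel: MantelConfig = Field(default_factory=MantelConfig)
    select: SelectConfig = Field(default_factory=SelectConfig)
    fst_scan: FstScanConfig = Field(default_factory=FstScanConfig)


def validate_config(source) -> RunConfig:
    """Validate a config mapping, YAML text, or YAML file path."""
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, (str, Path)) and Path(source).exists():
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    elif isinstance(source, str):
        data = yaml.safe_load(source) or {}
    else:
        data = dict(source or {})
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as e:
        raise ValueError(f"invalid configuration: {e}") from None
    unknown = [s for s in cfg.stages if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    # cross-stage requirements when the producing stage is absent
    has = set(cfg.stages)
    def need(stage, field_, value):
        if stage in has and value is None and "simulate" not in has:
            raise ValueError(f"stage {stage!r} requires {field_!r} "
                             "(no simulate stage to provide it)")
    need("grm", "grm.freq", cfg.grm.freq)
    need("fst_scan", "fst_scan.groups", cfg.fst_scan.groups)
    need("select", "select.groups", cfg.select.groups)
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed."""
    idx = STAGE_ORDER.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config) -> dict:
    """Execute the configured stages; return the run report dict.

    The report lists each executed stage with timing and its output
    files with SHA-256 hashes, and is also written to
    ``<outdir>/run_report.json``.
    """
    cfg = validate_config(config)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGE_ORDER if s in cfg.stages]
    report: dict = {"seed": cfg.seed, "stages": [], "status": "complete"}
    artifacts: dict[str, Path] = {}

    for stage in ordered:
        t0 = time.time()
        entry = {"stage": stage, "seed": stage_seed(cfg.seed, stage),
                 "outputs": {}, "status": "ok"}
        try:
            files = _STAGE_RUNNERS[stage](cfg, out, artifacts,
                                          entry["seed"])
            for name, path in files.items():
                entry["outputs"][name] = {"path": str(path),
                                          "sha256": _sha256(path)}
                artifacts[name] = path
        except Exception as e:
            logger.error("stage %s failed: %s", stage, e)
            entry["status"] = f"failed: {e}"
            report["status"] = "partial"
            entry["elapsed_s"] = round(time.time() - t0, 3)
            report["stages"].append(entry)
            break
        entry["elapsed_s"] = round(time.time() - t0, 3)
        report["stages"].append(entry)

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


# ---------------------------------------------------------------------------
# Stage runners (return {artifact name: written path})
# ---------------------------------------------------------------------------

def _resolve(explicit: str | None, artifacts: dict, key: str,
             what: str) -> Path:
    if explicit:
        return Path(explicit)
    if key in artifacts:
        return artifacts[key]
    raise FileNotFoundError(f"no input available for {what}")


def _run_simulate(cfg: RunConfig, out: Path, artifacts, seed) -> dict:
    p = cfg.simulate
    truth_g = synthetic.simulate_group_frequencies(
        p.n_groups, p.n_markers, p.fst_neutral, p.outlier_fraction,
        p.fst_outlier, seed=seed,
    )
    sizes = {g: p.group_size for g in truth_g.group_labels}
    afm, group_of = synthetic.simulate_panel(
        sizes, truth_g, pool_chromosomes=p.pool_chromosomes, seed=seed + 1,
    )
    grm = geno.compute_relationship(afm)
    acc = afm.accession_ids
    n_plots = p.n_rows * p.n_cols
    layout_acc = list(acc)[:n_plots] if len(acc) >= n_plots else list(acc)
    layout = synthetic.simulate_trial(p.n_rows, p.n_cols, layout_acc,
                                      seed=seed + 2)
    surface = synthetic.simulate_spatial_surface(
        p.n_rows, p.n_cols, p.spatial_length_scale, p.var_spatial,
        seed=seed + 3,
    )
    plots, truth = synthetic.simulate_phenotypes(
        grm, layout, surface, p.var_additive, p.var_residual, p.n_traits,
        mu=p.mu, group_of=group_of, seed=seed + 4,
    )
    truth.group_truth = truth_g

    files = {
        "freq": out / "sim_freq.tsv",
        "marker_map": out / "sim_markers.tsv",
        "plots": out / "sim_plots.tsv",
        "groups": out / "sim_groups.tsv",
        "truth": out / "sim_truth.json",
    }
    geno.write_frequency_table(afm, files["freq"], files["marker_map"])
    plots.to_csv(files["plots"], sep="\t", index=False)
    pd.Series(group_of, name="group").rename_axis("accession") \
        .to_csv(files["groups"], sep="\t")
    truth.to_json(files["truth"])
    return files


def _load_afm(cfg: RunConfig, artifacts,
              freq_path: str | None = None) -> geno.AlleleFrequencyMatrix:
    freq = _resolve(freq_path or cfg.grm.freq, artifacts, "freq",
                    "frequency table")
    mmap = cfg.grm.marker_map or artifacts.get("marker_map")
    afm = geno.read_frequency_table(freq, mmap)
    afm = geno.filter_markers(afm, cfg.grm.max_missing, cfg.grm.maf_min,
                              cfg.grm.drop_unmapped)
    return geno.impute_missing(afm)


def _run_grm(cfg: RunConfig, out: Path, artifacts, seed) -> dict:
    afm = _load_afm(cfg, artifacts)
    grm = geno.compute_relationship(afm, cfg.grm.n_scale, cfg.grm.auto_scale)
    path = out / "grm.tsv"
    geno.write_relationship(grm, path)
    return {"grm": path}


def _run_adjust(cfg: RunConfig, out: Path, artifacts, seed) -> dict:
    plots = pd.read_csv(
        _resolve(cfg.adjust.plots, artifacts, "plots", "plot table"),
        sep="\t",
    )
    grm = geno.read_relationship(
        _resolve(cfg.adjust.grm, artifacts, "grm", "relationship matrix"))
    knot_grid = [tuple(k) for k in cfg.adjust.knot_grid] \
        if cfg.adjust.knot_grid else None
    adjusted, fits = spatial.adjust_trial_traits(
        plots, grm, knot_grid=knot_grid, knots=tuple(cfg.adjust.knots),
        s_structure=cfg.adjust.s_structure,
    )
    std = spatial.standardize_traits(adjusted)
    files = {"adjusted_traits": out / "adjusted_traits.tsv",
             "fit_summary": out / "spatial_fits.json"}
    std.rename_axis("accession").to_csv(files["adjusted_traits"], sep="\t")
    summary = {
        tr: {"mu": f.mu, "var_additive": f.var_additive,
             "var_spatial": f.var_spatial, "var_residual": f.var_residual,
             "knots": list(f.knots), "aic": f.aic, "loglik": f.loglik}
        for tr, f in fits.items()
    }
    with open(files["fit_summary"], "w") as fh:
        json.dump(summary, fh, indent=1)
    return files


def _read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _run_structure(cfg: RunConfig, out: Path, artifacts, seed) -> dict:
    traits = _read_traits(_resolve(cfg.structure.traits, artifacts,
                                   "adjusted_traits", "trait matrix"))
    scores, loadings, var_frac = structure.run_pca(traits)
    d = structure.n_pcs_for_variance(var_frac, cfg.structure.variance_target)
    sol = structure.kmeans_bic_scan(
        scores.iloc[:, :d], range(cfg.structure.k_min, cfg.structure.k_max + 1),
        n_restarts=cfg.structure.n_restarts, seed=seed,
    )
    dapc = structure.run_dapc(traits, sol.assignment, retained_pcs=d) \
        if sol.k >= 2 else None
    files = {
        "pca_scores": out / "pca_scores.tsv",
        "pca_loadings": out / "pca_loadings.tsv",
        "bic_curve": out / "bic_curve.tsv",
        "assignment": out / "cluster_assignment.tsv",
    }
    scores.rename_axis("accession").to_csv(files["pca_scores"], sep="\t")
    loadings.rename_axis("trait").to_csv(files["pca_loadings"], sep="\t")
    pd.Series(sol.bic_by_k, name="bic").rename_axis("k") \
        .to_csv(files["bic_curve"], sep="\t")
    sol.assignment.rename_axis("accession") \
        .to_csv(files["assignment"], sep="\t")
    if dapc is not None:
        files["dapc_loadings"] = out / "dapc_trait_loadings.tsv"
        dapc.trait_loadings.rename_axis("trait") \
            .to_csv(files["dapc_loadings"], sep="\t")
    return files


def _run_mantel(cfg: RunConfig, out: Path, artifacts, seed) -> dict:
    afm = _load_afm(cfg, artifacts, cfg.mantel.freq)
    traits = _read_traits(_resolve(cfg.mantel.traits, artifacts,
                                   "adjusted_traits", "trait matrix"))
    common = [a for a in afm.accession_ids if a in set(traits.index)]
    if len(common) < 4:
        raise ValueError("fewer than 4 accessions shared between panels")
    keep = [afm.accession_ids.index(a) for a in common]
    sub = geno.AlleleFrequencyMatrix(
        values=afm.values[keep], missing_mask=afm.missing_mask[keep],
        accession_ids=common, marker_ids=afm.marker_ids,
        marker_map=afm.marker_map,
    )
    gd = concordance.genetic_distance(sub)
    pdm = concordance.phenotypic_distance(traits.loc[common],
                                          shrinkage=cfg.mantel.shrinkage)
    res = concordance.mantel_test(gd, pdm, cfg.mantel.n_permutations,
                                  seed=seed)
    files = {"genetic_distance": out / "genetic_distance.tsv",
             "phenotypic_distance": out / "phenotypic_distance.tsv",
             "mantel": out / "mantel.json"}
    gd.to_frame().to_csv(files["genetic_distance"], sep="\t",
                         index_label="accession")
    pdm.to_frame().to_csv(files["phenotypic_distance"], sep="\t",
                          index_label="accession")
    with open(files["mantel"], "w") as fh:
        json.dump({"r_obs": res.r_obs, "p_value": res.p_value,
                   "n_permutations": res.n_permutations,
                   "method": res.method, "seed": res.seed}, fh, indent=1)
    return files


def _read_groups(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]


def _run_select(cfg: RunConfig, out: Path, artifacts, seed) -> dict:
    traits = _read_traits(_resolve(cfg.select.traits, artifacts,
                                   "adjusted_traits", "trait matrix"))
    groups = _read_groups(_resolve(cfg.select.groups, artifacts, "groups",
                                   "group table"))
    kept, dropped = selection.prefilter_correlated(
        traits, cfg.select.prefilter_threshold)
    res = selection.boruta_select(
        traits[kept], groups.reindex(traits.index), alpha=cfg.select.alpha,
        max_runs=cfg.select.max_runs, n_trees=cfg.select.n_trees, seed=seed,
    )
    files = {"boruta_decisions": out / "boruta_decisions.tsv",
             "prefilter_dropped": out / "prefilter_dropped.tsv"}
    selection.importance_table(res).to_csv(files["boruta_decisions"],
                                           sep="\t")
    dropped.to_csv(files["prefilter_dropped"], sep="\t", index=False)
    return files


def _run_fst_scan(cfg: RunConfig, out: Path, artifacts, seed) -> dict:
    afm = _load_afm(cfg, artifacts, cfg.fst_scan.freq)
    groups = _read_groups(_resolve(cfg.fst_scan.groups, artifacts, "groups",
                                   "group table"))
    annotation = None
    if cfg.fst_scan.gff:
        annotation = fst.read_gene_models(cfg.fst_scan.gff)
    res = fst.scan(
        afm, groups, neutral=cfg.fst_scan.neutral_size,
        q_threshold=cfg.fst_scan.q_threshold,
        min_group_size=cfg.fst_scan.min_group_size,
        annotation=annotation, window=cfg.fst_scan.window, seed=seed,
    )
    files = {"fst_summary": out / "fst_summary.tsv"}
    res["summary"].to_csv(files["fst_summary"], sep="\t", index=False)
    outlier_tabs = []
    for pair_res in res["pairs"]:
        name = f"fst_{pair_res.pair[0]}_{pair_res.pair[1]}"
        path = out / f"{name}.tsv"
        pair_res.table.to_csv(path, sep="\t", index=False)
        files[name] = path
        outlier_tabs.append(pair_res.table[pair_res.table["outlier"]])
    combined = pd.concat(outlier_tabs).drop_duplicates("marker") \
        if outlier_tabs else pd.DataFrame(columns=["marker", "chrom", "pos"])
    bed = out / "fst_outliers.bed"
    fst.write_outlier_bed(combined, bed)
    files["outlier_bed"] = bed
    if res["hits"] is not None:
        path = out / "candidate_gene_hits.tsv"
        res["hits"].to_csv(path, sep="\t", index=False)
        files["gene_hits"] = path
    return files


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "grm": _run_grm,
    "adjust": _run_adjust,
    "structure": _run_structure,
    "mantel": _run_mantel,
    "select": _run_select,
    "fst_scan": _run_fst_scan,
}
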