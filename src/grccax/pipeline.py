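"""End-to-end pipeline: simulate/ingest -> preprocess -> MCA -> modules ->
GRCCA + DGE -> enrichment -> report.

Every stage writes its artifacts under the run directory and registers them in
``manifest.json`` together with the parameter hash and the per-stage seeds
(split deterministically from the global seed). Re-running with the same
configuration and seed reproduces all outputs; with ``resume=True`` stages
whose outputs already exist are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as gio
from .cca import GRCCA, optimize_variance_fraction, significant_features
from .dge import compare_to_grcca, fit_dge
from .enrichment import gsea_preranked, read_gmt
from .mca import MCA, impute_unknown, select_dimensions
from .network import ModuleDetector
from .preprocess import filter_by_cv, filter_min_counts, normalize_transform, residualize
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "StageFailure"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "mca", "modules", "grcca", "dge", "enrichment", "report")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class SimulateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    n_per_group: tuple[int, int, int, int] = (55, 44, 35, 51)
    n_genes: int = 2000
    module_sizes: list[int] = Field(default_factory=lambda: [60] * 20)
    within_module_cor: float = 0.7
    effect_modules: list[int] = Field(default_factory=lambda: [1, 2, 3])
    effect_size: float = 0.4
    effect_group: str = "SCZ"
    n_tox: int = 17
    nb_dispersion: float = 0.1


class PipelineConfig(BaseModel):
    """Validated pipeline parameters; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    counts: str | None = None
    covariates: str | None = None
    gene_sets: str | None = None  # GMT; optional extra enrichment input
    simulate: SimulateSection = Field(default_factory=SimulateSection)

    min_count: int = 10
    min_fraction: float = 0.8
    cv_cutoff: float | None = None  # transcript-level option; off for genes
    mca_min_var: float = 0.05
    mca_cum_var: float = 0.75
    beta: float = 3.0
    cut_height: float = 0.980
    min_module_size: int = 40
    mu: float = 0.1
    grid: list[float] = Field(default_factory=lambda: [round(0.1 * i, 1) for i in range(1, 11)])
    n_perm: int = 1000
    n_boot: int = 1000
    z_thresh: float = 2.0
    fdr: float = 0.05
    gsea_n_perm: int = 1000
    seed: int = 0


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        return PipelineConfig(**(yaml.safe_load(fh) or {}))


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {stage: int(s % (2**31 - 1)) for stage, s in zip(STAGES, state)}


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir, resume: bool = False) -> Path:
    """Execute all stages; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict[str, Any] = {
        "config": config.model_dump(),
        "param_hash": hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seeds": seeds,
        "stages": {},
    }

    state: dict[str, Any] = {}

    def record(stage: str, outputs: dict[str, Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "hashes": {k: _hash_file(v) for k, v in outputs.items()},
            "wall_time_s": round(time.time() - t0, 3),
        }

    def stage_done(paths: list[Path]) -> bool:
        return resume and paths and all(p.exists() for p in paths)

    # ---- simulate / ingest -------------------------------------------------
    t0 = time.time()
    counts_path = outdir / "counts.tsv"
    cov_path = outdir / "covariates.csv"
    truth_path = outdir / "truth.tsv"
    try:
        if config.simulate.enabled:
            if stage_done([counts_path, cov_path, truth_path]):
                counts = gio.read_counts_tsv(counts_path)
                samples = gio.read_covariates_csv(cov_path)
                truth_df = gio.read_table_tsv(truth_path)
            else:
                sim = SimulationConfig(
                    n_per_group=tuple(config.simulate.n_per_group),
                    n_genes=config.simulate.n_genes,
                    module_sizes=tuple(config.simulate.module_sizes),
                    within_module_cor=config.simulate.within_module_cor,
                    effect_modules=tuple(config.simulate.effect_modules),
                    effect_size=config.simulate.effect_size,
                    effect_group=config.simulate.effect_group,
                    n_tox=config.simulate.n_tox,
                    nb_dispersion=config.simulate.nb_dispersion,
                    seed=seeds["simulate"],
                )
                counts, samples, truth = simulate_dataset(sim)
                truth_df = pd.DataFrame(
                    {"module_id": truth.true_modules, "true_effect": truth.true_effect}
                )
                gio.write_counts_tsv(counts, counts_path)
                gio.write_covariates_csv(samples, cov_path)
                gio.write_table_tsv(truth_df, truth_path)
            state["truth"] = truth_df
        else:
            if config.counts is None or config.covariates is None:
                raise ValueError("counts and covariates paths required when simulation is off")
            counts = gio.read_counts_tsv(config.counts)
            samples = gio.read_covariates_csv(config.covariates)
            gio.write_counts_tsv(counts, counts_path)
            gio.write_covariates_csv(samples, cov_path)
        state["counts"], state["samples"] = counts, samples
        record("simulate", {"counts": counts_path, "covariates": cov_path}, t0)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("simulate", exc) from exc

    # ---- preprocess --------------------------------------------------------
    t0 = time.time()
    expr_path = outdir / "expression.tsv"
    try:
        if stage_done([expr_path]):
            expr = gio.read_table_tsv(expr_path)
        else:
            filtered = filter_min_counts(state["counts"], config.min_count, config.min_fraction)
            if config.cv_cutoff is not None:
                filtered, _ = filter_by_cv(filtered, config.cv_cutoff)
            expr = normalize_transform(filtered)
            numeric = state["samples"].select_dtypes(include=[np.number])
            if numeric.shape[1]:
                expr = residualize(expr, numeric)
            gio.write_table_tsv(expr, expr_path)
        state["expr"] = expr
        record("preprocess", {"expression": expr_path}, t0)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("preprocess", exc) from exc

    # ---- toxicology MCA ----------------------------------------------------
    t0 = time.time()
    mca_path = outdir / "mca_coordinates.tsv"
    loadings_path = outdir / "mca_loadings.tsv"
    try:
        tox_cols = [c for c in state["samples"].columns if c.startswith("tox")]
        if tox_cols:
            if stage_done([mca_path, loadings_path]):
                coords = gio.read_table_tsv(mca_path)
            else:
                table = impute_unknown(state["samples"][tox_cols])
                model = MCA().fit(table)
                dims = select_dimensions(model.explained_inertia_, config.mca_min_var, config.mca_cum_var)
                coords = model.sample_coordinates_.iloc[:, [d - 1 for d in dims]]
                gio.write_table_tsv(coords, mca_path)
                gio.write_table_tsv(model.loadings_, loadings_path)
            state["mca"] = coords
            record("mca", {"coordinates": mca_path, "loadings": loadings_path}, t0)
        else:
            state["mca"] = pd.DataFrame(index=state["samples"].index)
            record("mca", {}, t0)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("mca", exc) from exc

    # ---- co-expression modules --------------------------------------------
    t0 = time.time()
    modules_path = outdir / "modules.tsv"
    try:
        if stage_done([modules_path]):
            labels = gio.read_table_tsv(modules_path)["module_id"]
        else:
            det = ModuleDetector(beta=config.beta, cut_height=config.cut_height,
                                 min_module_size=config.min_module_size)
            det.fit(state["expr"])
            labels = det.assignment_.labels
            gio.write_table_tsv(labels.to_frame(), modules_path)
        state["modules"] = labels
        record("modules", {"modules": modules_path}, t0)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("modules", exc) from exc

    # ---- GRCCA -------------------------------------------------------------
    t0 = time.time()
    selection_path = outdir / "grcca_model_selection.tsv"
    xw_path = outdir / "grcca_features.tsv"
    yw_path = outdir / "grcca_covariates.tsv"
    null_path = outdir / "grcca_permutation_null.tsv"
    try:
        X = state["expr"].T  # samples x features
        Y = pd.concat(
            [pd.get_dummies(state["samples"]["diagnosis"])[["SCZ", "BD", "MDD"]].astype(float),
             state["mca"]],
            axis=1,
        )
        groups = state["modules"].loc[X.columns].to_numpy()
        model, table = optimize_variance_fraction(
            X, Y, groups=groups, mu=config.mu, grid=config.grid,
            n_perm=config.n_perm, seed=seeds["grcca"],
        )
        model.bootstrap_z(X, Y, n_boot=config.n_boot, seed=seeds["grcca"] + 1)
        sig = significant_features(model, config.z_thresh, config.fdr)
        xout = model.x_structure_.copy()
        xout.insert(0, "weight", model.x_weights_)
        xout["Z"] = model.z_x_
        xout["significant"] = xout.index.isin(sig.index)
        yout = model.y_structure_.copy()
        yout.insert(0, "weight", model.y_weights_)
        yout["Z"] = model.z_y_
        gio.write_table_tsv(table, selection_path)
        gio.write_table_tsv(xout.rename_axis("feature_id"), xw_path)
        gio.write_table_tsv(yout.rename_axis("covariate"), yw_path)
        gio.write_table_tsv(pd.DataFrame({"null_correlation": model.perm_null_}), null_path)
        state["grcca"] = model
        record("grcca", {"model_selection": selection_path, "features": xw_path,
                         "covariates": yw_path, "null": null_path}, t0)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("grcca", exc) from exc

    # ---- DGE ---------------------------------------------------------------
    t0 = time.time()
    dge_path = outdir / "dge.tsv"
    try:
        dge = fit_dge(state["expr"], state["samples"], state["mca"])
        gio.write_table_tsv(dge, dge_path)
        r, p, _ = compare_to_grcca(dge, state["grcca"].x_structure_)
        state["dge"] = dge
        state["dge_grcca_r"] = (r, p)
        record("dge", {"dge": dge_path}, t0)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("dge", exc) from exc

    # ---- enrichment --------------------------------------------------------
    t0 = time.time()
    gsea_path = outdir / "gsea.tsv"
    try:
        sets: dict[str, list[str]] = {}
        if config.gene_sets:
            sets.update(read_gmt(config.gene_sets))
        if "truth" in state:
            truth = state["truth"]
            effect_genes = list(truth.index[truth["true_effect"] != 0])
            effect_genes = [g for g in effect_genes if g in state["grcca"].x_structure_.index]
            if effect_genes:
                sets["planted_effect_genes"] = effect_genes
        if sets:
            ranks = state["grcca"].x_structure_["r"]
            gsea = gsea_preranked(ranks, sets, n_perm=config.gsea_n_perm,
                                  seed=seeds["enrichment"])
            gio.write_table_tsv(gsea, gsea_path)
            state["gsea"] = gsea
            record("enrichment", {"gsea": gsea_path}, t0)
        else:
            record("enrichment", {}, t0)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("enrichment", exc) from exc

    # ---- report ------------------------------------------------------------
    t0 = time.time()
    report_path = outdir / "report.json"
    try:
        model = state["grcca"]
        report = {
            "chosen_f": getattr(model, "chosen_f_", model.variance_fraction),
            "latent_correlation": model.latent_correlation_,
            "perm_p": model.perm_p_,
            "n_significant_features": int(
                ((model.z_x_.abs() >= config.z_thresh) & (model.x_structure_["fdr"] < config.fdr)).sum()
            ),
            "top_covariate": str(model.y_structure_["r"].abs().idxmax()),
            "dge_grcca_correlation": state["dge_grcca_r"][0],
            "n_modules": int((state["modules"] > 0).max()),
        }
        report_path.write_text(json.dumps(report, indent=2))
        record("report", {"report": report_path}, t0)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("report", exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
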