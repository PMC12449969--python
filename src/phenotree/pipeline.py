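"""End-to-end pipeline orchestration.

Runs generate → preprocess → VAE → tree → projection → outcome models →
CRT analysis from a single configuration, writing per-stage artifacts and
a run manifest (config, seeds, row counts, artifact hashes, timings).
The derivation cohort builds the tree; external cohorts are only ever
projected onto the frozen tree, never refit.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crt as crt_mod
from . import outcomes as out_mod
from .preprocess import apply_selection, build_median_beat, \
    filter_and_resample
from .projection import fit_projection, project_cohort
from .synthetic import SyntheticOutcomeSpec, generate_cohort
from .tree import assign_branches, compute_pseudotime, fit_ddrtree, \
    merge_branches
from .io import save_tree
from .vae import VaeConfig, VaeModel, encode, train_vae

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One config for the whole run; every stochastic stage has a seed."""

    out_dir: str = "phenotree_run"
    n_derivation: int = 600
    n_external: int = 0
    seed: int = 0
    class_mix: tuple[float, float, float] = (0.35, 0.45, 0.20)
    noise_sd: float = 0.02
    rhythm_strips: bool = False
    band: tuple[float, float] = (0.5, 100.0)
    notch_hz: float = 60.0
    target_fs: float = 400.0
    vae: dict = field(default_factory=lambda: {
        "latent_dim": 51, "n_blocks": 4, "epochs": 12, "batch_size": 64,
    })
    n_centroids: int = 60
    n_phenogroups: int = 6
    tree_params: dict = field(default_factory=dict)
    projection_split: float = 0.75
    knn_max: int = 60
    crt_endpoint: str = "resp_lvef"
    stages: tuple[str, ...] = (
        "generate", "preprocess", "vae", "tree", "project", "outcomes",
        "crt",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False, float_format="%.10g").encode()
    ).hexdigest()[:16]


def _hash_arr(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest.

    A stage failure raises with the failing stage named; artifacts written
    before the failure are retained in ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}}
    state: dict = {}
    for stage in cfg.stages:
        t0 = time.time()
        try:
            _STAGES[stage](cfg, state, out, manifest)
        except Exception as e:
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=1, default=str))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
        manifest["stages"].setdefault(stage, {})["seconds"] = round(
            time.time() - t0, 2)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))
    return manifest


def _stage_generate(cfg, state, out, manifest):
    beats, table = generate_cohort(
        cfg.n_derivation, class_mix=cfg.class_mix, seed=cfg.seed,
        noise_sd=cfg.noise_sd, rhythm_strips=cfg.rhythm_strips,
    )
    table["ecg_date"] = 0.0
    state["derivation"] = (beats, table)
    table.to_csv(out / "derivation_outcomes.csv", index=False)
    if cfg.n_external > 0:
        ext = generate_cohort(
            cfg.n_external, class_mix=cfg.class_mix, seed=cfg.seed + 1000,
            noise_sd=cfg.noise_sd, rhythm_strips=cfg.rhythm_strips,
        )
        ext[1]["ecg_date"] = 0.0
        state["external"] = ext
        ext[1].to_csv(out / "external_outcomes.csv", index=False)
    manifest["stages"]["generate"] = {
        "n_derivation": cfg.n_derivation, "n_external": cfg.n_external,
        "outcomes_hash": _hash_df(table),
    }


def _stage_preprocess(cfg, state, out, manifest):
    counts = {}
    for role in [r for r in ("derivation", "external") if r in state]:
        records, table = state[role]
        if cfg.rhythm_strips:
            beats = []
            kept_rows = []
            for rec in records:
                filt = filter_and_resample(rec, cfg.band, cfg.notch_hz,
                                           cfg.target_fs)
                try:
                    beats.append(build_median_beat(filt))
                    kept_rows.append(True)
                except ValueError:
                    kept_rows.append(False)
            table = table[np.asarray(kept_rows)].reset_index(drop=True)
        else:
            beats = records
        eligible = table["eligible"].to_numpy(bool)
        state[f"{role}_beats"] = [b for b, e in zip(beats, eligible) if e]
        state[f"{role}_all_beats"] = beats
        state[f"{role}_table"] = table[eligible].reset_index(drop=True)
        counts[role] = {
            "input": len(beats), "eligible": int(eligible.sum()),
        }
    manifest["stages"]["preprocess"] = counts


def _stage_vae(cfg, state, out, manifest):
    vcfg = VaeConfig(seed=cfg.seed, **cfg.vae)
    model = train_vae(state["derivation_all_beats"], vcfg)
    model.save(out / "vae")
    state["vae"] = model
    for role in [r for r in ("derivation", "external") if r in state]:
        latents = encode(model, state[f"{role}_beats"])
        state[f"{role}_latents"] = latents
        np.savetxt(out / f"{role}_latents.csv", latents, delimiter=",")
    manifest["stages"]["vae"] = {
        "n_parameters": model.n_parameters(),
        "final_loss": model.loss_trace[-1],
    }


def _stage_tree(cfg, state, out, manifest):
    X = state["derivation_latents"]
    model = fit_ddrtree(X, n_centroids=cfg.n_centroids, seed=cfg.seed,
                        **cfg.tree_params)
    model = compute_pseudotime(merge_branches(
        assign_branches(model), n_groups=min(
            cfg.n_phenogroups, model.hyperparams["n_subbranches"])))
    state["tree"] = model
    save_tree(model, out / "tree")
    table = state["derivation_table"].copy()
    table["dim1"] = model.Z[:, 0]
    table["dim2"] = model.Z[:, 1]
    table["phenogroup"] = model.phenogroup
    table["pseudotime"] = model.pseudotime_global
    table["pseudotime_branch"] = model.pseudotime_branch
    state["derivation_table"] = table
    table.to_csv(out / "derivation_tree_table.csv", index=False)
    manifest["stages"]["tree"] = {
        "n_subbranches": model.hyperparams["n_subbranches"],
        "n_phenogroups": int(model.hyperparams["n_groups"]),
        "objective_final": model.objective_trace[-1],
        "tree_hash": _hash_arr(model.Y) + _hash_arr(model.B),
    }


def _stage_project(cfg, state, out, manifest):
    tree = state["tree"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        proj = fit_projection(
            tree, state["derivation_latents"], split=cfg.projection_split,
            k_grid=range(1, cfg.knn_max + 1), seed=cfg.seed,
        )
    state["projection"] = proj
    info = {"k": proj.k, **{k: round(v, 4)
                            for k, v in proj.train_metrics.items()}}
    if "external" in state:
        raw, snap, grp = project_cohort(proj, state["external_latents"])
        t = state["external_table"].copy()
        t[["dim1_raw", "dim2_raw"]] = raw
        t[["dim1", "dim2"]] = snap
        t["phenogroup"] = grp
        state["external_table"] = t
        t.to_csv(out / "external_tree_table.csv", index=False)
        info["external_projected"] = len(t)
        # frozen-tree contract: projection must not alter the tree
        info["tree_hash_after"] = _hash_arr(tree.Y) + _hash_arr(tree.B)
    manifest["stages"]["project"] = info


def _stage_outcomes(cfg, state, out, manifest):
    table = state["derivation_table"]
    tree = state["tree"]
    results = {}
    ref = int(pd.Series(table["phenogroup"]).mode()[0])
    covs = ["age", "sex", "heart_rate", "qtc_ms", "qrs_ms", "morphology"]

    def fit_with_fallback(outcome, kind, frame):
        # phenogroups can align with morphology classes on small cohorts,
        # making the full design collinear; fall back to the
        # morphology-omitting model (the published sensitivity analysis)
        try:
            return out_mod.fit_adjusted_model(
                frame, outcome, ["phenogroup"], covs, kind=kind,
                reference_phenogroup=ref), covs
        except out_mod.ModelFitError:
            slim = [c for c in covs if c != "morphology"]
            return out_mod.fit_adjusted_model(
                frame, outcome, ["phenogroup"], slim, kind=kind,
                reference_phenogroup=ref), slim

    # prevalent disease ~ phenogroup + covariates (logistic)
    res_prev, used_prev = fit_with_fallback(
        "prevalent_disease", "logistic",
        table.assign(prevalent_disease=table["prevalent_disease"]
                     .astype(int)))
    res_prev.table.to_csv(out / "prevalent_model.csv", index=False)
    # incident nonfatal event ~ phenogroup (Fine-Gray, death competing)
    res_inc, used_inc = fit_with_fallback("incident_event", "fine_gray",
                                          table)
    res_inc.table.to_csv(out / "incident_model.csv", index=False)
    results["covariates_prevalent"] = used_prev
    results["covariates_incident"] = used_inc
    out_mod.adjust_pvalues([res_prev, res_inc])
    # risk surface + spatial autocorrelation
    risk = out_mod.risk_surface(tree, table, outcome="event")
    np.savetxt(out / "risk_surface.csv", risk, delimiter=",")
    mi = out_mod.morans_i(
        table["qrs_ms"].to_numpy(), tree.Z, n_perm=199, seed=cfg.seed)
    results["morans_qrs"] = {k: round(float(v), 4) for k, v in mi.items()}
    results["risk_range"] = [float(risk.min()), float(risk.max())]
    results["prevalent_terms"] = len(res_prev.table)
    results["incident_terms"] = len(res_inc.table)
    manifest["stages"]["outcomes"] = results


def _stage_crt(cfg, state, out, manifest):
    table = state["derivation_table"]
    crt = table[table["crt"].astype(bool)].copy()
    info = {"n_crt": len(crt)}
    if len(crt) >= 20:
        crt = crt_mod.add_crt_endpoints(crt)
        try:
            res = crt_mod.model_crt_response(
                crt, endpoint=cfg.crt_endpoint, predictors=["dim1"],
            )
            res.table.to_csv(out / "crt_model.csv", index=False)
            info["or_dim1"] = float(res.term("dim1")["exp_estimate"])
        except (ValueError, out_mod.ModelFitError) as e:
            info["model_skipped"] = str(e)
    else:
        info["model_skipped"] = "fewer than 20 CRT records"
    manifest["stages"]["crt"] = info


_STAGES = {
    "generate": _stage_generate,
    "preprocess": _stage_preprocess,
    "vae": _stage_vae,
    "tree": _stage_tree,
    "project": _stage_project,
    "outcomes": _stage_outcomes,
    "crt": _stage_crt,
}
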