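"""Pipeline driver: stages that communicate through a workspace directory.

Each stage reads its inputs from the workspace written by earlier stages,
so the CLI subcommands compose to exactly the same result as
:func:`run_pipeline`, which simply runs the stages in order.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as behav
from . import designmat, inference, io, modelcheck, synthdata
from .config import PipelineConfig
from .firstlevel import encoding_coefficients, fit_voxelwise
from .grouplevel import fit_wls, stack_group_data

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_design",
    "stage_fit",
    "stage_group",
    "stage_infer",
    "stage_ppc",
    "stage_behavior",
]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "design", "fit", "group", "infer", "ppc", "behavior")


def _subject_ids(cfg: PipelineConfig) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(cfg.n_subjects)]


def _subject_seed(cfg: PipelineConfig, index: int) -> int:
    return cfg.seed + 1000 * (index + 1)


def _dataset_dir(cfg) -> Path:
    return Path(cfg.out_dir) / "dataset"


def _sub_path(cfg, sid, name, ext="tsv") -> Path:
    return _dataset_dir(cfg) / sid / f"{sid}_{name}.{ext}"


def stage_simulate(cfg: PipelineConfig) -> None:
    """Generate and write the synthetic cohort."""
    spec = cfg.acquisition
    for i, sid in enumerate(_subject_ids(cfg)):
        seed = _subject_seed(cfg, i)
        truth = synthdata.default_ground_truth(
            spec,
            generative_model=cfg.generative_model,
            seed=seed,
            gamma0=cfg.gamma0,
            gamma1=cfg.gamma1,
            noise_sd=cfg.noise_sd,
        )
        subject = synthdata.simulate_subject(
            spec, truth, seed=seed, subject_id=sid, hrf_params=cfg.hrf
        )
        synthdata.write_dataset(subject, _dataset_dir(cfg))
        logger.info("simulate: wrote %s (seed %d)", sid, seed)


def _load_subject_tables(cfg, sid):
    schedule = io.read_table(_sub_path(cfg, sid, "schedule"))
    trials = io.read_table(_sub_path(cfg, sid, "behavior"))
    motion = io.read_table(_sub_path(cfg, sid, "motion"))
    return schedule, trials, motion


def stage_design(cfg: PipelineConfig) -> None:
    """Build and write each subject's first-level design matrix."""
    out = Path(cfg.out_dir) / "design"
    out.mkdir(parents=True, exist_ok=True)
    for sid in _subject_ids(cfg):
        schedule, trials, motion = _load_subject_tables(cfg, sid)
        design = designmat.build_design(
            schedule, trials, motion, cfg.analysis_model, cfg.acquisition, cfg.hrf
        )
        design.write_tsv(out / f"{sid}_design.tsv")
        (out / f"{sid}_design.json").write_text(
            json.dumps({"interest_columns": design.interest_columns})
        )
        logger.info("design: %s -> %d columns", sid, design.n_columns)


def _load_design(cfg, sid) -> designmat.DesignMatrix:
    out = Path(cfg.out_dir) / "design"
    frame = io.read_table(out / f"{sid}_design.tsv")
    meta = json.loads((out / f"{sid}_design.json").read_text())
    spec = cfg.acquisition
    return designmat.DesignMatrix(
        values=frame.to_numpy(dtype=float),
        column_names=list(frame.columns),
        interest_columns=meta["interest_columns"],
        run_of_row=np.repeat(np.arange(spec.n_runs), spec.volumes_per_run),
    )


def stage_fit(cfg: PipelineConfig) -> None:
    """Voxel-wise first-level fits; writes per-category coefficient tables."""
    out = Path(cfg.out_dir) / "firstlevel"
    out.mkdir(parents=True, exist_ok=True)
    for sid in _subject_ids(cfg):
        bold, _ = io.read_bold(_sub_path(cfg, sid, "bold", "nii"))
        design = _load_design(cfg, sid)
        result = fit_voxelwise(bold, design)
        io.write_table(encoding_coefficients(result), out / f"{sid}_coefficients.tsv")
        (out / f"{sid}_fit.json").write_text(
            json.dumps({"df": result.df, "n_voxels": result.n_voxels})
        )
        logger.info("fit: %s df=%d", sid, result.df)


def _load_stacked(cfg):
    out = Path(cfg.out_dir) / "firstlevel"
    tables = {
        sid: io.read_table(out / f"{sid}_coefficients.tsv")
        for sid in _subject_ids(cfg)
    }
    return stack_group_data(tables)


def stage_group(cfg: PipelineConfig) -> None:
    """Weighted least squares group fit; writes slope/t maps and a table."""
    out = Path(cfg.out_dir) / "group"
    out.mkdir(parents=True, exist_ok=True)
    stacked = _load_stacked(cfg)
    fit = fit_wls(stacked)
    grid = cfg.acquisition.grid_shape
    affine = cfg.acquisition.affine
    io.write_volume(fit.t_stat.reshape(grid), affine, out / "t_map.nii")
    io.write_volume(fit.slope.reshape(grid), affine, out / "slope_map.nii")
    io.write_table(
        pd.DataFrame(
            {
                "voxel": np.arange(stacked.n_voxels),
                "slope": fit.slope,
                "slope_se": fit.slope_se,
                "t": fit.t_stat,
            }
        ),
        out / "group_fit.tsv",
    )
    (out / "group_fit.json").write_text(
        json.dumps({"df": fit.df, "n_points": fit.n_points})
    )
    logger.info("group: df=%d over %d voxels", fit.df, stacked.n_voxels)


def stage_infer(cfg: PipelineConfig) -> None:
    """Uncorrected thresholding, clusters, and permutation FWE correction."""
    out = Path(cfg.out_dir) / "inference"
    out.mkdir(parents=True, exist_ok=True)
    grid = cfg.acquisition.grid_shape
    gdir = Path(cfg.out_dir) / "group"
    t_map = io.read_volume(gdir / "t_map.nii")[0]
    meta = json.loads((gdir / "group_fit.json").read_text())
    thr = inference.threshold_map(t_map, meta["df"], cfg.alpha)
    clusters = inference.label_clusters(
        thr.signed_map, t_map, cfg.connectivity, cfg.acquisition.affine
    )
    io.write_table(clusters, out / "clusters.tsv")
    summary = {
        "alpha": cfg.alpha,
        "critical_value": thr.critical_value,
        "n_positive": thr.n_positive,
        "n_negative": thr.n_negative,
    }
    if cfg.n_permutations < 1:
        logger.warning("infer: n_permutations=0, skipping permutation FWE")
        summary["permutation"] = "skipped"
    else:
        stacked = _load_stacked(cfg)
        null, p = inference.permutation_fwe(
            stacked,
            B=cfg.n_permutations,
            scheme=cfg.permutation_scheme,
            seed=cfg.seed,
        )
        io.write_volume(p.reshape(grid), cfg.acquisition.affine, out / "corrected_p.nii")
        io.write_table(
            pd.DataFrame({"max_abs_t": null.max_abs_t}), out / "null_max_t.tsv"
        )
        summary["permutation"] = {
            "B": null.B,
            "scheme": null.scheme,
            "seed": null.seed,
            "n_fwe_corrected_le_05": int(np.sum(p <= 0.05)),
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("infer: %d/%d voxels above uncorrected threshold",
                thr.n_flagged, t_map.size)


def stage_ppc(cfg: PipelineConfig) -> None:
    """Posterior-predictive model comparison at the group peak voxel."""
    out = Path(cfg.out_dir) / "ppc"
    out.mkdir(parents=True, exist_ok=True)
    t_map = io.read_volume(Path(cfg.out_dir) / "group" / "t_map.nii")[0]
    peak = np.unravel_index(np.argmax(t_map), t_map.shape)
    spec = cfg.acquisition
    series, schedules, behaviors, motions = [], [], [], []
    for sid in _subject_ids(cfg):
        bold, affine = io.read_bold(_sub_path(cfg, sid, "bold", "nii"))
        series.append(
            modelcheck.extract_sphere_signal(bold, peak, cfg.roi_radius, affine)
        )
        schedule, trials, motion = _load_subject_tables(cfg, sid)
        schedules.append(schedule)
        behaviors.append(trials)
        motions.append(motion)
    ranking = modelcheck.compare_models(
        series, schedules, behaviors, motions, spec,
        models=list(cfg.ppc_models), hrf_params=cfg.hrf,
        n_sim=cfg.ppc_n_sim, seed=cfg.seed,
    )
    io.write_table(ranking, out / "model_ranking.tsv")
    observed = modelcheck.trial_average(series, schedules, behaviors, spec)
    io.write_table(modelcheck.timecourse_frame(observed), out / "timecourse.tsv")
    (out / "peak.json").write_text(
        json.dumps({"peak_voxel": [int(v) for v in peak],
                    "radius_mm": cfg.roi_radius, "seed": cfg.seed})
    )
    logger.info("ppc: best model %s", ranking.iloc[0]["model"])


def stage_behavior(cfg: PipelineConfig) -> None:
    """Behavioral scoring across the cohort."""
    out = Path(cfg.out_dir) / "behavior"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid in _subject_ids(cfg):
        trials = io.read_table(_sub_path(cfg, sid, "behavior"))
        lures = io.read_table(_sub_path(cfg, sid, "lures"))
        dms = behav.dms_accuracy(trials)
        smt = behav.smt_score(trials, lures)
        rows.append(
            {
                "subject": sid,
                "dms_percent_correct": dms["overall"],
                "dms_match": dms["match"],
                "dms_nonmatch": dms["nonmatch"],
                "smt_tpr": smt.true_positive_rate,
                "smt_fpr": smt.false_positive_rate,
                "smt_corrected_accuracy": smt.corrected_accuracy,
            }
        )
    frame = pd.DataFrame(rows)
    io.write_table(frame, out / "scores.tsv")
    logger.info(
        "behavior: median DMS %.1f%%, median corrected accuracy %.2f",
        frame["dms_percent_correct"].median(),
        frame["smt_corrected_accuracy"].median(),
    )


def _write_report(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    lines = ["# Pipeline report", "", f"- seed: {cfg.seed}",
             f"- subjects: {cfg.n_subjects}",
             f"- generative model: {cfg.generative_model}",
             f"- analysis model: {cfg.analysis_model}", ""]
    summary_path = out / "inference" / "summary.json"
    if summary_path.exists():
        lines += ["## Inference", "", "```json",
                  summary_path.read_text().strip(), "```", ""]
    clusters = out / "inference" / "clusters.tsv"
    if clusters.exists():
        lines += ["## Clusters", "", clusters.read_text().strip(), ""]
    ranking = out / "ppc" / "model_ranking.tsv"
    if ranking.exists():
        lines += ["## PPC model ranking", "", ranking.read_text().strip(), ""]
    scores = out / "behavior" / "scores.tsv"
    if scores.exists():
        lines += ["## Behavior", "", scores.read_text().strip(), ""]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "design": stage_design,
    "fit": stage_fit,
    "group": stage_group,
    "infer": stage_infer,
    "ppc": stage_ppc,
    "behavior": stage_behavior,
}


def run_stage(cfg: PipelineConfig, name: str) -> None:
    try:
        _STAGE_FUNCS[name](cfg)
    except KeyError:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}") from None
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in order and write a markdown report.

    Returns a small summary dict (paths and headline numbers).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    for name in STAGES:
        run_stage(cfg, name)
    report = _write_report(cfg)
    summary = {"out_dir": str(out), "report": str(report), "seed": cfg.seed}
    summary_path = out / "inference" / "summary.json"
    if summary_path.exists():
        summary["inference"] = json.loads(summary_path.read_text())
    return summary
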