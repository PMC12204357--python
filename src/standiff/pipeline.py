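"""End-to-end workbench: staging -> inference -> prediction -> analyses.

``run_pipeline`` chains every module on file inputs and writes a directory
of CSV/JSON artifacts, each stamped with the package version, config hash
and RNG seed.  Any stage failure aborts with a stage-named error; partial
outputs are retained for inspection.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import archetypes as arch_mod
from . import heterogeneity as het_mod
from .connectome import build_laplacian, load_connectome, read_region_mask
from .diffusion import KineticParams
from .inference import (
    FitConfig,
    fit_cohort_iterative,
    fit_cohort_subjects,
    strategy_aic,
)
from .io import (
    RunConfig,
    config_hash,
    read_biomarker_table,
    read_longitudinal_table,
    read_region_table,
    write_table,
)
from .prediction import validate_longitudinal
from .staging import (
    cohort_trajectory,
    prepare_biomarkers,
    select_thresholds,
    stage_posteriors,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Run the full workbench; returns the output directory."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.to_dict())
    seed = config.rng_seed
    t0 = time.time()

    def _stamp(df, name, index_label="subject_id"):
        write_table(df, out / name, seed=seed, cfg_hash=chash,
                    index_label=index_label)

    stage_name = "load"
    try:
        conn = load_connectome(config.connectome)
        lap = build_laplacian(conn)
        labels = conn.region_labels
        tau = read_region_table(config.tau, labels)
        bio = read_biomarker_table(config.biomarkers)
        excl_labels = read_region_mask(config.mask) if config.mask else []
        excl_mask = np.array([r in excl_labels for r in labels])

        stage_name = "staging"
        common = [s for s in bio.index if s in tau.index]
        bio = bio.loc[common]
        tau = tau.loc[common]
        control_mask = (bio["diagnosis"].str.lower() == "control").to_numpy()
        marker_cols = [c for c in bio.columns if c not in ("diagnosis", "age")]
        Z = prepare_biomarkers(
            bio[marker_cols], bio["age"].to_numpy(dtype=float),
            control_mask, decreasing=config.decreasing_biomarkers,
        )
        B = len(marker_cols)
        candidates = [
            np.tile(np.asarray(trip, dtype=float), (B, 1))
            for trip in config.threshold_grid
        ]
        model, thr_table = select_thresholds(
            Z, candidates, n_iter=config.n_mcmc_iter, rng_seed=seed
        )
        post = stage_posteriors(Z, model)
        traj = cohort_trajectory(post, tau)
        stages = post.most_likely_stage.astype(float)

        post_df = pd.DataFrame(
            post.probs, index=Z.index,
            columns=[f"stage_{s}" for s in range(post.probs.shape[1])],
        )
        post_df["most_likely_stage"] = post.most_likely_stage
        _stamp(post_df, "stage_posteriors.csv")
        _stamp(
            pd.DataFrame(traj.tau, columns=labels,
                         index=pd.Index(traj.stages, name="stage")),
            "trajectory.csv", index_label="stage",
        )
        (out / "event_model.json").write_text(json.dumps({
            "version_hash": chash, "seed": seed,
            "thresholds": model.thresholds.tolist(),
            "sequence": [list(ev) for ev in model.sequence],
            "log_likelihood": model.log_likelihood,
            "biomarker_names": marker_cols,
            "threshold_candidates": thr_table.to_dict(orient="records"),
        }, indent=2))
        logger.info("staging done in %.1fs", time.time() - t0)

        stage_name = "cohort_fit"
        fit_cfg = FitConfig(
            strategy=config.strategy, lam=config.lam, rng_seed=seed,
            excluded_region_mask=excl_mask if excl_mask.any() else None,
        )
        theta_c, x0_c, trace = fit_cohort_iterative(traj, lap, fit_cfg)
        (out / "cohort_fit.json").write_text(json.dumps({
            "version_hash": chash, "seed": seed,
            "alpha": theta_c.alpha, "beta": theta_c.beta,
            "seed_vector": x0_c.tolist(), "cost_trace": trace,
        }, indent=2))

        stage_name = "subject_fits"
        eligible = (~control_mask) & (stages >= 1)
        fits = fit_cohort_subjects(
            tau.loc[eligible], stages[eligible], config.strategy, lap,
            fit_cfg, cohort_fit=(theta_c, x0_c),
        )
        fits_df = pd.DataFrame([{
            "subject_id": f.subject_id, "alpha": f.params.alpha,
            "beta": f.params.beta, "stage": f.stage, "cost": f.cost,
            "pearson_r": f.pearson_r, "k": f.n_inferred,
            "mse": f.extras["mse"],
        } for f in fits]).set_index("subject_id")
        _stamp(fits_df, "subject_fits.csv")
        seeds_df = pd.DataFrame(
            np.stack([f.seed for f in fits]),
            index=[f.subject_id for f in fits], columns=labels,
        )
        _stamp(seeds_df, "subject_seeds.csv")
        (out / "strategy_aic.json").write_text(json.dumps({
            "strategy": config.strategy, "aic": strategy_aic(fits),
        }, indent=2))

        stage_name = "prediction"
        if config.longitudinal:
            records = read_longitudinal_table(config.longitudinal, labels)
            stage_by_id = dict(zip(tau.index, stages))
            usable = []
            for rec in records:
                if rec.subject_id in stage_by_id:
                    rec.baseline_stage = float(stage_by_id[rec.subject_id])
                    usable.append(rec)
            include_idx = fit_cfg.include_idx(lap.n_regions)
            report = validate_longitudinal(
                {f.subject_id: f for f in fits}, usable, lap,
                include_idx=include_idx,
            )
            _stamp(report.per_visit.set_index("subject_id"), "validation_visits.csv")
            _stamp(report.per_subject.set_index("subject_id"),
                   "validation_subjects.csv")

        stage_name = "heterogeneity"
        stage_grid = np.arange(model.n_stages, dtype=float)
        conv = het_mod.convergence_curve(fits, lap, stage_grid)
        _stamp(conv.set_index("stage"), "convergence.csv", index_label="stage")
        emp = het_mod.empirical_cov_by_stage(
            tau.loc[eligible].to_numpy(), stages[eligible]
        )
        _stamp(emp.set_index("subject"), "empirical_cov.csv", index_label="subject")

        stage_name = "archetypes"
        A = arch_mod.seed_covariance(seeds_df.to_numpy())
        vecs, vals = arch_mod.svd_archetypes(A, k=min(3, len(fits) - 1))
        labels_svd = arch_mod.classify_by_svd(seeds_df.to_numpy(), vecs)
        km = arch_mod.kmeans_archetypes(
            seeds_df.to_numpy(), k_grid=config.k_grid, rng_seed=seed
        )
        arch_df = pd.DataFrame({
            "label_svd": labels_svd, "label_kmeans": km.labels,
        }, index=seeds_df.index)
        _stamp(arch_df, "archetype_labels.csv")
        _stamp(
            pd.DataFrame(vecs, index=labels,
                         columns=[f"sv{k+1}" for k in range(vecs.shape[1])]),
            "singular_vectors.csv", index_label="region",
        )
        _stamp(
            pd.DataFrame(km.centroids, columns=labels,
                         index=pd.Index(range(km.selected_k), name="cluster")),
            "kmeans_centroids.csv", index_label="cluster",
        )
        traj_df = arch_mod.archetype_trajectories(km.labels, fits, lap, stage_grid)
        _stamp(traj_df.set_index("archetype"), "archetype_trajectories.csv",
               index_label="archetype")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage_name, exc) from exc

    logger.info("pipeline finished in %.1fs -> %s", time.time() - t0, out)
    return out
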