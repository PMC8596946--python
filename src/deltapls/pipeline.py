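"""End-to-end orchestration: simulate/load -> QC -> score -> PLS ->
bootstrap -> clusters -> ROI and clinical reports.

Every stochastic stage draws its seed deterministically from the master
seed, so a rerun with the same configuration reproduces the bundle
exactly.  The bundle is a nested dict; ``write_results`` serializes it to
NIfTI maps, CSV tables and a JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from .bootstrap import bootstrap_pls, roi_statistics
from .clusters import estimate_fwhm, extract_clusters, simulate_cluster_threshold
from .impute import ImputationModel, select_lambda_cv
from .io import SESSIONS, MaskGeometry, write_stat_map
from .normative import MatchCriteria, score_cohort
from .pls import MEAN, SEXCORR
from .qc import MultivariateOutlierDetector
from .simulate import SimulationConfig, simulate_cohort, truth_report

log = logging.getLogger("deltapls")


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the study's stated values."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    modalities: tuple[str, ...] | None = None   # default: simulation's
    criteria: MatchCriteria = field(default_factory=MatchCriteria)
    huber_k: float = 1.35
    n_boot: int = 1000
    voxel_p: float = 0.005
    cluster_alpha: float = 0.05
    n_sim: int = 2000
    connectivity: int = 1
    cv_repeats: int = 200
    cv_holdout: float = 0.05
    lambda_grid: np.ndarray | None = None
    impute_sweeps: int = 100     # SVT sweep cap inside bootstrap replicates
    fdr_q: float = 0.05
    run_qc: bool = True
    qc_alpha: float = 0.05
    seed: int = 0


def _child_seeds(master: int, n: int) -> list[int]:
    rng = np.random.default_rng(master)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def _qc_exclusions(records, maps, modalities, alpha) -> tuple[set, pd.DataFrame]:
    """Screen each modality's scans with the multivariate detector fit on
    control scans; return excluded (subject_id, session, modality) keys."""
    excluded = set()
    rows = []
    for modality in modalities:
        ctrl = [m for m in maps
                if m.modality == modality and m.session == "CONTROL"]
        others = [m for m in maps
                  if m.modality == modality and m.session != "CONTROL"]
        if len(ctrl) < 5:
            continue
        det = MultivariateOutlierDetector(alpha=alpha).fit(
            np.vstack([m.values for m in ctrl])
        )
        for batch in (ctrl, others):
            if len(batch) < 5:
                continue
            flags = det.predict(np.vstack([m.values for m in batch]))
            for m, f in zip(batch, flags):
                if f:
                    excluded.add((m.subject_id, m.session, m.modality))
                rows.append({"subject_id": m.subject_id, "session": m.session,
                             "modality": modality, "flagged": bool(f)})
    return excluded, pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis on a simulated cohort; returns the bundle.

    Per modality, two PLS analyses are run (MEAN = main concussion effect,
    SEXCORR = sex-specific effect), each with bootstrap inference, cluster
    extraction, and — when clusters survive — ROI statistics: the MEAN
    clusters are summarized for all athletes, the SEXCORR clusters per sex
    with a female-minus-male contrast over the FDR-significant sessions.
    """
    sim = config.simulation
    records, maps, symptoms, truth = simulate_cohort(sim)
    geometry = sim.geometry()
    modalities = config.modalities or sim.modalities
    seeds = iter(_child_seeds(config.seed, 4 + 10 * len(modalities)))

    qc_log = pd.DataFrame()
    excluded_scans: set = set()
    if config.run_qc:
        excluded_scans, qc_log = _qc_exclusions(
            records, maps, modalities, config.qc_alpha
        )
        if excluded_scans:
            log.info("QC excluded %d scans", len(excluded_scans))
    kept_maps = [m for m in maps
                 if (m.subject_id, m.session, m.modality) not in excluded_scans]

    results: dict = {
        "config": config,
        "truth": truth,
        "truth_report": truth_report(truth),
        "qc_log": qc_log,
        "modalities": {},
    }

    for modality in modalities:
        athlete_ids, sex, deltas, match_report = score_cohort(
            records, kept_maps, modality, criteria=config.criteria,
            k=config.huber_k,
        )
        log.info("%s: %d athletes scored; matched-control median %d",
                 modality, len(athlete_ids),
                 int(match_report["n_matched"].median()))
        n, n_sessions, V = deltas.shape

        has_missing = bool(np.isnan(deltas[:, :, 0]).any())
        imputation: ImputationModel | None = None
        cv_seed = next(seeds)
        if has_missing:
            imputation = select_lambda_cv(
                deltas.reshape(n, -1),
                lambda_grid=config.lambda_grid,
                n_iter=config.cv_repeats,
                holdout_frac=config.cv_holdout,
                seed=cv_seed,
            )
            log.info("%s: chosen lambda %.4g", modality,
                     imputation.chosen_lambda)

        # Smoothness from session-demeaned residual maps.
        session_means = np.nanmean(deltas, axis=0)
        residuals = []
        for i in range(n):
            for s in range(n_sessions):
                if np.isfinite(deltas[i, s, 0]):
                    residuals.append(deltas[i, s] - session_means[s])
        smoothness = estimate_fwhm(np.asarray(residuals), geometry)
        min_size = simulate_cluster_threshold(
            geometry, smoothness.fwhm_mean, voxel_p=config.voxel_p,
            alpha=config.cluster_alpha, n_sim=config.n_sim,
            connectivity=config.connectivity, seed=next(seeds),
        )
        log.info("%s: FWHM %.2f mm, min cluster %d voxels", modality,
                 smoothness.fwhm_mean, min_size)

        mod_result = {
            "athlete_ids": athlete_ids,
            "sex": sex,
            "deltas": deltas,
            "match_report": match_report,
            "imputation": imputation,
            "smoothness": smoothness,
            "min_cluster_size": min_size,
            "analyses": {},
        }

        for analysis in (MEAN, SEXCORR):
            boot = bootstrap_pls(
                deltas, sex, analysis=analysis, n_boot=config.n_boot,
                seed=next(seeds), imputation=imputation,
                impute_max_iter=config.impute_sweeps,
            )
            table = extract_clusters(
                boot.voxel_bsr, geometry, min_size=min_size,
                voxel_p=config.voxel_p, connectivity=config.connectivity,
            )
            entry = {"bootstrap": boot, "clusters": table, "roi": None}
            if table.n_clusters > 0:
                if analysis == MEAN:
                    roi = roi_statistics(
                        deltas, sex, table.cluster_mask, groups=("all",),
                        n_boot=config.n_boot, seed=next(seeds),
                        q=config.fdr_q, cv_repeats=config.cv_repeats,
                        impute_max_iter=config.impute_sweeps,
                    )
                else:
                    sig = [
                        s for s, p in zip(SESSIONS, boot.session_p)
                        if p < config.fdr_q
                    ]
                    roi = roi_statistics(
                        deltas, sex, table.cluster_mask,
                        groups=("male", "female"),
                        n_boot=config.n_boot, seed=next(seeds),
                        contrast_sessions=tuple(sig) or None,
                        q=config.fdr_q, cv_repeats=config.cv_repeats,
                        impute_max_iter=config.impute_sweeps,
                    )
                entry["roi"] = roi
            else:
                next(seeds)   # keep downstream seeds stable
            mod_result["analyses"][analysis] = entry
        results["modalities"][modality] = mod_result

    scores = clin.score_symptom_table(symptoms)
    subj_df = pd.DataFrame([{
        "subject_id": r.subject_id, "group": r.group, "sex": r.sex,
        "age": r.age, "hoc": r.hoc, "days_to_rtp": r.days_to_rtp,
    } for r in records])
    results["clinical"] = clin.clinical_report(scores, subj_df, q=config.fdr_q)

    conc = subj_df[subj_df["group"] == "concussed"].set_index("subject_id")
    base = scores[scores["session"] == "baseline"].set_index("subject_id")
    variables = pd.DataFrame({
        "age": conc["age"], "sex": conc["sex"], "hoc": conc["hoc"],
        "days_to_rtp": conc["days_to_rtp"].astype(float),
        "baseline_severity": base["total_severity"].reindex(conc.index),
    })
    results["attrition"] = clin.attrition_check(
        truth.retained, variables, q=config.fdr_q
    )

    if out_dir is not None:
        write_results(results, geometry, Path(out_dir))
    return results


def write_results(results: dict, geometry: MaskGeometry, out_dir: Path) -> None:
    """Serialize a results bundle: NIfTI BSR maps, CSV tables, JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": results["config"].seed, "modalities": {}}
    results["truth_report"].to_csv(out_dir / "truth_report.csv", index=False)
    if len(results["qc_log"]):
        results["qc_log"].to_csv(out_dir / "qc_log.csv", index=False)
    results["clinical"].to_csv(out_dir / "clinical_report.csv", index=False)
    results["attrition"].to_csv(out_dir / "attrition_report.csv", index=False)
    for modality, mod in results["modalities"].items():
        mdir = out_dir / modality
        mdir.mkdir(exist_ok=True)
        mod["match_report"].to_csv(mdir / "match_report.csv", index=False)
        msum = {
            "fwhm_mm": float(mod["smoothness"].fwhm_mean),
            "min_cluster_size": int(mod["min_cluster_size"]),
            "chosen_lambda": (
                None if mod["imputation"] is None
                else float(mod["imputation"].chosen_lambda)
            ),
            "analyses": {},
        }
        for analysis, entry in mod["analyses"].items():
            boot = entry["bootstrap"]
            write_stat_map(boot.voxel_bsr, geometry,
                           mdir / f"{analysis}_voxel_bsr.nii.gz")
            write_stat_map(boot.component.voxel_salience, geometry,
                           mdir / f"{analysis}_voxel_salience.nii.gz")
            entry["clusters"].table.to_csv(
                mdir / f"{analysis}_clusters.csv", index=False
            )
            asum = {
                "pct_covariance": boot.pct_cov_point,
                "pct_covariance_ci": list(boot.pct_cov_ci),
                "session_bsr": [float(b) for b in boot.session_bsr],
                "session_p": [float(p) for p in boot.session_p],
                "n_clusters": entry["clusters"].n_clusters,
            }
            if entry["roi"] is not None:
                entry["roi"].table.to_csv(
                    mdir / f"{analysis}_roi_stats.csv", index=False
                )
                if entry["roi"].contrast:
                    c = dict(entry["roi"].contrast)
                    c["sessions"] = list(c["sessions"])
                    asum["sex_contrast"] = c
            msum["analyses"][analysis] = asum
        summary["modalities"][modality] = msum
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
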