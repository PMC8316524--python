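"""End-to-end analysis pipeline: simulate → extract → PCA → verify → report.

Every stage writes its results as delimited tables under the output
directory; the final ``report.json`` collects the seeds and every count
that appears in the results, so a run is fully reproducible from its
config file alone.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import verification as verif
from .anatomy import SegmentSet
from .config import RunConfig
from .fileio import save_model, write_gait_vectors
from .kinematics import build_gait_vector, trial_to_cycles
from .simulate import generate_marker_cohort

log = logging.getLogger("gaituniq")


def extract_cohort_vectors(trials, registry, side="right", frames=101,
                           max_cycles_per_trial=2, segments=None):
    """Run the kinematics pipeline over a cohort of trials.

    Returns the pooled gait-vector matrix and a per-cycle metadata table
    (subject, trial, cycle, duration, cadence, step length, velocity).
    """
    segments = segments if segments is not None else SegmentSet()
    vectors = []
    rows = []
    for (subject_id, trial_id), series in trials.items():
        cycles = trial_to_cycles(series, segments=segments, side=side,
                                 max_cycles=max_cycles_per_trial,
                                 target_frames=frames)
        for c in cycles:
            vectors.append(build_gait_vector(c.orientations))
            rows.append(dict(subject_id=subject_id, trial_id=trial_id,
                             cycle_index=c.cycle_index, duration=c.duration,
                             cadence=c.spatiotemporal.cadence,
                             step_length=c.spatiotemporal.step_length,
                             velocity=c.spatiotemporal.velocity))
    return np.asarray(vectors), pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages and write result tables; returns the report dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seeds": {"cohort": config.cohort.seed,
                              "pairs": config.pair_seed,
                              "cv": config.cv_seed}}

    log.info("simulating cohort: %d subjects, seed %d",
             config.cohort.n_subjects, config.cohort.seed)
    trials, registry = generate_marker_cohort(config.cohort)
    registry.to_csv(outdir / "registry.csv", index=False)

    log.info("extracting gait vectors from %d trials", len(trials))
    vectors, meta = extract_cohort_vectors(
        trials, registry, side=config.side, frames=config.frames,
        max_cycles_per_trial=config.cohort.n_cycles_per_trial)
    write_gait_vectors(outdir / "gait_vectors.csv", outdir / "cycle_meta.csv",
                       vectors, meta)
    report["counts"] = {"subjects": int(registry.subject_id.nunique()),
                        "trials": len(trials),
                        "gait_vectors": len(vectors)}

    log.info("fitting PCA on %d x %d matrix", *vectors.shape)
    labels = meta.subject_id.to_numpy()
    model = feat.fit_gait_pca(vectors, labels)
    save_model(outdir / "pca_model.npz", model)
    if config.pca_k is not None:
        k = min(config.pca_k, model.n_components)
    else:
        k = feat.components_for_variance(model, config.pca_variance)
    intra = feat.intra_subject_variance(model.scores, labels)
    profile = feat.variance_ratio(model.explained_variance, intra)
    pd.DataFrame({"explained_variance": profile.explained,
                  "intra_subject_variance": profile.intra,
                  "variance_ratio": profile.ratio}).to_csv(
        outdir / "variance_profile.csv", index_label="component")
    corr = feat.correlate_with_parameters(
        model.scores[:, :min(8, model.n_components)],
        meta[["cadence", "step_length", "velocity"]])
    corr.to_csv(outdir / "pc_parameter_correlations.csv", index_label="component")
    total = float(np.sum(model.explained_variance))
    report["pca"] = {
        "components_retained": model.n_components,
        "k_used": int(k),
        "explained_fraction_at_k": float(
            np.sum(model.explained_variance[:k]) / total) if total else 0.0,
    }

    log.info("building pair cases (k = %d features)", k)
    features_k = model.scores[:, :k]
    dataset = verif.build_pair_dataset(features_k, labels, seed=config.pair_seed)
    report["pairs"] = {"same": dataset.n_same, "diff": dataset.n_diff,
                       "total": len(dataset),
                       "diff_population": verif.count_diff_pairs(labels)}

    results = {}
    for method in config.methods:
        log.info("cross-validating %s (%d folds)", method, config.folds)
        res = verif.cross_validate(dataset, method, folds=config.folds,
                                   seed=config.cv_seed)
        results[method] = res
        pd.DataFrame({"threshold": res.thresholds, "far": res.far_curve,
                      "frr": res.frr_curve}).to_csv(
            outdir / f"roc_{method}.csv", index=False)
        pd.DataFrame({"score": res.scores, "label_same": res.labels,
                      "fold": res.fold_assignment}).to_csv(
            outdir / f"scores_{method}.csv", index=False)
    summary = pd.DataFrame(
        [{"method": m, "accuracy": r.accuracy, "eer": r.eer, "folds": r.folds}
         for m, r in results.items()])
    summary.to_csv(outdir / "verification_summary.csv", index=False)
    report["verification"] = {
        m: {"accuracy": r.accuracy, "eer": r.eer} for m, r in results.items()}

    best = min(results.values(), key=lambda r: r.eer)
    bound, special, general = verif.uniqueness_estimates(best.eer, config.population)
    report["uniqueness"] = {"method": best.method, "eer": best.eer,
                            "population": config.population,
                            "special_error_bound": bound,
                            "special_uniqueness": special,
                            "general_uniqueness": general}

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", outdir / "report.json")
    return report
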