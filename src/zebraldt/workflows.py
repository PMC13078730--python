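"""End-to-end workflow stages: simulate, screen, classify, calibrate, compare.

Each stage is an importable function that consumes explicit inputs, writes
plain CSV/JSON reports into an output directory, and records a manifest
(configuration + seeds + package version) sufficient to reproduce the run.
The command-line interface in :mod:`zebraldt.cli` is a thin wrapper over
these functions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import FeatureMatrix
from .harness import (
    ClassifierSpec,
    FAMILIES,
    compute_metrics,
    dual_coding_run,
    make_folds,
)
from .ingest import assemble_matrix, read_long_table
from .nullcal import (
    NullDistribution,
    is_significant,
    permutation_baseline,
    pool_families,
    random_data_baseline,
)
from .screen import results_to_frame, screen_features
from .synthetic import GeneratorConfig, config_to_dict, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


def _write_manifest(outdir: Path, stage: str, payload: dict) -> None:
    manifest = {"stage": stage, "package_version": __version__, **payload}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _load_matrix(cohort_csv) -> FeatureMatrix:
    records = read_long_table(cohort_csv)
    return assemble_matrix(records)


def simulate(config: GeneratorConfig, outdir) -> Path:
    """Generate a cohort and write it as long CSV plus manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_cohort(config)
    cohort_csv = outdir / "cohort.csv"
    write_cohort(records, cohort_csv)
    _write_manifest(outdir, "simulate", {"generator_config": config_to_dict(config)})
    logger.info("wrote %d records to %s", len(records), cohort_csv)
    return cohort_csv


def screen(cohort_csv, outdir, alpha: float = 0.05) -> int:
    """Univariate Mann-Whitney/Bonferroni screen; returns NSUP."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = _load_matrix(cohort_csv)
    results, n_sig = screen_features(matrix, alpha=alpha)
    results_to_frame(results).to_csv(outdir / "screen.csv", index=False)
    (outdir / "screen_summary.json").write_text(
        json.dumps({"alpha": alpha, "n_features": matrix.n_features,
                    "count_significant": n_sig}, indent=2)
    )
    _write_manifest(outdir, "screen", {"input": str(cohort_csv), "alpha": alpha})
    logger.info("screen: %d of %d features significant", n_sig, matrix.n_features)
    return n_sig


def classify(cohort_csv, outdir, families=None, k: int = 5, seed: int = 0) -> pd.DataFrame:
    """Dual-coding fivefold classification for each family; returns summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    families = list(families or FAMILIES)
    matrix = _load_matrix(cohort_csv)
    folds = make_folds(matrix.labels, k=k, seed=seed, sample_ids=matrix.sample_ids)

    pred_rows, summary_rows = [], []
    for fam in families:
        preds = dual_coding_run(matrix, ClassifierSpec(fam), folds)
        metrics = compute_metrics(preds)
        summary_rows.append({"family": fam, **metrics.as_dict()})
        for coding in preds.codings:
            for sid, truth, pred, fold in zip(
                preds.sample_ids, preds.true_labels, preds.predicted[coding], preds.folds
            ):
                pred_rows.append(
                    {"family": fam, "coding": coding, "fold": int(fold),
                     "sample_id": sid, "true": truth, "predicted": pred}
                )
        logger.info("classify: %s accuracy %.3f", fam, metrics.accuracy)
    pd.DataFrame(pred_rows).to_csv(outdir / "predictions.csv", index=False)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "classification_summary.csv", index=False)
    _write_manifest(
        outdir, "classify",
        {"input": str(cohort_csv), "families": families, "k": k, "seed": seed},
    )
    return summary


def calibrate(
    outdir,
    families=None,
    n_per_class: int = 36,
    n_features: int = 780,
    n_reps: int = 100,
    seed: int = 0,
    cohort_csv=None,
    kinds=("random_data", "label_permutation"),
    n_reps_per_family: dict[str, int] | None = None,
) -> dict:
    """Build null baselines and the significance threshold.

    Random-data nulls need only a shape; the label-permutation null
    additionally needs a real or synthetic cohort CSV.  Writes per-replicate
    accuracies and a JSON summary with per-family and pooled mean/sd/upper95.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    families = list(families or FAMILIES)
    if n_reps < 10:
        logger.warning("n_reps=%d is low; null summaries will be unstable", n_reps)

    dists: list[NullDistribution] = []
    if "random_data" in kinds:
        rd = random_data_baseline(
            n_per_class, n_features, families, n_reps=n_reps, seed=seed
        )
        dists.extend(rd.values())
    if "label_permutation" in kinds:
        if cohort_csv is None:
            raise ValueError("label-permutation calibration requires a cohort CSV")
        matrix = _load_matrix(cohort_csv)
        lp = permutation_baseline(
            matrix, families, n_perms=n_reps, seed=seed,
            n_perms_per_family=n_reps_per_family,
        )
        dists.extend(lp.values())

    rows = [
        {"kind": d.kind, "family": d.family, "rep": i, "accuracy": a}
        for d in dists
        for i, a in enumerate(d.accuracies)
    ]
    pd.DataFrame(rows).to_csv(outdir / "null_accuracies.csv", index=False)

    summary: dict = {"families": {}, "pooled": {}}
    for kind in kinds:
        kind_dists = [d for d in dists if d.kind == kind]
        if not kind_dists:
            continue
        for d in kind_dists:
            summary["families"].setdefault(d.family, {})[kind] = {
                "n_reps": d.n_reps, "mean": d.mean, "sd": d.sd, "upper95": d.upper95,
            }
        pooled = pool_families(kind_dists)
        summary["pooled"][kind] = {
            "mean": pooled.overall_mean,
            "sd": pooled.overall_sd,
            "upper95": pooled.overall_upper95,
        }
    (outdir / "null_summary.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(
        outdir, "calibrate",
        {"families": families, "n_per_class": n_per_class, "n_features": n_features,
         "n_reps": n_reps, "seed": seed, "kinds": list(kinds),
         "cohort": str(cohort_csv) if cohort_csv else None},
    )
    return summary


def compare_groups(
    cohort_csv,
    outdir,
    families=None,
    k: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
    null_upper95: float | None = None,
) -> pd.DataFrame:
    """Pairwise two-group report: NSUP plus each family's pooled accuracy.

    If a calibrated ``null_upper95`` threshold is supplied, each accuracy
    also gets a significance call against it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    families = list(families or FAMILIES)
    matrix = _load_matrix(cohort_csv)
    g0, g1 = matrix.require_two_groups()
    _, n_sig = screen_features(matrix, alpha=alpha)
    folds = make_folds(matrix.labels, k=k, seed=seed, sample_ids=matrix.sample_ids)

    rows = [{"comparison": f"{g0} vs {g1}", "measure": "NSUP", "value": n_sig,
             "significant": n_sig > 0}]
    for fam in families:
        acc = compute_metrics(dual_coding_run(matrix, ClassifierSpec(fam), folds)).accuracy
        rows.append(
            {"comparison": f"{g0} vs {g1}", "measure": f"accuracy_{fam}", "value": acc,
             "significant": (acc > null_upper95) if null_upper95 is not None else None}
        )
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "group_comparison.csv", index=False)
    _write_manifest(
        outdir, "compare-groups",
        {"input": str(cohort_csv), "families": families, "k": k, "alpha": alpha,
         "seed": seed, "null_upper95": null_upper95},
    )
    return report
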