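"""Top-level pipeline: records in, stability grid + classification report out.

``run_pipeline`` ties the stages together in order: load or simulate the
records, compute per-subject windowed ASI summaries, build the
pair-by-scheme MSD stability grid, score every subject with ASI_class,
classify at the configured threshold, and evaluate with ROC/AUC, the group
t-test and the PMA regression.  Everything is deterministic given the
configuration and its seeds; every output directory carries the resolved
configuration and its hash, and a re-run with a different configuration
refuses to overwrite silently.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .classify import (
    asi_class,
    classify,
    group_difference_test,
    pma_regression,
    roc,
    youden_threshold,
)
from .config import PipelineConfig, config_hash
from .errors import ConfigError, StatisticsError
from .io import read_edf
from .pipeline import SCHEMES, optimization_grid, summarize_subject
from .records import EEGRecord
from .synthetic import CohortSpec, generate_cohort

__all__ = ["run_pipeline", "load_inputs"]

logger = logging.getLogger(__name__)

#: Scheme used for the classification statistic (mean of four 2.5-min windows).
CLASSIFY_SCHEME = SCHEMES["4x2.5"]


def load_inputs(inputs: list[str | Path] | CohortSpec) -> list[EEGRecord]:
    """Resolve pipeline inputs: EDF paths, or a synthetic cohort spec."""
    if isinstance(inputs, CohortSpec):
        return [rec for rec, _g, _p in generate_cohort(inputs)]
    if not inputs:
        raise ConfigError("no input records given")
    return [read_edf(p) for p in inputs]


def run_pipeline(config: PipelineConfig,
                 inputs: list[str | Path] | CohortSpec) -> dict:
    """Run the full analysis and write a report bundle to ``config.outdir``.

    Writes ``config.yaml``, ``subjects.csv`` (per-subject epoch means for
    the classification scheme), ``grid.csv`` (MSD stability grid),
    ``predictions.csv``, ``roc.csv``, ``metrics.json`` and a human-readable
    ``report.txt``.  Returns the metrics dict.  Raises on any strict-mode
    window rejection (the caller maps this to a nonzero exit code).
    """
    records = load_inputs(inputs)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    marker = outdir / "config.yaml"
    if marker.exists():
        import yaml
        old = yaml.safe_load(marker.read_text()) or {}
        if old.get("config_hash") not in (None, chash):
            raise ConfigError(
                f"output directory {outdir} holds results for config "
                f"{old.get('config_hash')}; refusing to overwrite with {chash}")
    config.dump(marker)

    by_name = {p.name: p for p in config.pairs}
    pair = by_name.get("C3O1-C4O2", config.pairs[0])
    summaries = [
        summarize_subject(rec, pair, CLASSIFY_SCHEME, config.asi,
                          config.qs_tags, config.rejection_mode)
        for rec in records
    ]
    subj_rows = [{
        "subject_id": s.subject_id, "pair": s.pair.name,
        "scheme": s.scheme.scheme_id, "asi_epoch1": s.asi_epoch1,
        "asi_epoch2": s.asi_epoch2,
        "asi_class": asi_class(s.asi_epoch1, s.asi_epoch2),
        "group": s.group, "pma_weeks": s.pma_weeks,
        "config_hash": chash,
    } for s in summaries]
    subjects = pd.DataFrame(subj_rows)
    subjects.to_csv(outdir / "subjects.csv", index=False)

    grid = optimization_grid(records, config.pairs, config.schemes,
                             config.asi, config.qs_tags, config.rejection_mode)
    grid.assign(config_hash=chash).to_csv(outdir / "grid.csv")

    metrics: dict = {"config_hash": chash, "n_subjects": len(records),
                     "classification_pair": pair.name,
                     "classification_scheme": CLASSIFY_SCHEME.scheme_id,
                     "msd_grid_argmin": list(grid.attrs.get("argmin", ()))}

    labelled = subjects.dropna(subset=["group"]) if "group" in subjects else subjects.iloc[0:0]
    if not labelled.empty and labelled["group"].nunique() == 2:
        pairs_sl = list(zip(labelled["asi_class"], labelled["group"]))
        cls = classify(pairs_sl, config.classification)
        labelled = labelled.assign(prediction=cls["predictions"])
        labelled.to_csv(outdir / "predictions.csv", index=False)
        r = roc(pairs_sl)
        pd.DataFrame({
            "threshold": r.thresholds, "sensitivity": r.sensitivity,
            "specificity": r.specificity, "config_hash": chash,
        }).to_csv(outdir / "roc.csv", index=False)
        youden, j = youden_threshold(r)
        metrics.update({
            "threshold": config.classification.threshold,
            "accuracy": cls["accuracy"], "sensitivity": cls["sensitivity"],
            "specificity": cls["specificity"], "confusion": cls["confusion"],
            "auc": r.auc, "youden_threshold": youden, "youden_j": j,
        })
        try:
            t_stat, t_p = group_difference_test(
                labelled.loc[labelled.group == "normal", "asi_class"].tolist(),
                labelled.loc[labelled.group == "abnormal", "asi_class"].tolist())
            metrics.update({"group_t": t_stat, "group_p": t_p})
        except StatisticsError as exc:
            logger.warning("group test skipped: %s", exc)
        if labelled["pma_weeks"].notna().all() and len(labelled) >= 3:
            try:
                metrics["pma_regression"] = pma_regression(list(zip(
                    labelled["asi_class"], labelled["pma_weeks"],
                    labelled["group"])))
            except StatisticsError as exc:
                logger.warning("PMA regression skipped: %s", exc)
    else:
        logger.warning("no two-class labels available; classification skipped")

    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    (outdir / "report.txt").write_text(_report_text(metrics, grid))
    return metrics


def _report_text(metrics: dict, grid: pd.DataFrame) -> str:
    lines = [
        "neoasi pipeline report",
        f"config hash: {metrics['config_hash']}",
        f"subjects:    {metrics['n_subjects']}",
        "",
        "MSD stability grid (rows: window schemes, cols: derivation pairs):",
        grid.to_string(float_format=lambda v: f"{v:.3f}"),
        "",
    ]
    if metrics.get("msd_grid_argmin"):
        lines.append("most stable cell (scheme, pair): "
                     f"{tuple(metrics['msd_grid_argmin'])}")
    if "accuracy" in metrics:
        lines += [
            "",
            f"classification at ASI_class <= {metrics['threshold']}:",
            f"  accuracy    {100 * metrics['accuracy']:.2f}%",
            f"  sensitivity {metrics['sensitivity']:.3f}"
            f"  specificity {metrics['specificity']:.3f}",
            f"  ROC AUC     {metrics['auc']:.3f}"
            f"  (Youden threshold {metrics['youden_threshold']:.2f},"
            f" J = {metrics['youden_j']:.3f})",
        ]
        if "group_t" in metrics:
            lines.append(f"  group difference: t = {metrics['group_t']:.2f},"
                         f" p = {metrics['group_p']:.2e}")
    if "pma_regression" in metrics:
        pooled = metrics["pma_regression"].get("pooled", {})
        if pooled:
            lo, hi = pooled["slope_ci"]
            lines.append(
                f"  PMA slope (pooled): {pooled['slope']:.3f} ASI/week "
                f"[{lo:.3f}, {hi:.3f}], p = {pooled['p_value']:.2f}")
    return "\n".join(lines) + "\n"
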