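"""End-to-end orchestration: simulate -> extract -> compare -> classify.

A single :func:`run_pipeline` call reproduces the whole analysis from a
config: generate (or read) the tensile records, extract the five-property
table, filter extreme outliers, run the 15 univariate comparisons (five
properties x three rates) with the effect-size and sample-size block, and
run the four LOOCV classification tasks (one per rate plus the rate-combined
task).  Identical config and seed yield an identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, io, mechanics, synthetic, univariate

logger = logging.getLogger("burnmech")

#: property-table columns used as classifier features / tested properties
FEATURE_COLUMNS = ("ut_stress_MPa", "ut_strain", "toughness_MJm3", "mu_MPa", "gamma")


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    ``curves_path``/``metadata_path`` switch the first stage from the
    synthetic generator to user-supplied files; the downstream schema is
    identical either way.
    """

    seed: int = 0
    alpha: float = 0.01                    # significance of every univariate test
    outlier_k: float = 3.0                 # fence multiple on the IQR
    power_alpha: float = 0.01
    power_target: float = 0.99
    allocation_ratio: float = 2.5
    n_points_per_curve: int = 200
    noise_sd_rel: float = 0.02
    curves_path: str | None = None
    metadata_path: str | None = None
    preload_zero: float | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class StudyReport:
    """Consolidated outcome of one pipeline run."""

    univariate: list[univariate.UnivariateResult]
    effect_size: float
    sample_size: dict
    classification: list[classify.ClassificationReport]
    outliers: pd.DataFrame = field(repr=False)
    properties: pd.DataFrame = field(repr=False)
    provenance: dict = field(default_factory=dict)


def _univariate_block(props: pd.DataFrame, alpha: float) -> list[univariate.UnivariateResult]:
    results = []
    for rate in synthetic.RATES:
        sub = props[props["rate_mm_s"] == rate]
        human = sub[sub["tissue"] == "human"]
        porcine = sub[sub["tissue"] == "porcine"]
        for col in FEATURE_COLUMNS:
            res = univariate.decision_tree_compare(
                human[col], porcine[col], alpha,
                property_name=col, loading_rate=rate)
            logger.info("univariate %s @ %.1f mm/s: %s p=%.3g reject=%s",
                        col, rate, res.final_test, res.final_p, res.reject)
            results.append(res)
    return results


def _classification_block(props: pd.DataFrame) -> list[classify.ClassificationReport]:
    reports = []
    per_rate = []
    for rate in synthetic.RATES:
        sub = props[props["rate_mm_s"] == rate]
        per_rate.append(sub)
        rep = classify.loocv_classify(sub[list(FEATURE_COLUMNS)], sub["tissue"],
                                      task_label=f"{rate:g} mm/s")
        logger.info("classification %s: accuracy=%.4f", rep.task_label, rep.accuracy)
        reports.append(rep)
    combined = classify.combine_rates(per_rate)
    rep = classify.loocv_classify(combined[list(FEATURE_COLUMNS)], combined["tissue"],
                                  task_label="combined")
    logger.info("classification combined: accuracy=%.4f", rep.accuracy)
    reports.append(rep)
    return reports


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute every stage and return the consolidated report."""
    # stage 1: records
    if config.curves_path is not None:
        if config.metadata_path is None:
            raise ValueError("curves_path requires metadata_path")
        records = io.read_curves(config.curves_path, config.metadata_path)
        logger.info("read %d records from %s", len(records), config.curves_path)
    else:
        gen_config = synthetic.default_config(
            seed=config.seed, n_points_per_curve=config.n_points_per_curve,
            noise_sd_rel=config.noise_sd_rel)
        records, truth = synthetic.generate_study(gen_config)
        logger.info("generated %d synthetic records (seed %d)", len(records), config.seed)
        if config.out_dir is not None:
            io.write_study(records, truth, config.out_dir)

    # stage 2: property extraction + outlier filter
    props = mechanics.extract_properties(records, preload_zero=config.preload_zero)
    kept, removed = mechanics.remove_outliers(props, k=config.outlier_k)
    for _, row in removed.iterrows():
        logger.info("outlier removed: %s (%s=%.4g outside [%.4g, %.4g])",
                    row["sample_id"], row["property"], row["value"],
                    row["lower"], row["upper"])

    # stage 3: univariate comparisons + effect size / sample size
    uni = _univariate_block(kept, config.alpha)
    d_pooled = univariate.pooled_cohens_d(
        kept, kept["tissue"].to_numpy(), FEATURE_COLUMNS)
    spec = univariate.PowerSpec(d=d_pooled, alpha=config.power_alpha,
                                power=config.power_target,
                                allocation_ratio=config.allocation_ratio)
    n_small, n_large = univariate.required_sample_sizes(spec)
    sample_size = {"cohens_d_pooled": d_pooled, "alpha": config.power_alpha,
                   "power": config.power_target,
                   "allocation_ratio": config.allocation_ratio,
                   "n_small": n_small, "n_large": n_large,
                   "rounding": "total-N search, n_small = round(N/(1+ratio))"}

    # stage 4: classification
    reports = _classification_block(kept)

    provenance = {"config_digest": config.digest(), "seed": config.seed,
                  "package_version": __version__,
                  "n_records": len(records), "n_kept": int(len(kept)),
                  "n_removed": int(kept.shape[0] < props.shape[0] and
                                   props.shape[0] - kept.shape[0] or 0)}
    report = StudyReport(univariate=uni, effect_size=d_pooled,
                         sample_size=sample_size, classification=reports,
                         outliers=removed, properties=kept,
                         provenance=provenance)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_properties(kept, out / "properties.tsv")
        io.write_properties(removed, out / "outliers.tsv")
        write_report(report, out / "report.json")
    return report


def report_to_dict(report: StudyReport) -> dict:
    """JSON-serializable view of a StudyReport."""
    return {
        "provenance": report.provenance,
        "univariate": [
            {"property": r.property_name, "rate_mm_s": r.loading_rate,
             "path": [{"test": s.test, "statistic": s.statistic, "p": s.p_value}
                      for s in r.path],
             "final_test": r.final_test, "final_p": r.final_p,
             "reject": r.reject, "alpha": r.alpha}
            for r in report.univariate
        ],
        "effect_size": {"cohens_d_pooled": report.effect_size},
        "sample_size": report.sample_size,
        "classification": [
            {"task": rep.task_label,
             "confusion": {"tp": rep.confusion.tp, "fp": rep.confusion.fp,
                           "fn": rep.confusion.fn, "tn": rep.confusion.tn},
             "metrics": rep.metrics(),
             "contributions": rep.contributions,
             "notes": rep.notes}
            for rep in report.classification
        ],
        "outliers": report.outliers.to_dict(orient="records"),
    }


def write_report(report: StudyReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def summary_table(report: StudyReport) -> str:
    """Plain-text metric table, one row per classification task."""
    names = ["accuracy", "sensitivity", "specificity", "f1", "roc_auc",
             "mcc", "fmi", "ari"]
    header = "task        " + "  ".join(f"{n:>11s}" for n in names)
    lines = [header]
    for rep in report.classification:
        vals = rep.metrics()
        lines.append(f"{rep.task_label:<12s}" +
                     "  ".join(f"{vals[n]:11.4f}" for n in names))
    return "\n".join(lines)
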