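"""End-to-end orchestration: simulate/load → score → evaluate → curves → compare.

``run_pipeline`` takes a :class:`~thyrisk.io.RunConfig` and writes a report
bundle into the output directory:

* ``cohort.tsv`` — the scored nodule table (simulated or loaded);
* ``metrics.tsv`` / ``metrics.json`` — ROM, resection rates and the full
  accuracy block per classifier under the configured borderline policy and
  CI dialect;
* ``comparisons.json`` — chi-squared comparisons against the published
  external comparators (expression classifier, DNA-RNA panel);
* ``curves_rna.tsv`` / ``curves_gc.tsv`` and ``mode.json`` — predictive
  value curves and the rule-in/rule-out recommendation at the cohort's ROM;
* ``summary.txt`` — a human-readable digest;
* ``metadata.json`` — version, seed, config echo and config hash.

Identical config + seed reproduce an identical bundle.  Stage failures are
re-raised with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alterations import DEFAULT_WEIGHT_TABLE, read_weight_table
from .classifier import ExpressionScoreClassifier, GenomicClassifier
from .errors import ThyriskError
from .io import RunConfig, read_nodule_table, write_nodule_table
from .performance import (
    alteration_summaries,
    binary_metrics,
    compare_proportions,
    confusion_table,
    resection_rates,
    rom,
)
from .prevalence import PrevalenceCurve, recommend_mode
from .reference import GEC_2012, THYROSEQ_V3_2020
from .simulate import CohortConfig, generate_cohort

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(ThyriskError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ThyriskError as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("input")
def _load_cohort(config: RunConfig) -> pd.DataFrame:
    if config.simulate is not None:
        sim = CohortConfig.from_dict({**config.simulate, "seed": config.seed})
        return generate_cohort(sim)
    return read_nodule_table(config.nodule_table)


@_stage("score")
def _score(frame: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    frame = frame.copy()
    weights = (
        read_weight_table(config.weight_table)
        if config.weight_table
        else DEFAULT_WEIGHT_TABLE
    )
    gc = GenomicClassifier(weight_table=weights, threshold=config.gc_threshold,
                           rule=config.rule).fit([])
    need_gc = frame["gc_call"].isna() if "gc_call" in frame else pd.Series(True, index=frame.index)
    if need_gc.any():
        sub = frame.loc[need_gc]
        frame.loc[need_gc, "gc_score"] = gc.decision_function(sub)
        frame.loc[need_gc, "gc_call"] = gc.predict_calls(sub)
    need_rna = frame["rna_call"].isna() & frame["rna_score"].notna()
    if need_rna.any():
        rna = ExpressionScoreClassifier(threshold=config.rna_threshold).fit([])
        frame.loc[need_rna, "rna_call"] = rna.predict_calls(frame.loc[need_rna, "rna_score"])
    return frame


def _metric_rows(name: str, metrics: dict) -> list[dict]:
    return [
        {
            "classifier": name,
            "metric": m.metric,
            "numerator": m.numerator,
            "denominator": m.denominator,
            "point": round(m.point, 6),
            "ci_low": round(m.ci_low, 6),
            "ci_high": round(m.ci_high, 6),
            "ci_method": m.ci_method,
        }
        for m in metrics.values()
    ]


@_stage("evaluate")
def _evaluate(frame: pd.DataFrame, config: RunConfig) -> dict:
    resected = frame[frame["resected"]].reset_index(drop=True)
    out: dict = {"policy": config.borderline_policy, "n_resected": int(len(resected))}
    rom_est = rom(resected, config.borderline_policy, config.ci_method)
    out["rom"] = _metric_rows("cohort", {"rom": rom_est})[0]
    rows: list[dict] = []
    out["confusion"] = {}
    out["operating_points"] = {}
    for clf, call_field in (("rna", "rna_call"), ("gc", "gc_call")):
        if resected[call_field].isna().any():
            continue
        ct = confusion_table(resected, call_field, config.borderline_policy)
        mets = binary_metrics(ct, config.ci_method)
        rows += _metric_rows(clf, mets)
        out["confusion"][clf] = {"tp": ct.tp, "fp": ct.fp, "tn": ct.tn, "fn": ct.fn}
        out["operating_points"][clf] = {
            "sens": mets["sensitivity"].point,
            "spec": mets["specificity"].point,
        }
        if frame[call_field].notna().all():
            pos, neg, cmp = resection_rates(frame, call_field, config.correction,
                                            config.ci_method)
            rows.append({**_metric_rows(clf, {"rr": pos})[0], "metric": "resection_rate_positive"})
            rows.append({**_metric_rows(clf, {"rr": neg})[0], "metric": "resection_rate_negative"})
            out.setdefault("resection_comparison", {})[clf] = {
                "chi2": cmp.chi2_stat, "p_value": cmp.p_value, "correction": cmp.correction,
            }
    try:
        summ = alteration_summaries(resected)
        rows += _metric_rows("alterations", summ)
    except ThyriskError:
        pass  # cohorts without the relevant strata simply omit the block
    out["metrics_table"] = rows
    return out


@_stage("compare")
def _compare(evaluation: dict, config: RunConfig) -> dict:
    comparators = {"rna": ("GEC_2012", GEC_2012), "gc": ("ThyroSeq_v3_2020", THYROSEQ_V3_2020)}
    own = {
        (r["classifier"], r["metric"]): (r["numerator"], r["denominator"])
        for r in evaluation["metrics_table"]
    }
    out: dict = {}
    for clf, (label, published) in comparators.items():
        block = {}
        for metric, (k2, n2) in published.items():
            if (clf, metric) not in own:
                continue
            k1, n1 = own[(clf, metric)]
            cmp = compare_proportions(k1, n1, k2, n2, correction=config.correction)
            block[metric] = {
                "own": f"{k1}/{n1}",
                "published": f"{k2}/{n2}",
                "chi2": round(cmp.chi2_stat, 4),
                "p_value": round(cmp.p_value, 4),
            }
        if block:
            out[clf] = {"comparator": label, "metrics": block}
    return out


@_stage("curves")
def _curves(evaluation: dict, config: RunConfig, out_dir: Path) -> dict:
    rom_point = evaluation["rom"]["point"]
    modes = {}
    for clf, op in evaluation["operating_points"].items():
        curve = PrevalenceCurve.from_operating_point(op["sens"], op["spec"])
        curve.to_frame().to_csv(out_dir / f"curves_{clf}.tsv", sep="\t", index=False,
                                float_format="%.6g")
        rec = recommend_mode(op["sens"], op["spec"], rom_point,
                             npv_target=config.npv_target, ppv_target=config.ppv_target)
        modes[clf] = rec.to_dict()
    return modes


def _summary_text(evaluation: dict, modes: dict) -> str:
    lines = [
        f"thyrisk {__version__} — diagnostic evaluation summary",
        f"borderline policy: {evaluation['policy']}; resected nodules: {evaluation['n_resected']}",
        "rom: {point:.3f} ({numerator}/{denominator}, CI {ci_low:.3f}-{ci_high:.3f}, {ci_method})".format(
            **evaluation["rom"]
        ),
        "",
    ]
    for r in evaluation["metrics_table"]:
        lines.append(
            f"{r['classifier']:>12s} {r['metric']:<28s} "
            f"{100 * r['point']:5.1f}% ({r['numerator']}/{r['denominator']}) "
            f"CI {100 * r['ci_low']:.1f}-{100 * r['ci_high']:.1f}% [{r['ci_method']}]"
        )
    for clf, rec in modes.items():
        lines.append(
            f"\n{clf}: recommended mode at ROM {rec['rom_used']:.3f} -> {rec['mode']} "
            f"(PPV {rec['ppv_at_rom']:.3f} vs target {rec['ppv_target']:.2f}; "
            f"NPV {rec['npv_at_rom']:.3f} vs target {rec['npv_target']:.2f})"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle; returns it."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    frame = _load_cohort(config)
    frame = _score(frame, config)
    write_nodule_table(frame, out_dir / "cohort.tsv")

    evaluation = _evaluate(frame, config)
    pd.DataFrame(evaluation["metrics_table"]).to_csv(
        out_dir / "metrics.tsv", sep="\t", index=False
    )
    (out_dir / "metrics.json").write_text(json.dumps(evaluation, indent=2) + "\n")

    comparisons = _compare(evaluation, config)
    (out_dir / "comparisons.json").write_text(json.dumps(comparisons, indent=2) + "\n")

    modes = _curves(evaluation, config, out_dir)
    (out_dir / "mode.json").write_text(json.dumps(modes, indent=2) + "\n")

    (out_dir / "summary.txt").write_text(_summary_text(evaluation, modes))

    cfg = config.to_dict()
    metadata = {
        "tool": "thyrisk",
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out_dir / "metadata.json").write_text(json.dumps(metadata, indent=2) + "\n")
    return {
        "evaluation": evaluation,
        "comparisons": comparisons,
        "modes": modes,
        "metadata": metadata,
    }
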