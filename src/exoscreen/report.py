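"""End-to-end orchestration: simulate -> filter -> ROC -> combination search.

:func:`run_all` executes the enabled stages in order and emits a per-marker
summary table (AUC, Hanley-McNeil SE and 95% CI, one-tailed Mann-Whitney p,
sensitivity at the forced specificity, PPV at the configured prevalence)
plus a best-combination row, mirroring the screening-statistics table of a
biomarker study.  Every reported number is recomputed from the persisted
intermediate artifacts, and a structured JSON log captures every resolved
parameter so a run is reproducible from its log alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import corefilter, panelselect, rocstats, synthdata
from .io_tables import MarkerPanel, read_panel, write_filter_trace, write_panel

logger = logging.getLogger("exoscreen")


@dataclass
class RunConfig:
    """Parameters of an end-to-end run."""

    seed: int = 0
    out_dir: str = "exoscreen_run"
    run_corefilter: bool = True
    run_roc: bool = True
    run_combine: bool = True
    # panel source: explicit files, or synthetic when None
    panel_path: Optional[str] = None
    panel_labels_path: Optional[str] = None
    # stage parameters
    log2fc_threshold: float = -0.58
    target_specificity: float = panelselect.DEFAULT_TARGET_SPECIFICITY
    prevalence: float = panelselect.DEFAULT_PREVALENCE
    length_tolerance: float = 0.02
    smooth: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


REPORT_COLUMNS = [
    "marker", "auc", "se", "ci_lower", "ci_upper", "p_one_tailed",
    "sensitivity_at_target_spec", "ppv",
]


def _marker_row(name: str, pos: np.ndarray, neg: np.ndarray, cfg: RunConfig) -> dict:
    ev = rocstats.evaluate_marker(
        name, pos, neg,
        rocstats.RocClassifierConfig(length_tolerance=cfg.length_tolerance),
        smooth=cfg.smooth,
    )
    sens, _ = panelselect.sensitivity_at_specificity(pos, neg, cfg.target_specificity)
    return {
        "marker": name,
        "auc": ev.auc,
        "se": ev.se,
        "ci_lower": ev.ci_lower,
        "ci_upper": ev.ci_upper,
        "p_one_tailed": ev.p_one_tailed,
        "sensitivity_at_target_spec": sens,
        "ppv": panelselect.ppv(sens, cfg.target_specificity, cfg.prevalence),
    }


def run_all(cfg: RunConfig) -> dict:
    """Execute the enabled stages; return a bundle and persist all artifacts.

    Bundle keys: ``report`` (the per-marker DataFrame), ``trace`` (filter
    trace or None), ``best_model`` (or None), ``panel``, ``log`` (dict).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": dataclasses.asdict(cfg), "stages": {}}

    trace = None
    if cfg.run_corefilter:
        sim = synthdata.AbundanceSimConfig(seed=cfg.seed)
        study, truth, refs = synthdata.generate_abundance_study(sim)
        fcfg = corefilter.FilterConfig(
            log2fc_threshold=cfg.log2fc_threshold,
            tm_list=refs["tm"],
            common_ev_list=refs["common_ev"],
            exclusion_list=refs.get("exclusion"),
        )
        trace = corefilter.run_pipeline(study, fcfg)
        write_filter_trace(trace, out / "filter_trace.jsonl")
        log["stages"]["corefilter"] = {
            "counts": [
                {"stage": n, "n_in": a, "n_out": b} for n, a, b in trace.counts
            ]
        }
        logger.info("corefilter stage counts: %s", trace.counts)

    if cfg.panel_path is not None:
        if cfg.panel_labels_path is None:
            raise ValueError("panel_labels_path required with panel_path")
        panel = read_panel(cfg.panel_path, cfg.panel_labels_path)
    else:
        panel, true_auc = synthdata.generate_marker_panel(
            synthdata.PanelSimConfig(seed=cfg.seed)
        )
        write_panel(panel, out / "panel.tsv", out / "panel_labels.tsv")
        log["stages"]["simulate_panel"] = {"true_auc": true_auc}

    rows = []
    if cfg.run_roc:
        for m in panel.markers:
            pos = panel.values_for(m, "case")
            neg = panel.values_for(m, "control")
            rows.append(_marker_row(m, pos, neg, cfg))

    best = None
    if cfg.run_combine:
        best, models = panelselect.exhaustive_search(panel, panel.markers)
        perf = panelselect.evaluate_fixed_combination(
            best, panel, cfg.target_specificity, cfg.prevalence
        )
        scores = panelselect.linear_score(best, panel)
        pos = scores[panel.labels == "case"].to_numpy()
        neg = scores[panel.labels == "control"].to_numpy()
        combo_name = "combination(" + "+".join(best.markers) + ")"
        emp = rocstats.empirical_roc(pos, neg)
        a = rocstats.auc(emp)
        se, lo, hi = rocstats.auc_se_ci(a, emp.n_pos, emp.n_neg)
        _, _, p1 = rocstats.mann_whitney(pos, neg)
        rows.append(
            {
                "marker": combo_name,
                "auc": a,
                "se": se,
                "ci_lower": lo,
                "ci_upper": hi,
                "p_one_tailed": p1,
                "sensitivity_at_target_spec": perf.sensitivity,
                "ppv": perf.ppv,
            }
        )
        with open(out / "best_model.json", "w") as fh:
            json.dump(best.to_dict(), fh, indent=2, sort_keys=True)
        log["stages"]["combine"] = {
            "n_models": len(models),
            "best_markers": list(best.markers),
            "best_aic": best.aic,
        }

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report.to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.6g")
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return {
        "report": report,
        "trace": trace,
        "best_model": best,
        "panel": panel,
        "log": log,
    }


def compare_groups(
    panel: MarkerPanel,
    class_a: str,
    class_b: str,
    adjust: Optional[str] = None,
) -> pd.DataFrame:
    """Per-marker Mann-Whitney comparison of two label classes.

    Returns a DataFrame with U, two-tailed and one-tailed p per marker.  No
    multiplicity adjustment by default; ``adjust='bh'`` adds
    Benjamini-Hochberg adjusted two-tailed p-values.
    """
    for c in (class_a, class_b):
        if c not in set(panel.labels):
            raise ValueError(f"unknown class label {c!r}")
    rows = []
    for m in panel.markers:
        u, p2, p1 = rocstats.mann_whitney(
            panel.values_for(m, class_a), panel.values_for(m, class_b)
        )
        rows.append({"marker": m, "U": u, "p_two_tailed": p2, "p_one_tailed": p1})
    df = pd.DataFrame(rows)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = multipletests(df["p_two_tailed"], method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df
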