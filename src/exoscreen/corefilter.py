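"""Candidate-selection cascade for EV surface-protein biomarker discovery.

The cascade narrows a label-free proteome down to ranked transmembrane
candidates in six steps:

1. per-unit replicate detection (a protein counts as detected in a cell line
   or tissue set only if seen in enough biological replicates),
2. per-lineage sets (cell-line evidence intersected with tissue evidence),
3. the core proteome shared by the healthy-FT and tumor lineages,
4. restriction to predicted-transmembrane proteins,
5. subtraction of ubiquitous EV proteins,
6. a log2 fold-change screen keeping proteins that do not drop in the tumor
   group, followed by removal of a manual exclusion list.

Every step records its input/output sets in a :class:`FilterTrace` so the
whole run is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .io_tables import AbundanceStudy, ReferenceList

logger = logging.getLogger("exoscreen")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionRule:
    """Replicate-detection thresholds per unit type.

    Defaults reflect the study design: a protein must appear in >= 2 of the
    3 tumor cell-line passages, in both FT cell-line passages, and in every
    explant of a tissue set.
    """

    min_replicates_hgsoc_cell: int = 2
    min_replicates_ft_cell: int = 2
    tissue_rule: Literal["all_replicates"] = "all_replicates"

    def min_for(self, group: str, source: str, n_replicates: int) -> int:
        if source == "tissue":
            return n_replicates
        m = (
            self.min_replicates_ft_cell
            if group == "FT"
            else self.min_replicates_hgsoc_cell
        )
        if m > n_replicates:
            raise ValueError(
                f"detection rule requires {m} replicates but unit has {n_replicates}"
            )
        return m


@dataclass
class FilterConfig:
    """All parameters of the filtering cascade."""

    detection: DetectionRule = field(default_factory=DetectionRule)
    log2fc_threshold: float = -0.58
    pseudocount: float = 1.0
    tm_list: Optional[ReferenceList] = None
    common_ev_list: Optional[ReferenceList] = None
    exclusion_list: Optional[ReferenceList] = None
    cell_aggregation: Literal["union", "intersection"] = "union"
    fold_change_basis: Literal["pooled", "tissue", "cell_line"] = "pooled"
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass(frozen=True)
class FilterStage:
    name: str
    params: dict
    set_in: frozenset[str]
    set_out: frozenset[str]

    def __post_init__(self) -> None:
        if not self.set_out <= self.set_in:
            raise ValueError(f"stage {self.name!r}: output set is not a subset of input")


@dataclass
class FilterTrace:
    """Ordered record of every cascade stage plus the final ranked list."""

    stages: list[FilterStage] = field(default_factory=list)
    final_ranked: Optional[list[tuple[str, float]]] = None

    def add(self, name: str, params: dict, set_in: frozenset, set_out: frozenset) -> None:
        self.stages.append(FilterStage(name, params, frozenset(set_in), frozenset(set_out)))

    @property
    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, len(s.set_in), len(s.set_out)) for s in self.stages]


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def detected_set(
    study: AbundanceStudy,
    unit: tuple[str, str, str],
    rule: DetectionRule,
) -> frozenset[str]:
    """Proteins detected in a replicate unit under the rule.

    ``unit`` is a (group, source, line_or_patient) key; detection means a
    non-missing and strictly positive intensity, counted across the unit's
    replicates.
    """
    units = study.units()
    if unit not in units or not units[unit]:
        raise ValueError(f"unit {unit!r} has no samples")
    cols = units[unit]
    group, source, _ = unit
    need = rule.min_for(group, source, len(cols))
    vals = study.intensities[cols].to_numpy(dtype=float)
    present = np.nan_to_num(vals, nan=0.0) > 0
    hits = present.sum(axis=1) >= need
    return frozenset(np.asarray(study.proteins)[hits])


def lineage_set(
    study: AbundanceStudy,
    group: str,
    rule: DetectionRule,
    cell_aggregation: Literal["union", "intersection"] = "union",
) -> frozenset[str]:
    """Proteins attributed to a lineage: cell-line evidence ∩ tissue evidence.

    Cell-line detected sets within the group are combined by union (default)
    or intersection; tissue sets (each under the all-replicates rule) are
    combined by union; the two aggregates are intersected.
    """
    cell_units = [u for u in study.units() if u[0] == group and u[1] == "cell_line"]
    tissue_units = [u for u in study.units() if u[0] == group and u[1] == "tissue"]
    if not cell_units or not tissue_units:
        raise ValueError(
            f"group {group!r} needs at least one cell-line and one tissue unit"
        )
    cell_sets = [detected_set(study, u, rule) for u in cell_units]
    if cell_aggregation == "union":
        cells = frozenset().union(*cell_sets)
    elif cell_aggregation == "intersection":
        cells = frozenset.intersection(*cell_sets)
    else:
        raise ValueError(f"unknown cell_aggregation {cell_aggregation!r}")
    tissue = frozenset().union(*(detected_set(study, u, rule) for u in tissue_units))
    return cells & tissue


def core_proteome(ft_set: frozenset[str], hgsoc_set: frozenset[str]) -> frozenset[str]:
    """Proteins shared by the FT and HGSOC lineage sets."""
    if not ft_set or not hgsoc_set:
        raise ValueError("both lineage sets must be non-empty")
    core = frozenset(ft_set) & frozenset(hgsoc_set)
    if not core:
        logger.warning("core proteome is empty: lineage sets are disjoint")
    return core


def transmembrane_filter(core: frozenset[str], tm: ReferenceList) -> frozenset[str]:
    """Restrict to proteins on the predicted-transmembrane reference list."""
    return frozenset(core) & tm.members


def subtract_common_ev(s: frozenset[str], common: ReferenceList) -> frozenset[str]:
    """Remove ubiquitous EV proteins (top-100 common-EV list)."""
    return frozenset(s) - common.members


def _normalized(study: AbundanceStudy, cfg: FilterConfig) -> pd.DataFrame:
    """Per-sample total-intensity normalization to the median sample total."""
    mat = study.intensities
    if not cfg.normalize:
        return mat
    totals = mat.sum(axis=0, skipna=True)
    target = float(np.median(totals))
    return mat * (target / totals)


def _fc_columns(study: AbundanceStudy, group: str, cfg: FilterConfig) -> list[str]:
    if cfg.fold_change_basis == "pooled":
        keep = lambda s: s.group == group
    elif cfg.fold_change_basis == "tissue":
        keep = lambda s: s.group == group and s.source == "tissue"
    else:
        keep = lambda s: s.group == group and s.source == "cell_line"
    return [s.sample_id for s in study.samples if keep(s)]


def log2_fold_change(
    study: AbundanceStudy,
    protein: str,
    cfg: FilterConfig,
    _normed: Optional[pd.DataFrame] = None,
) -> float:
    """log2 of (mean tumor intensity + pc) / (mean FT intensity + pc).

    Means are over non-missing cells of the configured sample basis on the
    normalized scale; measured zeros enter the mean, missing cells do not.
    """
    mat = _normed if _normed is not None else _normalized(study, cfg)
    if protein not in mat.index:
        raise KeyError(f"protein {protein!r} not in study")
    row = mat.loc[protein]
    means = {}
    for group in ("FT", "HGSOC"):
        cols = _fc_columns(study, group, cfg)
        vals = row[cols].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        means[group] = float(vals.mean()) if len(vals) else 0.0
    return float(
        np.log2((means["HGSOC"] + cfg.pseudocount) / (means["FT"] + cfg.pseudocount))
    )


def fold_change_filter(
    s: frozenset[str],
    study: AbundanceStudy,
    cfg: FilterConfig,
) -> list[tuple[str, float]]:
    """Keep proteins with log2FC >= threshold (boundary inclusive), ranked.

    Sorted descending by fold change; ties broken lexicographically by id.
    """
    normed = _normalized(study, cfg)
    fcs = [(p, log2_fold_change(study, p, cfg, _normed=normed)) for p in sorted(s)]
    kept = [(p, fc) for p, fc in fcs if fc >= cfg.log2fc_threshold]
    return sorted(kept, key=lambda t: (-t[1], t[0]))


def run_pipeline(study: AbundanceStudy, cfg: FilterConfig) -> FilterTrace:
    """Execute the full cascade and return its trace.

    Stages: replicate detection -> lineage sets -> core proteome ->
    transmembrane filter -> common-EV subtraction -> fold-change screen ->
    manual exclusion.  Counts are non-increasing along the trace.
    """
    if cfg.tm_list is None or cfg.common_ev_list is None:
        raise ValueError("tm_list and common_ev_list must be configured")
    trace = FilterTrace()
    all_proteins = frozenset(study.proteins)

    detected_any = frozenset().union(
        *(detected_set(study, u, cfg.detection) for u in study.units())
    )
    trace.add(
        "detection",
        {"rule": cfg.detection.__dict__.copy()},
        all_proteins,
        detected_any,
    )

    ft = lineage_set(study, "FT", cfg.detection, cfg.cell_aggregation)
    hg = lineage_set(study, "HGSOC", cfg.detection, cfg.cell_aggregation)
    core = core_proteome(ft, hg)
    trace.add(
        "core_proteome",
        {
            "n_ft_lineage": len(ft),
            "n_hgsoc_lineage": len(hg),
            "cell_aggregation": cfg.cell_aggregation,
        },
        detected_any,
        core,
    )

    tm = transmembrane_filter(core, cfg.tm_list)
    trace.add("transmembrane", {"list": cfg.tm_list.name}, core, tm)

    minus_ev = subtract_common_ev(tm, cfg.common_ev_list)
    trace.add("common_ev_subtraction", {"list": cfg.common_ev_list.name}, tm, minus_ev)

    ranked = fold_change_filter(minus_ev, study, cfg)
    fc_pass = frozenset(p for p, _ in ranked)
    trace.add(
        "fold_change",
        {
            "threshold": cfg.log2fc_threshold,
            "basis": cfg.fold_change_basis,
            "pseudocount": cfg.pseudocount,
            "normalize": cfg.normalize,
        },
        minus_ev,
        fc_pass,
    )

    excl = cfg.exclusion_list.members if cfg.exclusion_list is not None else frozenset()
    final_ranked = [(p, fc) for p, fc in ranked if p not in excl]
    final = frozenset(p for p, _ in final_ranked)
    trace.add(
        "manual_exclusion",
        {"excluded": sorted(excl & fc_pass)},
        fc_pass,
        final,
    )
    trace.final_ranked = final_ranked
    return trace
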