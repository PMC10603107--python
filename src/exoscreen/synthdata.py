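"""Synthetic study-shaped inputs with known ground truth.

Two generators cover the toolkit's inputs:

* :func:`generate_abundance_study` builds a label-free EV proteome table over
  the study design (3 FT cell lines with 2 replicate passages, 6 tumor cell
  lines with 3, and 21 tissue explants split into an FT set, a primary-tumor
  set and an omental-metastasis set).  Membership in every cascade stage is
  planted first and intensities are drawn second, so the filtering pipeline
  recovers the configured stage counts exactly — by default the study flow
  985 core -> 75 transmembrane -> 66 after common-EV subtraction -> 47 past
  the fold-change screen -> 45 after manual exclusion.

* :func:`generate_marker_panel` draws chip-style fluorescence panels that
  are binormal on the log scale: controls ~ exp(N(mu0, sigma0)), cases ~
  exp(N(mu0 + delta, sigma1)), so each marker's true AUC is the closed form
  Phi(delta / sqrt(sigma0^2 + sigma1^2)).

All randomness flows from a single integer seed through numpy's PCG64
generator; regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_tables import AbundanceStudy, MarkerPanel, ReferenceList, SampleMeta

# Study design constants: cell lines with replicate passage counts and the
# tissue-explant sets.
FT_CELL_LINES = {"FT240": 2, "FT246": 2, "FT282": 2}
HGSOC_CELL_LINES = {
    "OVCAR2": 3, "OVCAR3": 3, "OVCAR4": 3, "OVCAR8": 3, "PEO1": 3, "PEO4": 3
}
TISSUE_SETS = {
    ("FT", "FT_tissue"): 6,
    ("HGSOC", "HGSOC_primary"): 9,
    ("HGSOC", "HGSOC_omental"): 6,
}

# Table-style marker panel defaults: seven chip markers with per-marker true
# AUCs matching the case-control study, unit log-scale spreads.
DEFAULT_MARKER_AUCS = {
    "ACSL4": 0.915,
    "IGSF8": 0.895,
    "ITGA2": 0.885,
    "ITGA5": 0.950,
    "ITGB3": 0.980,
    "MYOF": 0.850,
    "FOLR1": 0.925,
}


def delta_for_auc(auc: float, sigma0: float = 1.0, sigma1: float = 1.0) -> float:
    """Log-scale mean shift giving a binormal marker the requested true AUC."""
    return float(norm.ppf(auc) * np.hypot(sigma0, sigma1))


@dataclass(frozen=True)
class MarkerSpec:
    name: str
    delta: float          # log-scale case mean shift
    sigma0: float = 1.0   # control log-sd
    sigma1: float = 1.0   # case log-sd

    def true_auc(self) -> float:
        return float(norm.cdf(self.delta / np.hypot(self.sigma0, self.sigma1)))


def default_marker_specs() -> list[MarkerSpec]:
    return [MarkerSpec(m, delta_for_auc(a)) for m, a in DEFAULT_MARKER_AUCS.items()]


# ---------------------------------------------------------------------------
# Abundance-study generator
# ---------------------------------------------------------------------------

@dataclass
class AbundanceSimConfig:
    """Planted stage sizes and noise for the proteome generator.

    The defaults mirror the study's printed flow: 985 shared core proteins of
    which 75 are transmembrane, 9 of those on the common-EV list, 47 of the
    remaining 66 passing the fold-change screen and 2 of the 47 on the
    manual exclusion list (leaving 45).  Lineage-only counts (208 FT, 324
    tumor) reproduce the per-lineage totals 1193 and 1309.
    """

    n_shared_core: int = 985
    n_ft_only: int = 208
    n_hgsoc_only: int = 324
    n_cellline_only_per_group: int = 120
    n_tissue_only_per_group: int = 80
    n_tm_in_core: int = 75
    n_common_ev_in_tm: int = 9
    n_fc_pass: int = 47
    n_excluded_in_fc: int = 2
    detection_dropout: float = 0.05
    intensity_lognormal_params: tuple[float, float] = (9.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_shared_core, self.n_ft_only, self.n_hgsoc_only,
            self.n_cellline_only_per_group, self.n_tissue_only_per_group,
            self.n_tm_in_core, self.n_common_ev_in_tm, self.n_fc_pass,
            self.n_excluded_in_fc,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if not (self.n_common_ev_in_tm <= self.n_tm_in_core <= self.n_shared_core):
            raise ValueError(
                "nesting violated: need n_common_ev_in_tm <= n_tm_in_core <= n_shared_core"
            )
        if self.n_fc_pass > self.n_tm_in_core - self.n_common_ev_in_tm:
            raise ValueError("n_fc_pass exceeds the post-subtraction set size")
        if self.n_excluded_in_fc > self.n_fc_pass:
            raise ValueError("n_excluded_in_fc exceeds n_fc_pass")
        if not 0 <= self.detection_dropout < 1:
            raise ValueError("detection_dropout must be in [0, 1)")


def _sample_design() -> list[SampleMeta]:
    samples = []
    for line, reps in FT_CELL_LINES.items():
        for r in range(1, reps + 1):
            samples.append(SampleMeta(f"{line}_r{r}", "FT", "cell_line", line, r))
    for line, reps in HGSOC_CELL_LINES.items():
        for r in range(1, reps + 1):
            samples.append(SampleMeta(f"{line}_r{r}", "HGSOC", "cell_line", line, r))
    for (group, tset), n in TISSUE_SETS.items():
        for r in range(1, n + 1):
            samples.append(SampleMeta(f"{tset}_e{r}", group, "tissue", tset, r))
    return samples


def generate_abundance_study(
    cfg: AbundanceSimConfig,
) -> tuple[AbundanceStudy, dict, dict[str, ReferenceList]]:
    """Build an abundance study with planted cascade membership.

    Returns (study, truth, reference_lists) where ``truth`` holds the exact
    protein sets every pipeline stage must recover and ``reference_lists``
    has keys ``tm``, ``common_ev`` and ``exclusion``.

    Membership logic: shared-core proteins are present in every replicate of
    every unit; lineage-only proteins only in their lineage's units;
    cell-line-only and tissue-only proteins are planted to fail the
    cell-evidence x tissue-evidence intersection.  Detection dropout removes
    single replicates only where the detection rule tolerates it (tumor cell
    lines, which need 2 of 3 passages), so planted membership never breaks.
    Fold changes for the 66 candidate proteins are planted as explicit tumor
    vs FT group multipliers with margins well clear of the -0.58 threshold;
    those proteins carry reduced multiplicative noise so pooled group means
    cannot cross it.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = _sample_design()
    sample_ids = [s.sample_id for s in samples]
    mu, sigma = cfg.intensity_lognormal_params

    def ids(prefix: str, n: int, start: int = 1) -> list[str]:
        return [f"{prefix}{i:04d}" for i in range(start, start + n)]

    core = ids("CORE", cfg.n_shared_core)
    ft_only = ids("FTONLY", cfg.n_ft_only)
    hg_only = ids("HGONLY", cfg.n_hgsoc_only)
    ft_cell_only = ids("FTCELL", cfg.n_cellline_only_per_group)
    hg_cell_only = ids("HGCELL", cfg.n_cellline_only_per_group)
    ft_tissue_only = ids("FTTISS", cfg.n_tissue_only_per_group)
    hg_tissue_only = ids("HGTISS", cfg.n_tissue_only_per_group)

    tm_core = core[: cfg.n_tm_in_core]
    common_ev_in_tm = tm_core[: cfg.n_common_ev_in_tm]
    candidates = tm_core[cfg.n_common_ev_in_tm :]  # the 66
    fc_pass = list(candidates[: cfg.n_fc_pass])
    fc_fail = list(candidates[cfg.n_fc_pass :])
    # give the planted exclusions their literature names
    excl_names = ["IGHM", "ADAM10", *ids("EXCL", max(0, cfg.n_excluded_in_fc - 2))]
    exclusions = []
    for i in range(cfg.n_excluded_in_fc):
        new = excl_names[i]
        old = fc_pass[i]
        fc_pass[i] = new
        candidates = [new if p == old else p for p in candidates]
        tm_core = [new if p == old else p for p in tm_core]
        core = [new if p == old else p for p in core]
        exclusions.append(new)

    all_proteins = (
        core + ft_only + hg_only
        + ft_cell_only + hg_cell_only + ft_tissue_only + hg_tissue_only
    )

    # planted log2 fold changes for the 66 candidates, margins >= 0.28 from
    # the -0.58 threshold on either side
    planted_fc: dict[str, float] = {}
    pass_vals = np.linspace(-0.30, 2.2, max(len(fc_pass), 1))
    for p, v in zip(fc_pass, pass_vals):
        planted_fc[p] = float(v)
    fail_vals = np.linspace(-2.5, -1.1, max(len(fc_fail), 1))
    for p, v in zip(fc_fail, fail_vals):
        planted_fc[p] = float(v)

    # presence[protein, unit] in {"all", "none"}
    units = {}
    for s in samples:
        units.setdefault((s.group, s.source, s.line_or_patient), []).append(s.sample_id)

    def present_units(pid: str) -> set:
        if pid in core_set:
            return set(units)
        if pid in ft_only_set:
            return {u for u in units if u[0] == "FT"}
        if pid in hg_only_set:
            return {u for u in units if u[0] == "HGSOC"}
        if pid in ft_cell_set:
            return {u for u in units if u[0] == "FT" and u[1] == "cell_line"}
        if pid in hg_cell_set:
            return {u for u in units if u[0] == "HGSOC" and u[1] == "cell_line"}
        if pid in ft_tiss_set:
            return {u for u in units if u[0] == "FT" and u[1] == "tissue"}
        return {u for u in units if u[0] == "HGSOC" and u[1] == "tissue"}

    core_set, ft_only_set, hg_only_set = set(core), set(ft_only), set(hg_only)
    ft_cell_set, hg_cell_set = set(ft_cell_only), set(hg_cell_only)
    ft_tiss_set, hg_tiss_set = set(ft_tissue_only), set(hg_tissue_only)
    candidate_set = set(candidates)

    n_p, n_s = len(all_proteins), len(sample_ids)
    col_of = {sid: j for j, sid in enumerate(sample_ids)}
    group_of = {s.sample_id: s.group for s in samples}

    # group-specific proteins get a lower intensity scale than the shared
    # core so per-sample totals (hence the normalization factors) are
    # dominated by the shared mass and stay comparable across lineages
    base = np.empty(n_p)
    for i, pid in enumerate(all_proteins):
        shift = 0.0 if pid in core_set else -3.0
        base[i] = np.exp(rng.normal(mu + shift, sigma))

    mat = np.full((n_p, n_s), np.nan)
    for i, pid in enumerate(all_proteins):
        noise_sd = 0.05 if pid in candidate_set else 0.2
        fc_mult = 2.0 ** planted_fc.get(pid, 0.0)
        for u in present_units(pid):
            cols = [col_of[sid] for sid in units[u]]
            vals = base[i] * np.exp(rng.normal(0.0, noise_sd, size=len(cols)))
            if pid in planted_fc and u[0] == "HGSOC":
                vals = vals * fc_mult
            mat[i, cols] = vals
        # sub-threshold presence in one replicate of an absent tumor cell
        # line, to exercise the 2-of-3 rule without affecting membership
        if pid in hg_only_set | hg_cell_set:
            continue
        if pid not in core_set and rng.random() < 0.3:
            absent_hg_cells = [
                u for u in units
                if u[0] == "HGSOC" and u[1] == "cell_line" and u not in present_units(pid)
            ]
            if absent_hg_cells:
                u = absent_hg_cells[rng.integers(len(absent_hg_cells))]
                j = col_of[units[u][rng.integers(len(units[u]))]]
                mat[i, j] = base[i] * np.exp(rng.normal(0.0, 0.2))

    # dropout: only tumor cell lines tolerate losing one of three passages
    if cfg.detection_dropout > 0:
        for i, pid in enumerate(all_proteins):
            for u in present_units(pid):
                if u[1] == "cell_line" and u[0] == "HGSOC":
                    if rng.random() < cfg.detection_dropout:
                        j = col_of[units[u][rng.integers(len(units[u]))]]
                        mat[i, j] = np.nan

    order = rng.permutation(n_p)
    all_proteins = [all_proteins[i] for i in order]
    mat = mat[order]

    study = AbundanceStudy(
        intensities=pd.DataFrame(mat, index=all_proteins, columns=sample_ids),
        samples=samples,
    )

    # reference lists: transmembrane = planted 75 + decoys outside the study;
    # common-EV = planted 9 padded to the conventional top-100
    tm_members = set(tm_core) | set(ids("TMDECOY", 50))
    ev_members = set(common_ev_in_tm) | set(ids("EVDECOY", 100 - cfg.n_common_ev_in_tm))
    refs = {
        "tm": ReferenceList("predicted_transmembrane", frozenset(tm_members), "synthetic"),
        "common_ev": ReferenceList("common_ev_top100", frozenset(ev_members), "synthetic"),
    }
    if exclusions:
        refs["exclusion"] = ReferenceList(
            "manual_exclusion", frozenset(exclusions), "synthetic"
        )

    truth = {
        "ft_lineage": frozenset(core) | frozenset(ft_only),
        "hgsoc_lineage": frozenset(core) | frozenset(hg_only),
        "core": frozenset(core),
        "tm": frozenset(tm_core),
        "after_common_ev": frozenset(candidates),
        "fc_pass": frozenset(fc_pass),
        "final": frozenset(fc_pass) - frozenset(exclusions),
        "planted_log2fc": planted_fc,
    }
    return study, truth, refs


# ---------------------------------------------------------------------------
# Marker-panel generators
# ---------------------------------------------------------------------------

@dataclass
class PanelSimConfig:
    """Chip-panel generator settings.

    Defaults emulate the case-control chip study: 10 cases vs 20 controls
    over seven markers whose log-scale shifts reproduce the reported
    single-marker AUCs, with unit log-sds in both classes.
    """

    n_cases: int = 10
    n_controls: int = 20
    markers: list[MarkerSpec] = field(default_factory=default_marker_specs)
    mu0: float = 6.0                # control log-mean (fluorescence ~ e^6)
    background_level: float = 0.0
    n_cancer_types: int = 12
    n_per_cancer_type: int = 5
    non_ovarian_shift: float = 0.0  # log-scale shift of non-ovarian classes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        for m in self.markers:
            if m.sigma0 <= 0 or m.sigma1 <= 0:
                raise ValueError(f"marker {m.name!r}: sigmas must be positive")


def _draw_class(
    rng: np.random.Generator,
    n: int,
    cfg: PanelSimConfig,
    shift_of,
    sigma_of,
) -> np.ndarray:
    cols = []
    for m in cfg.markers:
        cols.append(np.exp(rng.normal(cfg.mu0 + shift_of(m), sigma_of(m), size=n)))
    return np.column_stack(cols)


def generate_marker_panel(cfg: PanelSimConfig) -> tuple[MarkerPanel, dict[str, float]]:
    """Binormal-on-log-scale case/control panel with known true AUC per marker."""
    rng = np.random.default_rng(cfg.seed)
    names = [m.name for m in cfg.markers]
    controls = _draw_class(rng, cfg.n_controls, cfg, lambda m: 0.0, lambda m: m.sigma0)
    cases = _draw_class(rng, cfg.n_cases, cfg, lambda m: m.delta, lambda m: m.sigma1)
    intens = np.vstack([cases, controls]) + cfg.background_level
    index = [f"case_{i+1:03d}" for i in range(cfg.n_cases)] + [
        f"control_{i+1:03d}" for i in range(cfg.n_controls)
    ]
    labels = pd.Series(
        ["case"] * cfg.n_cases + ["control"] * cfg.n_controls, index=index
    )
    background = (
        {m: cfg.background_level for m in names} if cfg.background_level > 0 else None
    )
    panel = MarkerPanel(
        intensities=pd.DataFrame(intens, index=index, columns=names),
        labels=labels,
        background=background,
    )
    truth = {m.name: m.true_auc() for m in cfg.markers}
    return panel, truth


def generate_multicancer_panel(cfg: PanelSimConfig) -> MarkerPanel:
    """Multi-class specificity panel: healthy controls, ovarian cases, and
    non-ovarian cancer classes drawn from the control distribution plus a
    configurable small shift."""
    if cfg.n_cancer_types < 1:
        raise ValueError("need at least one non-ovarian cancer type")
    rng = np.random.default_rng(cfg.seed)
    names = [m.name for m in cfg.markers]
    blocks, labels, index = [], [], []
    for t in range(1, cfg.n_cancer_types + 1):
        blocks.append(
            _draw_class(
                rng, cfg.n_per_cancer_type, cfg,
                lambda m: cfg.non_ovarian_shift, lambda m: m.sigma0,
            )
        )
        labels += [f"cancer_{t:02d}"] * cfg.n_per_cancer_type
        index += [
            f"cancer_{t:02d}_{i+1:02d}" for i in range(cfg.n_per_cancer_type)
        ]
    blocks.append(_draw_class(rng, cfg.n_cases, cfg, lambda m: m.delta, lambda m: m.sigma1))
    labels += ["ovarian"] * cfg.n_cases
    index += [f"ovarian_{i+1:03d}" for i in range(cfg.n_cases)]
    blocks.append(_draw_class(rng, cfg.n_controls, cfg, lambda m: 0.0, lambda m: m.sigma0))
    labels += ["healthy"] * cfg.n_controls
    index += [f"healthy_{i+1:03d}" for i in range(cfg.n_controls)]
    intens = np.vstack(blocks) + cfg.background_level
    return MarkerPanel(
        intensities=pd.DataFrame(intens, index=index, columns=names),
        labels=pd.Series(labels, index=index),
    )
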