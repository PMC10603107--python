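# exoscreen

Toolkit for discovering and evaluating extracellular-vesicle (EV) surface-protein
biomarkers for early cancer detection, modelled on the analysis path used in
high-grade serous ovarian carcinoma (HGSOC) screening studies: from a label-free
EV proteome to a ranked list of transmembrane candidates, and from a chip-style
marker panel to screening operating characteristics.

## Who it is for

Computational biologists and biostatisticians working on EV proteomics
biomarker discovery who need a reproducible, auditable implementation of:

1. **Core-proteome filtering** — replicate-detection rules (a protein counts
   only if seen in ≥ 2 of 3 tumor cell-line passages, both fallopian-tube (FT)
   cell-line passages, and every explant of a tissue set), per-lineage
   cell-line × tissue evidence intersection, the FT/HGSOC shared core
   proteome, restriction to predicted-transmembrane proteins, subtraction of
   the top-100 common-EV proteins, and a log₂ fold-change screen
   (log₂FC ≥ −0.58, boundary inclusive) with a manual exclusion list.
2. **Single-marker ROC statistics** — tie-aware empirical ROC curves (AUC =
   U/(n₁n₀) exactly), Gaussian-kernel smoothed ROC estimates
   ROC(t) = 1 − F̂₁(F̂₀⁻¹(1 − t)), Hanley–McNeil standard errors and 95% CIs,
   one-tailed Mann–Whitney p-values, and the ROC **arc length** statistic
   (2 for a perfect monotone marker, √2 for chance) used to flag
   *non-monotone* markers: length > 1.6 with AUC ∈ [0.35, 0.65], markers
   that differ in spread rather than location.
3. **Marker-panel selection** — exhaustive logistic-regression search over
   all 2ᵏ − 1 marker subsets on log intensities, AIC = 2k − 2·lnL selection,
   the intercept-free linear score Σ βᵢ·log(xᵢ), Youden-index cutoffs,
   sensitivity at a forced specificity (0.998), and positive predictive value
   PPV = s·p / (s·p + (1 − q)(1 − p)) at population prevalence p = 1/2500.
4. **Synthetic data with ground truth** — a proteome generator that plants
   stage membership so the full cascade is exactly verifiable, and a
   binormal-on-log-scale panel generator whose per-marker true AUC is the
   closed form Φ(δ/√(σ₀² + σ₁²)).

## Worked example

```bash
exoscreen run-all --seed 0 --out demo/
```

simulates the default study (a planted proteome over 3 FT cell lines, 6 HGSOC
cell lines and 21 tissue explants, plus a 10-case / 20-control seven-marker
chip panel), runs the filtering cascade, and prints the screening table:

```
            marker   auc       se  ci_lower  ci_upper  p_one_tailed  sensitivity_at_target_spec      ppv
             ACSL4 0.950 0.050375  0.851266  1.000000      0.000041                         0.8 0.137979
             IGSF8 0.845 0.084525  0.679334  1.000000      0.001291                         0.4 0.074102
             ITGA2 0.850 0.083373  0.686592  1.000000      0.001116                         0.4 0.074102
             ITGA5 0.920 0.062958  0.796605  1.000000      0.000120                         0.8 0.137979
             ITGB3 1.000 0.000000  1.000000  1.000000      0.000006                         1.0 0.166722
              MYOF 0.785 0.096120  0.596609  0.973391      0.006465                         0.3 0.056625
             FOLR1 0.925 0.061087  0.805272  1.000000      0.000101                         0.7 0.122850
combination(ITGB3) 1.000 0.000000  1.000000  1.000000      0.000006                         1.0 0.166722
```

Each row is one marker: empirical AUC with Hanley–McNeil SE and truncated 95%
CI, the one-tailed Mann–Whitney p against AUC = 0.5, the sensitivity at a
cutoff forcing specificity ≥ 0.998, and the PPV of that operating point at
prevalence 1/2500 (e.g. a marker with sensitivity 0.8 at specificity 0.998
gives PPV ≈ 0.138 — of women flagged positive, ~13.8% would truly have the
disease). The final row is the minimum-AIC marker combination; with 30
samples and an essentially perfectly separating marker, AIC picks the single
marker ITGB3 here. `demo/filter_trace.jsonl` records the cascade stage by
stage — with the default generator the counts run
985 core → 75 transmembrane → 66 after common-EV subtraction → 47 past the
fold-change screen → 45 after manual exclusion.

Library use mirrors the CLI:

```python
from exoscreen import (AbundanceSimConfig, FilterConfig,
                       generate_abundance_study, run_pipeline, ppv)

study, truth, refs = generate_abundance_study(AbundanceSimConfig(seed=0))
trace = run_pipeline(study, FilterConfig(tm_list=refs["tm"],
                                         common_ev_list=refs["common_ev"],
                                         exclusion_list=refs["exclusion"]))
print(trace.counts)              # stage-by-stage (name, n_in, n_out)
print(ppv(0.80, 0.998, 1/2500))  # 0.1379...
```

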