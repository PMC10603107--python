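# Methods

## Problem setting

EVs shed by fallopian-tube (FT) epithelium and by high-grade serous ovarian
carcinoma (HGSOC) carry surface proteins that can be immunocaptured from a
few drops of plasma. A screening biomarker for this disease must satisfy two
very different kinds of constraints at once: it must be *lineage-associated*
(present on EVs from both the healthy tissue of origin and the tumor, so it
can flag disease while still confined to the tube), and its panel must reach
extreme specificity, because at a population prevalence of 1/2500 even a 1%
false-positive rate swamps the true positives. The package implements the
analysis chain for both halves: proteome-level candidate filtering, and
panel-level screening statistics.

## Filtering cascade (corefilter)

Detection is per replicate unit: a protein is "detected" in a cell line or
tissue-explant set when it has a non-missing, strictly positive intensity in
enough replicates — at least 2 of the 3 passages for a tumor cell line, both
passages for an FT cell line, and *all* explants of a tissue set. Missing
cells (empty in the table) and measured zeros both fail detection, but only
missing cells are excluded from fold-change means; label-free tables
routinely distinguish the two and the convention is configurable upstream of
the package by how the table is written.

A lineage set is (aggregate of the lineage's cell-line detected sets) ∩
(union of its tissue sets). Whether cell lines are combined by union or
intersection is genuinely open; the default is union, reading "proteins
found in the group" as any-cell-line evidence and maximizing sensitivity at
the discovery stage, with intersection available via
`FilterConfig.cell_aggregation`. The core proteome is the intersection of
the two lineage sets; it is then intersected with a predicted-transmembrane
reference list, the top-100 common-EV list is subtracted, and the survivors
pass a log₂ fold-change screen.

Fold changes default to pooled means over all of a lineage's samples (cell
lines and tissues), after per-sample total-intensity normalization to the
median sample total (removing loading differences), with a pseudocount of
1.0 on the normalized scale guarding log₂ of zero means. The threshold
log₂FC ≥ −0.58 is *inclusive* — a protein exactly at the boundary is
retained; the intent of a slightly negative threshold is to keep proteins
already present in FT that do not fall as disease progresses. The ranked
list is sorted by descending fold change with lexicographic tie-breaks for
determinism, and a manual exclusion list (literature-known common EV
proteins such as IGHM and ADAM10) is removed last. Every stage logs its
input/output sets in a `FilterTrace`, so n_out is provably non-increasing
and any run can be audited from its JSON-lines trace.

## Single-marker statistics (rocstats)

The empirical ROC curve sweeps pooled distinct scores from high to low;
scores tied at a threshold advance TPR and FPR simultaneously (a diagonal
segment). With this convention the trapezoidal AUC equals the midrank
Mann–Whitney U divided by n₁n₀ *exactly*, which the test suite asserts to
1e-12; p-values come from `scipy.stats.mannwhitneyu` (exact enumeration when
both n ≤ 8 without ties, tie-corrected normal approximation otherwise). The
reported one-tailed p is the tail in the observed direction, which for a
case-elevated marker is the test against AUC = 0.5 from above.

The smoothed ROC estimates each group's score distribution by a
Gaussian-kernel CDF, F̂(x) = mean Φ((x − xᵢ)/h), with per-group Silverman
bandwidths h = 0.9·min(sd, IQR/1.34)·n^(−1/5); the curve is
ROC(t) = 1 − F̂₁(F̂₀⁻¹(1 − t)) evaluated on a 2001-point FPR grid, the
control-CDF inverse taken by monotone interpolation on a 4001-point support
grid spanning both samples ± 6 bandwidths. A zero-spread group makes the
kernel degenerate; the estimator then falls back to the empirical curve with
a warning.

Arc length is the polygonal length Σ√(ΔFPR² + ΔTPR²), compensated-summed so
the axis-aligned steps of a perfectly separating empirical curve telescope
to exactly 2.0 (and a pure diagonal to √2). Classification is joint on
(AUC, length): *monotone* needs length within a tolerance ε of 2 — ε
defaults to 0.02 because a smooth estimate never attains 2 exactly — and
AUC > 0.8 or < 0.2; *non-monotone* needs length > 1.6 and AUC in
[0.35, 0.65]; monotone wins if both fire. Non-monotone markers matter
because a scale difference between classes bows the ROC curve on both sides
of the diagonal while leaving AUC near 0.5: AUC alone would discard them.

AUC standard errors use the Hanley–McNeil moments (Q₁ = A/(2−A),
Q₂ = 2A²/(1+A)) with a normal 95% CI truncated to [0,1]; DeLong-style
resampling is out of scope. These are the defaults of the classic graphics
packages such tables are produced with; they are the package's choice, not a
claim about any particular historical computation.

## Panel selection and screening statistics (panelselect)

Case/control status is regressed on natural-log marker intensities by
maximum likelihood (`statsmodels.Logit`). Natural logs are the package's
convention; the base only rescales coefficients and leaves rankings and all
operating characteristics unchanged, so externally printed coefficients are
comparable only up to that base. The exhaustive search fits all 2ᵏ − 1
non-empty subsets (127 for 7 markers) and selects minimum AIC = 2k − 2lnL
(k counting the intercept), ties broken toward fewer markers, then
lexicographic names.

Small high-AUC panels routinely separate perfectly, and the logistic MLE
then does not exist. Fits that fail to converge, return non-finite
parameters, or exceed |β| > 10³ are redone with a weak ridge penalty
(λ = 1e-4 on slopes only, intercept unpenalized, BFGS on the penalized
likelihood) and flagged `separation=True`; the reported log-likelihood and
AIC are the *unpenalized* values at the returned coefficients, so the AIC
identity holds for every model.

The combined marker score is the intercept-free linear term Σ βᵢ·log(xᵢ).
Operating points treat a sample as positive when its score exceeds the
cutoff; candidate cutoffs are midpoints of adjacent distinct scores plus
sentinels beyond the range. The Youden cutoff maximizes J = sens + spec − 1
(ties → higher specificity, then lower cutoff). "Sensitivity at forced
specificity q" takes the smallest cutoff with empirical specificity ≥ q;
with 20 controls and q = 0.998 the only admissible cutoffs sit above the
control maximum, so the achieved empirical specificity is 1.0 — this literal
reading is implemented and noted in the output. PPV is the exact Bayes form
s·p/(s·p + (1−q)(1−p)) and, when a fixed combination is applied to a panel,
is evaluated at the *forced target* specificity (the screening operating
point being quoted), not at the empirical 1.0 that a small control group
cannot distinguish from it; this is the only reading under which the
published-style table values (sens 0.30 → PPV 0.057, …, 0.80 → 0.138,
0.90 → 0.153 at p = 1/2500) back out. Fixed-model application never refits;
the caller is responsible for panel independence.

## Synthetic data (synthdata)

The proteome generator plants membership first and draws intensities second.
Each protein belongs to one category — shared core, FT-only, tumor-only,
cell-line-only or tissue-only per lineage — and is present in exactly the
replicate patterns that category implies, so the cascade's set logic is
verifiable exactly, independent of noise. Defaults reproduce the reference
study flow: 985 shared core (75 transmembrane, 9 on the common-EV list, 47
of the 66 candidates passing the fold-change screen, 2 of those on the
exclusion list → 45 final) and lineage totals 1193 (FT) and 1309 (tumor).
Detection dropout (default 5%) removes single replicates only where the rule
tolerates it (tumor cell lines, 2-of-3), so planted membership is invariant
to it. Base intensities are lognormal (ln-mean 9, ln-sd 1 for shared
proteins); group-restricted proteins sit three log units lower so per-sample
totals — and hence normalization factors — are dominated by shared mass and
comparable across lineages. The 66 fold-change candidates carry explicit
tumor/FT multipliers 2^fc with planted fc at least 0.25 bits clear of the
−0.58 threshold and reduced per-sample noise (ln-sd 0.05), which keeps
pooled group means from crossing the boundary at any seed.

The panel generator draws controls ~ exp(N(μ₀, σ₀)) and cases ~
exp(N(μ₀ + δ, σ₁)) per marker, so the true AUC is Φ(δ/√(σ₀² + σ₁²)) and δ
can be chosen in closed form for any target AUC. Defaults emulate the chip
study: 10 cases vs 20 controls, seven markers at AUCs 0.85–0.98, unit
log-sds, μ₀ = 6 (fluorescence ≈ 400 a.u.). The multi-class variant adds 12
non-ovarian cancer classes of 5 samples drawn from the control distribution
(plus a configurable shift, default 0), 10 ovarian cases and 20 healthy
controls — 90 samples.

What the generators deliberately do not emulate: correlated markers (real
integrins co-vary), batch and chip-to-chip effects, heavy-tailed or censored
fluorescence, missing-not-at-random dropout tied to abundance, and
peptide-level identification uncertainty. Passing tests therefore
demonstrate the *statistical machinery* is correct under the stated model,
not that the biological conclusions transfer to any particular real dataset.

## Numerical choices and problem sizes

Determinism: every stochastic routine takes a single integer seed through
`numpy.random.default_rng`; ranked outputs use lexicographic tie-breaks.
Table round-trips write `%.17g` floats and read with round-trip parsing.
The test suite exercises the heavy simulations at sizes chosen to make the
checks sharp yet quick: the smoothed-ROC closed-form comparison at
n = 2000/2000 per δ ∈ {0, 0.5, 1, 2} (tolerance 0.02), the AUC–U identity on
1000 random instances (1e-12), AIC subset recovery over 50 seeded panels of
n = 400 (both planted markers recovered in ≥ 90%), and null calibration of
the rank test over 500 seeds (KS at α = 0.01).

## Known limitations

- No DeLong SE/CI, partial AUC, covariate-adjusted ROC or multi-reader
  designs.
- No accession↔symbol mapping: identifiers are opaque case-normalized keys.
- Multi-class panels are handled only by per-class Mann–Whitney comparisons;
  there is no multi-class classifier.
- The ridge fallback under separation makes coefficient *magnitudes*
  penalty-dependent; only the separating direction and the downstream
  operating points are stable.
- No multiple-testing correction by default (per-marker reporting fidelity);
  Benjamini–Hochberg is available via a flag.
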