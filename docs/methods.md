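# Methods

## Problem setting

Untargeted reversed-phase LC–MS lipidomics produces tables of putative
lipid identifications: a molecular formula, a lipid class, a retention
time (*t*ᵣ, minutes), whether the call is backed by fragmentation data
(MS², versus precursor-only MS¹), and a name. Two different processing
platforms given identical spectra frequently disagree, and neither
platform's confidence score cleanly separates good calls from bad ones.
`lipidqc` quantifies (a) how much two platforms agree and (b) how
internally coherent a single platform's calls are with their own
elution order, and surfaces suspect annotations for manual review. It
deliberately stops there: spectra are never re-processed, platform
scores are carried through untouched, and no external retention library
is consulted.

## Concordance rule and pairing

Two identifications agree when their formulas are identical (compared
as canonical Hill strings), their class tokens are identical (after
whitespace canonicalization and an optional user-supplied synonym map,
e.g. collapsing ceramide subclasses), and |Δ*t*ᵣ| ≤ 5 s. The tolerance
is configurable and supplied in seconds; times are held in minutes
internally.

Pairing is one-to-one. Annotations are blocked by (formula, class) —
only within-block pairs can be eligible — and each block is solved by
optimal assignment (`scipy.optimize.linear_sum_assignment`) with cost
|Δ*t*ᵣ| for eligible pairs and a constant larger than any achievable
total for ineligible ones. This maximizes the number of matched pairs
and, among maximum matchings, minimizes the total retention gap. We
chose assignment over greedy nearest-gap matching because greedy is not
maximum-cardinality: with tolerance τ, rows A = {t, t+1.2τ} and
B = {t+τ, t+2.2τ} let greedy take the middle pair and strand both ends,
reporting 1 common where 2 exist. Rows are sorted canonically
(formula, class, *t*ᵣ, id) before assignment, so results do not depend
on input order, and the matching count is symmetric in A and B.

Agreement is n_common / n_union with n_union = |A| + |B| − n_common.
Before counting, rows within one table identical in (formula, class)
and within the retention tolerance of their group's earliest member are
collapsed onto that member. Platforms commonly emit the same species
several times across adducts or alignment slices; counting those as
distinct inflates the union and depresses agreement. The collapse is
configurable (`dedup=False` / `--no-dedup`) because the right
granularity depends on how the export was produced.

## Retention-time model

Features are the element counts of the parent formula (columns fixed by
the table's element universe in Hill order — C, H, then alphabetical)
plus a one-hot column per lipid class present (alphabetical).
Deuterium is kept as its own element column by default, since
deuterated internal standards (e.g. d7-DG) are real, slightly
retention-shifted species; `merge_deuterium=True` folds D into H.
Numeric columns are auto-scaled (zero mean, unit variance over the full
table); one-hot columns are left as 0/1. *t*ᵣ is regressed in raw
minutes.

The regressor is an ε-insensitive linear SVR (libsvm via scikit-learn),
kernel fixed to linear, C = 10, solver tolerance 1e−4. The linear
kernel encodes the working assumption that the latent drivers —
acyl length (H count), saturation (the C–H relationship, equivalently
double-bond equivalents), headgroup polarity (class) — act additively
on elution time over the span of one run; it also keeps the fit
deterministic, fast, and stable under the strong C–H collinearity.
ε defaults to 0.1 min: comfortably above solver noise, well below the
0.75-min flagging threshold, so the tube absorbs alignment-level jitter
without blunting outlier detection. Both C and ε are configurable.

Every annotation is predicted by a model trained on all other
annotations (leave-one-out cross-validation, LOOCV). The
implementation exploits an exact property of the SVR dual: a training
point strictly inside the ε-tube has zero dual coefficient, so deleting
it leaves the KKT conditions — hence the fitted function — unchanged,
and its held-out prediction equals the full-model prediction. Only
support-vector folds are therefore refitted. This is an identity, not
an approximation; the test suite checks the shortcut against an
explicit n-refit loop. With per-fold feature scaling (below) the design
matrix itself changes in every fold, so that mode always takes the
explicit loop.

Scaling scope is `global` by default: the scaler is fitted once on the
full table before cross-validation. This mirrors preprocessing applied
to the table as a whole and keeps LOOCV folds comparable; it leaks one
row's contribution to the column means into its own fold, which for
tables of ≥ 100 rows is negligible. `per_fold` refits the scaler inside
each training fold for a strictly leakage-free protocol; on synthetic
tables the two differ by well under the flagging threshold.

A one-hot column is defined over the full table, so a fold that removes
a class's only member still has that (all-zero in training) column; the
held-out prediction then rests on the intercept and element features.

## Flagging and consistency

An annotation is flagged when |observed − predicted| exceeds 5 % of the
run time — strictly: a residual of exactly the threshold passes. The
run time is a user input (default 15 min, so the default threshold is
0.75 min), not the last eluting feature, so the threshold does not
shrink when a run is truncated. Internal consistency is
1 − flagged/evaluated, reported overall and per MS level. Annotations
below 1 min are excluded before modelling as unretained (solvent-front)
features with no usable dependent variable; the boundary value is kept
("below" is strict), and the filter is idempotent.

The saturation-series diagnostic groups annotations by (class, all
element counts except H), orders each group by H count, and reports
every adjacent pair whose retention time strictly decreases — on C18,
retention should rise with saturation, so an inversion inside a
double-bond series marks a likely misassignment even when the global
model tolerates it.

## Attribution

Feature importance is the exact closed-form SHAP value of a linear
model under an independent-feature background: φᵢⱼ = wⱼ(xᵢⱼ − x̄ⱼ),
base value f(x̄). The explained model is a single SVR fitted on the
full table, with the full table as background — one attribution per
annotation, no sampling, so local accuracy (base + Σφ = prediction) and
zero background mean hold to machine precision. Attributing the
full-data model (rather than aggregating per-LOOCV-fold models) matches
how a single beeswarm summary per dataset is read. Caveat inherited
from the model: C and H counts are driven by the same latent acyl
length (non-confounding redundancy), so attribution mass can shift
between them — and class offsets can shift onto perfectly
class-identifying heteroatoms such as P for PC — without changing
any prediction. Rankings of individual collinear features should be
read accordingly.

## Synthetic lipidome generator

The generator draws annotation tables from the same structure the model
assumes, making every pipeline stage testable without data downloads:

  *t*ᵣ = offset(class) + coef_H·H + coef_unsat·DBE + 𝒩(0, noise_sd),

clipped into (min_rt, runtime]. Formulas come from per-class
homologous-series templates H = 2C + h_offset − 2·DBE with fixed
heteroatoms: TG (h_offset −4, O₆), DG (−2, O₅), PC (0, NO₈P), Cer (+1,
NO₃). Defaults: offsets 6.0 / 5.0 / 4.2 / 5.5 min (PC earliest: the
charged choline headgroup is the most hydrophilic), coef_H = 0.03
min/H, coef_unsat = −0.15 min/DBE, noise 0.1 min, 15-min run, carbon
and DBE ranges typical of each class. These place retention times in
the 5–9.5 min heart of a 15-min reversed-phase gradient, consistent
with the 1–12.5 min windows seen in real runs. The default table size
is 250 rows, a moderate single-platform table after void-volume
filtering. Within a seed, rows, classes, noise and misannotation
choices are all drawn from one `numpy` generator, so tables are fully
reproducible.

Misannotations (a configurable fraction, default 0 in the generator,
0.1 in the simulation entry points) corrupt the *recorded identity*
while leaving the observed retention time at the true lipid's value:

- **class swap** — the lipid is relabelled to another class and its
  formula rebuilt from that class's template at the same carbon count
  and unsaturation, as a real misidentification reports a formula
  consistent with the wrong class. (Keeping the true formula would
  leave heteroatom counts that still identify the true class, making
  the swap invisible to any composition-based model — and indeed to
  chemistry.)
- **saturation error** — the recorded H count is shifted by ±2k
  (k ∈ 4…10), i.e. the double-bond count is wrong by k.

The generating-model retention difference between recorded and true
identity is stored per row as the induced shift, so detection tests can
condition on detectability (|shift| ≥ 2× the flagging threshold)
instead of asserting on borderline cases. Under the defaults, detectable
corruptions are TG↔PC swaps (|shift| ≈ 1.7–2.1 min) and large
saturation errors (k ≥ 8).

What the generator does *not* emulate: co-elution and precursor-window
interference, adducts and isotope patterns, platform scoring, class
imbalance as extreme as real runs (64 classes with a long tail), and
nonlinear retention behaviour at gradient edges. Passing the synthetic
suite therefore demonstrates the statistical machinery — not that a
given real-world consistency percentage is "correct"; on real exports
the flagged set is a review queue, and final adjudication of MS²
spectra stays manual.

## Numerical and degenerate-input conventions

- Formula parsing is a strict left-to-right single pass; brackets,
  charges, adducts and explicit zero counts are rejected with the
  offending position. Repeated element symbols sum.
- Constant feature columns pass through scaling centred with unit
  divisor (weight and SHAP exactly 0); a constant target warns and
  proceeds (the model degenerates to the mean).
- Tables with fewer than two rows are rejected (LOOCV undefined);
  empty flag lists and empty element universes are errors, while an
  empty void-volume filter result is legal.
- Assignment ties (equal |Δ*t*ᵣ|) are resolved deterministically by
  the canonical pre-sort; saturation-series ties in H sort by
  (*t*ᵣ, id).
- No randomness anywhere in the QC path: libsvm's linear SVR fit is
  deterministic, tolerance 1e−4, echoed in every report.
- QC report CSVs round numerics to 6 decimals; a read-back round trip
  reproduces flags exactly.

## Problem sizes

The test suite runs entirely on synthetic tables: 12-row tables for the
LOOCV loop-oracle equivalence, 30–120 rows for model-behaviour checks,
and 20 × 250-row simulations for the pooled flag-recall / false-flag
estimates. `scripts/acceptance.py` uses the same 250-row default
conditions with 20 replicate seeds. Reproduction of the archived
PANC-1 platform exports (907 and 979 annotations) runs only when the
Zenodo deposit is present under `data/zenodo/`.
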