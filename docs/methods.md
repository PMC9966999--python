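# Methods

This note documents the models, conventions and numerical choices behind
`cyp17space`, and what the synthetic-data tests do and do not demonstrate.

## Data model and curation

A compound record carries a salt-stripped canonical SMILES, a pIC50
(−log₁₀ of the molar IC50), a four-level activity class and a
steroidal/nonsteroidal category flag. Conventions:

* **Unit handling.** IC50 inputs are converted to mol/L before the log
  transform. When a file declares no unit, nM is assumed — the dominant
  convention in public bioactivity databases — and a warning is logged.
* **Class boundaries are closed above**: pIC50 = 8.0 is potent, 7.0 is
  active. The cut points (8, 7, 6) are configurable via
  `ActivityClassScheme`.
* **Standardization.** The largest organic fragment is kept (counter-ion
  removal) and the canonical tautomer is taken via RDKit's standardizer;
  the operation is idempotent, which the tests check on generated SMILES.
  Duplicate ids and duplicate structures after standardization are
  rejected, keeping the first occurrence.
* **Balancing before splitting.** Random oversampling pads each minority
  class with uniform-with-replacement copies until all classes match the
  majority count, and the balanced set is then split 80:20 (ceiling rule on
  the test size: 448 × 0.2 → 90). Balancing before the split means
  duplicates of one source molecule can land on both sides of the split —
  an information-leakage caveat inherent to this protocol; test accuracies
  under it should be read as optimistic. The alternative (balance inside
  the training folds only) is not what this pipeline models.
* Oversampled copies get a `__dupN` id suffix so compound ids stay unique;
  their structure and potency are verbatim copies.

## EDA statistics

Summaries report bias-corrected sample skewness and **excess** kurtosis
(the convention under which a normal distribution scores 0; a raw-kurtosis
flag adds back 3). Zero-variance or n < 3 samples report NaN rather than a
misleading 0. Normality uses Shapiro–Wilk for 3 ≤ n ≤ 5000. The two-group
comparison is the two-sided Mann–Whitney U test: when both samples have
n ≤ 8 the p-value is exact, by enumerating all C(na+nb, na) assignments of
the pooled values (ties contribute ½ to U, and the U null distribution
remains symmetric under exchangeability, so the two-sided p is twice the
smaller tail, capped at 1); larger samples use the tie-corrected normal
approximation. The method actually used is recorded in the result.

## PCA chemical space and applicability domain

The six descriptors (MW, LogP, nHA, nHD, nRot, TPSA) have incommensurate
units, so the PCA standardizes to z-scores first — correlation-matrix PCA.
Constant columns are dropped with a warning. Component signs are fixed so
the largest-magnitude loading of each component is positive; published
loading tables are therefore matched up to per-component sign flips.

The applicability domain is the axis-aligned bounding box of the training
scores over the leading components (closed intervals, so boundary points
are in-domain), optionally expanded by a fractional margin. By default the
box uses the smallest number of components reaching 90 % cumulative
explained variance (`components_for_coverage`), configurable.

## Scaffolds

Murcko frameworks come from RDKit's implementation, which retains
exocyclic double-bonded atoms (e.g. a ring carbonyl oxygen) — the dominant
toolkit convention. The **cyclic skeleton** is defined here as the
framework with every atom genericized to carbon and every bond to a single
bond; `cyclic_skeleton(murcko_scaffold(x)) = cyclic_skeleton(x)` holds by
construction and is property-tested. Acyclic molecules map to an
empty-scaffold sentinel: they count in N but contribute no scaffold to
Ns/Nss/Ncsk, preserving the usual diversity-table semantics.

**Enrichment factors** are computed two ways: against the exact dataset
active proportion, and against the proportion rounded to two decimals (the
form in which the statistic is customarily quoted — 351/683 → 0.51 makes an
all-active scaffold score 1/0.51 = 1.961). The rounded variant is the
reporting default; both appear in the scaffold CSV. Frequency ties in the
scaffold ranking break lexicographically on the scaffold SMILES.

Representative scaffolds are those with frequency ≥ 10 **or** EF ≥ 1
(both thresholds configurable), ranked by EF then frequency. Skeleton
grouping merges scaffolds sharing a cyclic skeleton; hand-curated merges
can be supplied explicitly and are validated against the scaffold table.
R-group decomposition delegates to RDKit's `rdRGroupDecomposition` — a
deliberately simplified core/substituent table, not a full SAR engine.

## Activity landscape

Pairwise similarity is Tanimoto — |A∩B|/|A∪B| on bit vectors, Σmin/Σmax on
count vectors — streamed over the upper triangle so n ≈ 5000 stays in
modest memory. The SAS-map quadrant thresholds default to similarity ≥ 0.5
and |ΔpIC50| ≥ 2.0; these are explicit parameters echoed into outputs, not
inferences from any particular dataset. SALI = |ΔpIC50|/(1 − similarity);
the identical-fingerprint cases are handled by convention (∞ for a nonzero
gap, 0 otherwise) and infinite values serialize as the string `"inf"`.
AC generators are compounds recurring in ≥ `min_count` activity-cliff
pairs; the consensus set intersects the generator lists across fingerprint
schemes. No SALI percentile cut is applied — quadrant membership plus the
recurrence threshold defines a generator.

## QSAR modeling

* **Feature filter**: drop columns with sample variance < 0.1, then scan
  the survivors in index order and drop any column whose |Pearson r| with
  an earlier *retained* column exceeds 0.90. Keeping the earlier-indexed
  column is the deterministic tie-break. The mask is fitted on training
  data only and applied unchanged to the test set — the leakage-free
  choice.
* **Registry**: DT, ET, RF, GB, LGBM, XGB, MLP, LR, KNN, SVM, NB, GP, each
  wrapped one-vs-rest with library-default hyperparameters and a fixed
  seed (default 42); the defaults are echoed into every report for
  auditability. No hyperparameter tuning is performed.
* **Cross-validation**: stratified 10-fold on the training set; out-of-fold
  predictions are pooled into a single confusion matrix whose metrics are
  reported (per-fold accuracies are also emitted). A class smaller than
  the fold count reduces the fold count with a warning.
* **Binary collapse** uses the marginal-chance formula for Q₂,rnd
  (Σₖ rowₖ·colₖ/s², which equals 0.5 exactly when the binary marginals are
  balanced). A verbal shorthand sometimes seen for this quantity ("0.5 if
  balanced, otherwise zero") is not a formula and is not emulated.
* Groups too small to support a split plus CV (default < 20 compounds), or
  with a single class, are skipped with a structured warning rather than
  modeled.

## Synthetic data generator

The generator is the pipeline's ground-truth instrument. It enumerates
molecules from 18 hand-written scaffold templates — bicyclic and fused
aromatic systems, azole-bearing aromatics and three steroid-like
tetracyclics — decorated at one or two ring positions with substituents
from a 15-member R-group library. Activity is additive: true pIC50 =
scaffold baseline + Σ substituent effects, plus optional Gaussian noise
(default SD 0.3 pIC50 units, the scale of within-assay variability).
Because all substituents are acyclic, each product's Murcko scaffold equals
its template's framework exactly, giving an exact scaffold ground truth.

Activity cliffs are planted as pairs sharing a scaffold and all but one
substituent, the swapped group being a nitro (effect −3.5 pIC50 units, an
activity-killing substitution); a candidate pair is only accepted if its
ECFP4 Tanimoto similarity exceeds 0.5, enforcing the planted-cliff contract
at generation time.

`make_paper_shaped_fixture` instantiates the study-shaped conditions:
~292 compounds over 18 scaffolds with frequencies 60 down to singletons,
four unbalanced activity classes, a potent-heavy steroid-like subset,
several all-active scaffolds (EF = 1/p), one all-inactive scaffold
(EF = 0), and 5 planted cliff pairs. The fixture is **noise-free** so that
ground-truth quantities (EF, cliff recall) are recovered exactly; noisy
variants are exercised separately in the tests. Baselines and effect sizes
were chosen once so the largest scaffold spans all four classes (baseline
6.9, effect sums ±2.0) — a separable but not trivial classification task.

What passing on this generator shows: the pipeline's bookkeeping,
formulas and recovery logic are correct under a known additive SAR. What
it does not show: performance on real assay data, where activity is not
additive, scaffolds are confounded with assay series, noise is heavier
tailed, and class labels concentrate near the cut points.

## Problem sizes and determinism

The shipped analyses run on the ~300-compound fixture (≈43 k pairs for a
full SAS map; the cliff-recovery tests restrict to the planted scaffolds'
subset), 10-fold CV on ~450 balanced records, and 1000-matrix sweeps for
the metric identities — sizes chosen so the full suite and the acceptance
script each complete in well under a minute on one CPU while still
exercising every code path. All stochastic steps flow through explicit
seeds (package default 42); rerunning any entry point with the same seed
reproduces its output byte for byte.

## Known limitations

* PubChem/Klekota–Roth keys are not re-derived: the package guarantees
  MACCS and ECFP4 natively and accepts any substructure-key SMARTS list or
  precomputed fingerprint table for the rest. Exact parity with a specific
  external fingerprint program is a data file, not an algorithm, and the
  pipeline is fingerprint-agnostic.
* LogP is RDKit's Crippen atom-contribution estimate; other toolkits'
  LogP variants will differ at the decimal level.
* The R-group decomposition reports core/substituent tables only; it does
  not attempt automated SAR interpretation.
* Oversampling before splitting (see above) inflates test metrics; the
  reports are comparative across algorithms, not unbiased generalization
  estimates.
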