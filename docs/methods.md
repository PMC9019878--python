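# Methods

## Problem setting

Cytologically indeterminate thyroid nodules (Bethesda III/IV) carry a risk
of malignancy (ROM) that varies enormously between practice settings —
10–40% in North-American series against ~74% in strictly triaged Asian
institutions, where surgery is offered only on concerning ultrasound,
clinical features and patient preference. A molecular test with fixed
sensitivity and specificity therefore changes clinical meaning with the
population: its predictive values are functions of prevalence. The package
implements the full evaluation chain for such a test: classifier calling
from molecular alterations, accuracy estimation on the resected subset,
cross-study comparison, and prevalence-projected decision analysis.

## Alteration model

An alteration is (gene, kind ∈ {snv, indel, fusion, expression}, detail,
optional population frequency). Three rules govern pre-processing and
interpretation:

* **Common-variant filter.** Variants with a *known* population frequency
  strictly above 0.1% (threshold configurable) are treated as germline
  polymorphisms and removed before scoring; unknown frequency is retained,
  because only variants known to be common can be excluded. The filter is
  order-preserving and idempotent.
* **Risk tiers.** BRAF V600E, TERT promoter mutations and any gene fusion
  are *high-risk* (near-deterministic markers of malignancy in this
  setting); NRAS/HRAS/KRAS and BRAF K601E are *RAS-like*
  (follicular-patterned neoplasia, not specific for carcinoma); everything
  else is *other*. The map is pure and configurable.
* **Weights.** The weight table resolves every alteration through a
  most-specific-first lookup: exact (gene, detail) → (gene, kind) → gene →
  kind-wide wildcard → default. The wildcard slot exists so "any fusion"
  can carry one weight, mirroring the tier semantics. All weights are
  percentages in [0, 100].

The per-alteration percentages of the platform that motivated this package
are proprietary and unpublished; the shipped defaults (V600E 95, TERT 90,
fusions 90, RAS family 60, K601E 55, expression flag 75, default 20) are
this package's own documented stand-in, chosen so that any high-risk
alteration alone is call-positive and any RAS-like alteration alone is
call-negative, reproducing the qualitative call structure of the reference
listing. Users evaluating a real platform should supply its weight table.

## Classifier calls

The genomic-classifier score combines per-alteration weights with the
saturating sum `min(100, Σ wᵢ)` by default — an additive evidence rule,
capped so the score remains a percentage. The `noisy_or` alternative
`100·(1 − Π(1 − wᵢ/100))` treats weights as independent detection
probabilities; both rules agree on single alterations, are
permutation-invariant and monotone under added evidence. Calls are
strictly-greater threshold rules (score ≤ threshold is negative) at 70%
for the genomic classifier and 10% for the expression classifier. The
expression score itself is an input (the SVM producing it is out of
scope); a documented ambiguity is whether the 10% rule was conceived per
alteration or per nodule — it is implemented as a per-nodule score
threshold, and the per-alteration reading is noted here without leaking
into behaviour.

Both classifiers are scikit-learn estimators (`GenomicClassifier`,
`ExpressionScoreClassifier`) so they compose with pipelines and model
selection; `fit` validates parameters and freezes fitted attributes but
estimates nothing, as with rule-based sklearn classifiers.

## Reference cohort

`thyrisk.reference` constructs, in code, the complete published listing of
a 140-nodule indeterminate cohort: 58 resected nodules (15 benign, 10
borderline, 33 malignant) with per-histology molecular-call counts and the
full gene-alteration listing, and the unresected remainder's call totals.
Within a histology row only marginal call counts are printed; the
per-nodule assignment honours every marginal and every printed
false-negative identity (the expression classifier misses 2 WT-UMP and 1
Hürthle cell carcinoma; the genomic classifier misses 4 WT-UMP and 1
papillary carcinoma), and nests genomic-classifier positives within
expression positives where nothing forces otherwise. Nodule sizes and
Bethesda categories are deterministic fillers matching the cohort-level
distributions (87 III / 53 IV; size quartiles 0.7/1.0/1.5 cm) and carry no
per-nodule information.

One discrepancy is preserved rather than resolved: the histology listing
implies 8 benign-side genomic-classifier positives while the published
per-test 2×2 implies 7 (tp 38, fp 7, tn 8, fn 5). Both objects are
first-class — `confusion_table` on the cohort returns the listing-derived
table, `DNA_RNA_PRINTED_CONFUSION` the published counts — and accuracy
summaries quoted for that classifier use the published counts.

## Accuracy machinery

* Confusion tables require fully resected input; restricting to the
  resected subset is the caller's explicit step because that is precisely
  where verification bias enters.
* The borderline policy (NIFTP/WT-UMP as disease vs not) is a parameter on
  every truth-dependent operation, defaulting to `as_malignant` since
  borderline lesions are managed surgically.
* Proportions get 95% Wilson score intervals by default (via statsmodels).
  The `wald_cc` dialect (p̂ ± (z·√(p̂q̂/n) + 1/(2n)), clipped) is provided
  because some published interval bounds follow it; published CI dialects
  are not consistent with any single method, so no further
  reverse-engineering is attempted and printed CI bounds are not
  reproduction targets. Undefined metrics raise; nothing returns NaN.
* 2×2 comparisons use the Pearson chi-squared statistic (df = 1, scipy)
  without continuity correction by default — this reproduces the published
  cross-study PPV comparison (38/45 vs 31/49 → χ² ≈ 5.39, p ≈ 0.020) —
  with Yates as an option. The published resection-rate p-values (0.511,
  0.431) match neither dialect exactly from the printed counts and are not
  targeted; the package's comparison on those counts agrees qualitatively
  (no significant difference).
* AUC is the Mann–Whitney pair statistic computed through midranks, ties
  counted half. The published AUCs (0.81/0.77) require per-nodule
  continuous scores that were never released, so they are exercised only
  through property tests against brute-force pair enumeration.

## Prevalence projection

Expected PPV/NPV follow Bayes' theorem from (Se, Sp, p); curves are
evaluated on a 1001-point uniform grid with endpoint limits substituted
analytically (PPV(1) = 1, NPV(0) = 1; degenerate operating points emit a
warning). Crossover prevalences use the closed forms

    p*₍NPV≥t₎ = (1−t)·Sp / ((1−t)·Sp + t·(1−Se))
    p*₍PPV≥t₎ = t·(1−Sp) / (t·(1−Sp) + (1−t)·Se)

verified against numeric root-finding to 1e-9. The mode recommendation
evaluates both curves at the cohort ROM with targets NPV ≥ 0.90 (the
conventional rule-out bar) and PPV ≥ 0.75 (no numeric rule-in convention
exists; the default is motivated by the reference operating points, PPV
0.82–0.84 at ROM 0.74, and is fully configurable). At the reference
operating point (Se 0.884, Sp 0.533) the NPV ≥ 90% crossover falls at
33.8% prevalence (38.9% for Se 0.930/Sp 0.400); a published crossover
figure of 30.9% is not derivable from any printed operating-point pair and
is deliberately not hard-coded or targeted.

## Cohort simulator

`generate_cohort` draws, per nodule: outcome class (benign/borderline/
malignant, default 15:10:33), histology subtype within class, per-
alteration independent Bernoulli carriers at the class-conditional
frequencies read off the reference listing, classifier scores, calls,
and a resection indicator with per-call probabilities (defaults 0.43
positive / 0.35 negative — the regime in which management is effectively
blind to the test and the resection-rate comparison is null). Histology of
unresected nodules is masked to `unresected` by default, reproducing the
verification bias of the real design; `observe_unresected_histology=True`
reveals the latent truth for simulation studies. A single seeded NumPy
`default_rng` drives all draws: identical config and seed give bit-for-bit
identical cohorts, and the config (seed included) is echoed into the
output metadata.

Scores are class-conditional Beta draws on [0, 100]. `calibrate_score_
distributions` fixes one shape (default 4.0) and solves the other by Brent
root-finding on the log scale so that the diseased tail mass above the
threshold equals the target sensitivity and the benign head mass equals
the target specificity, to well within 1e-6; boundary targets (0 or 1) are
infeasible for a Beta and raise. Borderline nodules score from the
diseased-side distribution by default (most borderline nodules test
positive in the reference listing); a separate borderline Beta is
configurable. Two deliberate simplifications: the simulated
genomic-classifier score is drawn from its calibrated Beta rather than
recomputed from the simulated alterations (the simulator's contract is the
operating point; the weight arithmetic has its own module and tests), and
alterations are drawn independently per gene, so co-mutation structure
(e.g. TERT co-occurring with V600E) is not reproduced. Passing tests on
simulated cohorts therefore validate the estimation machinery under the
assumed structure, not the biology of any real cohort.

Problem sizes for the statistical checks were chosen to make Monte-Carlo
error negligible relative to the tolerance being asserted: the parameter-
recovery study uses 500 replicates of n = 5000 resected nodules at the
reference sensitivity/specificity (0.93/0.40), checking per-metric Wilson
coverage ≥ 93%; Wilson coverage itself is checked at p = 0.3, n = 50 over
10,000 replicates against the [0.93, 0.97] band; oracle-equivalence checks
run 1000 random 2×2 tables and 100 random AUC problems of ≤ 50 points.

## Pipeline and IO

Nodule tables are TSV (UTF-8, tab-separated, `.` decimal, mandatory
header) with the alterations cell a semicolon-joined list in the
`GENE[:DETAIL][:KIND]` / `GENE1-GENE2:fusion` grammar; loading validates
every row and reports 1-based row numbers and column names on failure, and
writing is canonical so write∘read is byte-identical. An optional VCF v4.2
reader (cyvcf2) maps SNV/indel records with ANN-style annotations to
alterations; fusions and expression flags enter only via the tabular path.
No live population-database annotation is performed — frequencies are
taken as given. `run_pipeline` orchestrates simulate/load → score →
evaluate → curves → compare into a bundle (cohort, metrics, comparisons,
curves, mode recommendation, human-readable summary, metadata with version,
seed and config hash); identical config + seed reproduce identical bundles
and stage failures carry the stage name.

## Known limitations

* The weight defaults are qualitative stand-ins, not the unpublished
  platform's values; absolute genomic-classifier scores on real data are
  only as meaningful as the supplied weight table.
* Accuracy estimates condition on resection; the simulator can quantify
  but the estimator cannot remove verification bias.
* The borderline-policy sensitivity analysis is a toggle on the truth
  definition; no latent-class or disagreement modelling of the borderline
  diagnoses themselves is attempted.
* Cross-study chi-squared comparisons treat published counts as fixed
  denominators and ignore between-study heterogeneity.
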