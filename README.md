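# thyrisk

Molecular risk stratification of cytologically indeterminate thyroid
nodules.

Around one fifth of thyroid fine-needle aspirations come back
cytologically indeterminate (Bethesda category III, AUS/FLUS, or IV,
FN/SFN). Molecular testing of the aspirate — DNA mutations, gene fusions
and expression profiles — is used to refine the decision between diagnostic
surgery and observation. `thyrisk` is an analysis toolkit for evaluating
such tests: it scores nodules with an alteration-weighted genomic
classifier, estimates diagnostic accuracy against histopathology of the
resected subset, compares performance with published series, and projects
predictive values across malignancy prevalence to recommend whether the
test should be used in *rule-in* or *rule-out* mode. It is aimed at
cytopathologists and biostatisticians evaluating molecular platforms,
particularly in settings whose risk of malignancy (ROM) differs sharply
from the North-American series most published operating points come from.

## The model

**Classifier calls.** Each detected alteration *i* carries a percentage
weight *wᵢ* reflecting its association with malignancy. The genomic
classifier (GC) score of a nodule is the saturating sum
`min(100, Σ wᵢ)` (a `noisy_or` combination `100·(1 − Π(1 − wᵢ/100))` is
available), positive strictly above 70%. An expression-classifier score is
thresholded at 10% under the same strictly-greater rule. Default weights
put BRAF V600E, TERT promoter mutations and oncogenic fusions (the
*high-risk* tier) individually above the positivity threshold, while
RAS-family and BRAF K601E (*RAS-like*) alterations alone stay below it.

**Accuracy.** With histopathology as gold standard and borderline lesions
(NIFTP, WT-UMP) counted as disease by default (an explicit, switchable
policy), the usual 2×2 quantities are reported with 95% Wilson score
intervals (Wald-with-continuity-correction available), cross-study
differences tested by Pearson chi-squared on 2×2 counts, and ranking
ability by the Mann–Whitney AUC.

**Decision analysis.** Sensitivity and specificity are prevalence-free;
predictive values are not:

    PPV(p) = Se·p / (Se·p + (1−Sp)(1−p))
    NPV(p) = Sp(1−p) / (Sp(1−p) + (1−Se)·p)

Evaluating both curves at the local ROM yields the mode recommendation
(rule-in when PPV(ROM) clears its target, rule-out when NPV(ROM) does), and
closed-form crossover prevalences mark where a test switches roles.

Because no individual-level dataset is published for this setting, the
package ships (a) a code-constructed **reference cohort** of 140
indeterminate nodules — 58 resected with full histology, molecular calls
and gene-alteration listing — and (b) a **cohort simulator** whose
class-conditional Beta score distributions are calibrated numerically to
any requested sensitivity/specificity, for power and coverage studies.

## Worked example

```python
import thyrisk as tk

cohort = tk.reference_cohort(resected_only=True)   # 58 resected nodules
ct = tk.confusion_table(cohort, "rna_call", "as_malignant")
for est in tk.binary_metrics(ct).values():
    print(est)
print(tk.rom(cohort))
```

prints

```
sensitivity = 93.0% (40/43; 95% wilson CI 81.4–97.6%)
specificity = 40.0% (6/15; 95% wilson CI 19.8–64.3%)
ppv = 81.6% (40/49; 95% wilson CI 68.6–90.0%)
npv = 66.7% (6/9; 95% wilson CI 35.4–87.9%)
accuracy = 79.3% (46/58; 95% wilson CI 67.2–87.7%)
rom = 74.1% (43/58; 95% wilson CI 61.6–83.7%)
```

— the expression classifier misses 3 of 43 diseased nodules but flags 9 of
15 benign ones, and nearly three quarters of the resected indeterminate
nodules turn out borderline or malignant. At that prevalence the test is a
rule-in tool:

```python
rec = tk.recommend_mode(sens=0.884, spec=0.533, rom=43 / 58)
print(rec.mode, round(rec.ppv_at_rom, 3), round(rec.npv_at_rom, 3))
# rule_in 0.844 0.616
print(round(tk.npv_crossover(38 / 43, 8 / 15, target=0.90), 4))
# 0.3376  — below ~34% prevalence the same test sustains NPV ≥ 90%
```

The same operations are available from a shell:

```sh
thyrisk simulate --n 200 --seed 7 --out cohort.tsv
thyrisk score --nodules cohort.tsv --out scored.tsv
thyrisk evaluate --nodules scored.tsv --call-field gc_call --out metrics.json
thyrisk curves --sens 0.884 --spec 0.533 --rom 0.741 --out curve.tsv
thyrisk compare 38 45 31 49        # chi-squared on two proportions
thyrisk run --config run.yaml      # full pipeline bundle
```

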