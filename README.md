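# sensits

Integrated testing strategy (ITS) for skin-sensitization hazard and GHS
potency of single chemicals and agrochemical formulations — without animal
testing.

Skin sensitization is assessed along its adverse outcome pathway by
combining one assay per key event with a structure-based prediction:

* **DPRA** (direct peptide reactivity assay, protein binding): mean %
  depletion of cysteine and lysine peptides → score 0–3
  (bins 6.38 / 22.62 / 42.47 %; cysteine-only bins under lysine co-elution),
* **h-CLAT** (human cell line activation test, dendritic-cell activation):
  minimum induction threshold MIT in µg/mL → score 0–3
  (≤ 10 → 3, ≤ 150 → 2, ≤ 5000 → 1, negative → 0),
* **in silico**: a multitask extremely-randomized-trees model over molecular
  fingerprints, trusted only inside an applicability domain → score 0–1.
  For pesticides the domain is a CART-derived exclusion ruleset marking the
  consensus space where predictions and animal data agree; an in-domain
  score ≤ 0.4 is called nonsensitizer.

The total score S = S_DPRA + S_hCLAT + S_insilico ∈ [0, 7] classifies

* hazard: S ≥ 2 → skin sensitizer, S ≤ 1 → not classified,
* potency: S ∈ [6, 7] → GHS Category 1A, S ∈ [2, 5] → 1B, S ≤ 1 → NC.

When a component is missing or out of domain, the attainable totals form a
range; if the range straddles a cutoff the verdict is **inconclusive**
rather than a guess. For formulations, DPRA/h-CLAT are measured on the
mixture itself while the in silico call is aggregated over active
ingredients (positive if any positive ingredient reaches 0.1 % w/w;
inconclusive if an unpredictable ingredient blocks an otherwise-negative
call).

The package is aimed at regulatory and discovery toxicologists who have
assay results in hand and want reproducible, auditable ITS calls plus the
standard benchmark metrics (sensitivity, specificity, accuracy, balanced
accuracy, coverage; potency correct/under/over-prediction rates).

## Worked example

Formulations with a negative DPRA, a weakly positive h-CLAT and a trusted
negative in silico call — the pattern where purely assay-based strategies
overpredict:

```python
from sensits import itscore

dpra = itscore.score_dpra(itscore.DpraResult(cys_depletion=5.0, lys_depletion=5.0))
hclat = itscore.score_hclat(itscore.HclatResult(mit=2000.0))
call = itscore.call_insilico(0.30, mode="pesticide", in_domain=True)
res = itscore.combine_and_classify(dpra, hclat, call.its_score)
print(dpra, hclat, call.its_score, res.total_min, res.hazard, res.potency)
```

prints

```
0 1 0 1 not_classified NC
```

The mean depletion of 5.0 % is below the 6.38 % reactivity cutoff (score 0),
an MIT of 2000 µg/mL falls in the weak 150–5000 band (score 1), and the
in-domain score of 0.30 ≤ 0.4 is a trusted nonsensitizer call (score 0):
total 1 → not classified. With the same assays but the in silico prediction
out of domain, `combine_and_classify(0, 1, None)` spans totals 1–2 and
returns `inconclusive` — the behavior the pesticide applicability domain was
introduced to resolve.

The same flow from the shell:

```bash
sensits synth --n 27 --mix 15,11,1 --noise 0 --seed 3 --out panel/
sensits score --assays panel/assays.csv --out results.json --csv preds.csv
sensits evaluate --predictions preds.csv --truth panel/truth.csv --markdown report.md
```

Other subcommands: `train` (fit the multitask forest from a
`smiles,task,label` CSV), `derive-ad` (exclusion rules from a concordance
table), `predict` (per-SMILES calls), `evaluate-formulation` (join
formulation and assay CSVs).

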