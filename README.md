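# fragfocus

Curate **target-focused small-molecule screening libraries** with a
fragment-aware consensus ensemble classifier.

Virtual screening campaigns start from vendor libraries of 10⁵–10⁶
compounds, far more than docking or assays can absorb.  `fragfocus`
implements a pipeline that shrinks such a library to a *focused* subset
enriched for predicted activity against one protein target, using only a
table of known bioactivities for that target:

1. **Ingest & label** — canonicalize SMILES, deduplicate keeping the most
   potent measurement, and label compounds active/inactive by a potency
   cutoff (default 10,000 nM on Kd/EC50/IC50).
2. **Prefilter** — remove PAINS alert matches and compounds with
   QED ≤ 0.25 from screening libraries.
3. **Fragment mining** — enumerate connected, *ring-complete* substructures
   (no partial rings) of the active class and keep those with molecule-level
   support ≥ 1% among actives and ≤ 20% among inactives.  These fragments are
   the target-specific chemical vocabulary.
4. **Featurize** — each molecule becomes 1024 ECFP bits ‖ one Tanimoto
   similarity per library fragment ‖ a fragment match count.  With a
   266-fragment library: 1024 + 266 + 1 = **1291 features**.
5. **Ensemble** — six members (logistic regression, k-NN, RBF-SVM, random
   forest, XGBoost, feed-forward net) are individually tuned by seeded random
   search (default 300 trials, 10-fold CV) for **precision** (with a recall
   floor) and combined by vote counting.  A compound enters the focused
   library only when at least the vote threshold — by default **all six** —
   members call it active.  Unanimity makes the consensus positive set the
   intersection of member positive sets, so the ensemble's false-positive
   count provably never exceeds any single member's.
6. **Screen & analyze** — stream any `.smi` library through the ensemble in
   chunks; export vote histograms, similarity matrices, cluster
   representatives, 2-D chemical-space projections, and per-match-count
   activity profiles.
7. **Explain** — generate molecular counterfactuals: minimally edited valid
   variants whose predicted class flips, ranked by fingerprint similarity to
   the parent and annotated with the mined fragments each edit loses or
   gains.

A seeded synthetic benchmark generator (`fragfocus.synthetic_data`)
reproduces the statistical shape of this problem — an imbalanced labeled
set with planted scaffolds, a scaffold-free negative pool, and a large
screening stream — so the entire pipeline is testable offline.

## Worked example

```python
from fragfocus.pipeline import run_benchmark_pipeline

res = run_benchmark_pipeline(seed=1)   # ~4 min on one CPU
print(f"fragments mined:        {res.n_fragments_mined}")
print(f"scaffolds recovered:    {len(res.recovered_scaffolds)}/{len(res.scaffolds)}")
print(f"worst member test AUC:  {min(m.roc_auc for m in res.member_metrics.values()):.2f}")
print(f"ensemble precision:     {res.ensemble_metrics.precision:.2f}")
print(f"six-vote FPR (990 decoys): {res.negative_fpr[6]:.2%}")
print(f"library reduction:      {res.screening_report.reduction_fraction:.2%}")
print(f"planted-active enrichment: {res.enrichment:.0f}x")
```

prints

```
fragments mined:        577
scaffolds recovered:    3/3
worst member test AUC:  0.98
ensemble precision:     1.00
six-vote FPR (990 decoys): 0.00%
library reduction:      99.50%
planted-active enrichment: 112x
```

Reading: from a 500-compound benchmark (10% active) the miner recovered all
three planted scaffold ring systems among 577 discriminative fragments; the
tuned ensemble classifies a held-out split with AUC ≥ 0.98 per member; the
strict six-vote consensus produces zero false positives on a 990-compound
held-out decoy pool; and screening a 10,000-compound stream with 1% planted
actives keeps 0.5% of the library while concentrating planted actives
112-fold.

The same stages are available as shell commands (`fragfocus ingest`,
`prefilter`, `mine`, `featurize`, `train`, `eval`, `screen`, `explain`,
`simulate`); run `fragfocus --help`.

## Layout

- `src/fragfocus/chem_io.py` — records, datasets, CSV/SMILES/SDF I/O, dedup, labeling
- `src/fragfocus/prefilter.py` — PAINS + QED prefilters
- `src/fragfocus/fragment_miner.py` — ring-complete frequent-substructure mining
- `src/fragfocus/featurizer.py` — ECFP bits, fragment similarities, match count
- `src/fragfocus/ensemble.py` — member tuning, consensus voting, evaluation
- `src/fragfocus/screener.py` — streaming screen, similarity/diversity analyses
- `src/fragfocus/counterfactual.py` — decision-flipping molecular edits
- `src/fragfocus/synthetic_data.py` — seeded benchmark/pool/stream generators
- `docs/methods.md` — models, assumptions, parameter choices, limitations
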