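# Methods

## Problem setting

Given a labeled bioactivity table for one protein target and a large
unlabeled vendor library, produce a small focused sub-library enriched for
probable actives, at high precision (a false positive costs a docking run or
an assay well).  The pipeline treats activity as a binary label derived
from a potency cutoff, learns a fragment-aware representation from the
labeled set, and filters the vendor library with a unanimous-vote ensemble.

## Data model and labeling

A compound record carries an identifier, a canonical aromatic SMILES
(RDKit canonicalization; idempotent), an optional potency in nM with its
measurement type (Kd, EC50, IC50, or percent inhibition), and an optional
class label.  Potencies below the cutoff (default 10,000 nM) are active, at
or above it inactive; the boundary value is assigned to the inactive side
because a compound exactly at the cutoff does not demonstrate sub-cutoff
potency.  Percent-inhibition measurements are not concentrations and are
carried through unlabeled.  Mixed Kd/EC50/IC50 values are compared on raw
nM without conversion — a deliberate simplification matching how single
cutoffs are applied to aggregated public bioactivity data.

Duplicates (identical canonical structure) keep the most potent record.
Stereochemistry is preserved in stored structures but ignored for duplicate
detection only when structures differ solely by *unspecified* stereo:
within a group sharing the same stereo-stripped structure, distinct
specified stereoisomers stay separate, and unannotated records merge with
the group only when at most one specified form exists (otherwise they form
their own group rather than being arbitrarily assigned to an isomer).

## Prefilters

Screening libraries are cleaned before featurization by (1) the published
PAINS A/B/C substructure alerts, via RDKit's FilterCatalog, and (2) the
quantitative estimate of druglikeness (QED, mean-weighted desirability
form), removing QED ≤ 0.25.  The QED implementation is cross-checked in the
test suite against an independent reimplementation of the double-sigmoid
desirability formula with the published parameter table.  PAINS is applied
before QED purely so each removed compound is counted once; the kept set is
order-independent and the filter is idempotent.

## Fragment mining

A fragment is a connected heavy-atom subgraph with element, aromaticity,
formal charge, and bond orders preserved, and with **no partial rings**:
every bond of the fragment that is a ring bond in its source molecule is
covered by a complete SSSR ring inside the fragment.  This "ring mining"
convention prevents chemically meaningless open-ring artifacts (e.g. four
consecutive atoms of a benzene ring).

Search: depth-first extension of induced atom subsets inside each active
molecule, starting from single atoms.  After adding a neighbor atom, any
uncovered induced ring bond is immediately completed by adding an SSSR ring
covering it; where several smallest rings cover the same bond (fused
systems) every completion alternative is explored.  Candidates are
deduplicated by canonical fragment SMILES.  The minimum active support
(default 1%) is anti-monotone — a fragment below it cannot have a superset
above it — and prunes the search; the maximum inactive support (default
20%, not anti-monotone) is applied as an output filter.  Support is
molecule-level: the fraction of class members containing at least one
embedding, counted by subgraph-isomorphism matching (explicit SMARTS-atom
queries, because RDKit's default mol-on-mol matching ignores formal charge
and the aromatic flag of atoms whose bonds are all non-aromatic).

Fragment identity is the heavy-atom graph; hydrogen counts are not part of
it (pyrazole's fragment form is `c1ccnn1`).  Library order is
deterministic — descending active support, then ascending size, then
lexicographic SMILES — so downstream feature columns are stable.  The
default size cap of 15 heavy atoms bounds the search; the correctness of
the whole scheme is checked against brute-force enumeration (all connected
induced subgraphs, ring-completeness by definition, VF2 support counting on
networkx graphs) on small random datasets.

The candidate space is the induced ring-complete subgraphs *of the active
molecules*; a graph that only embeds into actives across ring closures
(e.g. an open chain embedding into a ring) is not a candidate.  This is the
semantics a ring-mining substructure miner produces and is what the oracle
enumerates.

## Featurization

Three blocks, concatenated in fixed order: (1) a folded Morgan fingerprint,
default 1024 bits, radius 2 (the ECFP4-equivalent field convention; the
radius is configurable); (2) one Tanimoto similarity per library fragment
between the molecule's fingerprint and the fragment's fingerprint under the
same bits/radius configuration — using one shared configuration keeps
molecule-fragment similarity well-defined; (3) the number of library
fragments embedded in the molecule as substructures (a
similarity-threshold alternative definition is available for sensitivity
analysis).  With 1024 bits and a 266-fragment library the vector has 1291
columns.  Bits and similarities are left unscaled; members that need
standardization scale inside their own pipelines, so tree models see the
raw match count.

## Ensemble

Six members: logistic regression, k-nearest neighbors, RBF-kernel SVM,
random forest, gradient-boosted trees (XGBoost), and a feed-forward network
(sklearn MLP).  Linear/SVM/MLP members standardize features inside a
pipeline; k-NN uses cosine distance on the raw vectors, which suits sparse
fingerprint blocks far better than euclidean distance on standardized bits;
tree models take raw features.  Class imbalance is handled by class
weighting where supported (balanced weights for LR/SVM/RF, scale_pos_weight
for XGBoost), never by resampling.

Tuning is a seeded random search over documented spaces (default 300
trials, 10-fold stratified CV; the desk-scale benchmark uses 20 trials and
5 folds).  The objective is mean CV precision subject to a recall floor
(default 0.25): pure precision is degenerate — predicting almost nothing is
"perfect" — so trials below the floor are rejected, and ties on the
objective (common on separable data) break by mean CV recall, which favors
configurations with informative continuous scores.  The best trial is refit
on the full training split.  Per-member seeds derive from the base seed
plus the member index, so runs are bit-reproducible.

Decision rule: positive-class probability ≥ 0.5 per member; a compound's
vote count is the number of positive members, and the consensus is positive
at `vote_threshold` votes (default 6 of 6).  At the unanimous threshold the
consensus positive set is the intersection of member positive sets, so the
ensemble false-positive count is provably bounded by every member's — the
property the whole design optimizes for.  The train/test split is
stratified 90/10.  Evaluation reports confusion counts with precision,
recall, accuracy, FPR, ROC AUC and average precision, plus
threshold-ordered curve points; the ensemble is scored by vote count.  A
held-out assumed-inactive pool yields a per-threshold false-positive table
(non-increasing in the threshold by construction).

## Screening and analyses

Libraries are streamed in chunks (results are chunk-size invariant; corrupt
records are skipped and counted).  Downstream analyses: pairwise Tanimoto
similarity matrices; cluster representatives by seeded k-means on
fingerprint vectors with the medoid-like rule "molecule nearest its cluster
center" (default 30 clusters); seeded 2-D principal-component projection of
fingerprints (a neighbor embedding is available behind a flag; PCA is the
default because it is deterministic); and the fragment-match/label profile,
binning compounds by match count (0, 1–4, 5–9, 10–19, ≥20) and reporting
the active fraction per bin.

## Counterfactuals

Variants of a base compound are generated by seeded local graph edits —
atom substitution among C/N/O/S/F/Cl, bond-order change, terminal-atom
deletion, single-atom insertion — applied to a kekulized copy with full
RDKit sanitization as the validity guarantee; invalid edits are discarded
and uniqueness is enforced.  This graph-edit generator was chosen over
grammar-based string mutation: sanitization gives the same validity
guarantee while keeping edits interpretable as single chemical changes.
Among variants whose predicted class differs from the base (judged by the
ensemble consensus, or a named single member), the top k by fingerprint
Tanimoto to the base are returned (defaults: 2000 samples, top 10), each
re-verifiable against the model, with per-fragment lost/retained/gained
annotations.  An empty result is valid and flagged with a warning.

## Synthetic benchmark

The generator decorates curated ring systems with 1–3 random substituents
at carbon positions.  Actives carry one of three planted scaffolds
(pyridine, pyrimidine, pyrazole) at 90% penetrance — applied as an exact
count, so the stated penetrance is a floor at any sample size — while
inactives are decoys built from seven scaffold-free cores, except a 2%
contamination fraction.  Default class balance is 1:9 (50 actives, 450
inactives), mirroring the imbalance typical of curated bioactivity sets.
Potencies are log-normal per class (log₁₀ means 2.0 and 5.0, i.e. 100 nM
and 100,000 nM, SD 0.4), and labels are then re-derived through the
10,000 nM cutoff, so a small fraction of records crosses class lines —
exactly the label noise a hard potency cutoff produces on real data.  The
negative pool (default 990 decoys) and the screening stream (default
10,000 molecules, 1% planted actives) draw from separate seeded RNG
streams; the pool accepts an exclusion list to guarantee disjointness from
the benchmark.

What the benchmark does *not* emulate: real target chemistry, activity
cliffs, assay noise beyond the potency spread, tautomers/stereochemistry,
and vendor-library size.  Passing tests therefore demonstrate that the
machinery — mining, featurization, consensus voting, screening — behaves
correctly and recovers planted structure under realistic imbalance; they do
not certify predictive performance on any real target.

## Problem sizes and numerical choices

The packaged benchmark runs use 500 labeled compounds, a fragment library
capped at the 266 highest-support fragments, 20 tuning trials with 5-fold
CV, a 990-compound negative pool, and a 10,000-compound stream — sizes
chosen so a full pipeline run completes in a few minutes on one CPU while
every stage still has measurable statistical structure.  Support-threshold
comparisons are plain `>=`/`<=` on exact fractions (counts divided by class
sizes), so boundary cases like exactly 1% support behave as stated.
Tanimoto of two empty bit vectors is defined as 0.  The self-similarity
diagonal of a similarity matrix is set to exactly 1.  Metric identities
(precision, recall, accuracy, FPR versus confusion counts) hold to 1e-12 by
construction and are asserted in tests.

## Known limitations

- The miner is exact but exhaustive up to the atom cap; on large, flexible
  molecules (≫20 heavy atoms) with a high cap the candidate space grows
  quickly.  The anti-monotone support prune helps only when the minimum
  support is high enough to bite.
- Member probabilities are not calibrated; the 0.5 decision rule is a
  convention, and the vote count is a coarse score for ranking.
- Counterfactual edits are single local changes; multi-step edits (ring
  fusions, scaffold hops) are outside the generator's move set.
- Percent-inhibition records are carried but excluded from cutoff labeling;
  callers wanting to use them must label externally.
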