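# Methods

`hitfinder` implements a target-driven, ligand-based virtual screening (LBVS)
workflow for early-stage hit identification: when a protein target has little
or no annotated chemistry of its own, training data are borrowed from
sequence-similar proteins, classifiers are trained to separate their active
from inactive ligands, and a screening library is ranked by predicted
activity. This note records the model, its assumptions, the tunable
parameters, and the design choices made where the design was genuinely open.

## Pipeline model

1. **Target expansion.** The query protein (a UniProt accession) is expanded
   to a set of sequence-similar proteins via a homology-search backend.
   The working hypothesis is that high sequence identity correlates with
   related binding-site structure and hence shared ligand chemistry. Hits at
   or above the identity cutoff (default **40%**, inclusive) are retained;
   the query itself is always kept, because its own ligands — when they
   exist — are the most relevant training data. When a backend reports
   several alignments for one subject, the maximum percent identity is kept.
   The offline backend is a precomputed CSV; a live BLASTp backend (Biopython)
   exists behind the same interface but requires network access.

2. **Compound retrieval and labeling.** Bioactivity records (compound SMILES,
   target, assay value type, value, units) are fetched for every expanded
   target. The assay value type with the most records over the whole corpus
   is selected (ties broken by the fixed, binding-first priority
   Ki > IC50 > EC50 > %INH). Concentrations are normalized to nM
   (pM/nM/µM/mM/M accepted; anything else flags the record non-normalizable
   and excludes it from labeling). Replicate measurements per compound are
   pooled **across all expanded targets and aggregated by median** — the
   median is robust to the order-of-magnitude outliers common in public
   bioactivity data; no aggregation rule is canonical here, and an
   "any-active" per-target policy is available by configuration. Labels:
   active when median potency ≤ **1000 nM** (Ki/IC50/EC50) or median
   inhibition ≥ **50%** (%INH); both comparisons are inclusive at the
   boundary. Every labelable compound gets exactly one label, keyed by its
   InChI key.

3. **Standardization and identity.** All structures pass through one
   standardizer: largest covalent fragment kept (salt stripping; ties broken
   by molecular weight), RDKit canonical SMILES, identity = full
   (stereo-sensitive) InChI key. No charge neutralization or tautomer
   canonicalization is attempted — a documented limitation; two protomers of
   the same compound can therefore count as distinct.

4. **Vectorization.** Binary fingerprints via RDKit: Morgan (radius 2,
   1024 bits), atom-pair (1024), topological torsion (1024) or MACCS keys
   (167-long vector, bit 0 unused so key *i* sits at index *i*). Chirality
   is not hashed (toolkit default). Morgan/1024 is the pipeline default.

5. **Balanced training.** Public corpora are inactive-heavy, so the majority
   class is randomly undersampled without replacement to the minority size,
   once, before cross-validation, using the run seed. Doing the balancing
   outside the CV loop keeps folds comparable across hyperparameters but
   means the CV estimate is mildly optimistic relative to re-balancing
   within each fold; at the enrichment levels this pipeline targets the
   distinction is immaterial, and it is flagged here for completeness.
   Two model families are trained by exhaustive grid search scored by mean
   10-fold cross-validated AUC (scikit-learn `GridSearchCV`, seeded
   stratified folds):

   * random forest: `n_estimators` ∈ {50, 100, 200}, `max_depth` ∈ {4, 6, 10, 12};
   * multilayer perceptron: `hidden_layer_sizes` ∈ {(50,50,50), (50,50), (50)},
     `activation` ∈ {tanh, relu}, `alpha` ∈ {0.01, 0.0001}.

   AUC was chosen as the search criterion because the pipeline's consumers
   read ranked lists; it is threshold-free and matches the ROC-centric
   reporting. Confusion-based metrics use a 0.5 probability threshold.
   Seven metrics are reported per fold: AUC (trapezoidal integration of the
   ROC), precision, recall, specificity, F1, geometric mean
   √(recall·specificity), and the index of balanced accuracy
   IBA_α = (1 + α(recall − specificity))·recall·specificity with the
   conventional α = 0.1. Undefined ratios (zero denominators) report 0 with
   an explicit flag rather than NaN.

6. **Screening and rank aggregation.** Each model assigns every library
   compound a probability-of-active score. Per model, compounds are ranked
   1..N by descending score with ties broken lexicographically by InChI key,
   so ranks are a strict permutation and reports are bit-reproducible. The
   ensemble rank is the arithmetic **mean of rank positions**, not of
   scores — rank averaging is scale-free, so a sharply calibrated model and
   a diffuse one contribute equally. The virtual-hit list is the union of
   the top ⌈top_fraction·N⌉ compounds (default 1%) of each model ranking
   and of the ensemble ranking, deduplicated by InChI key; the ceiling
   guarantees a non-empty list for small libraries.

7. **Post-screening analysis.** QED plus molecular weight, LogP, H-bond
   acceptors/donors, rotatable bonds and TPSA per compound (RDKit
   descriptors; QED uses the toolkit's published desirability-function
   implementation — its eight curves are not re-derived here). Score
   distributions are summarized on a fixed 50-bin grid over [0, 1].
   Chemical-space structure: k-means over fingerprint bits (default k = 100,
   10 restarts keeping the best inertia, seeded) with per-cluster score
   statistics; a seeded t-SNE (perplexity 30, capped at (n−1)/3 for small
   sets) for visualization only. A classical similarity baseline ranks the
   library by Tanimoto coefficient Tc = |a∧b|/|a∨b| against a query
   compound; Tc of an empty union is defined as 0.

8. **Retrospective hold-out validation.** To simulate a novel-target
   campaign, compounds whose *active* evidence comes solely from the query
   target are withheld from training and reintroduced at scoring time; a
   compound also active on another expanded target stays in training, since
   removing it would discard legitimate homolog evidence. The withheld-active
   vs library score gap is tested with a two-sided Welch unequal-variance
   t-test (no canonical test exists for this design; Welch is robust to the
   unequal sizes and variances involved, and a Mann-Whitney rank test is
   available by flag), starred at p < 0.05 / 0.01 / 0.001. A query with no
   withholdable actives reports "not evaluable" rather than failing.

## The synthetic fixture world

All tests run offline against a generated structure–activity world:
5 pseudo-targets (identities 100/85/70/55/45%), 40 actives and 160 inactives
per target, and a 5000-compound screening library with 5% planted decoys.
Actives are assembled combinatorially from benzenesulfonamide scaffolds ×
fragment lists; inactives and library decoys come from amide/ester/aniline/
pyridine-sulfonamide scaffolds that cannot contain the motif. Potencies are
lognormal: actives with median 100 nM, inactives with median 30 µM (both
σ = 1 on the log scale), straddling the 1000 nM cutoff by more than an order
of magnitude each side so that labeling is nearly deterministic yet still
exercises the tail-crossing logic — the expected recovery of planted actives
is Φ(ln 10/σ) ≈ 98.9% in closed form, and tests assert the observed rate
against that oracle. About 20% of records are expressed in µM rather than nM
to exercise unit normalization. Generation is fully seeded and
byte-reproducible.

What the fixture does **not** emulate: realistic medicinal-chemistry property
distributions, property-matched decoys (DUD-E style), assay noise structure,
activity cliffs, or inter-target selectivity patterns. Passing tests
therefore demonstrate that the machinery is correct and that a clear planted
signal is recovered end-to-end; they do not certify enrichment rates on real
screening corpora, where signal-to-noise is far worse.

## Numerical and degenerate-input choices

* All randomness flows from a single run seed; per-fold estimator seeds are
  derived deterministically from it. Reruns with identical config and
  fixtures reproduce the summary JSON except for its timestamp fields.
* Stratified folds are re-drawn with a shifted seed (up to 5 tries, with a
  warning) if any fold would contain a single class.
* MLP fits are capped at 300 iterations; convergence warnings are
  suppressed — on fingerprint data the optimum is reached far earlier, and
  the AUC criterion is insensitive to the last fractional loss digits.
* Unparseable structures are skipped with a warning and counted, never fatal
  mid-stream; zero valid structures is fatal.
* An all-zero query fingerprint in the Tanimoto search scores 0 against
  everything, with a warning.
* Problem sizes in the test suite are the package's own desk-scale defaults:
  the fixture above for end-to-end checks, and scaled-down variants
  (12/36 compounds per target, 300-compound library) for unit-level
  integration tests.

## Known limitations

* No assay-confidence filtering, pChEMBL harmonization or mutant-target
  disambiguation during curation.
* No probability calibration across models; the ensemble is rank-based
  precisely to avoid depending on calibration.
* No applicability-domain or diversity-aware hit picking.
* The live BLAST and ChEMBL backends are thin and untested offline; the CSV
  fixture backends are the supported path.
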