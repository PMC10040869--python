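# hitfinder

Target-driven, machine-learning-enabled ligand-based virtual screening for
early-stage hit identification.

Early drug discovery campaigns for novel protein targets usually lack the
known ligands that ligand-based virtual screening needs. `hitfinder`
addresses this by *target expansion*: starting from a single UniProt
accession, it collects sequence-similar proteins (identity ≥ 40% by
default), pools their experimentally annotated ligands, labels them
active/inactive (median potency ≤ 1000 nM, or ≥ 50% inhibition), trains
balanced random-forest and multilayer-perceptron classifiers on molecular
fingerprints (Morgan/atom-pair/torsion/MACCS), and scores a screening
library. Compounds are ranked per model (rank 1 = best), combined by
ensemble rank averaging

    ensemble_rank(c) = mean_m rank_m(c)

and the union of the top 1% of each model ranking and of the ensemble
ranking, deduplicated by InChI key, is reported as the virtual-hit list with
QED and physicochemical profiles (MW, LogP, HBA, HBD, rotatable bonds,
TPSA). Model quality is reported per cross-validation fold as AUC,
precision, recall, specificity, F1, geometric mean √(recall·specificity) and
the index of balanced accuracy (1 + α(recall − specificity))·recall·specificity
(α = 0.1). A retrospective hold-out protocol withholds the query target's own
actives from training and tests (Welch's t) whether the models score them
above a background library. Everything runs offline against CSV fixtures; a
seeded synthetic structure–activity generator (planted benzenesulfonamide
actives, lognormal potencies, decoy library) provides a complete test world.

Intended users: computational chemists and ML practitioners triaging
chemical libraries at the start of a discovery campaign, and anyone needing
a reproducible, scriptable LBVS baseline.

## Worked example

Generate the synthetic world and run the full pipeline with the query's
actives withheld (retrospective validation):

```bash
hitfinder make-fixtures --out-dir fixtures --seed 1
hitfinder retro --uniprot P10001 --fixtures fixtures --seed 1 --out-dir demo_run
```

The run prints per-model retro-validation results; with seed 1 the JSON is:

```json
{
  "rf": {
    "mean_score_actives": 0.948,
    "mean_score_library": 0.118,
    "p_value": 7.44e-85,
    "significance_stars": "***",
    "direction": "actives_higher"
  },
  "mlp": {
    "mean_score_actives": 0.998,
    "mean_score_library": 0.066,
    "p_value": 0.0,
    "significance_stars": "***",
    "direction": "actives_higher"
  }
}
```

(values abbreviated) — both models score the 39 withheld query actives far
above the 5000-compound decoy library, i.e. the classifiers learned the
shared active chemotype from the homologous targets alone. Stage outputs
land in numbered folders under `demo_run/` (expansion table, labeled
compound tables, fingerprints, per-fold metric tables, score files, property
profiles, cluster statistics, the full scored list and the merged top-1%
virtual-hit list), with a machine-readable `summary.json` and a
human-readable `report.txt` in `07_data_processing/`.

Each stage is also available standalone (`hitfinder expand`, `retrieve`,
`vectorize`, `analyze`, `run`, …) and as library functions
(`hitfinder.run_pipeline`, `hitfinder.train_model`,
`hitfinder.rank_and_merge`, `hitfinder.tanimoto_search`, …).

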