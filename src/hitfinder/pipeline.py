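"""End-to-end pipeline orchestration.

Seven stages run in sequence — target expansion, compound retrieval,
vectorization, model training, virtual screening, post-screening analysis and
data processing — each writing to its own numbered folder under the run's
output directory.  Three starting points are supported:

* ``target_id`` — start from a single protein accession (all stages run);
* ``target_list`` — user-supplied targets (expansion skipped);
* ``compound_list`` — user-supplied labeled compounds (expansion and
  retrieval skipped).

A machine-readable ``summary.json`` (config hash, seed, per-stage counts and
headline results) and a human-readable ``report.txt`` are produced; with
identical config and fixtures the summary is reproducible except for its
timestamp field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .chem_io import (
    CompoundLibrary,
    InputError,
    read_library,
    write_table,
)
from .compound_curation import (
    CsvBioactivitySource,
    LabeledCompound,
    LabelingConfig,
    datatype_distribution,
    fetch_records,
    label_compounds,
    labeled_to_frames,
    select_primary_value_type,
    standardize_molecule,
)
from .model_training import (
    TrainedClassifier,
    TrainingConfig,
    metrics_table,
    train_model,
    undersample,
)
from .postvs_analysis import (
    ClusteringSpec,
    cluster_library,
    plot_property_distributions,
    plot_score_distributions,
    profile_library,
    summarize_scores,
)
from .retro_validation import compare_scores, plot_retro_bars, withhold_query_actives
from .screening_ranking import EnsembleSpec, rank_and_merge, score_library, top_hits
from .synthetic_fixtures import plant_check
from .target_expansion import (
    CsvHomologyBackend,
    ExpansionConfig,
    HomologHit,
    TargetQuery,
    expand_target,
    expansion_table,
)
from .vectorization import FingerprintMatrix, FingerprintSpec, vectorize_set

logger = logging.getLogger(__name__)

StartingPoint = Literal["target_id", "target_list", "compound_list"]

STAGE_DIRS = {
    "expansion": "01_target_expansion",
    "retrieval": "02_compound_retrieval",
    "vectorization": "03_vectorization",
    "training": "04_model_training",
    "screening": "05_virtual_screening",
    "postvs": "06_postvs_analysis",
    "processing": "07_data_processing",
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; exactly one starting point is active."""

    starting_point: StartingPoint = "target_id"
    query_uniprot: str | None = None
    target_list: list[str] | None = None
    compound_list_path: str | None = None  # CSV: smiles,label columns
    homology_fixture: str | None = None
    bioactivity_fixture: str | None = None
    library_path: str | None = None
    out_dir: str = "hitfinder_run"
    offline: bool = True
    seed: int = 0
    expansion: ExpansionConfig = field(default_factory=ExpansionConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    fingerprint: FingerprintSpec = field(default_factory=FingerprintSpec)
    training: TrainingConfig | None = None
    ensemble: EnsembleSpec = field(default_factory=EnsembleSpec)
    clustering: ClusteringSpec | None = None
    value_type_override: str | None = None
    do_clustering: bool = True
    make_plots: bool = True
    retro_holdout: bool = False  # withhold the query target's own actives

    def __post_init__(self) -> None:
        if self.training is None:
            self.training = TrainingConfig(seed=self.seed)
        if self.clustering is None:
            self.clustering = ClusteringSpec(seed=self.seed)
        points = {
            "target_id": self.query_uniprot is not None,
            "target_list": self.target_list is not None,
            "compound_list": self.compound_list_path is not None,
        }
        if not points.get(self.starting_point, False):
            raise InputError(
                f"starting point {self.starting_point!r} needs its input "
                "(query_uniprot / target_list / compound_list_path)"
            )

    def config_hash(self) -> str:
        # out_dir and plotting do not affect the science; exclude them so a
        # rerun into a different folder hashes identically.
        payload = dataclasses.asdict(self)
        for key in ("out_dir", "make_plots"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(_jsonable(payload), sort_keys=True).encode()
        ).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name for resumability."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _load_compound_list(path: str, labeling: LabelingConfig) -> list[LabeledCompound]:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols or "label" not in cols:
        raise InputError(f"{path}: compound list needs 'smiles' and 'label' columns")
    labeled: list[LabeledCompound] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        label = str(getattr(row, cols["label"])).strip().lower()
        if label not in ("active", "inactive"):
            raise InputError(f"{path}: label must be active/inactive, got {label!r}")
        mol = standardize_molecule(str(getattr(row, cols["smiles"])))
        if mol.inchikey in seen:
            continue
        seen.add(mol.inchikey)
        labeled.append(LabeledCompound(molecule=mol, label=label))
    return labeled


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline and return the summary dictionary.

    The summary is also written to ``<out_dir>/07_data_processing/summary.json``
    together with a human-readable ``report.txt``.  All randomness derives
    from ``config.seed``; reruns with identical config and fixtures reproduce
    the summary except for the ``timestamp`` field.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "starting_point": config.starting_point,
        "stages": {},
    }
    stage_counts = summary["stages"]

    # -- Stage 1: target expansion ------------------------------------------
    hits: list[HomologHit] = []
    if config.starting_point == "target_id":
        try:
            if not config.offline:  # pragma: no cover - network path
                from .target_expansion import NcbiBlastBackend

                backend = NcbiBlastBackend()
            else:
                backend = CsvHomologyBackend(config.homology_fixture)
            query = TargetQuery(config.query_uniprot)
            hits = expand_target(
                query, backend, config.expansion,
                out_path=out / STAGE_DIRS["expansion"] / "expanded_targets.csv",
            )
        except Exception as exc:
            raise StageFailure("expansion", exc) from exc
        stage_counts["expansion"] = {"n_targets": len(hits)}
    elif config.starting_point == "target_list":
        hits = [HomologHit(t, t, 100.0) for t in config.target_list]
        stage_counts["expansion"] = {"n_targets": len(hits), "skipped": True}

    # -- Stage 2: compound retrieval + labeling -----------------------------
    records = []
    chosen_type = None
    withheld: list[LabeledCompound] = []
    if config.starting_point == "compound_list":
        labeled = _load_compound_list(config.compound_list_path, config.labeling)
        stage_counts["retrieval"] = {"skipped": True, "n_labeled": len(labeled)}
    else:
        try:
            source = CsvBioactivitySource(config.bioactivity_fixture)
            records = fetch_records(hits, source)
            stage_dir = out / STAGE_DIRS["retrieval"]
            dist = datatype_distribution(records)
            write_table(dist, stage_dir / "datatype_distribution.csv")
            chosen_type = config.value_type_override or select_primary_value_type(records)
            labeled = label_compounds(records, chosen_type, config.labeling)
            if config.retro_holdout and config.query_uniprot:
                labeled, withheld = withhold_query_actives(
                    labeled, records, config.query_uniprot, chosen_type, config.labeling
                )
                if withheld:
                    withheld_df, _ = labeled_to_frames(withheld)
                    write_table(withheld_df, stage_dir / "withheld_compounds.csv")
            active_df, inactive_df = labeled_to_frames(labeled)
            if not active_df.empty:
                write_table(active_df, stage_dir / "active_compounds.csv")
            if not inactive_df.empty:
                write_table(inactive_df, stage_dir / "inactive_compounds.csv")
        except Exception as exc:
            raise StageFailure("retrieval", exc) from exc
        stage_counts["retrieval"] = {
            "n_records": len(records),
            "value_type": chosen_type,
            "n_labeled": len(labeled),
            "n_active": sum(1 for c in labeled if c.label == "active"),
            "n_withheld": len(withheld),
        }

    # -- Stage 3: vectorization (after undersampling) -----------------------
    try:
        balanced = undersample(labeled, seed=config.seed)
        features = vectorize_set([c.molecule for c in balanced], config.fingerprint)
        labels = np.array([1 if c.label == "active" else 0 for c in balanced], dtype=int)
        features.to_csv(out / STAGE_DIRS["vectorization"] / "training_fingerprints.csv")
    except Exception as exc:
        raise StageFailure("vectorization", exc) from exc
    stage_counts["vectorization"] = {
        "n_compounds": len(features),
        "n_bits": int(features.bits.shape[1]),
        "n_balanced_active": int(labels.sum()),
    }

    # -- Stage 4: model training --------------------------------------------
    models: dict[str, TrainedClassifier] = {}
    try:
        train_dir = out / STAGE_DIRS["training"]
        for kind in config.training.models:
            clf = train_model(features, labels, kind, config.training)
            clf.save(train_dir / f"{kind}_model.joblib")
            write_table(metrics_table(clf), train_dir / f"{kind}_cv_metrics.csv")
            models[kind] = clf
    except Exception as exc:
        raise StageFailure("training", exc) from exc
    stage_counts["training"] = {
        kind: {
            "chosen_hyperparameters": _jsonable(clf.chosen_hyperparameters),
            "mean_cv_metrics": clf.mean_metrics(),
        }
        for kind, clf in models.items()
    }

    # -- Stage 5: virtual screening -----------------------------------------
    try:
        library = read_library(config.library_path)
        lib_features = vectorize_set(library, config.fingerprint)
        scores = {kind: score_library(clf, lib_features) for kind, clf in models.items()}
        screen_dir = out / STAGE_DIRS["screening"]
        for kind, vec in scores.items():
            write_table(
                pd.DataFrame({"inchikey": lib_features.keys, "score": vec}),
                screen_dir / f"{kind}_scores.csv",
            )
    except Exception as exc:
        raise StageFailure("screening", exc) from exc
    stage_counts["screening"] = {"library_size": len(lib_features)}

    # -- Stage 7 input: ranking (needed by post-VS summaries) ---------------
    try:
        key_to_smiles = {m.inchikey: m.smiles for m in library}
        report = rank_and_merge(
            scores, lib_features.keys, config.ensemble,
            smiles=[key_to_smiles[k] for k in lib_features.keys],
        )
    except Exception as exc:
        raise StageFailure("processing", exc) from exc

    # -- Stage 6: post-VS analysis ------------------------------------------
    try:
        postvs_dir = out / STAGE_DIRS["postvs"]
        profiles = profile_library(library)
        write_table(profiles, postvs_dir / "property_profiles.csv")
        score_summaries = summarize_scores(report)
        with open(postvs_dir / "score_summaries.json", "w", encoding="utf-8") as fh:
            json.dump(_jsonable(score_summaries), fh, indent=2, sort_keys=True)
        cluster_summary = None
        if config.do_clustering and len(lib_features) >= config.clustering.n_clusters:
            primary = "rf" if "rf" in scores else sorted(scores)[0]
            assignments, cluster_table = cluster_library(
                lib_features, config.clustering, scores[primary]
            )
            write_table(
                pd.DataFrame({"inchikey": lib_features.keys, "cluster": assignments}),
                postvs_dir / "cluster_assignments.csv",
            )
            write_table(cluster_table, postvs_dir / "cluster_scores.csv")
            cluster_summary = {
                "score_model": primary,
                "top_cluster": int(cluster_table.loc[0, "cluster"]),
                "top_cluster_mean_score": float(cluster_table.loc[0, "mean_score"]),
                "library_mean_score": float(np.mean(scores[primary])),
            }
        if config.make_plots:
            plot_score_distributions(score_summaries, postvs_dir / "plots")
            plot_property_distributions(profiles, postvs_dir / "plots")
    except Exception as exc:
        raise StageFailure("postvs", exc) from exc
    stage_counts["postvs"] = {
        "n_profiled": int(len(profiles)),
        "score_means": {m: s["mean"] for m, s in score_summaries.items()},
        "clustering": cluster_summary,
    }

    # -- Retro validation (optional) ----------------------------------------
    if withheld:
        try:
            retro_dir = out / STAGE_DIRS["processing"]
            withheld_features = vectorize_set([c.molecule for c in withheld], config.fingerprint)
            retro_results = []
            for kind, clf in models.items():
                w_scores = score_library(clf, withheld_features)
                res = compare_scores(w_scores, scores[kind], model_kind=kind)
                retro_results.append(res)
            write_table(
                pd.DataFrame([r.to_dict() for r in retro_results]),
                retro_dir / "retro_validation.csv",
            )
            if config.make_plots:
                plot_retro_bars(retro_results, retro_dir / "retro_validation.png")
            summary["retro_validation"] = {r.model_kind: r.to_dict() for r in retro_results}
        except Exception as exc:
            raise StageFailure("processing", exc) from exc

    # -- Stage 7: data processing / final report ----------------------------
    try:
        proc_dir = out / STAGE_DIRS["processing"]
        write_table(report, proc_dir / "full_scored_list.csv")
        hits_df = top_hits(report)
        write_table(hits_df, proc_dir / "top_virtual_hits.csv")
        planted_in_hits = sum(
            plant_check(s) for s in hits_df["smiles"]
        ) if "smiles" in hits_df else None
        summary["processing"] = {
            "n_ranked": int(len(report)),
            "n_top_hits": int(len(hits_df)),
        }
        summary["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        summary["elapsed_seconds"] = round(time.time() - t0, 1)
        summary_clean = _jsonable(summary)
        with open(proc_dir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary_clean, fh, indent=2, sort_keys=True)
        _write_report_txt(summary_clean, proc_dir / "report.txt")
    except Exception as exc:
        raise StageFailure("processing", exc) from exc
    logger.info("pipeline finished in %.1f s; outputs under %s", time.time() - t0, out)
    return summary_clean


def _write_report_txt(summary: dict, path: Path) -> None:
    lines = [
        "Virtual screening run summary",
        "=============================",
        f"package version : {summary['package_version']}",
        f"config hash     : {summary['config_hash']}",
        f"seed            : {summary['seed']}",
        f"starting point  : {summary['starting_point']}",
        "",
    ]
    for stage, counts in summary["stages"].items():
        lines.append(f"[{stage}]")
        lines.append(json.dumps(counts, indent=2, sort_keys=True))
        lines.append("")
    if "retro_validation" in summary:
        lines.append("[retro validation]")
        for kind, res in summary["retro_validation"].items():
            lines.append(
                f"  {kind}: withheld actives {res['mean_score_actives']:.3f} "
                f"vs library {res['mean_score_library']:.3f} "
                f"(p = {res['p_value']:.3g}, {res['significance_stars']})"
            )
        lines.append("")
    proc = summary.get("processing", {})
    lines.append(
        f"Ranked {proc.get('n_ranked', 0)} compounds; "
        f"{proc.get('n_top_hits', 0)} merged top virtual hits."
    )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
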