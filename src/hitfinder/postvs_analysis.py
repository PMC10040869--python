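"""Post-screening analysis: drug-likeness, score distributions, chemical space.

* Physicochemical profiling: QED plus molecular weight, LogP, H-bond
  acceptor/donor counts, rotatable bonds and TPSA per compound (RDKit
  descriptors).
* Score-distribution summaries: fixed 50-bin histograms on [0, 1] plus
  mean/SD/quantiles per model.
* Chemical-space structure: k-means clustering of fingerprints (default
  k=100, 10 restarts) with per-cluster score statistics, and a seeded 2-D
  t-SNE embedding for visualization.
* A classical Tanimoto-similarity baseline search against a query compound:
  Tc(a, b) = |a AND b| / |a OR b| on fingerprint bit-sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import Descriptors, QED
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .chem_io import CompoundLibrary, Molecule
from .vectorization import ConfigError, FingerprintMatrix, FingerprintSpec, compute_fingerprint

logger = logging.getLogger(__name__)

SCORE_BINS = 50

PROFILE_COLUMNS = ["qed", "mw", "logp", "hba", "hbd", "rotatable_bonds", "tpsa"]


@dataclass(frozen=True)
class PropertyProfile:
    qed: float
    mw: float
    logp: float
    hba: int
    hbd: int
    rotatable_bonds: int
    tpsa: float

    def to_dict(self) -> dict:
        return {
            "qed": self.qed,
            "mw": self.mw,
            "logp": self.logp,
            "hba": self.hba,
            "hbd": self.hbd,
            "rotatable_bonds": self.rotatable_bonds,
            "tpsa": self.tpsa,
        }


@dataclass(frozen=True)
class ClusteringSpec:
    n_clusters: int = 100
    seed: int = 0
    n_restarts: int = 10

    def validate(self, n_compounds: int) -> None:
        if not 2 <= self.n_clusters <= n_compounds:
            raise ConfigError(
                f"n_clusters must be in [2, {n_compounds}], got {self.n_clusters}"
            )


def profile_compound(molecule: Molecule) -> PropertyProfile:
    """QED and the six key physicochemical descriptors for one compound."""
    mol = molecule.to_rdkit()
    return PropertyProfile(
        qed=float(QED.qed(mol)),
        mw=float(Descriptors.MolWt(mol)),
        logp=float(Descriptors.MolLogP(mol)),
        hba=int(Descriptors.NumHAcceptors(mol)),
        hbd=int(Descriptors.NumHDonors(mol)),
        rotatable_bonds=int(Descriptors.NumRotatableBonds(mol)),
        tpsa=float(Descriptors.TPSA(mol)),
    )


def profile_library(library: CompoundLibrary | Sequence[Molecule]) -> pd.DataFrame:
    """Property table for a compound set; failed rows are flagged, not fatal."""
    molecules = list(library.molecules if isinstance(library, CompoundLibrary) else library)
    rows = []
    for mol in molecules:
        row: dict = {"inchikey": mol.inchikey, "smiles": mol.smiles, "profile_failed": False}
        try:
            row.update(profile_compound(mol).to_dict())
        except Exception:  # noqa: BLE001 - descriptor failure flags the row
            row.update({c: np.nan for c in PROFILE_COLUMNS})
            row["profile_failed"] = True
            logger.warning("descriptor calculation failed for %s", mol.inchikey)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_scores(report: pd.DataFrame) -> dict[str, dict]:
    """Histograms (50 bins on [0, 1]) and summary stats per score column."""
    if report.empty:
        raise ValueError("empty screen report")
    edges = np.linspace(0.0, 1.0, SCORE_BINS + 1)
    out: dict[str, dict] = {}
    for col in sorted(c for c in report.columns if c.startswith("score_")):
        scores = report[col].to_numpy(dtype=float)
        counts, _ = np.histogram(scores, bins=edges)
        out[col.removeprefix("score_")] = {
            "bin_edges": edges.tolist(),
            "counts": counts.tolist(),
            "mean": float(np.mean(scores)),
            "sd": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
            "quantiles": {
                q: float(np.quantile(scores, float(q))) for q in ("0.05", "0.25", "0.5", "0.75", "0.95")
            },
        }
    return out


def cluster_library(
    features: FingerprintMatrix,
    spec: ClusteringSpec,
    scores: np.ndarray | Sequence[float],
) -> tuple[np.ndarray, pd.DataFrame]:
    """K-means over fingerprint bits + per-cluster score statistics.

    Returns (assignments, cluster table).  The cluster table is sorted by
    descending mean score, so its first row is the top-scoring cluster.
    """
    spec.validate(len(features))
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(features):
        raise ValueError("scores are not aligned with the fingerprint matrix")
    km = KMeans(
        n_clusters=spec.n_clusters,
        n_init=spec.n_restarts,
        random_state=spec.seed,
    )
    assignments = km.fit_predict(features.bits.astype(np.float64))
    rows = []
    for cluster in range(spec.n_clusters):
        mask = assignments == cluster
        cluster_scores = scores[mask]
        if mask.sum() == 0:
            continue
        rows.append(
            {
                "cluster": cluster,
                "n_compounds": int(mask.sum()),
                "mean_score": float(np.mean(cluster_scores)),
                "median_score": float(np.median(cluster_scores)),
                "q1_score": float(np.quantile(cluster_scores, 0.25)),
                "q3_score": float(np.quantile(cluster_scores, 0.75)),
                "max_score": float(np.max(cluster_scores)),
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["mean_score", "cluster"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    logger.info(
        "k-means k=%d: top cluster #%d mean score %.3f vs library %.3f",
        spec.n_clusters, int(table.loc[0, "cluster"]), table.loc[0, "mean_score"], float(np.mean(scores)),
    )
    return assignments, table


def embed_2d(
    features: FingerprintMatrix,
    groups: Sequence[str] | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
) -> pd.DataFrame:
    """Seeded 2-D t-SNE of fingerprint space, for visualization only."""
    n = len(features)
    if n < 2:
        raise ValueError("need at least 2 compounds to embed")
    perplexity = min(perplexity, max(1.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=500,
    )
    coords = tsne.fit_transform(features.bits.astype(np.float64))
    df = pd.DataFrame(
        {"inchikey": features.keys, "x": coords[:, 0], "y": coords[:, 1]}
    )
    df["group"] = list(groups) if groups is not None else "library"
    return df


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two binary vectors.

    Defined as 0 when both vectors are all-zero (empty union).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return float(np.sum(a & b)) / union


def tanimoto_search(
    query: Molecule,
    library: CompoundLibrary | FingerprintMatrix,
    spec: FingerprintSpec = FingerprintSpec(),
) -> pd.DataFrame:
    """Rank a library by Tanimoto similarity to the query compound.

    Ties are broken by InChI key for a reproducible ordering.  An all-zero
    query fingerprint yields Tc = 0 against everything, with a warning.
    """
    query_fp = compute_fingerprint(query, spec)
    if query_fp.sum() == 0:
        logger.warning("query %s has an all-zero fingerprint; all Tc = 0", query.inchikey)
    if isinstance(library, FingerprintMatrix):
        matrix = library
    else:
        from .vectorization import vectorize_set

        matrix = vectorize_set(library, spec)
    if matrix.spec != spec:
        raise ConfigError("library fingerprints do not match the requested spec")
    q = query_fp.astype(bool)
    bits = matrix.bits.astype(bool)
    inter = (bits & q).sum(axis=1)
    union = (bits | q).sum(axis=1)
    tc = np.where(union == 0, 0.0, inter / np.maximum(union, 1))
    df = pd.DataFrame({"inchikey": matrix.keys, "tanimoto": tc})
    df = df.sort_values(["tanimoto", "inchikey"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Plotting (matplotlib Agg; files only, no interactive backend)
# ---------------------------------------------------------------------------

def plot_score_distributions(summaries: dict[str, dict], out_dir: str | Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for model, summary in summaries.items():
        fig, ax = plt.subplots(figsize=(5, 3.5))
        edges = np.asarray(summary["bin_edges"])
        ax.bar(edges[:-1], summary["counts"], width=np.diff(edges), align="edge")
        ax.set_xlabel(f"{model.upper()} prediction score")
        ax.set_ylabel("compounds")
        fig.tight_layout()
        path = out_dir / f"score_distribution_{model}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def plot_property_distributions(profiles: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for col in PROFILE_COLUMNS:
        values = profiles[col].dropna()
        if values.empty:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.hist(values, bins=40)
        ax.set_xlabel(col)
        ax.set_ylabel("compounds")
        fig.tight_layout()
        path = out_dir / f"property_{col}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def plot_embedding(embedding: pd.DataFrame, out_path: str | Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 5))
    for group, sub in embedding.groupby("group"):
        ax.scatter(sub["x"], sub["y"], s=6, alpha=0.6, label=str(group))
    ax.legend(markerscale=2, fontsize=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
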