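"""Library scoring, rank aggregation and the top-1% virtual-hit list.

Each trained model assigns every library compound a probability-of-active
score.  Per model, compounds are ranked 1..N by descending score (ties broken
by InChI key so ranks form a strict permutation).  The ensemble rank of a
compound is the arithmetic mean of its per-model ranks — rank averaging is
scale-free, so models with differently calibrated scores contribute equally.
The virtual-hit list is the union of the top ``ceil(top_fraction * N)``
compounds from each individual model ranking and from the ensemble ranking,
deduplicated by InChI key.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_training import TrainedClassifier
from .vectorization import ConfigError, FingerprintMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleSpec:
    top_fraction: float = 0.01
    rank_tie_break: str = "score-then-inchikey"

    def __post_init__(self) -> None:
        if not 0.0 < self.top_fraction <= 1.0:
            raise ConfigError(f"top_fraction out of (0, 1]: {self.top_fraction}")


def score_library(model: TrainedClassifier, features: FingerprintMatrix) -> np.ndarray:
    """Probability-of-active score per compound, in feature row order.

    Refuses to score when the library was vectorized under a different
    fingerprint spec than the model was trained on.
    """
    if model.fingerprint_spec != features.spec:
        raise ConfigError(
            f"fingerprint spec mismatch: model trained on {model.fingerprint_spec}, "
            f"library vectorized with {features.spec}"
        )
    scores = model.estimator.predict_proba(features.bits)[:, 1]
    return np.asarray(scores, dtype=float)


def _strict_ranks(scores: np.ndarray, keys: Sequence[str]) -> np.ndarray:
    """Ranks 1..N, best score first; ties broken lexicographically by key."""
    order = sorted(range(len(keys)), key=lambda i: (-scores[i], keys[i]))
    ranks = np.empty(len(keys), dtype=int)
    for pos, i in enumerate(order, start=1):
        ranks[i] = pos
    return ranks


def rank_and_merge(
    scores_by_model: Mapping[str, np.ndarray | Sequence[float]],
    keys: Sequence[str],
    spec: EnsembleSpec = EnsembleSpec(),
    smiles: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the full screen report and flag the merged top-hit list.

    Returns a table sorted by ensemble rank with one row per compound:
    per-model scores and ranks, the ensemble (mean) rank and a ``top_hit``
    flag marking membership in the merged top list.  The merged list is the
    union of the top ``ceil(top_fraction * N)`` compounds of every individual
    model ranking and of the ensemble ranking; dedup is by InChI key.
    """
    keys = list(keys)
    n = len(keys)
    if n == 0:
        raise ValueError("empty compound set")
    if len(set(keys)) != n:
        raise ValueError("duplicate inchikeys in the compound set")
    arrays: dict[str, np.ndarray] = {}
    for name, vec in scores_by_model.items():
        arr = np.asarray(vec, dtype=float)
        if arr.shape != (n,):
            raise ValueError(
                f"model {name!r} scored {arr.shape[0] if arr.ndim else '?'} compounds, expected {n}"
            )
        arrays[name] = arr
    if not arrays:
        raise ValueError("need at least one model's scores")

    data: dict[str, object] = {"inchikey": keys}
    if smiles is not None:
        data["smiles"] = list(smiles)
    rank_cols: list[str] = []
    for name in sorted(arrays):
        ranks = _strict_ranks(arrays[name], keys)
        data[f"score_{name}"] = arrays[name]
        data[f"rank_{name}"] = ranks
        rank_cols.append(f"rank_{name}")
    df = pd.DataFrame(data)
    df["ensemble_rank"] = df[rank_cols].mean(axis=1)

    k = math.ceil(spec.top_fraction * n)
    top_keys: set[str] = set()
    for col in rank_cols:
        top_keys.update(df.loc[df[col] <= k, "inchikey"])
    # Ensemble top-k under the same strict tie policy (mean rank, then key).
    ens_order = df.sort_values(["ensemble_rank", "inchikey"], kind="mergesort")
    top_keys.update(ens_order["inchikey"].head(k))
    df["top_hit"] = df["inchikey"].isin(top_keys)

    df = df.sort_values(["ensemble_rank", "inchikey"], kind="mergesort").reset_index(drop=True)
    logger.info(
        "ranked %d compounds; top-%d per ranking; merged hit list %d",
        n, k, int(df["top_hit"].sum()),
    )
    return df


def top_hits(report: pd.DataFrame) -> pd.DataFrame:
    """The merged virtual-hit rows of a screen report, in ensemble order."""
    return report[report["top_hit"]].reset_index(drop=True)
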