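"""Retrospective hold-out validation.

To simulate a hit-finding campaign for a novel target, the query target's own
known actives are withheld from training: models learn only from the chemistry
of the homologous (expanded) targets, and the withheld actives are reintroduced
at scoring time.  A useful model assigns them systematically higher scores
than a general screening library.

A compound is withheld only when its active evidence comes *solely* from the
query target; a compound that is also active on another expanded target stays
in training (removing it would discard legitimate homolog evidence).  The
significance of the withheld-vs-library score gap is assessed with a
two-sided Welch unequal-variance t-test (a Mann-Whitney rank test is available
as an alternative), with the usual star notation at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .compound_curation import (
    ActivityRecord,
    LabeledCompound,
    LabelingConfig,
    _median,
    _passes,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RetroResult:
    model_kind: str
    mean_score_actives: float
    mean_score_library: float
    sem_actives: float
    sem_library: float
    test_statistic: float
    p_value: float
    significance_stars: Literal["ns", "*", "**", "***"]
    direction: Literal["actives_higher", "library_higher", "equal"]
    test_name: str = "welch-t"
    evaluable: bool = True

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "mean_score_actives": self.mean_score_actives,
            "mean_score_library": self.mean_score_library,
            "sem_actives": self.sem_actives,
            "sem_library": self.sem_library,
            "test_statistic": self.test_statistic,
            "p_value": self.p_value,
            "significance_stars": self.significance_stars,
            "direction": self.direction,
            "test_name": self.test_name,
            "evaluable": self.evaluable,
        }


def stars_for(p_value: float) -> str:
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def withhold_query_actives(
    labeled: Sequence[LabeledCompound],
    records: Sequence[ActivityRecord],
    query_uniprot: str,
    chosen_type: str,
    config: LabelingConfig = LabelingConfig(),
) -> tuple[list[LabeledCompound], list[LabeledCompound]]:
    """Split a labeled set into (training set, withheld query actives).

    A labeled active moves to the withheld set when its per-target active
    evidence (median of normalized measurements passing the cutoff) exists for
    the query target and for no other target.  Everything else — inactives,
    and actives with homolog evidence — stays in training.
    """
    per_compound_target: dict[str, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    for rec in records:
        if rec.value_type != chosen_type or rec.value_nm is None:
            continue
        per_compound_target[rec.molecule.inchikey][rec.target_uniprot].append(rec.value_nm)

    def active_targets(inchikey: str) -> set[str]:
        return {
            target
            for target, values in per_compound_target.get(inchikey, {}).items()
            if _passes(_median(values), chosen_type, config)
        }

    training: list[LabeledCompound] = []
    withheld: list[LabeledCompound] = []
    n_shared = 0
    for compound in labeled:
        if compound.label != "active":
            training.append(compound)
            continue
        targets = active_targets(compound.molecule.inchikey)
        if targets == {query_uniprot}:
            withheld.append(compound)
        else:
            if query_uniprot in targets:
                n_shared += 1
            training.append(compound)
    logger.info(
        "withheld %d query-only actives; %d query actives shared with homologs stay in training",
        len(withheld), n_shared,
    )
    if not withheld:
        logger.warning("query %s has no withholdable actives; validation not evaluable", query_uniprot)
    return training, withheld


def compare_scores(
    withheld_scores: Sequence[float],
    library_scores: Sequence[float],
    model_kind: str = "model",
    test: Literal["welch-t", "mannwhitney"] = "welch-t",
) -> RetroResult:
    """Two-sided comparison of withheld-active vs library score means."""
    a = np.asarray(withheld_scores, dtype=float)
    b = np.asarray(library_scores, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score vectors must be non-empty")
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    sem_a = float(stats.sem(a)) if a.size > 1 else float("nan")
    sem_b = float(stats.sem(b)) if b.size > 1 else float("nan")
    direction = (
        "actives_higher" if mean_a > mean_b else "library_higher" if mean_b > mean_a else "equal"
    )
    if a.size < 2 or b.size < 2:
        logger.warning("a score vector has a single element; p-value undefined")
        return RetroResult(
            model_kind=model_kind,
            mean_score_actives=mean_a,
            mean_score_library=mean_b,
            sem_actives=sem_a,
            sem_library=sem_b,
            test_statistic=float("nan"),
            p_value=float("nan"),
            significance_stars="ns",
            direction=direction,
            test_name=test,
            evaluable=False,
        )
    if test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return RetroResult(
        model_kind=model_kind,
        mean_score_actives=mean_a,
        mean_score_library=mean_b,
        sem_actives=sem_a,
        sem_library=sem_b,
        test_statistic=float(res.statistic),
        p_value=p,
        significance_stars=stars_for(p),
        direction=direction,
        test_name=test,
    )


def plot_retro_bars(results: Sequence[RetroResult], out_path) -> None:
    """Bar plot of mean scores (library vs withheld actives) with SEM bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(1.8 * max(len(results), 1) + 1.5, 3.5))
    width = 0.35
    for i, res in enumerate(results):
        ax.bar(i - width / 2, res.mean_score_library, width, color="black",
               yerr=res.sem_library, capsize=3)
        ax.bar(i + width / 2, res.mean_score_actives, width, color="gray",
               yerr=res.sem_actives, capsize=3)
        top = max(res.mean_score_actives, res.mean_score_library)
        ax.text(i, top * 1.05, res.significance_stars, ha="center", fontsize=10)
    ax.set_xticks(range(len(results)))
    ax.set_xticklabels([r.model_kind.upper() for r in results])
    ax.set_ylabel("mean VS score")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
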