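"""Pathway rank tables, internal-correlation diagnostics, and ROC evaluation.

The per-gene pathway rank table is the method's end product: for one gene,
every pathway with its ORA p-values per threshold, GSEA ES and exact p,
percentile score, and a final rank under the combined sort key — ORA
top-500 p ascending, then p-score ascending, then set id.  Pathways with
no ORA signal (p = 1) are thereby ordered among themselves by p-score,
which is exactly the gap the percentile calibration fills.

The diagnostics quantify how a pathway's internal correlation (mean
pairwise Pearson r among its members) inflates enrichment p-values of
NON-member genes; ROC/AUC evaluation scores gene–pathway pairs against
annotated membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .expression import CorrelationMatrix
from .genesets import GeneSet, GeneSetCollection
from .gsea import EsResult
from .ora import OraResult
from .pscore import PScoreResult


def internal_correlation(corr: CorrelationMatrix, gene_set: GeneSet | Iterable[str]) -> float:
    """Mean Pearson r over all unordered distinct member pairs of a pathway."""
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    present = sorted(members.intersection(corr.gene_ids))
    if len(present) < 2:
        raise ValueError(f"need >=2 member genes in the matrix, got {len(present)}")
    sub = corr.values.loc[present, present].to_numpy(dtype=float)
    iu = np.triu_indices(len(present), k=1)
    return float(sub[iu].mean())


@dataclass
class DiagnosticsTable:
    """Per-pathway internal correlation vs mean non-member -log10 p.

    ``table`` is indexed by set_id with an ``internal_correlation`` column
    and one ``mean_neglog10_p[<approach>]`` column per approach.
    ``summary_r`` carries, per approach, the Pearson r between internal
    correlation and that mean across pathways — or None when either
    variable has zero variance (r undefined, never silent NaN).
    """

    table: pd.DataFrame
    summary_r: dict[str, float | None]


def inflation_diagnostic(
    pvalues: Mapping[str, Mapping[str, Mapping[str, float]]],
    coll: GeneSetCollection,
    corr: CorrelationMatrix,
) -> DiagnosticsTable:
    """Correlate pathway internal correlation with non-member significance.

    ``pvalues[approach][gene_id][set_id]`` holds the p-value of each
    (gene, pathway) pair under each approach.  For every pathway the mean
    of -log10 p over genes NOT in the pathway is computed; the summary per
    approach is the Pearson r of that mean against internal correlation
    across pathways.
    """
    if len(coll) < 2:
        raise ValueError("need >=2 pathways for a correlation across pathways")
    set_ids = coll.set_ids
    int_corr = {gs.set_id: internal_correlation(corr, gs) for gs in coll}
    membership = coll.as_dict()
    data: dict[str, dict[str, float]] = {sid: {} for sid in set_ids}
    summary_r: dict[str, float | None] = {}
    for approach, per_gene in pvalues.items():
        means = {}
        for gs in coll:
            vals = [
                -np.log10(per_gene[g][gs.set_id])
                for g in per_gene
                if g not in membership[gs.set_id] and gs.set_id in per_gene[g]
            ]
            if not vals:
                raise ValueError(f"no non-member p-values for pathway {gs.set_id!r}")
            means[gs.set_id] = float(np.mean(vals))
        x = np.array([int_corr[s] for s in set_ids])
        y = np.array([means[s] for s in set_ids])
        if np.std(x) == 0 or np.std(y) == 0:
            summary_r[approach] = None
        else:
            summary_r[approach] = float(np.corrcoef(x, y)[0, 1])
        for sid in set_ids:
            data[sid][f"mean_neglog10_p[{approach}]"] = means[sid]
    table = pd.DataFrame.from_dict(data, orient="index")
    table.insert(0, "internal_correlation", [int_corr[s] for s in table.index])
    table.index.name = "set_id"
    return DiagnosticsTable(table=table, summary_r=summary_r)


def combined_pathway_ranking(
    ora_p_at_500: Mapping[str, float],
    p_scores: Mapping[str, float],
) -> pd.DataFrame:
    """Rank pathways by (ORA top-500 p asc, p-score asc, set_id asc).

    Both mappings must cover the same pathways.  Returns a DataFrame
    indexed by set_id with ``ora_p``, ``p_score`` and ``final_rank``
    (a permutation of 1..P); the result is invariant to input order.
    """
    if set(ora_p_at_500) != set(p_scores):
        only_a = sorted(set(ora_p_at_500) - set(p_scores))
        only_b = sorted(set(p_scores) - set(ora_p_at_500))
        raise ValueError(f"pathway sets differ (ora-only {only_a[:5]}, pscore-only {only_b[:5]})")
    rows = sorted(
        ((ora_p_at_500[s], p_scores[s], s) for s in ora_p_at_500),
        key=lambda t: (t[0], t[1], t[2]),
    )
    df = pd.DataFrame(
        {
            "ora_p": [r[0] for r in rows],
            "p_score": [r[1] for r in rows],
            "final_rank": np.arange(1, len(rows) + 1),
        },
        index=pd.Index([r[2] for r in rows], name="set_id"),
    )
    return df


def build_rank_table(
    gene_id: str,
    ora_results: Iterable[OraResult],
    es_results: Iterable[EsResult],
    pscore_results: Iterable[PScoreResult],
    thresholds: Sequence[int],
) -> pd.DataFrame:
    """Assemble one gene's full pathway rank table.

    Rows are pathways; columns are ``ora_p_<t>`` per threshold, ``ES``,
    ``gsea_p``, ``p_score`` and ``final_rank`` under the combined key.
    Pathways missing an ORA entry (no member in the background) default to
    ora_p = 1 at every threshold.
    """
    es_by_set = {r.set_id: r for r in es_results}
    ps_by_set = {r.set_id: r for r in pscore_results if r.gene_id == gene_id}
    set_ids = sorted(es_by_set)
    ora_cols = {t: {} for t in thresholds}
    for r in ora_results:
        if r.threshold in ora_cols:
            ora_cols[r.threshold][r.set_id] = r.p_value
    tab = pd.DataFrame(index=pd.Index(set_ids, name="set_id"))
    for t in thresholds:
        tab[f"ora_p_{t}"] = [ora_cols[t].get(s, 1.0) for s in set_ids]
    tab["ES"] = [es_by_set[s].es for s in set_ids]
    tab["gsea_p"] = [
        es_by_set[s].p_value if es_by_set[s].p_value is not None else np.nan for s in set_ids
    ]
    tab["p_score"] = [ps_by_set[s].p_score for s in set_ids]
    key_t = 500 if 500 in thresholds else sorted(thresholds)[len(thresholds) // 2]
    ranking = combined_pathway_ranking(
        tab[f"ora_p_{key_t}"].to_dict(), tab["p_score"].to_dict()
    )
    tab["final_rank"] = ranking["final_rank"].reindex(tab.index)
    return tab.sort_values("final_rank")


@dataclass
class RocCurve:
    """ROC points ordered by threshold plus the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc outside [0, 1]")

    @property
    def points(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_auc(
    labels: Sequence[int] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
    orientation: str = "smaller-is-positive",
) -> RocCurve:
    """ROC curve and trapezoidal AUC for gene–pathway pair classification.

    Labels are 1 for annotated member pairs, 0 otherwise.  With
    ``smaller-is-positive`` (the natural orientation for p-values, p-scores
    and ranks) lower scores indicate the positive class.  Tied scores
    contribute trapezoidal (0.5-weight) area, so all-tied scores give
    AUC = 0.5.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores length mismatch")
    if orientation not in ("smaller-is-positive", "larger-is-positive"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if len(np.unique(labels)) < 2:
        raise ValueError("need both positive and negative labels")
    s = -scores if orientation == "smaller-is-positive" else scores
    fpr, tpr, _ = _sk_roc_curve(labels, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)
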