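"""End-to-end orchestration: preprocessing through rank tables and ROC.

`analyze_corpus` is the library-level driver used by the CLI, the tests
and the evaluation scripts: it derives every gene's ranked list from the
correlation matrix, runs multi-threshold ORA and unweighted GSEA, pools
the observed ES values into per-pathway distributions, fits the KDEs,
scores every (gene, pathway) pair, and assembles per-gene pathway rank
tables under the combined (ORA top-500 p, p-score) key.

Enrichment scores are computed for EVERY gene of the corpus — the
percentile score is only meaningful against the full observed-ES
distribution — while the more expensive exact GSEA p-values and ORA scans
can be restricted to a subset of target genes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .expression import (
    CorrelationMatrix,
    ExpressionMatrix,
    correlation_matrix,
    filter_samples_by_depth,
    log_transform,
    quantile_normalize,
    ranked_gene_list,
    upgma_dendrogram,
    write_correlation_tsv,
    write_expression_tsv,
)
from .genesets import GeneSetCollection, filter_gene_sets, parse_gmt
from .gsea import EsResult, exact_positive_pvalue_fraction, gsea_all_pathways
from .ora import DEFAULT_THRESHOLDS, OraResult, ora_profile
from .pscore import KdeModel, PScoreResult, collect_es_distribution, fit_kde, p_score
from .ranking import build_rank_table, inflation_diagnostic, roc_auc


def preprocess(
    expr: ExpressionMatrix,
    counts: Mapping[str, float] | None = None,
    min_total: float = 1e6,
    pseudo_count: float = 4.0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Depth filter (optional), quantile normalization, log2(x+pseudo).

    Returns ``(normalized, logged)``.  The depth filter runs only when
    per-sample count totals are supplied.
    """
    if counts is not None:
        expr = filter_samples_by_depth(expr, dict(counts), min_total=min_total)
    normalized = quantile_normalize(expr)
    logged = log_transform(normalized, pseudo_count=pseudo_count)
    return normalized, logged


@dataclass
class CorpusResult:
    """Everything the analysis produced for one corpus."""

    corr: CorrelationMatrix
    collection: GeneSetCollection
    thresholds: tuple[int, ...]
    ora: dict[str, list[OraResult]]
    gsea: dict[str, list[EsResult]]
    kde_models: dict[str, KdeModel]
    p_scores: dict[str, list[PScoreResult]]
    rank_tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def ora_p_at(self, gene: str, threshold: int) -> dict[str, float]:
        out = {r.set_id: r.p_value for r in self.ora[gene] if r.threshold == threshold}
        for sid in self.collection.set_ids:  # no-overlap pathways default to p=1
            out.setdefault(sid, 1.0)
        return out

    def p_score_of(self, gene: str) -> dict[str, float]:
        return {r.set_id: r.p_score for r in self.p_scores[gene]}


def analyze_corpus(
    logged: ExpressionMatrix,
    coll: GeneSetCollection,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    min_set_size: int = 15,
    max_set_size: int = 500,
    targets: Sequence[str] | None = None,
    gsea_pvalues: bool = True,
    exclude_members_from_kde: bool = False,
) -> CorpusResult:
    """Run ORA, GSEA, percentile scoring and ranking over a logged matrix.

    ``targets`` restricts ORA, exact GSEA p-values and rank tables to a
    subset of genes (default: all); enrichment scores are always computed
    corpus-wide so each pathway's observed-ES distribution is complete.
    ``exclude_members_from_kde`` drops member genes' ES from the observed
    distributions before fitting (by default they are pooled in, since the
    corpus pools every ranked list).
    """
    corr = correlation_matrix(logged)
    genes = corr.gene_ids
    coll = filter_gene_sets(coll, genes, min_size=min_set_size, max_size=max_set_size)
    if not len(coll):
        raise ValueError("no pathways survive the size filter against this universe")
    target_set = set(genes if targets is None else targets)
    missing = target_set - set(genes)
    if missing:
        raise KeyError(f"target genes not in matrix: {sorted(missing)[:5]}")
    thresholds = tuple(sorted({int(t) for t in thresholds if int(t) <= len(genes) - 1}))
    if not thresholds:
        raise ValueError("no threshold is <= n (ranked-list length)")

    gsea_res: dict[str, list[EsResult]] = {}
    ora_res: dict[str, list[OraResult]] = {}
    for g in genes:
        ranked = ranked_gene_list(corr, g)
        gsea_res[g] = gsea_all_pathways(ranked, coll, compute_pvalues=False)
        if g in target_set:
            ora_res[g] = ora_profile(ranked, coll, thresholds)

    if gsea_pvalues:
        for g in target_set:
            for r in gsea_res[g]:
                if r.es_int > 0:
                    r.p_value = float(exact_positive_pvalue_fraction(r.n, r.m, r.es_int))
                else:
                    r.p_value = 1.0

    dists = collect_es_distribution(gsea_res)
    membership = coll.as_dict()
    models: dict[str, KdeModel] = {}
    for sid, dist in dists.items():
        if exclude_members_from_kde:
            keep = np.array(
                [g not in membership[sid] for g in gsea_res], dtype=bool
            )
            dist = type(dist)(set_id=sid, es_values=dist.es_values[keep])
        models[sid] = fit_kde(dist)

    p_scores: dict[str, list[PScoreResult]] = {
        g: [
            PScoreResult(
                gene_id=g, set_id=r.set_id, es=r.es, p_score=p_score(models[r.set_id], r.es)
            )
            for r in rs
        ]
        for g, rs in gsea_res.items()
    }

    result = CorpusResult(
        corr=corr,
        collection=coll,
        thresholds=thresholds,
        ora=ora_res,
        gsea=gsea_res,
        kde_models=models,
        p_scores=p_scores,
    )
    for g in sorted(target_set):
        result.rank_tables[g] = build_rank_table(
            g, ora_res[g], gsea_res[g], p_scores[g], thresholds
        )
    return result


# ---------------------------------------------------------------------------
# File-level pipeline


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    expression: str
    gene_sets: str
    out_dir: str
    counts: str | None = None
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    min_set_size: int = 15
    max_set_size: int = 500
    pseudo_count: float = 4.0
    min_total_counts: float = 1e6
    exclude_members_from_kde: bool = False
    roc_mode: str = "pvalue"  # 'pvalue' (pooled p-values) or 'rank'
    seed: int = 0

    def __post_init__(self) -> None:
        for p, label in ((self.expression, "expression"), (self.gene_sets, "gene_sets")):
            if not Path(p).is_file():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.counts is not None and not Path(self.counts).is_file():
            raise FileNotFoundError(f"counts file not found: {self.counts}")
        if self.roc_mode not in ("pvalue", "rank"):
            raise ValueError(f"unknown roc_mode {self.roc_mode!r}")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(config: RunConfig) -> list[str]:
    return [
        f"copex {__version__}",
        f"config {config.digest()}",
        f"seed {config.seed}",
    ]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write the TSV artifacts into ``out_dir``.

    Stage order: normalized matrix, sample dendrogram, correlation matrix,
    ORA table, GSEA table, ES-distribution/KDE summary, p-score table,
    per-gene rank tables, diagnostics, ROC/AUC.  Files carry a comment
    header with the tool version, config hash and seed; reruns with an
    unchanged config are byte-identical.
    """
    from .expression import read_expression_tsv

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = _header(config)

    expr = read_expression_tsv(config.expression)
    counts = None
    if config.counts:
        counts_df = pd.read_csv(config.counts, sep="\t", index_col=0, comment="#")
        counts = counts_df.iloc[:, 0].to_dict()
    normalized, logged = preprocess(
        expr, counts, min_total=config.min_total_counts, pseudo_count=config.pseudo_count
    )
    write_expression_tsv(normalized, out / "normalized.tsv", hdr)
    (out / "samples.nwk").write_text(upgma_dendrogram(logged).to_newick() + "\n")

    coll = parse_gmt(config.gene_sets)
    result = analyze_corpus(
        logged,
        coll,
        thresholds=config.thresholds,
        min_set_size=config.min_set_size,
        max_set_size=config.max_set_size,
        exclude_members_from_kde=config.exclude_members_from_kde,
    )
    write_correlation_tsv(result.corr, out / "correlation.tsv", hdr)

    with open(out / "ora.tsv", "wt") as fh:
        for line in hdr:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tset_id\tthreshold\toverlap\tpathway_size\tp_value\n")
        for g in sorted(result.ora):
            for r in result.ora[g]:
                fh.write(f"{g}\t{r.set_id}\t{r.threshold}\t{r.k}\t{r.K}\t{r.p_value:.10g}\n")

    with open(out / "gsea.tsv", "wt") as fh:
        for line in hdr:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tset_id\tm\tES\tk_star\tp_value\n")
        for g in sorted(result.gsea):
            for r in result.gsea[g]:
                p = "" if r.p_value is None else f"{r.p_value:.10g}"
                fh.write(f"{g}\t{r.set_id}\t{r.m}\t{r.es:.10g}\t{r.k_star}\t{p}\n")

    with open(out / "es_kde.tsv", "wt") as fh:
        for line in hdr:
            fh.write(f"# {line}\n")
        fh.write("set_id\tN\tbandwidth\n")
        for sid in sorted(result.kde_models):
            mod = result.kde_models[sid]
            fh.write(f"{sid}\t{len(mod.centers)}\t{mod.bandwidth:.10g}\n")

    with open(out / "p_scores.tsv", "wt") as fh:
        for line in hdr:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tset_id\tES\tp_score\n")
        for g in sorted(result.p_scores):
            for r in result.p_scores[g]:
                fh.write(f"{g}\t{r.set_id}\t{r.es:.10g}\t{r.p_score:.10g}\n")

    with open(out / "rank_tables.tsv", "wt") as fh:
        for line in hdr:
            fh.write(f"# {line}\n")
        first = True
        for g in sorted(result.rank_tables):
            tab = result.rank_tables[g].reset_index()
            tab.insert(0, "gene_id", g)
            tab.to_csv(fh, sep="\t", index=False, header=first, float_format="%.10g")
            first = False

    pvals = {
        "gsea": {g: {r.set_id: r.p_value for r in rs} for g, rs in result.gsea.items()},
    }
    for t in result.thresholds:
        pvals[f"ora_top{t}"] = {g: result.ora_p_at(g, t) for g in result.ora}
    diag = inflation_diagnostic(pvals, result.collection, result.corr)
    with open(out / "diagnostics.tsv", "wt") as fh:
        for line in hdr:
            fh.write(f"# {line}\n")
        for approach, r in diag.summary_r.items():
            fh.write(f"# summary_r[{approach}] = {'NA' if r is None else f'{r:.10g}'}\n")
        diag.table.to_csv(fh, sep="\t", float_format="%.10g")

    membership = result.collection.as_dict()
    key_t = 500 if 500 in result.thresholds else sorted(result.thresholds)[len(result.thresholds) // 2]
    labels, scores = [], []
    for g in sorted(result.rank_tables):
        tab = result.rank_tables[g]
        for sid in tab.index:
            labels.append(1 if g in membership[sid] else 0)
            if config.roc_mode == "rank":
                scores.append(float(tab.loc[sid, "final_rank"]))
            else:
                scores.append(float(tab.loc[sid, f"ora_p_{key_t}"]))
    roc = roc_auc(labels, scores, orientation="smaller-is-positive")
    with open(out / f"roc_{config.roc_mode}.tsv", "wt") as fh:
        for line in hdr:
            fh.write(f"# {line}\n")
        fh.write(f"# auc = {roc.auc:.10g}\n")
        roc.points.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    return out
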