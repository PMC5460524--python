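"""Expression-matrix preprocessing and the gene–gene correlation machinery.

The preprocessing chain mirrors standard bulk RNA-seq co-expression
practice: drop shallow samples (total estimated counts below a cutoff),
quantile-normalize across samples, apply ``log2(x + pseudo_count)``, and
compute the Pearson gene–gene correlation matrix.  From the correlation
matrix, each gene gets a ranked list of all other genes in decreasing
order of correlation — the input to ORA and GSEA.  A UPGMA dendrogram of
samples (average linkage on ``1 - Pearson`` between sample profiles) is
provided as a quality-control view of the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

STAGES = ("raw", "normalized", "logged")


@dataclass
class ExpressionMatrix:
    """A gene × sample matrix with a processing-stage tag.

    ``values`` is a :class:`pandas.DataFrame` indexed by gene id with sample
    ids as columns.  ``stage`` is one of ``raw`` (expression units such as
    TPM), ``normalized`` (quantile-normalized) or ``logged``.
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression matrix contains NaN or infinite values")
        if self.stage in ("raw", "normalized") and arr.size and (arr < 0).any():
            raise ValueError(f"negative values in {self.stage} expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationMatrix:
    """Symmetric gene–gene Pearson correlation matrix with unit diagonal."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric within 1e-12")
        if not np.allclose(np.diag(arr), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal differs from 1")
        if arr.size and (np.abs(arr) > 1 + 1e-12).any():
            raise ValueError("correlation values outside [-1, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class RankedGeneList:
    """All genes except ``target``, ordered by decreasing correlation with it.

    Houses the ranked list L_t: entries ``(genes[j], corrs[j])`` with
    ``corrs`` non-increasing and ``n = len(genes)`` equal to the number of
    genes in the matrix minus one.  Ties are broken by lexicographic gene
    id so the ordering is deterministic across platforms.
    """

    target: str
    genes: list[str]
    corrs: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.corrs = np.asarray(self.corrs, dtype=float)
        if len(self.genes) != len(self.corrs):
            raise ValueError("genes and corrs length mismatch")
        if self.target in self.genes:
            raise ValueError("target gene present among ranked entries")
        if np.any(np.diff(self.corrs) > 1e-12):
            raise ValueError("correlations are not non-increasing")
        self.n = len(self.genes)
        self._genes_arr = np.asarray(self.genes)

    def membership_mask(self, members: frozenset[str] | set[str]) -> np.ndarray:
        """Boolean mask over list positions for genes in ``members``."""
        return np.isin(self._genes_arr, list(members))

    def positions(self, members: frozenset[str] | set[str]) -> np.ndarray:
        """0-based ranks of ``members`` within the list (sorted ascending)."""
        return np.flatnonzero(self.membership_mask(members)).astype(np.int64)


def filter_samples_by_depth(
    expr: ExpressionMatrix, counts: dict[str, float], min_total: float = 1e6
) -> ExpressionMatrix:
    """Drop samples whose total estimated counts fall below ``min_total``.

    ``counts`` must provide a total for every sample in the matrix.  Sample
    order of the survivors is preserved; removing every sample is an error.
    """
    if min_total <= 0:
        raise ValueError("min_total must be positive")
    missing = [s for s in expr.sample_ids if s not in counts]
    if missing:
        raise KeyError(f"no count totals for samples: {missing}")
    keep = [s for s in expr.sample_ids if counts[s] >= min_total]
    if not keep:
        raise ValueError(f"all {expr.n_samples} samples fall below min_total={min_total:g}")
    return ExpressionMatrix(values=expr.values[keep].copy(), stage=expr.stage)


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns so every sample shares the same distribution.

    The reference distribution is the across-sample mean of the order
    statistics (row means after sorting each column).  Tied values within a
    column receive the mean of the reference values over their tied rank
    span — the conventional tie policy of quantile-normalization
    implementations.
    """
    if expr.stage != "raw":
        raise ValueError(f"quantile_normalize expects a raw matrix, got stage={expr.stage!r}")
    if expr.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = expr.values.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)  # reference order statistics
    # cumulative means of ref allow O(1) mean over any rank span
    cum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        # average fractional rank r maps a tie-span [lo, hi] (1-based) to
        # mean(ref[lo-1:hi]); rankdata('average') gives (lo+hi)/2, and
        # 'min'/'max' recover the span endpoints.
        lo = rankdata(col, method="min").astype(np.int64)
        hi = rankdata(col, method="max").astype(np.int64)
        out[:, j] = (cum[hi] - cum[lo - 1]) / (hi - lo + 1)
    df = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(values=df, stage="normalized")


def log_transform(expr: ExpressionMatrix, pseudo_count: float = 4.0) -> ExpressionMatrix:
    """Apply ``log2(x + pseudo_count)`` elementwise (default pseudo-count 4)."""
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    if expr.stage == "logged":
        raise ValueError("matrix is already logged")
    if expr.stage == "raw":
        warnings.warn("log-transforming a raw (not quantile-normalized) matrix", stacklevel=2)
    df = np.log2(expr.values + pseudo_count)
    return ExpressionMatrix(values=df, stage="logged")


def correlation_matrix(expr: ExpressionMatrix) -> CorrelationMatrix:
    """Pearson correlation between all gene pairs across samples.

    Requires a logged matrix with at least 3 samples.  Genes with zero
    variance have no defined correlation; they are reported in the error so
    the caller can drop them explicitly rather than silently propagate NaN.
    """
    if expr.stage != "logged":
        raise ValueError(f"correlation_matrix expects a logged matrix, got stage={expr.stage!r}")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for a meaningful correlation matrix")
    X = expr.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = [g for g, s in zip(expr.gene_ids, sd) if s == 0.0]
    if flat:
        raise ValueError(
            f"{len(flat)} gene(s) with zero variance across samples "
            f"(drop them before correlating): {flat[:10]}"
        )
    R = np.corrcoef(X)
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0  # enforce exact symmetry against rounding
    df = pd.DataFrame(R, index=expr.values.index, columns=expr.values.index)
    return CorrelationMatrix(values=df)


def ranked_gene_list(corr: CorrelationMatrix, target: str) -> RankedGeneList:
    """Rank all genes except ``target`` by decreasing correlation with it.

    Ties are broken by lexicographic gene id, making the list deterministic.
    """
    ids = corr.values.index
    if target not in ids:
        raise KeyError(f"target gene {target!r} not in correlation matrix")
    row = corr.values.loc[target]
    others = ids[ids != target]
    r = row.loc[others].to_numpy(dtype=float)
    names = others.to_numpy(dtype=object).astype(str)
    order = np.lexsort((names, -r))  # primary: r descending; secondary: id ascending
    return RankedGeneList(target=target, genes=list(names[order]), corrs=r[order])


@dataclass
class SampleDendrogram:
    """UPGMA tree over samples: scipy linkage matrix plus Newick export."""

    sample_ids: list[str]
    linkage_matrix: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Serialize as a rooted ultrametric Newick string.

        Branch lengths are half the cophenetic-distance differences, so all
        leaves sit at the same depth (ultrametric convention).
        """
        root = to_tree(self.linkage_matrix)

        def fmt(node, parent_height: float) -> str:
            length = (parent_height - node.dist) / 2.0
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.10g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = fmt(root.left, root.dist)
        right = fmt(root.right, root.dist)
        return f"({left},{right});"


def upgma_dendrogram(expr: ExpressionMatrix) -> SampleDendrogram:
    """Average-linkage (UPGMA) clustering of samples.

    Distance between samples is ``1 - Pearson`` of their expression
    profiles, consistent with the gene-side correlation machinery.
    """
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples for a dendrogram")
    X = expr.values.to_numpy(dtype=float).T  # samples × genes
    sd = X.std(axis=1)
    if (sd == 0).any():
        flat = [s for s, v in zip(expr.sample_ids, sd) if v == 0]
        raise ValueError(f"sample(s) with zero variance across genes: {flat}")
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    return SampleDendrogram(sample_ids=expr.sample_ids, linkage_matrix=Z)


# ---------------------------------------------------------------------------
# TSV I/O — first column gene id, header row of sample ids; values written
# with 10 significant digits.

def read_expression_tsv(path, stage: str = "raw") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df, stage=stage)


def write_expression_tsv(expr: ExpressionMatrix, path, header_lines: list[str] | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        expr.values.to_csv(fh, sep="\t", float_format="%.10g", index_label="gene_id")


def read_correlation_tsv(path) -> CorrelationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    arr = df.to_numpy(dtype=float)
    arr = (arr + arr.T) / 2.0  # writers round to 10 significant digits
    np.fill_diagonal(arr, 1.0)
    return CorrelationMatrix(values=pd.DataFrame(arr, index=df.index, columns=df.columns))


def write_correlation_tsv(corr: CorrelationMatrix, path, header_lines: list[str] | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        corr.values.to_csv(fh, sep="\t", float_format="%.10g", index_label="gene_id")
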