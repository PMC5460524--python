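"""Unweighted GSEA with exact gene-permutation p-values.

The enrichment score (ES) of a pathway S for a ranked list of n genes is
the signed maximum deviation of the running sum that steps +1/m on the m
pathway members and -1/(n-m) on non-members.  The null model places the m
members uniformly at random among the n positions (gene permutation;
sample permutation is meaningless for a correlation-derived ranking), and
the exact p-value for a positive ES is obtained by a lattice-path dynamic
programme that counts, with arbitrary-precision integers, the arrangements
whose running sum never reaches the observed maximum.

All running sums are kept in rescaled integer units — a member step is
+(n-m), a non-member step is -m, and the true value is integer/(m(n-m)) —
so the statistic and the DP threshold are exact and no floating-point
comparison happens inside the DP.  Pathways with non-positive ES receive
p = 1: only enrichment at the top of the list is of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

from .expression import RankedGeneList
from .genesets import GeneSet, GeneSetCollection


@dataclass
class EsResult:
    """Enrichment score of one pathway for one target gene.

    ``es`` is the signed score in [-1, 1]; ``es_int`` its exact integer
    numerator on the m(n-m) scale; ``sign`` the score's sign f(S);
    ``k_star`` the 1-based position of the maximum deviation; ``p_value``
    the exact gene-permutation p (1 whenever es <= 0), or None if p-values
    were not requested.
    """

    set_id: str
    n: int
    m: int
    es: float
    es_int: int
    sign: int
    k_star: int
    p_value: float | None = None

    def __post_init__(self) -> None:
        if abs(self.es) > 1 + 1e-12:
            raise ValueError(f"|ES| = {abs(self.es)} exceeds 1")
        if self.p_value is not None:
            if not (0.0 < self.p_value <= 1.0):
                raise ValueError(f"p_value {self.p_value} outside (0, 1]")
            if self.es <= 0 and self.p_value != 1.0:
                raise ValueError("non-positive ES must carry p = 1")


def enrichment_score(ranked: RankedGeneList, gene_set: GeneSet | frozenset[str]) -> EsResult:
    """Signed maximum deviation of the running sum, computed exactly.

    The target gene is excluded from membership.  If the maximum |prefix|
    is attained by both a positive and a negative prefix, the positive sign
    wins and ``k_star`` is the earliest position attaining the positive
    maximum — top-enrichment is the detection target.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    set_id = gene_set.set_id if isinstance(gene_set, GeneSet) else ""
    members = members - {ranked.target}
    n = ranked.n
    in_set = ranked.membership_mask(members)
    m = int(in_set.sum())
    if m == 0 or m == n:
        raise ValueError(f"gene set {set_id!r}: m={m} of n={n} — ES undefined")
    steps = np.where(in_set, n - m, -m).astype(np.int64)
    prefix = np.cumsum(steps)
    assert prefix[-1] == 0, "running sum must return to zero"
    max_dev = int(np.abs(prefix).max())
    pos_hits = np.flatnonzero(prefix == max_dev)
    if pos_hits.size:  # positive sign wins ties
        sign, k_star = 1, int(pos_hits[0]) + 1
    else:
        sign, k_star = -1, int(np.flatnonzero(prefix == -max_dev)[0]) + 1
    es_int = sign * max_dev
    return EsResult(
        set_id=set_id,
        n=n,
        m=m,
        es=es_int / (m * (n - m)),
        es_int=es_int,
        sign=sign,
        k_star=k_star,
    )


@lru_cache(maxsize=100_000)
def _count_max_prefix_below(n: int, m: int, T: int) -> int:
    """Number of m-subsets of n positions whose every rescaled prefix sum
    (member step +(n-m), non-member step -m) stays <= T-1.

    Rolling-row lattice DP over (position j, members placed h); exact
    arbitrary-precision integers throughout.  O(n·m) time, O(m) memory.
    """
    nm = n - m
    row = [0] * (m + 1)
    row[0] = 1  # zero positions, zero members, prefix 0 <= T-1 (T >= 1)
    for j in range(1, n + 1):
        h_lo = max(0, m - (n - j))
        h_hi = min(j, m)
        new = [0] * (m + 1)
        for h in range(h_lo, h_hi + 1):
            if h * nm - (j - h) * m >= T:
                continue
            acc = row[h] if h <= j - 1 else 0
            if h > 0:
                acc += row[h - 1]
            new[h] = acc
        row = new
    return row[m]


def exact_positive_pvalue_fraction(n: int, m: int, es_int: int) -> Fraction:
    """Exact ``Pr(max rescaled prefix >= es_int)`` under random placement.

    ``es_int`` is the integer ES numerator on the m(n-m) scale.  Any
    threshold <= 0 gives p = 1: the running sum ends at 0, so the maximum
    prefix is always >= 0.
    """
    if not (1 <= m <= n - 1):
        raise ValueError(f"m={m} outside [1, n-1]")
    if es_int <= 0:
        return Fraction(1)
    if es_int > m * (n - m):
        raise ValueError(f"threshold {es_int} exceeds the maximum m(n-m)={m * (n - m)}")
    A = _count_max_prefix_below(n, m, es_int)
    return 1 - Fraction(A, math.comb(n, m))


def exact_positive_pvalue(n: int, m: int, es_plus: float) -> float:
    """Exact p-value for a positive ES given as a real number in (0, 1].

    The statistic is converted to its integer numerator by rounding
    ``es_plus * m * (n-m)`` — exact by construction when the score came from
    :func:`enrichment_score`.
    """
    if es_plus <= 0:
        return 1.0
    if es_plus > 1 + 1e-12:
        raise ValueError(f"es_plus={es_plus} exceeds 1")
    T = round(es_plus * m * (n - m))
    return float(exact_positive_pvalue_fraction(n, m, T))


def gsea_all_pathways(
    ranked: RankedGeneList,
    coll: GeneSetCollection,
    compute_pvalues: bool = True,
) -> list[EsResult]:
    """ES (and optionally exact p) of every pathway for one ranked list.

    Pathways with no member in the ranked universe are skipped.  With
    ``compute_pvalues=False`` only the scores are produced (sufficient for
    building observed-ES distributions and percentile scores).
    """
    out: list[EsResult] = []
    for gs in coll:
        members = gs.members - {ranked.target}
        if not members.intersection(ranked.genes):
            continue
        res = enrichment_score(ranked, GeneSet(gs.set_id, gs.name, frozenset(members)))
        if compute_pvalues:
            if res.es_int > 0:
                res.p_value = float(exact_positive_pvalue_fraction(res.n, res.m, res.es_int))
            else:
                res.p_value = 1.0
        out.append(res)
    return out
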