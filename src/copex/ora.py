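"""Over-representation analysis of top-N co-expressed genes.

For each target gene, the top N genes of its ranked co-expression list are
tested against each pathway with the one-sided ("greater") Fisher's exact
test, scanned over a list of thresholds N.  The background universe is the
n genes of the ranked list itself — all measured genes minus the target —
and the target is likewise excluded from pathway membership, keeping the
2×2 margins consistent.

The hypergeometric tail is evaluated with exact integer combinatorics
(a single rational division at the end), so p-values carry no accumulation
error; depletion is deliberately not tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .expression import RankedGeneList
from .genesets import GeneSetCollection

DEFAULT_THRESHOLDS = (100, 500, 1000, 1500, 2000, 2500, 3000)


@dataclass(frozen=True)
class ContingencyTable:
    """Margins of the 2×2 enrichment table.

    ``k``: overlap of selected genes with the pathway; ``K``: pathway size
    in the background; ``N_sel``: number of selected (top-N) genes;
    ``N_bg``: background size.
    """

    k: int
    K: int
    N_sel: int
    N_bg: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.N_sel)):
            raise ValueError(f"k={self.k} outside [0, min(K, N_sel)]")
        if not (0 <= self.K <= self.N_bg):
            raise ValueError(f"K={self.K} outside [0, N_bg]")
        if not (0 <= self.N_sel <= self.N_bg):
            raise ValueError(f"N_sel={self.N_sel} outside [0, N_bg]")
        if self.k < self.K + self.N_sel - self.N_bg:
            raise ValueError("k below the hypergeometric support minimum")


@dataclass(frozen=True)
class OraResult:
    set_id: str
    threshold: int
    k: int
    K: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


def hypergeom_tail_fraction(tab: ContingencyTable) -> Fraction:
    """Exact upper-tail hypergeometric probability P(X >= k) as a Fraction.

    Sums ``C(K, i) * C(N_bg - K, N_sel - i)`` for ``i`` from ``k`` up to
    ``min(K, N_sel)`` using an integer term recurrence, then divides once
    by ``C(N_bg, N_sel)``.
    """
    k, K, N_sel, N_bg = tab.k, tab.K, tab.N_sel, tab.N_bg
    hi = min(K, N_sel)
    if k <= max(0, K + N_sel - N_bg):
        return Fraction(1)
    term = math.comb(K, k) * math.comb(N_bg - K, N_sel - k)
    total = term
    for i in range(k, hi):
        # exact integer recurrence for C(K,i+1)*C(N_bg-K, N_sel-i-1)
        term = term * (K - i) * (N_sel - i) // ((i + 1) * (N_bg - K - N_sel + i + 1))
        total += term
    return Fraction(total, math.comb(N_bg, N_sel))


def fisher_greater_pvalue(tab: ContingencyTable) -> float:
    """One-sided Fisher's exact test p-value for enrichment (P(X >= k))."""
    return float(hypergeom_tail_fraction(tab))


def ora_profile(
    ranked: RankedGeneList,
    coll: GeneSetCollection,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> list[OraResult]:
    """ORA of one gene's ranked list against every pathway, per threshold.

    The background is the ranked list's n genes (target excluded); pathway
    size K is counted within that background, dropping the target from
    membership if present.  One :class:`OraResult` per (pathway, threshold).
    """
    n = ranked.n
    thresholds = sorted(set(int(t) for t in thresholds))
    if not thresholds:
        raise ValueError("no thresholds supplied")
    if thresholds[0] < 1:
        raise ValueError("thresholds must be >= 1")
    if thresholds[-1] > n:
        raise ValueError(f"threshold {thresholds[-1]} exceeds ranked-list length n={n}")
    results: list[OraResult] = []
    for gs in coll:
        members = gs.members - {ranked.target}
        pos = ranked.positions(members)  # 0-based ranks, ascending
        K = len(pos)
        if K == 0:
            continue
        for N in thresholds:
            k = int((pos < N).sum())
            tab = ContingencyTable(k=k, K=K, N_sel=N, N_bg=n)
            results.append(
                OraResult(
                    set_id=gs.set_id,
                    threshold=N,
                    k=k,
                    K=K,
                    p_value=fisher_greater_pvalue(tab),
                )
            )
    return results
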