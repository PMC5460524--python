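"""Percentile (p)-scores from observed enrichment-score distributions.

For each pathway, the ES values observed across every target gene in the
corpus form an empirical distribution.  A Gaussian kernel density is
fitted to it (Silverman rule-of-thumb bandwidth, the classic default of
statistical environments), and the p-score of a gene's ES is the survival
probability ``Pr(ES >= ES_e)`` under that density — evaluated in closed
form as the mean of Gaussian survival functions, since the KDE is a
Gaussian mixture.

Because the observed distribution already carries each pathway's internal
correlation, this per-pathway calibration removes the p-value inflation
that internal correlation causes, making pathways with very different
internal correlation comparable on one scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.special import ndtr

from .gsea import EsResult


@dataclass
class EsDistribution:
    """Observed ES values of one pathway across all target genes."""

    set_id: str
    es_values: np.ndarray

    def __post_init__(self) -> None:
        self.es_values = np.asarray(self.es_values, dtype=float)
        if self.es_values.ndim != 1 or self.es_values.size == 0:
            raise ValueError("es_values must be a non-empty 1-D array")
        if (np.abs(self.es_values) > 1 + 1e-12).any():
            raise ValueError("ES values outside [-1, 1]")

    @property
    def n(self) -> int:
        return int(self.es_values.size)


@dataclass
class KdeModel:
    """Gaussian KDE of an observed-ES distribution: centers + bandwidth."""

    set_id: str
    centers: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")

    def density(self, x: float | np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.centers[None, :]) / self.bandwidth
        phi = np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
        return phi.mean(axis=1) / self.bandwidth

    def survival(self, x: float | np.ndarray) -> np.ndarray:
        """Exact ``Pr(X >= x)`` of the Gaussian mixture (no quadrature)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.centers[None, :]) / self.bandwidth
        return ndtr(-z).mean(axis=1)


@dataclass(frozen=True)
class PScoreResult:
    gene_id: str
    set_id: str
    es: float
    p_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_score <= 1.0):
            raise ValueError(f"p_score {self.p_score} outside [0, 1]")


def collect_es_distribution(
    results: Mapping[str, Iterable[EsResult]],
) -> dict[str, EsDistribution]:
    """Group per-(gene, pathway) ES values by pathway.

    ``results`` maps each target gene id to its list of EsResult.  Every
    gene must contribute an ES for every pathway seen anywhere in the
    corpus (member genes included — the corpus pools all ranked lists);
    gaps are reported as an error rather than silently shortening a
    distribution.
    """
    per_set: dict[str, list[float]] = {}
    per_set_genes: dict[str, set[str]] = {}
    genes = list(results.keys())
    for gene, rs in results.items():
        for r in rs:
            per_set.setdefault(r.set_id, []).append(r.es)
            per_set_genes.setdefault(r.set_id, set()).add(gene)
    gaps = {
        sid: sorted(set(genes) - seen)
        for sid, seen in per_set_genes.items()
        if len(seen) != len(genes)
    }
    if gaps:
        detail = "; ".join(f"{sid}: missing {v[:5]}" for sid, v in sorted(gaps.items()))
        raise ValueError(f"incomplete (gene, pathway) ES coverage — {detail}")
    return {
        sid: EsDistribution(set_id=sid, es_values=np.asarray(vals))
        for sid, vals in per_set.items()
    }


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: ``0.9 * min(sd, IQR/1.34) * N^(-1/5)``.

    Uses the sample standard deviation (ddof=1) and type-7 quartiles.  When
    the IQR is zero but the spread is not, the sd term alone is used —
    otherwise a discrete-valued sample would get a degenerate bandwidth.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values for a bandwidth")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise ValueError("all values identical — bandwidth undefined")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # type-7 interpolation
    iqr = float(q3 - q1)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-1 / 5)


def fit_kde(dist: EsDistribution) -> KdeModel:
    """Gaussian KDE of a pathway's observed-ES distribution."""
    return KdeModel(
        set_id=dist.set_id,
        centers=dist.es_values.copy(),
        bandwidth=silverman_bandwidth(dist.es_values),
    )


def p_score(model: KdeModel, es_e: float) -> float:
    """Percentile score ``Pr(ES >= ES_e)`` under the fitted KDE."""
    return float(model.survival(es_e)[0])


def p_scores_for_corpus(
    results: Mapping[str, Iterable[EsResult]],
    models: Mapping[str, KdeModel] | None = None,
) -> list[PScoreResult]:
    """p-score of every (gene, pathway) pair in a corpus of GSEA results.

    Fits one KDE per pathway from the pooled observed ES values unless
    pre-fitted models are supplied.
    """
    if models is None:
        models = {sid: fit_kde(d) for sid, d in collect_es_distribution(results).items()}
    out: list[PScoreResult] = []
    for gene, rs in results.items():
        for r in rs:
            out.append(
                PScoreResult(
                    gene_id=gene,
                    set_id=r.set_id,
                    es=r.es,
                    p_score=p_score(models[r.set_id], r.es),
                )
            )
    return out
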