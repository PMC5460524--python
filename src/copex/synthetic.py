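"""Seeded synthetic expression corpora with planted co-expressed pathways.

Gene expression is drawn from a multivariate normal with block-exchangeable
covariance: each planted pathway is a block of genes sharing a within-block
correlation rho_p, all cross-block and background correlations equal rho0
(default 0).  The draw uses the factor representation

    z_gene = sqrt(rho0) * w_sample + sqrt(rho_p - rho0) * f_block,sample
             + sqrt(1 - rho_p) * eps_gene,sample

which realises the target covariance exactly and is positive semi-definite
whenever ``rho0 <= rho_p < 1``.  Values are then shifted and scaled to a
non-negative expression-like range (``baseline + z * noise_sd``, floored at
0) so quantile normalization and the log2(x+4) transform stay meaningful.
The planted blocks are emitted as a truth GMT, giving condition-positive /
condition-negative labels for ROC evaluation.

This emulates the correlation structure a real RNA-seq compendium induces,
not count-level realism (no negative-binomial noise or library-size
effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genesets import GeneSet, GeneSetCollection


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a planted-pathway simulation.

    ``pathways`` is a list of (size, within_correlation) pairs; blocks are
    disjoint and laid out over the first genes of the matrix.  ``seed`` is
    mandatory — every dataset is reproducible byte-identically from its
    config.
    """

    n_genes: int
    n_samples: int
    pathways: tuple[tuple[int, float], ...]
    background_correlation: float = 0.0
    noise_sd: float = 2.0
    baseline: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathways", tuple((int(s), float(r)) for s, r in self.pathways))
        if self.n_genes < 2 or self.n_samples < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        total = sum(s for s, _ in self.pathways)
        if total > self.n_genes:
            raise ValueError(f"pathway sizes sum to {total} > n_genes={self.n_genes}")
        rho0 = self.background_correlation
        if not (0.0 <= rho0 < 1.0):
            raise ValueError(f"background correlation {rho0} outside [0, 1)")
        for i, (size, rho) in enumerate(self.pathways):
            if size < 2:
                raise ValueError(f"pathway {i}: size must be >= 2")
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"pathway {i}: within-correlation {rho} outside [0, 1)")
            if rho < rho0:
                raise ValueError(
                    f"pathway {i}: within-correlation {rho} below background {rho0} — "
                    "covariance not positive semi-definite"
                )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_samples": self.n_samples,
            "pathways": [list(p) for p in self.pathways],
            "background_correlation": self.background_correlation,
            "noise_sd": self.noise_sd,
            "baseline": self.baseline,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(
            n_genes=int(d["n_genes"]),
            n_samples=int(d["n_samples"]),
            pathways=tuple((int(s), float(r)) for s, r in d["pathways"]),
            background_correlation=float(d.get("background_correlation", 0.0)),
            noise_sd=float(d.get("noise_sd", 2.0)),
            baseline=float(d.get("baseline", 10.0)),
            seed=int(d["seed"]),
        )


@dataclass
class SyntheticDataset:
    """A raw expression matrix, the planted-truth GMT, and the config."""

    expression: ExpressionMatrix
    truth: GeneSetCollection
    config: SimulationConfig = field(repr=False)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic dataset from a :class:`SimulationConfig`."""
    rng = np.random.default_rng(config.seed)
    G, S = config.n_genes, config.n_samples
    rho0 = config.background_correlation
    genes = _gene_ids(G)

    eps = rng.standard_normal((G, S))  # idiosyncratic noise
    w = rng.standard_normal(S)  # global factor shared by all genes
    Z = np.empty((G, S))
    start = 0
    block_slices: list[slice] = []
    for size, rho in config.pathways:
        f = rng.standard_normal(S)  # block factor
        sl = slice(start, start + size)
        Z[sl] = (
            np.sqrt(rho0) * w
            + np.sqrt(rho - rho0) * f
            + np.sqrt(1.0 - rho) * eps[sl]
        )
        block_slices.append(sl)
        start += size
    Z[start:] = np.sqrt(rho0) * w + np.sqrt(1.0 - rho0) * eps[start:]

    values = np.maximum(config.baseline + Z * config.noise_sd, 0.0)
    expr = ExpressionMatrix(
        values=pd.DataFrame(
            values, index=genes, columns=[f"s{j:03d}" for j in range(1, S + 1)]
        ),
        stage="raw",
    )
    sets = [
        GeneSet(
            set_id=f"PW{i + 1:02d}",
            name=f"planted block {i + 1} (size={sl.stop - sl.start}, rho={config.pathways[i][1]:g})",
            members=frozenset(genes[sl]),
        )
        for i, sl in enumerate(block_slices)
    ]
    truth = GeneSetCollection(sets=sets, universe=frozenset(genes))
    return SyntheticDataset(expression=expr, truth=truth, config=config)


def planted_truth_labels(dataset: SyntheticDataset) -> pd.DataFrame:
    """Binary condition-positive labels: 1 iff gene is in the planted pathway.

    Returns a genes × pathways 0/1 DataFrame with one row per gene of the
    matrix and one column per planted pathway, ready to be flattened into
    ROC labels.
    """
    genes = dataset.expression.gene_ids
    out = pd.DataFrame(
        0, index=pd.Index(genes, name="gene_id"), columns=dataset.truth.set_ids, dtype=int
    )
    for gs in dataset.truth:
        out.loc[sorted(gs.members), gs.set_id] = 1
    return out
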