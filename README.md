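# copex — pathway ranking from gene co-expression

`copex` predicts which pathways a gene works in, using nothing but an
expression compendium and a pathway collection. The premise is guilt by
association: genes acting in the same pathway tend to be co-expressed
across many conditions, so the genes most correlated with a target gene
should be enriched for the target's pathways. For every gene, `copex`
produces a ranked table of pathways, combining three statistics that probe
that enrichment in complementary ways.

## The method

Starting from a gene × sample matrix (e.g. TPM), samples shallower than
10⁶ total counts are dropped, columns are quantile-normalized, values are
mapped through log₂(x + 4), and the gene–gene Pearson correlation matrix
is computed. For each target gene *t* the remaining *n* genes are sorted
by decreasing correlation into a ranked list *L_t = {g₁, …, g_n}*. Three
scores are then computed for every pathway *S* (pathways outside the
15–500 gene size band, counted within the measured universe, are
excluded):

- **ORA** — a one-sided Fisher's exact test on the overlap between the top
  *N* genes of *L_t* and *S*, scanned over
  N ∈ {100, 500, 1000, 1500, 2000, 2500, 3000}. The hypergeometric tail
  is evaluated in exact integer arithmetic.
- **Unweighted GSEA with an exact p-value** — the running sum steps +1/m
  on members of *S* (m = |S|) and −1/(n−m) otherwise; the enrichment
  score ES is its signed maximum deviation. Under the gene-permutation
  null (m members placed uniformly among n positions), the p-value
  Pr(ES₊ⁿᵘˡˡ ≥ ES₊) is computed *exactly* by a lattice-path dynamic
  programme over big integers — no sampling, no asymptotics. Pathways
  with ES ≤ 0 get p = 1 (only top-of-list enrichment is of interest).
- **The percentile (p-)score** — GSEA p-values are inflated for pathways
  whose members are internally correlated: even unrelated genes get small
  p-values against a tight co-expression module. The p-score recalibrates
  per pathway: pool the observed ES of the pathway across *all* target
  genes in the corpus, fit a Gaussian KDE (Silverman bandwidth), and score
  a gene by the mixture's survival probability Pr(ES ≥ ES_e), evaluated in
  closed form. Internal correlation is baked into the reference
  distribution, so it cancels.

The final per-gene pathway ranking orders by ORA top-500 p-value, then by
p-score — the p-score breaks the ties among pathways the ORA cannot
distinguish and is comparable across pathways of different internal
correlation.

The package also ships the evaluation machinery (ROC/AUC of gene–pathway
pairs against annotated membership, internal-correlation inflation
diagnostics) and a seeded generator of synthetic corpora with planted
co-expressed pathways, so every claim is testable without any download.

## Worked example

Plant two 20-gene pathways in a 300-gene corpus — one tightly co-expressed
(ρ = 0.8), one near background (ρ = 0.1) — and rank pathways for a member
of the tight block:

```python
from copex import SimulationConfig, simulate_dataset, preprocess, analyze_corpus

cfg = SimulationConfig(n_genes=300, n_samples=50,
                       pathways=((20, 0.8), (20, 0.1)), seed=42)
ds = simulate_dataset(cfg)
_, logged = preprocess(ds.expression)
result = analyze_corpus(logged, ds.truth, thresholds=(100,),
                        min_set_size=15, max_set_size=500)

gene = sorted(ds.truth.sets[0].members)[0]
print(result.rank_tables[gene].to_string(float_format=lambda v: f"{v:.3g}"))
```

```
        ora_p_100     ES  gsea_p  p_score  final_rank
set_id
PW01     2.65e-10      1   2e-30   0.0362           1
PW02        0.947 -0.158       1    0.644           2
```

Gene `g0001` belongs to `PW01`: its 19 co-members crowd the top of its
ranked list, so the ORA overlap p-value is ~10⁻¹⁰, the ES reaches the
maximum +1, and the exact permutation p is ~10⁻³⁰. The p-score (0.036)
says this ES is high *even against PW01's own observed-ES distribution* —
the signal is not an internal-correlation artifact. `PW02`, which the
gene does not belong to, shows no enrichment under any score.

The same pipeline is available from the shell:

```sh
copex simulate --n-genes 300 --n-samples 50 --pathway 20:0.8 --pathway 20:0.1 \
      --seed 42 --out-dir sim/
copex run --expression sim/expression.tsv --gmt sim/truth.gmt \
      --thresholds 100 --out-dir run/
```

which writes every intermediate artifact (normalized matrix, correlation
matrix, ORA/GSEA/p-score tables, rank tables, inflation diagnostics,
ROC) as headered TSV.

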