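# gsebench

A self-contained benchmarking framework for **gene set enrichment analysis
(GSEA) methods**, for method developers and analysts who want to know — with
controlled experiments rather than anecdotes — how an enrichment method
behaves: does it control its type-I error under label randomization, does its
significance depend on gene set size, and does it put phenotype-relevant
gene sets at the top of its ranking?

The package re-implements six classic methods behind one interface
(dataset + gene set collection in, ranking out):

| method | null hypothesis | gene statistic | set statistic | significance |
|--------|-----------------|----------------|---------------|--------------|
| ORA    | competitive     | user-defined DE call | DE/set overlap | hypergeometric (Fisher) |
| GSEA   | competitive     | signal-to-noise t | weighted KS running sum | sample permutation |
| SAFE   | competitive     | Student t (pluggable) | Wilcoxon rank sum | sample permutation |
| PADOG  | competitive     | \|moderated t\| | overlap-down-weighted mean | sample permutation |
| CAMERA | competitive     | moderated t → z | correlation-adjusted two-sample t | parametric |
| SAMGS  | self-contained  | SAM t | sum of squared SAM t | sample permutation |

Four more well-known methods (GLOBALTEST, GSA, ROAST, GSVA) are registered
as explicit stubs demonstrating the plugin interface.

Everything runs on synthetic data with known ground truth: a generator
produces expression matrices (Gaussian log-intensities or negative-binomial
RNA-seq counts) with a controlled DE fraction, effect size and inter-gene
correlation, plus gene set collections with designated truly-enriched sets
and a noisy relevance ranking. RNA-seq counts are made usable by the
t-statistic methods through a variance-stabilizing transformation: moderated
log2 counts-per-million with prior count `0.5 / φ̂`, where `φ̂` is the
estimated common negative-binomial dispersion.

## The relevance score

A method *m* applied to dataset *d* ranks `N_GS` gene sets. Absolute ranks
`r_A ∈ {1..N_GS}` become relative ranks `r_R = r_A / N_GS` and weights

```
w = 1 − r_R            (with ties: w = 1 − P(S ≥ s), the fraction of sets
                        whose ranking statistic is at least as extreme)
```

Given an a-priori relevance score `S_p(i) ≥ 0` per set, the ranking's
relevance score and its optimum-normalized form are

```
X_m(d) = Σ_i w(i) · S_p(i)        X̄_m(d) = X_m(d) / O_p ∈ [0, 1]
```

where `O_p` is the score of the ranking ordered exactly by `S_p`. Two
empirical nulls calibrate an observed `X`: random rankings of the same sets
(enumerated exhaustively when `N_GS! ≤ 10⁴`), and rankings from re-running
the method under permuted sample labels, which preserves dependencies caused
by overlapping sets.

## Worked example

```sh
python examples/02_run_enrichment_methods.py
```

```
method  hypothesis      top set    min p  frac p<.05
ora     competitive     GS004     0.0004        0.13
gsea    competitive     GS023     0.0100        0.10
safe    competitive     GS004     0.0050        0.17
padog   competitive     GS001     0.0348        0.07
camera  competitive     GS019     0.0474        0.03
samgs   self_contained  GS004     0.0050        0.87
truly enriched sets: ['GS000', 'GS001', 'GS002', 'GS003', 'GS004', 'GS005']
```

On a simulated dataset (1000 genes, 30% DE) with 30 gene sets of which six
are truly enriched, the competitive methods flag a small fraction of sets
and tend to rank a truly enriched set first; the self-contained SAMGS calls
87% of all sets significant — the characteristic difference between the two
null hypotheses. Scoring the same rankings against the a-priori relevance
ranking (`examples/03_relevance_scoring.py`) gives, for PADOG, `X = 65.03`,
`O_p = 68.69`, `X̄ = 0.947`, with random-ranking null p = 0.002: the method
recovers 95% of the attainable relevance, far beyond chance.

Other examples cover scenario generation (`01`), the type-I error assay
(`04`), the set-size dependency assay (`05`) and the RNA-seq VST (`06`).
A thin CLI wraps the same machinery:

```sh
gsebench simulate --out scenario/ --seed 1
gsebench run --scenario scenario/ --method padog --out ranking.tsv
gsebench assay type1 --scenario scenario/ --method camera --out type1.tsv
gsebench benchmark --scenario scenario/ --out-dir results/
gsebench report results/report.json
```

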