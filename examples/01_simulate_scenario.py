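"""Generate a synthetic benchmark scenario and write it to disk.

A scenario is the triple every benchmark assay needs: an expression matrix
with known differentially expressed (DE) genes, a gene set collection with
designated truly-enriched sets, and a noisy-but-informative relevance
ranking over those sets.
"""

from gsebench import make_scenario, save_scenario, simulate_expression

dataset, truth = simulate_expression(
    n_genes=1000, n_per_group=10, de_fraction=0.3, effect_size=1.0, seed=1
)
collection, relevance, truth = make_scenario(
    dataset, truth, n_sets=30, frac_enriched=0.2, relevance_noise=1.0, seed=2
)
out = save_scenario("scenario_demo", dataset, collection, relevance, truth)

print(f"dataset: {dataset.n_genes} genes x {dataset.n_samples} samples "
      f"({len(truth.de_genes)} DE genes at |log2 FC| = 1)")
print(f"collection: {len(collection)} sets, "
      f"{len(truth.enriched_sets)} designated enriched: {sorted(truth.enriched_sets)}")
top = relevance.ordered_ids()[:3]
print("most relevant sets a priori:", {s: round(relevance[s], 2) for s in top})
print(f"written to {out}/ (matrix.tsv, sets.gmt, relevance.tsv, truth.json)")
# The enriched sets draw ~70% of their genes from the DE pool, so they should
# head both the relevance ranking and any decent enrichment ranking.
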