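"""Run the implemented enrichment method panel on one synthetic dataset.

Each method gets the same inputs (expression matrix + binary groups + gene
sets) and returns a ranking with one row per set: statistic, p-value,
BH-adjusted p-value, rank, and rank weight.
"""

from gsebench import get_method, make_scenario, run_method, simulate_expression

dataset, truth = simulate_expression(
    n_genes=1000, n_per_group=10, de_fraction=0.3, seed=1
)
collection, relevance, truth = make_scenario(dataset, truth, n_sets=30, seed=2)

print(f"{'method':<8}{'hypothesis':<16}{'top set':<8}{'min p':>8}{'frac p<.05':>12}")
for method in ["ora", "gsea", "safe", "padog", "camera", "samgs"]:
    params = {"n_perm": 200, "seed": 3} if get_method(method).needs_permutations else {}
    ranking = run_method(method, dataset, collection, **params)
    tab = ranking.table
    best = tab.loc[tab["rank"] == 1, "set_id"].iloc[0]
    frac = float((tab.p_value < 0.05).mean())
    print(f"{method:<8}{ranking.hypothesis.value:<16}{best:<8}"
          f"{tab.p_value.min():>8.4f}{frac:>12.2f}")
# Self-contained SAMGS flags far more sets than the competitive methods on
# the same data — the hallmark difference between the two null hypotheses.
print("truly enriched sets:", sorted(truth.enriched_sets))
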