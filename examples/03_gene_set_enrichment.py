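"""Hypergeometric over-representation of DE gene lists against a
user-supplied gene-set collection.

A synthetic collection is built so that one set coincides with truly
up-regulated genes; that set should dominate the ranking.
"""

from uuoseq import (
    GeneSetCollection,
    PipelineConfig,
    enrich_de_lists,
    normalize_and_filter,
    run_contrasts,
    simulate_scenario,
)
from uuoseq.diffexpr import de_gene_set

annotation, design, counts, truth, params = simulate_scenario("default", seed=1)
config = PipelineConfig(seed=1)
normalized, report = normalize_and_filter(counts, annotation, config)
de_tables = run_contrasts(normalized.subset_genes(report.surviving), design, config)

up = de_gene_set(de_tables["SO_vs_2D"], "up")
universe = sorted(de_tables["SO_vs_2D"]["gene_id"])
collection = GeneSetCollection(sets={
    "planted_up_module": set(list(up)[:30]),
    "random_module_a": set(universe[::7][:40]),
    "random_module_b": set(universe[3::11][:40]),
})

results = enrich_de_lists(de_tables, collection, direction="up", top=3)
print("top sets for the SO_vs_2D up-regulated list "
      "(k of K set members among n query genes, universe N):")
print(results["SO_vs_2D"].to_string(index=False))
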