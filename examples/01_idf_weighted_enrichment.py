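"""IDF-weighted gene set enrichment on a synthetic two-class experiment.

Builds a small pathway collection in which one gene is shared by every
pathway (a housekeeping-like gene) while the rest are pathway-specific,
plants differential expression in one pathway, and compares the
equal-weight enrichment ranking with the appearance-frequency (IDF)
weighted one.
"""

from pathweight import af, enrichment, fixtures

spec = fixtures.FixtureSpec(
    seed=0,
    n_genes=120,
    n_pathways=10,
    set_size_range=(8, 30),
    sharing_profile={1: 0.9, 10: 0.1},  # 10% of genes sit in every pathway
    n_samples_per_class=8,
    effect_size=1.5,
    de_fraction=0.8,
)
collection = fixtures.generate_collection(spec)
dataset = fixtures.generate_expression(spec, collection, ["P01"])

counts = af.appearance_counts(collection)
print("appearance-frequency histogram (count -> n_genes, proportion):")
for c, (n, p) in af.frequency_histogram(counts).items():
    print(f"  {c:>2}: {n:>4} genes  ({p:.2%})")

base = enrichment.enrichment_table(dataset, collection, n_perm=200, seed=1)
weighted = af.run_af_analysis(dataset, collection, n_perm=200, seed=1)

print("\npathway   base ES  base p   AF ES    AF p    AF rank")
merged = base.merge(weighted, on="pathway_id", suffixes=("_base", "_af"))
for _, r in merged.sort_values("rank_af").iterrows():
    print(f"{r.pathway_id:>7}  {r.score_base:+.3f}  {r.p_value_base:.3f}"
          f"   {r.score_af:+.3f}  {r.p_value_af:.3f}   {int(r.rank_af):>4}")

print("\nP01 carries the planted signal; IDF weighting discounts the")
print("ubiquitous genes every set shares, so its hits are the specific,")
print("truly shifted genes and it stays at the top of the ranking.")
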