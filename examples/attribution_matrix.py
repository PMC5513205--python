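"""Who is doing what: the carbohydrate-metabolism attribution matrix.

Builds the pathway-by-taxon matrix from the expressed-protein layer with the
cohort prevalence rules (enzymes in at least half of the subjects; genera
expressing a function in at least two subjects) and reports each pathway's
and phylum's share of total carbohydrate metabolism.  The demo cohort plants
glycolysis at 50%, butyrogenesis at 12%, propionogenesis at 3% and phylum
weights of 46/51/3% (Firmicutes/Bacteroidetes/Actinobacteria).
"""

from metaratio import build_attribution, default_pathways, pathway_shares, taxon_shares
from metaratio.simulate import attribution_demo_spec, default_taxonomy, generate_cohort

spec = attribution_demo_spec(seed=5, mp_depth=100_000)
records = generate_cohort(spec)
tree = default_taxonomy()

matrix = build_attribution(records, default_pathways(), tree,
                           n_subjects=spec.n_subjects)
print(f"Retained enzyme rows: {len(matrix.retained_kos)} "
      f"(detected in >= {spec.n_subjects // 2 + 1} of {spec.n_subjects} subjects)")
print(f"Retained genus columns: {matrix.retained_genera}\n")

print("Pathway shares of total carbohydrate metabolism (planted 50/12/3%):")
for name, share in sorted(pathway_shares(matrix).items(), key=lambda kv: -kv[1]):
    print(f"  {name:35s} {100 * share:5.1f}%")
print("\nPhylum shares (planted 46/51/3%; single-cohort estimates move a few")
print("points through between-subject compositional noise):")
for name, share in sorted(taxon_shares(matrix).items(), key=lambda kv: -kv[1]):
    print(f"  {name:35s} {100 * share:5.1f}%")
print("\nHeatmap-ready log10(mean abundance + CF) values: matrix.log_values")
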