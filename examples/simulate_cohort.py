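"""Generate a synthetic paired MG/MP gut cohort and inspect its structure.

The default cohort has 15 subjects with Firmicutes/Bacteroidetes-dominated
communities, 200,000 metagenome reads and 7,000 spectra per subject, and
extra between-subject dispersion on the expressed (MP) functional layer.
"""

from metaratio import default_cohort_spec, default_taxonomy, generate_cohort

spec = default_cohort_spec(seed=1, mg_depth=20_000, mp_depth=2_000)  # reduced depth
records = generate_cohort(spec)
tree = default_taxonomy()

print(records.head(8).to_string(index=False))
totals = records.groupby(["subject", "layer"])["weight"].sum().unstack()
print("\nUnits per subject and layer (each column equals the layer depth):")
print(totals.head().to_string())
phyla = records[records.layer == "MG"].assign(
    phylum=lambda d: d.taxon.map(lambda t: tree.ancestor_at_rank(t, "phylum"))
)
share = phyla.groupby("phylum")["weight"].sum() / phyla["weight"].sum()
print("\nCohort-pooled MG phylum shares (Firmicutes+Bacteroidetes dominate):")
print(share.round(3).to_string())
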