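"""Phylum-specific functions: the Firmicutes/Bacteroidetes contrast.

Splits the expressed-protein records into the two dominant phyla, renormalizes
each partition per subject, and tests each KO's per-subject log F/B ratio
against zero.  In the default community butyrate-biosynthesis enzymes are
enriched in Firmicutes (Faecalibacterium and relatives) and polysaccharide
degradation/transport in Bacteroidetes, so those KOs should dominate the
extremes of the ranking.
"""

from metaratio import ContrastSpec, partition_contrast, ratio_test
from metaratio.simulate import default_cohort_spec, default_taxonomy, generate_cohort

spec = default_cohort_spec(seed=4, mg_depth=20_000, mp_depth=4_000)
records = generate_cohort(spec)
tree = default_taxonomy()

firmicutes, bacteroidetes = partition_contrast(
    records, ("p__Firmicutes", "p__Bacteroidetes"), tree, level="KO", layer="MP"
)
result = ratio_test(firmicutes, bacteroidetes, ContrastSpec(mode="fb"))
table = result.stats

print("Lowest log F/B ratios (Bacteroidetes-specific activities):")
print(table.head(4)[["mean_log_ratio", "p_adjusted", "significant"]].to_string())
print("\nHighest log F/B ratios (Firmicutes-specific activities):")
print(table.tail(4)[["mean_log_ratio", "p_adjusted", "significant"]].to_string())
print("\nButyrogenesis KOs (K00626, K00074, K00248, K01034) should rank high;")
print("degradation/transport KOs (K01176, K01181, K10112, K21572) rank low.")
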