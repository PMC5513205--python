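# metaratio

Comparative analysis of paired shotgun **metagenome (MG)** and
**metaproteome (MP)** profiles of a microbial-community cohort — for
microbiome researchers asking not just *which functions a community could
perform* (gene potential, read counts) but *which it actually expresses*
(protein abundance, spectral counts), and which taxa carry each activity.

The package takes per-unit annotation records (one row per read or
peptide-spectrum match: subject, layer, taxonomic lineage, KO function,
count) and provides:

* ranked-taxonomy handling with **lowest-common-ancestor** resolution of
  ambiguous assignments;
* relative-abundance tables at any rank, KO, or KO×rank level, with
  mean-abundance filtering (> 0.01%) and per-subject subsampling;
* the core statistic — per-subject **log₁₀((a + CF)/(b + CF))** expression
  ratios with CF = 10⁻⁵, tested feature-wise against zero by one-sample
  t test with **Benjamini-Hochberg** FDR control (α = 0.05), for MP-vs-MG
  and for Firmicutes-vs-Bacteroidetes partition contrasts;
* inter-individual variability: pairwise **Bray-Curtis** dissimilarities
  contrasted between layers by Wilcoxon signed-rank, **CV-based**
  conserved/variable classification (CV < 60% / > 150%), and per-subject
  MG–MP **Spearman** correlations;
* a pathway×taxon **attribution matrix** ("who is doing what") with cohort
  prevalence rules and pathway/phylum shares;
* a **synthetic cohort generator** (Dirichlet-multinomial communities,
  planted log-ratio effects, layer-specific functional dispersion) so the
  whole pipeline is testable end to end with known ground truth.

See `docs/methods.md` for the model and all statistical conventions.

## Worked example

Plant a +1 / −1 log₁₀ MP/MG effect on two functions in a 15-subject cohort
at depth 10⁵ and recover them:

```python
from metaratio import ratio_test, relative_abundance
from metaratio.simulate import null_cohort

effects = {"K00000": 1.0, "K00001": -1.0}
records, tree = null_cohort(15, 100, 100_000, seed=2, effect_log_ratio=effects)
mp = relative_abundance(records, "KO", layer="MP")
mg = relative_abundance(records, "KO", layer="MG")
print(ratio_test(mp, mg).stats.iloc[[0, -1]][["mean_log_ratio", "p_adjusted"]])
```

```
         mean_log_ratio    p_adjusted
feature
K00001        -1.037609  6.292256e-17
K00000         0.960427  5.829458e-23
```

The recovered mean log ratios sit at −1.04 and +0.96 rather than exactly
∓1 because proportions are compositional: boosting one feature's MP share
renormalizes every other feature down by log₁₀(1.09) ≈ 0.04, and the
planted features absorb the same shift. Both are BH-significant at
essentially zero FDR; the remaining features cluster at the −0.04 closure
offset.

The `examples/` directory holds one short script per capability
(simulation, MP/MG ratios, variability, F/B contrast, attribution), each
printing the numbers it computes and what they mean. A thin CLI wraps the
two shell workflows:

```sh
metaratio simulate --seed 1 --out sim/
metaratio full --records sim/records.tsv --taxonomy sim/taxonomy.tsv \
    --subsample 100000 --seed 1 --out results/
```

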