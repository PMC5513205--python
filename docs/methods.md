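# Methods

`metaratio` implements a comparative analysis of paired shotgun metagenome
(MG) and metaproteome (MP) profiles of a microbial-community cohort, of the
kind used to ask which gut-microbiota functions are actually expressed
relative to their genetic potential. This note documents the statistical
procedures, the synthetic-data model the package is validated on, the
numerical choices, and the limits of what the validation shows.

## Quantitation model

The observation unit is one annotated item: a sequencing read (MG) or a
peptide-spectrum match (MP), each carrying a subject, a taxon (resolvable in
a ranked taxonomy), and a KEGG-ortholog (KO) function. The relative
abundance of a feature in a subject is its unit count divided by the
subject's total at the analysis level, so each subject's profile sums to 1
over the features detected at that level. Analysis levels are any
taxonomic rank, KO, or KO×rank combinations.

Two denominator conventions exist for the read layer, depending on whether
units with no annotation at the level count toward the total. The default
(`denominator="annotated"`) excludes them, making MG and MP scales
commensurable (the spectral layer is inherently detected-features-only) —
a requirement for the ratio analysis below. `denominator="all"` is
available for depth-of-annotation bookkeeping.

Before differential analysis, features are filtered on cohort-mean relative
abundance with a strict `> 1e-4` (0.01%) threshold. Filtering never
renormalizes the surviving rows. MG records can be equalized across
subjects by per-subject subsampling without replacement; operating on
aggregated weights this is a multivariate hypergeometric draw, which is
exactly uniform sampling of units without replacement.

## LCA taxonomic resolution

Ambiguous candidate-taxon sets are resolved to the lowest common ancestor:
the deepest node ancestral-or-equal to every candidate. The tree is
validated at construction (single root, acyclic parent chains, strictly
deepening rank labels along every path; ranks may be skipped). A batch
classifier adds a minimum-support post-filter — nodes supported by fewer
than `min_support` units are truncated to a configurable fallback rank or
dropped — because production LCA tools expose such knobs; the defaults
(`min_support=0`, no fallback) are plain set-LCA and make no claim of
matching any particular external tool's defaults.

## The log expression-ratio statistic

For each feature and subject, the contrast statistic is

    log10((a + CF) / (b + CF)),  CF = 1e-5,

where `a` and `b` are the feature's relative abundances under the two
conditions (MP vs MG, or one taxonomic partition vs another within a
layer). The additive correction factor keeps the ratio finite and
continuous when a feature is missing on one side and vanishes for
abundances far above CF; with both sides absent the ratio is exactly 0.
The global log ratio is the arithmetic mean over subjects. Log base 10 is
used throughout (matching CF's power-of-ten form) and is configurable.

Each feature's per-subject ratio vector is tested against zero with a
two-tailed one-sample t test; p-values are adjusted across all tested
features by Benjamini-Hochberg (statsmodels' textbook step-up), and
significance is called at FDR 0.05. Features enter the test only if their
mean abundance pooled over both conditions passes the 0.01% filter.
Degenerate vectors are handled explicitly: zero variance with zero mean is
no evidence (p = 1, t = 0); zero variance with nonzero mean leaves t
undefined, so the raw p is floored at the smallest positive double and the
feature flagged `degenerate` rather than reported as p = 0.

For phylum contrasts (e.g. Firmicutes vs Bacteroidetes per function), the
layer's records are restricted to each of two disjoint subtrees and each
partition is renormalized per subject before the same ratio machinery runs.

## Variability analyses

* **Bray-Curtis**: 1 − 2·Σmin(x,y)/(Σx+Σy) for every subject pair
  (lexicographic pair order so paired sets align); pairs involving an
  all-zero profile are undefined and reported missing. The two layers'
  dissimilarity sets are compared with a paired Wilcoxon signed-rank test,
  zero differences dropped, exact distribution up to 25 informative pairs
  and the continuity-corrected normal approximation beyond. The C(n,2)
  pairs are not independent observations; as in common practice the test is
  run on them anyway, and p-values should be read as descriptive.
* **Coefficient of variation**: per feature, sd/mean across subjects in
  percent, computed on the filtered table with zeros included (excluding
  non-detections would bias sparse features conserved). Sample (n−1) sd by
  default, configurable. Strict thresholds classify features as variable
  (CV > 150%), conserved (CV < 60%), or intermediate (boundaries
  inclusive).
* **Between-layer correlation**: per subject, Spearman rank correlation
  (average ranks on ties) between the subject's MG and MP profiles over the
  feature union, summarized as cohort mean ± sd.

## Attribution matrix

Expressed-protein records are folded into a pathway/enzyme × phylum/genus
matrix of cohort-mean relative abundances, with prevalence rules: an enzyme
keeps its own row only when detected (any taxon) in at least half the
subjects (⌈n/2⌉ — for 15 subjects, 8); a genus keeps its own column only
when it expresses some configured function in at least two subjects.
Pathway rows and phylum columns aggregate all members (including
non-retained ones), so totals are conserved, and a grand-total row and
column close the matrix. Display values are log10(mean + CF), keeping
empty cells finite; shares are always computed pre-log.

Abundances here are normalized per subject over the configured KO universe
(carbohydrate metabolism by default) rather than the whole layer, so
pathway and phylum shares are exact fractions of the matrix total. Share
ratios are unaffected by this choice. The shipped pathway list
(polysaccharide degradation → sugar transport → interconversion →
catabolism → glycolysis → acetogenesis/propionogenesis/butyrogenesis) is a
plausible reconstruction with representative KO ids; it is fully
user-overridable and not a curated KEGG export.

## Synthetic cohort model

Validation data come from a generative model, not from any deposited study
data:

1. Subject community compositions (genus proportions) are Dirichlet draws
   centred on cohort base proportions with concentration
   `taxon_dispersion`. Both layers observe the same community.
2. The joint (genus, KO) expectation is composition × per-genus function
   profile. MP expectations multiply in `10**effect` per feature and
   renormalize; closure therefore shifts non-effect features slightly, and
   recovery tests compare against the generator's post-normalization
   expectation, not the raw planted value.
3. Optionally each subject's per-layer functional expectation is itself
   Dirichlet-jittered; giving MP a finite concentration and MG none encodes
   the empirical observation that expressed-protein profiles are more
   plastic than gene-potential profiles.
4. Unit counts are multinomial at fixed per-layer depth, so subject totals
   equal the depth exactly; an optional fraction of units is masked
   `unannotated`.

Default conditions: 15 subjects; 13 genera under 5 phyla with ~45%
Firmicutes / ~49% Bacteroidetes base mass; depths of 200,000 MG units
(a standard post-subsampling read target) and 7,000 MP units (a typical
per-sample PSM yield); `taxon_dispersion = 10`, which at a 45% phylum
share gives roughly a ±30-point between-subject range, the spread reported
for healthy gut cohorts; MP functional concentration 50, MG none. The
uniform-community null harness (`null_cohort`) uses concentration 500 so
that 100 equal features each have ~45% between-subject CV and every subject
carries every feature — the shared-core regime in which calibration and
power simulations are meaningful.

What the generator does **not** model: sequence/spectrum error processes,
annotation bias between layers, genome-size and gene-copy effects,
database incompleteness, or any covariance structure between taxa beyond
compositional closure. Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated under the stated model —
not that real MG/MP discrepancies of a given magnitude will be detected.

## Validation conditions and numerical choices

The cohort-scale test battery uses 50 replicates of 15-subject cohorts with
100 features at depth 1e5 (type-I error and ±1.0-effect recovery), 60
features at depth 2e4 for the directional Bray-Curtis contrast, and a
depth-1e5 attribution cohort with planted pathway weights 0.50/0.12/0.03
and phylum weights 0.46/0.51/0.03. Tolerances are statistical: binomial
3·SE for error rates, hypergeometric 3·SE for subsampling retention, and
3·SE of the cohort-mean estimate for phylum-share recovery (between-subject
compositional noise dominates that quantity at n = 15).

Other numerics: probability vectors validate to 1 within 1e-9; abundance
column sums are asserted to 1 within 1e-9; BH equivalence to the step-up
definition is asserted to 1e-12; all simulation is driven by numpy's PCG64
generator seeded explicitly, and identical spec + seed reproduces record
streams byte for byte.

## Known limitations

* CF, filter threshold, and CV thresholds are conventions, not estimates;
  results near those boundaries are sensitive to them.
* The t test on per-subject log ratios assumes approximate normality of the
  ratio noise; at very low depths (spectral counts of a few units) this is
  rough, and the degenerate-case handling becomes load-bearing.
* Compositional closure means a strong planted (or real) effect induces
  small opposite shifts in everything else; at high depth these are
  statistically significant. Interpretation should weigh effect sizes.
* The Wilcoxon contrast treats subject pairs as independent; they are not.
* LCA defaults do not reproduce any specific external annotation tool.
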