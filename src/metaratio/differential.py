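"""Per-subject log abundance-ratio statistics with FDR control.

The core statistic of the pipeline: for each feature, compute the per-subject
log10 ratio of two paired abundance profiles — expressed protein vs gene
potential (MP vs MG), or one taxonomic partition vs another within a layer
(e.g. Firmicutes vs Bacteroidetes per function) — with a small correction
factor CF added to numerator and denominator so that features missing from
one layer remain comparable.  The per-feature log-ratio vectors are tested
against zero with a one-sample two-tailed t test, and p-values are adjusted
across features by the Benjamini-Hochberg step-up procedure.

The global log ratio of a feature is the arithmetic mean of its per-subject
log ratios; a positive MP/MG value means the feature is expressed above its
genetic potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceTable, relative_abundance
from .taxonomy import TaxonomyTree

__all__ = [
    "ContrastSpec",
    "RatioTestTable",
    "AlignmentError",
    "log_ratio",
    "bh_adjust",
    "ratio_test",
    "partition_contrast",
    "write_results",
]

#: Correction factor: pseudo-abundance added to both sides of the ratio.
DEFAULT_CF = 1e-5


class AlignmentError(ValueError):
    """The two tables do not cover the same subjects."""


@dataclass(frozen=True)
class ContrastSpec:
    """Parameters of a ratio contrast.

    mode
        ``"mp-mg"`` (layer contrast) or ``"fb"`` (taxon-partition contrast);
        informational — the arithmetic is identical.
    cf
        Correction factor added to numerator and denominator (default 1e-5).
    alpha
        FDR level for the significance call (default 0.05).
    log_base
        Base of the logarithm (default 10, matching the power-of-ten CF).
    filter_threshold
        Features enter the test only if their mean abundance over the union
        of both conditions strictly exceeds this (default 0.01%); ``None``
        disables pre-filtering.
    """

    mode: str = "mp-mg"
    cf: float = DEFAULT_CF
    alpha: float = 0.05
    log_base: float = 10.0
    filter_threshold: float | None = 1e-4

    def __post_init__(self) -> None:
        if self.cf <= 0:
            raise ValueError("cf must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")


@dataclass
class RatioTestTable:
    """Results of one contrast.

    ``stats`` has one row per tested feature with columns ``mean_log_ratio,
    t_statistic, p_raw, p_adjusted, significant, degenerate, n_subjects``,
    sorted by mean_log_ratio.  ``log_ratios`` holds the underlying
    per-subject log-ratio matrix (features x subjects).
    """

    stats: pd.DataFrame
    log_ratios: pd.DataFrame
    spec: ContrastSpec


def log_ratio(a, b, cf: float = DEFAULT_CF, log_base: float = 10.0):
    """log((a + cf) / (b + cf)); scalar or elementwise on arrays.

    The additive correction keeps the ratio finite and continuous for all
    non-negative abundances and vanishes asymptotically for abundances far
    above cf.  Both inputs zero gives exactly 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if cf <= 0:
        raise ValueError("cf must be > 0")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    out = (np.log(a + cf) - np.log(b + cf)) / np.log(log_base)
    return out.item() if out.ndim == 0 else out


def bh_adjust(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=alpha, method="fdr_bh")[1]


def ratio_test(
    table_a: AbundanceTable,
    table_b: AbundanceTable,
    spec: ContrastSpec | None = None,
) -> RatioTestTable:
    """Test per-feature log(A/B) ratios for deviation from zero.

    Subjects must match between the tables; the feature set is the union,
    with absences treated as zero abundance.  Features pass the mean
    abundance pre-filter computed over both conditions pooled.  Degenerate
    features (zero-variance ratio vectors) are flagged: an all-zero vector
    is evidence of nothing (p = 1), a constant nonzero vector is maximal
    evidence but t is undefined, so p is floored at machine precision
    rather than reported as 0.
    """
    spec = spec or ContrastSpec()
    subj_a, subj_b = set(table_a.subjects), set(table_b.subjects)
    if subj_a != subj_b:
        raise AlignmentError(
            f"subject sets differ: {sorted(subj_a ^ subj_b)} not shared"
        )
    subjects = sorted(subj_a)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    features = sorted(set(table_a.features) | set(table_b.features))
    a = table_a.data.reindex(index=features, columns=subjects, fill_value=0.0)
    b = table_b.data.reindex(index=features, columns=subjects, fill_value=0.0)

    if spec.filter_threshold is not None:
        pooled_mean = (a.mean(axis=1) + b.mean(axis=1)) / 2.0
        keep = pooled_mean > spec.filter_threshold
        a, b = a.loc[keep], b.loc[keep]

    ratios = pd.DataFrame(
        log_ratio(a.values, b.values, cf=spec.cf, log_base=spec.log_base),
        index=a.index, columns=subjects,
    )
    mean = ratios.mean(axis=1)
    sd = ratios.std(axis=1, ddof=1)
    n = len(subjects)

    t_stat = np.full(len(ratios), np.nan)
    p_raw = np.ones(len(ratios))
    degenerate = (sd.values == 0)
    regular = ~degenerate
    if regular.any():
        res = stats.ttest_1samp(ratios.values[regular], popmean=0.0, axis=1)
        t_stat[regular] = res.statistic
        p_raw[regular] = res.pvalue
    # degenerate: zero-mean -> no evidence; nonzero-mean -> precision floor
    zero_mean = degenerate & (mean.values == 0)
    t_stat[zero_mean] = 0.0
    p_raw[zero_mean] = 1.0
    nz = degenerate & (mean.values != 0)
    t_stat[nz] = np.sign(mean.values[nz]) * np.inf
    p_raw[nz] = np.finfo(float).tiny

    p_adj = bh_adjust(p_raw, alpha=spec.alpha) if len(p_raw) else p_raw
    out = pd.DataFrame(
        {
            "mean_log_ratio": mean,
            "t_statistic": t_stat,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significant": p_adj <= spec.alpha,
            "degenerate": degenerate,
            "n_subjects": n,
        },
        index=ratios.index,
    ).sort_values("mean_log_ratio")
    out.index.name = "feature"
    return RatioTestTable(stats=out, log_ratios=ratios, spec=spec)


def partition_contrast(
    records: pd.DataFrame,
    partition: tuple[str, str],
    tree: TaxonomyTree,
    level: str = "KO",
    layer: str | None = None,
) -> tuple[AbundanceTable, AbundanceTable]:
    """Split one layer's records by two disjoint taxonomic subtrees.

    Returns KO-level (or other-level) abundance tables for the records under
    each partition node, each renormalized *within its partition* per
    subject, and reindexed to the union of subjects (a subject absent from
    one partition gets an all-zero column).  Typical use: Firmicutes vs
    Bacteroidetes contributions per function.
    """
    node_a, node_b = partition
    for node in partition:
        if node not in tree:
            raise ValueError(f"partition node {node!r} not in taxonomy")
    if tree.is_ancestor(node_a, node_b) or tree.is_ancestor(node_b, node_a):
        raise ValueError(f"partition subtrees overlap: {node_a!r}, {node_b!r}")
    if layer is not None:
        records = records[records["layer"] == layer]
    subjects = sorted(records["subject"].unique())
    tables = []
    for node in partition:
        members = {t for t in records["taxon"].unique()
                   if t in tree and tree.is_ancestor(node, t)}
        sub = records[records["taxon"].isin(members)]
        table = relative_abundance(sub, level, tree=tree)
        data = table.data.reindex(columns=subjects, fill_value=0.0)
        tables.append(AbundanceTable(data=data, layer=table.layer, level=table.level))
    return tables[0], tables[1]


def write_results(result: RatioTestTable, path) -> None:
    """Results TSV: feature, mean_log_ratio, t, p_raw, p_adjusted, significant."""
    result.stats.to_csv(path, sep="\t", lineterminator="\n")
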