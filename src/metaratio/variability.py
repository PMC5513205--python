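"""Inter-individual variability analyses.

Three complementary views of how much community profiles differ between
subjects and between omic layers:

* pairwise Bray-Curtis dissimilarities within a layer, and a paired Wilcoxon
  signed-rank contrast of the two layers' dissimilarity sets;
* per-feature coefficient of variation across subjects, classified as
  variable (CV > 150%), conserved (CV < 60%), or intermediate;
* per-subject Spearman rank correlation between a subject's MG and MP
  profiles, summarized as cohort mean +/- sd.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis

from .abundance import AbundanceTable

__all__ = [
    "DissimilarityContrast",
    "SpearmanSummary",
    "bray_curtis",
    "compare_dissimilarity",
    "cv_classify",
    "spearman_between_layers",
]

logger = logging.getLogger(__name__)

CV_HIGH = 150.0  # percent; above = variable
CV_LOW = 60.0    # percent; below = conserved

#: Pair count above which the signed-rank test switches from the exact
#: distribution to the normal approximation with continuity correction.
_EXACT_LIMIT = 25


@dataclass
class DissimilarityContrast:
    """Paired comparison of two Bray-Curtis dissimilarity sets."""

    pairs: list[tuple[str, str]]
    bc1: np.ndarray
    bc2: np.ndarray
    wilcoxon_statistic: float
    p_two_tailed: float


@dataclass
class SpearmanSummary:
    """Per-subject between-layer rank correlations with cohort summary."""

    per_subject: pd.Series
    mean: float
    sd: float


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity for every subject pair.

    Returns a DataFrame with columns ``subject_a, subject_b, dissimilarity``,
    pairs ordered lexicographically so that two tables over the same cohort
    align row-for-row.  1 - 2*sum(min(x, y)) / (sum(x) + sum(y)); 0 for
    identical profiles, 1 for disjoint supports.  Pairs involving an
    all-zero subject are undefined and reported as NaN.
    """
    subjects = sorted(table.subjects)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    cols = {s: table.data[s].to_numpy() for s in subjects}
    empty = {s for s in subjects if cols[s].sum() == 0}
    if empty:
        logger.warning("all-zero subject columns, pairs undefined: %s", sorted(empty))
    rows = []
    for sa, sb in itertools.combinations(subjects, 2):
        if sa in empty or sb in empty:
            d = np.nan
        else:
            d = float(braycurtis(cols[sa], cols[sb]))
        rows.append((sa, sb, d))
    return pd.DataFrame(rows, columns=["subject_a", "subject_b", "dissimilarity"])


def compare_dissimilarity(
    bc1: pd.DataFrame, bc2: pd.DataFrame
) -> DissimilarityContrast:
    """Wilcoxon signed-rank test between two paired dissimilarity sets.

    The two inputs must cover identical subject pairs in identical order
    (as produced by :func:`bray_curtis`).  Zero differences are dropped
    (classic signed-rank handling); with more than 25 informative pairs the
    normal approximation with continuity correction is used, otherwise the
    exact distribution.  All differences zero gives p = 1.
    """
    pairs1 = list(zip(bc1["subject_a"], bc1["subject_b"]))
    pairs2 = list(zip(bc2["subject_a"], bc2["subject_b"]))
    if pairs1 != pairs2:
        raise ValueError("dissimilarity sets cover different subject pairs")
    x = bc1["dissimilarity"].to_numpy()
    y = bc2["dissimilarity"].to_numpy()
    ok = ~(np.isnan(x) | np.isnan(y))
    d = x[ok] - y[ok]
    d = d[d != 0]
    if d.size == 0:
        return DissimilarityContrast(pairs1, x, y, np.nan, 1.0)
    method = "approx" if d.size > _EXACT_LIMIT else "exact"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=True, method=method,
        alternative="two-sided",
    )
    return DissimilarityContrast(
        pairs1, x, y, float(res.statistic), float(res.pvalue)
    )


def cv_classify(
    table: AbundanceTable,
    high: float = CV_HIGH,
    low: float = CV_LOW,
    ddof: int = 1,
) -> pd.DataFrame:
    """Classify features by their across-subject coefficient of variation.

    CV = sd / mean (sample sd by default), expressed in percent, with zeros
    from undetected-in-some-subjects features included — excluding them
    would understate the variability of sparse features.  Strict thresholds:
    cv > ``high`` is "variable", cv < ``low`` is "conserved", anything else
    (boundaries included) "intermediate".  All-zero features are skipped.
    """
    if not low <= high:
        raise ValueError("low threshold must not exceed high threshold")
    mean = table.data.mean(axis=1)
    sd = table.data.std(axis=1, ddof=ddof)
    zero = mean == 0
    if zero.any():
        logger.warning("skipping %d zero-mean features", int(zero.sum()))
    cv = (sd[~zero] / mean[~zero]) * 100.0
    klass = pd.Series(
        np.select([cv > high, cv < low], ["variable", "conserved"], "intermediate"),
        index=cv.index,
    )
    out = pd.DataFrame(
        {"mean_abundance": mean[~zero], "cv_percent": cv, "klass": klass}
    )
    out.index.name = "feature"
    return out


def spearman_between_layers(
    table_mg: AbundanceTable, table_mp: AbundanceTable
) -> SpearmanSummary:
    """Per-subject Spearman correlation between MG and MP feature profiles.

    Features are the union of both tables (absences = 0); ties receive
    average ranks.  Subjects with fewer than 3 features, or with a constant
    profile in either layer (correlation undefined), are excluded with a
    log entry.
    """
    subjects = sorted(set(table_mg.subjects))
    if set(table_mp.subjects) != set(subjects):
        raise ValueError("subject sets differ between layers")
    features = sorted(set(table_mg.features) | set(table_mp.features))
    if len(features) < 3:
        raise ValueError("need at least 3 features")
    mg = table_mg.data.reindex(index=features, columns=subjects, fill_value=0.0)
    mp = table_mp.data.reindex(index=features, columns=subjects, fill_value=0.0)
    rhos = {}
    for s in subjects:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho = stats.spearmanr(mg[s], mp[s]).statistic
        if np.isnan(rho):
            logger.warning("subject %s: Spearman rho undefined, excluded", s)
            continue
        rhos[s] = float(rho)
    per_subject = pd.Series(rhos, name="spearman_rho")
    return SpearmanSummary(
        per_subject=per_subject,
        mean=float(per_subject.mean()),
        sd=float(per_subject.std(ddof=1)),
    )
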