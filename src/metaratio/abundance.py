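"""Relative-abundance tables from annotation records.

A record stream (one weighted row per observed subject/layer/genus/KO cell)
is aggregated to any taxonomic rank, to KO level, or to KO x rank
combinations, and divided by the per-subject total so that each subject
column sums to 1 over the features detected at that level.  A mean-abundance
filter (default threshold 0.01%) and deterministic per-subject subsampling
without replacement round out the stage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .taxonomy import RANK_ORDER, UNASSIGNED, TaxonomyTree

__all__ = [
    "AbundanceTable",
    "DepthError",
    "subsample_units",
    "relative_abundance",
    "filter_features",
    "read_table",
    "write_table",
]

logger = logging.getLogger(__name__)

#: Fraction-scale default for the ">0.01% mean relative abundance" filter.
DEFAULT_FILTER_THRESHOLD = 1e-4

_KO_CROSS = re.compile(r"^KO[x×](\w+)$")


class DepthError(ValueError):
    """Requested subsample exceeds the units available for a subject."""


@dataclass
class AbundanceTable:
    """Features x subjects relative abundances for one layer and one level.

    ``data`` is a DataFrame indexed by feature id with one column per
    subject.  Before filtering, each column sums to 1 over detected
    features; filtering removes rows without renormalizing.
    """

    data: pd.DataFrame
    layer: str
    level: str
    filtered: bool = False

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.data.index.duplicated().any():
            raise ValueError("feature ids must be unique")

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def subjects(self) -> list[str]:
        return list(self.data.columns)

    def mean_abundance(self) -> pd.Series:
        return self.data.mean(axis=1)


def subsample_units(
    records: pd.DataFrame,
    n: int,
    seed: int,
    layers: tuple[str, ...] = ("MG",),
) -> pd.DataFrame:
    """Uniformly subsample ``n`` units without replacement per subject.

    Applied independently to every subject in each of ``layers`` (by default
    only the read layer, matching the usual practice of equalizing
    sequencing depth while leaving spectral counts untouched); records in
    other layers pass through unchanged.  Operating on the aggregated weight
    vector, sampling n of N units uniformly without replacement is a
    multivariate hypergeometric draw over the per-cell weights.
    Deterministic given ``seed``; subjects are processed in sorted order.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    keep_mask = records["layer"].isin(layers)
    passthrough = records[~keep_mask]
    sampled_parts = []
    grouped = records[keep_mask].groupby(["subject", "layer"], sort=True)
    for (subject, layer), grp in grouped:
        weights = grp["weight"].to_numpy()
        total = int(weights.sum())
        if n > total:
            raise DepthError(
                f"subject {subject} ({layer}) has {total} units, cannot sample {n}"
            )
        new_w = rng.multivariate_hypergeometric(weights, n)
        kept = grp.loc[new_w > 0].copy()
        kept["weight"] = new_w[new_w > 0]
        sampled_parts.append(kept)
    parts = [p for p in sampled_parts + [passthrough] if not p.empty]
    if not parts:
        return records.iloc[0:0]
    out = pd.concat(parts)
    return out.sort_index(kind="stable").reset_index(drop=True)


def _feature_keys(
    records: pd.DataFrame, level: str, tree: TaxonomyTree | None
) -> pd.Series:
    """Map each record to its feature id at ``level``; NaN = excluded."""
    cross = _KO_CROSS.match(level)
    if level == "KO":
        keys = records["function"].where(records["function"] != "unannotated")
    elif level in RANK_ORDER:
        if tree is None:
            raise ValueError(f"a taxonomy tree is required for level {level!r}")
        mapping = {
            t: tree.ancestor_at_rank(t, level)
            for t in records["taxon"].unique()
            if t in tree
        }
        keys = records["taxon"].map(lambda t: mapping.get(t))
    elif cross:
        rank = cross.group(1)
        ko = _feature_keys(records, "KO", tree)
        tax = _feature_keys(records, rank, tree)
        keys = ko.str.cat(tax, sep="|")
    else:
        raise ValueError(f"unknown level: {level!r}")
    return keys


def relative_abundance(
    records: pd.DataFrame,
    level: str,
    tree: TaxonomyTree | None = None,
    layer: str | None = None,
    denominator: str = "annotated",
) -> AbundanceTable:
    """Aggregate records to ``level`` and convert counts to proportions.

    ``level`` is a rank name (``"genus"``, ``"phylum"``, ...), ``"KO"``, or
    ``"KOxgenus"``-style combinations.  Records unresolvable at the level
    (taxa above the requested rank, unassigned taxa, unannotated functions)
    are excluded from the numerator; with ``denominator="annotated"`` (the
    default) they are excluded from the denominator too, so columns sum
    to 1 over detected features.  ``denominator="all"`` divides by each
    subject's total unit count instead.
    """
    if layer is not None:
        records = records[records["layer"] == layer]
    else:
        found = records["layer"].unique()
        if len(found) > 1:
            raise ValueError(
                f"records contain multiple layers {sorted(found)}; pass layer="
            )
        layer = found[0] if len(found) else "NA"
    if denominator not in ("annotated", "all"):
        raise ValueError("denominator must be 'annotated' or 'all'")

    keys = _feature_keys(records, level, tree)
    keys = keys.where(keys != UNASSIGNED)
    usable = records.assign(feature=keys).dropna(subset=["feature"])
    counts = usable.pivot_table(
        index="feature", columns="subject", values="weight",
        aggfunc="sum", fill_value=0,
    )
    if denominator == "annotated":
        totals = counts.sum(axis=0)
    else:
        totals = records.groupby("subject")["weight"].sum().reindex(counts.columns)
    empty = [s for s in records["subject"].unique() if s not in counts.columns]
    if empty:
        logger.warning("subjects with no records at level %s: %s", level, empty)
    data = counts / totals
    data = data.sort_index().sort_index(axis=1)
    data.index.name = "feature"
    data.columns.name = None
    return AbundanceTable(data=data.astype(float), layer=layer, level=level)


def filter_features(
    table: AbundanceTable, threshold: float = DEFAULT_FILTER_THRESHOLD
) -> AbundanceTable:
    """Keep features whose cohort-mean abundance strictly exceeds ``threshold``.

    Columns are deliberately NOT renormalized afterwards: downstream ratio
    statistics compare like-for-like proportions of the full community.
    """
    if table.data.empty:
        raise ValueError("cannot filter an empty table")
    keep = table.mean_abundance() > threshold
    return replace(table, data=table.data.loc[keep], filtered=True)


# ---------------------------------------------------------------------------
# TSV round-trip: '#'-prefixed metadata header then feature x subject matrix.


def write_table(table: AbundanceTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# layer: {table.layer}\n")
        fh.write(f"# level: {table.level}\n")
        fh.write(f"# filtered: {str(table.filtered).lower()}\n")
        table.data.to_csv(fh, sep="\t", lineterminator="\n")


def read_table(path) -> AbundanceTable:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition(": ")
            meta[key] = value
            pos = fh.tell()
        data = pd.read_csv(fh, sep="\t", index_col="feature")
    return AbundanceTable(
        data=data,
        layer=meta.get("layer", "NA"),
        level=meta.get("level", "NA"),
        filtered=meta.get("filtered") == "true",
    )
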