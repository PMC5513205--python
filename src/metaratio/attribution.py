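"""Taxon-by-function attribution matrices ("who is doing what").

The expressed-protein records of a cohort are folded into a matrix of
carbohydrate-metabolism pathways/enzymes (rows) by phyla/genera (columns),
holding the cohort-mean relative abundance of each function-taxon
combination.  Prevalence rules keep the display honest at cohort scale:

* an enzyme (KO) appears as its own row only if it was detected — in any
  taxon — in at least half of the subjects (ceiling for odd cohorts);
* a genus appears as its own column only if it expresses at least one
  configured function in at least two subjects;
* pathway total rows and phylum total columns aggregate *all* members,
  retained or not, so totals are conserved;
* a grand-total row ("Carbohydrate metabolism") and column ("Microbiota")
  close the matrix.

Shares of the grand total (per pathway or per phylum) are computed on the
pre-log abundances; the log10(mean + cf) transform is only for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import relative_abundance
from .taxonomy import TaxonomyTree

__all__ = [
    "PathwayConfig",
    "FunctionTaxonMatrix",
    "default_pathways",
    "build_attribution",
    "pathway_shares",
    "taxon_shares",
    "write_matrix",
]

TOTAL_ROW = "Carbohydrate metabolism"
TOTAL_COL = "Microbiota"


@dataclass(frozen=True)
class PathwayConfig:
    """Ordered pathway -> member-KO mapping; each KO belongs to one pathway."""

    pathways: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValueError("empty pathway config")
        names = [p for p, _ in self.pathways]
        if len(set(names)) != len(names):
            raise ValueError("pathway names must be unique")
        all_kos = [k for _, kos in self.pathways for k in kos]
        if len(set(all_kos)) != len(all_kos):
            raise ValueError("a KO may belong to exactly one pathway")

    @property
    def kos(self) -> list[str]:
        return [k for _, kos in self.pathways for k in kos]

    @property
    def ko_to_pathway(self) -> dict[str, str]:
        return {k: p for p, kos in self.pathways for k in kos}

    @classmethod
    def from_items(cls, items) -> "PathwayConfig":
        return cls(tuple((name, tuple(kos)) for name, kos in items))

    def to_file(self, path) -> None:
        """One line per pathway: name<TAB>comma-joined KO list."""
        with open(path, "w", encoding="utf-8") as fh:
            for name, kos in self.pathways:
                fh.write(f"{name}\t{','.join(kos)}\n")

    @classmethod
    def from_file(cls, path) -> "PathwayConfig":
        items = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, _, kos = line.partition("\t")
                items.append((name, [k for k in kos.split(",") if k]))
        return cls.from_items(items)


def default_pathways() -> PathwayConfig:
    """Carbohydrate-metabolism pathway list, polysaccharide uptake to SCFAs."""
    from .simulate import DEFAULT_PATHWAY_WEIGHTS

    return PathwayConfig.from_items(
        [(name, kos) for name, kos, _ in DEFAULT_PATHWAY_WEIGHTS]
    )


@dataclass
class FunctionTaxonMatrix:
    """Pathway/KO x phylum/genus cohort-mean abundance matrix.

    ``values`` is the assembled display matrix on the pre-log abundance
    scale (pathway and grand-total rows, phylum and grand-total columns,
    retained KO rows and genus columns).  ``cell_means`` keeps the full
    unfiltered KO x genus grid the totals were computed from;
    ``prevalence`` counts, per KO x genus cell, the subjects with nonzero
    abundance.
    """

    values: pd.DataFrame
    cell_means: pd.DataFrame
    prevalence: pd.DataFrame
    retained_kos: list[str]
    retained_genera: list[str]
    pathway_rows: list[str]
    phylum_cols: list[str]
    config: PathwayConfig
    n_subjects: int
    cf: float = 1e-5

    @property
    def log_values(self) -> pd.DataFrame:
        """Display scale: log10(mean abundance + cf); empty cells are finite."""
        return np.log10(self.values + self.cf)


def build_attribution(
    records: pd.DataFrame,
    config: PathwayConfig,
    tree: TaxonomyTree,
    n_subjects: int | None = None,
    layer: str = "MP",
    cf: float = 1e-5,
) -> FunctionTaxonMatrix:
    """Fold one layer's records into a prevalence-filtered attribution matrix.

    Abundances are per-subject proportions over the configured KO universe
    (so the matrix describes shares *of* the pathway collection, and the
    grand total of cohort means is 1 when every subject expressed at least
    one configured KO).  Subjects absent from the layer count as zeros in
    the cohort mean.
    """
    recs = records[records["layer"] == layer]
    recs = recs[recs["function"].isin(config.kos)]
    if recs.empty:
        raise ValueError(f"no records matching the pathway config in layer {layer}")
    if n_subjects is None:
        n_subjects = recs["subject"].nunique()

    table = relative_abundance(recs, "KO×genus", tree=tree, layer=layer)
    # split "KO|genus" feature keys back into a (function, genus) grid
    split = table.data.index.str.split("|", expand=True)
    data = table.data.copy()
    data.index = pd.MultiIndex.from_arrays(
        [split.get_level_values(0), split.get_level_values(1)],
        names=["function", "genus"],
    )
    cell_means = (
        data.sum(axis=1).div(n_subjects).unstack("genus", fill_value=0.0)
    )
    prevalence = (data > 0).sum(axis=1).unstack("genus", fill_value=0)
    cell_means = cell_means.reindex(index=config.kos, fill_value=0.0)
    prevalence = prevalence.reindex(index=config.kos, fill_value=0)

    # -- prevalence rules ----------------------------------------------
    min_subjects = math.ceil(n_subjects / 2)
    # a KO counts as detected in a subject if any taxon carried it
    per_subject_any = (
        (data > 0).groupby(level="function").any().reindex(config.kos, fill_value=False)
    )
    ko_detected_subjects = per_subject_any.sum(axis=1)
    retained_kos = [
        k for k in config.kos if ko_detected_subjects.get(k, 0) >= min_subjects
    ]
    genus_max_prev = prevalence.max(axis=0)
    retained_genera = sorted(genus_max_prev.index[genus_max_prev >= 2])

    phylum_of = {
        g: (tree.ancestor_at_rank(g, "phylum") or "p__unclassified")
        for g in cell_means.columns
    }
    phyla = sorted(set(phylum_of.values()))

    # -- assemble display matrix ---------------------------------------
    columns = [TOTAL_COL] + [
        c for ph in phyla
        for c in ([ph] + [g for g in retained_genera if phylum_of[g] == ph])
    ]
    col_vectors = {TOTAL_COL: cell_means.sum(axis=1)}
    for ph in phyla:
        members = [g for g in cell_means.columns if phylum_of[g] == ph]
        col_vectors[ph] = cell_means[members].sum(axis=1)
    for g in retained_genera:
        col_vectors[g] = cell_means[g]

    rows = [TOTAL_ROW]
    row_groups: dict[str, list[str]] = {TOTAL_ROW: config.kos}
    pathway_rows = []
    for name, kos in config.pathways:
        rows.append(name)
        pathway_rows.append(name)
        row_groups[name] = list(kos)
        for k in kos:
            if k in retained_kos:
                rows.append(k)
                row_groups[k] = [k]

    values = pd.DataFrame(
        {
            col: [col_vectors[col].loc[row_groups[r]].sum() for r in rows]
            for col in columns
        },
        index=rows,
    )
    values.index.name = "feature"
    return FunctionTaxonMatrix(
        values=values,
        cell_means=cell_means,
        prevalence=prevalence,
        retained_kos=retained_kos,
        retained_genera=retained_genera,
        pathway_rows=pathway_rows,
        phylum_cols=phyla,
        config=config,
        n_subjects=n_subjects,
        cf=cf,
    )


def pathway_shares(matrix: FunctionTaxonMatrix) -> dict[str, float]:
    """Each pathway's fraction of the grand-total abundance (sums to 1)."""
    grand = matrix.values.loc[TOTAL_ROW, TOTAL_COL]
    if grand == 0:
        raise ValueError("zero grand total; shares undefined")
    return {
        p: float(matrix.values.loc[p, TOTAL_COL] / grand)
        for p in matrix.pathway_rows
    }


def taxon_shares(matrix: FunctionTaxonMatrix) -> dict[str, float]:
    """Each phylum's fraction of the grand-total abundance (sums to 1)."""
    grand = matrix.values.loc[TOTAL_ROW, TOTAL_COL]
    if grand == 0:
        raise ValueError("zero grand total; shares undefined")
    return {
        ph: float(matrix.values.loc[TOTAL_ROW, ph] / grand)
        for ph in matrix.phylum_cols
    }


def write_matrix(matrix: FunctionTaxonMatrix, path, log_scale: bool = True) -> None:
    """Write the display matrix (log scale by default) plus a prevalence sidecar."""
    out = matrix.log_values if log_scale else matrix.values
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# layer-mean attribution matrix, n_subjects: {matrix.n_subjects}\n")
        fh.write(f"# scale: {'log10(mean+cf)' if log_scale else 'mean'}\n")
        out.to_csv(fh, sep="\t", lineterminator="\n")
    sidecar = str(path) + ".prevalence"
    matrix.prevalence.to_csv(sidecar, sep="\t", lineterminator="\n")
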