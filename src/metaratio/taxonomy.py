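"""Ranked taxonomy trees and lowest-common-ancestor (LCA) resolution.

Shotgun annotation tools assign each read or peptide-spectrum match a set of
candidate taxa (all database hits above a score cutoff).  The classical way to
turn that ambiguous set into a single assignment is the lowest common
ancestor: the deepest taxonomy node that is an ancestor-or-self of every
candidate.  This module provides the tree container, validated construction
from an edge list, the LCA query itself, and a batch classifier with an
optional minimum-support post-filter.

Taxon identifiers are opaque strings; by convention they carry a rank prefix
(``p__Firmicutes``, ``g__Faecalibacterium``) and lineages serialize as
semicolon-joined root-to-node paths.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RANK_ORDER",
    "UNASSIGNED",
    "TaxonomyError",
    "TaxonomyTree",
    "LcaConfig",
    "build_taxonomy",
    "lca",
    "classify_units",
    "read_taxonomy",
    "write_taxonomy",
]

#: Ordered rank labels from shallowest to deepest.  Ranks may be absent on a
#: given lineage (e.g. a phylum directly under the root), but the labels that
#: do occur along any root-to-leaf path must be strictly deepening.
RANK_ORDER = ("root", "superkingdom", "phylum", "class", "order", "family", "genus")

_RANK_INDEX = {r: i for i, r in enumerate(RANK_ORDER)}

#: Sentinel returned for unresolvable assignments (empty candidate sets, or
#: support-filtered nodes with no fallback).
UNASSIGNED = "unassigned"


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy: cycles, conflicting parents, bad ranks."""


@dataclass(frozen=True)
class LcaConfig:
    """Post-processing knobs for batch LCA classification.

    min_support
        Number of units resolving to a node required to report it.  Nodes
        with fewer supporting units are truncated to ``fallback_rank`` (the
        nearest ancestor at that rank) or, with ``fallback_rank=None``,
        reported as unassigned.
    fallback_rank
        Rank to truncate under-supported assignments to, or ``None``.
    """

    min_support: int = 0
    fallback_rank: str | None = None

    def __post_init__(self) -> None:
        if self.min_support < 0:
            raise ValueError("min_support must be >= 0")
        if self.fallback_rank is not None and self.fallback_rank not in _RANK_INDEX:
            raise ValueError(f"unknown fallback_rank: {self.fallback_rank!r}")


@dataclass(frozen=True)
class TaxonomyTree:
    """A ranked, rooted taxonomy.

    ``parent`` maps every node to its parent; the root maps to itself.
    Constructed via :func:`build_taxonomy`, which validates the invariants
    (single root, acyclic chains, strictly deepening ranks).
    """

    root: str
    parent: Mapping[str, str]
    rank: Mapping[str, str]
    name: Mapping[str, str]
    _lineages: dict[str, tuple[str, ...]] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def nodes(self) -> set[str]:
        return set(self.parent)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.parent

    def lineage(self, taxon: str) -> tuple[str, ...]:
        """Root-first path from the root to ``taxon`` (inclusive)."""
        cached = self._lineages.get(taxon)
        if cached is not None:
            return cached
        if taxon not in self.parent:
            raise KeyError(f"unknown taxon: {taxon!r}")
        path = [taxon]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        out = tuple(reversed(path))
        self._lineages[taxon] = out
        return out

    def depth(self, taxon: str) -> int:
        return len(self.lineage(taxon)) - 1

    def lineage_string(self, taxon: str) -> str:
        return ";".join(self.lineage(taxon))

    def ancestor_at_rank(self, taxon: str, rank: str) -> str | None:
        """Ancestor-or-self of ``taxon`` with the given rank, or None.

        Returns None both when the lineage skips the rank and when ``taxon``
        itself sits above it (a phylum has no genus-level ancestor).
        """
        if rank not in _RANK_INDEX:
            raise ValueError(f"unknown rank: {rank!r}")
        for node in self.lineage(taxon):
            if self.rank[node] == rank:
                return node
        return None

    def is_ancestor(self, ancestor: str, taxon: str) -> bool:
        """True if ``ancestor`` is an ancestor-or-self of ``taxon``."""
        return ancestor in self.lineage(taxon)

    def subtree(self, taxon: str) -> set[str]:
        """All nodes whose lineage passes through ``taxon`` (including itself)."""
        return {n for n in self.parent if taxon in self.lineage(n)}


def build_taxonomy(
    edges: Iterable[tuple[str, str, str, str]],
) -> TaxonomyTree:
    """Build a validated :class:`TaxonomyTree` from (child, parent, rank, name) rows.

    The root may appear as a self-edge, or implicitly as a parent that is
    never listed as a child (it is then given rank ``root``).  Raises
    :class:`TaxonomyError` on duplicate children with conflicting parents,
    cycles, multiple roots, or rank labels that do not strictly deepen from
    parent to child.
    """
    edges = list(edges)
    if not edges:
        raise TaxonomyError("empty edge list")

    parent: dict[str, str] = {}
    rank: dict[str, str] = {}
    name: dict[str, str] = {}
    for child, par, rk, nm in edges:
        if rk not in _RANK_INDEX:
            raise TaxonomyError(f"unknown rank {rk!r} for taxon {child!r}")
        if child in parent and parent[child] != par:
            raise TaxonomyError(
                f"duplicate child {child!r} with conflicting parents "
                f"{parent[child]!r} and {par!r}"
            )
        parent[child] = par
        rank[child] = rk
        name[child] = nm

    # Implicit root: a parent never seen as a child.
    implicit = {p for p in parent.values() if p not in parent}
    self_roots = {c for c, p in parent.items() if c == p}
    roots = implicit | self_roots
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one root, found {sorted(roots)}")
    root = roots.pop()
    parent[root] = root
    rank.setdefault(root, "root")
    name.setdefault(root, root)

    # Cycle check + rank ordering along every parent chain.
    for node in parent:
        seen = {node}
        cur = node
        while cur != root:
            nxt = parent[cur]
            if _RANK_INDEX[rank[cur]] <= _RANK_INDEX[rank[nxt]]:
                raise TaxonomyError(
                    f"rank of {cur!r} ({rank[cur]}) does not deepen from "
                    f"parent {nxt!r} ({rank[nxt]})"
                )
            if nxt in seen:
                raise TaxonomyError(f"cycle detected through {nxt!r}")
            seen.add(nxt)
            cur = nxt

    return TaxonomyTree(root=root, parent=parent, rank=rank, name=name)


def lca(tree: TaxonomyTree, taxa: Iterable[str]) -> str:
    """Lowest common ancestor of a set of taxa; ``UNASSIGNED`` for the empty set."""
    taxa = set(taxa)
    if not taxa:
        return UNASSIGNED
    lineages = [tree.lineage(t) for t in taxa]
    shortest = min(len(ln) for ln in lineages)
    result = tree.root
    for i in range(shortest):
        level = {ln[i] for ln in lineages}
        if len(level) > 1:
            break
        result = level.pop()
    return result


def classify_units(
    tree: TaxonomyTree,
    candidate_sets: Sequence[Iterable[str]],
    config: LcaConfig | None = None,
) -> list[str]:
    """Resolve each candidate set by LCA, then apply the support filter.

    With ``min_support > 0``, assignments to nodes supported by fewer than
    ``min_support`` units are truncated to the nearest ancestor at
    ``fallback_rank`` (or dropped to ``UNASSIGNED`` with no fallback).
    """
    config = config or LcaConfig()
    assigned = [lca(tree, s) for s in candidate_sets]
    if config.min_support <= 0:
        return assigned
    support = Counter(assigned)
    out = []
    for node in assigned:
        if node == UNASSIGNED or support[node] >= config.min_support:
            out.append(node)
        elif config.fallback_rank is not None:
            anc = tree.ancestor_at_rank(node, config.fallback_rank)
            out.append(anc if anc is not None else UNASSIGNED)
        else:
            out.append(UNASSIGNED)
    return out


def read_taxonomy(path) -> TaxonomyTree:
    """Read a taxonomy from TSV with header columns child, parent, rank, name."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"child", "parent", "rank", "name"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TaxonomyError(
                f"taxonomy file {path} must have columns {sorted(required)}"
            )
        edges = [(r["child"], r["parent"], r["rank"], r["name"]) for r in reader]
    return build_taxonomy(edges)


def write_taxonomy(tree: TaxonomyTree, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["child", "parent", "rank", "name"])
        for child in sorted(tree.parent):
            writer.writerow(
                [child, tree.parent[child], tree.rank[child], tree.name[child]]
            )
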