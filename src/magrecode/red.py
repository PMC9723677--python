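"""Relative evolutionary divergence (RED) and taxonomic rank normalisation.

RED places every node of a rooted tree on a [0, 1] scale with the root at 0
and all extant taxa (leaves) at 1. The value of an internal node ``n`` with
parent ``P`` is linearly interpolated as

    RED(n) = p + (a / (a + b)) * (1 - p)

where ``p`` is the parent's RED, ``a`` the branch length from ``P`` to ``n``
and ``b`` the mean branch-length distance from ``n`` to its descendant
leaves. Because root placement moves every value, a tree is rooted once at
the midpoint of the stem of each phylum containing two or more classes, and
the RED of a taxon is the median over those rootings, excluding the rooting
in which the taxon's own phylum was the outgroup. Rank intervals are the
per-rank median of those taxon medians ± a half-width (0.1 by default),
clipped to [0, 1], and serve as a guide for assigning ranks to new lineages.

This module also carries the alignment post-processing used before tree
building: dropping columns below a consensus threshold and rows that lost
too many residues to that trimming.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

import dendropy

from .treeutil import mrca as _mrca

__all__ = [
    "compute_red",
    "phylum_midpoint_rootings",
    "median_red",
    "rank_intervals",
    "assign_rank",
    "red_pipeline",
    "Rooting",
    "RankIntervals",
    "RankAssignment",
    "Msa",
    "trim_columns_by_consensus",
    "drop_gappy_rows",
]

#: ranks ordered from most to least inclusive
RANK_ORDER = ("d", "p", "c", "o", "f", "g", "s")


# ---------------------------------------------------------------------------
# RED on a single rooted tree


def _branch_length(node: dendropy.Node) -> float:
    return node.edge.length if node.edge.length is not None else 0.0


def compute_red(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Compute RED for every node of a rooted tree.

    Returns a mapping from dendropy node to RED. The root gets 0, leaves get
    1, and internal nodes are interpolated; multifurcations need no special
    treatment. An internal node whose subtree has zero total length
    (``a + b == 0``) inherits its parent's value, with a warning.
    """
    # mean distance from each node to its descendant leaves, bottom-up
    mean_leaf_dist: dict[dendropy.Node, tuple[float, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mean_leaf_dist[node] = (0.0, 1)
        else:
            total, count = 0.0, 0
            for child in node.child_nodes():
                ct, cc = mean_leaf_dist[child]
                total += ct + _branch_length(child) * cc
                count += cc
            mean_leaf_dist[node] = (total, count)

    red: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            red[node] = 0.0
        elif node.is_leaf():
            red[node] = 1.0
        else:
            p = red[node.parent_node]
            a = _branch_length(node)
            total, count = mean_leaf_dist[node]
            b = total / count
            if a + b == 0:
                warnings.warn(
                    "zero-length subtree: internal node inherits parent RED",
                    stacklevel=2,
                )
                red[node] = p
            else:
                red[node] = p + (a / (a + b)) * (1.0 - p)
    return red


# ---------------------------------------------------------------------------
# multi-rooting


@dataclass
class Rooting:
    """One phylum-midpoint rooting: the rooted tree, its outgroup phylum and
    the per-node RED values."""

    outgroup_phylum: str
    tree: dendropy.Tree
    node_red: dict[dendropy.Node, float]


def _phylum_and_class_sets(
    taxonomy: dict[str, list[tuple[str, str]]],
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Leaf sets per phylum, and class names per phylum."""
    phylum_leaves: dict[str, set[str]] = {}
    phylum_classes: dict[str, set[str]] = {}
    for genome_id, ranks in taxonomy.items():
        by_rank = dict(ranks)
        phylum = by_rank.get("p")
        if phylum is None:
            continue
        phylum_leaves.setdefault(phylum, set()).add(genome_id)
        if "c" in by_rank:
            phylum_classes.setdefault(phylum, set()).add(by_rank["c"])
    return phylum_leaves, phylum_classes


def _find_split_edge(tree: dendropy.Tree, leafset: set[str]):
    """Edge whose removal separates ``leafset`` from the rest (unrooted
    monophyly), or None."""
    all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    complement = all_leaves - leafset
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == leafset or below == complement:
            return node.edge
    return None


def phylum_midpoint_rootings(
    tree: dendropy.Tree,
    taxonomy: dict[str, list[tuple[str, str]]],
) -> list[Rooting]:
    """Root the tree once per phylum having at least two classes.

    The root is placed at the midpoint of the branch separating that phylum
    from the rest of the tree. Phyla that are not monophyletic (in the
    unrooted sense) are skipped with a warning. Rootings are returned in
    lexicographic order of phylum name.

    Raises ``ValueError`` if no phylum qualifies; use a single fixed rooting
    in that case.
    """
    phylum_leaves, phylum_classes = _phylum_and_class_sets(taxonomy)
    qualifying = sorted(
        p for p, classes in phylum_classes.items() if len(classes) >= 2
    )
    rootings: list[Rooting] = []
    for phylum in qualifying:
        work = tree.clone(depth=1)
        if len(work.seed_node.child_nodes()) == 2:
            # a basal bifurcation is a rooting artefact of the unrooted
            # input: merge the two root edges so the full stem is split
            work.collapse_basal_bifurcation()
        edge = _find_split_edge(work, phylum_leaves[phylum])
        if edge is None:
            warnings.warn(
                f"phylum {phylum} is not monophyletic; rooting skipped",
                stacklevel=2,
            )
            continue
        length = edge.length if edge.length is not None else 0.0
        work.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)
        rootings.append(Rooting(phylum, work, compute_red(work)))
    if not rootings:
        raise ValueError(
            "no phylum with >= 2 classes (or none monophyletic): "
            "multi-rooting impossible, use a single fixed rooting"
        )
    return rootings


# ---------------------------------------------------------------------------
# per-taxon medians and rank intervals


def _taxon_tables(
    taxonomy: dict[str, list[tuple[str, str]]],
) -> tuple[dict[str, set[str]], dict[str, str | None]]:
    """taxon → leaf set, and taxon → its phylum (None for domain-level)."""
    taxon_leaves: dict[str, set[str]] = {}
    taxon_phylum: dict[str, str | None] = {}
    for genome_id, ranks in taxonomy.items():
        by_rank = dict(ranks)
        phylum = by_rank.get("p")
        for _rank, taxon in ranks:
            taxon_leaves.setdefault(taxon, set()).add(genome_id)
            taxon_phylum.setdefault(taxon, phylum if _rank != "d" else None)
    return taxon_leaves, taxon_phylum


def median_red(
    rootings: list[Rooting],
    taxonomy: dict[str, list[tuple[str, str]]],
) -> dict[str, float | None]:
    """Median RED per taxon over rootings, excluding a taxon's own-phylum
    rooting.

    A taxon is located in each rooted tree as the MRCA of the leaves
    labelled with it. Taxa excluded from every rooting map to ``None``
    (unassessable). An even number of retained rootings yields the mean of
    the two central values.
    """
    if not rootings:
        raise ValueError("at least one rooting required")
    taxon_leaves, taxon_phylum = _taxon_tables(taxonomy)
    medians: dict[str, float | None] = {}
    for taxon, leaves in taxon_leaves.items():
        values: list[float] = []
        for rooting in rootings:
            if taxon_phylum.get(taxon) == rooting.outgroup_phylum:
                continue
            node = _mrca(rooting.tree, leaves)
            if node is None:
                continue
            values.append(rooting.node_red[node])
        medians[taxon] = statistics.median(values) if values else None
    return medians


@dataclass
class RankIntervals:
    """Per-rank RED interval (median ± h, clipped to [0, 1])."""

    medians: dict[str, float] = field(default_factory=dict)
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    h: float = 0.1


def rank_intervals(
    taxon_medians: dict[str, float | None],
    h: float = 0.1,
) -> RankIntervals:
    """Aggregate per-taxon median RED values into per-rank intervals.

    The rank of a taxon is read from its name prefix (``c__...`` → class).
    Ranks with no assessable taxon are omitted.
    """
    by_rank: dict[str, list[float]] = {}
    for taxon, value in taxon_medians.items():
        if value is None:
            continue
        rank = taxon[0]
        if rank in RANK_ORDER:
            by_rank.setdefault(rank, []).append(value)
    result = RankIntervals(h=h)
    for rank, values in by_rank.items():
        m = statistics.median(values)
        result.medians[rank] = m
        result.intervals[rank] = (max(0.0, m - h), min(1.0, m + h))
    return result


@dataclass
class RankAssignment:
    rank: str
    in_interval: bool
    alternatives: list[str]


def assign_rank(value: float, intervals: RankIntervals) -> RankAssignment:
    """Assign a rank to a RED value.

    The primary rank is the containing interval whose median is nearest
    (ties broken toward the more inclusive rank); the other containing
    ranks are reported as alternatives. If no interval contains the value
    the nearest-median rank is returned with ``in_interval=False``.
    """
    if not intervals.intervals:
        raise ValueError("no rank intervals available")

    def sort_key(rank: str) -> tuple[float, int]:
        return (abs(value - intervals.medians[rank]), RANK_ORDER.index(rank))

    containing = sorted(
        (r for r, (lo, hi) in intervals.intervals.items() if lo <= value <= hi),
        key=sort_key,
    )
    if containing:
        return RankAssignment(containing[0], True, containing[1:])
    nearest = min(intervals.medians, key=sort_key)
    return RankAssignment(nearest, False, [])


def red_pipeline(
    tree: dendropy.Tree,
    taxonomy: dict[str, list[tuple[str, str]]],
    h: float = 0.1,
) -> tuple[list[Rooting], dict[str, float | None], RankIntervals]:
    """Multi-root, take per-taxon medians and derive rank intervals."""
    rootings = phylum_midpoint_rootings(tree, taxonomy)
    medians = median_red(rootings, taxonomy)
    return rootings, medians, rank_intervals(medians, h=h)


# ---------------------------------------------------------------------------
# alignment trimming

GAP_CHARS = frozenset("-.")


@dataclass
class Msa:
    """A multiple sequence alignment: parallel lists of ids and rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def trim_columns_by_consensus(msa: Msa, min_consensus: float = 0.4) -> Msa:
    """Drop alignment columns whose consensus falls below a threshold.

    A column is kept iff its most frequent non-gap residue occurs in at
    least ``min_consensus`` of **all** rows (gaps count in the denominator).
    Column order is preserved. Removing every column yields an empty
    alignment with a warning.
    """
    if not msa.rows:
        return Msa(list(msa.ids), list(msa.rows))
    n_rows = len(msa.rows)
    keep: list[int] = []
    for col in range(msa.n_columns):
        counts: dict[str, int] = {}
        for row in msa.rows:
            ch = row[col]
            if ch not in GAP_CHARS:
                counts[ch] = counts.get(ch, 0) + 1
        best = max(counts.values()) if counts else 0
        if best / n_rows >= min_consensus:
            keep.append(col)
    if not keep:
        warnings.warn("consensus trimming removed every column", stacklevel=2)
    rows = ["".join(row[c] for c in keep) for row in msa.rows]
    return Msa(list(msa.ids), rows)


def drop_gappy_rows(
    msa: Msa,
    min_fraction: float = 0.8,
    original: Msa | None = None,
) -> Msa:
    """Drop rows that retain too few residues after column trimming.

    A row is kept iff (non-gap residues now) / (non-gap residues it had in
    ``original``, i.e. before trimming) >= ``min_fraction``. With no
    ``original`` the row's own residue count is the baseline (every
    non-empty row is then kept)."""
    ids: list[str] = []
    rows: list[str] = []
    for i, (rid, row) in enumerate(zip(msa.ids, msa.rows)):
        now = sum(1 for ch in row if ch not in GAP_CHARS)
        base_row = original.rows[i] if original is not None else row
        before = sum(1 for ch in base_row if ch not in GAP_CHARS)
        if before == 0:
            continue
        if now / before >= min_fraction:
            ids.append(rid)
            rows.append(row)
    return Msa(ids, rows)
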