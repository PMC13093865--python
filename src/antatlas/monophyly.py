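"""Species monophyly classification and lineage counting on gene trees.

Given a rooted genus-level gene tree whose tips map to specimen records, each
species is classified as:

* **monophyletic** — the MRCA clade of its tips contains no other species
  (a single tip in a monotypic genus group also counts as monophyletic);
* **singleton** — a single tip in a genus group with other sequenced species,
  where monophyly is untestable;
* **paraphyletic** — not exclusive, but *convex*: the minimal subtree
  (Steiner tree) connecting its tips shares no node with the Steiner tree of
  any other species;
* **polyphyletic** — its Steiner tree is entangled with another species'.

The number of mitochondrial lineages per species is the number of maximal
clades whose tips all belong to that species; these clades partition the
species' tips, and a species is monophyletic exactly when it has one lineage
covering all its tips.

Classification is purely topological: branch lengths, node support labels and
polytomies are all tolerated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .records import SpecimenRecord, ValidationError

__all__ = [
    "GeneTree",
    "MonophylyResult",
    "read_gene_tree",
    "root_on_outgroup",
    "prune_to_identified",
    "classify_species",
    "classify_all",
    "count_lineages",
    "summarize_monophyly",
    "LightTree",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# light topological representation (used by the classifier core)

@dataclass
class LightTree:
    """Rooted tree as children lists; leaves carry species labels.

    Node 0 is the root.  ``species[i]`` is None for internal nodes.
    """

    children: list[list[int]]
    species: list[str | None]
    parent: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.parent:
            self.parent = [-1] * len(self.children)
            for u, kids in enumerate(self.children):
                for v in kids:
                    self.parent[v] = u

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def leaves(self) -> list[int]:
        return [i for i, kids in enumerate(self.children) if not kids]

    def tips_of(self, species: str) -> list[int]:
        return [i for i in self.leaves() if self.species[i] == species]

    def species_present(self) -> list[str]:
        return sorted({s for s in self.species if s is not None})

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            u = stack.pop()
            order.append(u)
            stack.extend(self.children[u])
        order.reverse()
        return order

    def mrca(self, nodes: Sequence[int]) -> int:
        """MRCA via ancestor-set intersection (depth-ordered)."""
        paths = []
        for n in nodes:
            path = []
            while n != -1:
                path.append(n)
                n = self.parent[n]
            paths.append(path[::-1])
        k = min(len(p) for p in paths)
        mrca = 0
        for depth in range(k):
            anc = paths[0][depth]
            if all(p[depth] == anc for p in paths):
                mrca = anc
            else:
                break
        return mrca

    def steiner_nodes(self, species: str) -> set[int]:
        """Nodes of the minimal subtree connecting the species' tips.

        Equals the union over tips of the path tip -> MRCA(all tips).
        """
        tips = self.tips_of(species)
        if not tips:
            return set()
        top = self.mrca(tips)
        nodes: set[int] = set()
        for t in tips:
            n = t
            while True:
                nodes.add(n)
                if n == top:
                    break
                n = self.parent[n]
        return nodes

    def clade_leafset(self) -> list[set[str]]:
        """Per node: the set of species labels below (leaves: own label)."""
        sets: list[set[str]] = [set() for _ in range(self.n_nodes)]
        for u in self.postorder():
            if not self.children[u]:
                if self.species[u] is not None:
                    sets[u] = {self.species[u]}
            else:
                for v in self.children[u]:
                    sets[u] |= sets[v]
        return sets


@dataclass(frozen=True)
class MonophylyResult:
    species: str
    status: str  # monophyletic | paraphyletic | polyphyletic | singleton
    n_lineages: int
    n_tips: int
    intruders: tuple[str, ...] = ()


def _classify_light(
    tree: LightTree, species: str, monotypic: bool = False
) -> MonophylyResult:
    tips = tree.tips_of(species)
    if not tips:
        raise ValidationError(f"species {species!r} has no tips in the tree")
    n_tips = len(tips)
    n_lin = _count_lineages_light(tree, species)
    if n_tips == 1:
        if monotypic:
            return MonophylyResult(species, "monophyletic", 1, 1)
        return MonophylyResult(species, "singleton", 1, 1)

    top = tree.mrca(tips)
    clade_species = set()
    stack = [top]
    while stack:
        u = stack.pop()
        if not tree.children[u]:
            if tree.species[u] is not None:
                clade_species.add(tree.species[u])
        else:
            stack.extend(tree.children[u])
    intruders = tuple(sorted(clade_species - {species}))
    if not intruders:
        return MonophylyResult(species, "monophyletic", n_lin, n_tips)

    focal_steiner = tree.steiner_nodes(species)
    for other in tree.species_present():
        if other == species:
            continue
        if focal_steiner & tree.steiner_nodes(other):
            return MonophylyResult(species, "polyphyletic", n_lin, n_tips, intruders)
    return MonophylyResult(species, "paraphyletic", n_lin, n_tips, intruders)


def _count_lineages_light(tree: LightTree, species: str) -> int:
    """Maximal clades whose tips are exclusively the focal species'."""
    pure = [False] * tree.n_nodes
    has_tip = [False] * tree.n_nodes
    for u in tree.postorder():
        kids = tree.children[u]
        if not kids:
            pure[u] = tree.species[u] == species
            has_tip[u] = pure[u]
        else:
            pure[u] = all(pure[v] for v in kids)
            has_tip[u] = any(has_tip[v] for v in kids)
    count = 0
    for u in range(tree.n_nodes):
        if pure[u] and has_tip[u] and (u == 0 or not pure[tree.parent[u]]):
            count += 1
    return count


# ---------------------------------------------------------------------------
# dendropy-backed gene tree

@dataclass
class GeneTree:
    """Rooted gene tree plus the specimen metadata its tips resolve to."""

    tree: dendropy.Tree
    tip_records: dict[str, SpecimenRecord]
    outgroups: tuple[str, ...] = ()

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def to_light(self) -> LightTree:
        """Project to the topological representation (species labels on tips)."""
        nodes = list(self.tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        children: list[list[int]] = [[] for _ in nodes]
        species: list[str | None] = [None] * len(nodes)
        for n in nodes:
            i = index[id(n)]
            for c in n.child_nodes():
                children[i].append(index[id(c)])
            if n.is_leaf():
                label = n.taxon.label
                rec = self.tip_records.get(label)
                species[i] = rec.species if rec is not None else label
        return LightTree(children, species)

    def monotypic_groups(self) -> set[str]:
        """Genus groups with a single identified species among the tips."""
        by_group: dict[str, set[str]] = {}
        for rec in self.tip_records.values():
            if rec.species is not None:
                by_group.setdefault(rec.genus_group, set()).add(rec.species)
        return {g for g, sp in by_group.items() if len(sp) == 1}


def read_gene_tree(
    path_or_newick: str,
    records: Sequence[SpecimenRecord],
    outgroups: Iterable[str] = (),
) -> GeneTree:
    """Load a Newick tree; support values on nodes are tolerated."""
    source = str(path_or_newick)
    kwargs = dict(
        schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True
    )
    if source.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=source, **kwargs)
    else:
        tree = dendropy.Tree.get(path=source, **kwargs)
    rec_by_id = {r.specimen_id: r for r in records}
    out = tuple(outgroups)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [o for o in out if o not in tips]
    if missing:
        raise ValidationError(f"outgroup tips absent from tree: {missing}")
    unmapped = sorted(t for t in tips if t not in rec_by_id and t not in out)
    if unmapped:
        raise ValidationError(f"tree tips without specimen records: {unmapped}")
    return GeneTree(tree, {t: rec_by_id[t] for t in tips if t in rec_by_id}, out)


def root_on_outgroup(gtree: GeneTree) -> GeneTree:
    """Root on the edge subtending the outgroup clade, then drop outgroups.

    When the outgroups do not form a separable set the tree is rooted on the
    first outgroup's pendant edge instead (logged).  A single outgroup is
    allowed with a warning; two or more are recommended.
    """
    out = gtree.outgroups
    if not out:
        raise ValidationError("no outgroups designated")
    if len(out) == 1:
        logger.warning("only one outgroup tip; two or more are recommended")
    tree = gtree.tree.clone(depth=1)
    tree.is_rooted = True
    taxa = [tree.taxon_namespace.get_taxon(o) for o in out]
    if len(taxa) == 1:
        node = tree.find_node_with_taxon_label(out[0])
        edge = node.edge
    else:
        mrca = tree.mrca(taxa=taxa)
        mrca_leaves = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        if mrca_leaves == set(out) and mrca.parent_node is not None:
            edge = mrca.edge
        else:
            logger.warning(
                "outgroup not monophyletic; rooting on pendant edge of %s", out[0]
            )
            edge = tree.find_node_with_taxon_label(out[0]).edge
    length = edge.length or 0.0
    tree.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)
    # drop the outgroup tips; classification covers the ingroup only
    keep = [
        t for t in tree.taxon_namespace if t.label not in out
    ]
    tree.retain_taxa(keep)
    tree.purge_taxon_namespace()
    if not any(tree.leaf_node_iter()):
        raise ValidationError("rooting removed every ingroup tip")
    return GeneTree(tree, dict(gtree.tip_records), ())


def prune_to_identified(gtree: GeneTree) -> GeneTree:
    """Keep only tips identified at species level; path lengths conserved.

    Degree-2 nodes created by pruning are suppressed with their branch
    lengths summed, so root-to-tip distances of retained tips are unchanged.
    """
    tree = gtree.tree.clone(depth=1)
    keep_labels = {
        label
        for label, rec in gtree.tip_records.items()
        if rec.det_status == "identified" and rec.species is not None
    }
    keep = [t for t in tree.taxon_namespace if t.label in keep_labels]
    if not keep:
        raise ValidationError("pruning to identified tips removed the whole tree")
    tree.retain_taxa(keep)
    tree.purge_taxon_namespace()
    records = {l: r for l, r in gtree.tip_records.items() if l in keep_labels}
    return GeneTree(tree, records, gtree.outgroups)


def classify_species(gtree: GeneTree, species: str) -> MonophylyResult:
    """Classify one species on a rooted, pruned gene tree."""
    light = gtree.to_light()
    rec = next(
        (r for r in gtree.tip_records.values() if r.species == species), None
    )
    monotypic = rec is not None and rec.genus_group in gtree.monotypic_groups()
    return _classify_light(light, species, monotypic=monotypic)


def classify_all(gtree: GeneTree) -> list[MonophylyResult]:
    light = gtree.to_light()
    monotypic_groups = gtree.monotypic_groups()
    group_of = {
        r.species: r.genus_group
        for r in gtree.tip_records.values()
        if r.species is not None
    }
    results = []
    for sp in light.species_present():
        mono = group_of.get(sp) in monotypic_groups
        results.append(_classify_light(light, sp, monotypic=mono))
    return results


def count_lineages(gtree: GeneTree, species: str) -> int:
    light = gtree.to_light()
    if not light.tips_of(species):
        raise ValidationError(f"species {species!r} has no tips in the tree")
    return _count_lineages_light(light, species)


def summarize_monophyly(results: Sequence[MonophylyResult]) -> dict[str, float | int]:
    """Counts and one-decimal percentages per monophyly status.

    Singleton percentage is over all species; monophyletic / paraphyletic /
    polyphyletic percentages are over the multi-sequence (non-singleton)
    species, matching how reference-library summaries are conventionally
    reported.
    """
    from .distances import percent

    n_total = len(results)
    n_single = sum(1 for r in results if r.status == "singleton")
    n_multi = n_total - n_single
    counts = {
        s: sum(1 for r in results if r.status == s)
        for s in ("monophyletic", "paraphyletic", "polyphyletic")
    }
    return {
        "n_species_in_trees": n_total,
        "n_singletons_tree": n_single,
        "pct_singletons_tree": percent(n_single, n_total) if n_total else 0.0,
        "n_multi_sequence": n_multi,
        "n_monophyletic": counts["monophyletic"],
        "pct_monophyletic": percent(counts["monophyletic"], n_multi) if n_multi else 0.0,
        "n_paraphyletic": counts["paraphyletic"],
        "pct_paraphyletic": percent(counts["paraphyletic"], n_multi) if n_multi else 0.0,
        "n_polyphyletic": counts["polyphyletic"],
        "pct_polyphyletic": percent(counts["polyphyletic"], n_multi) if n_multi else 0.0,
        "n_non_monophyletic": counts["paraphyletic"] + counts["polyphyletic"],
        "pct_non_monophyletic": (
            percent(counts["paraphyletic"] + counts["polyphyletic"], n_multi)
            if n_multi
            else 0.0
        ),
    }


def results_to_frame(results: Sequence[MonophylyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "status": r.status,
                "n_lineages": r.n_lineages,
                "n_tips": r.n_tips,
                "intruders": ";".join(r.intruders),
            }
            for r in results
        ]
    )
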