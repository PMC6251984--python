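"""Gene trees with evolutionary-event labels and homology typing.

A gene tree relates the members of one gene family; each internal node
carries the event that created the bifurcation — speciation, duplication
or gene split — and each leaf is one gene in one species.  Pair types
follow the usual copy-number logic: under a speciation ancestor, the pair
is a 1:1 / 1:many / many:many ortholog depending on how many gene copies
each species kept in its side of the tree; a duplication ancestor makes
paralogs (within-species if the two genes share a genome, between-species
otherwise).  Gene-split nodes mark a gene annotated as fragments; for
typing they behave like speciation nodes but keep their own label for
rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .cigar_core import AlignmentCigar, PairStats, pairwise_stats
from .errors import ModelError

__all__ = [
    "EVENTS",
    "HOMOLOGY_TYPES",
    "TreeNode",
    "GeneTree",
    "HomologyRecord",
    "classify_pair",
    "homology_table",
    "leaf_order",
]

EVENTS = ("leaf", "speciation", "duplication", "gene_split")

HOMOLOGY_TYPES = (
    "ortholog_one2one",
    "ortholog_one2many",
    "ortholog_many2many",
    "within_species_paralog",
    "between_species_paralog",
)


@dataclass
class TreeNode:
    """One node of a gene tree.  Leaves carry species + gene_id."""

    event: str = "speciation"
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None
    branch_length: Optional[float] = None
    species: Optional[str] = None
    gene_id: Optional[str] = None

    def __post_init__(self):
        if self.event not in EVENTS:
            raise ModelError(f"unknown tree event {self.event!r}")

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def iter_preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_leaves(self) -> Iterator["TreeNode"]:
        for node in self.iter_preorder():
            if node.is_leaf:
                yield node


class GeneTree:
    """Rooted gene tree; leaves indexed by gene_id."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._leaves: dict[str, TreeNode] = {}
        for leaf in root.iter_leaves():
            if leaf.gene_id is None:
                raise ModelError("leaf without a gene_id")
            if leaf.event != "leaf":
                leaf.event = "leaf"
            if leaf.gene_id in self._leaves:
                raise ModelError(f"duplicate leaf gene_id {leaf.gene_id!r}")
            self._leaves[leaf.gene_id] = leaf
        for node in root.iter_preorder():
            if not node.is_leaf and node.gene_id is not None:
                raise ModelError("internal node must not carry a gene_id")

    def leaf(self, gene_id: str) -> TreeNode:
        try:
            return self._leaves[gene_id]
        except KeyError:
            raise ModelError(f"gene {gene_id!r} is not a leaf of this tree") from None

    @property
    def leaves(self) -> list[TreeNode]:
        return [self._leaves[g] for g in leaf_order(self)]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.iter_preorder() if not n.is_leaf]


def leaf_order(tree: GeneTree) -> list[str]:
    """Gene ids depth-first, left to right — the row order of the views."""
    out: list[str] = []

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            out.append(node.gene_id)  # type: ignore[arg-type]
        for child in node.children:
            walk(child)

    walk(tree.root)
    return out


def _path_to_root(node: TreeNode) -> list[TreeNode]:
    path = [node]
    while path[-1].parent is not None:
        path.append(path[-1].parent)
    return path


def _lca(a: TreeNode, b: TreeNode) -> TreeNode:
    ancestors_a = set(map(id, _path_to_root(a)))
    for node in _path_to_root(b):
        if id(node) in ancestors_a:
            return node
    raise ModelError("leaves do not share a root")  # pragma: no cover


def _species_count(subtree: TreeNode, species: str) -> int:
    return sum(1 for leaf in subtree.iter_leaves() if leaf.species == species)


def classify_pair(tree: GeneTree, gene_a: str, gene_b: str) -> str:
    """Homology type of one gene pair from the labeled tree.

    Same-species pairs are always within-species paralogs regardless of
    the ancestor event.  Cross-species pairs under a duplication ancestor
    are between-species paralogs.  Otherwise (speciation or gene-split
    ancestor) the copy counts of each species within its side of the
    ancestor decide 1:1 vs 1:many vs many:many.
    """
    if gene_a == gene_b:
        raise ModelError("a gene cannot be its own homologue")
    leaf_a = tree.leaf(gene_a)
    leaf_b = tree.leaf(gene_b)
    if leaf_a.species is None or leaf_b.species is None:
        raise ModelError("both leaves must carry a species label")
    if leaf_a.species == leaf_b.species:
        return "within_species_paralog"
    lca = _lca(leaf_a, leaf_b)
    if lca.event == "duplication":
        return "between_species_paralog"
    # speciation (or gene_split, treated alike): count copies per side
    side_a = side_b = None
    set_a = set(map(id, _path_to_root(leaf_a)))
    set_b = set(map(id, _path_to_root(leaf_b)))
    for child in lca.children:
        if id(child) in set_a or child is leaf_a:
            side_a = child
        if id(child) in set_b or child is leaf_b:
            side_b = child
    if side_a is None or side_b is None:  # pragma: no cover
        raise ModelError("LCA sides could not be resolved")
    n_a = _species_count(side_a, leaf_a.species)
    n_b = _species_count(side_b, leaf_b.species)
    if n_a == 1 and n_b == 1:
        return "ortholog_one2one"
    if n_a == 1 or n_b == 1:
        return "ortholog_one2many"
    return "ortholog_many2many"


def coarse_type(homology_type: str) -> str:
    """Collapse the five fine types into the two buckets of the table view."""
    return "ortholog" if homology_type.startswith("ortholog") else "paralog"


@dataclass(frozen=True)
class HomologyRecord:
    """One guide/target pair with its type and pair statistics."""

    guide_gene: str
    target_gene: str
    target_species: str
    homology_type: str
    stats: PairStats

    def __post_init__(self):
        if self.guide_gene == self.target_gene:
            raise ModelError("guide and target must differ")
        if self.homology_type not in HOMOLOGY_TYPES:
            raise ModelError(f"unknown homology type {self.homology_type!r}")

    @property
    def coarse_type(self) -> str:
        return coarse_type(self.homology_type)


def homology_table(
    tree: GeneTree,
    guide_gene: str,
    cigars: dict[str, AlignmentCigar],
    seqs: dict[str, str],
    matrix=None,
) -> list[HomologyRecord]:
    """One record per non-guide leaf, in tree leaf order.

    Every leaf must have an alignment member; a missing one is an error
    naming the gene rather than a silently shorter table.
    """
    guide = tree.leaf(guide_gene)  # validates membership
    records: list[HomologyRecord] = []
    for gene_id in leaf_order(tree):
        if gene_id == guide_gene:
            continue
        if gene_id not in cigars or gene_id not in seqs:
            raise ModelError(f"leaf {gene_id!r} has no alignment member")
        if guide_gene not in cigars or guide_gene not in seqs:
            raise ModelError(f"leaf {guide_gene!r} has no alignment member")
        stats = pairwise_stats(
            cigars[guide_gene], seqs[guide_gene], cigars[gene_id], seqs[gene_id],
            matrix=matrix,
        )
        leaf = tree.leaf(gene_id)
        records.append(
            HomologyRecord(
                guide_gene=guide_gene,
                target_gene=gene_id,
                target_species=leaf.species or "",
                homology_type=classify_pair(tree, guide_gene, gene_id),
                stats=stats,
            )
        )
    return records
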