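"""Parsimony duplication-loss reconciliation via LCA mapping.

Each gene-tree node is mapped to the lowest common ancestor, in the species
tree, of the species its descendant genes belong to.  An internal gene node
is a duplication when its mapping coincides with the mapping of at least one
child, otherwise a speciation.  Losses on the gene-tree edge u -> v with
species-path edge count d = depth(M(v)) - depth(M(u)) number max(d - 1, 0)
under a speciation at u and d under a duplication at u.  This is the
standard LCA parsimony count; it minimizes the duplication count over all
valid mappings.  Branch lengths are ignored; non-binary trees are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Union

import dendropy

from .io_formats import read_newick

TreeLike = Union[str, dendropy.Tree]


@dataclass
class ReconciliationResult:
    mapping: dict                # gene node id -> species node label
    events: dict                 # internal gene node id -> event
    duplications: int
    losses: int
    edge_losses: list = field(default_factory=list)  # (parent, child, losses)


def _as_tree(tree: TreeLike) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return read_newick(tree)


def _check_binary(tree: dendropy.Tree, name: str) -> None:
    for node in tree.preorder_node_iter():
        k = len(node.child_nodes())
        if k not in (0, 2):
            raise ValueError(
                f"{name} tree is not binary: a node has {k} children")


def _gene_node_ids(tree: dendropy.Tree) -> dict:
    ids = {}
    k = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label if node.taxon else f"leaf{k}"
        else:
            ids[node] = f"node{k}"
        k += 1
    return ids


class _SpeciesIndex:
    """Leaf lookup, depths, parents, and LCA queries on a species tree."""

    def __init__(self, tree: dendropy.Tree):
        _check_binary(tree, "species")
        self.tree = tree
        self.leaf: dict[str, dendropy.Node] = {}
        for lf in tree.leaf_node_iter():
            label = lf.taxon.label if lf.taxon else None
            if label is None:
                raise ValueError("species tree has an unlabeled leaf")
            if label in self.leaf:
                raise ValueError(
                    f"duplicate leaf label {label!r} in species tree")
            self.leaf[label] = lf
        self.depth: dict[dendropy.Node, int] = {}
        self.parent: dict[dendropy.Node, Optional[dendropy.Node]] = {}
        self.label: dict[dendropy.Node, str] = {}
        for node in tree.preorder_node_iter():
            par = node.parent_node
            self.parent[node] = par
            self.depth[node] = 0 if par is None else self.depth[par] + 1
        leafset: dict[dendropy.Node, set] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self.label[node] = node.taxon.label
                leafset[node] = {node.taxon.label}
            else:
                leafset[node] = set().union(
                    *(leafset[c] for c in node.child_nodes()))
                self.label[node] = \
                    "mrca(" + ",".join(sorted(leafset[node])) + ")"

    def lca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while a is not b:
            if self.depth[a] < self.depth[b]:
                b = self.parent[b]
            else:
                a = self.parent[a]
        return a

    def path_edges(self, anc: dendropy.Node, desc: dendropy.Node) -> int:
        return self.depth[desc] - self.depth[anc]

    def ancestors_or_self(self, node: dendropy.Node) -> list:
        out = [node]
        while self.parent[out[-1]] is not None:
            out.append(self.parent[out[-1]])
        return out


def _default_leaf_map(label: str) -> str:
    return label.split("_", 1)[0]


def lca_map(gene_tree: TreeLike, species_tree: TreeLike,
            leaf_to_species: Optional[Mapping[str, str]] = None
            ) -> dict[str, str]:
    """Map every gene-tree node to its species-tree LCA node.

    ``leaf_to_species`` maps gene leaf labels to species leaf labels; by
    default the prefix of the leaf label up to the first underscore names
    the species.  Returns ``{gene node id: species node label}`` with gene
    leaves keyed by their labels and internal nodes by postorder ids.
    """
    gtree, stree = _as_tree(gene_tree), _as_tree(species_tree)
    _check_binary(gtree, "gene")
    index = _SpeciesIndex(stree)
    ids = _gene_node_ids(gtree)
    mapping = _compute_lca_map(gtree, index, leaf_to_species)
    return {ids[node]: index.label[sp] for node, sp in mapping.items()}


def _compute_lca_map(gtree: dendropy.Tree, index: _SpeciesIndex,
                     leaf_to_species: Optional[Mapping[str, str]]) -> dict:
    mapping: dict = {}
    for node in gtree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else ""
            if leaf_to_species is not None:
                if label not in leaf_to_species:
                    raise ValueError(
                        f"gene leaf {label!r} has no species assignment")
                species = leaf_to_species[label]
            else:
                species = _default_leaf_map(label)
            if species not in index.leaf:
                raise ValueError(
                    f"species {species!r} (for gene leaf {label!r}) absent "
                    "from species tree")
            mapping[node] = index.leaf[species]
        else:
            left, right = node.child_nodes()
            mapping[node] = index.lca(mapping[left], mapping[right])
    return mapping


def reconcile_dl(gene_tree: TreeLike, species_tree: TreeLike,
                 leaf_to_species: Optional[Mapping[str, str]] = None
                 ) -> ReconciliationResult:
    """Count duplications and losses for a gene tree against a species tree."""
    gtree, stree = _as_tree(gene_tree), _as_tree(species_tree)
    _check_binary(gtree, "gene")
    index = _SpeciesIndex(stree)
    ids = _gene_node_ids(gtree)
    mapping = _compute_lca_map(gtree, index, leaf_to_species)

    events: dict[str, str] = {}
    duplications = 0
    for node in gtree.postorder_node_iter():
        if node.is_leaf():
            continue
        if any(mapping[node] is mapping[c] for c in node.child_nodes()):
            events[ids[node]] = "duplication"
            duplications += 1
        else:
            events[ids[node]] = "speciation"

    losses = 0
    edge_losses = []
    for node in gtree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        d = index.path_edges(mapping[parent], mapping[node])
        if events[ids[parent]] == "duplication":
            edge = d
        else:
            edge = max(d - 1, 0)
        losses += edge
        if edge:
            edge_losses.append((ids[parent], ids[node], edge))

    return ReconciliationResult(
        mapping={ids[n]: index.label[sp] for n, sp in mapping.items()},
        events=events, duplications=duplications, losses=losses,
        edge_losses=edge_losses)


def min_duplications_bruteforce(gene_tree: TreeLike, species_tree: TreeLike,
                                leaf_to_species: Optional[
                                    Mapping[str, str]] = None) -> int:
    """Exhaustive minimum duplication count over all valid node mappings.

    A mapping is valid when every internal gene node maps to an ancestor (or
    equal) of the LCA of its children's mappings; a node is a duplication
    unless it maps exactly to that LCA and neither child maps to the same
    node.  Exponential; intended as an independent optimality oracle on
    small trees.
    """
    gtree, stree = _as_tree(gene_tree), _as_tree(species_tree)
    _check_binary(gtree, "gene")
    index = _SpeciesIndex(stree)
    lca_mapping = _compute_lca_map(gtree, index, leaf_to_species)

    internals = [n for n in gtree.postorder_node_iter() if not n.is_leaf()]
    choices = [index.ancestors_or_self(lca_mapping[n]) for n in internals]

    best = None
    for assignment in product(*choices):
        chosen = dict(zip(internals, assignment))

        def mapped(node):
            return chosen[node] if node in chosen else lca_mapping[node]

        valid = True
        dups = 0
        for node in internals:
            kids = [mapped(c) for c in node.child_nodes()]
            lca = index.lca(kids[0], kids[1])
            m = chosen[node]
            if index.lca(m, lca) is not m:  # m must be ancestor-or-self
                valid = False
                break
            if m is not lca or any(k is m for k in kids):
                dups += 1
        if valid and (best is None or dups < best):
            best = dups
    return best if best is not None else 0
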