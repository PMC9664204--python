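"""LCA gene-tree/species-tree reconciliation and WGD-window timing.

Each gene-tree node is mapped to the lowest common ancestor (in the species
tree) of its descendant species.  An internal node is a duplication iff its
image equals the image of at least one child.  Losses are counted as
species-tree edges skipped along each gene-tree edge, with the usual extra
loss charged at a duplication node whose child maps strictly below it;
pass-through (unary) species nodes contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

from wgdkit.io_formats.trees import Tree


class ReconciliationError(ValueError):
    pass


SPECIES_SEP = "|"


def leaf_species(label: str) -> str:
    """Gene-tree leaves are labeled ``species|gene_id``."""
    if SPECIES_SEP not in label:
        raise ReconciliationError(
            f"gene-tree leaf {label!r} is not of the form species{SPECIES_SEP}gene_id"
        )
    return label.split(SPECIES_SEP, 1)[0]


@dataclass
class ReconciliationResult:
    node_map: Dict[str, str]                 # gene node -> species node
    node_events: Dict[str, str]              # internal gene node -> event
    n_duplications: int
    n_losses: int
    duplication_assignments: Dict[str, str]  # duplication node -> species branch


def lca_reconcile(gene_tree: Tree, species_tree: Tree) -> ReconciliationResult:
    """Standard LCA reconciliation of a rooted binary gene tree."""
    for node in gene_tree.nodes():
        if node.children and len(node.children) != 2:
            raise ReconciliationError(
                f"gene tree must be binary; node {node.label!r} has "
                f"{len(node.children)} children"
            )
    for leaf in gene_tree.root.leaves():
        sp = leaf_species(leaf.label)
        if sp not in species_tree:
            raise ReconciliationError(f"leaf species {sp!r} not in species tree")

    # species-node depths for path computations
    depth: Dict[str, int] = {}
    parent: Dict[str, Optional[str]] = {}
    nchildren: Dict[str, int] = {}
    for node in species_tree.nodes():
        depth[node.label] = species_tree.depth(node.label)
        parent[node.label] = node.parent.label if node.parent else None
        nchildren[node.label] = len(node.children)

    node_map: Dict[str, str] = {}
    node_events: Dict[str, str] = {}
    dup_assign: Dict[str, str] = {}

    for gnode in gene_tree.root.postorder():
        if gnode.is_leaf:
            node_map[gnode.label] = leaf_species(gnode.label)
        else:
            images = [node_map[c.label] for c in gnode.children]
            image = species_tree.mrca(images).label
            node_map[gnode.label] = image
            if any(img == image for img in images):
                node_events[gnode.label] = "duplication"
                dup_assign[gnode.label] = image
            else:
                node_events[gnode.label] = "speciation"

    n_losses = 0
    for gnode in gene_tree.nodes():
        if gnode.is_leaf:
            continue
        up = node_map[gnode.label]
        is_dup = node_events[gnode.label] == "duplication"
        for child in gnode.children:
            down = node_map[child.label]
            # skipped species nodes strictly between `up` and `down` each
            # cost (children - 1) lost copies; a duplication node whose
            # child descends strictly below it additionally loses the
            # copies in the unvisited children of `up` itself.
            label = down
            intermediates: List[str] = []
            while label != up:
                label = parent[label]  # type: ignore[assignment]
                if label is None:
                    raise ReconciliationError("inconsistent node mapping")
                if label != up:
                    intermediates.append(label)
            for mid in intermediates:
                n_losses += nchildren[mid] - 1
            if is_dup and down != up:
                n_losses += nchildren[up] - 1

    return ReconciliationResult(
        node_map=node_map,
        node_events=node_events,
        n_duplications=sum(1 for e in node_events.values() if e == "duplication"),
        n_losses=n_losses,
        duplication_assignments=dup_assign,
    )


def classify_duplication(
    result: ReconciliationResult, species_tree: Tree
) -> Dict[str, str]:
    """Label each duplication node with a timing class.

    A duplication on a WGD-tagged branch becomes ``WGD:<tag>`` (a candidate
    ohnolog pair; synteny corroboration is a separate step).  A duplication
    on an untagged internal branch ancestral to some WGD-tagged branch is
    ``local_prewindow``; anything else is ``lineage_specific``.
    """
    labels: Dict[str, str] = {}
    for gnode, branch in result.duplication_assignments.items():
        tag = species_tree.wgd_tags.get(branch)
        if tag is not None:
            labels[gnode] = f"WGD:{tag}"
            continue
        node = species_tree.node(branch)
        if not node.is_leaf and any(
            tagged in species_tree
            and species_tree.is_ancestor(branch, tagged)
            and tagged != branch
            for tagged in species_tree.wgd_tags
        ):
            labels[gnode] = "local_prewindow"
        else:
            labels[gnode] = "lineage_specific"
    return labels


def infer_gain_constraint(
    result: ReconciliationResult,
    gene_tree: Tree,
    subtype_of: Dict[str, str],
) -> str:
    """Species node where a two-subtype gene tree splits its subtypes.

    ``subtype_of`` maps each gene-tree leaf label to its subtype.  The
    returned label is usable as a Dollo ``gain_constraint``: it is where
    the duplication separating the two subtypes maps, i.e. the earliest
    node at which the younger subtype must already have existed.
    """
    leaves = [l.label for l in gene_tree.root.leaves()]
    subtypes = sorted({subtype_of[l] for l in leaves})
    if len(subtypes) < 2:
        raise ReconciliationError(
            f"gene tree holds a single subtype {subtypes}; cannot infer a "
            "gain constraint"
        )
    if len(subtypes) > 2:
        raise ReconciliationError(
            f"expected a two-subtype gene tree, got {subtypes}"
        )
    # the split node is the MRCA (in the gene tree) of the two subtype sets
    split = gene_tree.mrca(leaves)
    return result.node_map[split.label]
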