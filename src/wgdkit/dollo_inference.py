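"""Dollo parsimony: single gain, minimal independent losses.

The gain sits at the MRCA of all non-absent taxa (pseudogene cells count as
present: the lineage persists), unless an explicit ``gain_constraint``
forces an earlier node.  Losses are the maximal branches below the gain
whose subtrees contain no non-absent taxon; unknown states are free and are
resolved so as to minimize the loss count.  The resulting loss set is an
antichain covering every absent taxon, which is the exhaustive minimum
(verified against brute force in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set

from wgdkit.io_formats.matrix import PresenceMatrix, State
from wgdkit.io_formats.trees import Tree, TreeNode


class DolloError(ValueError):
    pass


@dataclass
class DolloResult:
    subtype: str
    gain_branch: str
    loss_branches: Set[str]
    n_losses: int
    ambiguous: bool = False


_NON_ABSENT = {State.PRESENT, State.PSEUDOGENE}


def _normalize(column: Dict[str, State]) -> Dict[str, State]:
    out = {}
    for taxon, state in column.items():
        if isinstance(state, str):
            state = State(state)
        out[taxon] = state
    return out


def _min_loss_solution(
    tree: Tree, column: Dict[str, State], gain_constraint: Optional[str]
):
    """Return (gain_node, loss_labels) for one minimal solution."""
    non_absent = [t for t, s in column.items() if s in _NON_ABSENT]
    if not non_absent:
        raise DolloError("column has no non-absent taxon")
    mrca = tree.mrca(non_absent)
    if gain_constraint is not None:
        if not tree.is_ancestor(gain_constraint, mrca.label):
            raise DolloError(
                f"gain_constraint {gain_constraint!r} is not an ancestor of all "
                f"non-absent taxa (their MRCA is {mrca.label!r})"
            )
        gain = tree.node(gain_constraint)
    else:
        gain = mrca

    # per-node: does the subtree contain any non-absent leaf?
    has_presence: Dict[str, bool] = {}
    for node in gain.postorder():
        if node.is_leaf:
            has_presence[node.label] = column.get(node.label) in _NON_ABSENT
        else:
            has_presence[node.label] = any(
                has_presence[c.label] for c in node.children
            )

    losses: Set[str] = set()
    for leaf in gain.leaves():
        if column.get(leaf.label) != State.ABSENT:
            continue
        # walk up to the maximal presence-free ancestor strictly below gain
        node: TreeNode = leaf
        while node.parent is not gain and not has_presence[node.parent.label]:
            node = node.parent
        losses.add(node.label)
    return gain, losses


def dollo_reconstruct(
    tree: Tree,
    column: Dict[str, State],
    gain_constraint: Optional[str] = None,
    subtype: str = "",
) -> DolloResult:
    """Reconstruct gain branch and minimal loss branches for one character."""
    column = _normalize(column)
    gain, losses = _min_loss_solution(tree, column, gain_constraint)
    n = len(losses)

    # Ambiguity: an unknown taxon admits multiple minimal solutions when
    # forcing it present vs absent yields the same minimal loss count but
    # different reconstructions.
    ambiguous = False
    for taxon, state in column.items():
        if state != State.UNKNOWN:
            continue
        alt: List[tuple] = []
        for forced in (State.PRESENT, State.ABSENT):
            col2 = dict(column)
            col2[taxon] = forced
            try:
                _, l2 = _min_loss_solution(tree, col2, gain_constraint)
            except DolloError:
                continue
            alt.append((len(l2), frozenset(l2)))
        if len(alt) == 2 and alt[0][0] == alt[1][0] and alt[0][1] != alt[1][1]:
            ambiguous = True
            break

    return DolloResult(
        subtype=subtype,
        gain_branch=gain.label,
        loss_branches=losses,
        n_losses=n,
        ambiguous=ambiguous,
    )


def count_independent_losses(
    tree: Tree, column: Dict[str, State], gain_constraint: Optional[str] = None
) -> int:
    return dollo_reconstruct(tree, column, gain_constraint).n_losses


def dollo_all(
    tree: Tree,
    matrix: PresenceMatrix,
    constraints: Optional[Dict[str, str]] = None,
) -> List[DolloResult]:
    """Run Dollo reconstruction per matrix row; failures propagate per row."""
    constraints = constraints or {}
    results: List[DolloResult] = []
    for subtype in matrix.subtypes:
        column = matrix.row(subtype)
        try:
            res = dollo_reconstruct(
                tree, column, constraints.get(subtype), subtype=subtype
            )
        except DolloError as exc:
            res = DolloResult(
                subtype=subtype, gain_branch=f"ERROR: {exc}",
                loss_branches=set(), n_losses=-1,
            )
        results.append(res)
    return results
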