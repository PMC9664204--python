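"""Propagate an event history along a species tree into per-node repertoires.

This is the executable form of the evolutionary scenario: whole-genome
duplications double every coding lineage on their branch, local duplications
insert named copies, losses remove a lineage from that branch's subtree
only, and pseudogenizations flip a lineage's status.  Children inherit the
parent's post-event repertoire, so an event is local to its branch's
subtree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

from wgdkit.io_formats.events import Event, EventHistory
from wgdkit.io_formats.matrix import PresenceMatrix, State
from wgdkit.io_formats.trees import Tree


class PropagationError(ValueError):
    """An event targeted a lineage that does not exist on its branch."""


@dataclass(frozen=True)
class Lineage:
    """One gene lineage in a repertoire.

    ``provenance`` records the duplication steps that created the lineage:
    a tuple of ``(kind, tag_or_branch, copy_index, parent_name)`` entries,
    used by the nomenclature rules.
    """

    name: str
    subtype: str
    status: str = "coding"
    provenance: Tuple[Tuple[str, str, int, str], ...] = ()

    @property
    def is_coding(self) -> bool:
        return self.status == "coding"


class Repertoire:
    """Node label -> ordered list of lineages; plus name aliases."""

    def __init__(self):
        self._nodes: Dict[str, List[Lineage]] = {}
        self.aliases: Dict[str, str] = {}

    def set(self, node: str, lineages: Iterable[Lineage]) -> None:
        lst = list(lineages)
        names = [l.name for l in lst]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PropagationError(f"duplicate lineage names at {node!r}: {dupes}")
        self._nodes[node] = lst

    def at(self, node: str) -> List[Lineage]:
        try:
            return list(self._nodes[node])
        except KeyError:
            raise KeyError(f"no repertoire recorded for node {node!r}") from None

    def nodes(self) -> List[str]:
        return list(self._nodes)

    def __contains__(self, node: str) -> bool:
        return node in self._nodes


@dataclass
class NomenclatureScheme:
    """Naming rules for duplication products.

    ``wgd_suffixes`` maps a WGD tag to the ordered suffixes its two copies
    receive (e.g. 3R -> a/b, 4R -> α/β).  ``dup_prefixes`` maps a lineage
    prefix key (referenced by events via ``name_rule: "prefix:<key>"``) to
    itself; serial duplicates become ``<prefix><base>-<k>`` with the
    original as ``-1``.  ``aliases`` records alternative community names.
    """

    wgd_suffixes: Dict[str, List[str]] = field(
        default_factory=lambda: {"3R": ["a", "b"], "4R": ["α", "β"]}
    )
    dup_prefixes: Dict[str, str] = field(
        default_factory=lambda: {
            "m": "mammal",
            "sau": "sauropsid",
            "am": "amphibian",
            "ch": "chondrichthyan",
            "po": "Polypteridae",
            "cy": "cyclostome",
        }
    )
    aliases: Dict[str, str] = field(default_factory=lambda: {"mTRPV5-2": "TRPV6"})


DEFAULT_SCHEME = NomenclatureScheme()


def _apply_wgd(lineages: List[Lineage], event: Event,
               scheme: NomenclatureScheme) -> List[Lineage]:
    out: List[Lineage] = []
    suffixes = scheme.wgd_suffixes.get(event.tag or "", None)
    for lin in lineages:
        if not lin.is_coding:
            out.append(lin)  # pseudogenes do not produce functional copies
            continue
        if lin.name in event.renames:
            names = event.renames[lin.name]
            if len(names) != 2:
                raise PropagationError(
                    f"wgd rename of {lin.name!r} must list exactly 2 names"
                )
        elif suffixes is not None:
            names = [lin.name + suffixes[0], lin.name + suffixes[1]]
        else:
            names = [lin.name, f"{lin.name}.{event.tag or 'wgd'}2"]
        for i, name in enumerate(names):
            out.append(
                Lineage(
                    name=name,
                    subtype=event.subtypes.get(name, lin.subtype),
                    status=lin.status,
                    provenance=lin.provenance
                    + (("wgd", event.tag or "wgd", i, lin.name),),
                )
            )
    return out


def _apply_local_duplication(lineages: List[Lineage], event: Event,
                             branch: str) -> List[Lineage]:
    idx = next((i for i, l in enumerate(lineages) if l.name == event.target), None)
    if idx is None:
        raise PropagationError(
            f"local_duplication on branch {branch!r}: no lineage {event.target!r}"
        )
    parent = lineages[idx]
    out = list(lineages)
    if event.rename_target:
        out[idx] = replace(parent, name=event.rename_target,
                           subtype=event.subtypes.get(event.rename_target,
                                                      parent.subtype))
    if event.new_names:
        if len(event.new_names) != event.copies:
            raise PropagationError(
                f"local_duplication on {branch!r}: {event.copies} copies but "
                f"{len(event.new_names)} new_names"
            )
        names = list(event.new_names)
    else:
        names = [f"{parent.name}.d{k + 1}" for k in range(event.copies)]
    copies = [
        Lineage(
            name=name,
            subtype=event.subtypes.get(name, parent.subtype),
            status=parent.status,
            provenance=parent.provenance + (("dup", branch, k + 1, parent.name),),
        )
        for k, name in enumerate(names)
    ]
    # tandem copies sit next to their parent
    return out[: idx + 1] + copies + out[idx + 1:]


def _apply_event(lineages: List[Lineage], event: Event, branch: str,
                 scheme: NomenclatureScheme) -> List[Lineage]:
    if event.kind == "wgd":
        return _apply_wgd(lineages, event, scheme)
    if event.kind == "local_duplication":
        return _apply_local_duplication(lineages, event, branch)
    idx = next((i for i, l in enumerate(lineages) if l.name == event.target), None)
    if idx is None:
        raise PropagationError(
            f"{event.kind} on branch {branch!r}: no lineage {event.target!r}"
        )
    if event.kind == "loss":
        return lineages[:idx] + lineages[idx + 1:]
    # pseudogenization
    out = list(lineages)
    out[idx] = replace(out[idx], status="pseudogene")
    return out


def propagate(
    species_tree: Tree,
    history: EventHistory,
    root_repertoire: Optional[List[Lineage]] = None,
    scheme: NomenclatureScheme = DEFAULT_SCHEME,
) -> Repertoire:
    """Apply the history preorder along the tree; returns all node repertoires.

    The repertoire recorded at each node is the state *after* the events on
    the branch leading into it.  The root branch is addressable by the root
    label.
    """
    history.validate_against(species_tree)
    if root_repertoire is None:
        root_repertoire = [
            Lineage(name=d["name"], subtype=d.get("subtype", d["name"]))
            for d in history.root_repertoire
        ]
    if not root_repertoire:
        raise PropagationError("root repertoire is empty")

    repertoire = Repertoire()
    repertoire.aliases = dict(scheme.aliases)

    def visit(node, incoming: List[Lineage]) -> None:
        state = list(incoming)
        for event in history.on_branch(node.label):
            state = _apply_event(state, event, node.label, scheme)
        repertoire.set(node.label, state)
        for child in node.children:
            visit(child, state)

    visit(species_tree.root, root_repertoire)
    return repertoire


def count_by_subtype(
    repertoire: Repertoire,
    node: str,
    subtype_filter: Optional[str] = None,
    include_pseudogenes: bool = False,
) -> int:
    """Count lineages at a node, optionally restricted to one subtype.

    Pseudogenes are excluded unless flagged, matching the convention that
    published per-species totals count intact genes only.
    """
    lineages = repertoire.at(node)
    n = 0
    for lin in lineages:
        if subtype_filter is not None and lin.subtype != subtype_filter:
            continue
        if not lin.is_coding and not include_pseudogenes:
            continue
        n += 1
    return n


def apply_nomenclature(
    repertoire: Repertoire, scheme: NomenclatureScheme = DEFAULT_SCHEME
) -> Repertoire:
    """Rename auto-named duplication products according to the scheme.

    WGD copies whose tag has registered suffixes get ``<parent><suffix>``;
    copies of already-renamed lineages are untouched.  Scheme aliases are
    attached to the result.  Name collisions raise
    :class:`PropagationError` (transforms must stay injective per node).
    """
    out = Repertoire()
    out.aliases = dict(scheme.aliases)
    for node in repertoire.nodes():
        renamed: List[Lineage] = []
        for lin in repertoire.at(node):
            name = lin.name
            if lin.provenance:
                kind, tag, idx, parent = lin.provenance[-1]
                if kind == "wgd" and tag in scheme.wgd_suffixes:
                    autogen = (name == parent
                               or name == f"{parent}.{tag}2"
                               or name == f"{parent}.wgd2")
                    if autogen:
                        name = parent + scheme.wgd_suffixes[tag][idx]
            renamed.append(replace(lin, name=name))
        out.set(node, renamed)  # raises on collisions
    return out


@dataclass(frozen=True)
class Discrepancy:
    subtype: str
    species: str
    kind: str        # predicted_only | observed_only | status_mismatch
    predicted: str
    observed: str


def _predicted_state(lineages: List[Lineage], label: str) -> State:
    hits = [l for l in lineages if l.name == label or l.subtype == label]
    if any(l.is_coding for l in hits):
        return State.PRESENT
    if hits:
        return State.PSEUDOGENE
    return State.ABSENT


def diff_vs_observed(
    predicted: Repertoire, observed: PresenceMatrix, leaf_species: List[str]
) -> Dict[str, object]:
    """Compare a propagated repertoire against an observed presence matrix.

    Matrix rows may name either a subtype (``TRPV5``) or a specific lineage
    (``sauTRPV5-2``).  Unknown cells match anything.  Species present in
    only one input are listed as uncovered, never an error.
    """
    discrepancies: List[Discrepancy] = []
    shared = [sp for sp in observed.species if sp in predicted and sp in leaf_species]
    uncovered_observed = [sp for sp in observed.species if sp not in shared]
    uncovered_predicted = [sp for sp in leaf_species
                           if sp in predicted and sp not in observed.species]
    for subtype in observed.subtypes:
        row = observed.row(subtype)
        for sp in shared:
            obs = row[sp]
            if obs == State.UNKNOWN:
                continue
            pred = _predicted_state(predicted.at(sp), subtype)
            if pred == obs:
                continue
            if pred == State.ABSENT:
                kind = "observed_only"
            elif obs == State.ABSENT:
                kind = "predicted_only"
            else:
                kind = "status_mismatch"
            discrepancies.append(
                Discrepancy(subtype, sp, kind, pred.value, obs.value)
            )
    return {
        "discrepancies": discrepancies,
        "uncovered_observed": uncovered_observed,
        "uncovered_predicted": uncovered_predicted,
    }
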