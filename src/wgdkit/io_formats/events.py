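"""Ordered per-branch evolutionary event histories (YAML/JSON).

An event lives on the species-tree branch identified by its child node's
label; events listed on the same branch are applied in file order.  WGD
events may carry explicit copy renames (the curated fixtures do); local
duplications may either name their copies explicitly or defer to a
nomenclature scheme via ``name_rule``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import yaml

from wgdkit.io_formats.tables import ValidationError
from wgdkit.io_formats.trees import Tree

EVENT_KINDS = {"wgd", "local_duplication", "loss", "pseudogenization"}


@dataclass
class Event:
    branch: str
    kind: str
    target: Optional[str] = None           # lineage name (non-WGD kinds)
    copies: int = 1                        # extra copies (local_duplication)
    tag: Optional[str] = None              # WGD tag, e.g. "3R"
    renames: Dict[str, List[str]] = field(default_factory=dict)   # wgd copy names
    rename_target: Optional[str] = None    # serial-duplication rename of original
    new_names: List[str] = field(default_factory=list)            # names for copies
    subtypes: Dict[str, str] = field(default_factory=dict)        # name -> subtype
    name_rule: Optional[str] = None        # nomenclature-scheme reference

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.kind == "local_duplication" and self.copies < 1:
            raise ValidationError(
                f"local_duplication on {self.branch!r}: copies must be >= 1, "
                f"got {self.copies}"
            )
        if self.kind in {"loss", "pseudogenization", "local_duplication"} and not self.target:
            raise ValidationError(f"{self.kind} event on {self.branch!r} needs a target")


@dataclass
class EventHistory:
    events: List[Event]
    wgd_tags: Dict[str, str] = field(default_factory=dict)
    root_repertoire: List[Dict[str, str]] = field(default_factory=list)

    def on_branch(self, branch: str) -> List[Event]:
        return [e for e in self.events if e.branch == branch]

    def wgd_events(self) -> List[Event]:
        return [e for e in self.events if e.kind == "wgd"]

    def validate_against(self, tree: Tree) -> None:
        missing = sorted({e.branch for e in self.events if e.branch not in tree})
        if missing:
            raise ValidationError(f"events reference unknown branches: {missing}")
        for branch in self.wgd_tags:
            if branch not in tree:
                raise ValidationError(f"wgd tag on unknown branch {branch!r}")


def _event_from_dict(d: dict) -> Event:
    known = {
        "branch", "kind", "target", "copies", "tag", "renames",
        "rename_target", "new_names", "subtypes", "name_rule",
    }
    extra = set(d) - known
    if extra:
        raise ValidationError(f"unknown event fields {sorted(extra)}")
    return Event(**d)


def read_event_history(path, tree: Optional[Tree] = None) -> EventHistory:
    """Read an event history from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "events" not in data:
        raise ValidationError(f"{path}: expected a mapping with an 'events' list")
    events = [_event_from_dict(d) for d in data["events"]]
    history = EventHistory(
        events=events,
        wgd_tags=dict(data.get("wgd_tags", {})),
        root_repertoire=list(data.get("root_repertoire", [])),
    )
    if tree is not None:
        history.validate_against(tree)
    return history


def write_event_history(history: EventHistory, path) -> None:
    data = {
        "wgd_tags": dict(history.wgd_tags),
        "root_repertoire": list(history.root_repertoire),
        "events": [],
    }
    for e in history.events:
        d: dict = {"branch": e.branch, "kind": e.kind}
        if e.target:
            d["target"] = e.target
        if e.kind == "local_duplication":
            d["copies"] = e.copies
        if e.tag:
            d["tag"] = e.tag
        if e.renames:
            d["renames"] = {k: list(v) for k, v in e.renames.items()}
        if e.rename_target:
            d["rename_target"] = e.rename_target
        if e.new_names:
            d["new_names"] = list(e.new_names)
        if e.subtypes:
            d["subtypes"] = dict(e.subtypes)
        if e.name_rule:
            d["name_rule"] = e.name_rule
        data["events"].append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)
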