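"""Packaged curated fixtures: species tree, event history, presence matrix.

The species tree covers the vertebrate species analyzed in the TRPV study,
with named clades usable as event branches.  The event history is the
machine-readable evolutionary scenario; the presence matrix records the
observed per-species repertoire.  All three are plain-text resources.
"""

from __future__ import annotations

from importlib import resources

from wgdkit.io_formats.events import EventHistory, read_event_history
from wgdkit.io_formats.matrix import PresenceMatrix, read_presence_matrix
from wgdkit.io_formats.trees import Tree, parse_newick

__all__ = ["species_tree", "event_history", "presence_matrix", "fixture_path"]


def fixture_path(name: str):
    return resources.files(__package__).joinpath(name)


def species_tree() -> Tree:
    """The fixture species tree, with WGD tags applied from the history file."""
    text = fixture_path("species_tree.nwk").read_text()
    tree = parse_newick(text)
    tree.wgd_tags = dict(event_history(tree=None).wgd_tags)
    return tree


def event_history(tree: Tree | None = None) -> EventHistory:
    with resources.as_file(fixture_path("event_history.yaml")) as path:
        return read_event_history(path, tree=tree)


def presence_matrix() -> PresenceMatrix:
    with resources.as_file(fixture_path("presence_matrix.tsv")) as path:
        return read_presence_matrix(path)
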