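"""Rooted trees with named nodes, MRCA queries and Newick round-tripping.

Newick parsing is delegated to :mod:`dendropy`; the parsed structure is
converted into a lightweight :class:`Tree` whose nodes carry parent
pointers, which is what every downstream algorithm (reconciliation, Dollo,
scenario propagation) actually needs.  Branches are identified by the label
of their child node; the root branch is addressable by the root label.
Unlabeled internal nodes receive deterministic preorder auto-labels so that
event files remain stable across runs.
"""

from __future__ import annotations

import io
from typing import Dict, Iterator, List, Optional, Sequence

import dendropy


class ParseError(ValueError):
    """Raised when a Newick string cannot be parsed or violates invariants."""


class TreeNode:
    __slots__ = ("label", "parent", "children", "length")

    def __init__(self, label: str, length: Optional[float] = None):
        self.label = label
        self.parent: Optional[TreeNode] = None
        self.children: List[TreeNode] = []
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out: List[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> List["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def ancestors(self, include_self: bool = False) -> Iterator["TreeNode"]:
        node = self if include_self else self.parent
        while node is not None:
            yield node
            node = node.parent

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.label!r})"


class Tree:
    """A rooted tree with unique node labels.

    ``wgd_tags`` maps branch labels (child-node labels) to WGD tags such as
    ``"1R"``/``"3R"``; they are carried here so that reconciliation timing
    and the simulator can share one annotated species tree.
    """

    def __init__(self, root: TreeNode, wgd_tags: Optional[Dict[str, str]] = None):
        self.root = root
        self.wgd_tags: Dict[str, str] = dict(wgd_tags or {})
        self._index: Dict[str, TreeNode] = {}
        self._reindex()

    def _reindex(self) -> None:
        self._index.clear()
        for node in self.root.preorder():
            if node.label in self._index:
                raise ParseError(f"duplicate node label {node.label!r}")
            self._index[node.label] = node

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def node(self, label: str) -> TreeNode:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"no node labeled {label!r} in tree") from None

    def nodes(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def leaf_labels(self) -> List[str]:
        return [n.label for n in self.root.leaves()]

    def is_binary(self) -> bool:
        """True when every internal node has at most two children.

        Unary (pass-through) nodes are tolerated: they carry WGD tags on
        stem branches and never create reconciliation ambiguity.
        """
        return all(len(n.children) <= 2 for n in self.nodes())

    def depth(self, label: str) -> int:
        return sum(1 for _ in self.node(label).ancestors())

    def mrca(self, labels: Sequence[str]) -> TreeNode:
        if not labels:
            raise ValueError("mrca of empty label set")
        nodes = [self.node(lbl) for lbl in labels]
        paths = []
        for n in nodes:
            path = list(n.ancestors(include_self=True))
            path.reverse()
            paths.append(path)
        mrca = None
        for tier in zip(*paths):
            first = tier[0]
            if all(t is first for t in tier):
                mrca = first
            else:
                break
        assert mrca is not None  # all nodes share the root
        return mrca

    def is_ancestor(self, anc_label: str, desc_label: str) -> bool:
        anc = self.node(anc_label)
        return any(n is anc for n in self.node(desc_label).ancestors(include_self=True))

    def subtree_leaves(self, label: str) -> List[str]:
        return [n.label for n in self.node(label).leaves()]

    def copy(self) -> "Tree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root), wgd_tags=self.wgd_tags)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(n_leaves={len(self.root.leaves())})"


def _auto_label_taken(counter: int) -> str:
    return f"node{counter}"


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Branch lengths are parsed and stored but ignored by every algorithm.
    Unlabeled internal nodes are auto-labeled ``node<i>`` by preorder index.
    Duplicate leaf labels and malformed input raise :class:`ParseError`
    naming the offending token.
    """
    text = text.strip()
    if not text:
        raise ParseError("empty Newick string")
    if text.count("(") != text.count(")"):
        raise ParseError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"malformed Newick: {exc}") from exc

    seen: Dict[str, int] = {}
    counter = 0

    def convert(dnode) -> TreeNode:
        nonlocal counter
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        else:
            label = _auto_label_taken(counter)
        counter += 1
        if label in seen:
            raise ParseError(f"duplicate node label {label!r}")
        seen[label] = 1
        node = TreeNode(label, dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return Tree(convert(dtree.seed_node))


def write_newick(tree: Tree, include_lengths: bool = False) -> str:
    """Serialize a tree to Newick; inverse of :func:`parse_newick`."""
    out = io.StringIO()

    def emit(node: TreeNode) -> None:
        if node.children:
            out.write("(")
            for i, child in enumerate(node.children):
                if i:
                    out.write(",")
                emit(child)
            out.write(")")
        out.write(_quote(node.label))
        if include_lengths and node.length is not None:
            out.write(f":{node.length}")

    emit(tree.root)
    out.write(";")
    return out.getvalue()


_NEWICK_UNSAFE = set("()[]{}/\\,;:=*'\"`+<> ")


def _quote(label: str) -> str:
    if any(c in _NEWICK_UNSAFE for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label
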