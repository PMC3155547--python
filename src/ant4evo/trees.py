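"""Phylogenetic trees with per-branch class labels.

Trees carry two quantities per branch: a length (expected substitutions per
codon site) and an integer class id used to assign branch-specific omega
parameters in codon branch models. The Newick dialect follows PAML: an
optional ``#k`` mark after the branch length places that branch in class k;
unmarked branches default to class 0.
"""
from __future__ import annotations

import re
from typing import Callable, Iterator


class TreeError(ValueError):
    """Malformed Newick input or invalid tree structure."""


class Node:
    __slots__ = ("name", "length", "cls", "parent", "children", "id")

    def __init__(self, name: str = "", length: float = 0.0, cls: int = 0):
        self.name = name
        self.length = length
        self.cls = cls
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.id: str = ""

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        kind = "leaf" if self.is_leaf else "internal"
        return f"<Node {self.id or self.name!r} ({kind}) t={self.length} #{self.cls}>"


class Tree:
    """Rooted tree over :class:`Node`; each non-root node owns its parent edge.

    Branch ids are stable: a leaf's id is its label, an internal node's id is
    ``node<i>`` numbered in preorder.
    """

    def __init__(self, root: Node):
        self.root = root
        self._assign_ids()
        names = [n.name for n in self.leaves()]
        dupes = {x for x in names if names.count(x) > 1}
        if dupes:
            raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")
        if not all(x for x in names):
            raise TreeError("unnamed leaf")
        for node in self.preorder():
            if node.length < 0 or not _finite(node.length):
                raise TreeError(f"invalid branch length {node.length!r} on {node.id!r}")

    def _assign_ids(self) -> None:
        i = 0
        for node in self.preorder():
            if node.is_leaf:
                node.id = node.name
            else:
                node.id = f"node{i}"
                i += 1

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[Node]:
        """All nodes except the root; each represents its edge to the parent."""
        return [n for n in self.preorder() if n.parent is not None]

    @property
    def n_classes(self) -> int:
        ids = sorted({b.cls for b in self.branches()})
        if ids != list(range(len(ids))):
            raise TreeError(f"branch class ids not contiguous from 0: {ids}")
        return len(ids)

    def find(self, name: str) -> Node:
        for node in self.preorder():
            if node.name == name or node.id == name:
                return node
        raise TreeError(f"no node named {name!r}")

    def mrca(self, names: list[str]) -> Node:
        paths = []
        for name in names:
            node = self.find(name)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = self.root
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        return mrca

    def clade_nodes(self, node: Node) -> list[Node]:
        """node and all of its descendants."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            new = Node(node.name, node.length, node.cls)
            for child in node.children:
                new.add(rec(child))
            return new

        return Tree(rec(self.root))

    def with_classes(self, assign: Callable[[Node], int]) -> "Tree":
        """Copy of the tree with branch classes reassigned by ``assign(node)``."""
        new = self.copy()
        for node in new.branches():
            node.cls = int(assign(node))
        return new

    def with_lengths(self, lengths: dict[str, float]) -> "Tree":
        new = self.copy()
        for node in new.branches():
            node.length = float(lengths[node.id])
        return new

    def __str__(self) -> str:
        return write_newick(self)


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


_TOKEN = re.compile(r"\s*([(),;:]|#\s*\d+|[^\s(),;:#]+)")


def parse_newick(text: str) -> Tree:
    """Parse a Newick string with optional PAML-style ``#k`` branch-class marks.

    ``#k`` may follow the branch length (or the label when no length is
    given); unmarked branches are class 0. Raises :class:`TreeError` naming
    the offending token on malformed input.
    """
    tokens = _TOKEN.findall(text)
    if not tokens:
        raise TreeError("empty Newick string")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise TreeError("unexpected end of Newick string")
        tok = tokens[pos]
        pos += 1
        return tok

    def subtree() -> Node:
        node = Node()
        if peek() == "(":
            take()
            node.add(subtree())
            while peek() == ",":
                take()
                node.add(subtree())
            if peek() != ")":
                raise TreeError(f"unbalanced parentheses near token {peek()!r}")
            take()
            if peek() not in ("(", ")", ",", ";", ":", None) and not str(peek()).startswith("#"):
                node.name = take()
        else:
            tok = take()
            if tok in ("(", ")", ",", ";", ":") or tok.startswith("#"):
                raise TreeError(f"expected a leaf label, found {tok!r}")
            node.name = tok
        if peek() == ":":
            take()
            tok = take()
            try:
                node.length = float(tok)
            except ValueError:
                raise TreeError(f"invalid branch length token {tok!r}") from None
            if node.length < 0:
                raise TreeError(f"negative branch length {tok!r}")
        tok = peek()
        if tok is not None and tok.startswith("#"):
            take()
            node.cls = int(tok[1:].strip())
        return node

    root = subtree()
    if peek() != ";":
        raise TreeError(f"expected ';' at end, found {peek()!r}")
    take()
    if peek() is not None:
        raise TreeError(f"trailing content after ';': {peek()!r}")
    return Tree(root)


def write_newick(tree: Tree, decimals: int = 6, classes: bool = True) -> str:
    """Serialize, writing ``#k`` marks for branches with class != 0."""

    def rec(node: Node) -> str:
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(rec(c) for c in node.children) + ")" + node.name
        if node.parent is None:
            return body
        s = f"{body}:{node.length:.{decimals}f}"
        if classes and node.cls != 0:
            s += f" #{node.cls}"
        return s

    return rec(tree.root) + ";"


def patristic_distance(tree: Tree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    a, b = tree.find(leaf_a), tree.find(leaf_b)
    if not a.is_leaf or not b.is_leaf:
        raise TreeError("patristic distance is defined between leaves")

    def path_up(node: Node) -> list[Node]:
        out = [node]
        while out[-1].parent is not None:
            out.append(out[-1].parent)
        return out

    pa, pb = path_up(a), path_up(b)
    ancestors_a = {id(n): i for i, n in enumerate(pa)}
    for j, n in enumerate(pb):
        if id(n) in ancestors_a:
            i = ancestors_a[id(n)]
            return sum(x.length for x in pa[:i]) + sum(x.length for x in pb[:j])
    raise TreeError("leaves do not share an ancestor")  # pragma: no cover
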