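"""Phylogenetic trees with per-branch class labels.

Branch (two-ratio) and branch-site codon models partition branches into
classes: 0 = background, 1 = foreground. The field convention for marking
foreground branches in newick is a ``#1`` tag after a node (PAML style), e.g.::

    (Ylip,((Egos,(Klac,(Lklu,Lwal))),(Dbru #1,Dano #1) #1));

``#1`` after a leaf labels its terminal branch; after a closing parenthesis it
labels the stem branch of that clade. These tags are not standard newick, so
this module carries its own small recursive-descent parser and writer that
round-trip them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # length of the branch above this node (root: ignored)
    branch_class: int = 0  # class of the branch above this node
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self


class BranchClassTree:
    """Rooted tree storage; likelihoods under reversible models are
    root-invariant, so the stored rooting is a convenience only."""

    def __init__(self, root: TreeNode):
        self.root = root
        for node in root.postorder():
            for ch in node.children:
                ch.parent = node

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "BranchClassTree":
        parser = _NewickParser(text)
        root = parser.parse()
        return cls(root)

    def copy(self) -> "BranchClassTree":
        def _copy(node: TreeNode) -> TreeNode:
            return TreeNode(
                name=node.name,
                length=node.length,
                branch_class=node.branch_class,
                children=[_copy(c) for c in node.children],
            )

        return BranchClassTree(_copy(self.root))

    # -- queries ------------------------------------------------------------

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[TreeNode]:
        """All non-root nodes; each represents the branch above it."""
        return [n for n in self.root.postorder() if n is not self.root]

    def branch_classes(self) -> set[int]:
        return {b.branch_class for b in self.branches()}

    def set_branch_lengths(self, lengths: dict[int, float] | list[float]) -> None:
        br = self.branches()
        if isinstance(lengths, dict):
            for i, b in enumerate(br):
                b.length = lengths[i]
        else:
            if len(lengths) != len(br):
                raise ValueError("length vector size mismatch")
            for b, t in zip(br, lengths):
                b.length = float(t)

    def branch_lengths(self) -> list[float]:
        return [b.length for b in self.branches()]

    def scale_lengths(self, factor: float) -> None:
        for b in self.branches():
            b.length *= factor

    # -- rerooting ----------------------------------------------------------

    def rerooted_at(self, name: str) -> "BranchClassTree":
        """Return a copy rerooted so that the named internal node (or the
        parent of the named leaf) is the new root. The unrooted branch set,
        lengths and classes are preserved; a degree-2 former root whose two
        incident branches share a class is spliced out with lengths summed."""
        tree = self.copy()
        target = None
        for node in tree.root.postorder():
            if node.name == name:
                target = node
                break
        if target is None:
            raise ValueError(f"no node named {name!r}")
        if target.is_leaf:
            target = target.parent
        if target is tree.root:
            return tree
        # Reverse parent links on the path target -> old root.
        path = []
        node = target
        while node is not None:
            path.append(node)
            node = node.parent
        for child, parent in zip(path, path[1:]):
            parent.children.remove(child)
            child.children.append(parent)
            parent.length, parent.branch_class = child.length, child.branch_class
            parent.parent = child
        target.parent = None
        target.length = 0.0
        old_root = path[-1]
        if len(old_root.children) == 1 and old_root.parent is not None:
            (only,) = old_root.children
            if only.branch_class == old_root.branch_class:
                grand = old_root.parent
                idx = grand.children.index(old_root)
                only.length += old_root.length
                only.parent = grand
                grand.children[idx] = only
        return BranchClassTree(target)

    # -- newick -------------------------------------------------------------

    def to_newick(self, labels: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    s += node.name
            if node is not self.root:
                s += f":{node.length:.6g}"
                if labels and node.branch_class != 0:
                    s += f" #{node.branch_class}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"BranchClassTree({self.to_newick()})"


_TOKEN = re.compile(r"\s*([(),;]|#\d+|:[^\s(),;#]+|[^\s(),;:#]+)")


class _NewickParser:
    def __init__(self, text: str):
        self.tokens = _TOKEN.findall(text)
        self.pos = 0

    def _peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise ValueError("unexpected end of newick string")
        self.pos += 1
        return tok

    def parse(self) -> TreeNode:
        node = self._node()
        if self._peek() == ";":
            self._next()
        if self._peek() is not None:
            raise ValueError(f"trailing tokens after ';': {self.tokens[self.pos:]}")
        return node

    def _node(self) -> TreeNode:
        node = TreeNode()
        if self._peek() == "(":
            self._next()
            node.children.append(self._node())
            while self._peek() == ",":
                self._next()
                node.children.append(self._node())
            if self._next() != ")":
                raise ValueError("unbalanced parentheses in newick string")
            tok = self._peek()
            if tok is not None and not tok.startswith((":", "#")) and tok not in "(),;":
                node.name = self._next()
        else:
            tok = self._next()
            if tok in "(),;" or tok.startswith((":", "#")):
                raise ValueError(f"expected a taxon name, got {tok!r}")
            node.name = tok
        while self._peek() is not None and self._peek().startswith((":", "#")):
            tok = self._next()
            if tok.startswith(":"):
                node.length = float(tok[1:])
            else:
                node.branch_class = int(tok[1:])
        return node


#: Seven-taxon non-WGD yeast guide tree; the two Dekkera terminal branches and
#: their stem form the foreground class (#1).
GUIDE_TREE_NEWICK = (
    "(Ylipolytica,((Egossypii,(Klactis,(Lkluyveri,Lwaltii))),"
    "(Dbruxellensis #1,Danomala #1) #1));"
)


def guide_tree(branch_length: float = 0.2) -> BranchClassTree:
    """The fixed seven-species guide tree with uniform starting branch lengths."""
    tree = BranchClassTree.from_newick(GUIDE_TREE_NEWICK)
    for b in tree.branches():
        b.length = branch_length
    return tree
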