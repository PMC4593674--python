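"""Rooted phylogenies with branch lengths and a designated foreground branch.

Trees are read and written in Newick, including the ``#1`` branch-label
dialect used by codeml to mark the foreground branch of a branch-site test
(``(A,B)#1`` marks the branch subtending the clade; ``A#1`` marks a terminal
branch).  Internally the foreground mark is a structural flag on the node
whose parent edge is tested, so nothing downstream depends on label strings.

Trees are treated as rooted exactly as written: the focal branches of a
branch-site scan are directional (they lead to a specific ancestor), so the
orientation of the input tree is meaningful and preserved.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = ["TreeNode", "PhyloTree", "parse_newick", "tag_foreground", "prune_to_taxa"]


class TreeNode:
    """A node of a rooted tree; ``length`` is the length of its parent edge."""

    __slots__ = ("name", "length", "foreground", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 foreground: bool = False):
        self.name = name
        self.length = float(length)
        self.foreground = bool(foreground)
        self.children: list["TreeNode"] = []
        self.parent: "TreeNode | None" = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<TreeNode {self.name or '?'} {kind} t={self.length:g}{' #1' if self.foreground else ''}>"


class PhyloTree:
    """A rooted tree with non-negative branch lengths and foreground flags."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    # -- construction / validation ------------------------------------------------

    def _validate(self) -> None:
        names = [n.name for n in self.tips()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tip names in tree")
        if any(n.name is None for n in self.tips()):
            raise ValueError("unnamed tip in tree")
        for node in self.postorder():
            if node.length < 0 or node.length != node.length:
                raise ValueError(f"negative or non-finite branch length on {node!r}")
        if self.root.foreground:
            # the root has no parent edge, so a flag there is meaningless
            raise ValueError("root cannot carry a foreground flag")

    # -- traversal ----------------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    @property
    def tip_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.tips())

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def foreground_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.foreground]

    @property
    def has_foreground(self) -> bool:
        return bool(self.foreground_nodes())

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    # -- copying ------------------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length, node.foreground)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    # -- queries ------------------------------------------------------------------

    def find_tip(self, name: str) -> TreeNode:
        for tip in self.tips():
            if tip.name == name:
                return tip
        raise KeyError(f"tip {name!r} not in tree")

    def mrca(self, names: Sequence[str]) -> TreeNode:
        """Most recent common ancestor of the named tips."""
        names = set(names)
        if not names:
            raise ValueError("empty tip set")
        # count tips below each node; the MRCA is the deepest node covering all
        below: dict[TreeNode, set[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                below[node] = {node.name} if node.name in names else set()
            else:
                below[node] = set().union(*(below[c] for c in node.children))
        candidates = [n for n in self.postorder() if below[n] >= names]
        if not candidates:
            missing = names - set(self.tip_names)
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        # postorder yields descendants before ancestors; first cover is deepest
        return candidates[0]

    def clade_tip_names(self, node: TreeNode) -> set[str]:
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.add(n.name)
            stack.extend(n.children)
        return out

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths along the tip-to-tip path (test oracle helper)."""
        na, nb = self.find_tip(a), self.find_tip(b)

        def ancestors(n: TreeNode) -> list[TreeNode]:
            out = [n]
            while n.parent is not None:
                n = n.parent
                out.append(n)
            return out

        anc_a = ancestors(na)
        anc_b_set = set(map(id, ancestors(nb)))
        mrca = next(n for n in anc_a if id(n) in anc_b_set)
        dist = 0.0
        for start in (na, nb):
            n = start
            while n is not mrca:
                dist += n.length
                n = n.parent
        return dist

    # -- newick -------------------------------------------------------------------

    def newick(self) -> str:
        def render(node: TreeNode) -> str:
            tag = "#1" if node.foreground else ""
            if node.is_tip:
                return f"{node.name}{tag}:{node.length:.10g}"
            inner = ",".join(render(c) for c in node.children)
            label = node.name or ""
            if node.parent is None:
                return f"({inner}){label}{tag}"
            return f"({inner}){label}{tag}:{node.length:.10g}"

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree tips={self.n_tips} fg={len(self.foreground_nodes())}>"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string, honouring codeml-style ``#1`` foreground marks."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as err:
        raise ValueError(f"malformed Newick: {err}") from None

    def strip_tag(label: str | None) -> tuple[str | None, bool]:
        if label is None:
            return None, False
        if label.endswith("#1"):
            stripped = label[:-2] or None
            return stripped, True
        return label, False

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            raw = dnode.taxon.label if dnode.taxon is not None else dnode.label
            name, fg = strip_tag(raw)
            if name is None:
                raise ValueError("unnamed tip in Newick input")
        else:
            name, fg = strip_tag(dnode.label)
        node = TreeNode(name, dnode.edge.length or 0.0, fg)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def tag_foreground(tree: PhyloTree, clade_tips: Iterable[str]) -> PhyloTree:
    """Return a copy of ``tree`` with exactly one branch flagged foreground.

    ``clade_tips`` must name either a single tip (a terminal branch) or a
    monophyletic group, in which case the branch leading to its MRCA is
    flagged.  All pre-existing flags are cleared.
    """
    clade = set(clade_tips)
    if not clade:
        raise ValueError("empty clade definition")
    new = tree.copy()
    unknown = clade - set(new.tip_names)
    if unknown:
        raise KeyError(f"clade tips not in tree: {sorted(unknown)}")
    for node in new.postorder():
        node.foreground = False
    if len(clade) == 1:
        target = new.find_tip(next(iter(clade)))
    else:
        target = new.mrca(clade)
        subtended = new.clade_tip_names(target)
        if subtended != clade:
            raise ValueError(
                f"tips {sorted(clade)} are not monophyletic "
                f"(MRCA subtends {sorted(subtended)})"
            )
    if target.parent is None:
        raise ValueError("clade covers the whole tree; no parent branch to test")
    target.foreground = True
    return new


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Induced subtree on ``keep``, suppressing degree-2 nodes.

    Suppressed nodes have their branch length added to the surviving child's
    edge.  A foreground flag survives only while the flagged node itself
    survives; if the flagged node is removed or suppressed the returned tree
    simply has no foreground branch, which callers must treat as untestable.
    """
    keep = set(keep)
    present = keep & set(tree.tip_names)
    if len(present) < 3:
        raise ValueError(f"fewer than 3 tips would survive pruning ({len(present)})")

    def build(node: TreeNode) -> TreeNode | None:
        if node.is_tip:
            if node.name in present:
                return TreeNode(node.name, node.length, node.foreground)
            return None
        kept = [c for c in (build(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # suppress this degree-2 node: merge edge lengths, drop its flag
            child = kept[0]
            child.length += node.length
            return child
        new = TreeNode(node.name, node.length, node.foreground)
        for c in kept:
            new.add_child(c)
        return new

    root = build(tree.root)
    assert root is not None
    # collapse a unary chain at the root: the hanging edge is not part of the
    # induced subtree between surviving tips
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = 0.0
        root.foreground = False
    root.length = 0.0
    root.foreground = False
    return PhyloTree(root)
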