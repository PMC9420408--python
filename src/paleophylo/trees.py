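"""Rooted time trees with absolute node ages, and Newick/NEXUS I/O.

Two tree flavours share one node structure:

* :class:`TimeTree` — node ages in Ma before present are the primary
  representation; branch lengths (durations) are derived as
  ``parent.age - child.age``.  Every downstream stage (ancestral state
  reconstruction, lineage counting, tip grafting) reasons in absolute time.
* :class:`BranchLengthTree` — edge lengths in expected substitutions per
  site, with no age semantics (the non-clock tree used to derive the
  clock-rate prior).

Polytomies are allowed everywhere.  Label matching is exact and
case-sensitive; whitespace in labels is normalized to underscores on read.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "TimeTree",
    "BranchLengthTree",
    "TreeError",
    "read_newick",
    "read_nexus_trees",
    "write_newick",
    "read_tip_dates_csv",
]

#: tolerance (Ma) for tip-date / edge-length consistency on read
DEFAULT_AGE_TOL = 1e-6


class TreeError(ValueError):
    """Malformed tree input or an operation violating tree invariants."""


class Node:
    """One tree node. ``age`` is in Ma for time trees; ``length`` is the
    edge length above this node for branch-length trees."""

    __slots__ = ("label", "age", "length", "children", "parent", "id")

    def __init__(self, label=None, age=0.0, length=None):
        self.label: Optional[str] = label
        self.age: float = age
        self.length: Optional[float] = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.id: Optional[int] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "tip" if self.is_leaf else "node"
        return f"<{kind} {self.label or self.id} age={self.age:.4g}>"


class _BaseTree:
    def __init__(self, root: Node):
        self.root = root
        self.index_nodes()

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return [t.label for t in self.tips()]

    def node_for(self, label: str) -> Node:
        for n in self.preorder():
            if n.label == label:
                return n
        raise TreeError(f"unknown label: {label!r}")

    def index_nodes(self) -> None:
        """Assign stable integer ids in preorder (root = 0)."""
        for i, node in enumerate(self.preorder()):
            node.id = i

    def branch_iter(self) -> Iterator[tuple[Node, Node]]:
        """Yield (parent, child) pairs for every edge."""
        for node in self.preorder():
            for child in node.children:
                yield node, child

    def mrca(self, taxa: Iterable[str]) -> Node:
        labels = list(taxa)
        if not labels:
            raise TreeError("mrca of an empty taxon set")
        paths = []
        for lab in labels:
            node = self.node_for(lab)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = None
        for level in zip(*paths):
            first = level[0]
            if all(n is first for n in level):
                mrca = first
            else:
                break
        return mrca

    def __len__(self) -> int:
        return sum(1 for _ in self.preorder())


class TimeTree(_BaseTree):
    """Rooted tree whose nodes carry absolute ages (Ma before present)."""

    def validate(self, tol: float = 1e-9) -> None:
        for parent, child in self.branch_iter():
            if child.age > parent.age + tol:
                raise TreeError(
                    f"child {child.label or child.id} (age {child.age}) older "
                    f"than parent (age {parent.age})"
                )

    @property
    def root_age(self) -> float:
        return self.root.age

    def branch_duration(self, child: Node) -> float:
        if child.parent is None:
            raise TreeError("root has no branch")
        return child.parent.age - child.age

    def path_length(self, a: str, b: str) -> float:
        """Patristic distance in Ma between two tips."""
        na, nb = self.node_for(a), self.node_for(b)
        m = self.mrca([a, b])
        return (m.age - na.age) + (m.age - nb.age)

    def copy(self) -> "TimeTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.age)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return TimeTree(clone(self.root))

    # -- pruning / grafting ------------------------------------------------

    def prune_taxa(self, keep: Iterable[str]) -> "TimeTree":
        """Induced subtree on ``keep``: degree-2 internal nodes are
        suppressed and retained node ages are unchanged.  The new root is
        the MRCA of the kept tips."""
        keep = set(keep)
        if not keep:
            raise TreeError("keep set is empty")
        known = set(self.taxa)
        unknown = keep - known
        if unknown:
            raise TreeError(f"unknown labels in keep set: {sorted(unknown)}")

        def build(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if node.label in keep:
                    return Node(node.label, node.age)
                return None
            kept_children = [c for kid in node.children if (c := build(kid))]
            if not kept_children:
                return None
            if len(kept_children) == 1:
                return kept_children[0]
            new = Node(node.label, node.age)
            for c in kept_children:
                new.add_child(c)
            return new

        new_root = build(self.root)
        return TimeTree(new_root)

    def graft_subtree(
        self,
        at_tip: str,
        subtree: "TimeTree",
        attach_age: float,
        tol: float = DEFAULT_AGE_TOL,
    ) -> "TimeTree":
        """Replace tip ``at_tip`` by ``subtree`` whose root sits at
        ``attach_age``, shortening the original terminal branch.

        ``attach_age`` must lie in ``[tip.age, parent.age)``; equality with
        the tip age is only meaningful for a single-tip subtree (a pure
        relabel).  All original tip ages are preserved.
        """
        out = self.copy()
        tip = out.node_for(at_tip)
        if not tip.is_leaf:
            raise TreeError(f"{at_tip!r} is not a tip")
        parent = tip.parent
        if parent is None:
            raise TreeError("cannot graft at the root")
        if attach_age >= parent.age:
            raise TreeError(
                f"attach_age {attach_age} not below parent age {parent.age}"
            )
        if attach_age < tip.age - tol:
            raise TreeError(
                f"attach_age {attach_age} below tip age {tip.age}"
            )
        if abs(subtree.root.age - attach_age) > tol:
            raise TreeError(
                f"subtree root age {subtree.root.age} != attach_age {attach_age}"
            )
        graft = subtree.copy().root
        idx = parent.children.index(tip)
        graft.parent = parent
        parent.children[idx] = graft
        out.index_nodes()
        return out

    def write_newick(self, precision: int = 10) -> str:
        return write_newick(self, precision=precision)


class BranchLengthTree(_BaseTree):
    """Rooted tree with edge lengths in substitutions/site (no ages)."""

    def validate(self) -> None:
        for _, child in self.branch_iter():
            if child.length is None or child.length < 0:
                raise TreeError("missing or negative edge length")

    def path_to_root(self, label: str) -> float:
        node = self.node_for(label)
        total = 0.0
        while node.parent is not None:
            total += node.length or 0.0
            node = node.parent
        return total

    def path_length(self, a: str, b: str) -> float:
        m = self.mrca([a, b])

        def up(label):
            node = self.node_for(label)
            d = 0.0
            while node is not m:
                d += node.length or 0.0
                node = node.parent
            return d

        return up(a) + up(b)

    def copy(self) -> "BranchLengthTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.age, node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return BranchLengthTree(clone(self.root))

    def write_newick(self, precision: int = 10) -> str:
        return write_newick(self, precision=precision)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _norm_label(label: Optional[str]) -> Optional[str]:
    if label is None:
        return None
    return "_".join(str(label).split())


def _from_dendropy(dtree: dendropy.Tree) -> Node:
    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(_norm_label(label))
        node.length = dnode.edge.length
        if node.length is not None and node.length < -1e-12:
            raise TreeError(f"negative edge length: {node.length}")
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return convert(dtree.seed_node)


def _ages_from_lengths(
    root: Node, tip_dates: dict[str, float], tol: float
) -> None:
    """Set node ages so every root-to-tip path equals root_age - tip_age."""
    # depth of each node below the root, from edge lengths
    depth: dict[int, float] = {id(root): 0.0}
    order: list[Node] = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        for child in node.children:
            length = child.length if child.length is not None else 0.0
            depth[id(child)] = depth[id(node)] + length
            stack.append(child)
    tips = [n for n in order if n.is_leaf]
    root_ages = []
    for tip in tips:
        age = float(tip_dates.get(tip.label, 0.0))
        root_ages.append(depth[id(tip)] + age)
    root_age = root_ages[0]
    spread = max(root_ages) - min(root_ages)
    if spread > tol:
        raise TreeError(
            "edge lengths inconsistent with supplied tip dates: implied root "
            f"ages span {spread:.3g} Ma (> tolerance {tol:g})"
        )
    root_age = sum(root_ages) / len(root_ages)
    for node in order:
        node.age = root_age - depth[id(node)]
    # snap tip ages exactly to the supplied dates
    for tip in tips:
        tip.age = float(tip_dates.get(tip.label, 0.0))


def read_newick(
    text: str,
    tip_dates: Optional[dict[str, float]] = None,
    tol: float = DEFAULT_AGE_TOL,
):
    """Parse a Newick string.

    With ``tip_dates`` (taxon -> age in Ma; missing taxa default to 0,
    i.e. extant) the result is a :class:`TimeTree` whose node ages are
    computed from the edge lengths.  Without tip dates the result is a
    :class:`BranchLengthTree`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc
    root = _from_dendropy(dtree)
    if tip_dates is None:
        tree = BranchLengthTree(root)
        tree.validate()
        return tree
    _ages_from_lengths(root, tip_dates, tol)
    tree = TimeTree(root)
    tree.validate(tol=tol)
    return tree


def read_nexus_trees(
    source: str,
    tip_dates: Optional[dict[str, float]] = None,
    tol: float = DEFAULT_AGE_TOL,
) -> list:
    """Read every tree from a NEXUS TREES block (translate tables are
    honoured).  ``source`` is NEXUS text or a path to a file."""
    if "\n" in source or source.lstrip().upper().startswith("#NEXUS"):
        handle = io.StringIO(source)
        trees = dendropy.TreeList.get(
            file=handle, schema="nexus", preserve_underscores=True
        )
    else:
        trees = dendropy.TreeList.get(
            path=source, schema="nexus", preserve_underscores=True
        )
    out = []
    for dtree in trees:
        root = _from_dendropy(dtree)
        if tip_dates is None:
            out.append(BranchLengthTree(root))
        else:
            _ages_from_lengths(root, tip_dates, tol)
            out.append(TimeTree(root))
    return out


def write_newick(tree, precision: int = 10) -> str:
    """Serialize a tree to Newick.  For a :class:`TimeTree` edge lengths are
    ``parent.age - child.age``; for a :class:`BranchLengthTree` the stored
    lengths are written."""
    is_time = isinstance(tree, TimeTree)
    fmt = f"%.{precision}g"

    def render(node: Node) -> str:
        if node.is_leaf:
            body = node.label or ""
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.label:
                body += node.label
        if node.parent is None:
            return body
        if is_time:
            length = node.parent.age - node.age
        else:
            length = node.length if node.length is not None else 0.0
        return body + ":" + (fmt % length)

    return render(tree.root) + ";"


def read_tip_dates_csv(path_or_buf) -> dict[str, float]:
    """Read a two-column (taxon, age) CSV into a tip-date map."""
    import pandas as pd

    df = pd.read_csv(path_or_buf)
    cols = list(df.columns)
    return {
        _norm_label(str(t)): float(a)
        for t, a in zip(df[cols[0]], df[cols[1]])
    }
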