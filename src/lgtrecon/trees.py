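"""Phylogeny data model, Newick I/O, rooting, support collapsing, RF distance.

Trees are rooted node structures; split-based operations (Robinson-Foulds)
treat them as unrooted. Gene-tree leaves carry a species id encoded in the
label as ``species|gene``; a label without ``|`` is its own species id.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

SPECIES_SEP = "|"

_UNQUOTED_FORBIDDEN = set("()[]{}/\\,;:=*'\"`<> \t\n")


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset of the fault."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class TreeValidationError(ValueError):
    pass


@dataclass(eq=False)
class Node:
    label: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach_child(self, child: "Node") -> "Node":
        self.children.remove(child)
        child.parent = None
        return child

    def traverse_postorder(self) -> Iterator["Node"]:
        for ch in self.children:
            yield from ch.traverse_postorder()
        yield self

    def traverse_preorder(self) -> Iterator["Node"]:
        yield self
        for ch in self.children:
            yield from ch.traverse_preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.traverse_postorder() if n.is_leaf()]

    def copy(self) -> "Node":
        clone = Node(label=self.label, length=self.length, support=self.support)
        for ch in self.children:
            clone.add_child(ch.copy())
        return clone


class Tree:
    """Rooted tree; ``kind`` is ``"species"`` or ``"gene"``.

    ``unrooted`` flags inputs whose root placement is arbitrary (stored as a
    trifurcation or arbitrary bifurcation); split-based operations ignore it.
    """

    def __init__(self, root: Node, kind: str = "gene", unrooted: bool = False):
        if kind not in ("species", "gene"):
            raise ValueError(f"unknown tree kind: {kind!r}")
        self.root = root
        self.kind = kind
        self.unrooted = unrooted

    # -- basic accessors -------------------------------------------------

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def traverse_postorder(self) -> Iterator[Node]:
        return self.root.traverse_postorder()

    def traverse_preorder(self) -> Iterator[Node]:
        return self.root.traverse_preorder()

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), kind=self.kind, unrooted=self.unrooted)

    def is_binary(self) -> bool:
        return all(
            len(n.children) in (0, 2)
            for n in self.traverse_postorder()
            if n is not self.root
        ) and len(self.root.children) in (0, 2)

    def validate(self) -> None:
        labels = self.leaf_labels()
        if any(lb is None for lb in labels):
            raise TreeValidationError("unlabeled leaf")
        if len(labels) != len(set(labels)):
            dups = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise TreeValidationError(f"duplicate leaf labels: {dups}")
        for n in self.traverse_postorder():
            if n.support is not None and not (0.0 <= n.support <= 1.0):
                raise TreeValidationError(f"support {n.support} outside [0,1]")
        if self.kind == "species":
            for n in self.traverse_postorder():
                if n.children and len(n.children) != 2:
                    raise TreeValidationError(
                        "species tree must be binary; node with "
                        f"{len(n.children)} children"
                    )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    def __repr__(self) -> str:
        return f"Tree({write_newick(self)!r}, kind={self.kind!r})"


def species_of(leaf_label: str) -> str:
    """Species id of a gene-tree leaf label (``species|gene`` convention)."""
    return leaf_label.split(SPECIES_SEP, 1)[0]


@dataclass(frozen=True)
class Bipartition:
    """A two-block partition of a leaf-label set induced by an internal edge."""

    block_a: frozenset
    block_b: frozenset

    def __post_init__(self):
        if not self.block_a or not self.block_b:
            raise ValueError("both blocks must be non-empty")
        if self.block_a & self.block_b:
            raise ValueError("blocks must be disjoint")

    @property
    def leaf_set(self) -> frozenset:
        return self.block_a | self.block_b

    def canonical(self) -> frozenset:
        """Orientation-free key: the block not containing the min label."""
        lo = min(self.leaf_set)
        return self.block_b if lo in self.block_a else self.block_a

    def __eq__(self, other):
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self.leaf_set == other.leaf_set and self.canonical() == other.canonical()

    def __hash__(self):
        return hash((self.leaf_set, self.canonical()))


# ---------------------------------------------------------------------------
# Newick parsing


def _tokenize(text: str):
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "(),;:":
            yield c, i
            i += 1
        elif c == "'":
            j = i + 1
            buf = []
            while True:
                if j >= n:
                    raise NewickError("unterminated quoted label", i)
                if text[j] == "'":
                    if j + 1 < n and text[j + 1] == "'":
                        buf.append("'")
                        j += 2
                        continue
                    break
                buf.append(text[j])
                j += 1
            yield ("LABEL", "".join(buf)), i
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in "(),;:" and not text[j].isspace():
                j += 1
            yield ("LABEL", text[i:j]), i
            i = j


def parse_newick(text: str, kind: str = "gene") -> Tree:
    """Parse one Newick tree.

    Numeric internal-node labels in [0, 1] are stored as edge supports on
    gene trees. Branch lengths are preserved. Raises :class:`NewickError`
    with a character offset on malformed input and
    :class:`TreeValidationError` on duplicate leaf labels.
    """
    tokens = list(_tokenize(text))
    if not tokens:
        raise NewickError("empty input", 0)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(text))

    def take():
        nonlocal pos
        tok = peek()
        pos += 1
        return tok

    def parse_clade() -> Node:
        tok, off = peek()
        node = Node()
        if tok == "(":
            take()
            node.add_child(parse_clade())
            while True:
                tok, off = peek()
                if tok == ",":
                    take()
                    node.add_child(parse_clade())
                elif tok == ")":
                    take()
                    break
                else:
                    raise NewickError("expected ',' or ')'", off)
        # optional label
        tok, off = peek()
        if isinstance(tok, tuple) and tok[0] == "LABEL":
            take()
            node.label = tok[1]
        # optional branch length
        tok, off = peek()
        if tok == ":":
            take()
            tok, off = take()
            if not (isinstance(tok, tuple) and tok[0] == "LABEL"):
                raise NewickError("expected branch length after ':'", off)
            try:
                node.length = float(tok[1])
            except ValueError:
                raise NewickError(f"invalid branch length {tok[1]!r}", off) from None
        return node

    root = parse_clade()
    tok, off = peek()
    if tok != ";":
        raise NewickError("expected ';'", off)
    pos += 1
    if pos < len(tokens):
        raise NewickError("trailing content after ';'", tokens[pos][1])

    # internal-node labels that parse as numbers in [0,1] become supports
    for node in root.traverse_postorder():
        if node.children and node.label is not None:
            try:
                val = float(node.label)
            except ValueError:
                continue
            if 0.0 <= val <= 1.0:
                node.support = val
                node.label = None

    tree = Tree(root, kind=kind, unrooted=len(root.children) > 2)
    tree.validate()
    return tree


def _format_label(label: str) -> str:
    if any(c in _UNQUOTED_FORBIDDEN for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _min_leaf(node: Node) -> str:
    return min(lf.label for lf in node.leaves())


def _fmt_num(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(x)


def write_newick(tree: Tree) -> str:
    """Deterministic Newick: children ordered by smallest descendant leaf."""

    def fmt(node: Node) -> str:
        if node.is_leaf():
            s = _format_label(node.label)
        else:
            kids = sorted(node.children, key=_min_leaf)
            s = "(" + ",".join(fmt(ch) for ch in kids) + ")"
            if node.support is not None:
                s += _fmt_num(node.support)
            elif node.label is not None:
                s += _format_label(node.label)
        if node.length is not None:
            s += ":" + _fmt_num(node.length)
        return s

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Bipartitions & Robinson-Foulds


def bipartitions(tree: Tree) -> set[Bipartition]:
    """Non-trivial splits of the unrooted topology."""
    all_leaves = frozenset(tree.leaf_labels())
    splits: set[Bipartition] = set()
    for node in tree.traverse_postorder():
        if node is tree.root or node.is_leaf():
            continue
        below = frozenset(lf.label for lf in node.leaves())
        above = all_leaves - below
        if len(below) >= 2 and len(above) >= 2:
            splits.add(Bipartition(below, above))
    return splits


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Count of non-trivial bipartitions present in exactly one tree."""
    s1, s2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if s1 != s2:
        raise ValueError(
            "leaf sets differ; symmetric difference: "
            f"{sorted(s1 ^ s2)}"
        )
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


# ---------------------------------------------------------------------------
# Midpoint rooting


class MissingBranchLengthError(ValueError):
    pass


def _unrooted_adjacency(tree: Tree, unit_lengths: bool = False):
    """Adjacency map of the unrooted topology; a bifurcating root is
    suppressed (its two incident edges merged)."""
    adj: dict[int, list[tuple[int, float, Node]]] = {}
    nodes = {id(n): n for n in tree.traverse_postorder()}

    def edge_len(n: Node) -> float:
        if unit_lengths:
            return 1.0
        if n.length is None:
            raise MissingBranchLengthError(
                "branch lengths required; pass unit_lengths=True to fall back "
                "to unit edge lengths"
            )
        return n.length

    for n in tree.traverse_postorder():
        adj.setdefault(id(n), [])
    for n in tree.traverse_postorder():
        if n.parent is None:
            continue
        ln = edge_len(n)
        adj[id(n)].append((id(n.parent), ln, n.parent))
        adj[id(n.parent)].append((id(n), ln, n))
    root = tree.root
    if len(root.children) == 2:
        a, b = root.children
        merged = edge_len(a) + edge_len(b)
        adj[id(a)] = [e for e in adj[id(a)] if e[0] != id(root)] + [(id(b), merged, b)]
        adj[id(b)] = [e for e in adj[id(b)] if e[0] != id(root)] + [(id(a), merged, a)]
        del adj[id(root)]
    return adj, nodes


def midpoint_root(tree: Tree, unit_lengths: bool = False) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Diameter ties are broken by the lexicographically smallest (sorted)
    leaf-label pair.
    """
    tree = tree.copy()
    leaves = tree.leaves()
    if len(leaves) < 2:
        out = tree.copy()
        out.unrooted = False
        return out
    adj, _ = _unrooted_adjacency(tree, unit_lengths=unit_lengths)

    def paths_from(leaf: Node):
        dist = {id(leaf): 0.0}
        prev: dict[int, Node] = {}
        stack = [leaf]
        seen = {id(leaf)}
        while stack:
            cur = stack.pop()
            for nid, ln, nbr in adj[id(cur)]:
                if nid not in seen:
                    seen.add(nid)
                    dist[nid] = dist[id(cur)] + ln
                    prev[nid] = cur
                    stack.append(nbr)
        return dist, prev

    best = None  # (-(dist), sorted-label-pair, start_leaf, end_leaf, prev)
    for lf in leaves:
        dist, prev = paths_from(lf)
        for other in leaves:
            if other is lf:
                continue
            d = dist[id(other)]
            pair = tuple(sorted((lf.label, other.label)))
            key = (-d, pair)
            if best is None or key < best[0]:
                best = (key, lf, other, prev)
    (neg_d, _pair), start, end, prev = best[0], best[1], best[2], best[3]
    diameter = -neg_d
    # walk from `end` back to `start`; root at diameter/2 from start,
    # i.e. diameter/2 from end along this path as well
    path = [end]
    while path[-1] is not start:
        path.append(prev[id(path[-1])])
    path.reverse()  # start ... end
    # locate midpoint measuring from start
    target = diameter / 2.0
    acc = 0.0
    for i in range(len(path) - 1):
        a, b = path[i], path[i + 1]
        ln = next(l for nid, l, n in adj[id(a)] if nid == id(b))
        if acc + ln >= target - 1e-12:
            along = target - acc  # distance from a towards b
            return _reroot_on_edge(tree, a, b, along, unit_lengths)
        acc += ln
    return _reroot_on_edge(tree, path[-2], path[-1], 0.0, unit_lengths)


def _neighbor_edges(tree: Tree, unit_lengths: bool):
    return _unrooted_adjacency(tree, unit_lengths=unit_lengths)[0]


def _reroot_on_edge(
    tree: Tree, a: Node, b: Node, dist_from_a: float, unit_lengths: bool
) -> Tree:
    """Build a new rooted tree with the root on the unrooted edge (a, b),
    ``dist_from_a`` along it."""
    adj, _ = _unrooted_adjacency(tree, unit_lengths=unit_lengths)
    edge_total = next(l for nid, l, n in adj[id(a)] if nid == id(b))

    def build(node: Node, came_from: int) -> Node:
        out = Node(label=node.label, support=node.support)
        if node.is_leaf():
            out.label = node.label
        for nid, ln, nbr in sorted(adj[id(node)], key=lambda e: _min_leaf(e[2])):
            if nid == came_from:
                continue
            child = build(nbr, id(node))
            child.length = None if unit_lengths else ln
            out.add_child(child)
        return out

    root = Node()
    ca = build(a, id(b))
    ca.length = dist_from_a if not unit_lengths else None
    cb = build(b, id(a))
    cb.length = (edge_total - dist_from_a) if not unit_lengths else None
    root.add_child(ca)
    root.add_child(cb)
    # a midpoint exactly on a vertex leaves a zero-length root child, which
    # keeps the output binary; callers relying on topology are unaffected
    return Tree(root, kind=tree.kind, unrooted=False)


# ---------------------------------------------------------------------------
# Support-threshold collapsing


def collapse_weak_edges(tree: Tree, threshold: float = 0.9) -> Tree:
    """Contract internal edges with support strictly below ``threshold``.

    Edges without a support value are kept (treated as fully supported).
    The result may be non-binary; the leaf set is unchanged.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0,1]")
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.traverse_postorder()):
            if node.is_leaf() or node.parent is None:
                continue
            if node.support is not None and node.support < threshold:
                parent = node.parent
                idx = parent.children.index(node)
                parent.children.pop(idx)
                for j, ch in enumerate(node.children):
                    ch.parent = parent
                    parent.children.insert(idx + j, ch)
                changed = True
                break
    return tree


def read_newick_file(path, kind: str = "gene") -> list[Tree]:
    """One tree per non-empty line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line, kind=kind))
    return trees
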