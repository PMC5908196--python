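"""Duplication-transfer-loss parsimony reconciliation (undated model).

Transfers are permitted between any two species branches neither of which is
ancestral to the other; no global time consistency is imposed. Losses above
the gene-tree root mapping are not charged. Among co-optimal solutions the
canonical one minimizes the transfer count first, then resolves remaining
ties by a fixed event preference (speciation > duplication > transfer) and
deterministic traversal order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .trees import Node, Tree, species_of, write_newick

INF = math.inf


class ReconciliationError(ValueError):
    pass


class PolytomyDegreeError(ValueError):
    pass


@dataclass(frozen=True)
class CostScheme:
    """Event costs; speciation is free. Defaults: dup=1, loss=1, transfer=2."""

    dup_cost: float = 1.0
    transfer_cost: float = 2.0
    loss_cost: float = 1.0

    def __post_init__(self):
        for name in ("dup_cost", "transfer_cost", "loss_cost"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def ratio(self) -> float:
        """transfer:duplication cost ratio."""
        return self.transfer_cost / self.dup_cost

    @classmethod
    def from_ratio(cls, ratio: float) -> "CostScheme":
        return cls(dup_cost=1.0, transfer_cost=float(ratio), loss_cost=1.0)


@dataclass(frozen=True)
class EventRecord:
    kind: str  # speciation | duplication | transfer | loss
    gene_node: str
    species: str  # species node/edge id where the event occurs
    donor: str | None = None  # transfer only
    recipient: str | None = None  # transfer only

    def __post_init__(self):
        if self.kind not in ("speciation", "duplication", "transfer", "loss"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "transfer" and (self.donor is None or self.recipient is None):
            raise ValueError("transfer events need donor and recipient edges")


@dataclass
class Reconciliation:
    """An optimal event history embedding a gene tree into a species tree."""

    mapping: dict[str, str]  # gene node id -> species node id
    events: list[EventRecord]
    total_cost: float
    costs: CostScheme
    species_leafsets: dict[str, frozenset] = field(default_factory=dict)

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e.kind == "duplication")

    @property
    def n_transfers(self) -> int:
        return sum(1 for e in self.events if e.kind == "transfer")

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if e.kind == "loss")

    def verify(self, gene: Tree) -> None:
        """Consistency replay: leaf mapping and cost arithmetic."""
        for leaf in gene.leaves():
            sp = species_of(leaf.label)
            if self.mapping.get(leaf.label) != sp:
                raise ReconciliationError(
                    f"gene leaf {leaf.label!r} mapped to "
                    f"{self.mapping.get(leaf.label)!r}, not its species {sp!r}"
                )
        expected = (
            self.n_duplications * self.costs.dup_cost
            + self.n_transfers * self.costs.transfer_cost
            + self.n_losses * self.costs.loss_cost
        )
        if not math.isclose(expected, self.total_cost, abs_tol=1e-9):
            raise ReconciliationError(
                f"event tally {expected} != reported cost {self.total_cost}"
            )

    def transfers(self) -> list[EventRecord]:
        return [e for e in self.events if e.kind == "transfer"]

    def report(self) -> str:
        lines = [
            f"total_cost\t{self.total_cost}",
            f"duplications\t{self.n_duplications}",
            f"transfers\t{self.n_transfers}",
            f"losses\t{self.n_losses}",
        ]
        for e in self.events:
            lines.append(
                "\t".join(
                    [
                        e.kind,
                        e.gene_node,
                        e.species,
                        e.donor or "-",
                        e.recipient or "-",
                    ]
                )
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Indexed species/gene structures


class _SpeciesIndex:
    def __init__(self, tree: Tree):
        self.nodes: list[Node] = list(tree.traverse_postorder())
        self.idx = {id(n): i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.children = [
            [self.idx[id(c)] for c in nd.children] for nd in self.nodes
        ]
        self.parent = [None] * n
        for i, nd in enumerate(self.nodes):
            for c in self.children[i]:
                self.parent[c] = i
        self.depth = [0] * n
        root = self.idx[id(tree.root)]
        order = [root]
        while order:
            i = order.pop()
            for c in self.children[i]:
                self.depth[c] = self.depth[i] + 1
                order.append(c)
        # anc[x][y]: x is ancestor of or equal to y
        self.anc = [[False] * n for _ in range(n)]
        for y in range(n):
            x = y
            while x is not None:
                self.anc[x][y] = True
                x = self.parent[x]
        self.leaf_index = {
            nd.label: i for i, nd in enumerate(self.nodes) if nd.is_leaf()
        }
        self.names = []
        self.leafsets = []
        for i, nd in enumerate(self.nodes):
            leaves = frozenset(lf.label for lf in nd.leaves())
            self.leafsets.append(leaves)
            self.names.append(nd.label if nd.is_leaf() else f"S{i}")

    def comparable(self, x: int, y: int) -> bool:
        return self.anc[x][y] or self.anc[y][x]

    def dist_down(self, x: int, y: int) -> int:
        """Edge count from x down to descendant y."""
        return self.depth[y] - self.depth[x]


def _gene_node_names(gene: Tree) -> dict[int, str]:
    names = {}
    for i, nd in enumerate(gene.traverse_postorder()):
        names[id(nd)] = nd.label if nd.is_leaf() else f"G{i}"
    return names


# ---------------------------------------------------------------------------
# The DP

_INF_PAIR = (INF, INF)


def _dtl_tables(gene: Tree, species: Tree, costs: CostScheme, allow_transfer: bool):
    sp = _SpeciesIndex(species)
    nS = len(sp.nodes)
    gnodes = list(gene.traverse_postorder())

    for leaf in gene.leaves():
        s = species_of(leaf.label)
        if s not in sp.leaf_index:
            raise ReconciliationError(
                f"gene leaf {leaf.label!r} references species {s!r} absent "
                "from the species tree"
            )

    dup, tr, lo = costs.dup_cost, costs.transfer_cost, costs.loss_cost

    c: dict[int, list] = {}
    inn: dict[int, list] = {}
    out: dict[int, list] = {}
    cbp: dict[int, list] = {}
    inbp: dict[int, list] = {}
    outbp: dict[int, list] = {}

    def add(p, q):
        return (p[0] + q[0], p[1] + q[1])

    for u in gnodes:
        uid = id(u)
        c[uid] = [_INF_PAIR] * nS
        cbp[uid] = [None] * nS
        if u.is_leaf():
            xi = sp.leaf_index[species_of(u.label)]
            c[uid][xi] = (0.0, 0)
            cbp[uid][xi] = ("leaf",)
        else:
            u1, u2 = u.children
            for x in range(nS):
                cands = []  # (cost_pair, rank, det, bp)
                kids = sp.children[x]
                if kids:
                    x1, x2 = kids
                    cands.append(
                        (
                            add(inn[id(u1)][x1], inn[id(u2)][x2]),
                            0,
                            0,
                            ("spec", x1, x2),
                        )
                    )
                    cands.append(
                        (
                            add(inn[id(u1)][x2], inn[id(u2)][x1]),
                            0,
                            1,
                            ("spec", x2, x1),
                        )
                    )
                dpair = add(inn[id(u1)][x], inn[id(u2)][x])
                cands.append(((dpair[0] + dup, dpair[1]), 1, 0, ("dup",)))
                if allow_transfer:
                    for det, (stay, move) in enumerate(((u1, u2), (u2, u1))):
                        o = out[id(move)][x]
                        if o[0] < INF:
                            pair = add(inn[id(stay)][x], o)
                            cands.append(
                                (
                                    (pair[0] + tr, pair[1] + 1),
                                    2,
                                    det,
                                    ("transfer", stay, move, outbp[id(move)][x]),
                                )
                            )
                best = min(cands, key=lambda t: (t[0], t[1], t[2]))
                c[uid][x] = best[0]
                cbp[uid][x] = best[3]

        # in: allow descending with losses
        inn[uid] = [_INF_PAIR] * nS
        inbp[uid] = [None] * nS
        for x in range(nS):  # postorder: children before parents
            best = (c[uid][x], ("here",))
            for ci, xc in enumerate(sp.children[x]):
                cand = ((inn[uid][xc][0] + lo, inn[uid][xc][1]), ("loss", ci))
                if cand[0] < best[0]:
                    best = cand
            inn[uid][x] = best[0]
            inbp[uid][x] = best[1]

        if allow_transfer:
            out[uid] = [_INF_PAIR] * nS
            outbp[uid] = [None] * nS
            for x in range(nS):
                best, arg = _INF_PAIR, None
                for y in range(nS):
                    if not sp.comparable(x, y) and inn[uid][y] < best:
                        best, arg = inn[uid][y], y
                out[uid][x] = best
                outbp[uid][x] = arg

    return sp, gnodes, c, inn, cbp, inbp


def _extract(gene: Tree, sp: _SpeciesIndex, c, inn, cbp, inbp, root_x: int):
    names = _gene_node_names(gene)
    mapping: dict[str, str] = {}
    events: list[EventRecord] = []

    def resolve_in(u: Node, x: int):
        uid = id(u)
        while inbp[uid][x] != ("here",):
            _tag, ci = inbp[uid][x]
            kids = sp.children[x]
            lost = kids[1 - ci]
            events.append(
                EventRecord("loss", names[uid], sp.names[lost])
            )
            x = kids[ci]
        emit(u, x)

    def emit(u: Node, x: int):
        uid = id(u)
        mapping[names[uid]] = sp.names[x]
        bp = cbp[uid][x]
        if bp == ("leaf",):
            return
        if bp[0] == "spec":
            _tag, x1, x2 = bp
            events.append(EventRecord("speciation", names[uid], sp.names[x]))
            u1, u2 = u.children
            resolve_in(u1, x1)
            resolve_in(u2, x2)
        elif bp[0] == "dup":
            events.append(EventRecord("duplication", names[uid], sp.names[x]))
            u1, u2 = u.children
            resolve_in(u1, x)
            resolve_in(u2, x)
        else:
            _tag, stay, move, y = bp
            events.append(
                EventRecord(
                    "transfer",
                    names[uid],
                    sp.names[x],
                    donor=sp.names[x],
                    recipient=sp.names[y],
                )
            )
            resolve_in(stay, x)
            resolve_in(move, y)

    emit(gene.root, root_x)
    return mapping, events


def _check_reconcilable(gene: Tree, species: Tree):
    if gene.unrooted or len(gene.root.children) != 2:
        raise ReconciliationError(
            "gene tree must be rooted and binary; root ambiguous trees with "
            "optimal_root() first"
        )
    for nd in gene.traverse_postorder():
        if nd.children and len(nd.children) != 2:
            raise ReconciliationError(
                "gene tree has polytomies; resolve with resolve_polytomies()"
            )


def dtl_reconcile(
    gene: Tree, species: Tree, costs: CostScheme = CostScheme()
) -> Reconciliation:
    """Minimum-cost DTL reconciliation of a rooted binary gene tree.

    The cost is the global optimum of the undated DTL recurrence; the
    returned event history is the canonical co-optimum (fewest transfers,
    then deterministic traversal).
    """
    _check_reconcilable(gene, species)
    sp, gnodes, c, inn, cbp, inbp = _dtl_tables(
        gene, species, costs, allow_transfer=True
    )
    ruid = id(gene.root)
    root_x = min(range(len(sp.nodes)), key=lambda x: (c[ruid][x], x))
    mapping, events = _extract(gene, sp, c, inn, cbp, inbp, root_x)
    rec = Reconciliation(
        mapping=mapping,
        events=events,
        total_cost=c[ruid][root_x][0],
        costs=costs,
        species_leafsets={sp.names[i]: sp.leafsets[i] for i in range(len(sp.nodes))},
    )
    rec.verify(gene)
    return rec


def dl_reconcile(
    gene: Tree, species: Tree, costs: CostScheme = CostScheme()
) -> Reconciliation:
    """Minimum duplication-loss reconciliation (transfers forbidden)."""
    _check_reconcilable(gene, species)
    sp, gnodes, c, inn, cbp, inbp = _dtl_tables(
        gene, species, costs, allow_transfer=False
    )
    ruid = id(gene.root)
    root_x = min(range(len(sp.nodes)), key=lambda x: (c[ruid][x], x))
    mapping, events = _extract(gene, sp, c, inn, cbp, inbp, root_x)
    rec = Reconciliation(
        mapping=mapping,
        events=events,
        total_cost=c[ruid][root_x][0],
        costs=costs,
        species_leafsets={sp.names[i]: sp.leafsets[i] for i in range(len(sp.nodes))},
    )
    rec.verify(gene)
    return rec


# ---------------------------------------------------------------------------
# Rooting and polytomy resolution


def _enumerate_rootings(gene: Tree) -> list[Tree]:
    """All rootings of the unrooted topology underlying ``gene``."""
    from .trees import _reroot_on_edge, _unrooted_adjacency

    adj, nodes = _unrooted_adjacency(gene, unit_lengths=True)
    seen = set()
    rootings = []
    for aid, edges in adj.items():
        for bid, _ln, _nb in edges:
            key = frozenset((aid, bid))
            if key in seen:
                continue
            seen.add(key)
            a = nodes[aid]
            b = nodes[bid]
            rooted = _reroot_on_edge(gene, a, b, 0.5, unit_lengths=True)
            rooted.unrooted = False
            rootings.append(rooted)
    return rootings


def optimal_root(
    gene: Tree, species: Tree, costs: CostScheme = CostScheme()
) -> Tree:
    """Root an unrooted gene tree on the edge minimizing the DTL cost.

    Ties are broken by the lexicographically smallest canonical Newick
    string of the rooted candidate.
    """
    best = None
    for cand in _enumerate_rootings(gene):
        cand2 = cand.copy()
        rec = dtl_reconcile(cand2, species, costs)
        key = (rec.total_cost, rec.n_transfers, write_newick(cand))
        if best is None or key < best[0]:
            best = (key, cand)
    out = best[1]
    out.kind = gene.kind
    return out


def _binary_shapes(items: list):
    """All rooted binary topologies over the given items, as nested pairs."""
    if len(items) == 1:
        yield items[0]
        return

    def insert(t, x):
        yield (t, x)
        if isinstance(t, tuple):
            for sub in insert(t[0], x):
                yield (sub, t[1])
            for sub in insert(t[1], x):
                yield (t[0], sub)

    for base in _binary_shapes(items[:-1]):
        yield from insert(base, items[-1])


def resolve_polytomies(
    gene: Tree,
    species: Tree,
    costs: CostScheme = CostScheme(),
    max_degree: int = 8,
) -> Tree:
    """Resolve each polytomy to the binary shape minimizing total DTL cost.

    Polytomies are handled one at a time in post-order; each is resolved by
    exhaustive search over all rooted binary arrangements of its children
    (the remaining polytomies are temporarily resolved arbitrarily so the
    tree is scoreable). Ties break on the canonical Newick string.
    """
    work = gene.copy()

    def arbitrary_binarize(t: Tree) -> Tree:
        t = t.copy()
        for nd in list(t.traverse_postorder()):
            while len(nd.children) > 2:
                a = nd.children[0]
                b = nd.children[1]
                nd.detach_child(a)
                nd.detach_child(b)
                joint = Node()
                joint.add_child(a)
                joint.add_child(b)
                nd.children.insert(0, joint)
                joint.parent = nd
        return t

    def build_from_shape(shape) -> Node:
        if isinstance(shape, tuple):
            nd = Node()
            nd.add_child(build_from_shape(shape[0]))
            nd.add_child(build_from_shape(shape[1]))
            return nd
        return shape.copy()

    while True:
        poly = None
        for nd in work.traverse_postorder():
            if len(nd.children) > 2:
                poly = nd
                break
        if poly is None:
            break
        k = len(poly.children)
        if k > max_degree:
            raise PolytomyDegreeError(
                f"polytomy of degree {k} exceeds cap {max_degree}; raise "
                "max_degree or pre-resolve the tree"
            )
        best = None
        for shape in _binary_shapes(list(poly.children)):
            resolved_children = (
                [build_from_shape(shape[0]), build_from_shape(shape[1])]
                if isinstance(shape, tuple)
                else [build_from_shape(shape)]
            )
            cand = work.copy()
            # locate the corresponding polytomy node in the copy by identity
            # of traversal order
            orig_order = list(work.traverse_postorder())
            cand_order = list(cand.traverse_postorder())
            target = cand_order[orig_order.index(poly)]
            for ch in list(target.children):
                target.detach_child(ch)
            for ch in resolved_children:
                target.add_child(ch)
            scoreable = arbitrary_binarize(cand)
            scoreable.unrooted = False
            rec = dtl_reconcile(scoreable, species, costs)
            key = (rec.total_cost, rec.n_transfers, write_newick(cand))
            if best is None or key < best[0]:
                best = (key, cand)
        work = best[1]
    work.unrooted = False
    return work


# ---------------------------------------------------------------------------
# Brute-force oracle


def bruteforce_min_cost(
    gene: Tree, species: Tree, costs: CostScheme = CostScheme()
) -> float:
    """Exact minimum DTL cost by exhaustive enumeration (test oracle).

    Enumerates every assignment of internal gene nodes to species nodes and
    scores each by replaying the implied events. Limited to 7 leaves per
    tree.
    """
    if len(gene.leaves()) > 7 or len(species.leaves()) > 7:
        raise ValueError("brute-force oracle limited to 7 leaves per tree")
    _check_reconcilable(gene, species)
    sp = _SpeciesIndex(species)
    nS = len(sp.nodes)
    dup, tr, lo = costs.dup_cost, costs.transfer_cost, costs.loss_cost

    gnodes = list(gene.traverse_postorder())
    internal = [n for n in gnodes if not n.is_leaf()]
    fixed = {
        id(n): sp.leaf_index[species_of(n.label)] for n in gnodes if n.is_leaf()
    }

    def node_cost(x: int, y1: int, y2: int) -> float:
        best = INF
        kids = sp.children[x]
        if kids:
            c1, c2 = kids
            for a, b in ((c1, c2), (c2, c1)):
                if sp.anc[a][y1] and sp.anc[b][y2]:
                    best = min(
                        best, lo * (sp.dist_down(a, y1) + sp.dist_down(b, y2))
                    )
        if sp.anc[x][y1] and sp.anc[x][y2]:
            best = min(
                best, dup + lo * (sp.dist_down(x, y1) + sp.dist_down(x, y2))
            )
        if sp.anc[x][y1] and not sp.comparable(x, y2):
            best = min(best, tr + lo * sp.dist_down(x, y1))
        if sp.anc[x][y2] and not sp.comparable(x, y1):
            best = min(best, tr + lo * sp.dist_down(x, y2))
        return best

    best_total = INF
    for assignment in itertools.product(range(nS), repeat=len(internal)):
        placed = dict(fixed)
        for node, x in zip(internal, assignment):
            placed[id(node)] = x
        total = 0.0
        for node in internal:
            x = placed[id(node)]
            y1 = placed[id(node.children[0])]
            y2 = placed[id(node.children[1])]
            total += node_cost(x, y1, y2)
            if total >= best_total:
                break
        if total < best_total:
            best_total = total
    return best_total
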