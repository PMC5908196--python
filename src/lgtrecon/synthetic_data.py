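"""Seeded generators for every input the pipeline consumes, with ground
truth event logs, so each stage is testable without external downloads.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .neutrality import SiteMatrix
from .synteny import Neighborhood, OrthologMap
from .trees import Node, Tree, write_newick


@dataclass(frozen=True)
class SimParams:
    """Event rates are per unit branch length on the depth-1 species tree."""

    r_dup: float = 0.0
    r_transfer: float = 0.0
    r_loss: float = 0.0
    seed: int = 0
    focal_clade: frozenset = frozenset()

    def __post_init__(self):
        if min(self.r_dup, self.r_transfer, self.r_loss) < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class SimEvent:
    time: float
    kind: str  # origin | speciation | duplication | transfer | loss
    lineage: str
    species: str  # branch (child-node id) the lineage occupies
    children: tuple = ()  # lineage ids created by this event
    recipient: Optional[str] = None  # transfer: recipient branch


@dataclass
class TrueHistory:
    events: list[SimEvent]

    def replay(self, species: Tree) -> Optional[Tree]:
        """Rebuild the gene tree from the event log alone.

        Used as an oracle: the result must equal the emitted tree exactly.
        """
        binfo = _branch_table(species)
        nodes: dict[str, Node] = {}
        branch_of: dict[str, str] = {}
        for ev in self.events:
            if ev.kind == "origin":
                nodes[ev.lineage] = Node()
                branch_of[ev.lineage] = ev.species
            elif ev.kind in ("speciation", "duplication", "transfer"):
                parent = nodes[ev.lineage]
                for i, ch in enumerate(ev.children):
                    child = Node()
                    nodes[ch] = child
                    parent.add_child(child)
                    if ev.kind == "speciation":
                        branch_of[ch] = binfo.children_of[ev.species][i]
                    elif ev.kind == "transfer" and i == 1:
                        branch_of[ch] = ev.recipient
                    else:
                        branch_of[ch] = ev.species
            elif ev.kind == "loss":
                nodes[ev.lineage].label = "__dead__"
        for lid, node in nodes.items():
            if not node.children and node.label is None:
                node.label = f"{branch_of[lid]}|{lid}"
        root = nodes[self.events[0].lineage]
        return _clean_gene_tree(root)


class _BranchTable:
    def __init__(self):
        self.names: list[str] = []
        self.span: dict[str, tuple] = {}
        self.children_of: dict[str, list] = {}
        self.comparable: dict[tuple, bool] = {}
        self.is_leaf: dict[str, bool] = {}


def _branch_table(species: Tree) -> _BranchTable:
    """Branch ids (child-node based, matching the reconcile module naming),
    time spans on the depth-normalized tree, and comparability."""
    post = list(species.traverse_postorder())
    name = {}
    for i, nd in enumerate(post):
        name[id(nd)] = nd.label if nd.is_leaf() else f"S{i}"
    times = {id(species.root): 0.0}
    for nd in species.traverse_preorder():
        if nd.parent is not None:
            times[id(nd)] = times[id(nd.parent)] + (nd.length or 1.0)
    tab = _BranchTable()
    desc = {}
    for nd in post:
        d = {id(nd)}
        for ch in nd.children:
            d |= desc[id(ch)]
        desc[id(nd)] = d
    for nd in post:
        nm = name[id(nd)]
        tab.names.append(nm)
        tab.is_leaf[nm] = nd.is_leaf()
        tab.children_of[nm] = [name[id(c)] for c in nd.children]
        if nd.parent is not None:
            tab.span[nm] = (times[id(nd.parent)], times[id(nd)])
        else:
            tab.span[nm] = (-1.0, 0.0)  # the root stem; events never fire here
    for a in post:
        for b in post:
            tab.comparable[(name[id(a)], name[id(b)])] = (
                id(b) in desc[id(a)] or id(a) in desc[id(b)]
            )
    return tab


def simulate_species_tree(n_taxa: int, seed: int) -> Tree:
    """Rooted binary tree from a Yule (pure-birth) process, branch lengths
    positive, total depth normalized to 1. Leaves are sp01, sp02, ..."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    root = Node()
    a, b = Node(), Node()
    root.add_child(a)
    root.add_child(b)
    active = [(a, 0.0), (b, 0.0)]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.length = t - birth
        c1, c2 = Node(), Node()
        node.add_child(c1)
        node.add_child(c2)
        active.append((c1, t))
        active.append((c2, t))
    t_end = t + rng.exponential(1.0 / len(active)) + 0.05
    labels = iter(f"sp{i+1:02d}" for i in range(n_taxa))
    for node, birth in active:
        node.length = t_end - birth
    # label leaves in deterministic traversal order
    tree = Tree(root, kind="species")
    for leaf in tree.leaves():
        leaf.label = next(labels)
    for nd in tree.traverse_postorder():
        if nd.parent is not None:
            nd.length = nd.length / t_end
    tree.validate()
    return tree


def _clean_gene_tree(root: Node) -> Optional[Tree]:
    """Drop dead subtrees and suppress unifurcations; None if nothing
    survives."""

    def clean(node: Node) -> Optional[Node]:
        if not node.children:
            return None if node.label == "__dead__" else node
        kept = [c for c in (clean(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        out = Node(label=node.label)
        for c in kept:
            out.add_child(c)
        return out

    cleaned = clean(root)
    if cleaned is None or not cleaned.children and cleaned.label is None:
        return None
    if cleaned is not None and not cleaned.children:
        # single surviving tip: still a (degenerate) family
        t = Tree(cleaned, kind="gene")
        return t
    return Tree(cleaned, kind="gene")


def simulate_dtl_family(
    species: Tree,
    params: SimParams,
    forced_transfer: Optional[tuple] = None,
) -> tuple[Optional[Tree], TrueHistory]:
    """Evolve one gene lineage down the species tree with Poisson
    duplication / transfer / loss events.

    A transfer copies the lineage onto a uniformly chosen contemporaneous
    non-comparable branch (time-sliced on the depth-normalized tree).
    Returns (gene tree, true history); the tree is None when every lineage
    is lost (empty-family sentinel — resampling is the caller's choice).

    ``forced_transfer=(donor_branch, recipient_branch, time)`` injects one
    deterministic transfer; only supported with all rates zero.
    """
    rng = np.random.default_rng(params.seed)
    tab = _branch_table(species)
    rates = np.array([params.r_dup, params.r_transfer, params.r_loss])
    total_rate = rates.sum()
    if forced_transfer is not None and total_rate > 0:
        raise ValueError("forced_transfer requires all event rates to be 0")
    forced_fired = [False]
    events: list[SimEvent] = []
    counter = [0]

    def new_lineage() -> str:
        counter[0] += 1
        return f"L{counter[0]}"

    nodes: dict[str, Node] = {}
    root_branches = tab.children_of[tab.names[-1]]  # species root children

    def walk(lineage: str, branch: str, t: float):
        node = nodes[lineage]
        t_end = tab.span[branch][1]
        if (
            forced_transfer is not None
            and not forced_fired[0]
            and forced_transfer[0] == branch
            and t <= forced_transfer[2] < t_end
        ):
            forced_fired[0] = True
            donor, recip, tf = forced_transfer
            c1, c2 = new_lineage(), new_lineage()
            events.append(
                SimEvent(tf, "transfer", lineage, branch, (c1, c2), recipient=recip)
            )
            for cid in (c1, c2):
                nodes[cid] = Node()
                node.add_child(nodes[cid])
            walk(c2, recip, tf)
            walk(c1, branch, tf)
            return
        while True:
            dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            if t + dt >= t_end:
                break
            t += dt
            kind = ("duplication", "transfer", "loss")[
                int(rng.choice(3, p=rates / total_rate))
            ]
            if kind == "loss":
                events.append(SimEvent(t, "loss", lineage, branch))
                node.label = "__dead__"
                return
            if kind == "duplication":
                c1, c2 = new_lineage(), new_lineage()
                events.append(
                    SimEvent(t, "duplication", lineage, branch, (c1, c2))
                )
                for cid in (c1, c2):
                    nodes[cid] = Node()
                    node.add_child(nodes[cid])
                walk(c1, branch, t)
                lineage, node = c2, nodes[c2]
                continue
            # transfer
            recips = [
                b
                for b in tab.names
                if b != branch
                and not tab.comparable[(branch, b)]
                and tab.span[b][0] < t < tab.span[b][1]
            ]
            if not recips:
                continue  # no contemporaneous recipient exists; event voided
            recip = recips[int(rng.integers(len(recips)))]
            c1, c2 = new_lineage(), new_lineage()
            events.append(
                SimEvent(t, "transfer", lineage, branch, (c1, c2), recipient=recip)
            )
            for cid in (c1, c2):
                nodes[cid] = Node()
                node.add_child(nodes[cid])
            walk(c2, recip, t)
            lineage, node = c1, nodes[c1]
        # reached the bottom of the branch
        if tab.is_leaf[branch]:
            node.label = f"{branch}|{lineage}"
            return
        c1, c2 = new_lineage(), new_lineage()
        events.append(SimEvent(t_end, "speciation", lineage, branch, (c1, c2)))
        for cid in (c1, c2):
            nodes[cid] = Node()
            node.add_child(nodes[cid])
        for cid, cb in zip((c1, c2), tab.children_of[branch]):
            walk(cid, cb, t_end)

    # the ancestral gene enters at the species root and immediately splits
    origin = new_lineage()
    nodes[origin] = Node()
    events.append(
        SimEvent(0.0, "origin", origin, tab.names[-1])
    )
    c1, c2 = new_lineage(), new_lineage()
    events.append(
        SimEvent(0.0, "speciation", origin, tab.names[-1], (c1, c2))
    )
    for cid in (c1, c2):
        nodes[cid] = Node()
        nodes[origin].add_child(nodes[cid])
    for cid, cb in zip((c1, c2), root_branches):
        walk(cid, cb, 0.0)

    gene = _clean_gene_tree(nodes[origin])
    return gene, TrueHistory(events=events)


def simulate_family_with_one_transfer(
    species: Tree, focal_clade: frozenset, seed: int
) -> tuple[Tree, TrueHistory]:
    """A family with exactly one transfer into the focal clade and no other
    events, built by injecting the transfer into an event-free history.

    The recipient is a uniformly chosen branch subtending a proper subclade
    of the focal clade; the donor, uniform among contemporaneous branches
    wholly outside it. Transfers onto the branch ancestral to the whole
    focal clade pre-date its diversification and are flagged (not called)
    by the classifier, so they are excluded here.
    """
    focal_clade = frozenset(focal_clade)
    tab = _branch_table(species)
    leafsets = _branch_leafsets(species)
    rng = np.random.default_rng(seed)
    recips = sorted(
        b
        for b in tab.names
        if leafsets[b] < focal_clade and tab.span[b][0] >= 0.0
    )
    if not recips:
        raise ValueError("focal clade has no proper subclade branch")
    for _ in range(1000):
        r = recips[int(rng.integers(len(recips)))]
        t = float(rng.uniform(*tab.span[r]))
        donors = sorted(
            d
            for d in tab.names
            if not (leafsets[d] & focal_clade)
            and not tab.comparable[(d, r)]
            and tab.span[d][0] < t < tab.span[d][1]
        )
        if donors:
            d = donors[int(rng.integers(len(donors)))]
            gene, hist = simulate_dtl_family(
                species, SimParams(seed=0), forced_transfer=(d, r, t)
            )
            return gene, hist
    raise RuntimeError("no contemporaneous out-of-clade donor found")


def _branch_leafsets(species: Tree) -> dict[str, frozenset]:
    post = list(species.traverse_postorder())
    out = {}
    for i, nd in enumerate(post):
        nm = nd.label if nd.is_leaf() else f"S{i}"
        out[nm] = frozenset(lf.label for lf in nd.leaves())
    return out


def perturb_supports(tree: Tree, weak_fraction: float, seed: int) -> Tree:
    """Set every internal-edge support to 1.0, then downgrade a random
    ``weak_fraction`` of them to uniform(0.3, 0.89)."""
    if not 0.0 <= weak_fraction <= 1.0:
        raise ValueError("weak_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    out = tree.copy()
    internal = [
        n for n in out.traverse_postorder() if n.children and n.parent is not None
    ]
    for n in internal:
        n.support = 1.0
    k = int(round(weak_fraction * len(internal)))
    if k:
        idx = rng.choice(len(internal), size=k, replace=False)
        for i in sorted(idx):
            internal[i].support = float(rng.uniform(0.3, 0.89))
    return out


def simulate_neutral_sites(n: int, theta: float, seed: int) -> SiteMatrix:
    """Standard neutral coalescent of n samples with infinite-sites
    mutations at rate theta/2 per unit branch length (time in 2N units).

    Returns a binary haplotype matrix ('0' ancestral, '1' derived)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(seed)
    lineages = [frozenset([i]) for i in range(n)]
    branch_len: dict[frozenset, float] = {ln: 0.0 for ln in lineages}
    segments: list[tuple[frozenset, float]] = []
    while len(lineages) > 1:
        k = len(lineages)
        t = rng.exponential(2.0 / (k * (k - 1)))
        for ln in lineages:
            branch_len[ln] += t
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        segments.append((a, branch_len.pop(a)))
        segments.append((b, branch_len.pop(b)))
        merged = a | b
        lineages.append(merged)
        branch_len[merged] = 0.0
    columns = []
    for carriers, length in segments:
        n_mut = rng.poisson(theta / 2.0 * length)
        for _ in range(n_mut):
            columns.append(carriers)
    seqs = [
        "".join("1" if i in col else "0" for col in columns) for i in range(n)
    ]
    return SiteMatrix(sequences=seqs, ids=[f"h{i}" for i in range(n)])


@dataclass
class SimNeighborhoods:
    hoods: dict[str, Neighborhood]
    ortholog_maps: dict[str, OrthologMap]  # other genome -> map vs genome g01


def simulate_neighborhoods(
    n_genomes: int, n_genes: int, shuffle_rate: float, seed: int
) -> SimNeighborhoods:
    """Genome g01 is the reference gene order; every other genome applies
    random adjacent transpositions and occasional deletions at
    ``shuffle_rate`` (expected ops per gene). The true ortholog map of each
    genome against the reference is returned."""
    if not 0.0 <= shuffle_rate <= 1.0:
        raise ValueError("shuffle_rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    ref_genes = [f"g01_{i:04d}" for i in range(n_genes)]
    hoods = {"g01": Neighborhood(genome="g01", genes=list(ref_genes))}
    maps = {}
    for g in range(2, n_genomes + 1):
        name = f"g{g:02d}"
        genes = [f"{name}_{i:04d}" for i in range(n_genes)]
        pairs = {(ref_genes[i], genes[i]) for i in range(n_genes)}
        n_ops = int(round(shuffle_rate * n_genes))
        for _ in range(n_ops):
            if len(genes) < 2:
                break
            if rng.random() < 0.8:  # adjacent transposition
                i = int(rng.integers(len(genes) - 1))
                genes[i], genes[i + 1] = genes[i + 1], genes[i]
            else:  # deletion
                i = int(rng.integers(len(genes)))
                gone = genes.pop(i)
                pairs = {(a, b) for a, b in pairs if b != gone}
        hoods[name] = Neighborhood(genome=name, genes=genes)
        maps[name] = OrthologMap(pairs=pairs)
    return SimNeighborhoods(hoods=hoods, ortholog_maps=maps)


def simulate_hit_table(
    n_hits: int, seed: int, frac_passing: float = 0.5
) -> list:
    """Homology-hit records with controlled coverage/e-value mixture:
    about ``frac_passing`` of the hits satisfy the paper's cutoffs
    (coverage > 0.90, e-value < 1e-100)."""
    from .lgt_caller import HitRecord

    rng = np.random.default_rng(seed)
    lineages = [
        ("Eurotiomycetes", "Eurotiales", "Aspergillus"),
        ("Sordariomycetes", "Xylariales", "Pestalotiopsis"),
        ("Leotiomycetes", "Helotiales", "Oidiodendron"),
        ("Dothideomycetes", "Pleosporales", "Alternaria"),
    ]
    hits = []
    for i in range(n_hits):
        passing = rng.random() < frac_passing
        if passing:
            cov = float(rng.uniform(0.905, 1.0))
            ev = float(10.0 ** rng.uniform(-250, -101))
        else:
            if rng.random() < 0.5:
                cov = float(rng.uniform(0.2, 0.90))
                ev = float(10.0 ** rng.uniform(-250, -101))
            else:
                cov = float(rng.uniform(0.905, 1.0))
                ev = float(10.0 ** rng.uniform(-99, -5))
        lin = lineages[int(rng.integers(len(lineages)))]
        hits.append(
            HitRecord(
                query=f"q{i:03d}",
                subject=f"s{i:03d}",
                subject_species=f"{lin[2]}_sp{i%7}",
                lineage=lin,
                coverage=cov,
                evalue=ev,
            )
        )
    return hits
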