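"""End-to-end LGT decision procedure.

Homolog filtering, per-family classification across transfer:duplication
cost ratios with an independent SPR/RF cross-check, donor assignment, and
the aggregate summary table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from . import trees as T
from .reconcile import CostScheme, Reconciliation, dl_reconcile, dtl_reconcile, resolve_polytomies, optimal_root

CATEGORIES = ("vertical", "lgt", "unresolved", "conflicting")


# ---------------------------------------------------------------------------
# Homolog filtering


@dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    subject_species: str
    lineage: tuple  # ordered, broad to narrow: (class, order, genus)
    coverage: float  # query coverage, fraction
    evalue: float

    def __post_init__(self):
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0,1]")
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


def filter_homologs(
    hits, min_coverage: float = 0.90, max_evalue: float = 1e-100
):
    """Keep hits with coverage strictly above and e-value strictly below
    the cutoffs; input order is preserved."""
    return [
        h for h in hits if h.coverage > min_coverage and h.evalue < max_evalue
    ]


@dataclass(frozen=True)
class SeqRecord:
    id: str
    species: str
    sequence: str


def dedupe_by_species(records):
    """Drop records whose (species, sequence) pair was already seen; the
    first occurrence (input order) wins. Identical sequences from different
    species are all kept."""
    seen = set()
    out = []
    for r in records:
        key = (r.species, r.sequence)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# SPR/RF cross-check


@dataclass(frozen=True)
class CandidateTransfer:
    moved_clade: frozenset  # species labels of the pruned subtree
    destination: frozenset  # species subtended by the regraft edge
    rf_before: int
    rf_after: int
    resolved_splits: tuple = ()  # conflicting splits this move eliminated

    def involves(self, focal: frozenset, leaves: frozenset) -> bool:
        """Whether this candidate implicates the focal clade: it moves into
        or out of it, or it resolves a split that tears the clade apart.

        An SPR repair can be phrased as moving either side of a conflicting
        edge, so the moved/destination sets alone under-report involvement.
        """
        if (self.moved_clade & focal) or (self.destination & focal):
            return True
        present = focal & leaves
        if len(present) < 2:
            return False
        for side in self.resolved_splits:
            if (present & side) and (present - side):
                return True
        return False


def _path_support(leaf: T.Node) -> float:
    s = 1.0
    n = leaf
    while n is not None:
        if n.support is not None:
            s = min(s, n.support)
        n = n.parent
    return s


def _tip_selections(gene: T.Tree, max_selections: int):
    """Deterministic one-tip-per-species selections of a gene tree.

    Per species, candidate tips are ranked by descending root-path support
    (missing supports count as 1.0), then gene label; the first selection is
    the canonical one. For multi-copy families the Cartesian product of
    per-species alternatives is enumerated up to ``max_selections`` so a
    transferred extra copy is not silently hidden by its vertical paralog.
    """
    per_species: dict[str, list[str]] = {}
    for leaf in gene.leaves():
        sp = T.species_of(leaf.label)
        per_species.setdefault(sp, []).append(leaf.label)
    ordered = []
    for sp in sorted(per_species):
        tips = sorted(
            per_species[sp],
            key=lambda lb: (-_path_support(_find_leaf(gene, lb)), lb),
        )
        ordered.append(tips)
    count = 0
    for combo in itertools.product(*ordered):
        if count >= max_selections:
            break
        count += 1
        yield set(combo)


def _find_leaf(tree: T.Tree, label: str) -> T.Node:
    for leaf in tree.leaves():
        if leaf.label == label:
            return leaf
    raise KeyError(label)


def _reduce_to_selection(gene: T.Tree, keep_labels: set) -> T.Tree:
    """Prune to the selected tips and relabel them to species ids."""
    tree = gene.copy()
    for leaf in list(tree.leaves()):
        if leaf.label not in keep_labels:
            _prune_leaf(tree, leaf)
    for leaf in tree.leaves():
        leaf.label = T.species_of(leaf.label)
    return tree


def _prune_leaf(tree: T.Tree, leaf: T.Node) -> None:
    parent = leaf.parent
    parent.detach_child(leaf)
    _suppress_unary(tree, parent)


def _suppress_unary(tree: T.Tree, node: T.Node) -> None:
    while node is not None and len(node.children) == 1:
        child = node.children[0]
        if node.parent is None:
            child.parent = None
            if child.length is not None and node.length is not None:
                child.length += node.length
            tree.root = child
            node = None
        else:
            parent = node.parent
            idx = parent.children.index(node)
            node.detach_child(child)
            if child.length is not None and node.length is not None:
                child.length += node.length
            parent.children[idx] = child
            child.parent = parent
            node = None


def _spr_moves(tree: T.Tree):
    """All (pruned-subtree, regraft-target) SPR variants of a rooted tree."""
    out = []
    nodes = list(tree.traverse_preorder())
    for s in nodes:
        if s.parent is None:
            continue
        moved = frozenset(lf.label for lf in s.leaves())
        cand = tree.copy()
        orig = list(tree.traverse_preorder())
        copy_nodes = list(cand.traverse_preorder())
        s_c = copy_nodes[orig.index(s)]
        parent = s_c.parent
        parent.detach_child(s_c)
        _suppress_unary(cand, parent)
        if len(cand.root.children) < 2:
            continue
        remaining = list(cand.traverse_preorder())
        for t_idx, t in enumerate(remaining):
            if t is cand.root:
                continue
            regraft = cand.copy()
            rnodes = list(regraft.traverse_preorder())
            t_r = rnodes[t_idx]
            p = t_r.parent
            idx = p.children.index(t_r)
            joint = T.Node()
            p.children[idx] = joint
            joint.parent = p
            joint.add_child(t_r)
            joint.add_child(s_c.copy())
            dest = frozenset(lf.label for lf in t_r.leaves())
            out.append((moved, dest, regraft))
    return out


def spr_transfer_scan(
    gene: T.Tree,
    species: T.Tree,
    max_moves: int = 5,
    max_selections: int = 32,
) -> list[CandidateTransfer]:
    """Greedy SPR walk moving the gene tree toward the species topology.

    The gene tree is reduced to one tip per species (every bounded copy
    selection is scanned, canonical first) and midpoint-rooted; each
    accepted move maximally reduces the (unrooted) RF distance to the
    species tree and is reported as a candidate transfer. Each walk stops at
    distance zero, at ``max_moves``, or when no move strictly improves;
    candidates are pooled over selections without duplicates.
    """
    candidates: list[CandidateTransfer] = []
    seen = set()
    for keep in _tip_selections(gene, max_selections):
        current = _reduce_to_selection(gene, keep)
        have_lengths = all(
            n.length is not None
            for n in current.traverse_postorder()
            if n.parent is not None
        )
        current = T.midpoint_root(current, unit_lengths=not have_lengths)
        pruned_species = _restrict_species(species, set(current.leaf_labels()))
        sp_splits = {b.canonical() for b in T.bipartitions(pruned_species)}

        def conflicts(tree):
            return {
                b.canonical() for b in T.bipartitions(tree)
            } - sp_splits

        dist = T.rf_distance(current, pruned_species)
        moves = 0
        while dist > 0 and moves < max_moves:
            best = None
            for moved, dest, cand in _spr_moves(current):
                d = T.rf_distance(cand, pruned_species)
                key = (d, T.write_newick(cand))
                if best is None or key < best[0]:
                    best = (key, moved, dest, cand, d)
            if best is None or best[4] >= dist:
                break
            _key, moved, dest, cand, d = best
            if (moved, dest) not in seen:
                seen.add((moved, dest))
                resolved = conflicts(current) - conflicts(cand)
                candidates.append(
                    CandidateTransfer(
                        moved_clade=moved,
                        destination=dest,
                        rf_before=dist,
                        rf_after=d,
                        resolved_splits=tuple(sorted(resolved, key=sorted)),
                    )
                )
            current, dist = cand, d
            moves += 1
    return candidates


def _restrict_species(species: T.Tree, keep: set) -> T.Tree:
    tree = species.copy()
    for leaf in list(tree.leaves()):
        if leaf.label not in keep:
            _prune_leaf(tree, leaf)
    return tree


# ---------------------------------------------------------------------------
# Per-family classification


@dataclass(frozen=True)
class RatioOutcome:
    ratio: float
    n_transfers: int
    dtl_cost: float
    dl_cost: float


@dataclass
class FamilyClassification:
    family_id: str
    per_ratio: dict[float, RatioOutcome]
    spr_candidates: list[CandidateTransfer]
    category: str
    donor_lineages: list[str] = field(default_factory=list)
    pre_diversification: bool = False
    ratio_unstable: bool = False

    def __post_init__(self):
        # classify_family emits only CATEGORIES; externally built tables may
        # carry extra residual categories, which the summary must tolerate
        if not self.category:
            raise ValueError("category must be non-empty")


def classify_family(
    gene: T.Tree,
    species: T.Tree,
    ratios=(2.0, 4.0, 6.0),
    threshold: float = 0.9,
    focal_clade: frozenset = frozenset(),
    family_id: str = "family",
    taxonomy: dict | None = None,
) -> FamilyClassification:
    """Classify one gene family as vertical / lgt / unresolved / conflicting.

    Pipeline: collapse weakly supported edges, resolve polytomies, reconcile
    at every transfer:duplication ratio (dup = loss = 1), and cross-check
    with the SPR/RF scan. The decision is taken at the primary (smallest)
    ratio; instability across ratios is flagged, not averaged.
    """
    ratios = sorted(float(r) for r in ratios)
    primary = ratios[0]
    focal_clade = frozenset(focal_clade)

    leaf_species = {T.species_of(lb) for lb in gene.leaf_labels()}
    if focal_clade and leaf_species <= focal_clade:
        return FamilyClassification(
            family_id=family_id,
            per_ratio={},
            spr_candidates=[],
            category="unresolved",
        )

    work = T.collapse_weak_edges(gene, threshold)
    if work.unrooted or len(work.root.children) != 2:
        work = optimal_root(work, species, CostScheme.from_ratio(primary))
    work = resolve_polytomies(work, species, CostScheme.from_ratio(primary))

    per_ratio: dict[float, RatioOutcome] = {}
    recs: dict[float, Reconciliation] = {}
    for r in ratios:
        scheme = CostScheme.from_ratio(r)
        rec = dtl_reconcile(work, species, scheme)
        dl = dl_reconcile(work, species, scheme)
        recs[r] = rec
        per_ratio[r] = RatioOutcome(
            ratio=r,
            n_transfers=rec.n_transfers,
            dtl_cost=rec.total_cost,
            dl_cost=dl.total_cost,
        )

    spr = spr_transfer_scan(gene, species)

    primary_out = per_ratio[primary]
    all_leaves = frozenset(leaf_species)
    spr_focal = [c for c in spr if c.involves(focal_clade, all_leaves)]
    if primary_out.n_transfers == 0:
        category = "vertical"
    elif primary_out.dtl_cost < primary_out.dl_cost and (
        spr_focal or not focal_clade
    ):
        category = "lgt"
    else:
        category = "conflicting"

    transfer_counts = [per_ratio[r].n_transfers for r in ratios]
    unstable = len(set(tc > 0 for tc in transfer_counts)) > 1

    donors: list[str] = []
    pre_div = False
    if category == "lgt":
        rec = recs[primary]
        donors = assign_donor(
            rec, species, taxonomy or {}, focal_clade=focal_clade
        ) if taxonomy else _donor_edges(rec, focal_clade)
        for e in rec.transfers():
            if focal_clade and rec.species_leafsets[e.recipient] == focal_clade:
                pre_div = True

    return FamilyClassification(
        family_id=family_id,
        per_ratio=per_ratio,
        spr_candidates=spr,
        category=category,
        donor_lineages=donors,
        pre_diversification=pre_div,
        ratio_unstable=unstable,
    )


def _donor_edges(rec: Reconciliation, focal_clade: frozenset) -> list[str]:
    """Donor edge descriptions when no taxonomy is supplied."""
    out = []
    for e in rec.transfers():
        if focal_clade and not (rec.species_leafsets[e.recipient] & focal_clade):
            continue
        leaves = sorted(rec.species_leafsets[e.donor])
        out.append(leaves[0] if len(leaves) == 1 else "+".join(leaves))
    return out


def assign_donor(
    rec: Reconciliation,
    species: T.Tree,
    taxonomy: dict[str, tuple],
    focal_clade: frozenset = frozenset(),
) -> list[str]:
    """Summarize each transfer's donor edge as the smallest taxonomic rank
    containing all species it subtends.

    ``taxonomy`` maps species id to an ordered lineage (broad to narrow,
    e.g. class > order > genus). A terminal donor edge reports the species
    itself; the species-tree root edge reports ``"unresolved (root)"``.
    """
    all_species = frozenset(species.leaf_labels())
    donors = []
    for e in rec.transfers():
        recipient_leaves = rec.species_leafsets[e.recipient]
        if focal_clade and not (recipient_leaves & focal_clade):
            continue
        donor_leaves = rec.species_leafsets[e.donor]
        if donor_leaves == all_species:
            donors.append("unresolved (root)")
            continue
        if len(donor_leaves) == 1:
            donors.append(next(iter(donor_leaves)))
            continue
        missing = sorted(s for s in donor_leaves if s not in taxonomy)
        if missing:
            raise KeyError(f"species missing from taxonomy: {missing}")
        lineages = [tuple(taxonomy[s]) for s in sorted(donor_leaves)]
        shared = None
        for level in range(min(len(ln) for ln in lineages)):
            vals = {ln[level] for ln in lineages}
            if len(vals) == 1:
                shared = vals.pop()
            else:
                break
        donors.append(shared if shared is not None else "unresolved (root)")
    return donors


# ---------------------------------------------------------------------------
# Summary


def round_half_up_pct(count: int, total: int) -> int:
    """Nearest-integer percentage, halves rounding up."""
    return int(math.floor(100.0 * count / total + 0.5))


@dataclass
class Summary:
    total: int
    counts: dict[str, int]
    percentages: dict[str, int]
    donor_frequency: list[tuple[str, int]]

    def count(self, category: str) -> int:
        return self.counts.get(category, 0)

    def pct(self, category: str) -> int:
        return self.percentages.get(category, 0)

    def pct_of_count(self, count: int) -> int:
        return round_half_up_pct(count, self.total)

    @property
    def discordant_count(self) -> int:
        """Groups not concordant with the species phylogeny and not
        unresolved (i.e. total minus vertical minus unresolved)."""
        return self.total - self.count("vertical") - self.count("unresolved")

    @property
    def discordant_pct(self) -> int:
        return round_half_up_pct(self.discordant_count, self.total)

    @property
    def remainder_count(self) -> int:
        """Groups left after removing the vertical and lgt categories."""
        return self.total - self.count("vertical") - self.count("lgt")

    @property
    def remainder_pct(self) -> int:
        return round_half_up_pct(self.remainder_count, self.total)

    def to_rows(self) -> list[tuple]:
        rows = [
            (cat, self.counts.get(cat, 0), self.percentages.get(cat, 0))
            for cat in sorted(self.counts)
        ]
        rows.append(("discordant*", self.discordant_count, self.discordant_pct))
        rows.append(("remainder*", self.remainder_count, self.remainder_pct))
        return rows


def summarize_classification(classifications) -> Summary:
    """Aggregate per-family classifications into the count/percentage table.

    Percentages are nearest-integer (half up) of 100*count/total; the donor
    frequency table is sorted by descending count, then name.
    """
    classifications = list(classifications)
    if not classifications:
        raise ValueError("no classifications to summarize")
    counts: dict[str, int] = {}
    donor_counts: dict[str, int] = {}
    for fc in classifications:
        counts[fc.category] = counts.get(fc.category, 0) + 1
        for d in getattr(fc, "donor_lineages", []):
            donor_counts[d] = donor_counts.get(d, 0) + 1
    total = len(classifications)
    percentages = {
        cat: round_half_up_pct(n, total) for cat, n in counts.items()
    }
    donor_frequency = sorted(donor_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return Summary(
        total=total,
        counts=counts,
        percentages=percentages,
        donor_frequency=donor_frequency,
    )


def occupancy_total(category_counts) -> int:
    """Sum of occupancy-category group counts (bookkeeping check)."""
    vals = list(category_counts)
    if any((not isinstance(v, int)) or v < 0 for v in vals):
        raise ValueError("occupancy counts must be non-negative integers")
    return sum(vals)
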