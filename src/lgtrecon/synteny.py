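"""Flanking-gene synteny scoring and the cluster-conservation test.

Order conservation is scored as the longest order-preserving (strictly
increasing) matching of flank positions; an inversion therefore counts as
broken order. Coordinates are 1-based gene ranks on a scaffold.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field


@dataclass
class Neighborhood:
    """Ordered gene ids along one genome's scaffold."""

    genome: str
    genes: list[str]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate gene ids in genome {self.genome!r}")
        self._pos = {g: i for i, g in enumerate(self.genes)}

    def position(self, gene: str) -> int:
        if gene not in self._pos:
            raise KeyError(f"gene {gene!r} absent from genome {self.genome!r}")
        return self._pos[gene]

    def flanks(self, gene: str, flank: int) -> tuple[list[str], bool]:
        """Up to ``flank`` genes on each side, in scaffold order; the flag is
        True when both sides were complete."""
        i = self.position(gene)
        left = self.genes[max(0, i - flank) : i]
        right = self.genes[i + 1 : i + 1 + flank]
        complete = len(left) == flank and len(right) == flank
        return left + right, complete


@dataclass
class OrthologMap:
    """One-to-one gene correspondences between two genomes."""

    pairs: set = field(default_factory=set)

    def __post_init__(self):
        self.pairs = set(self.pairs)
        a_seen, b_seen = set(), set()
        for a, b in self.pairs:
            if a in a_seen or b in b_seen:
                raise ValueError("ortholog map must be one-to-one")
            a_seen.add(a)
            b_seen.add(b)
        self._fwd = {a: b for a, b in self.pairs}
        self._rev = {b: a for a, b in self.pairs}

    def forward(self, gene: str):
        return self._fwd.get(gene)

    def reverse(self, gene: str):
        return self._rev.get(gene)


def _lis_length(seq: list[int]) -> int:
    """Longest strictly increasing subsequence length."""
    tails: list[int] = []
    for x in seq:
        i = bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


@dataclass
class SyntenyResult:
    score: float  # percentage in [0, 100]
    n_flanks: int  # flank positions actually scored
    truncated: bool  # fewer than `flank` genes available on a side


def synteny_score(
    focal_a: str,
    focal_b: str,
    hood_a: Neighborhood,
    hood_b: Neighborhood,
    orthos: OrthologMap,
    flank: int = 5,
) -> SyntenyResult:
    """Percentage of focal_a's flanking genes with an ortholog among
    focal_b's flanks in conserved relative order.

    100 iff every flank position is ortholog-matched in order. A side with
    fewer than ``flank`` genes is scored over the available positions and
    flagged as truncated.
    """
    hood_a.position(focal_a)
    hood_b.position(focal_b)
    flanks_a, complete_a = hood_a.flanks(focal_a, flank)
    flanks_b, complete_b = hood_b.flanks(focal_b, flank)
    if not flanks_a:
        return SyntenyResult(score=0.0, n_flanks=0, truncated=True)
    pos_b = {g: i for i, g in enumerate(flanks_b)}
    matched_positions = []
    for g in flanks_a:
        o = orthos.forward(g)
        if o is not None and o in pos_b:
            matched_positions.append(pos_b[o])
    k = _lis_length(matched_positions)
    return SyntenyResult(
        score=100.0 * k / len(flanks_a),
        n_flanks=len(flanks_a),
        truncated=not (complete_a and complete_b),
    )


def cluster_synteny_test(cluster, scores, cutoff: float = 80.0) -> bool:
    """Conserved iff the fraction of conserved gene positions across the
    cluster strictly exceeds ``cutoff`` percent.

    ``scores`` maps each cluster gene to its synteny percentage; a position
    contributes its fractional conservation.
    """
    cluster = list(cluster)
    if not cluster:
        raise ValueError("empty cluster")
    missing = [g for g in cluster if g not in scores]
    if missing:
        raise KeyError(f"no synteny score for cluster genes: {missing}")
    mean_pct = sum(scores[g] for g in cluster) / len(cluster)
    return mean_pct > cutoff


def read_gene_orders(path) -> dict[str, Neighborhood]:
    """TSV columns: genome, scaffold, rank, gene id. One Neighborhood per
    (genome, scaffold); multi-scaffold genomes are keyed genome:scaffold."""
    import pandas as pd

    df = pd.read_csv(
        path, sep="\t", names=["genome", "scaffold", "rank", "gene"], header=0
    )
    hoods = {}
    for (genome, scaffold), grp in df.groupby(["genome", "scaffold"]):
        genes = list(grp.sort_values("rank")["gene"])
        key = genome if df["scaffold"].nunique() == 1 else f"{genome}:{scaffold}"
        hoods[key] = Neighborhood(genome=str(key), genes=[str(g) for g in genes])
    return hoods


def read_ortholog_pairs(path) -> OrthologMap:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", names=["a", "b"], header=0)
    return OrthologMap(pairs={(str(r.a), str(r.b)) for r in df.itertuples()})
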