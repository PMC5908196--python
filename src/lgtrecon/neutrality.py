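"""Tajima's D and the phylogenomic-marker selection filter.

D contrasts mean pairwise diversity with the scaled segregating-site count:
D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)). Sites with gaps or more than two
alleles are excluded from both S and pi (infinite-sites assumptions).
Significance uses the beta-distribution approximation of the original test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

GAP_CHARS = set("-?NnXx.")

UNDEFINED = None  # sentinel for D when S == 0 or the variance vanishes


@dataclass
class SiteMatrix:
    """n aligned sequences; rows are haplotypes, columns are sites."""

    sequences: list[str]
    ids: Optional[list[str]] = None

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise ValueError("need at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("all rows must have equal length")
        if self.ids is None:
            self.ids = [f"seq{i}" for i in range(len(self.sequences))]

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def usable_columns(self):
        """Columns that are gap-free and at most biallelic."""
        for j in range(self.length):
            col = [s[j] for s in self.sequences]
            if any(c in GAP_CHARS for c in col):
                continue
            if len(set(col)) > 2:
                continue
            yield col

    @classmethod
    def from_fasta(cls, path) -> "SiteMatrix":
        from Bio import SeqIO

        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        return cls(sequences=seqs, ids=ids)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.ids, self.sequences):
                fh.write(f">{name}\n{seq}\n")


def _tajima_constants(n: int):
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def segregating_sites(sites: SiteMatrix) -> int:
    return sum(1 for col in sites.usable_columns() if len(set(col)) == 2)


def pairwise_diversity(sites: SiteMatrix) -> float:
    """Mean pairwise difference count over all n(n-1)/2 unordered pairs."""
    n = sites.n
    total = 0
    for col in sites.usable_columns():
        counts = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        if len(counts) == 2:
            k1 = next(iter(counts.values()))
            total += k1 * (n - k1)
    return total / (n * (n - 1) / 2.0)


def tajimas_d(sites: SiteMatrix) -> Optional[float]:
    """Tajima's D, or None (undefined) when S = 0 or the variance term is 0."""
    n = sites.n
    if n < 2:
        raise ValueError("need at least 2 sequences")
    S = segregating_sites(sites)
    if S == 0:
        return UNDEFINED
    a1, *_rest, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    pi = pairwise_diversity(sites)
    num = pi - S / a1
    # at n = 3 the variance term vanishes identically while the numerator is
    # exactly 0 (every site a singleton): take the 0/0 limit as D = 0
    if math.isclose(num, 0.0, abs_tol=1e-12):
        return 0.0
    if var <= 0:
        return UNDEFINED
    return num / math.sqrt(var)


def _beta_limits(n: int, alpha: float):
    """Two-sided confidence limits of the beta approximation for D."""
    a1 = _tajima_constants(n)[0]
    e2 = _tajima_constants(n)[7]
    d_min = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    if n % 2 == 0:
        pi_max = n / (2.0 * (n - 1))
    else:
        pi_max = (n + 1) / (2.0 * n)
    d_max = (pi_max - 1.0 / a1) / math.sqrt(e2)
    span = d_max - d_min
    mean_x = -d_min / span  # scaled so that E[D] = 0
    var_x = 1.0 / span**2  # and Var[D] = 1
    s = mean_x * (1 - mean_x) / var_x - 1.0
    p, q = mean_x * s, (1 - mean_x) * s
    dist = stats.beta(p, q, loc=d_min, scale=span)
    return dist.ppf(alpha / 2.0), dist.ppf(1.0 - alpha / 2.0)


def neutrality_classify(
    d: Optional[float], n: int, alpha: float = 0.05
) -> str:
    """Classify a D value as 'neutral', 'non-neutral', or 'undefined'."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    if d is UNDEFINED:
        return "undefined"
    if n < 4:
        # the variance term vanishes at n = 3; any defined D is 0
        return "neutral" if d == 0 else "non-neutral"
    lo, hi = _beta_limits(n, alpha)
    return "neutral" if lo <= d <= hi else "non-neutral"


@dataclass
class MarkerCandidate:
    gene_id: str
    syntenic_in_all: bool
    max_offtarget_similarity: float  # fraction in [0,1]
    tajima_d: Optional[float]
    d_classification: str

    def __post_init__(self):
        if not 0.0 <= self.max_offtarget_similarity <= 1.0:
            raise ValueError("similarity must be in [0,1]")


def select_markers(candidates, similarity_cutoff: float = 0.50):
    """Marker filter: syntenic in all genomes, no off-target protein above
    the similarity cutoff (strictly greater excludes), and neutral D."""
    return [
        c
        for c in candidates
        if c.syntenic_in_all
        and c.max_offtarget_similarity <= similarity_cutoff
        and c.d_classification == "neutral"
    ]
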