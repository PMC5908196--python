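"""Count-matrix analytics: hierarchical clustering, PCA, genome fraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class CountMatrix:
    """Species x family grid of non-negative integer gene counts."""

    data: pd.DataFrame  # rows: species, columns: family names

    def __post_init__(self):
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("row and column labels must be unique")
        if (self.data.values < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")


@dataclass
class Dendrogram:
    labels: list[str]
    merges: list[tuple[int, int, float]]  # scipy-style merge list

    @property
    def heights(self) -> list[float]:
        return [h for _a, _b, h in self.merges]

    def to_newick(self) -> str:
        n = len(self.labels)
        reps: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            left, right = sorted((reps[a], reps[b]))
            reps[n + k] = f"({left},{right})"
        return reps[n + len(self.merges) - 1] + ";"

    def to_text(self) -> str:
        lines = []
        for a, b, h in self.merges:
            lines.append(f"merge\t{a}\t{b}\t{h:.6g}")
        return "\n".join(lines) + "\n"


def cluster_rows(m: CountMatrix) -> Dendrogram:
    """Agglomerative clustering, Euclidean distance, complete linkage.

    Rows are pre-sorted lexicographically by label so merge order (and any
    distance ties) resolve deterministically.
    """
    if len(m.data) < 2:
        raise ValueError("need at least 2 rows to cluster")
    df = m.data.sort_index()
    z = hierarchy.linkage(pdist(df.values.astype(float)), method="complete")
    merges = [(int(a), int(b), float(h)) for a, b, h, _cnt in z]
    return Dendrogram(labels=list(df.index), merges=merges)


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # species x k
    explained_variance: np.ndarray  # fractions, non-increasing
    loadings: np.ndarray  # columns x k, orthonormal


def pca_coords(m: CountMatrix, k: int = 2, scale: bool = False) -> PCAResult:
    """PCA of the column-centered (optionally unit-variance scaled) counts.

    Coordinates reproduce the centered matrix's best rank-k approximation;
    signs are fixed so each loading's largest-magnitude entry is positive.
    """
    x = m.data.values.astype(float)
    if k > min(x.shape):
        raise ValueError("k exceeds matrix rank bound")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total_var = (s**2).sum()
    # deterministic sign convention
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    coords = u[:, :k] * s[:k]
    ev = (
        (s[:k] ** 2) / total_var
        if total_var > 0
        else np.zeros(k)
    )
    return PCAResult(
        coordinates=pd.DataFrame(
            coords,
            index=m.data.index,
            columns=[f"PC{i+1}" for i in range(k)],
        ),
        explained_variance=ev,
        loadings=vt[:k].T,
    )


def genome_fraction(pcwd_count: int, total_genes: int) -> float:
    """Percentage of the genome devoted to the gene set, to one decimal."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    if pcwd_count > total_genes:
        raise ValueError("subset cannot exceed the genome size")
    return round(100.0 * pcwd_count / total_genes, 1)
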