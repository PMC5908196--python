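"""Simulation-based operating characteristics of the LGT caller.

Used by the test suite and the acceptance report: false-positive control on
transfer-free families and power on single-transfer families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lgt_caller import classify_family
from .synthetic_data import (
    SimParams,
    simulate_dtl_family,
    simulate_family_with_one_transfer,
    simulate_species_tree,
)
from .trees import Tree


def _focal_clade(species: Tree) -> frozenset:
    """A proper focal clade: the smallest internal clade with at least two
    species that leaves at least two species outside it."""
    n = len(species.leaves())
    candidates = [
        frozenset(lf.label for lf in node.leaves())
        for node in species.traverse_postorder()
        if node.children and node.parent is not None
    ]
    candidates = [c for c in candidates if 2 <= len(c) <= n - 2]
    if not candidates:
        raise ValueError("species tree too small for a proper focal clade")
    return min(candidates, key=lambda s: (len(s), sorted(s)))


@dataclass
class BenchmarkResult:
    n_families: int
    n_lgt: int
    categories: dict[str, int]

    @property
    def lgt_rate(self) -> float:
        return self.n_lgt / self.n_families


def false_positive_benchmark(
    n_families: int = 200,
    n_taxa: int = 8,
    r_dup: float = 0.3,
    r_loss: float = 0.3,
    seed: int = 0,
    ratios=(2.0, 4.0, 6.0),
) -> BenchmarkResult:
    """Fraction of transfer-free (duplication+loss only) families the
    caller classifies as lgt; should be small."""
    rng = np.random.SeedSequence(seed)
    sp_seed, fam_seed = rng.spawn(2)
    species = simulate_species_tree(n_taxa, int(sp_seed.generate_state(1)[0]))
    focal = _focal_clade(species)
    cats: dict[str, int] = {}
    produced = 0
    for child in fam_seed.spawn(n_families * 20):
        if produced == n_families:
            break
        s = int(child.generate_state(1)[0])
        gene, _hist = simulate_dtl_family(
            species, SimParams(r_dup=r_dup, r_transfer=0.0, r_loss=r_loss, seed=s)
        )
        if gene is None or len(gene.leaves()) < 3:
            continue  # empty/degenerate family; resample explicitly
        if {l.split("|")[0] for l in gene.leaf_labels()} <= focal:
            continue  # would be trivially unresolved
        fc = classify_family(
            gene, species, ratios=ratios, focal_clade=focal,
            family_id=f"fam{produced}",
        )
        cats[fc.category] = cats.get(fc.category, 0) + 1
        produced += 1
    return BenchmarkResult(
        n_families=produced, n_lgt=cats.get("lgt", 0), categories=cats
    )


def power_benchmark(
    n_families: int = 200,
    n_taxa: int = 8,
    seed: int = 0,
    ratios=(2.0, 4.0, 6.0),
) -> BenchmarkResult:
    """Fraction of families carrying exactly one true transfer into the
    focal clade that the caller classifies as lgt at the primary ratio."""
    rng = np.random.SeedSequence(seed)
    sp_seed, fam_seed = rng.spawn(2)
    species = simulate_species_tree(n_taxa, int(sp_seed.generate_state(1)[0]))
    focal = _focal_clade(species)
    cats: dict[str, int] = {}
    for i, child in enumerate(fam_seed.spawn(n_families)):
        gene, _hist = simulate_family_with_one_transfer(
            species, focal, seed=int(child.generate_state(1)[0])
        )
        fc = classify_family(
            gene, species, ratios=ratios, focal_clade=focal, family_id=f"fam{i}"
        )
        cats[fc.category] = cats.get(fc.category, 0) + 1
    return BenchmarkResult(
        n_families=n_families, n_lgt=cats.get("lgt", 0), categories=cats
    )
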