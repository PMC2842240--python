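"""Phylogenetic resolution metrics per clade and year.

Resolution is the count of resolved nodes — nontrivial bipartitions
retained in a bootstrap consensus — divided by the node count of a fully
bifurcating tree of *all described* species in the clade, N - 2.  Because
support-bearing objects in an unrooted consensus are its splits (at most
N - 3 of them), a completely resolved, completely sampled clade scores
(N - 3)/(N - 2), just short of 1; the denominator is kept as the field
convention prints it.  Single-gene trees use the sampled-taxa denominator
(taxa in tree minus two) instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from .trees import ConsensusTree


@dataclass
class ResolutionRecord:
    """Resolution and dataset statistics for one (clade, year) supermatrix."""

    clade: str
    year: int
    n_described: int
    n_sampled: int
    resolved_50: int
    resolved_95: int
    density: float
    characters_per_species: float
    width: int

    def __post_init__(self) -> None:
        if self.n_described < 3:
            raise ValueError("resolution undefined for fewer than 3 described species")
        cap = max(self.n_sampled - 3, 0)
        if not (0 <= self.resolved_95 <= self.resolved_50 <= cap):
            raise ValueError(
                f"{self.clade}/{self.year}: need 0 <= resolved_95 <= resolved_50 <= {cap}"
            )

    @property
    def resolution_50(self) -> float:
        return clade_resolution(self.resolved_50, self.n_described)

    @property
    def resolution_95(self) -> float:
        return clade_resolution(self.resolved_95, self.n_described)


def count_resolved(consensus: ConsensusTree) -> int:
    """Number of nontrivial bipartitions retained at the consensus threshold."""
    return consensus.n_resolved


def clade_resolution(resolved: int, n_described: int) -> float:
    """resolved / (N - 2) with N the described species count (checklists)."""
    if n_described < 3:
        raise ValueError("need at least 3 described species")
    return resolved / (n_described - 2)


def pool_resolution(records: list[ResolutionRecord], level: int = 50) -> float:
    """Pooled resolution for one year: sum resolved / sum (N - 2).

    This is the all-species-pooled proportion, a (N-2)-weighted mean of
    the member clade resolutions.
    """
    if not records:
        raise ValueError("no records to pool")
    years = {r.year for r in records}
    if len(years) != 1:
        raise ValueError(f"records span multiple years: {sorted(years)}")
    if level not in (50, 95):
        raise ValueError("level must be 50 or 95")
    num = sum(r.resolved_50 if level == 50 else r.resolved_95 for r in records)
    den = sum(r.n_described - 2 for r in records)
    return num / den


def proportion_with_data(n_with_data: int, n_described: int) -> float:
    """Pooled fraction of described species with at least one record."""
    if n_described <= 0 or not 0 <= n_with_data <= n_described:
        raise ValueError("need 0 <= n_with_data <= n_described, n_described > 0")
    return n_with_data / n_described


def single_gene_resolution(consensus: ConsensusTree, n_taxa: int) -> float:
    """resolved / (n_taxa - 2): the sampled-taxa denominator for gene trees."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa in the tree")
    return consensus.n_resolved / (n_taxa - 2)
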