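"""Single-linkage gene clustering, year slicing, per-species deduplication.

Records are grouped into putative single-gene clusters by connected
components of a pairwise-similarity graph: two sequences are joined when a
free-end-gap global alignment reaches the identity threshold and covers
enough of both sequences.  This maps the classic all-against-all
BLAST-clustering contract (identity -S, coverage -L, both-sequences -b)
onto an explicit aligner; a shared-k-mer prefilter skips pairs that cannot
plausibly match.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .records import SequenceRecord

DEFAULT_YEARS = tuple(range(1993, 2009))


@dataclass(frozen=True)
class ClusteringParams:
    """Similarity thresholds for cluster edges.

    ``min_identity`` is percent identity over aligned columns (end gaps
    excluded); ``min_coverage`` is the aligned-region fraction of each
    sequence's own length.  With ``require_both`` the coverage rule must
    hold for both sequences of a pair.
    """

    min_coverage: float = 0.25
    min_identity: float = 75.0
    require_both: bool = True
    word_length: int = 11

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if self.word_length < 1:
            raise ValueError("word_length must be >= 1")


@dataclass
class GeneCluster:
    """One putative locus: a set of records, optionally year-sliced."""

    cluster_id: str
    members: list[SequenceRecord]
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have members")
        self.members = sorted(self.members, key=lambda r: r.accession)

    @property
    def species(self) -> set[str]:
        return {r.species for r in self.members}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    # mild mismatch and costly gaps: unrelated sequences align end-to-end
    # near the 25% background identity instead of gapping up to spurious
    # similarity; no indels are expected within a locus, only end truncation
    aligner.match_score = 1.0
    aligner.mismatch_score = -0.25
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -2.0
    # free end gaps: local-like placement of the shorter sequence
    aligner.end_gap_score = 0.0
    return aligner

_ALIGNER = _make_aligner()


def pair_similarity(a: SequenceRecord | str, b: SequenceRecord | str) -> tuple[float, float, float]:
    """(percent identity, coverage of a, coverage of b) for one pair.

    Identity counts matching columns over the aligned region — the span
    between the outermost columns where both sequences have started and
    not yet ended; end gaps are excluded, internal gaps count as
    mismatching columns.  Coverage is the aligned-region length in each
    sequence's own coordinates over its full length.
    """
    sa = a.sequence if isinstance(a, SequenceRecord) else a
    sb = b.sequence if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("sequences must be nonempty")
    aln = _ALIGNER.align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    # aligned span: from the later first-residue to the earlier last-residue
    def first_res(g: str) -> int:
        return len(g) - len(g.lstrip("-"))

    def last_res(g: str) -> int:
        return len(g.rstrip("-"))

    start = max(first_res(ga), first_res(gb))
    end = min(last_res(ga), last_res(gb))
    if end <= start:
        return 0.0, 0.0, 0.0
    cols = end - start
    matches = sum(
        1 for i in range(start, end) if ga[i] == gb[i] and ga[i] != "-"
    )
    res_a = sum(1 for i in range(start, end) if ga[i] != "-")
    res_b = sum(1 for i in range(start, end) if gb[i] != "-")
    identity = 100.0 * matches / cols
    return identity, res_a / len(sa), res_b / len(sb)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class _DSU:
    def __init__(self, n: int) -> None:
        self.p = list(range(n))

    def find(self, i: int) -> int:
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.p[max(ri, rj)] = min(ri, rj)


def cluster_records(
    records: list[SequenceRecord], params: ClusteringParams = ClusteringParams()
) -> list[GeneCluster]:
    """Single-linkage clusters of the similarity graph.

    Edge between a and b iff identity >= min_identity and the coverage rule
    holds.  Clusters are connected components, ordered and id-labelled by
    their smallest member accession.
    """
    recs = sorted(records, key=lambda r: r.accession)
    n = len(recs)
    kmer_sets = [_kmers(r.sequence, params.word_length) for r in recs]
    dsu = _DSU(n)
    for i in range(n):
        for j in range(i + 1, n):
            if dsu.find(i) == dsu.find(j):
                continue
            if not (kmer_sets[i] & kmer_sets[j]):
                continue
            ident, cov_a, cov_b = pair_similarity(recs[i], recs[j])
            if ident < params.min_identity:
                continue
            ok = (
                (cov_a >= params.min_coverage and cov_b >= params.min_coverage)
                if params.require_both
                else (cov_a >= params.min_coverage or cov_b >= params.min_coverage)
            )
            if ok:
                dsu.union(i, j)
    groups: dict[int, list[SequenceRecord]] = {}
    for i, r in enumerate(recs):
        groups.setdefault(dsu.find(i), []).append(r)
    comps = sorted(groups.values(), key=lambda g: g[0].accession)
    return [
        GeneCluster(cluster_id=f"c{k:04d}", members=g) for k, g in enumerate(comps)
    ]


def slice_by_year(
    clusters: list[GeneCluster],
    year: int,
    valid_years: tuple[int, ...] = DEFAULT_YEARS,
) -> list[GeneCluster]:
    """Keep only members deposited on or before Dec 31 of ``year``.

    Cluster ids are stable across slices; clusters left empty are dropped.
    """
    if valid_years is not None and year not in valid_years:
        raise ValueError(f"year {year} outside configured range {valid_years[0]}..{valid_years[-1]}")
    out: list[GeneCluster] = []
    for cl in clusters:
        members = [r for r in cl.members if r.deposition_date.year <= year]
        if members:
            out.append(GeneCluster(cluster_id=cl.cluster_id, members=members, year=year))
    return out


def dedup_longest(cluster: GeneCluster) -> GeneCluster:
    """One record per species: the longest, ties to the smallest accession."""
    best: dict[str, SequenceRecord] = {}
    for r in cluster.members:
        cur = best.get(r.species)
        if cur is None or (r.length, _neg_acc(r)) > (cur.length, _neg_acc(cur)):
            best[r.species] = r
    return GeneCluster(
        cluster_id=cluster.cluster_id, members=list(best.values()), year=cluster.year
    )


class _neg_acc:
    """Sort helper: larger is better, so invert accession order for ties."""

    __slots__ = ("acc",)

    def __init__(self, record: SequenceRecord) -> None:
        self.acc = record.accession

    def __lt__(self, other: "_neg_acc") -> bool:
        return self.acc > other.acc

    def __gt__(self, other: "_neg_acc") -> bool:
        return self.acc < other.acc

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_acc) and self.acc == other.acc
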