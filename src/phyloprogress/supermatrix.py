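"""Cluster alignment, informative-set selection, supermatrix concatenation.

The aligner is a deterministic progressive scheme with unit costs: records
are merged in guide order (decreasing length, then accession) by a
profile-to-sequence Needleman-Wunsch with free end gaps.  Columns are only
ever inserted, never edited, so ungapping any row returns its input
sequence exactly.  Alignment quality is deliberately simple — the pipeline
contract (which species end up in which partition) is what matters here,
and the aligner sits behind ``align_cluster`` so a heavier tool can be
plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clustering import GeneCluster

MISSING = "?"
GAP = "-"


@dataclass
class Alignment:
    """Gapped rows for one cluster; all rows share the same width."""

    cluster_id: str
    rows: dict[str, str]  # species -> gapped sequence

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.rows.values()}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in width")
        for sp, row in self.rows.items():
            if row.count(GAP) == len(row):
                raise ValueError(f"row {sp!r} is all gaps")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def species(self) -> set[str]:
        return set(self.rows)

    @property
    def n_species(self) -> int:
        return len(self.rows)


_BASE_ORDER = "ACGT"


def _profile_align(profile: list[str], seq: str) -> tuple[list[str], str]:
    """Align ``seq`` against gapped ``profile`` rows with unit costs.

    A column pairing scores -1 when the base occurs in the column (gaps
    ignored) and +1 otherwise; gaps cost +1 per column; end gaps are free
    (overlap alignment); the total cost is minimized.  Returns the profile
    rows and the new row, all at the merged width.

    The DP is vectorized per row: with unit gap costs the in-row
    recurrence D[i,j] = min(c[j], D[i,j-1]+1) collapses to a running
    minimum of c[k]-k, so each row is one numpy pass.
    """
    W = len(profile[0])
    L = len(seq)
    prof_arr = np.array([list(r) for r in profile])
    membT = np.stack(
        [(prof_arr == b).any(axis=0) for b in _BASE_ORDER] + [np.zeros(W, bool)],
        axis=1,
    )  # (W, 5); column 4 = "never matches"
    code = {b: k for k, b in enumerate(_BASE_ORDER)}
    seq_codes = np.array([code.get(b, 4) for b in seq])
    # match rewards -1, mismatch and gap cost +1: with free end gaps a
    # pure-cost scheme would always prefer the empty overlap, so matches
    # must pay for the columns they occupy
    match = membT[np.arange(W)[:, None], seq_codes[None, :]]
    sub = np.where(match, -1, 1).astype(np.int32)

    D = np.zeros((W + 1, L + 1), dtype=np.int32)
    j_idx = np.arange(L + 1, dtype=np.int32)
    base = np.empty(L + 1, dtype=np.int32)
    for i in range(1, W + 1):
        base[0] = 0  # leading seq gaps are free
        np.minimum(D[i - 1, :L] + sub[i - 1], D[i - 1, 1:] + 1, out=base[1:])
        D[i] = j_idx + np.minimum.accumulate(base - j_idx)
    # free trailing gaps: best endpoint on last row or last column,
    # preferring the longest aligned span, then the profile side
    ends = [(int(D[W, j]), -(W + j), 0, W, j) for j in range(L + 1)]
    ends += [(int(D[i, L]), -(i + L), 1, i, L) for i in range(W + 1)]
    _, _, _, ei, ej = min(ends)
    ops: list[str] = ["I"] * (L - ej) + ["D"] * (W - ei)
    i, j = ei, ej
    while i > 0 and j > 0:
        if D[i, j] == D[i - 1, j - 1] + sub[i - 1, j - 1]:
            ops.append("M")
            i, j = i - 1, j - 1
        elif D[i, j] == D[i - 1, j] + 1:
            ops.append("D")  # profile column, gap in seq
            i -= 1
        else:
            ops.append("I")  # seq base, gap column inserted into profile
            j -= 1
    ops.extend(["D"] * i)
    ops.extend(["I"] * j)
    ops.reverse()
    new_profile = ["" for _ in profile]
    new_row = []
    pi = si = 0
    for op in ops:
        if op == "M":
            for k, row in enumerate(profile):
                new_profile[k] += row[pi]
            new_row.append(seq[si])
            pi += 1
            si += 1
        elif op == "D":
            for k, row in enumerate(profile):
                new_profile[k] += row[pi]
            new_row.append(GAP)
            pi += 1
        else:
            for k in range(len(profile)):
                new_profile[k] += GAP
            new_row.append(seq[si])
            si += 1
    return new_profile, "".join(new_row)


def align_cluster(cluster: GeneCluster) -> Alignment:
    """Progressive alignment of a deduplicated cluster (one row per species).

    Guide order: decreasing sequence length, ties by accession.  A
    single-member cluster yields the trivial gapless alignment.
    """
    order = sorted(cluster.members, key=lambda r: (-r.length, r.accession))
    species_order = [r.species for r in order]
    if len(set(species_order)) != len(species_order):
        raise ValueError("cluster must be deduplicated to one record per species")
    profile = [order[0].sequence]
    for rec in order[1:]:
        profile, row = _profile_align(profile, rec.sequence)
        profile.append(row)
    return Alignment(
        cluster_id=cluster.cluster_id,
        rows={sp: row for sp, row in zip(species_order, profile)},
    )


def select_informative(
    alignments: list[Alignment], min_species: int = 4, min_overlap: int = 4
) -> list[Alignment]:
    """Iterate to a fixed point of the informativeness/overlap rule.

    A cluster survives while it holds at least ``min_species`` species and
    shares at least ``min_overlap`` species with some other surviving
    cluster.  If the survivors split into several connected components of
    the overlap graph, the component with the most species is kept (ties:
    more clusters, then smallest cluster id).  May return an empty list.
    """
    alive = {a.cluster_id: a for a in alignments}
    changed = True
    while changed and alive:
        changed = False
        for cid in sorted(alive):
            a = alive[cid]
            if a.n_species < min_species:
                del alive[cid]
                changed = True
                continue
            has_partner = any(
                len(a.species & b.species) >= min_overlap
                for ocid, b in alive.items()
                if ocid != cid
            )
            if not has_partner:
                del alive[cid]
                changed = True
    if not alive:
        return []
    # connected components of the overlap graph
    ids = sorted(alive)
    comp: dict[str, int] = {}
    for k, cid in enumerate(ids):
        comp[cid] = k
    merged = True
    while merged:
        merged = False
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if comp[a] != comp[b] and len(alive[a].species & alive[b].species) >= min_overlap:
                    old, new = max(comp[a], comp[b]), min(comp[a], comp[b])
                    for c in ids:
                        if comp[c] == old:
                            comp[c] = new
                    merged = True
    groups: dict[int, list[str]] = {}
    for cid in ids:
        groups.setdefault(comp[cid], []).append(cid)

    def key(g: list[str]):
        n_species = len(set().union(*(alive[c].species for c in g)))
        return (-n_species, -len(g), min(g))

    best = sorted(groups.values(), key=key)[0]
    return [alive[c] for c in sorted(best)]


@dataclass
class Supermatrix:
    """Concatenated alignment with partition map and missing-data mask.

    ``cells`` is an (n_species, width) array of single characters; '?'
    marks a species absent from a partition, '-' an alignment gap.
    Density counts nucleotide cells only (gaps and missing both excluded),
    so it tracks the amount of actual data in the matrix.
    """

    species: list[str]
    cells: np.ndarray  # dtype '<U1'
    partitions: list[tuple[str, int, int]]  # (cluster_id, start, end) half-open

    def __post_init__(self) -> None:
        if self.cells.shape != (len(self.species), self.width):
            raise ValueError("cell array shape mismatch")

    @property
    def width(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    @property
    def n_species(self) -> int:
        return len(self.species)

    def _data_mask(self) -> np.ndarray:
        return (self.cells != MISSING) & (self.cells != GAP)

    @property
    def density(self) -> float:
        return float(self._data_mask().mean())

    @property
    def characters_per_species(self) -> float:
        return float(self._data_mask().sum(axis=1).mean())

    def row(self, species: str) -> str:
        return "".join(self.cells[self.species.index(species)])

    def subset(self, keep: list[str]) -> "Supermatrix":
        idx = [self.species.index(s) for s in sorted(keep)]
        return Supermatrix(
            species=[self.species[i] for i in idx],
            cells=self.cells[idx].copy(),
            partitions=list(self.partitions),
        )

    # -- writers/readers ---------------------------------------------------

    def to_nexus(self, path: str | Path) -> None:
        """NEXUS with a SETS block of 1-based inclusive CHARSETs."""
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"    DIMENSIONS NTAX={self.n_species} NCHAR={self.width};\n")
            fh.write("    FORMAT DATATYPE=DNA MISSING=? GAP=-;\n    MATRIX\n")
            for i, sp in enumerate(self.species):
                label = sp.replace(" ", "_")
                fh.write(f"    {label}  {''.join(self.cells[i])}\n")
            fh.write("    ;\nEND;\n\nBEGIN SETS;\n")
            for cid, start, end in self.partitions:
                fh.write(f"    CHARSET {cid} = {start + 1}-{end};\n")
            fh.write("END;\n")

    def to_phylip(self, path: str | Path) -> None:
        """Relaxed PHYLIP (name, two spaces, full sequence)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_species} {self.width}\n")
            for i, sp in enumerate(self.species):
                fh.write(f"{sp.replace(' ', '_')}  {''.join(self.cells[i])}\n")

    @classmethod
    def from_nexus(cls, path: str | Path) -> "Supermatrix":
        import dendropy

        mat = dendropy.DnaCharacterMatrix.get(path=str(path), schema="nexus")
        species = sorted(t.label.replace("_", " ") for t in mat.taxon_namespace)
        rows = {
            t.label.replace("_", " "): mat[t].symbols_as_string()
            for t in mat.taxon_namespace
        }
        cells = np.array([list(rows[sp]) for sp in species], dtype="<U1")
        partitions: list[tuple[str, int, int]] = []
        for name in sorted(mat.character_subsets):
            subset = mat.character_subsets[name]
            idx = sorted(subset.character_indices)
            partitions.append((name, idx[0], idx[-1] + 1))
        partitions.sort(key=lambda p: p[1])
        return cls(species=species, cells=cells, partitions=partitions)


def concatenate(alignments: list[Alignment]) -> Supermatrix:
    """Row per species in the union; '?' fills absent partitions."""
    if not alignments:
        raise ValueError("nothing to concatenate")
    alns = sorted(alignments, key=lambda a: a.cluster_id)
    species = sorted(set().union(*(a.species for a in alns)))
    width = sum(a.width for a in alns)
    cells = np.full((len(species), width), MISSING, dtype="<U1")
    partitions: list[tuple[str, int, int]] = []
    start = 0
    for a in alns:
        end = start + a.width
        partitions.append((a.cluster_id, start, end))
        for i, sp in enumerate(species):
            if sp in a.rows:
                cells[i, start:end] = list(a.rows[sp])
        start = end
    return Supermatrix(species=species, cells=cells, partitions=partitions)
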