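"""Clade hierarchy with described (checklist) and sampled species counts.

The taxonomy is a rooted tree of named nodes.  Internal nodes are clades;
tips are species.  Every node carries a *described* species count taken from
checklists (for a species node this is 1, for a clade it is the number of
described species it contains, whether or not any of them have sequence
data).  *Sampled* counts — the number of species under a node with at least
one sequence record — are filled in from a record set and mimic an
NCBI-taxonomy-style database that only knows about sequenced species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

SPECIES_RANK = "species"


@dataclass
class Taxonomy:
    """Rooted clade hierarchy with per-node described/sampled counts."""

    parent: dict[str, str | None]
    described: dict[str, int]
    rank: dict[str, str]
    sampled: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self._root = roots[0]
        self._children: dict[str, list[str]] = {n: [] for n in self.parent}
        for n, p in self.parent.items():
            if p is not None:
                if p not in self.parent:
                    raise ValueError(f"node {n!r} has unknown parent {p!r}")
                self._children[p].append(n)
        for kids in self._children.values():
            kids.sort()
        for n, d in self.described.items():
            kid_max = max((self.described[c] for c in self._children[n]), default=0)
            if d < kid_max:
                raise ValueError(f"described count of {n!r} below a child's count")

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> str:
        return self._root

    def children(self, node: str) -> list[str]:
        return list(self._children[node])

    def is_species(self, node: str) -> bool:
        return self.rank.get(node) == SPECIES_RANK

    def contains(self, node: str) -> bool:
        return node in self.parent

    def ancestors(self, node: str, include_self: bool = False) -> list[str]:
        """Rootward path from ``node`` (tipmost first, root last)."""
        path = [node] if include_self else []
        cur = self.parent[node]
        while cur is not None:
            path.append(cur)
            cur = self.parent[cur]
        return path

    def species_under(self, node: str) -> list[str]:
        out: list[str] = []
        stack = [node]
        while stack:
            cur = stack.pop()
            if self.is_species(cur):
                out.append(cur)
            else:
                stack.extend(self._children[cur])
        return sorted(out)

    def clades(self, rank: str | None = None) -> list[str]:
        if rank is None:
            return sorted(n for n in self.parent if not self.is_species(n))
        return sorted(n for n in self.parent if self.rank.get(n) == rank)

    def overlap(self, a: str, b: str) -> bool:
        """True if one node is an ancestor of (or equal to) the other."""
        return a == b or a in self.ancestors(b) or b in self.ancestors(a)

    # -- counts ------------------------------------------------------------

    def described_count(self, node: str) -> int:
        return self.described[node]

    def sampled_count(self, node: str) -> int:
        return self.sampled.get(node, 0)

    def set_sampled_from_species(self, species: Iterable[str]) -> None:
        """Fill sampled counts from the set of species that have records.

        Species names not present in the taxonomy (misspellings, hybrids)
        are ignored — they are exactly the names an NCBI-style lookup
        would fail to resolve.
        """
        self.sampled = {n: 0 for n in self.parent}
        for sp in set(species):
            if sp in self.parent and self.is_species(sp):
                for node in self.ancestors(sp, include_self=True):
                    self.sampled[node] += 1
        for n in self.parent:
            if self.described[n] < self.sampled[n]:
                raise ValueError(f"sampled exceeds described at {n!r}")

    def sampled_species(self) -> list[str]:
        return sorted(
            n for n in self.parent if self.is_species(n) and self.sampled.get(n, 0) > 0
        )

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        df = pd.read_csv(path, sep="\t", dtype={"clade": str, "parent": str})
        parent = {}
        described = {}
        rank = {}
        for row in df.itertuples(index=False):
            p = None if pd.isna(row.parent) or row.parent == "" else str(row.parent)
            parent[str(row.clade)] = p
            described[str(row.clade)] = int(row.described_species)
            rank[str(row.clade)] = str(row.rank)
        return cls(parent=parent, described=described, rank=rank)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "clade": n,
                "parent": "" if self.parent[n] is None else self.parent[n],
                "described_species": self.described[n],
                "rank": self.rank[n],
            }
            for n in sorted(self.parent)
        ]
        pd.DataFrame(rows, columns=["clade", "parent", "described_species", "rank"]).to_csv(
            path, sep="\t", index=False
        )

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.parent))
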