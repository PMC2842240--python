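"""Sequence records, inclusion filters, name standardization, clade selection.

The record layer mirrors the front end of a GenBank mining run: parse the
deposited sequences plus their tabular sidecar, throw out entries that are
useless for phylogenetics (too short/long, microsatellites and other
unsuitable sequence classes, hybrids, model-organism dumps), resolve
misspelled taxon names against an alias table, and pick a set of
non-overlapping analysis clades each holding fewer than a cap of sampled
species.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .taxonomy import Taxonomy

CLASS_FLAGS = ("ok", "microsatellite", "repetitive", "paralog_suspect", "other_unsuitable")
HYBRID_MARK = " x "


@dataclass(frozen=True)
class SequenceRecord:
    """One deposited nucleotide sequence with its curation metadata."""

    accession: str
    species: str
    clade: str
    clade_path: tuple[str, ...]
    sequence: str
    deposition_date: _dt.date
    class_flag: str = "ok"
    hybrid: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.class_flag not in CLASS_FLAGS:
            raise ValueError(f"{self.accession}: unknown class flag {self.class_flag!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def year(self) -> int:
        return self.deposition_date.year


@dataclass(frozen=True)
class FilterPolicy:
    """Inclusion rules for the raw record pool.

    Length bounds are inclusive: a sequence is kept when
    ``min_len <= length <= max_len``.  ``model_threshold`` is the
    records-per-species count above which a species is treated as a model
    organism and excluded wholesale; the count is taken on the unfiltered
    pool, matching how a database-wide tally would be made.
    """

    min_len: int = 100
    max_len: int = 5000
    model_threshold: int = 10_000
    excluded_flags: frozenset[str] = frozenset(
        {"microsatellite", "repetitive", "paralog_suspect", "other_unsuitable"}
    )
    exclude_hybrids: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if self.model_threshold < 1:
            raise ValueError("model_threshold must be >= 1")


def read_records(
    fasta_path: str | Path,
    metadata_path: str | Path,
    taxonomy: Taxonomy,
    date_range: tuple[int, int] | None = None,
) -> list[SequenceRecord]:
    """Parse a FASTA file plus its metadata sidecar into records.

    Every FASTA entry must have a metadata row (keyed on accession); the
    clade named there must exist in the taxonomy.  Sequences are
    upper-cased.  ``date_range`` optionally bounds deposition years.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    meta_by_acc = {row.accession: row for row in meta.itertuples(index=False)}
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        acc = entry.id
        if acc not in meta_by_acc:
            raise KeyError(f"accession {acc!r} has no metadata row")
        row = meta_by_acc[acc]
        if not taxonomy.contains(row.clade):
            raise KeyError(f"accession {acc!r} names unknown clade {row.clade!r}")
        date = _dt.date.fromisoformat(row.date)
        if date_range is not None and not (date_range[0] <= date.year <= date_range[1]):
            raise ValueError(f"accession {acc!r}: year {date.year} outside {date_range}")
        path = tuple(reversed(taxonomy.ancestors(row.clade, include_self=True)))
        records.append(
            SequenceRecord(
                accession=acc,
                species=row.species,
                clade=row.clade,
                clade_path=path,
                sequence=str(entry.seq).upper(),
                deposition_date=date,
                class_flag=getattr(row, "class_flag", "ok") or "ok",
                hybrid=HYBRID_MARK in row.species,
            )
        )
    return records


def filter_records(
    records: list[SequenceRecord], policy: FilterPolicy
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Partition records into (kept, rejected-with-reason).

    Each rejected record gets exactly one reason, the first matching rule
    in the fixed order length -> class -> hybrid -> model-organism, so the
    rejection report is deterministic.
    """
    pool_counts: dict[str, int] = {}
    for r in records:
        pool_counts[r.species] = pool_counts.get(r.species, 0) + 1

    kept: list[SequenceRecord] = []
    rejected: list[tuple[SequenceRecord, str]] = []
    for r in records:
        if not (policy.min_len <= r.length <= policy.max_len):
            rejected.append((r, "length"))
        elif r.class_flag in policy.excluded_flags:
            rejected.append((r, "class"))
        elif policy.exclude_hybrids and r.hybrid:
            rejected.append((r, "hybrid"))
        elif pool_counts[r.species] > policy.model_threshold:
            rejected.append((r, "model-organism"))
        else:
            kept.append(r)
    return kept, rejected


def write_rejection_report(
    rejected: list[tuple[SequenceRecord, str]], path: str | Path
) -> None:
    rows = [{"accession": r.accession, "reason": reason} for r, reason in rejected]
    pd.DataFrame(rows, columns=["accession", "reason"]).to_csv(path, sep="\t", index=False)


def _resolve_alias(name: str, aliases: dict[str, str]) -> str:
    seen = {name}
    cur = name
    while cur in aliases:
        cur = aliases[cur]
        if cur in seen:
            raise ValueError(f"alias cycle involving {name!r}")
        seen.add(cur)
    return cur


def standardize_names(
    records: list[SequenceRecord],
    aliases: dict[str, str] | list[tuple[str, str]],
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Map variant spellings to canonical binomials via the alias table.

    Returns (standardized records, dropped-with-reason).  A name mapping to
    more than one canonical species (duplicate variant entries pointing at
    different targets, or a hybrid binomial) cannot be assigned to a single
    species and is dropped with reason ``ambiguous``.  Alias chains are
    followed; cycles raise.
    """
    ambiguous_variants: set[str] = set()
    table: dict[str, str] = {}
    pairs = aliases.items() if isinstance(aliases, dict) else aliases
    for variant, canonical in pairs:
        if variant in table and table[variant] != canonical:
            ambiguous_variants.add(variant)
        table[variant] = canonical

    kept: list[SequenceRecord] = []
    dropped: list[tuple[SequenceRecord, str]] = []
    for r in records:
        if r.hybrid or r.species in ambiguous_variants:
            dropped.append((r, "ambiguous"))
            continue
        canonical = _resolve_alias(r.species, table)
        if canonical == r.species:
            kept.append(r)
        else:
            kept.append(
                SequenceRecord(
                    accession=r.accession,
                    species=canonical,
                    clade=r.clade,
                    clade_path=r.clade_path,
                    sequence=r.sequence,
                    deposition_date=r.deposition_date,
                    class_flag=r.class_flag,
                    hybrid=r.hybrid,
                )
            )
    return kept, dropped


def walk_to_largest_clade(taxonomy: Taxonomy, species: str, max_sampled: int) -> str:
    """Largest ancestor of ``species`` with sampled_count < max_sampled.

    Walks rootward from the species and stops just before the first
    ancestor at or over the cap; the species itself (sampled count 1) is
    always a valid starting point, so the walk can return the tip.
    """
    best = species
    for node in taxonomy.ancestors(species):
        if taxonomy.sampled_count(node) < max_sampled:
            best = node
        else:
            break
    return best


def select_clades(
    taxonomy: Taxonomy,
    n_clades: int,
    max_sampled: int = 500,
    seed: int = 0,
) -> tuple[list[str], int]:
    """Draw non-overlapping analysis clades by the random-species walk.

    Sampled species are visited in a seeded random order; each maps to the
    largest containing clade with fewer than ``max_sampled`` sampled
    species.  A draw whose clade overlaps (is nested within, equal to, or
    contains) an already accepted clade is discarded.  Returns the accepted
    clades in acceptance order plus the number of clades short of the
    request when species were exhausted first.
    """
    species = taxonomy.sampled_species()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(species))
    selected: list[str] = []
    for idx in order:
        if len(selected) >= n_clades:
            break
        clade = walk_to_largest_clade(taxonomy, species[idx], max_sampled)
        if any(taxonomy.overlap(clade, c) for c in selected):
            continue
        selected.append(clade)
    return selected, max(0, n_clades - len(selected))
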