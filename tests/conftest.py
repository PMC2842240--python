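import datetime as dt

import numpy as np
import pytest

from phyloprogress.records import SequenceRecord
from phyloprogress.synthetic import WorldConfig, generate_world
from phyloprogress.taxonomy import Taxonomy


def make_record(
    accession: str,
    species: str = "Genus sp001",
    sequence: str | None = None,
    length: int = 300,
    year: int = 2005,
    clade: str = "cladeA",
    class_flag: str = "ok",
    seed: int | None = None,
) -> SequenceRecord:
    if sequence is None:
        rng = np.random.default_rng(seed if seed is not None else abs(hash(accession)) % 2**31)
        sequence = "".join(rng.choice(list("ACGT"), size=length))
    return SequenceRecord(
        accession=accession,
        species=species,
        clade=clade,
        clade_path=("root", clade),
        sequence=sequence,
        deposition_date=dt.date(year, 6, 15),
        class_flag=class_flag,
        hybrid=" x " in species,
    )


@pytest.fixture(scope="session")
def small_world():
    """Two-clade archive with every contaminant type present."""
    config = WorldConfig(
        n_clades=2,
        described_range=(12, 16),
        n_loci=3,
        seed=42,
        hybrid_rate=0.25,
        misspell_rate=0.1,
        unsuitable_rate=0.1,
        model_organism_rate=1.0,
        model_record_count=60,
    )
    return generate_world(config)


@pytest.fixture()
def toy_taxonomy():
    """root -> (A, B); A -> (A1, A2); species under each."""
    parent = {"root": None, "A": "root", "B": "root", "A1": "A", "A2": "A"}
    rank = {"root": "root", "A": "group", "B": "clade", "A1": "clade", "A2": "clade"}
    described = {}
    for clade, n in [("A1", 3), ("A2", 2), ("B", 4)]:
        for i in range(n):
            sp = f"{clade} sp{i}"
            parent[sp] = clade
            rank[sp] = "species"
            described[sp] = 1
    described.update({"A1": 3, "A2": 2, "B": 4, "A": 5, "root": 9})
    tax = Taxonomy(parent=parent, described=described, rank=rank)
    tax.set_sampled_from_species([s for s in parent if rank[s] == "species"])
    return tax
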