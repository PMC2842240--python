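"""Synthetic GenBank world: taxonomy, true trees, sequences, contaminants.

Everything downstream of this module treats the output as an opaque
sequence archive; the truth channel (true trees, per-record locus labels,
alias table) exists only so tests can score the pipeline against a known
answer.

The world is built in layers:

* a three-level taxonomy (root -> groups -> clades -> species) with
  described-species counts drawn per clade;
* one pure-birth (Yule) tree per clade, rescaled to a target root-to-tip
  depth in substitutions/site;
* per-locus sequences evolved along the true tree under an HKY substitution
  model, with per-locus rate multipliers creating a fast-mitochondrial /
  slow-nuclear contrast;
* deposition: each (species, locus) pair is sequenced with a probability
  set by the locus's popularity and the clade's per-species sampling
  intensity, and dated to a year drawn in proportion to the clade-by-year
  intensity matrix (1993-2008 by default, increasing through time);
* contaminants: hybrid binomials, misspelled names (recorded in the alias
  table), unsuitable sequence classes, and an oversampled model organism.
"""

from __future__ import annotations

import datetime as _dt
import random as _pyrandom
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .records import HYBRID_MARK, SequenceRecord
from .taxonomy import SPECIES_RANK, Taxonomy

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class WorldConfig:
    """Data-generating assumptions for one synthetic archive.

    Defaults describe a desk-scale archive: a handful of clades of modest
    diversity, a few loci with heterogeneous rates and popularity, sampling
    effort rising linearly over 1993-2008, and low contaminant rates.
    """

    n_clades: int = 8
    described_range: tuple[int, int] = (8, 24)
    n_groups: int = 2
    n_loci: int = 4
    locus_rates: tuple[float, ...] | None = None
    locus_lengths: tuple[int, ...] | None = None
    locus_sampling: tuple[float, ...] | None = None
    years: tuple[int, ...] = tuple(range(1993, 2009))
    year_intensity: np.ndarray | None = None  # (n_clades, n_years), >= 0
    clade_sampling: tuple[float, ...] | None = None  # per-species prob scale
    kappa: float = 4.0
    base_freqs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    root_depth: float = 0.15
    species_effort_sigma: float = 0.75
    fragment_prob: float = 0.25
    fragment_min_frac: float = 0.4
    duplicate_rate: float = 0.15
    hybrid_rate: float = 0.02
    misspell_rate: float = 0.03
    unsuitable_rate: float = 0.03
    model_organism_rate: float = 0.0
    model_record_count: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clades < 1:
            raise ValueError("n_clades must be >= 1")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        if self.locus_rates is None:
            # geometric spread, fastest first (mitochondrial-like)
            self.locus_rates = tuple(2.0 * 0.6**i for i in range(self.n_loci))
        if self.locus_lengths is None:
            self.locus_lengths = tuple(
                300 + 60 * (i % 4) for i in range(self.n_loci)
            )
        if self.locus_sampling is None:
            self.locus_sampling = tuple(
                max(0.2, 0.95 * 0.8**i) for i in range(self.n_loci)
            )
        if self.clade_sampling is None:
            self.clade_sampling = tuple(
                float(x) for x in np.linspace(0.95, 0.45, self.n_clades)
            )
        if self.year_intensity is None:
            base = np.arange(1, len(self.years) + 1, dtype=float)
            self.year_intensity = np.tile(base, (self.n_clades, 1))
        self.year_intensity = np.asarray(self.year_intensity, dtype=float)
        if self.year_intensity.shape != (self.n_clades, len(self.years)):
            raise ValueError("year_intensity must be (n_clades, n_years)")
        if (self.year_intensity < 0).any():
            raise ValueError("year intensities must be >= 0")
        if self.year_intensity.sum() == 0:
            raise ValueError("zero total sampling intensity: nothing to generate")
        if self.species_effort_sigma < 0:
            raise ValueError("species_effort_sigma must be >= 0")
        for name, v in [
            ("fragment_prob", self.fragment_prob),
            ("duplicate_rate", self.duplicate_rate),
            ("hybrid_rate", self.hybrid_rate),
            ("misspell_rate", self.misspell_rate),
            ("unsuitable_rate", self.unsuitable_rate),
            ("model_organism_rate", self.model_organism_rate),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.locus_rates) != self.n_loci or min(self.locus_rates) < 0:
            raise ValueError("locus_rates must be n_loci nonnegative reals")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or not np.isclose(freqs.sum(), 1.0) or (freqs <= 0).any():
            raise ValueError("base_freqs must be 4 positive values summing to 1")


@dataclass
class SyntheticWorld:
    """A generated archive plus its truth channel."""

    config: WorldConfig
    taxonomy: Taxonomy
    true_trees: dict[str, dendropy.Tree]
    records: list[SequenceRecord]
    locus_truth: dict[str, str]  # accession -> locus id
    aliases: dict[str, str]  # misspelling -> canonical name


# ---------------------------------------------------------------------------
# substitution model


def hky_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY instantaneous rate matrix, scaled to one expected sub/site/unit time.

    Base order A, C, G, T; transitions (A<->G, C<->T) run ``kappa`` times
    faster than transversions.
    """
    freqs = np.asarray(freqs, dtype=float)
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(freqs * np.diag(Q)).sum()
    return Q / mu


def transition_matrix(kappa: float, freqs: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via eigendecomposition of the HKY generator."""
    Q = hky_rate_matrix(kappa, np.asarray(freqs))
    w, V = np.linalg.eig(Q)
    P = (V * np.exp(w * t)) @ np.linalg.inv(V)
    P = np.real(P)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def expected_p_distance(kappa: float, freqs, total_depth: float) -> float:
    """Expected proportion of differing sites between two tips whose path
    length sums to ``total_depth`` substitutions/site (stationary root)."""
    freqs = np.asarray(freqs, dtype=float)
    P = transition_matrix(kappa, freqs, total_depth)
    same = sum(freqs[i] * P[i, i] for i in range(4))
    return float(1.0 - same)


def evolve_sequences(
    tree: dendropy.Tree,
    length: int,
    rate: float,
    kappa: float,
    freqs,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Simulate one locus along ``tree`` (edge lengths in subs/site).

    Returns taxon label -> ungapped sequence.  ``rate`` multiplies every
    edge length; rate 0 copies the root sequence to every tip.
    """
    freqs = np.asarray(freqs, dtype=float)
    root_seq = rng.choice(4, size=length, p=freqs)
    states: dict[int, np.ndarray] = {}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = root_seq
        else:
            parent = states[id(node.parent_node)]
            t = (node.edge.length or 0.0) * rate
            if t <= 0:
                child = parent.copy()
            else:
                P = transition_matrix(kappa, freqs, t)
                # sample each site's child state from its parent's row
                u = rng.random(length)
                cum = np.cumsum(P, axis=1)
                child = (u[:, None] > cum[parent]).sum(axis=1)
            states[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = "".join(_BASES[states[id(node)]])
    return out


# ---------------------------------------------------------------------------
# world generation


def _yule_tree(n_tips: int, labels: list[str], depth: float, seed: int) -> dendropy.Tree:
    """Pure-birth tree on ``labels`` rescaled to root-to-tip depth ``depth``."""
    if n_tips == 1:
        tree = dendropy.Tree()
        tree.seed_node.taxon = tree.taxon_namespace.new_taxon(label=labels[0])
        return tree
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=_pyrandom.Random(seed),
    )
    tips = tree.leaf_nodes()
    for tip, label in zip(tips, labels):
        tip.taxon.label = label
    max_depth = max(leaf.distance_from_root() for leaf in tree.leaf_nodes())
    if max_depth > 0:
        scale = depth / max_depth
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return tree


def _misspell(name: str, rng: np.random.Generator) -> str:
    """Swap two adjacent letters of the epithet (deterministic given rng)."""
    genus, epithet = name.split(" ", 1)
    if len(epithet) < 3:
        return genus + " " + epithet + "x"
    i = int(rng.integers(0, len(epithet) - 1))
    swapped = epithet[:i] + epithet[i + 1] + epithet[i] + epithet[i + 2 :]
    if swapped == epithet:
        swapped = epithet + "e"
    return f"{genus} {swapped}"


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the full archive deterministically from ``config.seed``."""
    root_ss = np.random.SeedSequence(config.seed)
    clade_seeds = root_ss.spawn(config.n_clades)
    rng_global = np.random.default_rng(root_ss.spawn(1)[0])

    # taxonomy scaffold
    parent: dict[str, str | None] = {"root": None}
    described: dict[str, int] = {}
    rank: dict[str, str] = {"root": "root"}
    clade_ids = [f"clade{c:03d}" for c in range(config.n_clades)]
    group_of = {}
    for g in range(config.n_groups):
        gid = f"group{g:02d}"
        parent[gid] = "root"
        rank[gid] = "group"
    for c, cid in enumerate(clade_ids):
        gid = f"group{c % config.n_groups:02d}"
        parent[cid] = gid
        rank[cid] = "clade"
        group_of[cid] = gid

    lo, hi = config.described_range
    n_described = rng_global.integers(lo, hi + 1, size=config.n_clades)
    species_of: dict[str, list[str]] = {}
    for c, cid in enumerate(clade_ids):
        genus = f"Genus{c:03d}"
        spp = [f"{genus} sp{i:03d}" for i in range(int(n_described[c]))]
        species_of[cid] = spp
        described[cid] = len(spp)
        for sp in spp:
            parent[sp] = cid
            rank[sp] = SPECIES_RANK
            described[sp] = 1
    for g in range(config.n_groups):
        gid = f"group{g:02d}"
        described[gid] = sum(described[c] for c in clade_ids if group_of[c] == gid)
    described["root"] = sum(described[f"group{g:02d}"] for g in range(config.n_groups))
    taxonomy = Taxonomy(parent=parent, described=described, rank=rank)

    all_species = {sp for spp in species_of.values() for sp in spp}
    years = np.asarray(config.years)
    trees: dict[str, dendropy.Tree] = {}
    records: list[SequenceRecord] = []
    locus_truth: dict[str, str] = {}
    aliases: dict[str, str] = {}
    acc_counter = 0

    def next_acc() -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"SYN{acc_counter:07d}"

    for c, cid in enumerate(clade_ids):
        crng = np.random.default_rng(clade_seeds[c])
        tree_seed = int(crng.integers(0, 2**31))
        spp = species_of[cid]
        trees[cid] = _yule_tree(len(spp), spp, config.root_depth, tree_seed)
        clade_path = ("root", group_of[cid], cid)
        intensity = config.year_intensity[c]
        year_p = intensity / intensity.sum() if intensity.sum() > 0 else None

        # full-length locus sequences for every described species
        locus_seqs: list[dict[str, str]] = []
        for l in range(config.n_loci):
            locus_seqs.append(
                evolve_sequences(
                    trees[cid],
                    config.locus_lengths[l],
                    config.locus_rates[l],
                    config.kappa,
                    config.base_freqs,
                    crng,
                )
            )

        def observed_fragment(full: str) -> str:
            if crng.random() < config.fragment_prob:
                frac = config.fragment_min_frac + crng.random() * (
                    1 - config.fragment_min_frac
                )
                n = max(30, int(round(frac * len(full))))
                if crng.random() < 0.5:
                    return full[:n]
                return full[-n:]
            return full

        def deposit(species_name: str, locus: int, seq: str, flag: str = "ok"):
            if year_p is None:
                return
            year = int(years[crng.choice(len(years), p=year_p)])
            day = int(crng.integers(1, 365))
            date = _dt.date(year, 1, 1) + _dt.timedelta(days=day - 1)
            acc = next_acc()
            name = species_name
            if flag == "ok" and HYBRID_MARK not in name and crng.random() < config.misspell_rate:
                variant = _misspell(name, crng)
                # a variant colliding with a real binomial would not be a
                # resolvable misspelling; skip it
                if variant not in all_species and (
                    variant not in aliases or aliases[variant] == name
                ):
                    aliases[variant] = name
                    name = variant
            if flag == "ok" and crng.random() < config.unsuitable_rate:
                flag = "microsatellite" if crng.random() < 0.5 else "repetitive"
            records.append(
                SequenceRecord(
                    accession=acc,
                    species=name,
                    clade=cid,
                    clade_path=clade_path,
                    sequence=seq,
                    deposition_date=date,
                    class_flag=flag,
                    hybrid=HYBRID_MARK in name,
                )
            )
            locus_truth[acc] = f"L{locus:02d}"

        # per-species research effort: popular species get sequenced for
        # many loci, which is what makes clusters overlap in species
        sigma = config.species_effort_sigma
        effort = (
            crng.lognormal(mean=0.0, sigma=sigma, size=len(spp))
            if sigma > 0
            else np.ones(len(spp))
        )
        if year_p is not None:
            for si, sp in enumerate(spp):
                for l in range(config.n_loci):
                    p = min(
                        1.0,
                        config.locus_sampling[l]
                        * config.clade_sampling[c]
                        * effort[si],
                    )
                    if crng.random() < p:
                        deposit(sp, l, observed_fragment(locus_seqs[l][sp]))
                        if crng.random() < config.duplicate_rate:
                            deposit(sp, l, observed_fragment(locus_seqs[l][sp]))

            # hybrids: named after two parents, sequence from one of them
            if len(spp) >= 2:
                n_hyb = crng.binomial(len(spp), config.hybrid_rate)
                for _ in range(int(n_hyb)):
                    a, b = crng.choice(len(spp), size=2, replace=False)
                    l = int(crng.integers(0, config.n_loci))
                    name = f"{spp[a]} x {spp[b]}"
                    deposit(name, l, observed_fragment(locus_seqs[l][spp[a]]))

            # model organism: one species buried in records
            if config.model_organism_rate > 0 and crng.random() < config.model_organism_rate:
                sp = spp[0]
                for _ in range(config.model_record_count):
                    l = int(crng.integers(0, config.n_loci))
                    deposit(sp, l, observed_fragment(locus_seqs[l][sp]))

    taxonomy.set_sampled_from_species([r.species for r in records])
    return SyntheticWorld(
        config=config,
        taxonomy=taxonomy,
        true_trees=trees,
        records=records,
        locus_truth=locus_truth,
        aliases=aliases,
    )


# ---------------------------------------------------------------------------
# persistence

METADATA_COLUMNS = ["accession", "species", "clade", "date", "locus_truth", "class_flag"]


def write_world(world: SyntheticWorld, directory: str | Path) -> None:
    """Write FASTA per clade, metadata/taxonomy/alias TSVs, and true trees."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "trees").mkdir(exist_ok=True)

    by_clade: dict[str, list[SequenceRecord]] = {}
    for r in world.records:
        by_clade.setdefault(r.clade, []).append(r)
    clade_list = world.taxonomy.clades(rank="clade")
    for cid in clade_list:
        with open(directory / f"{cid}.fasta", "w") as fh:
            for r in sorted(by_clade.get(cid, []), key=lambda r: r.accession):
                fh.write(f">{r.accession}\n{r.sequence}\n")

    rows = [
        {
            "accession": r.accession,
            "species": r.species,
            "clade": r.clade,
            "date": r.deposition_date.isoformat(),
            "locus_truth": world.locus_truth.get(r.accession, ""),
            "class_flag": r.class_flag,
        }
        for r in sorted(world.records, key=lambda r: r.accession)
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        directory / "metadata.tsv", sep="\t", index=False
    )
    world.taxonomy.to_tsv(directory / "taxonomy.tsv")
    alias_rows = [
        {"variant": v, "canonical": c} for v, c in sorted(world.aliases.items())
    ]
    pd.DataFrame(alias_rows, columns=["variant", "canonical"]).to_csv(
        directory / "aliases.tsv", sep="\t", index=False
    )
    for cid, tree in sorted(world.true_trees.items()):
        tree.write(path=str(directory / "trees" / f"{cid}.nwk"), schema="newick")


def read_aliases(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return {}
    return dict(zip(df["variant"], df["canonical"]))
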