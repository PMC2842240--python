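"""End-to-end orchestration of the per-clade-per-year supermatrix grid.

``run_pipeline`` enumerates every (clade, year) slot, builds a supermatrix
where the informative-cluster rule allows one, runs the
bootstrap/prune/consensus chain, and writes deterministic TSV/JSON
reports.  One global seed fans out to per-slot seeds by stable hashing of
(clade, year), so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ClusteringParams, cluster_records, dedup_longest, slice_by_year
from .records import (
    FilterPolicy,
    filter_records,
    read_records,
    select_clades,
    standardize_names,
    write_rejection_report,
)
from .resolution import ResolutionRecord, pool_resolution, single_gene_resolution
from .supermatrix import Supermatrix, align_cluster, concatenate, select_informative
from .synthetic import read_aliases
from .taxonomy import Taxonomy
from .trees import bootstrap_trees, majority_consensus, prune_rogues
from .progress import feature_regression, fit_trend, project, rank_genes


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to YAML."""

    world_dir: str
    out_dir: str
    years: tuple[int, ...] = tuple(range(1993, 2009))
    n_clades: int = 8
    clade_selection: str = "walk"  # "walk" (random-species rule) or "leaves"
    max_sampled: int = 500
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    min_species: int = 4
    min_overlap: int = 4
    n_boot_prelim: int = 100
    n_boot_final: int = 100
    prune_fraction: float = 0.05
    engine: str = "nj"
    thresholds: tuple[float, float] = (0.5, 0.95)
    min_genes: int = 20
    gene_analysis: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be sorted ascending and unique")
        if self.clade_selection not in ("walk", "leaves"):
            raise ValueError("clade_selection must be 'walk' or 'leaves'")
        if not 0 <= self.prune_fraction < 1:
            raise ValueError("prune_fraction must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(open(path))
        if "filter_policy" in raw:
            fp = dict(raw["filter_policy"])
            if "excluded_flags" in fp:
                fp["excluded_flags"] = frozenset(fp["excluded_flags"])
            raw["filter_policy"] = FilterPolicy(**fp)
        if "clustering" in raw:
            raw["clustering"] = ClusteringParams(**raw["clustering"])
        for key in ("years", "thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["filter_policy"]["excluded_flags"] = sorted(
            d["filter_policy"]["excluded_flags"]
        )
        d["years"] = list(self.years)
        d["thresholds"] = list(self.thresholds)
        return d


def slot_seed(global_seed: int, clade: str, year: int) -> int:
    """Stable per-slot seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{clade}:{year}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


RESOLUTION_COLUMNS = [
    "clade",
    "year",
    "N_described",
    "n_sampled",
    "resolved_50",
    "resolved_95",
    "resolution_50",
    "resolution_95",
    "density",
    "characters_per_species",
    "width",
]


def _analyze_slot(
    clade: str,
    year: int,
    matrix: Supermatrix,
    n_described: int,
    config: RunConfig,
) -> tuple[ResolutionRecord, object]:
    seed = slot_seed(config.seed, clade, year)
    prelim = bootstrap_trees(
        matrix, n_replicates=config.n_boot_prelim, seed=seed, engine=config.engine
    )
    pruned_species: list[str] = []
    if config.prune_fraction > 0 and int(config.prune_fraction * matrix.n_species) >= 1:
        try:
            matrix, pruned_species = prune_rogues(matrix, prelim, config.prune_fraction)
        except ValueError:
            pruned_species = []  # too few species to prune; analyse unpruned
    final = bootstrap_trees(
        matrix, n_replicates=config.n_boot_final, seed=seed + 1, engine=config.engine
    )
    lo, hi = config.thresholds
    cons50 = majority_consensus(final, lo)
    cons95 = majority_consensus(final, hi)
    record = ResolutionRecord(
        clade=clade,
        year=year,
        n_described=n_described,
        n_sampled=matrix.n_species,
        resolved_50=cons50.n_resolved,
        resolved_95=cons95.n_resolved,
        density=matrix.density,
        characters_per_species=matrix.characters_per_species,
        width=matrix.width,
    )
    return record, (cons50, cons95, pruned_species)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full grid; returns the run directory.

    Every (clade, year) slot is enumerated and logged with a status:
    ``built`` (supermatrix analysed), ``skipped`` (no informative cluster
    set that year) or ``failed`` (error, message logged, run continues).
    Raises only if every slot fails.
    """
    world = Path(config.world_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)

    taxonomy = Taxonomy.from_tsv(world / "taxonomy.tsv")
    aliases = read_aliases(world / "aliases.tsv") if (world / "aliases.tsv").exists() else {}
    records = []
    for fasta in sorted(world.glob("*.fasta")):
        records.extend(read_records(fasta, world / "metadata.tsv", taxonomy))
    records, ambiguous = standardize_names(records, aliases)
    kept, rejected = filter_records(records, config.filter_policy)
    write_rejection_report(
        rejected + ambiguous, out / "rejections.tsv"
    )
    taxonomy.set_sampled_from_species([r.species for r in kept])

    if config.clade_selection == "walk":
        clades, shortfall = select_clades(
            taxonomy, config.n_clades, config.max_sampled, seed=config.seed
        )
        clades = sorted(clades)
        if shortfall:
            warnings.warn(f"{shortfall} requested clades unattainable", stacklevel=2)
    else:
        clades = taxonomy.clades(rank="clade")[: config.n_clades]

    by_clade: dict[str, list] = {c: [] for c in clades}
    for r in kept:
        for c in clades:
            if c in r.clade_path or c == r.species:
                by_clade[c].append(r)
                break

    slot_rows = []
    res_records: list[ResolutionRecord] = []
    gene_rows = []
    final_year = config.years[-1]
    align_cache: dict[tuple[str, tuple[str, ...]], object] = {}

    for clade in clades:
        clade_records = by_clade[clade]
        n_described = taxonomy.described_count(clade)
        clusters = (
            cluster_records(clade_records, config.clustering) if clade_records else []
        )
        for year in config.years:
            status, reason = "built", ""
            try:
                sliced = slice_by_year(clusters, year, valid_years=tuple(config.years))
                deduped = [dedup_longest(c) for c in sliced]
                alignments = []
                for cl in deduped:
                    key = (cl.cluster_id, tuple(r.accession for r in cl.members))
                    if key not in align_cache:
                        align_cache[key] = align_cluster(cl)
                    alignments.append(align_cache[key])
                retained = select_informative(
                    alignments, config.min_species, config.min_overlap
                )
                if not retained:
                    status, reason = "skipped", "no informative cluster set"
                elif n_described < 3:
                    status, reason = "skipped", "fewer than 3 described species"
                else:
                    matrix = concatenate(retained)
                    if matrix.n_species < 4:
                        status, reason = "skipped", "fewer than 4 species in matrix"
                    else:
                        record, (cons50, cons95, pruned) = _analyze_slot(
                            clade, year, matrix, n_described, config
                        )
                        res_records.append(record)
                        reason = f"pruned={len(pruned)}"
                        if year == final_year:
                            cons50.write(out / "trees" / f"{clade}_50.nwk")
                            cons95.write(out / "trees" / f"{clade}_95.nwk")
                            if config.gene_analysis:
                                gene_rows.extend(
                                    _gene_analysis(clade, retained, config)
                                )
            except Exception as exc:  # per-slot failures must not kill the run
                status, reason = "failed", f"{type(exc).__name__}: {exc}"
            slot_rows.append(
                {"clade": clade, "year": year, "status": status, "detail": reason}
            )

    slots = pd.DataFrame(slot_rows, columns=["clade", "year", "status", "detail"])
    if len(slots) and (slots["status"] == "failed").all():
        raise RuntimeError("every slot failed")
    slots.to_csv(out / "slots.tsv", sep="\t", index=False)

    res_df = pd.DataFrame(
        [
            {
                "clade": r.clade,
                "year": r.year,
                "N_described": r.n_described,
                "n_sampled": r.n_sampled,
                "resolved_50": r.resolved_50,
                "resolved_95": r.resolved_95,
                "resolution_50": r.resolution_50,
                "resolution_95": r.resolution_95,
                "density": r.density,
                "characters_per_species": r.characters_per_species,
                "width": r.width,
            }
            for r in sorted(res_records, key=lambda r: (r.clade, r.year))
        ],
        columns=RESOLUTION_COLUMNS,
    )
    res_df.to_csv(out / "resolution.tsv", sep="\t", index=False, float_format="%.6f")

    gene_df = pd.DataFrame(
        gene_rows, columns=["clade", "gene", "n_taxa", "resolution"]
    )
    gene_df.to_csv(out / "genes.tsv", sep="\t", index=False, float_format="%.6f")

    # sampled-species accumulation per clade and year (post-filter records)
    acc_rows = []
    for clade in clades:
        n_desc = taxonomy.described_count(clade)
        for year in config.years:
            spp = {
                r.species
                for r in by_clade[clade]
                if r.deposition_date.year <= year and taxonomy.contains(r.species)
            }
            acc_rows.append(
                {
                    "clade": clade,
                    "year": year,
                    "n_described": n_desc,
                    "n_sampled_species": len(spp),
                }
            )
    pd.DataFrame(
        acc_rows, columns=["clade", "year", "n_described", "n_sampled_species"]
    ).to_csv(out / "sampling.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "config": config.to_jsonable(),
        "n_records_read": len(records) + len(ambiguous),
        "n_records_kept": len(kept),
        "clades": clades,
        "slots": {
            "total": int(len(slots)),
            "built": int((slots["status"] == "built").sum()),
            "skipped": int((slots["status"] == "skipped").sum()),
            "failed": int((slots["status"] == "failed").sum()),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _gene_analysis(clade: str, retained, config: RunConfig):
    """Single-gene bootstrap/consensus for the final-year retained clusters."""
    rows = []
    for aln in retained:
        if aln.n_species < 4:
            continue
        cells = np.array([list(aln.rows[sp]) for sp in sorted(aln.rows)])
        matrix = Supermatrix(
            species=sorted(aln.rows),
            cells=cells,
            partitions=[(aln.cluster_id, 0, aln.width)],
        )
        seed = slot_seed(config.seed, f"{clade}:{aln.cluster_id}", 0)
        profile = bootstrap_trees(
            matrix, n_replicates=config.n_boot_final, seed=seed, engine=config.engine
        )
        cons = majority_consensus(profile, config.thresholds[0])
        rows.append(
            {
                "clade": clade,
                "gene": aln.cluster_id,
                "n_taxa": matrix.n_species,
                "resolution": single_gene_resolution(cons, matrix.n_species),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# reporting


def report(run_dir: str | Path, min_genes: int | None = None) -> dict:
    """Summaries over a completed run directory.

    Writes the pooled accumulation table, per-clade curves, the
    dataset-characteristics table, trend fits with projections, the
    feature regression and the gene ranking; returns them as a dict.
    Partial runs (no built slots) yield a flagged partial report.
    """
    run_dir = Path(run_dir)
    manifest = json.load(open(run_dir / "manifest.json"))
    config = manifest["config"]
    res = pd.read_csv(run_dir / "resolution.tsv", sep="\t")
    sampling = pd.read_csv(run_dir / "sampling.tsv", sep="\t")
    out: dict = {"partial": res.empty, "slots": manifest["slots"]}

    # pooled accumulation (all species pooled): sum resolved / sum (N-2),
    # plus the pooled fraction of described species with data
    years = sorted(config["years"])
    pool_rows = []
    for year in years:
        sub = res[res["year"] == year]
        samp = sampling[sampling["year"] == year]
        row = {"year": year}
        if len(samp):
            row["proportion_with_data"] = (
                samp["n_sampled_species"].sum() / samp["n_described"].sum()
            )
        if len(sub):
            den = (sub["N_described"] - 2).sum()
            row["pooled_resolution_50"] = sub["resolved_50"].sum() / den
            row["pooled_resolution_95"] = sub["resolved_95"].sum() / den
        pool_rows.append(row)
    pooled = pd.DataFrame(pool_rows)
    pooled.to_csv(run_dir / "pooled.tsv", sep="\t", index=False, float_format="%.6f")
    out["pooled"] = pooled

    # dataset characteristics at the final year (scatterplot analogue)
    final_year = years[-1]
    chars = res[res["year"] == final_year].copy()
    if len(chars):
        chars["proportion_sampled"] = chars["n_sampled"] / chars["N_described"]
        chars = chars.rename(columns={"N_described": "clade_size"})
        chars[
            [
                "clade",
                "clade_size",
                "n_sampled",
                "proportion_sampled",
                "width",
                "characters_per_species",
                "density",
                "resolution_50",
                "resolution_95",
            ]
        ].to_csv(
            run_dir / "characteristics.tsv", sep="\t", index=False, float_format="%.6f"
        )
    out["characteristics"] = chars

    # trends and projections
    trends = {}
    projections = {}
    usable = pooled.dropna(subset=["pooled_resolution_50"]) if "pooled_resolution_50" in pooled else pooled.iloc[0:0]
    if len(usable) >= 4:
        for col, label in [
            ("proportion_with_data", "sampling"),
            ("pooled_resolution_50", "resolution_50"),
            ("pooled_resolution_95", "resolution_95"),
        ]:
            series = pd.Series(usable[col].values, index=usable["year"].values)
            lin = fit_trend(series, order=1)
            quad = fit_trend(series, order=2)
            trends[label] = {
                "linear_r2": lin.r_squared,
                "quadratic_r2": quad.r_squared,
                "p_improvement": quad.p_improvement,
            }
            target = 1.0 if label == "sampling" else 0.5
            projections[label] = {
                "target": target,
                "year": project(quad, target, last_year=final_year),
            }
    out["trends"] = trends
    out["projections"] = projections

    # dataset-feature regression at the final year
    regression = {}
    if len(chars) >= 6:
        try:
            reg = feature_regression(chars)
            regression = {
                "betas": reg.params.to_dict(),
                "r_squared": reg.r_squared,
                "p_value": reg.f_pvalue,
                "n": reg.n,
            }
        except ValueError as exc:
            regression = {"error": str(exc)}
    out["regression"] = regression

    # gene ranking
    genes = pd.read_csv(run_dir / "genes.tsv", sep="\t")
    mg = config["min_genes"] if min_genes is None else min_genes
    ranking = {}
    if len(genes):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gr = rank_genes(genes, min_genes=mg)
        ranking = {
            "clades": gr.clades,
            "freq_top5_taxa": gr.freq_top5_taxa,
            "freq_top5_resolution": gr.freq_top5_resolution,
            "sampling_vs_resolution": gr.sampling_vs_resolution,
        }
    out["ranking"] = ranking

    serializable = {
        k: v for k, v in out.items() if k not in ("pooled", "characteristics")
    }
    serializable["pooled"] = pooled.to_dict(orient="records")
    with open(run_dir / "report.json", "w") as fh:
        json.dump(serializable, fh, indent=2, sort_keys=True, default=float)
    return out
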