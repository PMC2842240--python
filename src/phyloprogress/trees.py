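"""Bootstrap tree estimation, majority-rule consensus, rogue-taxon pruning.

Replicates resample supermatrix columns with replacement and hand the
resampled matrix to an inference engine.  The default engine is
neighbor-joining on p-distances over shared non-missing sites; a parsimony
hill-climber (random-addition start, NNI refinement) is selectable through
the same interface.  Consensus trees retain bipartitions by replicate
frequency — strictly greater than 1/2 for the 50% rule (so retained splits
are always pairwise compatible) and at-least for higher thresholds such as
95%.  Taxon instability is scored from nodal (edge-count) leaf distances:
a taxon whose distances to the other taxa swing between replicate trees
scores high and is pruned first.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .supermatrix import Supermatrix

MIN_SHARED_SITES = 20
DISTANCE_CAP_FACTOR = 1.25

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_matrix(matrix: Supermatrix) -> np.ndarray:
    """(n_species, width) uint8 codes; 255 marks gap/missing/ambiguous."""
    cells = matrix.cells
    codes = np.full(cells.shape, 255, dtype=np.uint8)
    for b, k in _CODE.items():
        codes[cells == b] = k
    return codes


def p_distance_matrix(codes: np.ndarray) -> np.ndarray:
    """Pairwise p-distances over shared valid sites.

    Pairs sharing fewer than ``MIN_SHARED_SITES`` sites get a placeholder
    of 1.25 x the largest finite distance observed, so sparse overlap
    pushes taxa apart rather than spuriously together.
    """
    n = codes.shape[0]
    valid = codes != 255
    D = np.zeros((n, n))
    shared = valid.astype(np.int32) @ valid.astype(np.int32).T
    for i in range(n):
        both = valid[i][None, :] & valid
        diff = ((codes[i][None, :] != codes) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            D[i] = np.where(shared[i] > 0, diff / np.maximum(shared[i], 1), np.nan)
    np.fill_diagonal(D, 0.0)
    ok = shared >= MIN_SHARED_SITES
    np.fill_diagonal(ok, True)
    finite_ok = D[ok & np.isfinite(D)]
    cap = DISTANCE_CAP_FACTOR * (finite_ok.max() if finite_ok.size else 1.0)
    if cap <= 0:
        cap = 1.0
    D = np.where(ok & np.isfinite(D), D, cap)
    np.fill_diagonal(D, 0.0)
    return D


def _nj_engine(codes: np.ndarray, species: list[str], rng: np.random.Generator) -> dendropy.Tree:
    D = p_distance_matrix(codes)
    # infinitesimal symmetric jitter breaks exact ties (duplicate or
    # zero-variation sequences) randomly per replicate instead of letting
    # the agglomeration order manufacture support for one arbitrary tree
    n = D.shape[0]
    noise = rng.random((n, n)) * 1e-9
    D = D + noise + noise.T
    np.fill_diagonal(D, 0.0)
    ids = [f"t{i}" for i in range(len(species))]
    skb = _skbio_nj(DistanceMatrix(D, ids=ids))
    newick = str(skb).strip()
    tree = dendropy.Tree.get(data=newick, schema="newick")
    label_map = {f"t{i}": sp for i, sp in enumerate(species)}
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = label_map[leaf.taxon.label]
    return tree


# -- parsimony engine -------------------------------------------------------

_FITCH_MASK = {0: 1, 1: 2, 2: 4, 3: 8, 255: 15}


def _fitch_length(adj: dict[int, list[int]], leaves: dict[int, np.ndarray], root: int) -> int:
    """Fitch parsimony length of a rooted tree given leaf state masks."""
    order: list[int] = []
    stack = [(root, -1)]
    parents: dict[int, int] = {}
    while stack:
        node, par = stack.pop()
        parents[node] = par
        order.append(node)
        for ch in adj[node]:
            if ch != par:
                stack.append((ch, node))
    masks: dict[int, np.ndarray] = {}
    score = 0
    for node in reversed(order):
        kids = [c for c in adj[node] if c != parents[node]]
        if not kids:
            masks[node] = leaves[node]
            continue
        m = masks[kids[0]]
        for c in kids[1:]:
            inter = m & masks[c]
            union = m | masks[c]
            changed = inter == 0
            score += int(changed.sum())
            m = np.where(changed, union, inter)
        masks[node] = m
    return score


def _parsimony_engine(
    codes: np.ndarray, species: list[str], rng: np.random.Generator, nni_rounds: int = 3
) -> dendropy.Tree:
    """Random-addition start + NNI hill climb on Fitch length.

    Desk-scale only; informative enough to recover clean topologies but
    not a PAUP*-grade search.
    """
    n = len(species)
    masks = {
        i: np.array([_FITCH_MASK.get(int(c), 15) for c in codes[i]], dtype=np.uint8)
        for i in range(n)
    }
    order = list(rng.permutation(n))
    # adjacency over node ids; leaves are 0..n-1, internals from n up
    next_id = n
    adj: dict[int, list[int]] = {i: [] for i in order[:3]}
    center = next_id
    next_id += 1
    adj[center] = list(order[:3])
    for leaf in order[:3]:
        adj[leaf] = [center]

    def edges() -> list[tuple[int, int]]:
        out = []
        for a, nbrs in adj.items():
            for b in nbrs:
                if a < b:
                    out.append((a, b))
        return out

    def try_length() -> int:
        return _fitch_length(adj, masks, center)

    for leaf in order[3:]:
        best = None
        for a, b in edges():
            mid = next_id
            adj[a] = [mid if x == b else x for x in adj[a]]
            adj[b] = [mid if x == a else x for x in adj[b]]
            adj[mid] = [a, b, leaf]
            adj[leaf] = [mid]
            score = _fitch_length(adj, masks, center)
            if best is None or score < best[0]:
                best = (score, a, b)
            # undo
            adj[a] = [b if x == mid else x for x in adj[a]]
            adj[b] = [a if x == mid else x for x in adj[b]]
            del adj[mid]
            del adj[leaf]
        _, a, b = best
        mid = next_id
        next_id += 1
        adj[a] = [mid if x == b else x for x in adj[a]]
        adj[b] = [mid if x == a else x for x in adj[b]]
        adj[mid] = [a, b, leaf]
        adj[leaf] = [mid]

    def subtree_leaves(start: int, avoid: int) -> list[int]:
        out, stack = [], [(start, avoid)]
        while stack:
            node, par = stack.pop()
            if node < n:
                out.append(node)
            for ch in adj[node]:
                if ch != par:
                    stack.append((ch, node))
        return out

    current = try_length()
    for _ in range(nni_rounds):
        improved = False
        for a, b in edges():
            if a < n or b < n:
                continue  # internal edges only
            a_nbrs = [x for x in adj[a] if x != b]
            b_nbrs = [x for x in adj[b] if x != a]
            if len(a_nbrs) != 2 or len(b_nbrs) != 2:
                continue
            for swap_idx in (0, 1):
                x, y = a_nbrs[1], b_nbrs[swap_idx]
                adj[a] = [y if t == x else t for t in adj[a]]
                adj[b] = [x if t == y else t for t in adj[b]]
                adj[x] = [b if t == a else t for t in adj[x]]
                adj[y] = [a if t == b else t for t in adj[y]]
                score = try_length()
                if score < current:
                    current = score
                    improved = True
                    break
                adj[a] = [x if t == y else t for t in adj[a]]
                adj[b] = [y if t == x else t for t in adj[b]]
                adj[x] = [a if t == b else t for t in adj[x]]
                adj[y] = [b if t == a else t for t in adj[y]]
        if not improved:
            break

    # emit newick
    def to_newick(node: int, par: int) -> str:
        kids = [c for c in adj[node] if c != par]
        if not kids:
            return f"'{species[node]}'" if " " in species[node] else species[node]
        return "(" + ",".join(to_newick(c, node) for c in kids) + ")"

    newick = to_newick(center, -1) + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


ENGINES = {"nj": _nj_engine, "parsimony": _parsimony_engine}


# -- bootstrap --------------------------------------------------------------


@dataclass
class BootstrapProfile:
    """Replicate trees from column-resampled matrices."""

    trees: list[dendropy.Tree]
    species: list[str]
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or len(self.trees) != self.n_replicates:
            raise ValueError("profile must hold n_replicates >= 1 trees")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.trees:
                fh.write(t.as_string(schema="newick").strip() + "\n")

    @classmethod
    def read(cls, path, seed: int = 0) -> "BootstrapProfile":
        trees = [
            dendropy.Tree.get(data=line, schema="newick")
            for line in open(path)
            if line.strip()
        ]
        species = sorted(_leaf_labels(trees[0]))
        return cls(trees=trees, species=species, n_replicates=len(trees), seed=seed)


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def bootstrap_trees(
    matrix: Supermatrix,
    n_replicates: int = 100,
    seed: int = 0,
    engine: str = "nj",
) -> BootstrapProfile:
    """Column bootstrap: resample whole columns, infer one tree per replicate."""
    if matrix.n_species < 4:
        raise ValueError("need at least 4 species to bootstrap")
    codes = encode_matrix(matrix)
    infer = ENGINES[engine]
    rng = np.random.default_rng(seed)
    trees = []
    W = codes.shape[1]
    for _ in range(n_replicates):
        idx = rng.integers(0, W, size=W)
        trees.append(infer(codes[:, idx], matrix.species, rng))
    return BootstrapProfile(
        trees=trees, species=list(matrix.species), n_replicates=n_replicates, seed=seed
    )


# -- splits and consensus ----------------------------------------------------


def tree_splits(tree: dendropy.Tree, taxa: set[str] | None = None) -> set[frozenset[str]]:
    """Nontrivial unrooted bipartitions, each canonicalized to the side not
    containing the alphabetically smallest taxon (restricted to ``taxa``)."""
    leaves = _leaf_labels(tree)
    if taxa is not None:
        leaves = leaves & taxa
    if len(leaves) < 4:
        return set()
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if taxa is not None:
            below = below & leaves
        side = frozenset(leaves - below) if anchor in below else frozenset(below)
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def _splits_compatible(a: frozenset, b: frozenset, leaves: frozenset) -> bool:
    return (
        not (a & b)
        or a <= b
        or b <= a
        or (a | b) == leaves
    )


@dataclass
class ConsensusTree:
    """Majority-rule consensus: retained splits with exact support counts."""

    tree: dendropy.Tree
    splits: dict[frozenset[str], float]  # split -> support (count / n)
    threshold: float
    leaves: tuple[str, ...]

    @property
    def n_resolved(self) -> int:
        return len(self.splits)

    def write(self, path) -> None:
        self.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def _build_from_splits(
    leaves: list[str], splits: dict[frozenset[str], float]
) -> dendropy.Tree:
    """Assemble the (compatible) retained splits into a rooted-at-anchor tree."""

    def build(group: list[str], inner: list[frozenset[str]]) -> str:
        maximal = [
            s
            for s in inner
            if not any(s < t for t in inner)
        ]
        covered: set[str] = set().union(*maximal) if maximal else set()
        parts = []
        for s in sorted(maximal, key=lambda s: sorted(s)):
            sub = [t for t in inner if t < s]
            label = f"{splits[s]:.3f}"
            parts.append(build(sorted(s), sub) + label)
        for lf in sorted(set(group) - covered):
            parts.append(f"'{lf}'" if " " in lf else lf)
        return "(" + ",".join(parts) + ")"

    anchor = min(leaves)
    rest = [lf for lf in leaves if lf != anchor]
    inner = [s for s in splits]
    body = build(rest, inner)
    anchor_tok = f"'{anchor}'" if " " in anchor else anchor
    newick = f"({anchor_tok},{body});"
    return dendropy.Tree.get(data=newick, schema="newick")


def majority_consensus(profile: BootstrapProfile, threshold: float) -> ConsensusTree:
    """Consensus of the replicate trees at ``threshold``.

    Retention is strict (> threshold) at 0.5 and inclusive (>=) above, so
    the 50% rule can never admit two incompatible splits tied at exactly
    half the replicates.  Trees on unequal leaf sets are restricted to the
    shared leaves, which must number at least 4.
    """
    if not profile.trees:
        raise ValueError("empty profile")
    shared: set[str] | None = None
    for t in profile.trees:
        labels = _leaf_labels(t)
        shared = labels if shared is None else (shared & labels)
    if shared is None or len(shared) < 4:
        raise ValueError("fewer than 4 shared leaves across replicate trees")
    counts: Counter[frozenset[str]] = Counter()
    for t in profile.trees:
        for s in tree_splits(t, taxa=shared):
            counts[s] += 1
    n = len(profile.trees)
    retained: dict[frozenset[str], float] = {}
    for s, c in counts.items():
        freq = c / n
        keep = freq > threshold if threshold <= 0.5 else freq >= threshold
        if keep:
            retained[s] = freq
    leaves = sorted(shared)
    tree = _build_from_splits(leaves, retained)
    return ConsensusTree(
        tree=tree, splits=retained, threshold=threshold, leaves=tuple(leaves)
    )


# -- taxon instability and rogue pruning ------------------------------------


def _nodal_distances(tree: dendropy.Tree, index: dict[str, int]) -> np.ndarray:
    """(n, n) edge-count leaf distances on the global species index; NaN
    where a species is absent from this tree."""
    n = len(index)
    D = np.full((n, n), np.nan)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [t for t in tree.taxon_namespace if t.label in index]
    for a_i, ta in enumerate(taxa):
        ia = index[ta.label]
        D[ia, ia] = 0.0
        for tb in taxa[a_i + 1 :]:
            ib = index[tb.label]
            d = pdm.path_edge_count(ta, tb)
            D[ia, ib] = D[ib, ia] = float(d)
    return D


def taxon_instability(profile: BootstrapProfile) -> dict[str, float]:
    """Mean normalized nodal-distance disagreement per taxon.

    For every pair of trees (x, y) and every other shared taxon j, the
    taxon t accrues |D(t,j;x) - D(t,j;y)| / (D(t,j;x) + D(t,j;y))^2; the
    sum is divided by the number of contributing terms.  Taxa present in
    fewer than two trees have no defined score and are omitted.
    """
    if len(profile.trees) < 2:
        raise ValueError("need at least 2 trees")
    species = sorted({lab for t in profile.trees for lab in _leaf_labels(t)})
    index = {sp: i for i, sp in enumerate(species)}
    mats = [_nodal_distances(t, index) for t in profile.trees]
    n = len(species)
    total = np.zeros(n)
    terms = np.zeros(n)
    T = len(mats)
    for x in range(T):
        Dx = mats[x]
        for y in range(x + 1, T):
            Dy = mats[y]
            valid = np.isfinite(Dx) & np.isfinite(Dy)
            np.fill_diagonal(valid, False)
            den = (Dx + Dy) ** 2
            with np.errstate(invalid="ignore", divide="ignore"):
                contrib = np.where(valid & (den > 0), np.abs(Dx - Dy) / den, 0.0)
            total += contrib.sum(axis=1)
            terms += valid.sum(axis=1)
    out: dict[str, float] = {}
    present = np.zeros(n)
    for m in mats:
        present += np.isfinite(np.diagonal(m))
    for i, sp in enumerate(species):
        if present[i] >= 2 and terms[i] > 0:
            out[sp] = float(total[i] / terms[i])
    return out


def prune_rogues(
    matrix: Supermatrix, profile: BootstrapProfile, fraction: float
) -> tuple[Supermatrix, list[str]]:
    """Drop the floor(fraction * n) most unstable species from the matrix.

    Ties: higher raw instability first, then species name order.  Species
    with no defined score rank most unstable.  Raises if pruning would
    leave fewer than 4 species.
    """
    if fraction < 0 or fraction >= 1:
        raise ValueError("fraction must be in [0, 1)")
    n = matrix.n_species
    k = math.floor(fraction * n)
    if k == 0:
        return matrix, []
    if n - k < 4:
        raise ValueError("pruning would leave fewer than 4 species")
    scores = taxon_instability(profile)
    ranked = sorted(
        matrix.species,
        key=lambda sp: (-scores.get(sp, math.inf), sp),
    )
    pruned = ranked[:k]
    keep = [sp for sp in matrix.species if sp not in set(pruned)]
    return matrix.subset(keep), sorted(pruned)
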