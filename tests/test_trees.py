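"""Bootstrap, consensus (vs. an independent split-count oracle),
instability scoring and rogue pruning."""

import random
from collections import Counter

import dendropy
import numpy as np
import pytest

from phyloprogress.supermatrix import Supermatrix
from phyloprogress.synthetic import _yule_tree, evolve_sequences
from phyloprogress.trees import (
    BootstrapProfile,
    bootstrap_trees,
    majority_consensus,
    prune_rogues,
    taxon_instability,
    tree_splits,
)


def _matrix_from_seqs(seqs):
    species = sorted(seqs)
    cells = np.array([list(seqs[sp]) for sp in species], dtype="<U1")
    return Supermatrix(species=species, cells=cells, partitions=[("g", 0, cells.shape[1])])


def _signal_matrix(n_taxa=8, length=1200, edge=0.05, seed=0):
    labels = [f"sp{i}" for i in range(n_taxa)]
    tree = _yule_tree(n_taxa, labels, 0.3, seed + 500)
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = edge
    rng = np.random.default_rng(seed)
    seqs = evolve_sequences(tree, length, 1.0, 4.0, (0.25,) * 4, rng)
    return _matrix_from_seqs(seqs), tree


def _random_profile(n_taxa, n_trees, seed):
    rng = random.Random(seed)
    taxa = [f"sp{i}" for i in range(n_taxa)]
    trees = []
    for _ in range(n_trees):
        ns = dendropy.TaxonNamespace(taxa)
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, taxon_namespace=ns, num_extant_tips=n_taxa, rng=rng
        )
        trees.append(tree)
    return BootstrapProfile(trees=trees, species=taxa, n_replicates=n_trees, seed=seed)


# -- bootstrap ---------------------------------------------------------------


def test_bootstrap_deterministic_given_seed():
    mat, _ = _signal_matrix(seed=1)
    a = bootstrap_trees(mat, n_replicates=10, seed=7)
    b = bootstrap_trees(mat, n_replicates=10, seed=7)
    for ta, tb in zip(a.trees, b.trees):
        assert tree_splits(ta) == tree_splits(tb)


def test_bootstrap_requires_four_species():
    seqs = {f"sp{i}": "ACGTACGTACGTACGTACGT" for i in range(3)}
    with pytest.raises(ValueError, match="4 species"):
        bootstrap_trees(_matrix_from_seqs(seqs), n_replicates=5, seed=0)


def test_zero_variation_matrix_gives_no_support():
    """With no variable sites every replicate is arbitrary; no split can
    reach majority support systematically."""
    seqs = {f"sp{i}": "ACGT" * 100 for i in range(6)}
    prof = bootstrap_trees(_matrix_from_seqs(seqs), n_replicates=50, seed=3)
    cons = majority_consensus(prof, 0.95)
    assert cons.n_resolved <= 1


def test_high_signal_replicates_recover_truth():
    mat, true = _signal_matrix(seed=2)
    prof = bootstrap_trees(mat, n_replicates=20, seed=2)
    truth = tree_splits(true)
    exact = sum(tree_splits(t) == truth for t in prof.trees)
    assert exact >= 18


# -- consensus ---------------------------------------------------------------


def _oracle_split_counts(trees, taxa):
    """Independent split tally via dendropy's bipartition encoding."""
    counts: Counter = Counter()
    for t in trees:
        tc = t.clone(depth=1)
        tc.retain_taxa_with_labels(list(taxa))
        tc.encode_bipartitions()
        labels = {lf.taxon.label for lf in tc.leaf_node_iter()}
        anchor = min(labels)
        per_tree: set = set()
        for b in tc.bipartition_encoding:
            leafset = {
                tx.label
                for tx in tc.taxon_namespace.bitmask_taxa_list(b.leafset_bitmask)
                if tx.label in labels
            }
            side = frozenset(labels - leafset) if anchor in leafset else frozenset(leafset)
            if 2 <= len(side) <= len(labels) - 2:
                per_tree.add(side)  # a rooted tree shows the root split twice
        counts.update(per_tree)
    return counts


@pytest.mark.parametrize("n_taxa,n_trees,seed", [(6, 10, 0), (7, 15, 1), (8, 20, 2)])
def test_consensus_matches_exhaustive_split_tally(n_taxa, n_trees, seed):
    prof = _random_profile(n_taxa, n_trees, seed)
    counts = _oracle_split_counts(prof.trees, set(prof.species))
    for threshold in (0.5, 0.95):
        cons = majority_consensus(prof, threshold)
        expected = {
            s: c / n_trees
            for s, c in counts.items()
            if (c / n_trees > threshold if threshold <= 0.5 else c / n_trees >= threshold)
        }
        assert cons.splits == expected
        # the assembled tree displays exactly the retained splits
        assert tree_splits(cons.tree) == set(expected)


def test_identical_trees_full_support():
    mat, true = _signal_matrix(n_taxa=6, seed=3)
    ns = true.taxon_namespace
    trees = [
        dendropy.Tree.get(data=true.as_string(schema="newick"), schema="newick")
        for _ in range(100)
    ]
    prof = BootstrapProfile(trees=trees, species=sorted(t.label for t in ns), n_replicates=100, seed=0)
    cons = majority_consensus(prof, 0.5)
    assert cons.n_resolved == 3  # 6 - 3 nontrivial splits
    assert all(v == 1.0 for v in cons.splits.values())


def test_threshold_rules_strict_at_half_inclusive_above():
    """A split in 60/100 trees survives the 50% rule but not the 95% rule;
    one in exactly 95/100 survives the 95% rule."""
    base, alt = [], []
    t1 = dendropy.Tree.get(data="((a,b),(c,d),(e,f));", schema="newick")
    t2 = dendropy.Tree.get(data="((a,c),(b,d),(e,f));", schema="newick")
    trees = []
    for i in range(100):
        src = t1 if i < 60 else t2
        trees.append(dendropy.Tree.get(data=src.as_string(schema="newick"), schema="newick"))
    prof = BootstrapProfile(trees=trees, species=list("abcdef"), n_replicates=100, seed=0)
    c50 = majority_consensus(prof, 0.5)
    assert frozenset({"a", "b"}) in c50.splits or frozenset({"c","d","e","f"}) in c50.splits
    assert c50.splits.get(frozenset({"e", "f"})) == 1.0
    c95 = majority_consensus(prof, 0.95)
    assert frozenset({"e", "f"}) in c95.splits
    assert not any(s for s in c95.splits if c95.splits[s] < 0.95)


def test_consensus_nesting_95_within_50():
    for seed in range(3):
        prof = _random_profile(7, 12, seed + 10)
        c50 = majority_consensus(prof, 0.5)
        c95 = majority_consensus(prof, 0.95)
        assert set(c95.splits) <= set(c50.splits)


def test_consensus_needs_four_shared_leaves():
    t1 = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
    t2 = dendropy.Tree.get(data="((a,b),(e,f));", schema="newick")
    prof = BootstrapProfile(trees=[t1, t2], species=list("abcdef"), n_replicates=2, seed=0)
    with pytest.raises(ValueError, match="shared leaves"):
        majority_consensus(prof, 0.5)


def test_support_total_bounded():
    for seed in range(3):
        n_taxa, n_trees = 7, 12
        prof = _random_profile(n_taxa, n_trees, seed + 30)
        counts = _oracle_split_counts(prof.trees, set(prof.species))
        assert sum(counts.values()) <= n_trees * (n_taxa - 3)


# -- instability & pruning ---------------------------------------------------


def _trees_from_newicks(newicks):
    return [dendropy.Tree.get(data=nw, schema="newick") for nw in newicks]


def test_identical_trees_zero_instability():
    nw = "((a,b),((c,d),(e,f)));"
    prof = BootstrapProfile(
        trees=_trees_from_newicks([nw] * 4), species=list("abcdef"), n_replicates=4, seed=0
    )
    scores = taxon_instability(prof)
    assert set(scores) == set("abcdef")
    assert all(v == 0.0 for v in scores.values())


def test_alternating_taxon_scores_highest():
    """A taxon that jumps between two distant attachment points while the
    backbone stays fixed gets the top instability score."""
    near = "((((a,r),b),c),(d,(e,f)));"
    far = "(((a,b),c),(d,(e,(f,r))));"
    prof = BootstrapProfile(
        trees=_trees_from_newicks([near, far, near, far]),
        species=list("abcdef") + ["r"],
        n_replicates=4,
        seed=0,
    )
    scores = taxon_instability(prof)
    assert max(scores, key=scores.get) == "r"


def test_instability_invariant_to_tree_order():
    near = "((((a,r),b),c),(d,(e,f)));"
    far = "(((a,b),c),(d,(e,(f,r))));"
    other = "((((a,b),r),c),(d,(e,f)));"
    p1 = BootstrapProfile(
        trees=_trees_from_newicks([near, far, other]), species=list("abcdefr"), n_replicates=3, seed=0
    )
    p2 = BootstrapProfile(
        trees=_trees_from_newicks([other, near, far]), species=list("abcdefr"), n_replicates=3, seed=0
    )
    s1, s2 = taxon_instability(p1), taxon_instability(p2)
    assert s1.keys() == s2.keys()
    for k in s1:
        assert s1[k] == pytest.approx(s2[k])


def test_prune_counts_floor_arithmetic():
    mat, _ = _signal_matrix(n_taxa=40, length=400, seed=5)
    prof = bootstrap_trees(mat, n_replicates=8, seed=5)
    pruned_mat, pruned = prune_rogues(mat, prof, 0.05)
    assert len(pruned) == 2  # floor(0.05 * 40)
    assert pruned_mat.n_species == 38
    pruned_mat10, pruned10 = prune_rogues(mat, prof, 0.10)
    assert len(pruned10) == 4


def test_prune_fraction_zero_is_identity():
    mat, _ = _signal_matrix(seed=6)
    prof = bootstrap_trees(mat, n_replicates=5, seed=6)
    same, pruned = prune_rogues(mat, prof, 0.0)
    assert pruned == [] and same is mat


def test_prune_below_four_species_raises():
    mat, _ = _signal_matrix(n_taxa=4, seed=7)
    prof = bootstrap_trees(mat, n_replicates=5, seed=7)
    with pytest.raises(ValueError, match="fewer than 4"):
        prune_rogues(mat, prof, 0.25)


def test_planted_rogue_is_pruned():
    """A planted rogue — random characters at a small minority of sites,
    missing data elsewhere, so its placement jumps between replicates —
    is identified as least stable and removed at the 5% stringency."""
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        mat, _ = _signal_matrix(n_taxa=20, length=600, seed=seed + 100)
        rng = np.random.default_rng(seed)
        cells = mat.cells.copy()
        rogue_idx = mat.species.index("sp0")
        cells[rogue_idx, :] = "?"
        cells[rogue_idx, :80] = rng.choice(list("ACGT"), size=80)
        noisy = Supermatrix(species=mat.species, cells=cells, partitions=mat.partitions)
        prof = bootstrap_trees(noisy, n_replicates=16, seed=seed)
        _, pruned = prune_rogues(noisy, prof, 0.05)
        hits += "sp0" in pruned
    assert hits >= 9
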