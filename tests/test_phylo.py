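"""NJ correctness, bootstrap, recombination detection and the masking loop."""

import math

import dendropy
import numpy as np
import pytest

from paleostrain import (RefAnchoredMSA, SimParams, bootstrap_support,
                         build_nj_tree, detect_recombination,
                         external_tree_builder, iterative_mask_phylogeny,
                         jc_distance_matrix, neighbor_joining, rf_distance,
                         simulate_strain_set, transfer_tract)
from paleostrain.phylo import DistanceMatrix, bipartitions


def random_additive_tree(n_leaves, rng):
    """Random binary tree with branch lengths; returns (newick, D matrix).

    Distances are computed independently of any tree code under test by
    accumulating path lengths while merging clusters.
    """
    labels = [f"t{i}" for i in range(n_leaves)]
    D = np.zeros((n_leaves, n_leaves))
    clusters = [({i}, {i: 0.0}, labels[i]) for i in range(n_leaves)]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        (sa, da, na) = clusters[i]
        (sb, db, nb) = clusters[j]
        la, lb = rng.uniform(0.05, 1.0, 2)
        for x in sa:
            for y in sb:
                D[x, y] = D[y, x] = da[x] + la + db[y] + lb
        merged = ({*sa, *sb},
                  {**{x: d + la for x, d in da.items()},
                   **{y: d + lb for y, d in db.items()}},
                  f"({na}:{la},{nb}:{lb})")
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    newick = clusters[0][2] + ";"
    return labels, newick, D


class TestJCDistance:
    def test_identical_rows_zero(self):
        msa = RefAnchoredMSA("r", {"a": "ACGT" * 50, "b": "ACGT" * 50,
                                   "c": "ACGT" * 50})
        dm = jc_distance_matrix(msa)
        assert dm.matrix.max() == 0.0

    def test_closed_form_at_p_010(self):
        """p = 0.10 gives d = -(3/4) ln(1 - 0.4/3) = 0.107326 exactly."""
        L = 10_000
        a = "A" * L
        b = "C" * 1000 + "A" * (L - 1000)
        msa = RefAnchoredMSA("r", {"a": a, "b": b, "c": a})
        dm = jc_distance_matrix(msa)
        i, j = dm.ids.index("a"), dm.ids.index("b")
        assert dm.matrix[i, j] == pytest.approx(0.1073256, abs=1e-6)
        assert dm.pairwise_sites[i, j] == L

    def test_pairwise_deletion_counts(self):
        msa = RefAnchoredMSA("r", {"a": "AC-TAC", "b": "ACG-AC", "c": "ACGTAC"})
        dm = jc_distance_matrix(msa)
        i, j = dm.ids.index("a"), dm.ids.index("b")
        assert dm.pairwise_sites[i, j] == 4  # two columns dropped pairwise

    def test_saturation_reported(self):
        msa = RefAnchoredMSA("r", {"a": "A" * 100, "b": "C" * 100,
                                   "c": "A" * 100})
        dm = jc_distance_matrix(msa)
        assert ("a", "b") in dm.saturated
        assert math.isinf(dm.matrix[dm.ids.index("a"), dm.ids.index("b")])

    def test_zero_comparable_columns_raises(self):
        msa = RefAnchoredMSA("r", {"a": "AC--", "b": "--GT", "c": "ACGT"})
        with pytest.raises(ValueError, match="comparable"):
            jc_distance_matrix(msa)


class TestNeighborJoining:
    def test_recovers_random_additive_trees(self):
        """On additive distances NJ must recover the generating topology
        (RF = 0), across 50 random 8-leaf trees."""
        rng = np.random.default_rng(123)
        for _ in range(50):
            labels, newick, D = random_additive_tree(8, rng)
            dm = DistanceMatrix(labels, D, np.full_like(D, 1000, dtype=np.int64))
            est = neighbor_joining(dm)
            true = dendropy.Tree.get(data=newick, schema="newick")
            assert rf_distance(est, true) == 0

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5.0, 9.0], [5.0, 0, 10.0], [9.0, 10.0, 0]])
        dm = DistanceMatrix(["a", "b", "c"], D,
                            np.full((3, 3), 100, dtype=np.int64))
        tree = neighbor_joining(dm)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_tie_break_stable_under_relabeling(self):
        """An ultrametric matrix with two equal Q minima resolves by the
        lexicographic id rule, so relabeled inputs give the same joins."""
        D = np.array([[0, 2, 6, 6.0],
                      [2, 0, 6, 6.0],
                      [6, 6, 0, 2.0],
                      [6, 6, 2, 0.0]])
        sites = np.full((4, 4), 100, dtype=np.int64)
        t1 = neighbor_joining(DistanceMatrix(list("abcd"), D, sites))
        # same matrix with rows/cols permuted and relabeled back
        perm = [2, 3, 0, 1]
        Dp = D[np.ix_(perm, perm)]
        labels_p = [list("abcd")[k] for k in perm]
        t2 = neighbor_joining(DistanceMatrix(labels_p, Dp, sites))
        assert rf_distance(t1, t2) == 0
        assert bipartitions(t1) == {frozenset({"c", "d"})}

    def test_nonfinite_distances_rejected(self):
        D = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
        dm = DistanceMatrix(list("abc"), D, np.full((3, 3), 9, dtype=np.int64))
        with pytest.raises(ValueError, match="non-finite"):
            neighbor_joining(dm)


def test_nj_agrees_with_independent_implementation():
    """Cross-check against scikit-bio's NJ on noisy (non-additive) matrices."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(7)
    for _ in range(5):
        labels, newick, D = random_additive_tree(7, rng)
        noisy = D + rng.uniform(0, 0.01, D.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        mine = neighbor_joining(DistanceMatrix(
            labels, noisy, np.full_like(D, 100, dtype=np.int64)))
        ref = skbio.tree.nj(skbio.DistanceMatrix(noisy, labels))
        ref_dp = dendropy.Tree.get(data=str(ref), schema="newick")
        assert rf_distance(mine, ref_dp) == 0


@pytest.fixture(scope="module")
def two_clade_msa():
    p = SimParams(genome_length=20_000, n_species=2, n_strains_per_species=3,
                  between_species_divergence=0.01,
                  within_species_divergence=0.001, seed=21)
    genomes, _ = simulate_strain_set(p)
    return RefAnchoredMSA("r", genomes)


class TestBootstrap:
    def test_clear_split_gets_full_support(self, two_clade_msa):
        tree = bootstrap_support(two_clade_msa, n_reps=100, seed=5)
        split = frozenset({"sp2_st1", "sp2_st2", "sp2_st3"})
        supports = {frozenset(lf.taxon.label for lf in n.leaf_iter()): n.label
                    for n in tree.preorder_node_iter()
                    if not n.is_leaf() and n.parent_node is not None}
        found = [v for k, v in supports.items()
                 if k == split or k == frozenset(two_clade_msa.rows) - split]
        assert found and all(v == "100" for v in found)

    def test_zero_reps_returns_point_tree(self, two_clade_msa):
        tree = bootstrap_support(two_clade_msa, n_reps=0)
        assert all(n.label is None for n in tree.preorder_node_iter()
                   if not n.is_leaf())

    def test_fixed_seed_reproducible(self, two_clade_msa):
        t1 = bootstrap_support(two_clade_msa, n_reps=30, seed=9)
        t2 = bootstrap_support(two_clade_msa, n_reps=30, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


class TestRecombinationDetector:
    def test_identical_rows_no_tracts(self):
        msa = RefAnchoredMSA("r", {f"g{i}": "ACGT" * 1000 for i in range(4)})
        assert detect_recombination(msa) == []

    def test_false_positive_rate_under_clonal_null(self):
        """Clonal alignments (uniform substitution density) must trigger
        tracts in at most the configured family-wise fraction of rows."""
        rng = np.random.default_rng(31)
        rows_with_tracts = n_rows = 0
        for _ in range(100):
            root = rng.integers(0, 4, 10_000)
            mat = np.array([np.where(rng.random(root.size) < 0.005,
                                     (root + rng.integers(1, 4, root.size)) % 4,
                                     root)
                            for _ in range(4)])
            rows = {f"g{i}": "".join("ACGT"[b] for b in mat[i])
                    for i in range(4)}
            tracts = detect_recombination(RefAnchoredMSA("r", rows),
                                          window=1000, step=100, alpha=0.05)
            hit_rows = {t.row_id for t in tracts}
            rows_with_tracts += len(hit_rows)
            n_rows += 4
        assert rows_with_tracts / n_rows <= 0.05

    def test_import_recovered_with_jaccard(self):
        """A 2-kb import at 5% divergence is found with tract overlap
        (Jaccard) of at least 0.5 against the truth interval."""
        p = SimParams(genome_length=20_000, n_species=2,
                      n_strains_per_species=4,
                      between_species_divergence=0.025,
                      within_species_divergence=0.002, seed=4)
        genomes, truth = simulate_strain_set(p)
        genomes = transfer_tract(genomes, truth, "sp2_st1", "sp1_st1",
                                 5_000, 7_000)
        rows = {k: genomes[k] for k in
                ["sp1_st1", "sp1_st2", "sp1_st3", "sp1_st4"]}
        tracts = [t for t in detect_recombination(RefAnchoredMSA("r", rows))
                  if t.row_id == "sp1_st1"]
        assert len(tracts) == 1
        s, e = tracts[0].start, tracts[0].end
        jac = (min(e, 7000) - max(s, 5000)) / (max(e, 7000) - min(s, 5000))
        assert jac >= 0.5


class TestMaskingLoop:
    def test_clonal_input_terminates_immediately(self):
        p = SimParams(genome_length=20_000, n_species=1,
                      n_strains_per_species=5,
                      within_species_divergence=0.003, seed=41)
        genomes, _ = simulate_strain_set(p)
        res = iterative_mask_phylogeny(RefAnchoredMSA("r", genomes))
        assert res.status == "converged"
        assert res.iterations == 1 and res.masked_cells == 0

    def test_import_distorts_then_masking_restores_topology(self):
        """A host-to-host import pulls the recipient toward the donor clade
        and distorts NJ; after masking, the clonal topology is recovered
        (RF = 0) within a handful of iterations."""
        p = SimParams(genome_length=20_000, n_species=2,
                      n_strains_per_species=4,
                      between_species_divergence=0.025,
                      within_species_divergence=0.002, seed=4)
        genomes, truth = simulate_strain_set(p)
        contaminated = transfer_tract(genomes, truth, "sp2_st1", "sp1_st1",
                                      5_000, 7_000)
        keep = ["sp1_st1", "sp1_st2", "sp1_st3", "sp1_st4",
                "sp2_st1", "sp2_st2"]
        msa = RefAnchoredMSA("r", {k: contaminated[k] for k in keep})
        clonal_tree = build_nj_tree(RefAnchoredMSA(
            "r", {k: genomes[k] for k in keep}))
        assert rf_distance(build_nj_tree(msa), clonal_tree) > 0
        res = iterative_mask_phylogeny(msa)
        assert res.status == "converged"
        assert res.iterations <= 5
        assert rf_distance(res.tree, clonal_tree) == 0
        # masked cells accumulate monotonically by construction
        assert res.masked_cells > 0

    def test_max_iter_warning_status(self):
        """A detector that always reports a fresh tract hits max_iter with a
        warning status instead of raising."""
        calls = []

        def stubborn(msa):
            from paleostrain.phylo import RecombinationTract
            calls.append(1)
            return [RecombinationTract("a", len(calls) - 1, len(calls), 1e-9)]

        msa = RefAnchoredMSA("r", {"a": "ACGT" * 100, "b": "ACGT" * 100,
                                   "c": "ACGT" * 100})
        res = iterative_mask_phylogeny(msa, detector=stubborn, max_iter=3)
        assert res.status == "max_iter"
        assert res.iterations == 3

    def test_stalled_detector_stops(self):
        def fixed(msa):
            from paleostrain.phylo import RecombinationTract
            return [RecombinationTract("a", 0, 4, 1e-9)]

        msa = RefAnchoredMSA("r", {"a": "ACGT" * 100, "b": "ACGT" * 100,
                                   "c": "ACGT" * 100})
        res = iterative_mask_phylogeny(msa, detector=fixed, max_iter=10)
        assert res.status == "stalled"
        assert res.masked_cells == 4


def test_external_builder_adapter_with_fasttree():
    """The aligned-FASTA-in / Newick-out adapter contract, exercised with
    FastTree when available."""
    import shutil
    if shutil.which("fasttree") is None:
        pytest.skip("fasttree not on PATH")
    p = SimParams(genome_length=20_000, n_species=2, n_strains_per_species=3,
                  between_species_divergence=0.02,
                  within_species_divergence=0.002, seed=51)
    genomes, _ = simulate_strain_set(p)
    msa = RefAnchoredMSA("r", genomes)
    builder = external_tree_builder(["fasttree", "-nt", "-quiet", "{fasta}"])
    tree = builder(msa)
    assert rf_distance(tree, build_nj_tree(msa)) == 0
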