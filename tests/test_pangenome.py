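"""Gene clustering, core selection, concatenation, species-specific rules."""

import numpy as np
import pandas as pd
import pytest

from paleostrain import (cluster_genes, concatenate_core_alignment, core_genes,
                         presence_absence, simulate_gene_families,
                         species_specific_genes)
from paleostrain.pangenome import PresenceAbsenceMatrix
from paleostrain.simulate import arr_to_seq


def _pam(presence, species):
    return PresenceAbsenceMatrix(presence, species)


def test_identical_sequences_one_cluster():
    genes = [(f"g{i}", f"gene{i}", "ACGT" * 100) for i in range(5)]
    clusters = cluster_genes(genes, 0.85)
    assert len(clusters) == 1
    assert len(clusters[0].members) == 5


def test_distinct_families_stay_separate():
    rng = np.random.default_rng(1)
    fam_a = arr_to_seq(rng.integers(0, 4, 600).astype(np.uint8))
    fam_b = arr_to_seq(rng.integers(0, 4, 600).astype(np.uint8))
    genes = [("g1", "a1", fam_a), ("g2", "a2", fam_a),
             ("g1", "b1", fam_b), ("g2", "b2", fam_b)]
    clusters = cluster_genes(genes, 0.80)
    assert len(clusters) == 2
    for c in clusters:
        assert len({gid[0] for _, gid, _ in c.members}) == 1


def test_simulated_families_recovered_exactly():
    """Families mutated a few percent cluster back into exactly the truth
    partition at 80% identity, and every gene lands in exactly one cluster."""
    genes, truth = simulate_gene_families(
        60, {"A": 0.95, "B": 0.95, "C": 0.95}, seed=2, n_genomes_per_species=5)
    clusters = cluster_genes(genes, 0.80)
    by_family = {}
    for _, gid, _ in genes:
        by_family.setdefault(gid.split("|")[1], set()).add(gid)
    got = {frozenset(gid for _, gid, _ in c.members) for c in clusters}
    want = {frozenset(v) for v in by_family.values()}
    assert got == want
    assert sum(len(c.members) for c in clusters) == len(genes)


def test_clustering_determinism():
    genes, _ = simulate_gene_families(20, {"A": 0.9, "B": 0.9}, seed=3,
                                      n_genomes_per_species=4)
    c1 = cluster_genes(genes, 0.80)
    c2 = cluster_genes(list(reversed(genes)), 0.80)
    assert [{m[1] for m in c.members} for c in c1] == \
           [{m[1] for m in c.members} for c in c2]


class TestCoreRule:
    """Core = present in strictly more than core_frac of genomes."""

    def setup_method(self):
        self.species = {f"g{i}": "A" for i in range(10)}

    def _matrix(self, n_present):
        pres = pd.DataFrame(False, index=["c1"], columns=list(self.species))
        pres.iloc[0, :n_present] = True
        return _pam(pres, self.species)

    def test_all_present_is_core(self):
        assert core_genes(self._matrix(10)) == ["c1"]

    def test_exactly_90_percent_is_not_core(self):
        assert core_genes(self._matrix(9)) == []

    def test_95_percent_of_20_is_core(self):
        species = {f"g{i}": "A" for i in range(20)}
        pres = pd.DataFrame(False, index=["c1"], columns=list(species))
        pres.iloc[0, :19] = True
        assert core_genes(_pam(pres, species)) == ["c1"]

    def test_degenerate_fractions_brute_force(self):
        """core_frac=0 keeps everything carried; core_frac=1 keeps nothing;
        random matrices agree with a direct scan at any cutoff."""
        rng = np.random.default_rng(4)
        species = {f"g{i}": "A" for i in range(7)}
        pres = pd.DataFrame(rng.random((30, 7)) < 0.6,
                            index=[f"c{i}" for i in range(30)],
                            columns=list(species))
        pres.iloc[0] = True  # ensure at least one universal cluster
        m = _pam(pres, species)
        assert set(core_genes(m, 0.0)) == set(pres.index[pres.any(axis=1)])
        assert core_genes(m, 1.0) == []
        for frac in (0.3, 0.5, 0.9):
            want = [c for c in pres.index if pres.loc[c].mean() > frac]
            assert core_genes(m, frac) == want


class TestSpeciesSpecificRule:
    def setup_method(self):
        self.species = {**{f"a{i}": "A" for i in range(10)},
                        **{f"b{i}": "B" for i in range(5)},
                        **{f"c{i}": "C" for i in range(5)}}
        self.cols = list(self.species)

    def _pa(self, rows):
        pres = pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))],
                            columns=self.cols)
        return _pam(pres.astype(bool), self.species)

    def test_exclusive_full_presence_is_specific(self):
        row = [g.startswith("a") for g in self.cols]
        assert species_specific_genes(self._pa([row]))["A"] == ["c0"]

    def test_single_copy_elsewhere_disqualifies(self):
        row = [g.startswith("a") or g == "b0" for g in self.cols]
        spec = species_specific_genes(self._pa([row]))
        assert spec["A"] == [] and spec["B"] == []

    def test_80_percent_own_presence_not_specific_at_090(self):
        row = [g.startswith("a") and g not in ("a8", "a9") for g in self.cols]
        assert species_specific_genes(self._pa([row]))["A"] == []

    def test_exactly_90_percent_is_specific_inclusive(self):
        row = [g.startswith("a") and g != "a9" for g in self.cols]
        assert species_specific_genes(self._pa([row]))["A"] == ["c0"]

    def test_sets_disjoint_across_species(self):
        rng = np.random.default_rng(5)
        rows = rng.random((40, len(self.cols))) < 0.5
        spec = species_specific_genes(self._pa(list(rows)))
        seen = []
        for v in spec.values():
            seen.extend(v)
        assert len(seen) == len(set(seen))

    def test_small_species_warns(self):
        species = {"a1": "A", "a2": "A", "b1": "B"}
        pres = pd.DataFrame([[True, True, False]], index=["c0"],
                            columns=["a1", "a2", "b1"])
        with pytest.warns(UserWarning, match="fewer than 2"):
            species_specific_genes(_pam(pres, species))


class TestConcatenation:
    def test_identical_members_concatenate_without_gaps(self):
        genes = [(g, f"{g}|fam{k}", seq)
                 for k, seq in enumerate(["ACGTACGT" * 10, "GGCC" * 12])
                 for g in ("g1", "g2", "g3")]
        clusters = cluster_genes(genes, 0.9)
        species = {"g1": "A", "g2": "A", "g3": "A"}
        pam = presence_absence(clusters, species)
        core = core_genes(pam, 0.5)
        aln = concatenate_core_alignment(clusters, core, list(species))
        assert aln.length == 80 + 48
        assert set(aln.rows.values()) == {"ACGTACGT" * 10 + "GGCC" * 12}
        assert [b[1:] for b in aln.block_boundaries] == [(0, 80), (80, 128)]

    def test_total_length_is_sum_of_blocks(self):
        genes, _ = simulate_gene_families(8, {"A": 1.0, "B": 1.0}, seed=6,
                                          n_genomes_per_species=3)
        clusters = cluster_genes(genes, 0.8)
        species = {f"{sp}_g{j}": sp for sp in "AB" for j in (1, 2, 3)}
        pam = presence_absence(clusters, species)
        core = core_genes(pam, 0.9)
        aln = concatenate_core_alignment(clusters, core, list(species))
        assert aln.length == sum(e - s for _, s, e in aln.block_boundaries)
        assert len({len(r) for r in aln.rows.values()}) == 1

    def test_missing_genome_contributes_all_gap_block(self):
        genes = [("g1", "g1|f", "ACGT" * 50), ("g2", "g2|f", "ACGT" * 50)]
        clusters = cluster_genes(genes, 0.9)
        aln = concatenate_core_alignment(clusters, [clusters[0].cluster_id],
                                         ["g1", "g2", "g3"])
        assert aln.rows["g3"] == "-" * 200

    def test_species_topology_recovered_from_core_alignment(self):
        """NJ on the concatenated core alignment of a 3-species family set
        separates the species into clades."""
        from paleostrain import build_nj_tree
        from paleostrain.pangenome import ConcatenatedAlignment
        from paleostrain.phylo import bipartitions
        genes, truth = simulate_gene_families(
            25, {"A": 1.0, "B": 1.0, "C": 1.0}, seed=7,
            n_genomes_per_species=3, species_divergence=0.05,
            copy_divergence=0.005)
        clusters = cluster_genes(genes, 0.8)
        pam = presence_absence(clusters, truth.species, truth.genome_ids)
        core = core_genes(pam, 0.9)
        assert len(core) == 25
        aln = concatenate_core_alignment(clusters, core, truth.genome_ids)
        tree = build_nj_tree(aln)
        splits = bipartitions(tree)
        for sp in ("B", "C"):  # clade 'A' contains the anchor taxon
            clade = frozenset(g for g, s in truth.species.items() if s == sp)
            assert clade in splits
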