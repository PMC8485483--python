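"""Gene clustering, core-genome selection and species-specific gene calls.

Clustering is greedy centroid clustering: genes sorted by decreasing length
join the first already-founded centroid whose end-to-end alignment identity
reaches the threshold, else found a new cluster — a deliberate surrogate
for full pangenome pipelines whose paralog splitting and synteny steps are
out of scope here. Identity is matches over global-alignment columns with
end gaps penalized.

Two occupancy rules operate on the presence/absence matrix:

* core genes: present in strictly more than ``core_frac`` (default 90%) of
  all genomes;
* species-specific genes: present in at least ``presence_frac`` (default
  90%, inclusive) of one species' genomes and in zero genomes of every
  other species. The inclusive reading of "shared by 90%" is chosen in
  contrast to the explicitly strict core rule; both are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .alignment import global_alignment, global_identity


@dataclass
class PresenceAbsenceMatrix:
    """Boolean cluster x genome occupancy with genome->species labels."""

    presence: pd.DataFrame  # index: cluster ids; columns: genome ids
    species: dict[str, str]

    def __post_init__(self):
        missing = set(self.presence.columns) - set(self.species)
        if missing:
            raise ValueError(f"genomes without species label: {sorted(missing)}")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.presence.columns)

    def to_csv(self, path) -> None:
        out = self.presence.astype(int).copy()
        out.insert(0, "n_genomes", self.presence.sum(axis=1))
        out.to_csv(path)


@dataclass
class GeneCluster:
    cluster_id: str
    members: list[tuple[str, str, str]]  # (genome_id, gene_id, sequence)
    centroid_id: str

    @property
    def centroid_seq(self) -> str:
        return next(s for _, gid, s in self.members if gid == self.centroid_id)


def _kmer_set(seq: str, k: int = 9) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def cluster_genes(gene_sequences: list[tuple[str, str, str]],
                  min_identity: float) -> list[GeneCluster]:
    """Greedy centroid clustering at the given global-alignment identity.

    Sequences are processed by decreasing length (ties by genome then gene
    id, making the partition deterministic); each joins the first existing
    centroid with identity >= min_identity, else founds a cluster.
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    order = sorted(gene_sequences, key=lambda t: (-len(t[2]), t[0], t[1]))
    clusters: list[GeneCluster] = []
    centroids: list[tuple[str, set[str], int]] = []  # (seq, kmers, index)
    for genome_id, gene_id, seq in order:
        if not seq:
            raise ValueError(f"empty sequence: {gene_id}")
        kmers = _kmer_set(seq)
        placed = False
        for cseq, ckmers, ci in centroids:
            lo, hi = sorted((len(seq), len(cseq)))
            if lo / hi < min_identity:        # identity upper bound
                continue
            shared = len(kmers & ckmers)
            if shared / max(min(len(kmers), len(ckmers)), 1) < 0.05:
                continue                      # cheap dissimilarity screen
            if global_identity(seq, cseq) >= min_identity:
                clusters[ci].members.append((genome_id, gene_id, seq))
                placed = True
                break
        if not placed:
            ci = len(clusters)
            clusters.append(GeneCluster(f"cluster{ci + 1:04d}",
                                        [(genome_id, gene_id, seq)], gene_id))
            centroids.append((seq, kmers, ci))
    return clusters


def presence_absence(clusters: list[GeneCluster], species: dict[str, str],
                     genome_ids: list[str] | None = None) -> PresenceAbsenceMatrix:
    """Occupancy matrix of clusters over genomes (all labeled genomes by
    default, so genomes carrying no gene still appear as absent columns)."""
    if genome_ids is None:
        genome_ids = sorted(species)
    mat = pd.DataFrame(False, index=[c.cluster_id for c in clusters],
                       columns=genome_ids)
    for c in clusters:
        for genome_id, _, _ in c.members:
            mat.loc[c.cluster_id, genome_id] = True
    return PresenceAbsenceMatrix(mat, species)


def core_genes(matrix: PresenceAbsenceMatrix, core_frac: float = 0.90) -> list[str]:
    """Clusters present in strictly more than core_frac of genomes."""
    frac = matrix.presence.mean(axis=1)
    return list(frac.index[frac > core_frac])


def species_specific_genes(matrix: PresenceAbsenceMatrix,
                           presence_frac: float = 0.90) -> dict[str, list[str]]:
    """Clusters >= presence_frac within one species, absent in all others."""
    species_names = sorted(set(matrix.species.values()))
    if len(species_names) < 2:
        raise ValueError("need >= 2 species labels")
    cols_by_species = {sp: [g for g in matrix.genome_ids
                            if matrix.species[g] == sp]
                       for sp in species_names}
    for sp, cols in cols_by_species.items():
        if len(cols) < 2:
            warnings.warn(f"species '{sp}' has fewer than 2 genomes; its "
                          "specific-gene calls are weakly supported")
    out: dict[str, list[str]] = {sp: [] for sp in species_names}
    for sp in species_names:
        own = matrix.presence[cols_by_species[sp]]
        others = matrix.presence[[g for g in matrix.genome_ids
                                  if matrix.species[g] != sp]]
        ok = (own.mean(axis=1) >= presence_frac) & (others.sum(axis=1) == 0)
        out[sp] = list(ok.index[ok])
    return out


# ---------------------------------------------------------------------------
# Concatenated core alignment (center-star per cluster)
# ---------------------------------------------------------------------------

@dataclass
class ConcatenatedAlignment:
    """Core-gene blocks concatenated in sorted cluster-id order."""

    rows: dict[str, str]
    block_boundaries: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def _center_star(cluster: GeneCluster) -> dict[str, str]:
    """Align cluster members around the centroid; one row per genome
    (first member wins if a genome carries paralogs)."""
    centroid = cluster.centroid_seq
    n = len(centroid)
    per_member = []
    for genome_id, gene_id, seq in cluster.members:
        c_aln, m_aln = global_alignment(centroid, seq)
        ins = [""] * (n + 1)  # insertions before centroid position p
        cols = [""] * n
        cp = 0
        for cb, mb in zip(c_aln, m_aln):
            if cb == "-":
                ins[cp] += mb
            else:
                cols[cp] = mb
                cp += 1
        per_member.append((genome_id, ins, cols))
    max_ins = [max(len(m[1][p]) for m in per_member) for p in range(n + 1)]
    out: dict[str, str] = {}
    for genome_id, ins, cols in per_member:
        if genome_id in out:
            continue
        parts = []
        for p in range(n):
            parts.append(ins[p].ljust(max_ins[p], "-"))
            parts.append(cols[p])
        parts.append(ins[n].ljust(max_ins[n], "-"))
        out[genome_id] = "".join(parts)
    return out


def concatenate_core_alignment(clusters: list[GeneCluster],
                               core_ids: list[str],
                               genome_ids: list[str] | None = None
                               ) -> ConcatenatedAlignment:
    """Concatenate per-cluster center-star alignments over all genomes.

    A genome absent from a cluster contributes an all-gap block. Blocks are
    concatenated in sorted cluster-id order; boundaries are reported as
    (cluster_id, start, end) half-open column intervals.
    """
    by_id = {c.cluster_id: c for c in clusters}
    if genome_ids is None:
        genome_ids = sorted({g for c in clusters for g, _, _ in c.members})
    pieces: dict[str, list[str]] = {g: [] for g in genome_ids}
    boundaries = []
    offset = 0
    for cid in sorted(core_ids):
        block = _center_star(by_id[cid])
        blen = len(next(iter(block.values())))
        for g in genome_ids:
            pieces[g].append(block.get(g, "-" * blen))
        boundaries.append((cid, offset, offset + blen))
        offset += blen
    return ConcatenatedAlignment({g: "".join(p) for g, p in pieces.items()},
                                 boundaries)
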