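"""Synthetic ancient-metagenome generator with full ground truth.

Emulates the statistical structure that strain-level palaeogenomics of oral
microbiomes relies on: a few deeply diverged species (>15% nucleotide
divergence between species ancestors), near-clonal strains within each
species (pairwise divergence of order 1%), kilobase-scale homologous
recombination imports, short ancient-DNA fragments (>=25-30 nt), elevated
terminal C->T / G->A misincorporation decaying exponentially into the read,
and uniform sequencing error. Every stochastic event is recorded in a
:class:`SimTruth` so downstream stages can be scored as parameter-recovery
problems.

Coordinates are 0-based half-open throughout; FASTQ/SAM emission converts at
the boundary (see :mod:`paleostrain.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import ReadAlignment, revcomp

BASES = "ACGT"
_BASE_TO_INT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_TO_INT[ord(_b)] = _i
_INT_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def seq_to_arr(seq: str) -> np.ndarray:
    return _BASE_TO_INT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def arr_to_seq(arr: np.ndarray) -> str:
    return _INT_TO_BASE[arr].tobytes().decode()


class SimulationParameterError(ValueError):
    """Raised when a simulation parameter is out of range; names the field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic strain set and read generator.

    Divergence parameters are per-lineage expectations: ``within_species_
    divergence`` is the root-to-tip length of the (unit-depth, rescaled)
    strain tree, so the expected pairwise divergence between two strains of
    one species approaches twice that value; ``between_species_divergence``
    is the root-to-species-ancestor length, so species ancestors are
    separated by about twice that value. Recombination follows the
    import-from-outside parameterization: expected imports per branch
    (R/theta analog), mean tract length in bp (delta analog) and divergence
    of the imported tract from the clonal frame (nu analog).
    """

    genome_length: int = 50_000
    gc_content: float = 0.5
    n_species: int = 3
    between_species_divergence: float = 0.075
    n_strains_per_species: int = 4
    within_species_divergence: float = 0.005
    recomb_rate_per_branch: float = 0.0
    mean_tract_length: int = 2_000
    tract_divergence: float = 0.05
    mean_fragment_length: float = 60.0
    min_fragment_length: int = 30
    fragment_length_sigma: float = 0.35
    damage_rate_5p: float = 0.30
    damage_decay: float = 0.5
    seq_error: float = 0.001
    depth_per_strain: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("gc_content", "between_species_divergence",
                     "within_species_divergence", "tract_divergence",
                     "damage_rate_5p", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationParameterError(name, f"must be in [0, 1], got {v}")
        if self.min_fragment_length < 25:
            raise SimulationParameterError(
                "min_fragment_length", "must be >= 25 (shorter fragments are "
                f"not retained by ancient-DNA read processing), got {self.min_fragment_length}")
        if self.genome_length < 10 * self.mean_tract_length:
            raise SimulationParameterError(
                "genome_length", "must be >= 10 x mean_tract_length "
                f"({10 * self.mean_tract_length}), got {self.genome_length}")
        if self.n_species < 1:
            raise SimulationParameterError("n_species", "must be >= 1")
        if self.n_strains_per_species < 1:
            raise SimulationParameterError("n_strains_per_species", "must be >= 1")
        if self.depth_per_strain <= 0:
            raise SimulationParameterError("depth_per_strain", "must be > 0")
        if self.recomb_rate_per_branch < 0:
            raise SimulationParameterError("recomb_rate_per_branch", "must be >= 0")
        if self.damage_decay < 0:
            raise SimulationParameterError("damage_decay", "must be >= 0")
        if self.mean_fragment_length < self.min_fragment_length:
            raise SimulationParameterError(
                "mean_fragment_length", "must be >= min_fragment_length")


@dataclass
class SimTruth:
    """Ground truth of a simulated strain set.

    ``mutations`` records, per strain, the final substitutions relative to
    its species ancestor (the clonal frame). ``recomb_tracts`` are 0-based
    half-open intervals on the strain genome affected by an import.
    ``read_truth`` is filled by :func:`simulate_reads`.
    """

    species_tree: dendropy.Tree
    strain_trees: dict[str, dendropy.Tree]
    mutations: list[tuple[str, int, str, str]]
    recomb_tracts: list[tuple[str, int, int]]
    read_truth: list[tuple] = field(default_factory=list)
    # extras used by recovery scoring
    root_genome: str = ""
    species_ancestors: dict[str, str] = field(default_factory=dict)
    clonal_genomes: dict[str, str] = field(default_factory=dict)
    species_of: dict[str, str] = field(default_factory=dict)


def _mutate(arr: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    """Apply a Jukes-Cantor substitution process at the given expected
    substitutions/site; multiple hits compose (offsets add mod 4)."""
    out = arr.copy()
    n = rng.poisson(divergence * arr.size)
    if n:
        pos = rng.integers(0, arr.size, n)
        off = rng.integers(1, 4, n).astype(np.int64)
        delta = np.zeros(arr.size, dtype=np.int64)
        np.add.at(delta, pos, off)
        out = ((out.astype(np.int64) + delta) % 4).astype(np.uint8)
    return out


def _yule_tree(n_tips: int, labels: list[str],
               rng: np.random.Generator) -> dendropy.Tree:
    """Unit-depth (ultrametric) pure-birth tree over the given tip labels.

    Waiting times between splits are Exp(k) while k lineages are extant,
    with a final Exp(n) stretch after the last split so no tip edge is
    degenerate; all depths are then rescaled to 1.
    """
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    if n_tips == 1:
        tree.seed_node.add_child(dendropy.Node(taxon=taxa[0], edge_length=1.0))
        return tree
    # crown start: the root is the MRCA, splitting at time 0
    birth: dict = {}
    active = []
    for _ in range(2):
        child = dendropy.Node()
        tree.seed_node.add_child(child)
        birth[child] = 0.0
        active.append(child)
    t = 0.0
    for k in range(2, n_tips):
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(len(active))))
        node.edge.length = t - birth[node]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth[child] = t
            active.append(child)
    T = t + rng.exponential(1.0 / n_tips)
    for i, leaf in enumerate(active):
        leaf.taxon = taxa[i]
        leaf.edge.length = T - birth[leaf]
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= T
    return tree


def _scale_tree(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return out


def simulate_strain_set(params: SimParams) -> tuple[dict[str, str], SimTruth]:
    """Simulate genomes for n_species x n_strains_per_species strains.

    Substitutions are placed by a Jukes-Cantor process along a per-species
    unit-depth Yule tree rescaled to ``within_species_divergence``; each
    recombination import overwrites a contiguous tract with a copy of the
    local clonal frame mutated at ``tract_divergence``. Returns the strain
    genomes and a :class:`SimTruth` recording every event.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 0])
    L = params.genome_length
    gc = params.gc_content
    root = rng.choice(4, size=L, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
                      ).astype(np.uint8)

    species_names = [f"sp{i + 1}" for i in range(params.n_species)]
    sp_tree = dendropy.Tree.get(
        data="(" + ",".join(f"{s}:{params.between_species_divergence}"
                            for s in species_names) + ");",
        schema="newick")

    genomes: dict[str, str] = {}
    truth = SimTruth(species_tree=sp_tree, strain_trees={}, mutations=[],
                     recomb_tracts=[], root_genome=arr_to_seq(root))

    for si, sp in enumerate(species_names):
        ancestor = _mutate(root, params.between_species_divergence, rng)
        truth.species_ancestors[sp] = arr_to_seq(ancestor)
        labels = [f"{sp}_st{j + 1}" for j in range(params.n_strains_per_species)]
        tree = _yule_tree(params.n_strains_per_species, labels,
                          np.random.default_rng(int(rng.integers(2**31))))
        tree = _scale_tree(tree, params.within_species_divergence)
        truth.strain_trees[sp] = tree

        # preorder walk: clonal sequence per node, imports per edge
        node_seq = {tree.seed_node: ancestor}
        node_imports: dict = {tree.seed_node: []}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent = node.parent_node
            seq = _mutate(node_seq[parent], node.edge.length or 0.0, rng)
            imports = list(node_imports[parent])
            for _ in range(rng.poisson(params.recomb_rate_per_branch)):
                tlen = int(rng.geometric(1.0 / params.mean_tract_length))
                start = int(rng.integers(0, L))
                end = min(start + tlen, L)
                donor = _mutate(node_seq[parent][start:end],
                                params.tract_divergence, rng)
                imports.append((start, end, donor))
            node_seq[node] = seq
            node_imports[node] = imports

        for leaf in tree.leaf_node_iter():
            name = leaf.taxon.label
            clonal = node_seq[leaf]
            truth.clonal_genomes[name] = arr_to_seq(clonal)
            truth.species_of[name] = sp
            final = clonal.copy()
            for start, end, donor in node_imports[leaf]:
                final[start:end] = donor
                truth.recomb_tracts.append((name, start, end))
            diff = np.nonzero(final != ancestor)[0]
            for pos in diff:
                truth.mutations.append((name, int(pos), BASES[ancestor[pos]],
                                        BASES[final[pos]]))
            genomes[name] = arr_to_seq(final)

    return genomes, truth


def transfer_tract(genomes: dict[str, str], truth: SimTruth, donor: str,
                   recipient: str, start: int, end: int) -> dict[str, str]:
    """Overwrite recipient[start:end) with donor's sequence (host-to-host
    homologous recombination); the event is appended to the truth tracts.

    Returns an updated genome dict; the input dict is not modified.
    """
    if not 0 <= start < end <= len(genomes[recipient]):
        raise ValueError(f"tract [{start}, {end}) out of genome bounds")
    out = dict(genomes)
    out[recipient] = (genomes[recipient][:start] + genomes[donor][start:end]
                      + genomes[recipient][end:])
    truth.recomb_tracts.append((recipient, start, end))
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _draw_fragment_lengths(rng, params: SimParams, target_bases: float) -> np.ndarray:
    """Log-normal lengths truncated (by rejection) at min_fragment_length,
    drawn until their sum reaches target_bases."""
    sigma = params.fragment_length_sigma
    mu = math.log(params.mean_fragment_length) - sigma**2 / 2
    lengths: list[np.ndarray] = []
    total = 0.0
    while total < target_bases:
        batch = np.round(rng.lognormal(mu, sigma, size=2048)).astype(int)
        batch = batch[batch >= params.min_fragment_length]
        batch = np.minimum(batch, params.genome_length)
        lengths.append(batch)
        total += batch.sum()
    arr = np.concatenate(lengths)
    cut = int(np.searchsorted(np.cumsum(arr), target_bases)) + 1
    return arr[:cut]


def simulate_reads(genomes: dict[str, str], truth: SimTruth, params: SimParams
                   ) -> tuple[list[tuple[str, str]], list[ReadAlignment]]:
    """Shear each genome into damaged short reads with true placements.

    Fragments are drawn log-normally (truncated at ``min_fragment_length``)
    to a total of ``depth_per_strain x genome_length`` bases per strain.
    C->T damage is applied at 5' position p (1-based, read orientation) with
    probability ``damage_rate_5p * exp(-damage_decay * (p - 1))``, and G->A
    symmetrically from the 3' end; uniform sequencing error follows.
    Alignments are the true placements — no aligner is run. Reads from the
    reverse strand are emitted reverse-complemented, with damage applied in
    read orientation.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 1])
    reads: list[tuple[str, str]] = []
    alignments: list[ReadAlignment] = []
    C, G, T, A = 1, 2, 3, 0
    maxlen = 4096
    decay_tab = params.damage_rate_5p * np.exp(
        -params.damage_decay * np.arange(maxlen))

    for strain in sorted(genomes):
        garr = seq_to_arr(genomes[strain])
        L = garr.size
        lengths = _draw_fragment_lengths(rng, params,
                                         params.depth_per_strain * L)
        starts = rng.integers(0, np.maximum(L - lengths + 1, 1))
        strands = rng.random(lengths.size) < 0.5
        for k in range(lengths.size):
            ln, s = int(lengths[k]), int(starts[k])
            frag = garr[s:s + ln]
            minus = bool(strands[k])
            read = seq_to_arr(revcomp(arr_to_seq(frag))) if minus else frag.copy()
            # deamination in read orientation
            damaged: list[int] = []
            p5 = decay_tab[:ln]
            p3 = p5[::-1]
            u = rng.random(ln)
            hit5 = (read == C) & (u < p5)
            u2 = rng.random(ln)
            hit3 = (read == G) & (~hit5) & (u2 < p3)
            read = read.copy()
            read[hit5] = T
            read[hit3] = A
            damaged = np.nonzero(hit5 | hit3)[0].tolist()
            if params.seq_error > 0:
                err = rng.random(ln) < params.seq_error
                n_err = int(err.sum())
                if n_err:
                    read[err] = (read[err] + rng.integers(1, 4, n_err).astype(
                        np.uint8)) % 4
            read_id = f"{strain}_r{k}"
            read_seq = arr_to_seq(read)
            reads.append((read_id, read_seq))
            stored = seq_to_arr(revcomp(read_seq)) if minus else read
            pairs = [(i, s + i, BASES[stored[i]], BASES[garr[s + i]])
                     for i in range(ln)]
            alignments.append(ReadAlignment(read_id, strain, s,
                                            "-" if minus else "+", 60, pairs))
            truth.read_truth.append((read_id, strain, s, s + ln,
                                     "-" if minus else "+", tuple(damaged)))
    return reads, alignments


# ---------------------------------------------------------------------------
# Gene-family simulation (pangenome fixture)
# ---------------------------------------------------------------------------

def simulate_gene_families(n_families: int, occupancy: dict[str, float | list],
                           seed: int, n_genomes_per_species: int = 10,
                           species_divergence: float = 0.03,
                           copy_divergence: float = 0.02,
                           length_range: tuple[int, int] = (300, 900)):
    """Simulate gene families with per-species occupancy probabilities.

    ``occupancy`` maps each species to either one fraction (all families) or
    a sequence of per-family fractions. Each carried copy is the family
    sequence mutated at the species level then per genome. Returns
    ``(gene_sequences, truth_matrix)`` where gene_sequences is a list of
    (genome_id, gene_id, sequence) and truth_matrix a
    :class:`~paleostrain.pangenome.PresenceAbsenceMatrix` of true carriage.
    """
    from .pangenome import PresenceAbsenceMatrix
    import pandas as pd

    rng = np.random.default_rng([seed, 2])
    occ = {}
    for sp, val in occupancy.items():
        vec = np.full(n_families, float(val)) if np.isscalar(val) \
            else np.asarray(val, dtype=float)
        if vec.size != n_families:
            raise SimulationParameterError(
                "occupancy", f"{sp}: expected {n_families} fractions, got {vec.size}")
        if ((vec < 0) | (vec > 1)).any():
            raise SimulationParameterError("occupancy", f"{sp}: fractions must be in [0, 1]")
        occ[sp] = vec

    genome_ids = [f"{sp}_g{j + 1}" for sp in occ for j in range(n_genomes_per_species)]
    species_labels = {g: g.rsplit("_g", 1)[0] for g in genome_ids}
    presence = pd.DataFrame(False, index=[f"fam{i + 1}" for i in range(n_families)],
                            columns=genome_ids)
    gene_sequences: list[tuple[str, str, str]] = []

    for i in range(n_families):
        fam = f"fam{i + 1}"
        flen = int(rng.integers(length_range[0], length_range[1] + 1))
        root = rng.choice(4, size=flen).astype(np.uint8)
        for sp, vec in occ.items():
            sp_copy = _mutate(root, species_divergence, rng)
            carried = rng.random(n_genomes_per_species) < vec[i]
            for j in range(n_genomes_per_species):
                if carried[j]:
                    gid = f"{sp}_g{j + 1}"
                    copy = _mutate(sp_copy, copy_divergence, rng)
                    gene_sequences.append((gid, f"{gid}|{fam}", arr_to_seq(copy)))
                    presence.loc[fam, gid] = True

    truth = PresenceAbsenceMatrix(presence, species_labels)
    return gene_sequences, truth
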