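"""End-to-end orchestration: simulate -> authenticate -> consensus ->
screen -> MSA -> recombination-masked phylogeny -> ANI -> pangenome,
with every intermediate persisted and a parameter-recovery report.

Each simulated strain plays the role of one ancient sample: its reads are
placed (truthfully) on its own genome for damage profiling, then re-anchored
onto the species reference for consensus reconstruction — the strains of one
species are colinear with their reference, mirroring the reference-based
draft-genome step of strain-level palaeogenomics. Samples failing the
breadth screen are excluded from the alignment, and the per-species
phylogeny is built with the iterative recombination-masking loop.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import yaml
from sklearn.metrics import adjusted_rand_score

from . import ani as ani_mod
from . import io as pio
from .consensus import (ConsensusGenome, build_pileup, breadth_of_coverage,
                        call_consensus, detect_presence)
from .damage import authenticate, misincorporation_profile
from .msa import RefAnchoredMSA, clean_msa, write_msa_fasta
from .pangenome import (concatenate_core_alignment, cluster_genes, core_genes,
                        presence_absence, species_specific_genes)
from .phylo import (bootstrap_support, iterative_mask_phylogeny, rf_distance,
                    tracts_to_rows)
from .simulate import (SimParams, simulate_gene_families, simulate_reads,
                       simulate_strain_set)

log = logging.getLogger("paleostrain")


@dataclass
class PipelineConfig:
    """Every stage threshold, with the reference-based defaults.

    Unknown keys are rejected on load; the effective configuration is
    echoed into each run's log and summary.
    """

    sim: SimParams = field(default_factory=SimParams)
    # read/site gates for consensus reconstruction
    min_mapping_quality: int = 30
    min_aligned_length: int = 30
    min_read_identity: float = 0.97
    min_depth: int = 3
    min_dominant_freq: float = 0.80
    # sample screen
    breadth_threshold: float = 0.50
    # damage authentication
    damage_window: int = 25
    min_terminal_rate: float = 0.05
    min_fold_over_baseline: float = 2.0
    # contig-hit filters
    hit_min_length: int = 500
    hit_min_identity: float = 0.95
    # MSA cleaning
    max_row_gap_frac: float = 0.50
    max_col_missing_frac: float = 0.10
    # phylogeny / recombination
    n_bootstrap: int = 100
    recomb_window: int = 1000
    recomb_step: int = 100
    recomb_alpha: float = 0.05
    max_mask_iter: int = 20
    # ANI / delimitation
    ani_fragment_length: int = 1000
    ani_max_intra_distance: float = 0.05
    # pangenome
    cluster_identity: float = 0.85
    core_frac: float = 0.90
    specific_frac: float = 0.90
    n_core_families: int = 40
    n_specific_families_per_species: int = 5
    gene_genomes_per_species: int = 6
    # sample subset (None = all simulated strains)
    samples: list | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        known_sim = {f.name for f in dataclasses.fields(SimParams)}
        unknown = set(sim) - known_sim
        if unknown:
            raise ValueError(f"unknown sim keys: {sorted(unknown)}")
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=SimParams(**sim), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def demo_config(seed: int = 0) -> PipelineConfig:
    """The bundled demonstration: 3 species x 4 strains at palaeo-realistic
    divergences, short damaged reads at 20x, one deliberate host-to-host
    recombination import."""
    return PipelineConfig(sim=SimParams(
        genome_length=30_000, n_species=3, n_strains_per_species=4,
        between_species_divergence=0.075, within_species_divergence=0.005,
        mean_fragment_length=60.0, depth_per_strain=20.0,
        damage_rate_5p=0.30, damage_decay=0.5, seq_error=0.001, seed=seed))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, sample: str | None, message: str):
        self.stage, self.sample = stage, sample
        where = f"stage '{stage}'" + (f", sample '{sample}'" if sample else "")
        super().__init__(f"{where}: {message}")


def _write_truth(truth, run_dir: Path) -> None:
    tdir = run_dir / "truth"
    tdir.mkdir(exist_ok=True)
    pio.write_fasta(truth.clonal_genomes, tdir / "clonal_genomes.fasta")
    pio.write_fasta(truth.species_ancestors, tdir / "species_ancestors.fasta")
    for sp, tree in truth.strain_trees.items():
        pio.write_newick(tree, tdir / f"strain_tree_{sp}.nwk")
    pio.write_tsv([{"strain": s, "species": sp}
                   for s, sp in truth.species_of.items()],
                  tdir / "species_of.tsv", ["strain", "species"])
    pio.write_tsv([{"strain": s, "start": a, "end": b}
                   for s, a, b in truth.recomb_tracts],
                  tdir / "recomb_tracts.tsv", ["strain", "start", "end"])


def run_strain_pipeline(config: PipelineConfig, run_dir) -> Path:
    """Execute all stages; returns the run directory.

    Reruns with the same config reproduce all summaries (all randomness
    flows from the master seed in ``config.sim.seed``).
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    config.to_yaml(run_dir / "effective_config.yaml")
    log.info("effective config: %s", json.dumps(config.to_dict()))
    summary: dict = {"config": config.to_dict()}

    # --- simulate ---------------------------------------------------------
    genomes, truth = simulate_strain_set(config.sim)
    samples = config.samples if config.samples is not None else sorted(genomes)
    if not samples:
        raise PipelineError("simulate", None, "empty sample list")
    bad = set(samples) - set(genomes)
    if bad:
        raise PipelineError("simulate", sorted(bad)[0], "unknown sample id")
    pio.write_fasta(genomes, run_dir / "strain_genomes.fasta")
    _write_truth(truth, run_dir)
    reads, alignments = simulate_reads(genomes, truth, config.sim)
    by_sample: dict[str, list] = {s: [] for s in genomes}
    for aln in alignments:
        by_sample[aln.ref_id].append(aln)
    pio.write_fastq(reads, run_dir / "reads.fastq")

    # --- damage authentication -------------------------------------------
    auth_results = {}
    for s in samples:
        profile = misincorporation_profile(by_sample[s], config.damage_window)
        report = authenticate(profile, config.min_terminal_rate,
                              config.min_fold_over_baseline)
        pio.write_tsv(profile.to_rows(), run_dir / f"damage_{s}.tsv",
                      ["position", "ct_5p", "n_obs_5p", "ga_3p", "n_obs_3p"])
        (run_dir / f"auth_{s}.json").write_text(report.to_json())
        auth_results[s] = {"authentic": report.authentic,
                           "terminal_ct_5p": report.terminal_ct}
    summary["authentication"] = auth_results

    # --- consensus + breadth screen --------------------------------------
    species_names = sorted(set(truth.species_of.values()))
    consensus: dict[str, ConsensusGenome] = {}
    screen_rows = []
    retained: dict[str, list[str]] = {sp: [] for sp in species_names}
    for s in samples:
        sp = truth.species_of[s]
        ref = truth.species_ancestors[sp]
        alns = [a.reanchor(ref) for a in by_sample[s]]
        pileup = build_pileup(alns, ref, ref_id=s,
                              min_mq=config.min_mapping_quality,
                              min_len=config.min_aligned_length,
                              min_identity=config.min_read_identity)
        cons = call_consensus(pileup, config.min_depth, config.min_dominant_freq)
        breadth = breadth_of_coverage(pileup, config.min_depth)
        present = detect_presence(breadth, config.breadth_threshold)
        consensus[s] = cons
        if present:
            retained[sp].append(s)
        screen_rows.append({"sample": s, "species": sp,
                            "breadth": f"{breadth:.4f}",
                            "retained": present})
    pio.write_fasta({s: c.sequence for s, c in consensus.items()},
                    run_dir / "consensus_genomes.fasta")
    pio.write_tsv(screen_rows, run_dir / "breadth_screen.tsv",
                  ["sample", "species", "breadth", "retained"])
    summary["screen"] = {r["sample"]: r["retained"] for r in screen_rows}

    # --- MSA + recombination-masked phylogeny per species -----------------
    trees = {}
    summary["phylogeny"] = {}
    for sp in species_names:
        kept = retained[sp]
        if len(kept) < 2:
            log.info("species %s: %d retained samples, skipping phylogeny",
                     sp, len(kept))
            continue
        ref = truth.species_ancestors[sp]
        rows = {f"ref_{sp}": ref}
        rows.update({s: consensus[s].sequence for s in kept})
        msa = RefAnchoredMSA(sp, rows)
        cleaned = clean_msa(msa, config.max_row_gap_frac,
                            config.max_col_missing_frac, mode="strain")
        write_msa_fasta(cleaned, run_dir / f"msa_{sp}.fasta",
                        run_dir / f"msa_{sp}_coords.tsv")
        from functools import partial
        from .phylo import detect_recombination
        detector = partial(detect_recombination, window=config.recomb_window,
                           step=config.recomb_step, alpha=config.recomb_alpha)
        result = iterative_mask_phylogeny(cleaned, detector=detector,
                                          max_iter=config.max_mask_iter)
        tract_rows = []
        for it, tl in enumerate(result.tract_history, 1):
            tract_rows.extend(tracts_to_rows(tl, it))
        pio.write_tsv(tract_rows, run_dir / f"recomb_tracts_{sp}.tsv",
                      ["row_id", "start", "end", "score", "iteration"])
        tree = bootstrap_support(result.msa, config.n_bootstrap,
                                 seed=config.sim.seed + 1)
        trees[sp] = tree
        pio.write_newick(tree, run_dir / f"tree_{sp}.nwk")
        summary["phylogeny"][sp] = {
            "iterations": result.iterations, "status": result.status,
            "masked_cells": result.masked_cells,
            "n_rows": len(cleaned.rows), "n_columns": cleaned.length}

    # --- ANI species delimitation (on the strain genomes / MAG analogs) --
    mat = ani_mod.ani_matrix(genomes, config.ani_fragment_length)
    dframe = mat.distance_frame()
    dframe.to_csv(run_dir / "ani_distance.tsv", sep="\t")
    clusters = ani_mod.delimit_species(dframe, config.ani_max_intra_distance)
    pio.write_tsv([{"genome": g, "cluster": k}
                   for k, cl in enumerate(clusters) for g in sorted(cl)],
                  run_dir / "ani_clusters.tsv", ["genome", "cluster"])
    summary["ani"] = {"n_clusters": len(clusters)}

    # --- pangenome --------------------------------------------------------
    n_spec = config.n_specific_families_per_species
    n_fam = config.n_core_families + n_spec * len(species_names)
    occupancy = {}
    for k, sp in enumerate(species_names):
        occ = np.full(n_fam, 0.97)
        for j, _ in enumerate(species_names):
            lo = config.n_core_families + j * n_spec
            occ[lo:lo + n_spec] = 1.0 if j == k else 0.0
        occupancy[sp] = occ
    gene_seqs, truth_matrix = simulate_gene_families(
        n_fam, occupancy, seed=config.sim.seed,
        n_genomes_per_species=config.gene_genomes_per_species)
    gclusters = cluster_genes(gene_seqs, config.cluster_identity)
    pam = presence_absence(gclusters, truth_matrix.species,
                           truth_matrix.genome_ids)
    pam.to_csv(run_dir / "gene_presence_absence.csv")
    core = core_genes(pam, config.core_frac)
    specific = species_specific_genes(pam, config.specific_frac)
    core_aln = concatenate_core_alignment(gclusters, core, pam.genome_ids)
    pio.write_fasta(core_aln.rows, run_dir / "core_alignment.fasta")
    pio.write_tsv([{"cluster": c.cluster_id, "genome": g, "gene": gid}
                   for c in gclusters for g, gid, _ in c.members],
                  run_dir / "gene_cluster_members.tsv",
                  ["cluster", "genome", "gene"])
    pio.write_tsv([{"species": sp, "cluster": c}
                   for sp, cl in specific.items() for c in cl],
                  run_dir / "species_specific_genes.tsv", ["species", "cluster"])
    truth_matrix.presence.astype(int).to_csv(run_dir / "truth" / "gene_presence.csv")
    summary["pangenome"] = {"n_clusters": len(gclusters),
                            "n_core": len(core),
                            "core_alignment_length": core_aln.length,
                            "n_specific": {sp: len(v) for sp, v in specific.items()}}

    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return run_dir


def recovery_report(run_dir, truth=None) -> dict:
    """Score a persisted run against its simulation truth.

    Tabulates per-sample consensus error, damage-parameter recovery,
    per-species tree topology accuracy (Robinson-Foulds), ANI
    species-cluster agreement (adjusted Rand) and pangenome cluster purity.
    Everything is read back from the run directory; an explicit ``truth``
    overrides the recorded species labels and strain trees.
    """
    run_dir = Path(run_dir)
    if not (run_dir / "summary.json").exists():
        raise ValueError(f"{run_dir} does not contain a completed pipeline run")
    report: dict = {}
    genomes = pio.read_fasta(run_dir / "strain_genomes.fasta")
    if truth is not None:
        species_of = dict(truth.species_of)
        strain_trees = truth.strain_trees
        if set(genomes) != set(species_of):
            raise ValueError("truth does not match the recorded run")
    else:
        species_of = {r["strain"]: r["species"]
                      for r in pio.read_tsv(run_dir / "truth" / "species_of.tsv")}
        strain_trees = {}
        for p in sorted(run_dir.glob("truth/strain_tree_*.nwk")):
            sp = p.stem.replace("strain_tree_", "")
            strain_trees[sp] = dendropy.Tree.get(path=str(p), schema="newick", preserve_underscores=True)

    # consensus error: mismatches at non-gap sites vs the true strain genome
    consensus = pio.read_fasta(run_dir / "consensus_genomes.fasta")
    cons_err = {}
    for s, cseq in consensus.items():
        true_arr = np.frombuffer(genomes[s].encode(), dtype=np.uint8)
        cons_arr = np.frombuffer(cseq.encode(), dtype=np.uint8)
        called = cons_arr != ord("-")
        n_called = int(called.sum())
        n_err = int((cons_arr[called] != true_arr[called]).sum())
        cons_err[s] = {"sites_called": n_called,
                       "error_rate": n_err / n_called if n_called else None}
    report["consensus"] = cons_err
    rates = [v["error_rate"] for v in cons_err.values() if v["error_rate"] is not None]
    report["consensus_error_rate_mean"] = float(np.mean(rates)) if rates else None

    # damage recovery: terminal C->T estimates vs the simulated rate
    config = PipelineConfig.from_yaml(run_dir / "effective_config.yaml")
    term = []
    for p in sorted(run_dir.glob("auth_*.json")):
        d = json.loads(p.read_text())
        if d.get("terminal_ct_5p") is not None:
            term.append(d["terminal_ct_5p"])
    report["damage"] = {"true_rate": config.sim.damage_rate_5p,
                        "terminal_ct_5p_mean": float(np.mean(term)) if term else None}

    # tree accuracy per species (reference row pruned before comparison)
    rf = {}
    for p in sorted(run_dir.glob("tree_*.nwk")):
        sp = p.stem.replace("tree_", "")
        tree = dendropy.Tree.get(path=str(p), schema="newick", preserve_underscores=True)
        taxon = tree.taxon_namespace.get_taxon(f"ref_{sp}")
        if taxon is not None:
            tree.prune_taxa([taxon])
        true_tree = strain_trees[sp]
        est_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        true_leaves = {lf.taxon.label for lf in true_tree.leaf_node_iter()}
        if est_leaves != true_leaves:
            true_tree = true_tree.clone(depth=1)
            true_tree.prune_taxa([tx for tx in true_tree.taxon_namespace
                                  if tx.label not in est_leaves])
        rf[sp] = rf_distance(tree, true_tree)
    report["tree_rf"] = rf

    # species delimitation agreement
    rows = pio.read_tsv(run_dir / "ani_clusters.tsv")
    label_of = {r["genome"]: int(r["cluster"]) for r in rows}
    ids = sorted(label_of)
    report["species_ari"] = float(adjusted_rand_score(
        [species_of[g] for g in ids], [label_of[g] for g in ids]))
    report["n_species_clusters"] = len(set(label_of.values()))

    # pangenome: cluster purity vs truth families (gene ids carry families)
    members: dict[str, set[str]] = {}
    for r in pio.read_tsv(run_dir / "gene_cluster_members.tsv"):
        members.setdefault(r["cluster"], set()).add(r["gene"].split("|")[1])
    total = len(members)
    pure = sum(1 for fams in members.values() if len(fams) == 1)
    spec_rows = pio.read_tsv(run_dir / "species_specific_genes.tsv")
    spec_counts: dict[str, int] = {}
    for r in spec_rows:
        spec_counts[r["species"]] = spec_counts.get(r["species"], 0) + 1
    report["pangenome"] = {"n_clusters": total,
                           "cluster_purity": pure / total if total else None,
                           "specific_counts": spec_counts}

    (run_dir / "recovery_report.json").write_text(
        json.dumps(report, indent=2, default=str))
    return report
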