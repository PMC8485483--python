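# Methods

This note documents the models behind `paleostrain`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and the
numerical conventions that matter when reading results.

## Coordinate and boundary conventions

All coordinates are 0-based half-open internally; FASTQ/SAM/Newick emission
converts at the boundary. Every filter in the consensus stage is stated as a
strict "below" gap condition, so **equality at a threshold always passes**:
a read with mapping quality exactly 30, aligned length exactly 30 nt or
identity exactly 0.97 is used, and a site with depth exactly 3 or dominant
allele frequency exactly 0.80 is called. The breadth screen is likewise
inclusive (breadth exactly 0.50 counts as present). One deliberate
asymmetry: the core-gene rule is strict (present in *more than* 90% of
genomes) while the species-specific rule is inclusive (present in *at
least* 90% of one species' genomes); both are configurable
(`core_frac`, `specific_frac`).

A pileup site with two alleles at equal maximal count has no dominant
allele and is gapped. Ambiguity codes are excluded from damage and pileup
tallies on both sides of the pairing. `'-'` and `'N'` both count as missing
during MSA cleaning; only `'-'` is emitted internally.

## The simulator

**Genealogy.** Each species receives an ultrametric pure-birth (Yule) strain
tree sampled crown-first: the root is the most recent common ancestor, split
times use Exp(k) waiting times while k lineages are extant, plus a final
Exp(n) stretch so no tip edge is degenerate; depths are rescaled to 1 and
then multiplied by `within_species_divergence`. Both divergence parameters
are therefore **per-lineage** expectations: two strains of one species are
separated by at most 2 × `within_species_divergence` substitutions/site
(exactly 2× for a two-strain tree; less on average for larger trees, where
pairs coalesce below the root), and two species ancestors by
2 × `between_species_divergence` around a star species tree.

**Substitutions.** A Jukes–Cantor event process: the number of events on a
branch of length *t* over a genome of length *L* is Poisson(*tL*); each
event moves a uniform site to a uniform different base. Multiple hits
compose, so the observed mismatch fraction between two sequences at total
path distance *d* follows the closed form 3/4·(1 − e^(−4d/3)) — the
quantity the distance estimator later inverts.

**Recombination.** Each strain-tree branch acquires Poisson(`recomb_rate_
per_branch`) imports; an import overwrites a geometric-length tract (mean
`mean_tract_length`) with a copy of the local clonal frame mutated at
`tract_divergence`. This mirrors the import-from-outside parameterization
(R/θ, δ, ν) of clonal-frame analysis rather than host-to-host transfer.
Imports fixed on an internal branch are inherited by all descendant leaves
as written; substitutions accumulating below the import branch do not
further modify the tract, an approximation that is second-order
(within-divergence × tract divergence) in the regimes simulated.
`transfer_tract` additionally supports explicit host-to-host copies, used to
construct imports that demonstrably distort tree topology (an external
donor equidistant from all taxa inflates one taxon's distances roughly
uniformly, which neighbor joining absorbs into a terminal branch; only a
donor *inside* the alignment pulls the recipient's placement).

**Reads.** Fragment lengths are log-normal (σ = 0.35 by default, mean
`mean_fragment_length`) truncated by rejection at `min_fragment_length`
(floor 30 nt by default; 25 is the hard minimum accepted, matching the
shortest fragments such studies retain). Batches are drawn until the target
of `depth_per_strain × genome_length` bases is reached, so the emitted read
count is depth·L / (mean emitted length) by construction. Placements are
uniform on the linear genome and recorded as the truth — no aligner runs —
which leaves the two genome ends underscovered within about one fragment
length; coverage at an interior site is approximately Poisson(depth).
Consequence: at 10× nominal depth a fraction ~P(Poisson(10) < 3) ≈ 0.3% of
interior sites plus the genome margins fall below the 3× site filter, so
breadth is slightly below 1 even for perfect data. Tests assert breadth
against the truth-coverage value rather than an unattainable 1.0.

**Damage.** Deamination is applied in read orientation: a reference C at
5′ position *p* (1-based) is read as T with probability
`damage_rate_5p · e^(−damage_decay·(p−1))`; reference G near the 3′ end is
read as A with the mirrored profile. Defaults 0.3 / 0.5 are conventional
magnitudes for well-preserved ancient samples (terminal rates of tens of
percent decaying within ~10 positions); they are inputs, not fitted values.
Uniform sequencing error (default 10⁻³) follows damage. Reverse-strand
reads are emitted reverse-complemented with damage applied in read
orientation, matching the physical chemistry.

**Gene families.** `simulate_gene_families` draws a root sequence per
family (length uniform in 300–900 bp), a species-level copy at 3%
divergence, and per-genome copies at 2% divergence carried with the
species' occupancy probability. The genome count per species (default 10)
and divergences are parameters because the occupancy contract alone does
not fix them.

**Determinism.** All randomness flows from `SimParams.seed` through
deterministic child streams (strain set, reads, gene families), so
identical parameters reproduce byte-identical FASTQ/FASTA/truth output.

## Damage authentication

The profile is a frequency table, not a model fit: ct_5p[p] is the fraction
of reference-C opportunities at read position p read as T (ga_3p mirrored),
with the interior baseline pooled over positions more than `window`
(default 25) from both ends. A rate is defined only where opportunities
exist; a position with no reference C has an undefined (NaN) rate rather
than zero. The decision rule — terminal rate ≥ `min_terminal_rate` (0.05)
AND ≥ `min_fold_over_baseline` (2.0) × baseline, applied to the 3′ G→A
profile as well when 3′ observations exist — is a deliberately simple,
configurable stand-in for the visual inspection of damage plots; no
community-standard numeric cutoff exists, and the report echoes every
quantity so the call can be re-made under other thresholds. A profile with
zero terminal observations returns an "insufficient data" outcome
(`authentic=None`).

## Consensus reconstruction

Read identity is matches over aligned columns with gap columns counted as
mismatches; insertions relative to the reference never write into the
consensus (reference-coordinate model), and indel calling is out of scope.
The same depth rule (≥ 3) serves both the site filter and the breadth
screen: the two thresholds are printed inconsistently in common usage
("below 3" vs "above 3×"), and unifying them at ≥ 3 keeps detection and
consensus consistent; both are configurable.

## Local hits and the reference-anchored MSA

The built-in aligner is a desk-scale surrogate for BLASTn-style search:
exact 9-mer seeding on both strands, chaining of seeds on a diagonal (gaps
up to 200 bp between seeds), and ungapped X-drop extension. It is exact for
the colinear substitution-only genomes the simulator produces and for ANI
fragments at the divergences of interest; it does not model indels or
rearrangements. Externally produced hits can be substituted through a
tabular format carrying the two gapped aligned sequences
(`read_hits_tsv`), making the aligner replaceable without touching the
projection or cleaning stages.

Projection resolves per-query overlaps by higher identity, then longer hit,
then leftmost start. Cleaning order in strain mode is fixed: rows first
(> 50% gaps), then columns (> 10% missing computed over surviving rows),
each rule applied exactly once; genus mode applies the column rule only.

## Phylogeny and recombination masking

Distances are Jukes–Cantor with pairwise deletion; a pair at observed
mismatch fraction ≥ 3/4 is reported as saturated (infinite distance) and
blocks tree building explicitly rather than silently. Neighbor joining uses
the standard Q-criterion with two determinism guarantees: ties are broken
by the lexicographically smallest pair of cluster ids (a cluster is named
by its smallest leaf), and negative branch lengths are clamped to zero with
the deficit moved to the sister branch. Bootstrap support is the percentage
of column-resampled replicates containing each internal bipartition of the
point tree.

Maximum-likelihood tree building is deliberately **not** reimplemented: the
loop structure is the contribution here, and `external_tree_builder` lets
any aligned-FASTA→Newick program (FastTree, RAxML) stand in for the NJ
surrogate; the recombination detector is likewise replaceable by any
callable returning tracts.

The built-in detector scans, per row, windows (default 1000 columns, step
100) of substitutions against the column-majority base (ties A<C<G<T).
A window is flagged when its count is Poisson-improbable under the row's
own mean substitution density, Bonferroni-corrected across the row's
windows at `alpha` (0.05); flagged windows merge into tracts. Because the
row's density estimate includes any true import, the test is conservative;
on clonal data the family-wise false-positive rate per row stays below
alpha (verified over 100 replicates). The masking loop replaces detected
tracts with gaps and rebuilds until the detector returns nothing; masked
cells strictly accumulate, so the loop terminates, and a detector that
keeps reporting already-masked tracts yields a "stalled" status rather than
an infinite loop; reaching `max_iter` yields a "max_iter" warning status,
never an exception.

## ANI and species delimitation

ANI is estimated by fragment decomposition: the query is cut into
consecutive 1000-bp fragments, each fragment takes the identity of its best
local hit on the subject, and ANI is the mean over retained fragments. A
fragment is retained only if its best hit aligns ≥ 200 columns
(`min_fragment_aligned`) and reaches identity ≥ 0.30: without the length
floor, chance ~15-bp exact word matches between unrelated genomes would
contribute identity-1.0 fragments and spuriously merge unrelated genomes.
Under this rule unrelated random sequences yield no retained fragments
("no alignment"), which is also what makes such genomes singletons in
clustering. ANI is direction-dependent; both directions are computed and
clustering uses 1 − mean of the two. Species are single-linkage clusters
cut **strictly below** 0.05 distance — a pair at exactly 5% is not merged —
matching the operational ~95% ANI species boundary. Bit-compatibility with
MUMmer-based ANI tools is not claimed; correctness is established as
parameter recovery against simulated divergences (e.g. 2% simulated
divergence → ANI 0.980 ± 0.002).

## Pangenome rules

Greedy centroid clustering processes genes by decreasing length (ties by
genome then gene id, making the partition deterministic); a gene joins the
first centroid reaching the identity threshold, else founds a cluster.
Identity is matches over end-to-end alignment columns with end gaps
penalized, computed from an edit-distance-optimal alignment; a length-ratio
bound and a 9-mer containment screen skip hopeless alignments without
affecting the result at the thresholds used (members within 15% of a
centroid share far more 9-mers than the 5% screen requires). Paralog
splitting and synteny-aware refinement of full pangenome pipelines are not
reproduced. The core alignment is built per cluster by center-star
alignment around the centroid (members aligned pairwise to the centroid,
insertion columns merged by maximum length); genomes missing a cluster
contribute all-gap blocks, and blocks concatenate in sorted cluster-id
order with reported boundaries.

## Pipeline and the demonstration scale

The demo simulates 3 species × 4 strains on 30-kb genomes at 20× coverage
of ~60-nt reads. These sizes were chosen so the full chain — including
50,000-read damage recovery and 100-replicate analyses — runs in minutes on
one CPU while every recovery statistic (consensus error, tree topology, ANI
clustering, pangenome rules) is measured at sample sizes where failure
would be detectable, not absorbed by noise. Genome length is well above
10 × the mean recombination tract so imports are resolvable; 20× nominal
coverage leaves post-filter depth comfortably above the 3× site gate even
though terminal damage pushes some reads below the 97% identity gate.
Each simulated strain plays the role of one single-strain sample; reads are
profiled for damage against their own genome and re-anchored onto the
species ancestor (the colinear "reference genome") for consensus calling.

## What passing tests do and do not show

The simulator produces colinear genomes whose differences are point
substitutions, recombination imports and deamination — no indels, no
rearrangements, no gene gain/loss within the aligned genomes, no
contamination mixtures, no within-sample strain mixtures, and uniform
(Poisson) coverage rather than the strongly uneven coverage of real ancient
samples. Passing recovery tests therefore validates the logic and the
threshold semantics of each stage, and the stages' composition — not
robustness to mapping artifacts, mixed infections or reference bias, which
require real data and a real aligner upstream. The reference-anchored model
cannot see rearrangements or sequence absent from the reference by
construction.

## Known limitations

* The NJ/JC surrogate ignores rate heterogeneity and unequal base
  frequencies; for published-quality trees an external ML builder should be
  plugged in through the adapter.
* The recombination detector finds clustered substitutions relative to the
  column majority; imports shared by a majority of rows, or imports in
  alignments dominated by deep between-clade divergence, are outside its
  design envelope (detection is intended within near-clonal sets, as in the
  per-species stage of the pipeline).
* ANI fragments are fixed-length and ungapped; genomes with substantial
  indel divergence would be underestimated.
* The damage model is unstranded beyond the 5′/3′ mirroring and does not
  emulate partial repair (UDG treatment) or quality-score effects.
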