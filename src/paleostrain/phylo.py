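"""Distance phylogeny with bootstrap support and iterative recombination masking.

The tree builder is neighbor joining on Jukes-Cantor distances with
pairwise deletion — a deliberate surrogate for maximum-likelihood builders,
whose internals are not this package's concern; the adapter
:func:`external_tree_builder` lets any program that maps an aligned FASTA to
a Newick tree (e.g. FastTree, RAxML) stand in bit-compatibly. Likewise the
built-in recombination detector is a windowed clustered-substitution scan
(imports show up as windows whose substitution count against the column-wise
majority far exceeds the row's background density); any callable emitting
tracts can replace it.

The masking loop mirrors the standard iterative procedure: detect tracts,
replace them with gaps, rebuild the tree, and repeat until no further
recombination is detected. Masked cells strictly accumulate, which bounds
the number of iterations.
"""

from __future__ import annotations

import math
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.stats import poisson

ACGT = frozenset(b"ACGT")


class SaturatedDistanceError(ValueError):
    """A pairwise mismatch fraction at or beyond the Jukes-Cantor limit."""


@dataclass
class DistanceMatrix:
    """Pairwise evolutionary distances (substitutions/site)."""

    ids: list[str]
    matrix: np.ndarray
    pairwise_sites: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {(a, b): float(self.matrix[i, j])
                for i, a in enumerate(self.ids)
                for j, b in enumerate(self.ids) if i < j}


def _row_matrix(msa):
    ids = list(msa.rows)
    mat = np.frombuffer("".join(msa.rows[i] for i in ids).encode(),
                        dtype=np.uint8).reshape(len(ids), -1)
    return ids, mat


def jc_distance_matrix(msa) -> DistanceMatrix:
    """Jukes-Cantor distances under pairwise deletion.

    p = mismatches / comparable columns (both rows in {A,C,G,T});
    d = -(3/4) ln(1 - 4p/3). A pair with p >= 3/4 is reported as saturated
    (distance inf); a pair with zero comparable columns raises.
    """
    ids, mat = _row_matrix(msa)
    n = len(ids)
    if n < 3:
        raise ValueError("need >= 3 rows for a distance matrix")
    valid = (mat == ord("A")) | (mat == ord("C")) | (mat == ord("G")) | (mat == ord("T"))
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            n_comp = int(comp.sum())
            if n_comp == 0:
                raise ValueError(f"rows '{ids[i]}' and '{ids[j]}' share no "
                                 "comparable columns")
            p = int((mat[i] != mat[j])[comp].sum()) / n_comp
            sites[i, j] = sites[j, i] = n_comp
            if p >= 0.75:
                d[i, j] = d[j, i] = math.inf
                saturated.append((ids[i], ids[j]))
            else:
                d[i, j] = d[j, i] = -0.75 * math.log1p(-4.0 * p / 3.0)
    return DistanceMatrix(ids, d, sites, saturated)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard NJ agglomeration with deterministic tie-breaking.

    Ties in the Q-matrix minimum are broken by the lexicographically
    smallest pair of cluster ids (a cluster's id is its smallest leaf name).
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch. The returned tree is unrooted (trifurcating seed
    node).
    """
    if not np.isfinite(dm.matrix).all():
        raise ValueError("distance matrix contains non-finite entries "
                         f"(saturated pairs: {dm.saturated})")
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("need >= 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(i)) for i in dm.ids]
    canon = list(dm.ids)  # canonical id per active cluster
    D = dm.matrix.astype(float).copy()
    active = list(range(n0))

    def pick_pair():
        m = len(active)
        r = D[np.ix_(active, active)].sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * D[active[ai], active[aj]] - r[ai] - r[aj]
                key = tuple(sorted((canon[active[ai]], canon[active[aj]])))
                if best is None or q < best[0] - 1e-12 or \
                        (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, ai, aj)
        return best[2], best[3]

    while len(active) > 3:
        m = len(active)
        ai, aj = pick_pair()
        i, j = active[ai], active[aj]
        ri = D[i, active].sum()
        rj = D[j, active].sum()
        bi = 0.5 * D[i, j] + (ri - rj) / (2 * (m - 2))
        bj = D[i, j] - bi
        if bi < 0:
            bj, bi = D[i, j], 0.0
        if bj < 0:
            bi, bj = D[i, j], 0.0
        parent = dendropy.Node()
        nodes[i].edge.length = bi
        nodes[j].edge.length = bj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances to the new cluster (reuse slot i)
        for k in active:
            if k not in (i, j):
                D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[i] = parent
        canon[i] = min(canon[i], canon[j])
        active.remove(j)

    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.edge.length = max(ln, 0.0)
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def build_nj_tree(msa) -> dendropy.Tree:
    """Default builder: NJ on Jukes-Cantor distances of the alignment."""
    return neighbor_joining(jc_distance_matrix(msa))


# ---------------------------------------------------------------------------
# Bipartitions, RF distance, bootstrap
# ---------------------------------------------------------------------------

def _leaf_labels(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical leaf-label frozensets.

    Each split is represented by the side NOT containing the alphabetically
    first taxon, making representations comparable across rootings.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(all_leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _leaf_labels(node)
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance (symmetric difference of bipartitions)."""
    l1 = frozenset(lf.taxon.label for lf in t1.leaf_node_iter())
    l2 = frozenset(lf.taxon.label for lf in t2.leaf_node_iter())
    if l1 != l2:
        raise ValueError(f"trees have different leaf sets: {sorted(l1 ^ l2)}")
    return len(bipartitions(t1) ^ bipartitions(t2))


def bootstrap_support(msa, n_reps: int = 100, seed: int = 0,
                      builder=None) -> dendropy.Tree:
    """Attach column-resampling bootstrap support to the point-estimate tree.

    Support = % of replicates whose tree contains each internal bipartition
    of the point tree. n_reps=0 returns the point tree without supports.
    """
    builder = builder or build_nj_tree
    point = builder(msa)
    if n_reps == 0:
        return point
    ids, mat = _row_matrix(msa)
    L = mat.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    n_ok = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        sub = _MatrixMSA(ids, mat[:, cols])
        try:
            reptree = builder(sub)
        except ValueError:
            continue
        n_ok += 1
        for bp in bipartitions(reptree):
            counts[bp] = counts.get(bp, 0) + 1
    all_leaves = frozenset(lf.taxon.label for lf in point.leaf_node_iter())
    anchor = min(all_leaves)
    for node in point.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _leaf_labels(node)
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            pct = 100.0 * counts.get(side, 0) / max(n_ok, 1)
            node.label = str(int(round(pct)))
    return point


class _MatrixMSA:
    """Lightweight row-dict view over a byte matrix (duck-types an MSA)."""

    def __init__(self, ids, mat):
        self.rows = {i: mat[k].tobytes().decode() for k, i in enumerate(ids)}


# ---------------------------------------------------------------------------
# Recombination detection and the masking loop
# ---------------------------------------------------------------------------

@dataclass
class RecombinationTract:
    """A putative imported segment in one alignment row."""

    row_id: str
    start: int
    end: int  # 0-based half-open columns
    score: float  # Poisson tail p-value of the densest window


def detect_recombination(msa, window: int = 1000, step: int = 100,
                         alpha: float = 0.05) -> list[RecombinationTract]:
    """Windowed clustered-substitution scan for recombination imports.

    Per row, substitutions are columns where the row differs from the
    column-wise majority base (ties broken A<C<G<T). Windows whose
    substitution count is Poisson-improbable under the row's mean density
    (Bonferroni-corrected over the row's windows) are merged into tracts.
    """
    ids, mat = _row_matrix(msa)
    L = mat.shape[1]
    valid = (mat == ord("A")) | (mat == ord("C")) | (mat == ord("G")) | (mat == ord("T"))
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    counts = np.stack([((mat == code) & valid).sum(axis=0) for code in base_codes])
    majority = base_codes[counts.argmax(axis=0)]  # argmax tie -> first (A<C<G<T)
    has_majority = counts.max(axis=0) > 0
    tracts: list[RecombinationTract] = []
    if L < window:
        window = L
    starts = np.arange(0, max(L - window, 0) + 1, step)
    n_tests = len(starts)
    for r, rid in enumerate(ids):
        subs = valid[r] & has_majority & (mat[r] != majority)
        v = valid[r] & has_majority
        n_valid = int(v.sum())
        if n_valid == 0 or subs.sum() == 0:
            continue
        lam = subs.sum() / n_valid
        cs = np.concatenate([[0], np.cumsum(subs)])
        cv = np.concatenate([[0], np.cumsum(v)])
        wc = cs[starts + window] - cs[starts]
        wv = cv[starts + window] - cv[starts]
        mu = lam * wv
        pvals = poisson.sf(wc - 1, mu)
        flagged = pvals <= alpha / n_tests
        idx = np.nonzero(flagged)[0]
        if idx.size == 0:
            continue
        # merge overlapping flagged windows
        cur_s, cur_e, cur_p = int(starts[idx[0]]), int(starts[idx[0]]) + window, pvals[idx[0]]
        for k in idx[1:]:
            s = int(starts[k])
            if s <= cur_e:
                cur_e = s + window
                cur_p = min(cur_p, pvals[k])
            else:
                tracts.append(RecombinationTract(rid, cur_s, cur_e, float(cur_p)))
                cur_s, cur_e, cur_p = s, s + window, pvals[k]
        tracts.append(RecombinationTract(rid, cur_s, cur_e, float(cur_p)))
    return tracts


@dataclass
class MaskedPhylogenyResult:
    tree: dendropy.Tree
    msa: object
    tract_history: list[list[RecombinationTract]]
    iterations: int
    status: str  # 'converged' | 'max_iter' | 'stalled'
    masked_cells: int


def iterative_mask_phylogeny(msa, detector=None, builder=None,
                             max_iter: int = 20) -> MaskedPhylogenyResult:
    """Detect-mask-rebuild loop until no recombination is detected.

    Detected tracts are replaced with gaps; masked cells strictly
    accumulate across iterations. Reaching max_iter (or a detector that
    keeps reporting already-masked tracts) yields a warning status in the
    result rather than an exception.
    """
    detector = detector or detect_recombination
    builder = builder or build_nj_tree
    ids, mat = _row_matrix(msa)
    mat = mat.copy()
    row_index = {rid: k for k, rid in enumerate(ids)}
    history: list[list[RecombinationTract]] = []
    masked_total = 0
    status = "max_iter"
    it = 0
    for it in range(1, max_iter + 1):
        view = _MatrixMSA(ids, mat)
        tracts = detector(view)
        history.append(tracts)
        if not tracts:
            status = "converged"
            break
        newly = 0
        for t in tracts:
            seg = mat[row_index[t.row_id], t.start:t.end]
            newly += int((seg != ord("-")).sum())
            seg[:] = ord("-")
        masked_total += newly
        if newly == 0:
            status = "stalled"
            break
    final = _MatrixMSA(ids, mat)
    tree = builder(final)
    return MaskedPhylogenyResult(tree, final, history, it, status, masked_total)


# ---------------------------------------------------------------------------
# External-tool adapters
# ---------------------------------------------------------------------------

def external_tree_builder(argv: list[str]):
    """Adapter for an external tree program: aligned FASTA in, Newick out.

    ``argv`` is the command with the placeholder ``{fasta}``; the program's
    stdout must be Newick. Example: ``["fasttree", "-nt", "-quiet",
    "{fasta}"]``.
    """
    def builder(msa) -> dendropy.Tree:
        with tempfile.TemporaryDirectory() as td:
            fasta = Path(td) / "aln.fa"
            with open(fasta, "w") as fh:
                for rid, seq in msa.rows.items():
                    fh.write(f">{rid}\n{seq}\n")
            cmd = [a.format(fasta=str(fasta)) for a in argv]
            res = subprocess.run(cmd, capture_output=True, text=True, check=True)
            return dendropy.Tree.get(data=res.stdout, schema="newick",
                                     preserve_underscores=True)
    return builder


def tracts_to_rows(tracts: list[RecombinationTract], iteration: int = 0) -> list[dict]:
    """BED-like rows (row_id, start, end, score, iteration) for TSV export."""
    return [{"row_id": t.row_id, "start": t.start, "end": t.end,
             "score": f"{t.score:.3g}", "iteration": iteration} for t in tracts]
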