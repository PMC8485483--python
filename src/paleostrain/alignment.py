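"""Shared alignment primitives.

Two workhorses live here: :class:`ReadAlignment`, the per-read placement
record consumed by the damage profiler and the consensus caller, and a
word-seeded ungapped local aligner (:func:`find_local_hits`) used to anchor
contigs onto a reference and to decompose genomes into fragments for ANI.

The local aligner is a desk-scale surrogate for BLASTn-style search: exact
word seeding (default word size 9) on both strands, diagonal chaining, and
X-drop ungapped extension. It is adequate for colinear genomes whose
differences are substitutions — the regime the rest of the package targets —
and deliberately does not attempt gapped extension; externally produced
tabular hits can be substituted via :func:`read_hits_tsv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (gaps and N preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class ReadAlignment:
    """Placement of a single read on a reference.

    ``seq`` is stored in reference orientation (SAM convention: reads mapped
    to the reverse strand are stored reverse-complemented). ``aligned_pairs``
    holds ``(read_pos, ref_pos, read_base, ref_base)`` tuples with reference
    positions strictly increasing and ``read_pos`` indexing ``seq``. For
    reverse-strand reads the sequencing 5' end is therefore at the *last*
    pair; :meth:`pairs_in_read_orientation` undoes this for damage tallying.
    """

    read_id: str
    ref_id: str
    ref_start: int
    strand: str  # '+' or '-'
    mapping_quality: int
    aligned_pairs: list[tuple[int, int, str, str]]

    @property
    def aligned_length(self) -> int:
        return len(self.aligned_pairs)

    @property
    def ref_end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.aligned_pairs[-1][1] + 1 if self.aligned_pairs else self.ref_start

    @property
    def identity(self) -> float:
        """Matches over aligned columns; gap columns count as mismatches."""
        if not self.aligned_pairs:
            return 0.0
        matches = sum(1 for _, _, qb, rb in self.aligned_pairs
                      if qb == rb and qb in "ACGT")
        return matches / len(self.aligned_pairs)

    @property
    def seq(self) -> str:
        return "".join(qb for _, _, qb, _ in self.aligned_pairs)

    def pairs_in_read_orientation(self):
        """Yield (read_base, ref_base) pairs from the sequencing 5' end.

        For reverse-strand alignments the pair list is reversed and both
        bases complemented, so that post-mortem C deamination is always seen
        as C->T starting at the yielded 5' end.
        """
        if self.strand == "+":
            for _, _, qb, rb in self.aligned_pairs:
                yield qb, rb
        else:
            comp = COMPLEMENT
            for _, _, qb, rb in reversed(self.aligned_pairs):
                yield qb.translate(comp), rb.translate(comp)

    def reanchor(self, reference: str) -> "ReadAlignment":
        """Return a copy with ref_base re-read from ``reference``.

        Used to re-interpret a placement on one genome as a placement on a
        colinear genome (same coordinates, different sequence), e.g. truth
        placements on a strain re-anchored onto the species reference.
        """
        pairs = [(qp, rp, qb, reference[rp]) for qp, rp, qb, _ in self.aligned_pairs]
        return ReadAlignment(self.read_id, self.ref_id, self.ref_start,
                             self.strand, self.mapping_quality, pairs)


# ---------------------------------------------------------------------------
# Word-seeded local search
# ---------------------------------------------------------------------------

@dataclass
class LocalHit:
    """A local alignment between a query and a reference.

    Coordinates are 0-based half-open on the forward strands of both
    sequences; reverse-strand hits carry forward-strand query coordinates
    with ``aligned_query`` reverse-complemented into reference orientation.
    """

    query_id: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str
    identity: float
    length: int
    aligned_ref: str = field(repr=False, default="")
    aligned_query: str = field(repr=False, default="")

    @property
    def matches(self) -> int:
        return round(self.identity * self.length)


def _index_words(seq: str, w: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - w + 1):
        word = seq[i:i + w]
        if "N" in word:
            continue
        idx.setdefault(word, []).append(i)
    return idx


class ReferenceIndex:
    """Pre-built word index of a reference, reusable across queries."""

    def __init__(self, reference: str, word_size: int = 9):
        self.reference = reference.upper()
        self.word_size = word_size
        self.words = _index_words(self.reference, word_size)


def _extend_ungapped(query: str, ref: str, qs: int, qe: int, diag: int,
                     xdrop: int = 12, match: int = 1, mismatch: int = -2):
    """Extend the query interval [qs, qe) along a fixed diagonal with X-drop."""
    # leftward
    score, best, best_qs = 0, 0, qs
    i = qs - 1
    while i >= 0 and i + diag >= 0:
        score += match if query[i] == ref[i + diag] else mismatch
        if score > best:
            best, best_qs = score, i
        if best - score > xdrop:
            break
        i -= 1
    qs = best_qs
    # rightward
    score, best, best_qe = 0, 0, qe
    i = qe
    n, m = len(query), len(ref)
    while i < n and i + diag < m:
        score += match if query[i] == ref[i + diag] else mismatch
        if score > best:
            best, best_qe = score, i + 1
        if best - score > xdrop:
            break
        i += 1
    return qs, best_qe


def _hits_one_strand(query: str, index: ReferenceIndex, strand: str,
                     query_len: int, query_id: str, max_seed_gap: int,
                     min_hit_length: int) -> list[LocalHit]:
    w = index.word_size
    ref = index.reference
    words = index.words
    # collect seed positions grouped by diagonal (rpos - qpos)
    diagonals: dict[int, list[int]] = {}
    for q in range(len(query) - w + 1):
        word = query[q:q + w]
        for r in words.get(word, ()):
            diagonals.setdefault(r - q, []).append(q)
    hits: list[LocalHit] = []
    for diag, qpos_list in diagonals.items():
        qpos_list.sort()
        # chain seeds on the same diagonal, splitting on large gaps
        start = qpos_list[0]
        prev = qpos_list[0]
        segments = []
        for q in qpos_list[1:]:
            if q - prev > max_seed_gap:
                segments.append((start, prev + w))
                start = q
            prev = q
        segments.append((start, prev + w))
        for qs, qe in segments:
            qs, qe = _extend_ungapped(query, ref, qs, qe, diag)
            if qe - qs < min_hit_length:
                continue
            qseg = query[qs:qe]
            rseg = ref[qs + diag:qe + diag]
            matches = sum(a == b for a, b in zip(qseg, rseg))
            length = qe - qs
            if strand == "+":
                q0, q1, aln_q = qs, qe, qseg
            else:
                # map back to forward-strand query coordinates
                q0, q1 = query_len - qe, query_len - qs
                aln_q = qseg  # already reference-oriented (query was revcomp'd)
            hits.append(LocalHit(query_id, qs + diag, qe + diag, q0, q1, strand,
                                 matches / length, length, rseg, aln_q))
    return hits


def find_local_hits(query: str, reference: str | ReferenceIndex,
                    word_size: int = 9, max_seed_gap: int = 200,
                    min_hit_length: int = 30,
                    query_id: str = "query") -> list[LocalHit]:
    """Find maximal local hits of ``query`` on ``reference`` (both strands).

    Returns hits that do not overlap on the query; overlaps are resolved
    greedily by match count, then length, then leftmost query start.
    """
    query = query.upper()
    if isinstance(reference, str):
        index = ReferenceIndex(reference, word_size)
    else:
        index = reference
    raw = _hits_one_strand(query, index, "+", len(query), query_id,
                           max_seed_gap, min_hit_length)
    raw += _hits_one_strand(revcomp(query), index, "-", len(query), query_id,
                            max_seed_gap, min_hit_length)
    # greedy non-overlapping selection on the query
    raw.sort(key=lambda h: (-h.matches, -h.length, h.query_start))
    chosen: list[LocalHit] = []
    for h in raw:
        if all(h.query_end <= c.query_start or h.query_start >= c.query_end
               for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.query_start)
    return chosen


def filter_hits(hits: list[LocalHit], min_len: int = 500,
                min_identity: float = 0.95) -> list[LocalHit]:
    """Keep hits with length > min_len AND identity > min_identity (strict)."""
    return [h for h in hits if h.length > min_len and h.identity > min_identity]


def best_hit(hits: list[LocalHit]) -> LocalHit | None:
    """Hit with the most matching columns (ties: longer, then leftmost)."""
    if not hits:
        return None
    return max(hits, key=lambda h: (h.matches, h.length, -h.query_start))


# ---------------------------------------------------------------------------
# Global pairwise identity (edlib-backed)
# ---------------------------------------------------------------------------

def global_identity(a: str, b: str) -> float:
    """Identity of an end-to-end pairwise alignment: matches / alignment columns.

    End gaps are penalized (they are columns). Backed by edit-distance
    optimal alignment.
    """
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches = columns = 0
    for n, op in _iter_cigar(res["cigar"]):
        columns += n
        if op == "=":
            matches += n
    return matches / columns


def global_alignment(a: str, b: str) -> tuple[str, str]:
    """End-to-end alignment of a and b as two gapped strings."""
    res = edlib.align(a, b, mode="NW", task="path")
    ai = bi = 0
    out_a, out_b = [], []
    for n, op in _iter_cigar(res["cigar"]):
        if op in "=X":
            out_a.append(a[ai:ai + n]); out_b.append(b[bi:bi + n])
            ai += n; bi += n
        elif op == "I":  # present in a, gap in b
            out_a.append(a[ai:ai + n]); out_b.append("-" * n)
            ai += n
        elif op == "D":
            out_a.append("-" * n); out_b.append(b[bi:bi + n])
            bi += n
    return "".join(out_a), "".join(out_b)


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""
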