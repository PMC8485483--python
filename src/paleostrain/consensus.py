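"""Reference-anchored consensus draft genomes from read alignments.

A site of the reference receives the dominant allele of the gated read
pileup only when it survives all five site/read filters used for draft
genome reconstruction from metagenomic alignments; otherwise it is a gap:

* read-level gates: mapping quality >= 30, aligned length >= 30 nt,
  read identity >= 97% (reads below any threshold contribute nothing);
* site-level gates: depth >= 3 and dominant allele frequency >= 80%.

All thresholds are stated in the literature as strict "below" conditions,
so equality at a threshold always passes; this boundary convention is
applied uniformly and is covered by dedicated tests.

Sample-level presence of an organism is decided by breadth of coverage:
the fraction of reference sites at depth >= 3 must reach 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import ReadAlignment
from .simulate import BASES, _BASE_TO_INT


def gate_read(aln: ReadAlignment, min_mq: int = 30, min_len: int = 30,
              min_identity: float = 0.97) -> bool:
    """True iff the read passes all read-level filters (equality passes)."""
    return (aln.mapping_quality >= min_mq
            and aln.aligned_length >= min_len
            and aln.identity >= min_identity)


@dataclass
class Pileup:
    """Per-site allele counts over {A,C,G,T} after read-level gating."""

    ref_id: str
    counts: np.ndarray  # shape (4, L), rows in A,C,G,T order

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class ConsensusGenome:
    """Reference-length consensus over {A,C,G,T,'-'}."""

    ref_id: str
    sequence: str
    breadth_at_min_depth: float

    def export_sequence(self, gap_char: str = "-") -> str:
        """Sequence with the internal gap state rewritten (e.g. to 'N')."""
        return self.sequence.replace("-", gap_char)


def build_pileup(alignments: list[ReadAlignment], reference: str,
                 ref_id: str = "ref", min_mq: int = 30, min_len: int = 30,
                 min_identity: float = 0.97) -> Pileup:
    """Accumulate allele counts from gated-in reads at matched columns."""
    L = len(reference)
    counts = np.zeros((4, L), dtype=np.int32)
    for aln in alignments:
        if aln.ref_id != ref_id:
            raise ValueError(f"alignment {aln.read_id} is on reference "
                             f"'{aln.ref_id}', pileup is for '{ref_id}'")
        if not gate_read(aln, min_mq, min_len, min_identity):
            continue
        pos = np.fromiter((rp for _, rp, _, _ in aln.aligned_pairs),
                          dtype=np.int64, count=len(aln.aligned_pairs))
        base = _BASE_TO_INT[np.frombuffer(
            "".join(qb for _, _, qb, _ in aln.aligned_pairs).encode(),
            dtype=np.uint8)]
        ok = base < 4  # skip ambiguity codes
        np.add.at(counts, (base[ok], pos[ok]), 1)
    return Pileup(ref_id, counts)


def call_consensus(pileup: Pileup, min_depth: int = 3,
                   min_dominant_freq: float = 0.80) -> ConsensusGenome:
    """Dominant-allele consensus under depth and allele-frequency gates.

    A site receives its dominant allele iff depth >= min_depth, the dominant
    allele is unique, and its frequency >= min_dominant_freq; otherwise '-'.
    """
    counts = pileup.counts
    depth = counts.sum(axis=0)
    maxc = counts.max(axis=0)
    unique = (counts == maxc).sum(axis=0) == 1
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth > 0, maxc / np.maximum(depth, 1), 0.0)
    keep = (depth >= min_depth) & unique & (freq >= min_dominant_freq)
    alleles = counts.argmax(axis=0)
    seq = np.full(pileup.length, ord("-"), dtype=np.uint8)
    base_codes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    seq[keep] = base_codes[alleles[keep]]
    breadth = float((depth >= min_depth).mean()) if pileup.length else 0.0
    return ConsensusGenome(pileup.ref_id, seq.tobytes().decode(), breadth)


def breadth_of_coverage(pileup: Pileup, min_depth: int = 3) -> float:
    """Fraction of reference sites with post-gating depth >= min_depth."""
    if pileup.length == 0:
        raise ValueError("zero-length reference")
    return float((pileup.depth >= min_depth).mean())


def detect_presence(breadth: float, threshold: float = 0.50) -> bool:
    """Sample-level presence call: breadth >= threshold."""
    return breadth >= threshold
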