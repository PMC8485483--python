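"""Reference-anchored whole-genome multiple sequence alignment.

Rows come from two sources: consensus draft genomes (already in reference
coordinates) and local hits of assembled contigs against the reference
(filtered at length > 500 bp and identity > 95%). Query insertions relative
to the reference are dropped and query deletions become '-', so the MSA is
rectangular in reference coordinates; '-' means missing-or-deleted.

Cleaning applies the strain-level rule — first drop rows with > 50% gaps,
then drop columns with > 10% missing data computed over the surviving
rows — or the genus-level rule (column step only). Both fractions are
strict: a row at exactly 50% gaps or a column at exactly 10% missing is
retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import LocalHit
from .consensus import ConsensusGenome

MISSING = frozenset(b"-N")


class AlignmentEmptiedError(ValueError):
    """Cleaning removed every row or every column."""


@dataclass
class RefAnchoredMSA:
    """Rectangular alignment in reference coordinates.

    ``column_coords`` maps each retained column back to its original
    reference position (strictly increasing).
    """

    ref_id: str
    rows: dict[str, str]
    column_coords: np.ndarray = field(default=None)

    def __post_init__(self):
        lens = {len(s) for s in self.rows.values()}
        if len(lens) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lens)}")
        if self.column_coords is None:
            self.column_coords = np.arange(self.length)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def to_matrix(self) -> np.ndarray:
        """Rows as a (n, L) byte matrix in insertion order."""
        return np.frombuffer("".join(self.rows.values()).encode(),
                             dtype=np.uint8).reshape(len(self.rows), -1).copy()

    @classmethod
    def from_matrix(cls, ref_id, ids, matrix, column_coords) -> "RefAnchoredMSA":
        rows = {i: matrix[k].tobytes().decode() for k, i in enumerate(ids)}
        return cls(ref_id, rows, np.asarray(column_coords))


def project_row(source, reference: str, ref_id: str = "ref") -> str:
    """Project a consensus genome or a filtered hit list onto the reference.

    Consensus genomes project identically (they are already anchored). For
    hits, aligned query bases are written at matched reference columns;
    overlapping hits are resolved by higher identity, then longer hit, then
    leftmost reference start.
    """
    if isinstance(source, ConsensusGenome):
        if len(source.sequence) != len(reference):
            raise ValueError(f"consensus length {len(source.sequence)} != "
                             f"reference length {len(reference)}")
        return source.sequence
    row = np.full(len(reference), ord("-"), dtype=np.uint8)
    hits: list[LocalHit] = sorted(
        source, key=lambda h: (h.identity, h.length, -h.ref_start))
    for h in hits:
        if h.ref_end > len(reference):
            raise ValueError(f"hit [{h.ref_start},{h.ref_end}) exceeds reference "
                             f"'{ref_id}' of length {len(reference)}")
        rp = h.ref_start
        for rb, qb in zip(h.aligned_ref, h.aligned_query):
            if rb == "-":        # query insertion: no reference column
                continue
            row[rp] = ord("-") if qb == "-" else ord(qb.upper())
            rp += 1
    return row.tobytes().decode()


def clean_msa(msa: RefAnchoredMSA, max_row_gap_frac: float = 0.50,
              max_col_missing_frac: float = 0.10,
              mode: str = "strain") -> RefAnchoredMSA:
    """Apply row then column cleaning (strain mode) or column only (genus).

    Strain mode drops rows whose gap fraction exceeds max_row_gap_frac,
    THEN drops columns whose missing fraction over the surviving rows
    exceeds max_col_missing_frac; each rule is applied exactly once.
    """
    if mode not in ("strain", "genus"):
        raise ValueError(f"unknown cleaning mode: {mode!r}")
    mat = msa.to_matrix()
    ids = msa.ids
    missing = (mat == ord("-")) | (mat == ord("N"))
    if mode == "strain":
        keep_rows = missing.mean(axis=1) <= max_row_gap_frac
        if not keep_rows.any():
            raise AlignmentEmptiedError("alignment emptied by cleaning: "
                                        "every row exceeds the gap fraction")
        mat = mat[keep_rows]
        missing = missing[keep_rows]
        ids = [i for i, k in zip(ids, keep_rows) if k]
    keep_cols = missing.mean(axis=0) <= max_col_missing_frac
    if not keep_cols.any():
        raise AlignmentEmptiedError("alignment emptied by cleaning: "
                                    "every column exceeds the missing fraction")
    return RefAnchoredMSA.from_matrix(msa.ref_id, ids, mat[:, keep_cols],
                                      np.asarray(msa.column_coords)[keep_cols])


def write_msa_fasta(msa: RefAnchoredMSA, fasta_path, coords_path=None) -> None:
    from .io import write_fasta, write_tsv
    write_fasta(msa.rows, fasta_path)
    if coords_path is not None:
        write_tsv([{"column": i, "ref_position": int(c)}
                   for i, c in enumerate(msa.column_coords)],
                  coords_path, ["column", "ref_position"])


def read_hits_tsv(path) -> list[LocalHit]:
    """Read tabular local hits (12 standard columns extended with the two
    aligned, gapped sequences), allowing an external aligner's output to be
    substituted for the built-in seeded search."""
    from .io import read_tsv
    hits = []
    for r in read_tsv(path):
        hits.append(LocalHit(
            r["query_id"], int(r["ref_start"]), int(r["ref_end"]),
            int(r["query_start"]), int(r["query_end"]), r["strand"],
            float(r["identity"]), int(r["length"]),
            r["aligned_ref"], r["aligned_query"]))
    return hits


def write_hits_tsv(hits: list[LocalHit], path) -> None:
    from .io import write_tsv
    cols = ["query_id", "ref_start", "ref_end", "query_start", "query_end",
            "strand", "identity", "length", "aligned_ref", "aligned_query"]
    write_tsv([{c: getattr(h, c) for c in cols} for h in hits], path, cols)
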