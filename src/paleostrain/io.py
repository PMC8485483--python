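"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython; SAM is written as text (the alignments the
simulator emits are ungapped, so CIGAR/MD construction is direct) and read
back through pysam. Newick trees go through dendropy. Tabular truth files
are plain TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import ReadAlignment


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write (read_id, sequence) pairs with constant Phred+33 quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _md_and_nm(pairs) -> tuple[str, int]:
    """MD tag and NM count for an ungapped aligned-pair list."""
    md, run, nm = [], 0, 0
    for _, _, qb, rb in pairs:
        if qb == rb:
            run += 1
        else:
            md.append(str(run)); md.append(rb); run = 0; nm += 1
    md.append(str(run))
    return "".join(md), nm


def write_sam(alignments: list[ReadAlignment], ref_lengths: dict[str, int], path) -> None:
    """Write ungapped alignments as SAM with NM and MD tags."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref, ln in ref_lengths.items():
            fh.write(f"@SQ\tSN:{ref}\tLN:{ln}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            seq = a.seq
            cigar = f"{len(seq)}M"
            md, nm = _md_and_nm(a.aligned_pairs)
            fh.write(f"{a.read_id}\t{flag}\t{a.ref_id}\t{a.ref_start + 1}\t"
                     f"{a.mapping_quality}\t{cigar}\t*\t0\t0\t{seq}\t"
                     f"{'I' * len(seq)}\tNM:i:{nm}\tMD:Z:{md}\n")


def read_sam(path, references: dict[str, str] | None = None) -> list[ReadAlignment]:
    """Read SAM/BAM into ReadAlignment records.

    Reference bases come from ``references`` when given, otherwise from the
    MD tag; an alignment with neither raises a format error.
    """
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            seq = rec.query_sequence
            if references is not None and rec.reference_name in references:
                ref = references[rec.reference_name]
                pairs = [(q, r, seq[q], ref[r])
                         for q, r in rec.get_aligned_pairs(matches_only=True)]
            else:
                if not rec.has_tag("MD"):
                    raise ValueError(
                        f"alignment {rec.query_name}: no MD tag and no reference "
                        "sequence supplied; cannot recover per-base pairing")
                pairs = [(q, r, seq[q], rb.upper())
                         for q, r, rb in rec.get_aligned_pairs(matches_only=True,
                                                               with_seq=True)]
            out.append(ReadAlignment(
                rec.query_name, rec.reference_name, rec.reference_start,
                "-" if rec.is_reverse else "+", rec.mapping_quality, pairs))
    return out


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def write_tsv(rows: list[dict], path, columns: list[str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_tsv(path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def write_newick(tree, path) -> None:
    Path(path).write_text(tree.as_string(schema="newick", unquoted_underscores=True))
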