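"""Sequence and interval file I/O helpers.

FASTA/FASTQ go through Biopython; BED intervals are 0-based half-open on
disk and converted to the package's 1-based inclusive convention on read.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

PLACEMENT_COLUMNS = ["read_id", "sample", "chrom", "pos_3prime", "strand", "mapq"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FastqRecord:
    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FormatError(f"{self.read_id}: sequence/quality length mismatch")


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> list[FastqRecord]:
    with _open(path) as fh:
        return [
            FastqRecord(
                rec.id,
                str(rec.seq),
                "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(records, path) -> None:
    with _open(path, "wt") as fh:
        for r in records:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.qualities]
            SeqIO.write(rec, fh, "fastq")


def read_fasta(path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
            fh,
            "fasta",
        )


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED3+ file into 1-based inclusive (chrom, start, end) tuples."""
    out = []
    with _open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    return out


def write_bed(intervals, path) -> None:
    """Write 1-based inclusive (chrom, start, end[, name]) tuples as BED."""
    with _open(path, "wt") as fh:
        for iv in intervals:
            chrom, start, end = iv[:3]
            rest = "\t" + "\t".join(str(x) for x in iv[3:]) if len(iv) > 3 else ""
            fh.write(f"{chrom}\t{start - 1}\t{end}{rest}\n")


def read_placements(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PLACEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"placement table missing columns: {sorted(missing)}")
    return df


def write_placements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PLACEMENT_COLUMNS)
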