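"""Flat-file helpers: FASTA assemblies and simple GFF3 records."""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta_dict(path) -> dict[str, str]:
    """Read a (nucleotide or protein) FASTA into an ordered id -> sequence dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta_dict(seqs: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        str(path),
        "fasta",
    )


@dataclass
class Gff3Record:
    """One GFF3 feature line (1-based inclusive coordinates on disk;
    constructed from 0-based half-open in-memory coordinates)."""

    seqid: str
    type: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."
    source: str = "eprvscan"
    score: str = "."
    phase: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def to_line(self) -> str:
        attrs = ";".join(
            f"{k}={urllib.parse.quote(str(v), safe=' :_-.')}"
            for k, v in self.attributes.items()
        )
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.type,
                str(self.start + 1),
                str(self.end),
                self.score,
                self.strand,
                self.phase,
                attrs or ".",
            ]
        )

    @classmethod
    def from_line(cls, line: str) -> "Gff3Record":
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        attributes = {}
        if fields[8] != ".":
            for item in fields[8].split(";"):
                if item:
                    k, _, v = item.partition("=")
                    attributes[k] = urllib.parse.unquote(v)
        return cls(
            seqid=fields[0],
            source=fields[1],
            type=fields[2],
            start=int(fields[3]) - 1,
            end=int(fields[4]),
            score=fields[5],
            strand=fields[6],
            phase=fields[7],
            attributes=attributes,
        )


def write_gff3(records, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_gff3(path) -> list[Gff3Record]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            records.append(Gff3Record.from_line(line))
    return records
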