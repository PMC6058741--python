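"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython.  GFF3 is handled by a deliberately small
reader/writer pair because the pipeline only needs a flat record model
(no hierarchy, no fasta directives): internally every interval is 0-based
half-open and conversion to GFF3's 1-based inclusive coordinates happens
exactly here and nowhere else.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

GFF3_HEADER = "##gff-version 3"


@dataclass
class GffRecord:
    """One annotation line; ``start``/``end`` are 0-based half-open."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: float | None = None
    strand: str = "."
    phase: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InputError(f"interval end < start: {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _fmt_attrs(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    parts = []
    for key, value in attrs.items():
        parts.append(f"{urllib.parse.quote(str(key), safe='')}"
                     f"={urllib.parse.quote(str(value), safe=' ')}")
    return ";".join(parts)


def _parse_attrs(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if text in (".", ""):
        return attrs
    for chunk in text.split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise InputError(f"malformed GFF3 attribute: {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[urllib.parse.unquote(key)] = urllib.parse.unquote(value)
    return attrs


def write_gff3(records: Iterable[GffRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(GFF3_HEADER + "\n")
        for rec in records:
            score = "." if rec.score is None else f"{rec.score:g}"
            handle.write("\t".join([
                rec.seqid,
                rec.source,
                rec.type,
                str(rec.start + 1),  # to 1-based inclusive
                str(rec.end),
                score,
                rec.strand,
                rec.phase,
                _fmt_attrs(rec.attributes),
            ]) + "\n")


def read_gff3(path) -> list[GffRecord]:
    records = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise InputError(f"GFF3 line does not have 9 columns: {line!r}")
            score = None if fields[5] == "." else float(fields[5])
            records.append(GffRecord(
                seqid=fields[0],
                source=fields[1],
                type=fields[2],
                start=int(fields[3]) - 1,  # back to 0-based half-open
                end=int(fields[4]),
                score=score,
                strand=fields[6],
                phase=fields[7],
                attributes=_parse_attrs(fields[8]),
            ))
    return records


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Distance between the nearest ends of two intervals; 0 if they touch/overlap."""
    if a_start > b_start:
        a_start, a_end, b_start, b_end = b_start, b_end, a_start, a_end
    return max(0, b_start - a_end)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
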