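"""Core sequence/feature data types and readers/writers.

Coordinates are 1-based inclusive throughout, matching the convention of
published phage feature tables: the coding span *includes* the stop codon
while the amino-acid length *excludes* it, so a span of ``3*(n+1)`` bp
encodes ``n`` residues.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._round import round_half_up

__all__ = [
    "GenomeRecord",
    "FeatureTable",
    "FastaParseError",
    "UndefinedContentError",
    "FrameError",
    "read_fasta",
    "write_fasta",
    "gc_content",
    "coords_to_aa_length",
    "write_feature_table",
    "read_feature_table",
]

_ALPHABET = set("ACGTN")

# Columns of the tabular feature-table format (mirrors a published ORF table).
TSV_COLUMNS = [
    "orf_id",
    "strand",
    "start",
    "end",
    "size_aa",
    "mw_kda",
    "pi",
    "sd_context",
    "start_codon",
    "predicted_function",
]


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


class UndefinedContentError(ValueError):
    """GC content is undefined (empty or all-N sequence)."""


class FrameError(ValueError):
    """Coding span is not a whole number of codons."""


@dataclass(frozen=True)
class GenomeRecord:
    """A named linear DNA sequence over the {A,C,G,T,N} alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"genome {self.id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "GenomeRecord":
        return GenomeRecord(self.id, str(Seq(self.sequence).reverse_complement()))


@dataclass
class FeatureTable:
    """Ordered ORF rows (plus optional non-ORF features) for one genome.

    ``rows`` holds :class:`phagekit.orfs.OrfCandidate`-like objects sorted by
    start; ``extra_features`` holds (type, start, end) intervals such as a
    tRNA gene.
    """

    genome_id: str
    rows: list = field(default_factory=list)
    extra_features: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rows = sorted(self.rows, key=lambda r: (r.start, r.end))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (possibly multi-record) FASTA file into GenomeRecords.

    Sequences are uppercased; an empty file yields an empty list. A record
    whose sequence contains a character outside {A,C,G,T,N} raises
    :class:`FastaParseError` naming the line where its sequence starts.
    """
    path = Path(path)
    text = path.read_text()
    # Pre-scan for the line number of each header so parse errors are precise.
    header_lines: dict[str, int] = {}
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            header_lines.setdefault(line[1:].split()[0] if line[1:].split() else "", i)
        elif line.strip() and not header_lines:
            raise FastaParseError(f"{path}: line {i}: sequence before any '>' header")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        try:
            records.append(GenomeRecord(rec.id, str(rec.seq)))
        except ValueError as exc:
            line = header_lines.get(rec.id, "?")
            raise FastaParseError(f"{path}: record at line {line}: {exc}") from exc
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def gc_content(g: GenomeRecord) -> float:
    """GC percentage over unambiguous bases, rounded half-up to 2 dp.

    N bases are excluded from both numerator and denominator.
    """
    s = g.sequence
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise UndefinedContentError(
            f"genome {g.id!r}: GC content undefined (no unambiguous bases)"
        )
    gc = s.count("G") + s.count("C")
    return round_half_up(100.0 * gc / acgt, 2)


def coords_to_aa_length(start: int, end: int) -> int:
    """Amino-acid length of a 1-based inclusive coding span.

    The span includes the stop codon; the returned length excludes it.
    """
    if end <= start:
        raise ValueError(f"end ({end}) must exceed start ({start})")
    span = end - start + 1
    if span % 3 != 0:
        raise FrameError(f"span {start}..{end} ({span} bp) is not a multiple of 3")
    return span // 3 - 1


def _row_fields(row) -> dict:
    return {
        "orf_id": getattr(row, "id", ""),
        "strand": row.strand,
        "start": row.start,
        "end": row.end,
        "size_aa": row.size_aa,
        "mw_kda": getattr(row, "mw_kda", ""),
        "pi": getattr(row, "pi", ""),
        "sd_context": getattr(row, "sd_context", ""),
        "start_codon": row.start_codon,
        "predicted_function": getattr(row, "predicted_function", ""),
    }


def write_feature_table(t: FeatureTable, path: str | Path, format: str = "tsv") -> None:
    """Write a feature table as TSV or GFF3 (1-based inclusive coordinates)."""
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(TSV_COLUMNS)]
        for row in t.rows:
            f = _row_fields(row)
            lines.append("\t".join(str(f[c]) for c in TSV_COLUMNS))
        path.write_text("\n".join(lines) + "\n")
    elif format == "gff3":
        lines = ["##gff-version 3"]
        for typ, start, end in t.extra_features:
            lines.append(
                f"{t.genome_id}\tphagekit\t{typ}\t{start}\t{end}\t.\t+\t.\tID={typ}"
            )
        for row in t.rows:
            attrs = f"ID={getattr(row, 'id', '') or 'cds'}"
            fn = getattr(row, "predicted_function", "")
            if fn:
                attrs += f";product={fn}"
            lines.append(
                f"{t.genome_id}\tphagekit\tCDS\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t0\t{attrs}"
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown feature-table format: {format!r}")


def read_feature_table(path: str | Path, genome_id: str = "") -> FeatureTable:
    """Read a TSV feature table written by :func:`write_feature_table`."""
    from .orfs import OrfCandidate  # local import to avoid a cycle

    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != TSV_COLUMNS:
        raise ValueError(f"{path}: missing or unexpected feature-table header")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        vals = dict(zip(TSV_COLUMNS, line.split("\t")))
        rows.append(
            OrfCandidate(
                id=vals["orf_id"],
                start=int(vals["start"]),
                end=int(vals["end"]),
                strand=vals["strand"],
                start_codon=vals["start_codon"],
                sd_context=vals["sd_context"],
                mw_kda=float(vals["mw_kda"]) if vals["mw_kda"] else None,
                pi=float(vals["pi"]) if vals["pi"] else None,
                predicted_function=vals["predicted_function"],
            )
        )
    return FeatureTable(genome_id=genome_id, rows=rows)
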