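"""Genome and annotation I/O, coordinate conventions, sequence primitives.

Conventions owned here and used everywhere else in the package:

* internal coordinates are 0-based, half-open ``[start, end)``;
* GFF3 on disk is 1-based, inclusive; BED output is 0-based half-open;
* sequences are stored uppercase over the alphabet ``{A, C, G, T, N}``
  (``U`` is converted to ``T``; other IUPAC ambiguity codes collapse to
  ``N`` with a warning, since guide matching is defined only over
  unambiguous bases);
* translation uses the bacterial/archaeal code (NCBI table 11) with the
  initiator codon translated per table — no forced methionine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data import CodonTable as _BioCodonTable

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_IUPAC = set("ACGTUNRYSWKMBDHV")

# Bacterial, archaeal and plant plastid code.
_TABLE11 = _BioCodonTable.unambiguous_dna_by_id[11]
START_CODONS = ("ATG", "GTG", "TTG")


class GenomeIOError(ValueError):
    """Malformed FASTA/GFF3 input or violated sequence invariant."""


@dataclass(frozen=True)
class GenomeRecord:
    """One replicon: a named DNA sequence with a circularity flag."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise GenomeIOError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _VALID
        if bad:
            raise GenomeIOError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Feature:
    """An annotated interval (CDS, sRNA or other) on a replicon.

    ``start``/``end`` are internal 0-based half-open genomic coordinates.
    ``operon_id``/``operon_index`` place the feature in its transcription
    unit; features without operon annotation form singleton operons.
    """

    id: str
    record_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    ftype: str = "other"  # CDS | sRNA | other
    operon_id: str | None = None
    operon_index: int = 0
    non_triplet: bool = False  # CDS whose length is not divisible by 3

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"feature {self.id!r}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"feature {self.id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.operon_id is None:
            self.operon_id = self.id
        if self.ftype == "CDS" and (self.end - self.start) % 3 != 0:
            self.non_triplet = True

    def __len__(self) -> int:
        return self.end - self.start


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - _VALID
    if bad:
        raise GenomeIOError(f"illegal characters in sequence: {sorted(bad)}")
    return seq.translate(_COMP)[::-1]


def _normalize(raw: str, where: str) -> str:
    """Uppercase, U->T, collapse non-ACGTN IUPAC codes to N."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _IUPAC
    if bad:
        raise GenomeIOError(f"{where}: non-IUPAC characters {sorted(bad)}")
    ambiguous = set(seq) - _VALID
    if ambiguous:
        logger.warning(
            "%s: ambiguity codes %s collapsed to N", where, sorted(ambiguous)
        )
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq


def read_fasta(path: str | Path, circular: bool = False) -> list[GenomeRecord]:
    """Read a (multi-record) FASTA file into :class:`GenomeRecord` objects.

    Sequences are normalized (uppercase, U->T, ambiguity codes -> N with
    a logged warning). Records are returned in file order; duplicate ids
    are an error.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomeIOError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = _normalize(str(rec.seq), f"{path}:{rec.id}")
        records.append(GenomeRecord(id=rec.id, seq=seq, circular=circular))
    if not records:
        raise GenomeIOError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA with fixed line width."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col9.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise GenomeIOError(f"malformed GFF3 attribute {item!r}")
        key, value = item.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff3(path: str | Path, genome: list[GenomeRecord]) -> list[Feature]:
    """Read features from GFF3, converting to internal coordinates.

    Recognized types: ``CDS``, ``sRNA`` (SO synonyms ``ncRNA``/
    ``small_regulatory_ncRNA`` map to sRNA); anything else becomes
    ``other``. Optional ``operon_id``/``operon_index`` attributes carry
    transcription-unit grouping; features without them become singleton
    operons. Bounds are validated against the genome; a CDS whose length
    is not a multiple of 3 is flagged, not rejected.
    """
    path = Path(path)
    lengths = {r.id: len(r) for r in genome}
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start1, end1, _score, strand, _phase, col9 = cols
            if seqid not in lengths:
                raise GenomeIOError(f"{path}:{lineno}: unknown replicon {seqid!r}")
            if strand not in ("+", "-"):
                raise GenomeIOError(f"{path}:{lineno}: strand must be + or -")
            start = int(start1) - 1
            end = int(end1)
            if not (0 <= start < end <= lengths[seqid]):
                raise GenomeIOError(
                    f"{path}:{lineno}: interval {start1}-{end1} out of bounds "
                    f"for {seqid} (length {lengths[seqid]})"
                )
            attrs = _parse_attributes(col9)
            fid = attrs.get("ID", f"feature_{lineno}")
            if ftype in ("ncRNA", "small_regulatory_ncRNA"):
                ftype = "sRNA"
            elif ftype not in ("CDS", "sRNA"):
                ftype = "other"
            feat = Feature(
                id=fid,
                record_id=seqid,
                start=start,
                end=end,
                strand=strand,
                ftype=ftype,
                operon_id=attrs.get("operon_id"),
                operon_index=int(attrs.get("operon_index", 0)),
            )
            if feat.non_triplet:
                logger.warning(
                    "%s:%d: CDS %s length %d not divisible by 3",
                    path, lineno, fid, len(feat),
                )
            features.append(feat)
    _validate_operons(features)
    return features


def _validate_operons(features: list[Feature]) -> None:
    by_operon: dict[str, list[Feature]] = {}
    for f in features:
        by_operon.setdefault(f.operon_id, []).append(f)
    for oid, members in by_operon.items():
        strands = {m.strand for m in members}
        if len(strands) > 1:
            raise GenomeIOError(f"operon {oid!r}: members on mixed strands")
        idx = sorted(m.operon_index for m in members)
        if idx != list(range(len(members))):
            raise GenomeIOError(
                f"operon {oid!r}: operon_index values {idx} not consecutive from 0"
            )


def write_gff3(features: Iterable[Feature], path: str | Path, source: str = "crispritools") -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id};operon_id={f.operon_id};operon_index={f.operon_index}"
            fh.write(
                f"{f.record_id}\t{source}\t{f.ftype}\t{f.start + 1}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attrs}\n"
            )


def feature_sequence(feature: Feature, genome: list[GenomeRecord]) -> str:
    """Sense-strand (mRNA-like) sequence of a feature, 5'->3'.

    For a minus-strand feature this is the reverse complement of the
    plus-strand slice.
    """
    record = next((r for r in genome if r.id == feature.record_id), None)
    if record is None:
        raise GenomeIOError(f"feature {feature.id!r}: no record {feature.record_id!r}")
    if feature.end > len(record):
        raise GenomeIOError(f"feature {feature.id!r}: out of bounds")
    plus = record.seq[feature.start:feature.end]
    return plus if feature.strand == "+" else revcomp(plus)


def translate(cds_seq: str, table: int = 11) -> str:
    """Translate a CDS with the bacterial code (table 11).

    The initiator codon is translated per table (GTG -> V, TTG -> L).
    A single terminal stop is rendered as ``*``; an internal stop, a
    non-triplet length or an N anywhere is an error.
    """
    if len(cds_seq) % 3 != 0:
        raise GenomeIOError(f"CDS length {len(cds_seq)} not divisible by 3")
    if "N" in cds_seq:
        raise GenomeIOError("cannot translate sequence containing N")
    codon_table = _BioCodonTable.unambiguous_dna_by_id[table]
    protein = []
    n_codons = len(cds_seq) // 3
    for i in range(n_codons):
        codon = cds_seq[3 * i : 3 * i + 3]
        if codon in codon_table.stop_codons:
            if i != n_codons - 1:
                raise GenomeIOError(f"internal stop codon {codon} at codon {i}")
            protein.append("*")
        else:
            protein.append(codon_table.forward_table[codon])
    return "".join(protein)


def synonymous_codons(codon: str, table: int = 11) -> list[str]:
    """All sense codons encoding the same amino acid, excluding ``codon``."""
    codon_table = _BioCodonTable.unambiguous_dna_by_id[table]
    if codon in codon_table.stop_codons:
        return []
    aa = codon_table.forward_table[codon]
    return [
        c
        for c, a in codon_table.forward_table.items()
        if a == aa and c != codon
    ]
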