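"""Readers and writers for the plain-text formats the toolkit touches.

Formats: FASTA (references), FASTQ Phred+33 (amplicon reads), VCF v4.2
(SNVs only), GFF3 (gene models).

Coordinate convention: everything in memory is 0-based half-open. VCF and
GFF3 are 1-based inclusive on disk; the +/-1 arithmetic happens only inside
this module, at the format boundary. ``FeatureRecord`` mirrors the GFF3
convention (1-based inclusive) because it is a faithful image of a GFF3
line; derived objects such as :class:`CdsModel` are 0-based half-open.

Soft-masked (lowercase) sequence is uppercased on load; the toolkit never
distinguishes masked sequence. IUPAC ambiguity codes are accepted in
references (PAM patterns need them) but rejected in reads, where base
counting requires concrete bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

log = logging.getLogger("bedit")

REF_ALPHABET = frozenset("ACGTNRYSWKMBDHV")
READ_ALPHABET = frozenset("ACGTN")
BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file violated its format contract (message names the line)."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named reference sequence (uppercase IUPAC nucleotides)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - REF_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with Phred+33 qualities."""

    id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )
        bad = set(self.seq) - READ_ALPHABET
        if bad:
            raise ValueError(f"read {self.id!r} contains illegal characters {sorted(bad)}")


@dataclass(frozen=True)
class FeatureRecord:
    """One GFF3 feature line. start/end are 1-based inclusive (GFF3)."""

    seq_id: str
    type: str
    start: int
    end: int
    strand: str
    phase: str = "."
    parent: str = ""
    feature_id: str = ""

    VALID_TYPES = frozenset(
        {"gene", "mRNA", "CDS", "exon", "five_prime_UTR", "three_prime_UTR"}
    )

    def __post_init__(self) -> None:
        if self.type not in self.VALID_TYPES:
            raise ValueError(f"unsupported feature type {self.type!r}")
        if self.start > self.end:
            raise ValueError(
                f"feature {self.feature_id or self.type} on {self.seq_id}: "
                f"start {self.start} > end {self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def start0(self) -> int:
        """0-based half-open start (internal convention)."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end (internal convention)."""
        return self.end


@dataclass(frozen=True)
class SnvRecord:
    """A single-nucleotide variant. pos is 1-based (VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str = ""

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"SNV {self.chrom}:{self.pos} ref/alt must be single A/C/G/T")
        if self.ref == self.alt:
            raise ValueError(f"SNV {self.chrom}:{self.pos} ref == alt ({self.ref})")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass
class CdsModel:
    """Spliced coding sequence of one mRNA.

    ``segments`` are 0-based half-open genomic intervals in transcript
    (5'->3') order; for minus-strand genes that is descending genomic order.
    """

    cds_id: str
    seq_id: str
    strand: str
    segments: tuple[tuple[int, int], ...]
    spliced_seq: str = ""
    partial: bool = False

    @property
    def codon_count(self) -> int:
        return len(self.spliced_seq) // 3

    @property
    def complete(self) -> bool:
        s = self.spliced_seq
        return bool(s) and len(s) % 3 == 0 and s.startswith("ATG") and not self.partial

    def genomic_to_cds(self, pos0: int) -> int | None:
        """Map a 0-based genomic position to a 1-based CDS position.

        Returns None when the position is not inside any CDS segment.
        """
        offset = 0
        for start, end in self.segments:
            if start <= pos0 < end:
                if self.strand == "+":
                    return offset + (pos0 - start) + 1
                return offset + (end - 1 - pos0) + 1
            offset += end - start
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Map a 1-based CDS position to a 0-based genomic position."""
        if not 1 <= cds_pos <= sum(e - s for s, e in self.segments):
            raise ValueError(f"CDS position {cds_pos} out of range for {self.cds_id}")
        remaining = cds_pos - 1
        for start, end in self.segments:
            seg_len = end - start
            if remaining < seg_len:
                if self.strand == "+":
                    return start + remaining
                return end - 1 - remaining
            remaining -= seg_len
        raise AssertionError("unreachable")


@dataclass
class GenomeAnnotation:
    """Parsed gene models: raw features plus one CdsModel per mRNA."""

    features: list[FeatureRecord]
    cds_models: dict[str, CdsModel]
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_genome(path: str | Path) -> dict[str, SequenceRecord]:
    """Load a FASTA reference into ``{id: SequenceRecord}`` (uppercased).

    A small validating reader so that malformed headers and illegal
    characters are reported with their line number; duplicate ids are
    rejected.
    """
    path = Path(path)
    records: dict[str, SequenceRecord] = {}
    current_id: str | None = None
    chunks: list[str] = []

    def _flush(line_no: int) -> None:
        nonlocal current_id, chunks
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{line_no}: record {current_id!r} has no sequence")
        records[current_id] = SequenceRecord(current_id, seq)
        current_id, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush(line_no)
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{line_no}: empty FASTA header")
                rec_id = header.split()[0]
                if rec_id in records:
                    raise FormatError(f"{path}:{line_no}: duplicate sequence id {rec_id!r}")
                current_id = rec_id
            else:
                if current_id is None:
                    raise FormatError(f"{path}:{line_no}: sequence data before first header")
                chunk = line.strip().upper()
                bad = set(chunk) - REF_ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}:{line_no}: illegal character(s) {sorted(bad)} in sequence"
                    )
                chunks.append(chunk)
        _flush(line_no if current_id is not None else 0)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_genome(records: Mapping[str, SequenceRecord] | Iterable[SequenceRecord],
                 path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns, in input order."""
    if isinstance(records, Mapping):
        records = records.values()
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def load_reads(path: str | Path) -> list[ReadRecord]:
    """Load Phred+33 FASTQ reads (uppercased; ambiguity codes rejected)."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            ReadRecord(
                id=rec.id,
                seq=str(rec.seq).upper(),
                qual=tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_reads(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def load_snvs(path: str | Path, sample: str, level: str = "DNA"):
    """Load the SNVs of a VCF into an :class:`~bedit.snv_triage.SnvSet`.

    Multi-allelic rows are split; indels and multi-nucleotide variants are
    dropped (the drop count is logged and kept on the returned set).
    """
    import pysam

    from .snv_triage import SnvSet

    records: list[SnvRecord] = []
    seen: set[tuple[str, int, str, str]] = set()
    dropped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for row in vcf.fetch() if vcf.index is not None else vcf:
            if row.chrom is None or row.pos is None or row.ref is None:
                raise FormatError(f"{path}: record missing CHROM/POS/REF")
            if not row.alts:
                raise FormatError(f"{path}:{row.chrom}:{row.pos}: record missing ALT")
            ref = row.ref.upper()
            for alt in row.alts:
                alt = alt.upper()
                if len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES:
                    rec = SnvRecord(row.chrom, row.pos, ref, alt, sample)
                    if rec.key not in seen:
                        seen.add(rec.key)
                        records.append(rec)
                else:
                    dropped += 1
    if dropped:
        log.info("load_snvs(%s): dropped %d non-SNV allele(s)", path, dropped)
    return SnvSet(sample=sample, records=records, level=level, dropped=dropped)


def write_snvs(snvs, path: str | Path) -> None:
    """Write an SnvSet as a minimal sites-only VCF v4.2 (input order)."""
    contigs: list[str] = []
    for rec in snvs.records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=bedit sample={snvs.sample} level={snvs.level}\n")
        for chrom in sorted(contigs):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in snvs.records:
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def load_features(path: str | Path,
                  genome: Mapping[str, SequenceRecord] | None = None) -> GenomeAnnotation:
    """Parse a GFF3 into FeatureRecords and one CdsModel per mRNA.

    When ``genome`` is given the spliced CDS sequence of each mRNA is
    extracted (reverse-complemented for minus-strand genes) and frame
    consistency is checked: a total CDS length not divisible by 3, a
    missing ATG, or a phase column inconsistent with the cumulative length
    each produce a recorded warning, not an error. A CDS feature without a
    Parent is an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[FeatureRecord] = []
    warnings: list[str] = []
    cds_by_parent: dict[str, list] = {}
    mrna_strand: dict[str, tuple[str, str]] = {}

    for f in db.all_features():
        if f.featuretype not in FeatureRecord.VALID_TYPES:
            continue
        parents = f.attributes.get("Parent", [])
        if f.featuretype == "CDS" and not parents:
            raise FormatError(f"{path}: CDS at {f.seqid}:{f.start}-{f.end} has no Parent")
        rec = FeatureRecord(
            seq_id=f.seqid,
            type=f.featuretype,
            start=f.start,
            end=f.end,
            strand=f.strand if f.strand in "+-" else "+",
            phase=str(f.frame) if f.frame is not None else ".",
            parent=parents[0] if parents else "",
            feature_id=f.id or "",
        )
        features.append(rec)
        if rec.type == "mRNA":
            mrna_strand[rec.feature_id] = (rec.seq_id, rec.strand)
        elif rec.type == "CDS":
            cds_by_parent.setdefault(rec.parent, []).append(rec)

    cds_models: dict[str, CdsModel] = {}
    for mrna_id, segs in cds_by_parent.items():
        seq_id, strand = mrna_strand.get(mrna_id, (segs[0].seq_id, segs[0].strand))
        ordered = sorted(segs, key=lambda r: r.start0, reverse=(strand == "-"))
        intervals = [(r.start0, r.end0) for r in ordered]
        for (s1, e1), (s2, e2) in zip(sorted(intervals), sorted(intervals)[1:]):
            if s2 < e1:
                raise FormatError(
                    f"{path}: CDS segments of {mrna_id} overlap ({s1}-{e1} vs {s2}-{e2})"
                )
        spliced = ""
        if genome is not None:
            if seq_id not in genome:
                raise FormatError(f"{path}: {mrna_id} references unknown sequence {seq_id!r}")
            chrom_seq = genome[seq_id].seq
            parts = []
            for s, e in intervals:
                frag = chrom_seq[s:e]
                parts.append(reverse_complement(frag) if strand == "-" else frag)
            spliced = "".join(parts)
        total = sum(e - s for s, e in intervals)
        partial = False
        if total % 3 != 0:
            partial = True
            warnings.append(f"{mrna_id}: total CDS length {total} not divisible by 3")
        if spliced and total % 3 == 0 and not spliced.startswith("ATG"):
            warnings.append(f"{mrna_id}: spliced CDS does not begin with ATG")
        # phase column check: expected phase from cumulative upstream length
        cum = 0
        for rec, (s, e) in zip(ordered, intervals):
            expected = (3 - cum % 3) % 3
            if rec.phase not in (".", str(expected)):
                warnings.append(
                    f"{mrna_id}: CDS segment {rec.start}-{rec.end} phase {rec.phase} "
                    f"inconsistent with cumulative length (expected {expected})"
                )
            cum += e - s
        cds_models[mrna_id] = CdsModel(
            cds_id=mrna_id, seq_id=seq_id, strand=strand,
            segments=tuple(intervals), spliced_seq=spliced, partial=partial,
        )
    for msg in warnings:
        log.warning("load_features(%s): %s", path, msg)
    return GenomeAnnotation(features=features, cds_models=cds_models, warnings=warnings)


def write_features(features: Iterable[FeatureRecord], path: str | Path) -> None:
    """Write FeatureRecords as GFF3 in input order."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = []
            if f.feature_id:
                attrs.append(f"ID={f.feature_id}")
            if f.parent:
                attrs.append(f"Parent={f.parent}")
            fh.write(
                "\t".join(
                    [
                        f.seq_id, "bedit", f.type, str(f.start), str(f.end),
                        ".", f.strand, f.phase, ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )
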