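"""Quantification of base-editing outcomes from amplicon reads.

Reads are globally aligned to the amplicon (affine gap penalties,
CRISPResso-style), tallied into a per-position nucleotide matrix, and
summarised as:

* per-editable-position efficiency — percent of eligible reads carrying
  the converted base at that protospacer position;
* site efficiency — percent of aligned reads with at least one window
  conversion (the read-level statistic used for reporting editing
  efficiency of a target site);
* an allele table over the protospacer +/- a pad, with edit labels such
  as ``A4G;A6G`` (protospacer coordinates, strand-oriented bases);
* a sample classification: unedited / homogeneous / chimeric.

Filtering: reads whose global identity falls below ``min_match_frac``
are discarded (``low_identity``); reads with an indel overlapping the
quantification window are excluded from substitution statistics and
tallied separately (``window_indel``) — an adenine base editor is not
expected to create indels, so these are candidate Cas-independent
events, not edits. Bases with Phred < ``min_phred`` at an editable
position drop the read from that position's numerator *and* denominator,
so per-position denominators can differ.

Percentages are reported to one decimal, rounded half-up, matching the
convention of reporting e.g. 99.9%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from Bio import Align

from .editor_model import EditorProfile, GuideCandidate
from .seqio import CdsModel, ReadRecord, reverse_complement

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def round_half_up(x: float | Decimal, decimals: int = 1) -> float:
    """Round half away from zero at a decimal count (0.05 -> 0.1)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AlignConfig:
    """Global-alignment scoring (exposed because no canonical values exist)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    min_phred: int = 20


@dataclass
class AmpliconTarget:
    """An amplicon with its guide (guide coordinates relative to the amplicon)."""

    amplicon_seq: str
    guide: GuideCandidate
    profile: EditorProfile

    def __post_init__(self) -> None:
        g = self.guide
        frag = self.amplicon_seq[g.start:g.end]
        oriented = frag if g.strand == "+" else reverse_complement(frag)
        if oriented != g.protospacer:
            raise ValueError(
                "guide protospacer does not occur in the amplicon at its stated coordinates"
            )

    def editable_amplicon_positions(self) -> list[tuple[int, int, str]]:
        """(protospacer position, amplicon 0-based position, forward edited base)."""
        g, prof = self.guide, self.profile
        edited_fwd = prof.edit_to if g.strand == "+" else _COMP1[prof.edit_to]
        return [(p, g.forward_position(p), edited_fwd) for p in g.editable_positions]


@dataclass
class PositionProfile:
    """Per-amplicon-position base counts from aligned reads."""

    amplicon_seq: str
    counts: dict[str, np.ndarray]  # A,C,G,T,N and "del" arrays of length L
    insertion_start: np.ndarray
    aligned_reads: int
    discarded: Counter
    # per aligned read: base row over the amplicon ('-' = deletion) and quals
    rows: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)

    @property
    def input_reads(self) -> int:
        return self.aligned_reads + sum(self.discarded.values())


@dataclass
class AlleleRow:
    allele_seq: str
    read_count: int
    frequency: float
    edit_label: str
    consequence: str = ""


@dataclass
class AlleleTable:
    window: tuple[int, int]  # amplicon 0-based half-open quantification window
    rows: list[AlleleRow]
    aligned_reads: int


@dataclass
class EditingReport:
    per_position: dict[int, float]  # protospacer position -> percent
    per_position_denominator: dict[int, int]
    site_efficiency: float
    classification: str
    aligned_reads: int
    discarded: dict[str, int]


def _best_orientation(aligner: Align.PairwiseAligner, amplicon: str,
                      read: ReadRecord) -> tuple[Align.Alignment, str, tuple[int, ...]]:
    fwd = aligner.align(amplicon, read.seq)
    rc_seq = reverse_complement(read.seq)
    rev = aligner.align(amplicon, rc_seq)
    if rev.score > fwd.score:
        return rev[0], rc_seq, tuple(reversed(read.qual))
    return fwd[0], read.seq, read.qual


def align_reads(reads: Sequence[ReadRecord], target: AmpliconTarget,
                min_match_frac: float = 0.75,
                config: AlignConfig = AlignConfig()) -> PositionProfile:
    """Globally align reads to the amplicon and tally per-position bases.

    Orientation is auto-detected by best-strand alignment score; reverse
    reads are complemented before tallying. The quantification window used
    for the indel filter is the protospacer interval.
    """
    if not reads:
        raise ValueError("empty read pool")
    amplicon = target.amplicon_seq
    L = len(amplicon)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.match
    aligner.mismatch_score = config.mismatch
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend

    counts = {b: np.zeros(L, dtype=np.int64) for b in "ACGTN"}
    counts["del"] = np.zeros(L, dtype=np.int64)
    insertion_start = np.zeros(L, dtype=np.int64)
    discarded: Counter = Counter()
    rows: list[tuple[str, tuple[int, ...]]] = []
    win_lo, win_hi = target.guide.start, target.guide.end

    for read in reads:
        aln, seq, qual = _best_orientation(aligner, amplicon, read)
        blocks = aln.aligned  # ((t_blocks), (q_blocks))
        row = ["-"] * L
        row_q: list[int] = [-1] * L
        matches = 0
        ins_positions: list[int] = []
        prev_t_end = None
        for (t0, t1), (q0, q1) in zip(blocks[0], blocks[1]):
            if prev_t_end is not None and t0 == prev_t_end:
                # read bases consumed with no amplicon advance: insertion
                ins_positions.append(t0 if t0 < L else L - 1)
            for t, q in zip(range(t0, t1), range(q0, q1)):
                row[t] = seq[q]
                row_q[t] = qual[q]
                if seq[q] == amplicon[t]:
                    matches += 1
            prev_t_end = t1
        identity = matches / max(L, len(seq))
        if identity < min_match_frac:
            discarded["low_identity"] += 1
            continue
        window_del = any(row[t] == "-" for t in range(win_lo, win_hi))
        window_ins = any(win_lo < t < win_hi for t in ins_positions)
        if window_del or window_ins:
            discarded["window_indel"] += 1
            continue
        for t in range(L):
            base = row[t]
            if base == "-":
                counts["del"][t] += 1
            else:
                counts.setdefault(base, np.zeros(L, dtype=np.int64))
                counts[base][t] += 1
        for t in ins_positions:
            insertion_start[t] += 1
        rows.append(("".join(row), tuple(row_q)))

    return PositionProfile(
        amplicon_seq=amplicon, counts=counts, insertion_start=insertion_start,
        aligned_reads=len(rows), discarded=discarded, rows=rows,
    )


def editing_efficiency(profile: PositionProfile, target: AmpliconTarget,
                       min_phred: int = 20,
                       min_allele_frac: float = 0.05) -> EditingReport:
    """Per-position and read-level (site) editing efficiencies, in percent.

    Site efficiency is the percentage of aligned reads carrying the target
    conversion at >=1 editable window position — the read-counting
    statistic, not a per-event rate.
    """
    if profile.aligned_reads == 0:
        raise ValueError("no aligned reads")
    editable = target.editable_amplicon_positions()
    per_pos: dict[int, float] = {}
    per_den: dict[int, int] = {}
    site_hits = 0
    for row, quals in profile.rows:
        if any(
            row[amp] == edited and quals[amp] >= min_phred
            for (_, amp, edited) in editable
        ):
            site_hits += 1
    for proto_pos, amp_pos, edited_base in editable:
        num = den = 0
        for row, quals in profile.rows:
            if row[amp_pos] == "-" or quals[amp_pos] < min_phred:
                continue
            den += 1
            if row[amp_pos] == edited_base:
                num += 1
        per_den[proto_pos] = den
        per_pos[proto_pos] = round_half_up(100 * num / den, 1) if den else 0.0
    site = round_half_up(100 * site_hits / profile.aligned_reads, 1)
    table = build_allele_table(profile, target)
    classification = classify_sample(table, min_allele_frac=min_allele_frac)
    return EditingReport(
        per_position=per_pos, per_position_denominator=per_den,
        site_efficiency=site, classification=classification,
        aligned_reads=profile.aligned_reads, discarded=dict(profile.discarded),
    )


def _edit_label(target: AmpliconTarget, allele: str, window: tuple[int, int]) -> str:
    """Label window diffs in protospacer coordinates, e.g. ``A4G;A6G``."""
    g = target.guide
    amplicon = target.amplicon_seq
    lo, hi = window
    diffs = []
    for amp in range(lo, hi):
        a = allele[amp - lo]
        r = amplicon[amp]
        if a in "-N" or a == r:
            continue
        if g.start <= amp < g.end:
            if g.strand == "+":
                proto_pos, ref_b, alt_b = amp - g.start + 1, r, a
            else:
                proto_pos = g.end - amp
                ref_b, alt_b = _COMP1[r], _COMP1[a]
            diffs.append((proto_pos, f"{ref_b}{proto_pos}{alt_b}"))
    if not diffs:
        wt = allele == amplicon[lo:hi]
        return "WT" if wt else "other"
    diffs.sort()
    return ";".join(lab for _, lab in diffs)


def build_allele_table(profile: PositionProfile, target: AmpliconTarget,
                       window_pad: int = 5,
                       cds: CdsModel | None = None,
                       amplicon_offset: int = 0) -> AlleleTable:
    """Tabulate read alleles over the protospacer +/- ``window_pad``.

    With a CdsModel attached (``amplicon_offset`` placing the amplicon on
    the model's chromosome) each allele also receives its protein-level
    consequence label.
    """
    if profile.aligned_reads == 0:
        raise ValueError("no aligned reads")
    g = target.guide
    lo = max(0, g.start - window_pad)
    hi = min(len(target.amplicon_seq), g.end + window_pad)
    counter: Counter = Counter()
    for row, _ in profile.rows:
        counter[row[lo:hi]] += 1
    rows = []
    for allele, count in counter.items():
        label = _edit_label(target, allele, (lo, hi))
        consequence = ""
        if cds is not None and label not in ("WT", "other"):
            consequence = _allele_consequence(target, allele, (lo, hi), cds, amplicon_offset)
        rows.append(
            AlleleRow(
                allele_seq=allele, read_count=count,
                frequency=count / profile.aligned_reads,
                edit_label=label, consequence=consequence,
            )
        )
    rows.sort(key=lambda r: (-r.read_count, r.allele_seq))
    return AlleleTable(window=(lo, hi), rows=rows, aligned_reads=profile.aligned_reads)


def _allele_consequence(target: AmpliconTarget, allele: str,
                        window: tuple[int, int], cds: CdsModel,
                        amplicon_offset: int) -> str:
    from .consequence import combined_label, predict_consequence

    lo, hi = window
    edits = []
    for amp in range(lo, hi):
        a = allele[amp - lo]
        r = target.amplicon_seq[amp]
        if a in "-N" or a == r:
            continue
        genomic = amplicon_offset + amp
        cds_pos = cds.genomic_to_cds(genomic)
        if cds_pos is None:
            continue
        if cds.strand == "+":
            edits.append((cds_pos, r, a))
        else:
            edits.append((cds_pos, _COMP1[r], _COMP1[a]))
    if not edits:
        return "noncoding"
    return combined_label(predict_consequence(cds, edits))


def classify_sample(table: AlleleTable, min_allele_frac: float = 0.05) -> str:
    """unedited / homogeneous / chimeric from the allele spectrum.

    Unedited: no non-reference allele at or above ``min_allele_frac``.
    Homogeneous: exactly one such allele, itself at >= 90% of reads.
    Anything else (multiple edited alleles, or one well below fixation)
    is chimeric — the dominant outcome in first-generation regenerants.
    """
    if not table.rows:
        raise ValueError("empty allele table")
    edited = [r for r in table.rows if r.edit_label != "WT" and r.frequency >= min_allele_frac]
    if not edited:
        return "unedited"
    if len(edited) == 1 and edited[0].frequency >= 0.9:
        return "homogeneous"
    return "chimeric"
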