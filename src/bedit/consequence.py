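"""Codon and amino-acid consequences of base edits.

Maps edits expressed in CDS coordinates (1-based from the A of the start
codon) onto codons, translates under the standard nuclear genetic code,
and classifies the outcome. Bystander enumeration walks every non-empty
subset of a guide's editable window positions and reports the combined
protein-level label in ``K53G+S78G`` style (reference residue, 1-based
codon index, alternate residue).

Edits on minus-strand genes are handled by orientation: a T->C change on
the genomic forward strand is an A->G change on the transcript, so the
amino-acid call is independent of which strand the gene sits on.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .editor_model import EditorProfile, GuideCandidate
from .seqio import CdsModel, _COMPLEMENT

# standard nuclear code, with * for stop
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


class ReferenceMismatchError(ValueError):
    """An edit's from_base disagrees with the CDS sequence (stale coordinates)."""


def translate_codon(codon: str) -> str:
    """Single-letter amino acid (or *) for a DNA codon."""
    try:
        return CODON_TABLE[codon.upper()]
    except KeyError:
        raise ValueError(f"not a DNA codon: {codon!r}") from None


@dataclass(frozen=True)
class CodonConsequence:
    cds_id: str
    codon_index: int  # 1-based
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    klass: str  # synonymous | missense | nonsense | stop_loss | start_loss | noncoding

    @property
    def label(self) -> str:
        """Display label, e.g. ``K53G``; synonymous edits show e.g. ``A12A``."""
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


def map_to_codon(cds: CdsModel, cds_position: int) -> tuple[int, int]:
    """1-based codon index and offset-in-codon (1..3) of a CDS position."""
    n = len(cds.spliced_seq)
    if not 1 <= cds_position <= n:
        raise ValueError(f"CDS position {cds_position} out of range 1..{n}")
    return (cds_position - 1) // 3 + 1, (cds_position - 1) % 3 + 1


def _classify(codon_index: int, ref_aa: str, alt_aa: str) -> str:
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stop_loss"
    if codon_index == 1 and ref_aa == "M":
        return "start_loss"
    return "missense"


def predict_consequence(cds: CdsModel,
                        edits: Iterable[tuple[int, str, str]]) -> list[CodonConsequence]:
    """Consequences of a set of ``(cds_position, from_base, to_base)`` edits.

    Edits sharing a codon are applied jointly before translation; output
    is one entry per affected codon, ordered by codon index, and is
    invariant under any permutation of the input.
    """
    edits = list(edits)
    seq = cds.spliced_seq
    by_codon: dict[int, list[tuple[int, str]]] = {}
    for pos, from_base, to_base in edits:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"CDS position {pos} out of range for {cds.cds_id}")
        if seq[pos - 1] != from_base.upper():
            raise ReferenceMismatchError(
                f"{cds.cds_id}: expected {from_base} at CDS position {pos}, "
                f"found {seq[pos - 1]}"
            )
        idx, offset = map_to_codon(cds, pos)
        by_codon.setdefault(idx, []).append((offset, to_base.upper()))
    out: list[CodonConsequence] = []
    for idx in sorted(by_codon):
        ref_codon = seq[(idx - 1) * 3: idx * 3]
        if len(ref_codon) < 3:
            # trailing partial codon of an incomplete model
            out.append(
                CodonConsequence(cds.cds_id, idx, ref_codon, ref_codon, "?", "?", "noncoding")
            )
            continue
        alt = list(ref_codon)
        for offset, to_base in by_codon[idx]:
            alt[offset - 1] = to_base
        alt_codon = "".join(alt)
        ref_aa = translate_codon(ref_codon)
        alt_aa = translate_codon(alt_codon)
        out.append(
            CodonConsequence(
                cds.cds_id, idx, ref_codon, alt_codon, ref_aa, alt_aa,
                _classify(idx, ref_aa, alt_aa),
            )
        )
    return out


def combined_label(consequences: Sequence[CodonConsequence]) -> str:
    """Join per-codon labels with '+', e.g. ``K53G+S78G``; '' when empty."""
    return "+".join(c.label for c in consequences)


def candidate_cds_edits(candidate: GuideCandidate, cds: CdsModel,
                        profile: EditorProfile,
                        positions: Iterable[int]) -> list[tuple[int, str, str]]:
    """Translate protospacer window positions into CDS-coordinate edits.

    Positions whose genomic locus falls outside the CDS are dropped
    (they are noncoding for consequence purposes). The conversion is
    applied in protospacer orientation and re-oriented to the transcript
    strand.
    """
    edits = []
    for p in positions:
        g = candidate.forward_position(p)
        cds_pos = cds.genomic_to_cds(g)
        if cds_pos is None:
            continue
        # forward-strand representation of the conversion
        if candidate.strand == "+":
            f_from, f_to = profile.edit_from, profile.edit_to
        else:
            f_from = profile.edit_from.translate(_COMPLEMENT)
            f_to = profile.edit_to.translate(_COMPLEMENT)
        # transcript-strand representation
        if cds.strand == "+":
            t_from, t_to = f_from, f_to
        else:
            t_from = f_from.translate(_COMPLEMENT)
            t_to = f_to.translate(_COMPLEMENT)
        edits.append((cds_pos, t_from, t_to))
    return edits


def enumerate_bystanders(candidate: GuideCandidate, cds: CdsModel,
                         profile: EditorProfile,
                         max_positions: int = 6) -> list[tuple[tuple[int, ...], str]]:
    """Protein outcome of every non-empty subset of editable positions.

    Returns ``2**k - 1`` entries of ``(subset, label)`` for k editable
    positions; subsets whose edits all fall outside the CDS are labelled
    ``noncoding``. Refuses guides with more than ``max_positions``
    editable bases (the enumeration is exponential).
    """
    k = len(candidate.editable_positions)
    if k == 0:
        return []
    if k > max_positions:
        raise ValueError(
            f"guide has {k} editable positions > cap {max_positions}; "
            "raise max_positions to enumerate anyway"
        )
    if not any(
        cds.genomic_to_cds(candidate.forward_position(p)) is not None
        for p in candidate.editable_positions
    ) and all(
        cds.genomic_to_cds(g) is None for g in range(candidate.start, candidate.end)
    ):
        raise ValueError(f"guide {candidate.guide_id} does not overlap CDS {cds.cds_id}")
    out: list[tuple[tuple[int, ...], str]] = []
    for r in range(1, k + 1):
        for subset in combinations(candidate.editable_positions, r):
            cds_edits = candidate_cds_edits(candidate, cds, profile, subset)
            if not cds_edits:
                out.append((subset, "noncoding"))
                continue
            cons = predict_consequence(cds, cds_edits)
            out.append((subset, combined_label(cons)))
    return out
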