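"""Base-editor chemistries and protospacer scanning.

An :class:`EditorProfile` describes a base editor parametrically: the PAM
pattern and which side of the protospacer it sits on, the protospacer
length, the deamination window in protospacer coordinates (counted 1..L
from the 5' end, so for a Cas9-style editor the PAM occupies positions
L+1..L+3), and the conversion chemistry (A->G for an adenine base editor,
C->T for a cytosine base editor).

Built-in profiles model the editors characterised in cotton:

* ``GhABE8e``     — TadA8e(V106W)-nCas9, NGG 3' PAM, window A4–A10.
* ``GhABE8e-wide``— same editor with the reported extended A4–A12 window.
* ``GhABE7.10``   — earlier TadA7.10 fusion, active only at A5.
* ``GhABE8e-dCpf1`` — TadA8e-dLbCas12a, TTTV 5' PAM, 23-nt protospacer;
  window 8–14 is provisional (taken from ABE8e–dCas12a convention, the
  cotton work does not report one).
* ``CBE``         — a generic cytosine base editor (NGG, window 4–8, C->T).

Scanning reports every protospacer+PAM occurrence on both strands of a
reference; candidates carry their *editable positions*: window positions
whose protospacer base equals the editor's substrate base.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .seqio import BASES, SequenceRecord, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ConfigurationError(ValueError):
    """An editor profile or ranking configuration is malformed."""


def pam_matches(pam_seq: str, pattern: str) -> bool:
    """True when every PAM base is compatible with the IUPAC pattern.

    An ambiguous genome base matches only if every base it could be is
    allowed by the pattern (so genome N matches pattern N but not NGG's G).
    """
    if len(pam_seq) != len(pattern):
        return False
    for base, pat in zip(pam_seq, pattern):
        allowed = IUPAC[pat]
        possible = IUPAC.get(base)
        if possible is None or not set(possible) <= set(allowed):
            return False
    return True


@dataclass(frozen=True)
class EditorProfile:
    """Parametric description of a base editor."""

    name: str
    pam_pattern: str
    pam_side: str  # "three_prime" | "five_prime"
    protospacer_len: int
    window: tuple[int, int]  # inclusive, protospacer coordinates 1..L
    edit_from: str
    edit_to: str

    def __post_init__(self) -> None:
        if self.pam_side not in ("three_prime", "five_prime"):
            raise ConfigurationError(f"pam_side must be three_prime/five_prime, got {self.pam_side!r}")
        if not self.pam_pattern or any(c not in IUPAC for c in self.pam_pattern):
            raise ConfigurationError(f"malformed PAM pattern {self.pam_pattern!r}")
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.protospacer_len):
            raise ConfigurationError(
                f"window {self.window} outside 1..{self.protospacer_len}"
            )
        if self.edit_from not in BASES or self.edit_to not in BASES:
            raise ConfigurationError("edit_from/edit_to must be single A/C/G/T bases")
        if self.edit_from == self.edit_to:
            raise ConfigurationError("edit_from equals edit_to")

    @property
    def pam_len(self) -> int:
        return len(self.pam_pattern)


BUILTIN_PROFILES: dict[str, EditorProfile] = {
    p.name: p
    for p in [
        EditorProfile("GhABE8e", "NGG", "three_prime", 20, (4, 10), "A", "G"),
        EditorProfile("GhABE8e-wide", "NGG", "three_prime", 20, (4, 12), "A", "G"),
        EditorProfile("GhABE7.10", "NGG", "three_prime", 20, (5, 5), "A", "G"),
        EditorProfile("GhABE8e-dCpf1", "TTTV", "five_prime", 23, (8, 14), "A", "G"),
        EditorProfile("CBE", "NGG", "three_prime", 20, (4, 8), "C", "T"),
    ]
}


def get_profile(name: str) -> EditorProfile:
    try:
        return BUILTIN_PROFILES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown profile {name!r}; built-ins: {sorted(BUILTIN_PROFILES)}"
        ) from None


@dataclass
class GuideCandidate:
    """A protospacer hit on a reference.

    ``start``/``end`` delimit the protospacer on the forward strand
    (0-based half-open); ``protospacer`` and ``pam`` are strand-oriented
    5'->3'. ``editable_positions`` are 1-based protospacer coordinates
    inside the editing window whose base is the editor's substrate.
    """

    target_id: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    profile_name: str
    editable_positions: tuple[int, ...]
    score: float | None = None

    @property
    def guide_id(self) -> str:
        return f"{self.target_id}:{self.start}:{self.strand}"

    def forward_position(self, proto_pos: int) -> int:
        """Forward-strand 0-based coordinate of a 1-based protospacer position."""
        if not 1 <= proto_pos <= len(self.protospacer):
            raise ValueError(f"protospacer position {proto_pos} out of range")
        if self.strand == "+":
            return self.start + proto_pos - 1
        return self.end - proto_pos


def _footprint(profile: EditorProfile, start: int, strand: str) -> tuple[int, int]:
    """Forward-strand interval of the PAM for a protospacer at [start, start+L)."""
    L, P = profile.protospacer_len, profile.pam_len
    if (profile.pam_side == "three_prime") == (strand == "+"):
        return start + L, start + L + P  # PAM right of the protospacer
    return start - P, start  # PAM left of the protospacer


def scan_guides(ref: SequenceRecord, profile: EditorProfile,
                require_editable: bool = False) -> list[GuideCandidate]:
    """Report every protospacer+PAM occurrence on both strands of ``ref``.

    Protospacers containing ambiguity codes are skipped (a guide needs
    concrete bases). With ``require_editable`` candidates whose editing
    window holds no substrate base are suppressed. Output is sorted by
    (start, strand).
    """
    L, P = profile.protospacer_len, profile.pam_len
    if len(ref.seq) < L + P:
        return []  # nothing can fit; not an error
    lo, hi = profile.window
    seq = ref.seq
    n = len(seq)
    out: list[GuideCandidate] = []
    for strand in "+-":
        for start in range(0, n - L + 1):
            pam_s, pam_e = _footprint(profile, start, strand)
            if pam_s < 0 or pam_e > n:
                continue
            proto_fwd = seq[start:start + L]
            pam_fwd = seq[pam_s:pam_e]
            if strand == "+":
                proto, pam = proto_fwd, pam_fwd
            else:
                proto, pam = reverse_complement(proto_fwd), reverse_complement(pam_fwd)
            if set(proto) - BASES:
                continue
            if not pam_matches(pam, profile.pam_pattern):
                continue
            editable = tuple(
                p for p in range(lo, hi + 1) if proto[p - 1] == profile.edit_from
            )
            if require_editable and not editable:
                continue
            out.append(
                GuideCandidate(
                    target_id=ref.id, start=start, end=start + L, strand=strand,
                    protospacer=proto, pam=pam, profile_name=profile.name,
                    editable_positions=editable,
                )
            )
    out.sort(key=lambda c: (c.start, c.strand))
    return out


def apply_window_edits(candidate: GuideCandidate, positions: tuple[int, ...] | list[int],
                       profile: EditorProfile) -> str:
    """Apply the editor's conversion at chosen window positions.

    Returns the protospacer-length fragment in *forward-strand*
    orientation, differing from the reference exactly at the chosen
    positions. On a minus-strand guide an A->G conversion therefore
    surfaces as T->C on the forward strand.
    """
    if not positions:
        raise ValueError("positions must be a non-empty subset of editable_positions")
    bad = set(positions) - set(candidate.editable_positions)
    if bad:
        raise ValueError(
            f"position(s) {sorted(bad)} not in editable set {candidate.editable_positions}"
        )
    proto = list(candidate.protospacer)
    for p in positions:
        proto[p - 1] = profile.edit_to
    edited = "".join(proto)
    return edited if candidate.strand == "+" else reverse_complement(edited)


@dataclass(frozen=True)
class RankingConfig:
    """Weights for the heuristic guide score.

    The score rewards editable-window content, penalises a TTTT
    homopolymer (a U6 Pol-III terminator) and rewards a GC fraction in a
    workable range. The formula is a pragmatic default; no published
    scoring exists for these editors.
    """

    editable_weight: float = 1.0
    tttt_penalty: float = -2.0
    gc_bonus: float = 0.5
    gc_range: tuple[float, float] = (0.3, 0.7)
    # a guide with nothing to edit is useless whatever its composition, so
    # it must rank below every editable guide
    no_editable_penalty: float = -10.0


def score_guide(candidate: GuideCandidate, config: RankingConfig = RankingConfig()) -> float:
    score = config.editable_weight * len(candidate.editable_positions)
    if not candidate.editable_positions:
        score += config.no_editable_penalty
    if "TTTT" in candidate.protospacer:
        score += config.tttt_penalty
    gc = (candidate.protospacer.count("G") + candidate.protospacer.count("C")) / len(
        candidate.protospacer
    )
    if config.gc_range[0] <= gc <= config.gc_range[1]:
        score += config.gc_bonus
    return score


def rank_guides(candidates: list[GuideCandidate],
                config: RankingConfig = RankingConfig()) -> list[GuideCandidate]:
    """Deterministically order candidates by score (ties by start, strand)."""
    scored = [replace_score(c, score_guide(c, config)) for c in candidates]
    scored.sort(key=lambda c: (-c.score, c.start, c.strand))
    return scored


def replace_score(candidate: GuideCandidate, score: float) -> GuideCandidate:
    out = replace(candidate)
    out.score = score
    return out
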