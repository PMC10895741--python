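"""Genome/transcriptome SNV off-target triage.

The four-sample design: an *edited* plant (editor + guide), a
*vector_only* positive control (editor, no guide), a *negative*
tissue-culture control, and *wild_type*. SNVs seen in the negative or
wild-type samples are background and are subtracted (allele-aware: a
different alternate base at the same position is a different event);
the survivors are restricted to the editor-compatible classes (A>G and
T>C in forward-strand representation for an adenine deaminase, either
strand's deamination signature); those are intersected with predicted
off-target site footprints to separate guide-dependent from
guide-independent events, annotated by genomic region, and summarised.

Variants present at both the DNA and RNA level are flagged as
transcribed DNA variants rather than RNA off-targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .amplicon_quant import round_half_up
from .editor_model import EditorProfile
from .seqio import FeatureRecord, GenomeAnnotation, SnvRecord

SAMPLE_LABELS = ("edited", "vector_only", "negative", "wild_type")
REGION_CATEGORIES = (
    "exonic", "UTR", "intronic", "upstream2kb", "downstream2kb", "intergenic"
)

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SnvSet:
    """A named collection of SNVs from one sample at one level (DNA/RNA)."""

    sample: str
    records: list[SnvRecord]
    level: str = "DNA"
    dropped: int = 0

    def __post_init__(self) -> None:
        if self.level not in ("DNA", "RNA"):
            raise ValueError(f"level must be DNA or RNA, got {self.level!r}")
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError(f"SnvSet {self.sample!r} has duplicate records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def keys(self) -> set[tuple[str, int, str, str]]:
        return {r.key for r in self.records}


def subtract_background(target: SnvSet, controls: Iterable[SnvSet]) -> SnvSet:
    """Remove target records whose (chrom, pos, ref, alt) occur in any control."""
    controls = list(controls)
    for c in controls:
        if c.level != target.level:
            raise ValueError(
                f"cannot mix levels: target {target.level}, control {c.sample} {c.level}"
            )
    background: set = set()
    for c in controls:
        background |= c.keys
    kept = [r for r in target.records if r.key not in background]
    return SnvSet(sample=target.sample, records=kept, level=target.level)


def filter_editor_compatible(snvs: SnvSet, profile: EditorProfile) -> SnvSet:
    """Keep only the editor's deamination signatures.

    For an A->G editor these are A>G and T>C in forward-strand
    representation (deamination on either strand); for a C->T editor,
    C>T and G>A.
    """
    wanted = {
        (profile.edit_from, profile.edit_to),
        (_COMP1[profile.edit_from], _COMP1[profile.edit_to]),
    }
    kept = [r for r in snvs.records if (r.ref, r.alt) in wanted]
    return SnvSet(sample=snvs.sample, records=kept, level=snvs.level)


def intersect_predicted(snvs: SnvSet,
                        intervals: Mapping[str, Sequence[tuple[int, int]]]
                        ) -> tuple[list[SnvRecord], int]:
    """Records whose position falls inside a predicted-site footprint.

    ``intervals`` are 0-based half-open per chromosome (from
    ``offtarget_search.site_intervals``); an SNV overlaps when its 0-based
    position is inside an interval.
    """
    trees = {
        chrom: IntervalTree.from_tuples((lo, hi) for lo, hi in ivals if hi > lo)
        for chrom, ivals in intervals.items()
    }
    hits = [
        r for r in snvs.records
        if r.chrom in trees and trees[r.chrom].overlaps_point(r.pos0)
    ]
    return hits, len(hits)


class _RegionIndex:
    """Per-chromosome interval trees implementing the category priority."""

    def __init__(self, features: Sequence[FeatureRecord],
                 upstream_bp: int, downstream_bp: int) -> None:
        self.cds: dict[str, IntervalTree] = {}
        self.utr: dict[str, IntervalTree] = {}
        self.gene: dict[str, IntervalTree] = {}
        self.upstream: dict[str, IntervalTree] = {}
        self.downstream: dict[str, IntervalTree] = {}
        for f in features:
            if f.type in ("CDS", "exon") and f.type == "CDS":
                self._add(self.cds, f.seq_id, f.start0, f.end0)
            elif f.type in ("five_prime_UTR", "three_prime_UTR"):
                self._add(self.utr, f.seq_id, f.start0, f.end0)
            elif f.type == "gene":
                self._add(self.gene, f.seq_id, f.start0, f.end0)
                if f.strand == "+":
                    up = (f.start0 - upstream_bp, f.start0)
                    down = (f.end0, f.end0 + downstream_bp)
                else:
                    up = (f.end0, f.end0 + upstream_bp)
                    down = (f.start0 - downstream_bp, f.start0)
                self._add(self.upstream, f.seq_id, max(0, up[0]), up[1])
                self._add(self.downstream, f.seq_id, max(0, down[0]), down[1])

    @staticmethod
    def _add(trees: dict[str, IntervalTree], chrom: str, lo: int, hi: int) -> None:
        if hi > lo:
            trees.setdefault(chrom, IntervalTree()).addi(lo, hi)

    def category(self, chrom: str, pos0: int) -> str:
        def hit(trees: dict[str, IntervalTree]) -> bool:
            t = trees.get(chrom)
            return t is not None and t.overlaps_point(pos0)

        if hit(self.cds):
            return "exonic"
        if hit(self.utr):
            return "UTR"
        if hit(self.gene):
            return "intronic"
        if hit(self.upstream):
            return "upstream2kb"
        if hit(self.downstream):
            return "downstream2kb"
        return "intergenic"


def annotate_regions(snvs: SnvSet,
                     features: GenomeAnnotation | Sequence[FeatureRecord],
                     upstream_bp: int = 2000,
                     downstream_bp: int = 2000) -> dict[str, int]:
    """Assign each SNV exactly one region category and count them.

    Priority: exonic > UTR > intronic > upstream2kb > downstream2kb >
    intergenic (flanks strand-aware). All six categories appear in the
    result, zero-filled.
    """
    feats = features.features if isinstance(features, GenomeAnnotation) else features
    index = _RegionIndex(feats, upstream_bp, downstream_bp)
    counts = {c: 0 for c in REGION_CATEGORIES}
    for r in snvs.records:
        counts[index.category(r.chrom, r.pos0)] += 1
    return counts


def cross_level_shared(dna: SnvSet, rna: SnvSet) -> int:
    """Count variants present at both levels (transcribed DNA variants)."""
    return len(dna.keys & rna.keys)


def percent_of_total(filtered: int, total: int, decimals: int = 2) -> float | None:
    """100 * filtered / total, half-up at the configured decimals.

    Returns None (percent undefined) on a zero total. Computed in exact
    decimal arithmetic so printed ratios reproduce faithfully.
    """
    if total == 0:
        return None
    pct = Decimal(filtered) * 100 / Decimal(total)
    return round_half_up(pct, decimals)


@dataclass
class TriageReport:
    """Counts and category breakdowns from the off-target pipeline."""

    level: str
    total_snvs: dict[str, int]
    filtered_snvs: dict[str, int]
    percent_of_total: dict[str, float | None]
    overlap_with_predicted: int = 0
    shared_between_samples: int = 0
    region_category_counts: dict[str, int] = field(default_factory=dict)
    dna_rna_shared: int = 0

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "total_snvs": self.total_snvs,
            "filtered_snvs": self.filtered_snvs,
            "percent_of_total": self.percent_of_total,
            "overlap_with_predicted": self.overlap_with_predicted,
            "shared_between_samples": self.shared_between_samples,
            "region_category_counts": self.region_category_counts,
            "dna_rna_shared": self.dna_rna_shared,
        }


def summarize(level: str,
              totals: Mapping[str, int],
              filtered: Mapping[str, int],
              overlap_with_predicted: int = 0,
              shared_between_samples: int = 0,
              region_category_counts: Mapping[str, int] | None = None,
              dna_rna_shared: int = 0,
              decimals: int | None = None) -> TriageReport:
    """Assemble a TriageReport; default rounding is 2 dp for DNA, 1 for RNA."""
    if decimals is None:
        decimals = 2 if level == "DNA" else 1
    pct = {
        sample: percent_of_total(filtered.get(sample, 0), totals[sample], decimals)
        for sample in totals
    }
    return TriageReport(
        level=level,
        total_snvs=dict(totals),
        filtered_snvs=dict(filtered),
        percent_of_total=pct,
        overlap_with_predicted=overlap_with_predicted,
        shared_between_samples=shared_between_samples,
        region_category_counts=dict(region_category_counts or {}),
        dna_rna_shared=dna_rna_shared,
    )


def run_triage(snv_sets: Mapping[str, SnvSet],
               profile: EditorProfile,
               site_footprints: Mapping[str, Sequence[tuple[int, int]]] | None = None,
               annotation: GenomeAnnotation | Sequence[FeatureRecord] | None = None,
               upstream_bp: int = 2000,
               downstream_bp: int = 2000,
               rna_sets: Mapping[str, SnvSet] | None = None) -> TriageReport:
    """Run the full pipeline on one level's four-sample design.

    ``snv_sets`` must contain the labels edited, vector_only, negative and
    wild_type. Background subtraction uses negative + wild_type; the
    edited and vector_only survivors are filtered to editor-compatible
    classes; the edited survivors are intersected with predicted-site
    footprints and region-annotated.
    """
    missing = set(SAMPLE_LABELS) - set(snv_sets)
    if missing:
        raise ValueError(f"missing sample(s): {sorted(missing)}")
    level = snv_sets["edited"].level
    controls = [snv_sets["negative"], snv_sets["wild_type"]]
    totals = {s: len(snv_sets[s]) for s in SAMPLE_LABELS}
    filtered_sets = {}
    for s in ("edited", "vector_only"):
        filtered_sets[s] = filter_editor_compatible(
            subtract_background(snv_sets[s], controls), profile
        )
    filtered = {s: len(f) for s, f in filtered_sets.items()}
    overlap = 0
    if site_footprints is not None:
        _, overlap = intersect_predicted(filtered_sets["edited"], site_footprints)
    shared = len(filtered_sets["edited"].keys & filtered_sets["vector_only"].keys)
    region_counts: dict[str, int] = {}
    if annotation is not None:
        region_counts = annotate_regions(
            filtered_sets["edited"], annotation, upstream_bp, downstream_bp
        )
    dna_rna = 0
    if rna_sets is not None:
        rna_controls = [rna_sets["negative"], rna_sets["wild_type"]]
        rna_filtered = filter_editor_compatible(
            subtract_background(rna_sets["edited"], rna_controls), profile
        )
        dna_rna = cross_level_shared(filtered_sets["edited"], rna_filtered)
    return summarize(
        level=level, totals=totals, filtered=filtered,
        overlap_with_predicted=overlap, shared_between_samples=shared,
        region_category_counts=region_counts, dna_rna_shared=dna_rna,
    )
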