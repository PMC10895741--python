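"""Synthetic fixtures with exact ground truth for every pipeline stage.

Three generators, each a closed-loop oracle — running the corresponding
pipeline on a generator's output must reproduce its truth ledger (exactly
in error-free designs, within binomial sampling bounds otherwise):

* :func:`simulate_genome` — a random genome carrying gene models with
  known spliced CDS sequences, one planted on-target guide site and
  planted off-target copies at chosen Hamming distances; written as
  FASTA + GFF3 + a JSON ledger.
* :func:`simulate_amplicon_reads` — an amplicon read pool with programmed
  per-position conversion rates (or a programmed allele mixture for
  chimera studies), optional uniform sequencing error, full per-read
  bookkeeping; written as FASTA + FASTQ + ledger.
* :func:`simulate_snv_design` — the four-sample SNV comparison (edited /
  vector_only / negative / wild_type): shared background variants present
  in all samples plus per-sample private variants with a controlled
  editor-compatible class fraction and optional per-region placement;
  written as four VCFs + ledger.

Determinism: a single integer seed; each generator draws from its own
``numpy`` Generator seeded with ``[seed, stream]`` so outputs are stable
and independent across generators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .amplicon_quant import AmpliconTarget
from .editor_model import EditorProfile, GuideCandidate, get_profile
from .seqio import (
    FeatureRecord,
    ReadRecord,
    SequenceRecord,
    SnvRecord,
    reverse_complement,
    write_features,
    write_genome,
    write_reads,
    write_snvs,
)
from .snv_triage import SAMPLE_LABELS, SnvSet

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
]


class SpecError(ValueError):
    """A simulation spec is internally inconsistent."""


# ---------------------------------------------------------------------------
# spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    codons: int = 60  # incl. start and stop codons
    n_exons: int = 2
    strand: str = "+"
    utr_len: int = 50
    intron_len: int = 150


@dataclass(frozen=True)
class GenomeSpec:
    length: int = 100_000
    chrom: str = "chr1"
    genes: tuple[GeneSpec, ...] = (
        GeneSpec(codons=175, n_exons=1, strand="+"),  # 525-nt single-exon ORF
        GeneSpec(codons=60, n_exons=2, strand="-"),
        GeneSpec(codons=80, n_exons=3, strand="+"),
        GeneSpec(codons=50, n_exons=2, strand="-"),
        GeneSpec(codons=70, n_exons=2, strand="+"),
    )
    profile: str = "GhABE8e"
    offtarget_mismatches: tuple[int, ...] = (1, 2, 2, 3)
    planted_positions: tuple[int, ...] | None = None  # optional explicit starts


@dataclass(frozen=True)
class AmpliconSpec:
    length: int = 220
    guide_start: int = 90
    guide_strand: str = "+"
    profile: str = "GhABE8e"
    n_reads: int = 500
    rates: Mapping[int, float] | None = None  # protospacer position -> rate
    alleles: tuple[tuple[tuple[int, ...], float], ...] | None = None
    error_rate: float = 0.0
    base_quality: int = 40


@dataclass(frozen=True)
class SnvDesignSpec:
    shared_background: int = 300
    private: Mapping[str, int] = field(
        default_factory=lambda: {
            "edited": 50, "vector_only": 40, "negative": 25, "wild_type": 25
        }
    )
    compatible_frac: float = 1.0  # of edited/vector_only private SNVs
    region_counts: Mapping[str, int] | None = None  # edited compatible placement
    n_in_sites: int = 0  # edited compatible SNVs planted inside site footprints


@dataclass(frozen=True)
class SimSpec:
    """Everything the generators need; the seed fully determines output."""

    seed: int = 1
    genome: GenomeSpec = GenomeSpec()
    amplicon: AmpliconSpec = AmpliconSpec()
    snv: SnvDesignSpec = SnvDesignSpec()


# ---------------------------------------------------------------------------
# genome + gene models + planted sites
# ---------------------------------------------------------------------------

@dataclass
class GenomeSim:
    genome: dict[str, SequenceRecord]
    features: list[FeatureRecord]
    guide: GuideCandidate
    profile: EditorProfile
    ledger: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome(self.genome, outdir / "genome.fa")
        write_features(self.features, outdir / "genes.gff3")
        (outdir / "ledger.json").write_text(json.dumps(self.ledger, indent=1))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, n)])


def _build_gene_cassette(rng: np.random.Generator, spec: GeneSpec
                         ) -> tuple[str, str, list[tuple[int, int]], tuple[int, int], tuple[int, int]]:
    """Gene sequence in transcript-forward layout.

    Returns (cassette_seq, cds_seq, cds_intervals, utr5, utr3), intervals
    0-based half-open within the cassette.
    """
    if spec.codons < 3:
        raise SpecError("gene needs at least start, one internal and stop codon")
    body = [
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), spec.codons - 2)
    ]
    cds = "ATG" + "".join(body) + "TGA"
    n = len(cds)
    if spec.n_exons < 1 or spec.n_exons > spec.codons:
        raise SpecError("n_exons out of range")
    cut_points = sorted(
        rng.choice(np.arange(1, n), size=spec.n_exons - 1, replace=False).tolist()
    )
    pieces = []
    prev = 0
    for cut in cut_points + [n]:
        pieces.append(cds[prev:cut])
        prev = cut
    parts: list[str] = []
    cds_intervals: list[tuple[int, int]] = []
    offset = 0
    utr5_seq = _random_seq(rng, spec.utr_len)
    parts.append(utr5_seq)
    utr5 = (0, spec.utr_len)
    offset = spec.utr_len
    for i, piece in enumerate(pieces):
        if i > 0:
            intron = _random_seq(rng, spec.intron_len)
            # avoid accidental in-frame splice artefacts is unnecessary: the
            # CDS intervals are authoritative
            parts.append(intron)
            offset += spec.intron_len
        parts.append(piece)
        cds_intervals.append((offset, offset + len(piece)))
        offset += len(piece)
    utr3_seq = _random_seq(rng, spec.utr_len)
    parts.append(utr3_seq)
    utr3 = (offset, offset + spec.utr_len)
    offset += spec.utr_len
    return "".join(parts), cds, cds_intervals, utr5, utr3


def _make_guide_seq(rng: np.random.Generator, profile: EditorProfile) -> tuple[str, str]:
    """A concrete protospacer with >=2 substrate bases in the window, plus PAM."""
    lo, hi = profile.window
    while True:
        proto = _random_seq(rng, profile.protospacer_len)
        window_hits = [p for p in range(lo, hi + 1) if proto[p - 1] == profile.edit_from]
        if len(window_hits) >= 2 and "TTTT" not in proto:
            break
    from .editor_model import IUPAC

    pam = "".join(
        c if c in _BASES else IUPAC[c][rng.integers(0, len(IUPAC[c]))]
        for c in profile.pam_pattern
    )
    return proto, pam


def _site_string(profile: EditorProfile, proto: str, pam: str, strand: str) -> str:
    """Forward-strand insert for a site whose oriented protospacer is ``proto``."""
    if profile.pam_side == "three_prime":
        oriented = proto + pam
    else:
        oriented = pam + proto
    return oriented if strand == "+" else reverse_complement(oriented)


def simulate_genome(spec: SimSpec) -> GenomeSim:
    """Generate the genome, gene models and planted guide/off-target sites."""
    g = spec.genome
    rng = np.random.default_rng([spec.seed, 1])
    profile = get_profile(g.profile)
    seq = list(_random_seq(rng, g.length))

    # build gene cassettes, then lay everything out on an even grid
    cassettes = [_build_gene_cassette(rng, gs) for gs in g.genes]
    n_sites = 1 + len(g.offtarget_mismatches)
    n_units = len(cassettes) + n_sites
    slot = g.length // (n_units + 1)
    for i, c in enumerate(cassettes):
        if len(c[0]) > slot - 4200:  # leave room for 2-kb flanks between units
            raise SpecError(
                f"gene {i} cassette ({len(c[0])} nt) too large for genome length {g.length}"
            )

    features: list[FeatureRecord] = []
    gene_ledger = []
    occupied: list[tuple[int, int]] = []
    chrom = g.chrom
    for i, (gs, (cassette, cds_seq, cds_ivals, utr5, utr3)) in enumerate(
        zip(g.genes, cassettes)
    ):
        gid = f"gene{i + 1}"
        mid = f"{gid}.1"
        g0 = (i + 1) * slot
        M = len(cassette)
        placed = cassette if gs.strand == "+" else reverse_complement(cassette)
        seq[g0:g0 + M] = placed
        occupied.append((g0, g0 + M))

        def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
            a, b = iv
            if gs.strand == "+":
                return g0 + a, g0 + b
            return g0 + M - b, g0 + M - a

        span = (g0, g0 + M)
        features.append(FeatureRecord(chrom, "gene", span[0] + 1, span[1], gs.strand,
                                      feature_id=gid))
        features.append(FeatureRecord(chrom, "mRNA", span[0] + 1, span[1], gs.strand,
                                      parent=gid, feature_id=mid))
        u5 = to_genomic(utr5)
        u3 = to_genomic(utr3)
        features.append(FeatureRecord(chrom, "five_prime_UTR", u5[0] + 1, u5[1],
                                      gs.strand, parent=mid, feature_id=f"{mid}.utr5"))
        cum = 0
        genomic_cds = []
        for j, iv in enumerate(cds_ivals):  # cassette order == transcript order
            a, b = to_genomic(iv)
            phase = (3 - cum % 3) % 3
            features.append(
                FeatureRecord(chrom, "CDS", a + 1, b, gs.strand, phase=str(phase),
                              parent=mid, feature_id=f"{mid}.cds{j + 1}")
            )
            genomic_cds.append([a, b])
            cum += iv[1] - iv[0]
        features.append(FeatureRecord(chrom, "three_prime_UTR", u3[0] + 1, u3[1],
                                      gs.strand, parent=mid, feature_id=f"{mid}.utr3"))
        gene_ledger.append(
            {
                "gene_id": gid, "mrna_id": mid, "strand": gs.strand,
                "span": list(span), "cds_segments": genomic_cds, "cds_seq": cds_seq,
            }
        )

    # planted guide + off-target sites in the remaining slots
    proto, pam = _make_guide_seq(rng, profile)
    site_specs = [(0, ())] + [
        (k, tuple()) for k in g.offtarget_mismatches
    ]
    if g.planted_positions is not None:
        if len(g.planted_positions) != n_sites:
            raise SpecError(
                f"planted_positions has {len(g.planted_positions)} entries, "
                f"need {n_sites}"
            )
        starts = list(g.planted_positions)
        site_len = profile.protospacer_len + profile.pam_len
        ivals = sorted((s, s + site_len) for s in starts)
        for (a1, b1), (a2, b2) in zip(ivals, ivals[1:]):
            if a2 < b1:
                raise SpecError(f"planted sites overlap: {a1}-{b1} vs {a2}-{b2}")
        for s, e in ivals:
            if s < 0 or e > g.length:
                raise SpecError(f"planted site {s}-{e} outside genome 0-{g.length}")
    else:
        starts = [(len(cassettes) + 1 + j) * slot for j in range(n_sites)]

    planted = []
    strand_cycle = ["+", "-"]
    for j, ((k, _), start) in enumerate(zip(site_specs, starts)):
        strand = strand_cycle[j % 2] if j > 0 else "+"
        site_proto = list(proto)
        mpos: list[int] = []
        if k > 0:
            mpos = sorted(
                rng.choice(np.arange(1, profile.protospacer_len + 1), size=k,
                           replace=False).tolist()
            )
            for p in mpos:
                orig = site_proto[p - 1]
                alts = [b for b in _BASES if b != orig]
                site_proto[p - 1] = alts[rng.integers(0, 3)]
        insert = _site_string(profile, "".join(site_proto), pam, strand)
        L = len(insert)
        for a, b in occupied:
            if start < b and a < start + L:
                raise SpecError(
                    f"planted site {start}-{start + L} overlaps a placed unit at {a}-{b}"
                )
        seq[start:start + L] = insert
        occupied.append((start, start + L))
        # forward-strand protospacer interval
        if (profile.pam_side == "three_prime") == (strand == "+"):
            p_start = start
        else:
            p_start = start + profile.pam_len
        planted.append(
            {
                "chrom": chrom, "start": p_start,
                "end": p_start + profile.protospacer_len, "strand": strand,
                "mismatches": k, "mismatch_positions": mpos,
                "on_target": j == 0,
            }
        )

    genome = {chrom: SequenceRecord(chrom, "".join(seq))}
    lo, hi = profile.window
    on = planted[0]
    guide = GuideCandidate(
        target_id=chrom, start=on["start"], end=on["end"], strand="+",
        protospacer=proto, pam=pam, profile_name=profile.name,
        editable_positions=tuple(
            p for p in range(lo, hi + 1) if proto[p - 1] == profile.edit_from
        ),
    )
    ledger = {
        "seed": spec.seed, "chrom": chrom, "genome_length": g.length,
        "profile": profile.name, "genes": gene_ledger,
        "guide": {"protospacer": proto, "pam": pam, "start": on["start"],
                  "strand": "+"},
        "planted_sites": planted,
    }
    return GenomeSim(genome=genome, features=features, guide=guide,
                     profile=profile, ledger=ledger)


# ---------------------------------------------------------------------------
# amplicon read pools
# ---------------------------------------------------------------------------

@dataclass
class AmpliconSim:
    target: AmpliconTarget
    reads: list[ReadRecord]
    ledger: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome(
            {"amplicon": SequenceRecord("amplicon", self.target.amplicon_seq)},
            outdir / "amplicon.fa",
        )
        write_reads(self.reads, outdir / "reads.fastq")
        (outdir / "ledger.json").write_text(json.dumps(self.ledger, indent=1))


def simulate_amplicon_reads(spec: SimSpec) -> AmpliconSim:
    """Generate an edited amplicon read pool with exact bookkeeping."""
    a = spec.amplicon
    rng = np.random.default_rng([spec.seed, 2])
    profile = get_profile(a.profile)
    L, P = profile.protospacer_len, profile.pam_len
    if a.guide_start < P or a.guide_start + L + P > a.length:
        raise SpecError("guide does not fit in the amplicon with its PAM")
    if a.error_rate < 0 or a.error_rate > 1:
        raise SpecError("error_rate must be in [0, 1]")

    proto, pam = _make_guide_seq(rng, profile)
    amplicon = list(_random_seq(rng, a.length))
    insert = _site_string(profile, proto, pam, a.guide_strand)
    if (profile.pam_side == "three_prime") == (a.guide_strand == "+"):
        ins_start = a.guide_start
    else:
        ins_start = a.guide_start - P
    amplicon[ins_start:ins_start + len(insert)] = insert
    amplicon_seq = "".join(amplicon)

    lo, hi = profile.window
    editable = tuple(
        p for p in range(lo, hi + 1) if proto[p - 1] == profile.edit_from
    )
    guide = GuideCandidate(
        target_id="amplicon", start=a.guide_start, end=a.guide_start + L,
        strand=a.guide_strand, protospacer=proto, pam=pam,
        profile_name=profile.name, editable_positions=editable,
    )
    target = AmpliconTarget(amplicon_seq=amplicon_seq, guide=guide, profile=profile)

    rates = dict(a.rates or {})
    for p, r in rates.items():
        if p not in editable:
            raise SpecError(f"rate given for non-editable position {p} (editable {editable})")
        if not 0 <= r <= 1:
            raise SpecError(f"rate {r} for position {p} outside [0, 1]")
    alleles = a.alleles
    if alleles is not None:
        total = sum(frac for _, frac in alleles)
        if not np.isclose(total, 1.0):
            raise SpecError(f"allele fractions sum to {total}, expected 1")
        for subset, _ in alleles:
            if set(subset) - set(editable):
                raise SpecError(f"allele subset {subset} outside editable {editable}")

    edited_fwd = profile.edit_to if a.guide_strand == "+" else \
        {"A": "T", "C": "G", "G": "C", "T": "A"}[profile.edit_to]

    reads: list[ReadRecord] = []
    read_edits: list[list[int]] = []
    pos_counts = {p: 0 for p in editable}
    allele_counts: dict[str, int] = {}
    n_error_bases = 0
    qual = tuple([a.base_quality] * a.length)
    for i in range(a.n_reads):
        if alleles is not None:
            idx = rng.choice(len(alleles), p=[f for _, f in alleles])
            chosen = tuple(sorted(alleles[idx][0]))
        else:
            chosen = tuple(
                p for p in editable if p in rates and rng.random() < rates[p]
            )
        row = list(amplicon_seq)
        for p in chosen:
            row[guide.forward_position(p)] = edited_fwd
            pos_counts[p] += 1
        if a.error_rate > 0:
            errs = np.nonzero(rng.random(a.length) < a.error_rate)[0]
            for t in errs:
                cur = row[t]
                row[t] = [b for b in _BASES if b != cur][rng.integers(0, 3)]
            n_error_bases += len(errs)
        key = ",".join(map(str, chosen)) if chosen else "WT"
        allele_counts[key] = allele_counts.get(key, 0) + 1
        reads.append(ReadRecord(id=f"read{i + 1}", seq="".join(row), qual=qual))
        read_edits.append(list(chosen))

    n = a.n_reads
    ledger = {
        "seed": spec.seed, "n_reads": n, "amplicon_len": a.length,
        "guide_start": a.guide_start, "guide_strand": a.guide_strand,
        "profile": profile.name, "protospacer": proto,
        "editable_positions": list(editable),
        "programmed_rates": {str(k): v for k, v in rates.items()},
        "per_position_edit_counts": {str(k): v for k, v in pos_counts.items()},
        "realized_rates": {str(k): v / n for k, v in pos_counts.items()},
        "reads_with_any_edit": sum(1 for e in read_edits if e),
        "allele_counts": allele_counts,
        "read_edits": read_edits,
        "sequencing_error_bases": n_error_bases,
        "error_rate": a.error_rate,
    }
    return AmpliconSim(target=target, reads=reads, ledger=ledger)


# ---------------------------------------------------------------------------
# four-sample SNV designs
# ---------------------------------------------------------------------------

@dataclass
class SnvSim:
    sets: dict[str, SnvSet]
    ledger: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label, snv_set in self.sets.items():
            write_snvs(snv_set, outdir / f"{label}.vcf")
        (outdir / "ledger.json").write_text(json.dumps(self.ledger, indent=1))


def _category_intervals(genome_sim: GenomeSim, flank: int = 2000
                        ) -> dict[str, list[tuple[int, int]]]:
    """Region pools derived from the generator's own gene bookkeeping."""
    length = genome_sim.ledger["genome_length"]
    pools: dict[str, list[tuple[int, int]]] = {c: [] for c in (
        "exonic", "UTR", "intronic", "upstream2kb", "downstream2kb", "intergenic"
    )}
    blocked: list[tuple[int, int]] = []
    for gene in genome_sim.ledger["genes"]:
        span = tuple(gene["span"])
        cds = [tuple(iv) for iv in gene["cds_segments"]]
        pools["exonic"].extend(cds)
        strand = gene["strand"]
        if strand == "+":
            pools["upstream2kb"].append((max(0, span[0] - flank), span[0]))
            pools["downstream2kb"].append((span[1], min(length, span[1] + flank)))
        else:
            pools["upstream2kb"].append((span[1], min(length, span[1] + flank)))
            pools["downstream2kb"].append((max(0, span[0] - flank), span[0]))
        blocked.append(span)
        blocked.append((max(0, span[0] - flank), min(length, span[1] + flank)))
    # UTR + intronic from features
    for f in genome_sim.features:
        if f.type in ("five_prime_UTR", "three_prime_UTR"):
            pools["UTR"].append((f.start0, f.end0))
    # intronic: gene span minus CDS/UTR
    for gene in genome_sim.ledger["genes"]:
        span = tuple(gene["span"])
        covered = sorted(
            [tuple(iv) for iv in gene["cds_segments"]]
            + [
                (f.start0, f.end0)
                for f in genome_sim.features
                if f.type.endswith("UTR") and span[0] <= f.start0 < span[1]
            ]
        )
        cur = span[0]
        for a, b in covered:
            if a > cur:
                pools["intronic"].append((cur, a))
            cur = max(cur, b)
        if cur < span[1]:
            pools["intronic"].append((cur, span[1]))
    # intergenic: everything outside gene spans + flanks and site footprints
    for site in genome_sim.ledger["planted_sites"]:
        blocked.append((site["start"] - 50, site["end"] + 50))
    blocked.sort()
    cur = 0
    for a, b in blocked:
        if a > cur:
            pools["intergenic"].append((cur, a))
        cur = max(cur, b)
    if cur < length:
        pools["intergenic"].append((cur, length))
    return pools


def _sample_position(rng: np.random.Generator, intervals: Sequence[tuple[int, int]],
                     seq: str, used: set[int], ref_base: str | None,
                     max_tries: int = 10_000) -> int:
    lengths = np.array([b - a for a, b in intervals], dtype=np.int64)
    if lengths.sum() <= 0:
        raise SpecError("no positions available in the requested region pool")
    probs = lengths / lengths.sum()
    for _ in range(max_tries):
        i = rng.choice(len(intervals), p=probs)
        a, b = intervals[i]
        pos = int(rng.integers(a, b))
        if pos in used:
            continue
        if ref_base is not None and seq[pos] != ref_base:
            continue
        if seq[pos] == "N":
            continue
        used.add(pos)
        return pos
    raise SpecError("requested SNVs exceed available positions (sampling exhausted)")


def _make_snv(rng: np.random.Generator, seq: str, pos0: int, sample: str,
              compatible: bool | None, profile: EditorProfile,
              chrom: str = "chr1") -> SnvRecord:
    ref = seq[pos0]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if compatible is True:
        alt = profile.edit_to if ref == profile.edit_from else comp[profile.edit_to]
    elif compatible is False:
        wanted_out = {profile.edit_from: profile.edit_to,
                      comp[profile.edit_from]: comp[profile.edit_to]}
        alts = [b for b in _BASES if b != ref and wanted_out.get(ref) != b]
        alt = alts[rng.integers(0, len(alts))]
    else:
        alts = [b for b in _BASES if b != ref]
        alt = alts[rng.integers(0, len(alts))]
    return SnvRecord(chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, sample=sample)


def simulate_snv_design(spec: SimSpec, genome_sim: GenomeSim,
                        level: str = "DNA",
                        include_records: Iterable[SnvRecord] = (),
                        exclude_positions: Iterable[int] = ()) -> SnvSim:
    """Generate the four-sample SNV design with a full truth ledger.

    ``include_records`` are copied into the edited sample (used to plant
    DNA/RNA-shared variants across two designs); ``exclude_positions``
    (0-based) keeps a second design disjoint from a first one.
    """
    s = spec.snv
    rng = np.random.default_rng([spec.seed, 3 if level == "DNA" else 4])
    profile = genome_sim.profile
    chrom = genome_sim.ledger["chrom"]
    seq = genome_sim.genome[chrom].seq
    pools = _category_intervals(genome_sim)
    whole = [(0, len(seq))]
    used: set[int] = set(int(p) for p in exclude_positions)
    for rec in include_records:
        used.add(rec.pos0)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    shared: list[SnvRecord] = []
    for _ in range(s.shared_background):
        pos = _sample_position(rng, whole, seq, used, None)
        shared.append(_make_snv(rng, seq, pos, "shared", None, profile, chrom))

    private: dict[str, list[SnvRecord]] = {label: [] for label in SAMPLE_LABELS}
    edited_compatible: list[dict] = []
    for label in SAMPLE_LABELS:
        n = int(s.private.get(label, 0))
        controlled = label in ("edited", "vector_only")
        n_compat = round(n * s.compatible_frac) if controlled else 0
        placements: list[tuple[bool | None, str | None]] = []
        if controlled:
            placements += [(True, None)] * n_compat
            placements += [(False, None)] * (n - n_compat)
        else:
            placements += [(None, None)] * n
        # region-directed placement applies to the edited compatible SNVs
        if label == "edited" and s.region_counts:
            directed = []
            for cat, cnt in s.region_counts.items():
                if cat not in pools:
                    raise SpecError(f"unknown region category {cat!r}")
                directed += [(True, cat)] * int(cnt)
            if len(directed) > n_compat:
                raise SpecError("region_counts exceed the edited compatible count")
            placements = directed + placements[len(directed):]
        in_site_left = s.n_in_sites if label == "edited" else 0
        site_footprints = [
            (site["start"], site["end"])
            for site in genome_sim.ledger["planted_sites"]
            if not site["on_target"]
        ]
        for compatible, cat in placements:
            if in_site_left > 0 and compatible is True:
                intervals = site_footprints
                in_site_left -= 1
                in_site = True
            elif cat is not None:
                intervals = pools[cat]
                in_site = False
            elif compatible is True:
                intervals = pools["intergenic"]
                in_site = False
            else:
                intervals = whole
                in_site = False
            base = None
            if compatible is True:
                # need an editable substrate base on either strand
                base = (profile.edit_from, comp[profile.edit_from])[
                    int(rng.integers(0, 2))
                ]
            pos = _sample_position(rng, intervals, seq, used, base)
            rec = _make_snv(rng, seq, pos, label, compatible, profile, chrom)
            private[label].append(rec)
            if label == "edited" and compatible is True:
                edited_compatible.append(
                    {
                        "key": list(rec.key), "category": cat,
                        "in_site": in_site,
                    }
                )

    include = list(include_records)
    sets: dict[str, SnvSet] = {}
    for label in SAMPLE_LABELS:
        records = [
            SnvRecord(r.chrom, r.pos, r.ref, r.alt, label)
            for r in shared + private[label]
        ]
        if label == "edited":
            records += [
                SnvRecord(r.chrom, r.pos, r.ref, r.alt, label) for r in include
            ]
        records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
        sets[label] = SnvSet(sample=label, records=records, level=level)

    ledger = {
        "seed": spec.seed, "level": level,
        "shared_background": [list(r.key) for r in shared],
        "private": {
            label: [list(r.key) for r in private[label]] for label in SAMPLE_LABELS
        },
        "edited_compatible": edited_compatible,
        "injected": [list(r.key) for r in include],
        "n_in_sites": s.n_in_sites,
        "used_positions": sorted(used),
    }
    return SnvSim(sets=sets, ledger=ledger)
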