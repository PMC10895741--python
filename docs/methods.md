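# Methods

## Editor model

An editor profile is a tuple (PAM pattern, PAM side, protospacer length,
editing window, conversion). Protospacer positions are counted 1..L from
the 5′ end; for 3′-PAM (Cas9-style) editors the PAM therefore occupies
positions L+1..L+3, for 5′-PAM (Cas12a-style) editors it sits at
−P..−1. Built-in profiles:

| name            | PAM  | side | L  | window | conversion |
|-----------------|------|------|----|--------|------------|
| GhABE8e         | NGG  | 3′   | 20 | 4–10   | A→G |
| GhABE8e-wide    | NGG  | 3′   | 20 | 4–12   | A→G |
| GhABE7.10       | NGG  | 3′   | 20 | 5–5    | A→G |
| GhABE8e-dCpf1   | TTTV | 5′   | 23 | 8–14   | A→G |
| CBE             | NGG  | 3′   | 20 | 4–8    | C→T |

The 4–10 window is the default for the ABE8e profile; the reported
extended 4–12 behaviour is kept as a separate named profile rather than
widening the default, since bystander enumeration grows exponentially in
window content and the narrower window reflects the consistently active
positions. The dCas12a window (8–14) is provisional: no window has been
characterised for that fusion in cotton, so the value follows the
ABE8e–dCas12a literature convention and is exposed as ordinary profile
configuration.

PAM matching is IUPAC-aware on the pattern side only: an ambiguous
genome base matches a pattern position only when every base it could be
is allowed (genome N matches pattern N, never NGG's G). Protospacers
containing ambiguity codes are skipped during scanning — a guide needs
concrete bases. Guide ranking is an explicitly heuristic weighted sum
(editable-base count, TTTT Pol-III-terminator penalty, GC-range bonus,
and a fixed penalty that sends guides with an empty editable window to
the bottom); there is no published activity model for these editors, so
the weights are configuration, not science.

## Consequence prediction

CDS models are built from GFF3 (CDS segments ordered in transcript
orientation, spliced with reverse-complementation for minus-strand
genes). Codon arithmetic is 1-based and in-frame: position *n* lies in
codon ⌊(n−1)/3⌋+1. All edits falling in one codon are applied jointly
before translation (standard nuclear code; organellar tables are out of
scope for nuclear genes). Classes: synonymous, missense, nonsense,
stop_loss, start_loss; edits outside the CDS are reported as noncoding
rather than attempting splice or promoter effect prediction. Combined
outcomes are labelled in the conventional `K53G+S78G` style. Bystander
enumeration walks all 2^k−1 non-empty subsets of a guide's editable
positions and refuses k > 6 by default (the cap is a parameter).

## Off-target enumeration

Candidate sites are every genomic window on either strand whose PAM
matches the profile pattern and whose protospacer Hamming distance to
the guide is ≤ m (default m = 4; the parameter is required on the CLI so
reported counts always carry their provenance). Distance is pure
Hamming — DNA/RNA bulges are not modelled. Genome N never matches a
guide base. The scan is vectorised over numpy uint8 arrays (sliding
windows against the guide bytes; PAM positions tested through 256-entry
lookup tables), giving ~15 ms per 100-kb genome; tests validate it
against a literal per-offset enumeration. The on-target locus is
reported but flagged, mirroring the practice of removing on-target edits
before off-target analysis. Site footprints (protospacer + PAM ± flank)
are merged into half-open intervals for overlap queries.

## Amplicon quantification

Reads are globally aligned to the amplicon with affine gap scoring
(match +1, mismatch −1, gap open −5, gap extend −1 — configurable, as no
canonical parameter set exists), orientation auto-detected by
best-strand score. Filters, in order:

* identity < 0.75 (matches over the longer of read/amplicon) →
  discarded as `low_identity`;
* any indel overlapping the protospacer window → excluded from
  substitution statistics as `window_indel` (an ABE is not expected to
  create indels; such reads are candidate Cas-independent events and
  are tallied, not silently dropped);
* a base with Phred < 20 at an editable position removes the read from
  that position's numerator and denominator, so per-position
  denominators may differ — this prevents sequencing error from
  inflating (or deflating) efficiencies near the 100% regime.

Percentages are rounded half-up to one decimal. Allele tables key reads
by the protospacer ± 5 bp substring; edit labels use protospacer
coordinates and strand-oriented bases (`A4G;A6G`). Sample
classification: unedited when no non-reference allele reaches the 5%
calling floor; homogeneous when exactly one does and it is at ≥ 90%;
chimeric otherwise. The floor and fixation threshold are parameters.

## SNV triage

Background subtraction removes any (chrom, pos, ref, alt) key present in
the negative or wild-type control — allele-aware, since a different
alternate base at the same position is a different event. Editor
compatibility keeps the two forward-strand deamination signatures (A>G
and T>C for an ABE). Region annotation assigns exactly one category per
SNV with priority exonic > UTR > intronic > upstream2kb > downstream2kb
> intergenic; flanks default to 2 kb and are strand-aware. The category
set and flank sizes are conventional annotation bins, exposed as
configuration. Printed ratios are computed in exact decimal arithmetic
and rounded half-up — two decimals for DNA percentages and one for RNA
by default, matching the mixed precision convention of published
reports. Variants present at both the DNA and RNA level are flagged as
transcribed DNA variants, not RNA off-targets.

## Synthetic data

The generators produce every fixture with exact ground truth; each draws
from its own `numpy` Generator seeded with `[seed, stream]`, so one
integer seed fixes all outputs and generators are independent.

* **Genome** (default 100 kb, 5 genes): gene cassettes are
  UTR–CDS/intron–UTR layouts with CDS built as ATG + random non-stop
  codons + TGA, so every model is complete and in frame; the first gene
  is a 175-codon (525-nt) single-exon ORF. One on-target guide site and
  off-target copies at 1–3 mismatches are planted in intergenic slots;
  overlapping placements are a spec error. The ledger records every
  gene (with its spliced CDS string) and every planted site.
* **Amplicon pools** (default 220 bp, guide at position 90): per-read
  edits are drawn per position (independent Bernoulli at the programmed
  rate) or from a programmed allele mixture; optional uniform
  substitution error; constant Q40 qualities. The ledger stores
  per-read edit sets and realised per-position counts, so with zero
  sequencing error the quantification output must match it exactly.
* **SNV designs**: shared background SNVs present in all four samples
  plus per-sample private SNVs; the editor-compatible fraction of
  edited/vector-only privates is controlled, and edited compatible SNVs
  can be directed into specific region categories or planted inside
  off-target footprints. Region pools are derived from the generator's
  own gene geometry, not from the annotation module it is used to test.

What the generators do **not** emulate: platform-specific error
profiles, read-length variation, PCR/UMI duplication structure, real
linkage between variants, and genome-scale repeat content. Passing
closed-loop tests therefore demonstrates correctness of the arithmetic
and bookkeeping, not robustness to every artefact of real sequencing
data.

## Problem sizes and numerical choices

The test suite validates the scanners against literal brute-force
enumeration on 100 random references up to 1 kb (guide scanning) and
100 random 100-kb genomes (off-target enumeration, m = 4); parameter
recovery uses 1000-read pools across programmed rates of 5–95%. These
sizes give tight binomial bounds while keeping the whole suite under a
minute. Rounding is half-up everywhere percentages are printed, computed
via `decimal` to avoid float artefacts on exact ties. Interval
conventions are 0-based half-open internally, with ±1 conversion only at
the VCF/GFF3 boundary, asserted by boundary tests at position 1 and at
sequence end.

## Known limitations

* Hamming-only off-target search: bulged sites are invisible.
* No machine-learned on-target activity or CFD/MIT specificity scores.
* Splice-site disruption is reported as noncoding, not modelled.
* The four-sample triage assumes variant calling happened
  upstream; the toolkit consumes any SNV-bearing VCF and does not call
  variants.
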