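# bedit

A Python toolkit for the computational side of base-editing experiments
in plants: designing guides for adenine and cytosine base editors,
predicting amino-acid consequences (including bystander-edit
combinations), enumerating mismatch-tolerant off-target sites,
quantifying editing outcomes from amplicon deep sequencing, and triaging
whole-genome / whole-transcriptome SNV call sets for off-target
activity. It is aimed at groups running ABE/CBE experiments in crops
(the built-in editor profiles model the editors characterised in upland
cotton) who want a scriptable, testable alternative to ad-hoc spreadsheet
analysis.

## The model

A base editor is described parametrically by an `EditorProfile`:

* a PAM pattern and side — `NGG` 3′ of the protospacer for nCas9
  editors, `TTTV` 5′ for dCas12a (V = A/C/G);
* a protospacer length *L* (20 for nCas9, 23 for dCas12a), positions
  counted 1..*L* from the 5′ end so the NGG PAM occupies positions
  21–23;
* an editing window [lo, hi] in protospacer coordinates — A4–A10 for
  the high-activity ABE8e profile, A5 only for ABE7.10;
* a conversion chemistry: A→G for an adenine base editor (surfacing as
  T→C on the opposite strand), C→T for a cytosine base editor.

Editing efficiency at a position *p* is the read-counting statistic

    eff(p) = 100 × (# reads carrying the converted base at p) / (# aligned reads)

and the site-level efficiency counts reads with ≥ 1 window conversion.
Consequence prediction applies all edits of a codon jointly before
translating under the standard nuclear genetic code, producing labels
such as `K53G+S78G`. Off-target triage follows the four-sample design
(edited / vector-only / negative / wild-type): background subtraction is
allele-aware on (chrom, pos, ref, alt); survivors are restricted to the
deamination signatures (A>G, T>C for an ABE); and the remainder is
intersected with Cas-OFFinder-style predicted sites (Hamming distance ≤
*m*, PAM-aware, both strands) to separate guide-dependent from
guide-independent events.

## Worked example

Quantify a simulated 220-bp amplicon pool (500 reads, conversions
programmed at 85% and 30% on the two editable window adenines):

```python
from bedit import synthetic_data as sd
from bedit.amplicon_quant import align_reads, editing_efficiency, build_allele_table

rates = {6: 0.85, 7: 0.30}   # protospacer positions A6, A7
sim = sd.simulate_amplicon_reads(
    sd.SimSpec(seed=42, amplicon=sd.AmpliconSpec(n_reads=500, rates=rates)))
prof = align_reads(sim.reads, sim.target)
rep = editing_efficiency(prof, sim.target)
print(rep.per_position, rep.site_efficiency, rep.classification)
for r in build_allele_table(prof, sim.target).rows[:4]:
    print(f"{r.edit_label:12s} {r.read_count:4d} {r.frequency:.3f}")
```

prints

```
{6: 87.6, 7: 30.2} 90.6 chimeric
A6G           302 0.604
A6G;A7G       136 0.272
WT             47 0.094
A7G            15 0.030
```

i.e. 87.6% of reads carry A6→G and 30.2% carry A7→G (the binomial
realisations of the programmed 85%/30%), 90.6% of reads carry at least
one window conversion, and the sample is called chimeric because two
distinct edited alleles each exceed the 5% calling threshold — the
typical situation in first-generation regenerants.

The same operations are available from a thin CLI: `bedit design`,
`bedit offtarget`, `bedit quant`, `bedit triage`, `bedit simulate`.

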