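"""Amplicon quantification: alignment, efficiencies, alleles, classification."""

import math

import pytest
from scipy.stats import binom

from bedit import synthetic_data as sd
from bedit.amplicon_quant import (
    align_reads,
    build_allele_table,
    classify_sample,
    editing_efficiency,
    round_half_up,
)
from bedit.seqio import ReadRecord, reverse_complement


def perfect_read(sim, i=0):
    return ReadRecord(f"p{i}", sim.target.amplicon_seq,
                      tuple([40] * len(sim.target.amplicon_seq)))


@pytest.fixture(scope="module")
def unedited_sim():
    return sd.simulate_amplicon_reads(
        sd.SimSpec(seed=21, amplicon=sd.AmpliconSpec(n_reads=10, rates={}))
    )


@pytest.fixture(scope="module")
def programmed_sim():
    spec0 = sd.SimSpec(seed=22)
    editable = sd.simulate_amplicon_reads(spec0).target.guide.editable_positions
    rates = {editable[0]: 0.3}
    return sd.simulate_amplicon_reads(
        sd.SimSpec(seed=22, amplicon=sd.AmpliconSpec(n_reads=200, rates=rates))
    )


class TestAlign:
    def test_perfect_reads_all_aligned(self, unedited_sim):
        prof = align_reads(unedited_sim.reads, unedited_sim.target)
        assert prof.aligned_reads == 10
        assert sum(prof.discarded.values()) == 0
        amp = unedited_sim.target.amplicon_seq
        for t, base in enumerate(amp):
            assert prof.counts[base][t] == 10

    def test_reverse_complement_read_counted_forward(self, unedited_sim):
        amp = unedited_sim.target.amplicon_seq
        rc = ReadRecord("rc", reverse_complement(amp), tuple([40] * len(amp)))
        prof = align_reads([rc], unedited_sim.target)
        assert prof.aligned_reads == 1
        for t, base in enumerate(amp):
            assert prof.counts[base][t] == 1  # complemented before tallying

    def test_low_identity_discarded(self, unedited_sim):
        amp = unedited_sim.target.amplicon_seq
        junk = ReadRecord("junk", "ACGT" * (len(amp) // 4), tuple([40] * (len(amp) // 4 * 4)))
        prof = align_reads([perfect_read(unedited_sim), junk], unedited_sim.target)
        assert prof.aligned_reads == 1
        assert prof.discarded["low_identity"] == 1

    def test_window_indel_discarded_separately(self, unedited_sim):
        amp = unedited_sim.target.amplicon_seq
        g = unedited_sim.target.guide
        mid = (g.start + g.end) // 2
        deleted = amp[:mid] + amp[mid + 1:]
        read = ReadRecord("del", deleted, tuple([40] * len(deleted)))
        prof = align_reads([perfect_read(unedited_sim), read], unedited_sim.target)
        assert prof.aligned_reads == 1
        assert prof.discarded["window_indel"] == 1

    def test_count_conservation(self, programmed_sim):
        prof = align_reads(programmed_sim.reads, programmed_sim.target)
        assert prof.aligned_reads + sum(prof.discarded.values()) == len(programmed_sim.reads)
        # per-position invariant: base + deletion counts sum to aligned reads
        L = len(programmed_sim.target.amplicon_seq)
        for t in range(0, L, 37):
            total = sum(prof.counts[b][t] for b in ("A", "C", "G", "T", "N", "del"))
            assert total == prof.aligned_reads

    def test_empty_pool_is_error(self, unedited_sim):
        with pytest.raises(ValueError):
            align_reads([], unedited_sim.target)

    def test_simulator_bookkeeping_exact(self, programmed_sim):
        prof = align_reads(programmed_sim.reads, programmed_sim.target)
        target = programmed_sim.target
        for p_str, count in programmed_sim.ledger["per_position_edit_counts"].items():
            p = int(p_str)
            amp_pos = target.guide.forward_position(p)
            edited_base = [
                b for (pp, ap, b) in target.editable_amplicon_positions() if pp == p
            ][0]
            assert prof.counts[edited_base][amp_pos] == count


class TestEfficiency:
    def test_nine_of_ten(self, unedited_sim):
        target = unedited_sim.target
        p = target.guide.editable_positions[0]
        amp_pos, edited_base = [
            (ap, b) for (pp, ap, b) in target.editable_amplicon_positions() if pp == p
        ][0]
        amp = target.amplicon_seq
        edited_seq = amp[:amp_pos] + edited_base + amp[amp_pos + 1:]
        reads = [ReadRecord(f"e{i}", edited_seq, tuple([40] * len(amp))) for i in range(9)]
        reads.append(perfect_read(unedited_sim))
        rep = editing_efficiency(align_reads(reads, target), target)
        assert rep.per_position[p] == 90.0
        assert rep.site_efficiency == 90.0

    def test_unedited_sample(self, unedited_sim):
        prof = align_reads(unedited_sim.reads, unedited_sim.target)
        rep = editing_efficiency(prof, unedited_sim.target)
        assert all(v == 0.0 for v in rep.per_position.values())
        assert rep.site_efficiency == 0.0
        assert rep.classification == "unedited"

    def test_recovers_programmed_rates_exactly_without_error(self, programmed_sim):
        prof = align_reads(programmed_sim.reads, programmed_sim.target)
        rep = editing_efficiency(prof, programmed_sim.target)
        n = programmed_sim.ledger["n_reads"]
        for p_str, realized in programmed_sim.ledger["realized_rates"].items():
            assert rep.per_position[int(p_str)] == round_half_up(100 * realized, 1)
        assert rep.site_efficiency == round_half_up(
            100 * programmed_sim.ledger["reads_with_any_edit"] / n, 1
        )

    def test_parameter_recovery_within_binomial_interval(self):
        spec0 = sd.SimSpec(seed=31)
        editable = sd.simulate_amplicon_reads(spec0).target.guide.editable_positions
        rates = {editable[0]: 0.60, editable[1]: 0.25}
        n = 500
        sim = sd.simulate_amplicon_reads(
            sd.SimSpec(seed=31, amplicon=sd.AmpliconSpec(n_reads=n, rates=rates))
        )
        rep = editing_efficiency(align_reads(sim.reads, sim.target), sim.target)
        for p, rate in rates.items():
            lo, hi = binom.ppf([0.005, 0.995], n, rate)
            assert lo / n * 100 <= rep.per_position[p] <= hi / n * 100

    def test_orientation_invariance(self, programmed_sim):
        target = programmed_sim.target
        rep_fwd = editing_efficiency(align_reads(programmed_sim.reads, target), target)
        flipped = [
            ReadRecord(r.id, reverse_complement(r.seq), tuple(reversed(r.qual)))
            for r in programmed_sim.reads
        ]
        rep_rev = editing_efficiency(align_reads(flipped, target), target)
        assert rep_fwd.per_position == rep_rev.per_position
        assert rep_fwd.site_efficiency == rep_rev.site_efficiency

    def test_low_quality_base_leaves_denominator(self, unedited_sim):
        target = unedited_sim.target
        p = target.guide.editable_positions[0]
        amp_pos = target.guide.forward_position(p)
        amp = target.amplicon_seq
        qual_low = [40] * len(amp)
        qual_low[amp_pos] = 5
        reads = [perfect_read(unedited_sim),
                 ReadRecord("lowq", amp, tuple(qual_low))]
        rep = editing_efficiency(align_reads(reads, target), target)
        assert rep.per_position_denominator[p] == 1
        assert rep.aligned_reads == 2


class TestAlleles:
    def test_all_reference_single_wt_row(self, unedited_sim):
        prof = align_reads(unedited_sim.reads, unedited_sim.target)
        table = build_allele_table(prof, unedited_sim.target)
        assert len(table.rows) == 1
        row = table.rows[0]
        assert (row.edit_label, row.frequency) == ("WT", 1.0)

    def test_frequencies_sum_to_one(self, programmed_sim):
        prof = align_reads(programmed_sim.reads, programmed_sim.target)
        table = build_allele_table(prof, programmed_sim.target)
        assert math.isclose(sum(r.frequency for r in table.rows), 1.0, abs_tol=1e-9)
        assert [r.read_count for r in table.rows] == sorted(
            (r.read_count for r in table.rows), reverse=True
        )

    def test_programmed_mixture_recovered(self):
        spec0 = sd.SimSpec(seed=41)
        editable = sd.simulate_amplicon_reads(spec0).target.guide.editable_positions
        alleles = (((editable[0],), 0.7), ((), 0.3))
        n = 400
        sim = sd.simulate_amplicon_reads(
            sd.SimSpec(seed=41, amplicon=sd.AmpliconSpec(n_reads=n, alleles=alleles))
        )
        prof = align_reads(sim.reads, sim.target)
        table = build_allele_table(prof, sim.target)
        by_label = {r.edit_label: r for r in table.rows}
        edited_label = [lab for lab in by_label if lab != "WT"][0]
        lo, hi = binom.ppf([0.005, 0.995], n, 0.7) / n
        assert lo <= by_label[edited_label].frequency <= hi

    def test_edit_label_convention(self, unedited_sim):
        target = unedited_sim.target
        g = target.guide
        editable = g.editable_positions
        assert len(editable) >= 2
        p1, p2 = editable[0], editable[1]
        amp = list(target.amplicon_seq)
        for p in (p1, p2):
            amp[g.forward_position(p)] = "G" if g.strand == "+" else "C"
        read = ReadRecord("e", "".join(amp), tuple([40] * len(amp)))
        table = build_allele_table(align_reads([read], target), target)
        assert table.rows[0].edit_label == f"A{p1}G;A{p2}G"


class TestClassify:
    def _sim_with_alleles(self, seed, alleles, n=300):
        spec0 = sd.SimSpec(seed=seed)
        editable = sd.simulate_amplicon_reads(spec0).target.guide.editable_positions
        resolved = tuple(
            (tuple(editable[i] for i in subset), frac) for subset, frac in alleles
        )
        sim = sd.simulate_amplicon_reads(
            sd.SimSpec(seed=seed, amplicon=sd.AmpliconSpec(n_reads=n, alleles=resolved))
        )
        prof = align_reads(sim.reads, sim.target)
        return build_allele_table(prof, sim.target)

    def test_wild_type_unedited(self, unedited_sim):
        prof = align_reads(unedited_sim.reads, unedited_sim.target)
        assert classify_sample(build_allele_table(prof, unedited_sim.target)) == "unedited"

    def test_fixed_allele_homogeneous(self):
        table = self._sim_with_alleles(51, ((((0,)), 0.97), ((), 0.03)))
        assert classify_sample(table) == "homogeneous"

    def test_two_edited_alleles_chimeric(self):
        table = self._sim_with_alleles(52, (((0,), 0.60), ((0, 1), 0.35), ((), 0.05)))
        assert classify_sample(table) == "chimeric"


def test_round_half_up():
    assert round_half_up(6.25, 1) == 6.3
    assert round_half_up(0.344, 2) == 0.34
    assert round_half_up(0.345, 2) == 0.35
    assert round_half_up(99.94, 1) == 99.9
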