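"""Four-sample SNV triage: subtraction, class filter, intersection, regions."""

import itertools

import pytest

from bedit import synthetic_data as sd
from bedit.editor_model import get_profile
from bedit.offtarget_search import enumerate_offtargets, site_intervals
from bedit.seqio import FeatureRecord, SnvRecord
from bedit.snv_triage import (
    SnvSet,
    annotate_regions,
    cross_level_shared,
    filter_editor_compatible,
    intersect_predicted,
    percent_of_total,
    run_triage,
    subtract_background,
    summarize,
)


def snvs(sample, *triples, level="DNA"):
    return SnvSet(
        sample=sample,
        records=[SnvRecord("chr1", pos, ref, alt, sample) for pos, ref, alt in triples],
        level=level,
    )


class TestSubtract:
    def test_set_difference(self):
        target = snvs("edited", (100, "A", "G"), (200, "T", "C"))
        control = snvs("wild_type", (200, "T", "C"))
        out = subtract_background(target, [control])
        assert {r.pos for r in out.records} == {100}

    def test_allele_aware(self):
        # same position, different alt in the control: retained
        target = snvs("edited", (100, "A", "G"))
        control = snvs("wild_type", (100, "A", "T"))
        assert len(subtract_background(target, [control])) == 1

    def test_control_order_invariant(self):
        target = snvs("edited", *[(i, "A", "G") for i in range(1, 40)])
        c1 = snvs("negative", *[(i, "A", "G") for i in range(1, 15)])
        c2 = snvs("wild_type", *[(i, "A", "G") for i in range(10, 25)])
        for perm in itertools.permutations([c1, c2]):
            out = subtract_background(target, perm)
            assert {r.pos for r in out.records} == set(range(25, 40))

    def test_level_mixing_rejected(self):
        target = snvs("edited", (1, "A", "G"))
        rna = snvs("negative", (1, "A", "G"), level="RNA")
        with pytest.raises(ValueError, match="level"):
            subtract_background(target, [rna])


class TestClassFilter:
    def test_abe_signatures_only(self):
        s = snvs("edited", (1, "A", "G"), (2, "C", "T"), (3, "T", "C"), (4, "G", "A"))
        out = filter_editor_compatible(s, get_profile("GhABE8e"))
        assert {(r.ref, r.alt) for r in out.records} == {("A", "G"), ("T", "C")}

    def test_cbe_signatures(self):
        s = snvs("edited", (1, "A", "G"), (2, "C", "T"), (3, "T", "C"), (4, "G", "A"))
        out = filter_editor_compatible(s, get_profile("CBE"))
        assert {(r.ref, r.alt) for r in out.records} == {("C", "T"), ("G", "A")}

    def test_empty_in_empty_out(self):
        assert len(filter_editor_compatible(snvs("edited"), get_profile("GhABE8e"))) == 0


class TestIntersect:
    def test_boundary_half_open(self):
        intervals = {"chr1": [(100, 123)]}  # 0-based half-open
        inside = snvs("edited", (101, "A", "G"), (123, "A", "G"))  # pos0 100 and 122
        hits, n = intersect_predicted(inside, intervals)
        assert n == 2
        outside = snvs("edited", (100, "A", "G"), (124, "A", "G"))  # pos0 99 and 123
        _, n = intersect_predicted(outside, intervals)
        assert n == 0

    def test_constructed_disjoint_design_has_zero_overlap(self, small_genome_sim):
        spec = sd.SimSpec(seed=7, snv=sd.SnvDesignSpec(
            shared_background=0, private={"edited": 30}, compatible_frac=1.0))
        sim = sd.simulate_snv_design(spec, small_genome_sim)
        sites = enumerate_offtargets(
            small_genome_sim.genome, small_genome_sim.guide, small_genome_sim.profile, 2
        )
        _, n = intersect_predicted(sim.sets["edited"], site_intervals(sites))
        assert n == 0  # generator placed private SNVs away from site footprints


class TestRegions:
    def _features(self):
        # gene on +: 1000..2000 with CDS 1100..1400 and UTR 1000..1099
        return [
            FeatureRecord("chr1", "gene", 1001, 2000, "+", feature_id="g1"),
            FeatureRecord("chr1", "mRNA", 1001, 2000, "+", parent="g1", feature_id="m1"),
            FeatureRecord("chr1", "five_prime_UTR", 1001, 1099, "+", parent="m1"),
            FeatureRecord("chr1", "CDS", 1101, 1400, "+", parent="m1", phase="0"),
        ]

    @pytest.mark.parametrize("pos,category", [
        (1200, "exonic"),
        (1050, "UTR"),
        (1500, "intronic"),   # inside gene, outside CDS/UTR
        (500, "upstream2kb"),
        (2500, "downstream2kb"),
        (50000, "intergenic"),
    ])
    def test_priority_assignment(self, pos, category):
        counts = annotate_regions(snvs("edited", (pos, "A", "G")), self._features())
        assert counts[category] == 1
        assert sum(counts.values()) == 1

    def test_planted_categories_recovered(self, small_genome_sim):
        region_counts = {"exonic": 5, "intronic": 4, "UTR": 3,
                         "upstream2kb": 4, "downstream2kb": 2, "intergenic": 6}
        spec = sd.SimSpec(seed=9, snv=sd.SnvDesignSpec(
            shared_background=0, private={"edited": 24}, compatible_frac=1.0,
            region_counts=region_counts))
        sim = sd.simulate_snv_design(spec, small_genome_sim)
        counts = annotate_regions(sim.sets["edited"], small_genome_sim.features)
        assert counts == region_counts

    def test_every_snv_gets_exactly_one_category(self, small_genome_sim):
        spec = sd.SimSpec(seed=13, snv=sd.SnvDesignSpec(
            shared_background=50, private={"edited": 30}, compatible_frac=0.5))
        sim = sd.simulate_snv_design(spec, small_genome_sim)
        counts = annotate_regions(sim.sets["edited"], small_genome_sim.features)
        assert sum(counts.values()) == len(sim.sets["edited"])


class TestCrossLevel:
    def test_disjoint_and_identical(self):
        a = snvs("edited", (1, "A", "G"), (2, "T", "C"))
        b = snvs("edited", (3, "A", "G"), level="RNA")
        assert cross_level_shared(a, b) == 0
        c = snvs("edited", *[(i, "A", "G") for i in range(1, 8)])
        d = snvs("edited", *[(i, "A", "G") for i in range(1, 8)], level="RNA")
        assert cross_level_shared(c, d) == 7

    def test_planted_shared_variants(self, small_genome_sim):
        spec = sd.SimSpec(seed=15, snv=sd.SnvDesignSpec(
            shared_background=20, private={"edited": 30}, compatible_frac=1.0))
        dna = sd.simulate_snv_design(spec, small_genome_sim, level="DNA")
        dna_filtered = filter_editor_compatible(
            subtract_background(
                dna.sets["edited"], [dna.sets["negative"], dna.sets["wild_type"]]
            ),
            small_genome_sim.profile,
        )
        planted = dna_filtered.records[:12]
        rna = sd.simulate_snv_design(
            spec, small_genome_sim, level="RNA",
            include_records=planted,
            exclude_positions=dna.ledger["used_positions"],
        )
        rna_filtered = filter_editor_compatible(
            subtract_background(
                rna.sets["edited"], [rna.sets["negative"], rna.sets["wild_type"]]
            ),
            small_genome_sim.profile,
        )
        assert cross_level_shared(dna_filtered, rna_filtered) == 12


class TestSummarize:
    def test_printed_ratio_conventions(self):
        # DNA percentages at two decimals, RNA at one
        assert percent_of_total(4395, 1_274_475, 2) == 0.34
        assert percent_of_total(55, 20_664, 1) == 0.3
        assert percent_of_total(1727, 1_277_374, 1) == 0.1
        assert percent_of_total(0, 100, 2) == 0.0
        assert percent_of_total(5, 0, 2) is None  # undefined, not an error

    def test_report_assembly(self):
        rep = summarize(
            level="DNA",
            totals={"edited": 1000, "vector_only": 800},
            filtered={"edited": 10, "vector_only": 8},
            region_category_counts={"intergenic": 10},
        )
        assert rep.percent_of_total == {"edited": 1.0, "vector_only": 1.0}
        d = rep.to_dict()
        assert d["region_category_counts"]["intergenic"] == 10


class TestPipeline:
    def test_closed_loop_recovery(self, small_genome_sim):
        spec = sd.SimSpec(seed=17, snv=sd.SnvDesignSpec(
            shared_background=120,
            private={"edited": 40, "vector_only": 30, "negative": 10, "wild_type": 10},
            compatible_frac=0.5, n_in_sites=3))
        sim = sd.simulate_snv_design(spec, small_genome_sim)
        sites = enumerate_offtargets(
            small_genome_sim.genome, small_genome_sim.guide, small_genome_sim.profile, 2
        )
        footprints = site_intervals([s for s in sites if not s.on_target])
        rep = run_triage(
            sim.sets, small_genome_sim.profile,
            site_footprints=footprints, annotation=small_genome_sim.features,
        )
        assert rep.total_snvs["edited"] == 160
        assert rep.filtered_snvs["edited"] == 20  # compatible half of 40 private
        assert rep.filtered_snvs["vector_only"] == 15
        assert rep.overlap_with_predicted == 3  # the planted in-site SNVs
        assert rep.shared_between_samples == 0
        assert sum(rep.region_category_counts.values()) == 20
        # pipeline monotonicity
        assert (rep.total_snvs["edited"] >= rep.filtered_snvs["edited"]
                >= rep.overlap_with_predicted)
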