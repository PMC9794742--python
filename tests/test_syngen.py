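import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eprvscan import syngen
from eprvscan.align import AA20
from eprvscan.dna import revcomp, translate
from eprvscan.syngen import (
    ImplantSpec,
    TruthSet,
    build_wendovirus_element,
    generate_background,
    implant,
    mutate_coding,
    reverse_translate,
)

protein = st.text(alphabet=AA20, min_size=1, max_size=60)


class TestBackground:
    def test_deterministic_under_seed(self):
        a = generate_background(2, 5000, 0.4, 1e-4, seed=1)
        b = generate_background(2, 5000, 0.4, 1e-4, seed=1)
        assert a == b
        assert a != generate_background(2, 5000, 0.4, 1e-4, seed=2)

    def test_gc_zero_uses_only_at(self):
        seq = generate_background(1, 2000, 0.0, 0.0, seed=3)["contig1"]
        assert set(seq) <= {"A", "T", "N"}

    def test_gc_within_two_points_of_target(self):
        seq = generate_background(1, 100_000, 0.40, 0.0, seed=4)["contig1"]
        non_n = [c for c in seq if c != "N"]
        gc = sum(c in "GC" for c in non_n) / len(non_n)
        assert 0.38 <= gc <= 0.42

    def test_n_run_rate_inserts_runs(self):
        seq = generate_background(1, 100_000, 0.4, 5e-5, seed=5)["contig1"]
        assert "N" * 50 in seq

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_background(1, 0, 0.4)
        with pytest.raises(ValueError):
            generate_background(1, 100, 1.5)


class TestReverseTranslate:
    def test_methionine_is_atg(self):
        assert reverse_translate("M", seed=0) == "ATG"

    @settings(derandomize=True, max_examples=30)
    @given(protein)
    def test_round_trip(self, aa):
        assert translate(reverse_translate(aa, seed=1)) == aa

    def test_uniform_policy_varies_codons_not_protein(self):
        aa = "LLLLSSSSRRRRGGGG"
        d1 = reverse_translate(aa, "uniform", seed=1)
        d2 = reverse_translate(aa, "uniform", seed=2)
        assert d1 != d2
        assert translate(d1) == translate(d2) == aa

    def test_stop_and_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            reverse_translate("M*K")
        with pytest.raises(ValueError):
            reverse_translate("MBJ")


class TestMutateCoding:
    def test_zero_target_is_identity(self):
        dna = reverse_translate("MKVLYAADTRG" * 10, seed=0)
        assert mutate_coding(dna, 0.0, seed=1) == dna

    def test_divergence_hits_target_on_300_aa_orf(self, rng):
        aa = "".join(rng.choice(list(AA20), size=300))
        dna = reverse_translate(aa, seed=2)
        mutated = mutate_coding(dna, 0.05, seed=3)
        diffs = sum(a != b for a, b in zip(aa, translate(mutated)))
        assert 11 <= diffs <= 19  # binomial window around 15/300

    def test_never_introduces_stops(self, rng):
        aa = "".join(rng.choice(list(AA20), size=120))
        dna = reverse_translate(aa, seed=4)
        for seed in range(1000):
            assert "*" not in translate(mutate_coding(dna, 0.10, seed=seed))

    def test_impossible_target_rejected(self):
        dna = reverse_translate("M" * 50)
        with pytest.raises(ValueError):
            mutate_coding(dna, 0.96)


class TestImplant:
    def test_single_intact_copy(self, library):
        bg = generate_background(1, 50_000, 0.4, 0.0, seed=1)
        ref = library[0]
        asm, truth = implant(bg, [ref], [ImplantSpec(ref.id, 1, 0.0, strand_policy="plus")], seed=2)
        assert len(truth) == 1
        rec = truth.records[0]
        pep = translate(rec.element_dna(asm))
        assert "*" not in pep
        assert len(pep) >= 300
        assert pep == ref.aa_seq

    def test_minus_strand_copy_recovered_by_revcomp(self, library):
        bg = generate_background(1, 50_000, 0.4, 0.0, seed=1)
        ref = library[5]
        asm, truth = implant(bg, [ref], [ImplantSpec(ref.id, 1, 0.0, strand_policy="minus")], seed=3)
        rec = truth.records[0]
        assert rec.strand == "-"
        assert translate(rec.element_dna(asm)) == ref.aa_seq
        assert translate(asm[rec.contig][rec.start : rec.end]) != ref.aa_seq

    def test_burst_copies_identical_and_share_group(self, library):
        bg = generate_background(2, 100_000, 0.4, 0.0, seed=1)
        ref = library[10]
        asm, truth = implant(bg, [ref], [ImplantSpec(ref.id, 12, 0.0)], seed=4)
        assert len(truth) == 12
        peptides = {translate(r.element_dna(asm)) for r in truth}
        assert peptides == {ref.aa_seq}
        assert len({r.copy_group_id for r in truth}) == 1

    def test_tandem_gap_is_exact(self, library):
        bg = generate_background(1, 100_000, 0.4, 0.0, seed=1)
        ref = library[3]
        asm, truth = implant(
            bg, [ref], [ImplantSpec(ref.id, 2, 0.0, placement="tandem", tandem_gap_bp=800)], seed=5
        )
        a, b = sorted(truth.records, key=lambda r: r.start)
        assert b.start - a.end == 800

    def test_internal_stop_has_stop_inside(self, library):
        bg = generate_background(1, 50_000, 0.4, 0.0, seed=1)
        ref = library[7]
        asm, truth = implant(
            bg, [ref], [ImplantSpec(ref.id, 1, 0.0, degeneration="internal_stop")], seed=6
        )
        pep = translate(truth.records[0].element_dna(asm))
        inner = pep[:-1]  # exclude any terminal position
        assert "*" in inner

    def test_frameshift_breaks_any_300aa_frame(self, library):
        bg = generate_background(1, 50_000, 0.4, 0.0, seed=1)
        ref = library[9]
        asm, truth = implant(
            bg, [ref], [ImplantSpec(ref.id, 1, 0.0, degeneration="frameshift")], seed=7
        )
        rec = truth.records[0]
        assert (rec.end - rec.start) % 3 != 0  # 1- or 2-bp deletion
        # no single-frame, indel-free match of >= 300 aa survives the lesion
        from eprvscan import homsearch, screen

        hits = homsearch.search([ref], asm)
        assert hits  # the two fragments are still detectable homology
        assert screen.filter_intact(hits) == []

    def test_determinism_and_gff3_round_trip(self, library, tmp_path):
        bg = generate_background(1, 80_000, 0.4, 0.0, seed=1)
        specs = [ImplantSpec(library[0].id, 2, 0.05), ImplantSpec(library[170].id, 1, 0.0)]
        asm1, truth1 = implant(bg, library, specs, seed=9)
        asm2, truth2 = implant(bg, library, specs, seed=9)
        assert asm1 == asm2 and truth1.records == truth2.records
        path = tmp_path / "truth.gff3"
        truth1.to_gff3(path)
        assert TruthSet.from_gff3(path).records == truth1.records

    def test_truth_intervals_within_bounds(self, library):
        bg = generate_background(2, 60_000, 0.4, 0.0, seed=1)
        asm, truth = implant(bg, library, [ImplantSpec(library[2].id, 5)], seed=10)
        for rec in truth:
            assert 0 <= rec.start < rec.end <= len(asm[rec.contig])


class TestScenario:
    def test_default_scenario_composition(self):
        bundle = syngen.default_scenario(seed=2, n_contigs=3, contig_bp=300_000)
        by_class = bundle.truth.by_class()
        assert len(by_class["intact"]) == 32  # 20 dispersed + 12-copy burst
        assert len(by_class["intact_tandem"]) == 5
        assert len(by_class["internal_stop"]) == 10
        assert len(by_class["frameshift"]) == 10
        assert len(by_class["decoy"]) == 10

    def test_wendovirus_element_scale(self):
        dna, info = build_wendovirus_element()
        assert 7000 <= len(dna) <= 8500
        assert set(dna) <= set("ACGT")
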