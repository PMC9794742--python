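import numpy as np
import pytest

from eprvscan import align, homsearch, syngen
from eprvscan.dna import revcomp, translate
from eprvscan.homsearch import (
    RawHit,
    SearchParams,
    parse_external_hits,
    search,
    six_frame_translate,
)
from eprvscan.syngen import ImplantSpec, generate_background, implant

from oracles import sw_local_score


class TestSixFrameTranslate:
    def test_canonical_codons(self):
        assert six_frame_translate("ATGTAA")[0] == "M*"

    def test_reverse_frame_via_revcomp(self):
        # revcomp("TTACAT") == "ATGTAA"
        frames = six_frame_translate("TTACAT")
        assert "M*" in frames[3:]

    def test_ambiguous_base_renders_x(self):
        assert six_frame_translate("ATGNAA")[0] == "MX"

    def test_frame_offsets(self):
        dna = "AATGTAA"
        frames = six_frame_translate(dna)
        assert frames[1] == "M*"  # offset 1
        for f in range(3):
            assert frames[f] == translate(dna, f)
            assert frames[3 + f] == translate(revcomp(dna), f)


class TestSearch:
    def test_verbatim_implant_found_at_exact_interval(self, library):
        ref = library[20]
        for strand in ("plus", "minus"):
            bg = generate_background(1, 50_000, 0.4, 0.0, seed=11)
            asm, truth = implant(
                bg, [ref], [ImplantSpec(ref.id, 1, 0.0, strand_policy=strand)], seed=12
            )
            hits = search([ref], asm)
            rec = truth.records[0]
            exact = [
                h for h in hits
                if (h.start_bp, h.end_bp) == (rec.start, rec.end)
                and h.strand == rec.strand
            ]
            assert exact, f"no exact-interval hit on {strand} strand"
            assert exact[0].matched_peptide == ref.aa_seq

    def test_null_background_yields_no_hits(self, library):
        queries = library[:3]
        for seed in range(10):
            asm = generate_background(1, 50_000, 0.4, 0.0, seed=100 + seed)
            assert search(queries, asm) == []

    def test_empty_assembly_and_short_contig(self, library):
        assert search(library[:1], {}) == []
        assert search(library[:1], {"tiny": "AC"}) == []

    def test_no_queries_is_an_error(self):
        with pytest.raises(ValueError):
            search([], {"c": "ACGT" * 100})

    def test_hits_respect_thresholds(self, mini_bundle):
        params = SearchParams(evalue_max=1e-10, score_min=50.0)
        hits = search(mini_bundle.library[:5], mini_bundle.assembly, params)
        for h in hits:
            assert h.evalue <= params.evalue_max
            assert h.score_raw >= params.score_min

    def test_reported_interval_translates_to_matched_peptide(self, library):
        bg = generate_background(1, 60_000, 0.4, 0.0, seed=13)
        specs = [
            ImplantSpec(library[30].id, 1, 0.05, strand_policy="plus"),
            ImplantSpec(library[40].id, 1, 0.05, strand_policy="minus"),
        ]
        asm, _ = implant(bg, library, specs, seed=14)
        hits = search([library[30], library[40]], asm)
        assert hits
        for h in hits:
            seg = asm[h.contig][h.start_bp : h.end_bp]
            if h.strand == "-":
                seg = revcomp(seg)
            assert h.matched_peptide in translate(seg)

    def test_self_score_dominates_mutants(self, library, rng):
        query = library[0].aa_seq[:80]
        self_score = align.local_score(query, query)
        for _ in range(100):
            mutant = syngen.mutate_protein(query, int(rng.integers(1, 20)), rng)
            assert align.local_score(mutant, query) <= self_score


class TestOracleEquivalence:
    """Internal search vs a hand-rolled quadratic Smith-Waterman DP."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_search_score_equals_bruteforce_optimum(self, library, seed):
        rng = np.random.default_rng(seed)
        query = library[seed].aa_seq[:60]
        mutant = syngen.mutate_protein(query, 6, rng)
        bg = generate_background(1, 2_000, 0.4, 0.0, seed=seed)["contig1"]
        dna = syngen.reverse_translate(mutant, seed=seed)
        pos = 900
        subject_dna = bg[:pos] + dna + bg[pos + len(dna):]
        oracle = max(
            sw_local_score(pep, query) for pep in six_frame_translate(subject_dna)
        )
        for method in ("seed", "exhaustive"):
            hits = search(
                [("q", query)], {"c": subject_dna},
                SearchParams(evalue_max=10.0, score_min=25.0), method=method,
            )
            assert hits
            assert max(h.score_raw for h in hits) == pytest.approx(oracle)

    def test_local_aligner_matches_dp_on_random_pairs(self, rng):
        for _ in range(5):
            a = "".join(rng.choice(list(align.AA20), size=40))
            b = "".join(rng.choice(list(align.AA20), size=55))
            assert align.local_score(a, b) == pytest.approx(sw_local_score(a, b))


class TestExternalAdapter:
    def _row(self, sstart, send, extra=""):
        return (
            f"q1\tc1\t95.0\t300\t10\t0\t1\t300\t{sstart}\t{send}\t1e-50\t500{extra}\n"
        )

    def test_forward_coordinates_normalised(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("# comment\n" + self._row(101, 400))
        (h,) = parse_external_hits(path)
        assert (h.start_bp, h.end_bp, h.strand) == (100, 400, "+")

    def test_swapped_coordinates_mean_minus_strand(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self._row(400, 101))
        (h,) = parse_external_hits(path)
        assert (h.start_bp, h.end_bp, h.strand) == (100, 400, "-")

    def test_subject_peptide_column_used(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self._row(101, 400, "\tMKV-LY"))
        (h,) = parse_external_hits(path)
        assert h.matched_peptide == "MKVLY"

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("# header\nq1\tc1\tbroken\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_external_hits(path)


class TestRawHit:
    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            RawHit("c", 10, 10, "+", 0, "q", "", "", "M", 1.0, 1.0, 1e-20)

    def test_tsv_round_trip(self, tmp_path):
        hit = RawHit("c1", 0, 9, "+", 0, "q1", "MKV", "MKV", "MKV", 15.0, 10.2, 1e-12)
        path = tmp_path / "hits.tsv"
        homsearch.write_hits_tsv([hit], path, ["run_id: test"])
        (back,) = homsearch.read_hits_tsv(path)
        assert (back.contig, back.start_bp, back.end_bp, back.matched_peptide) == (
            "c1", 0, 9, "MKV",
        )
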