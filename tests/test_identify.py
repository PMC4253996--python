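"""The identification filter cascade, filter by filter."""

import numpy as np
import pandas as pd
import pytest

from ricelnc.identify import (
    FILTER_ORDER,
    coding_potential_filter,
    filter_expression,
    filter_length,
    filter_sense_overlap,
    filter_single_exon_proximity,
    filter_strandless,
    longest_orf_codons,
    run_identification,
)
from ricelnc.types import GenomicInterval, Transcript


def tx(tid, chrom, strand, exons, biotype="candidate"):
    return Transcript(
        tid,
        tid,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype,
    )


def fpkm_of(values):
    return pd.DataFrame(
        {f"s{i}": {tid: v[i] for tid, v in values.items()}
         for i in range(len(next(iter(values.values()))))}
    )


class TestStrandless:
    def test_dot_discarded_plus_kept(self):
        cands = [
            tx("a", "chr1", ".", [(0, 300)]),
            tx("b", "chr1", "+", [(1000, 1300)]),
        ]
        assert [t.id for t in filter_strandless(cands)] == ["b"]

    def test_kept_count_equals_known_strand_count(self, rng):
        strands = ["+", "-", "."]
        cands = [
            tx(f"t{i}", "chr1", strands[int(rng.integers(3))],
               [(i * 1000, i * 1000 + 300)])
            for i in range(10)
        ]
        kept = filter_strandless(cands)
        assert len(kept) == sum(1 for t in cands if t.strand != ".")


class TestSenseOverlap:
    known = [tx("g", "chr1", "+", [(100, 500), (800, 1200)], "known_mRNA")]

    def test_same_strand_exon_overlap_discarded(self):
        c = tx("c", "chr1", "+", [(400, 900)])
        assert filter_sense_overlap([c], self.known) == []

    def test_opposite_strand_overlap_kept(self):
        # the lncNAT candidate case
        c = tx("c", "chr1", "-", [(400, 900)])
        assert [t.id for t in filter_sense_overlap([c], self.known)] == ["c"]

    def test_sense_intronic_candidate_kept(self):
        # fully inside the known gene's intron: exon-level rule keeps it
        c = tx("c", "chr1", "+", [(550, 750)])
        kept = filter_sense_overlap([c], self.known)
        assert [t.id for t in kept] == ["c"]
        # per-base exon-set oracle agrees
        known_exon_bases = set(range(100, 500)) | set(range(800, 1200))
        cand_bases = set(range(550, 750))
        assert not (known_exon_bases & cand_bases)


class TestLength:
    @pytest.mark.parametrize(
        "length, kept", [(199, False), (200, True), (852, True)]
    )
    def test_boundary(self, length, kept):
        c = tx("c", "chr1", "+", [(0, length)])
        assert (filter_length([c]) == [c]) is kept

    def test_spliced_length_is_exon_sum(self):
        # span is 1000 bp but spliced length 150: discarded
        c = tx("c", "chr1", "+", [(0, 100), (950, 1000)])
        assert filter_length([c]) == []


class TestExpression:
    def test_multi_exon_threshold_half(self):
        c = tx("c", "chr1", "+", [(0, 100), (200, 400)])
        assert filter_expression([c], fpkm_of({"c": (0.0, 0.4)})) == []
        assert filter_expression([c], fpkm_of({"c": (0.0, 0.5)})) == [c]

    def test_single_exon_threshold_two(self):
        c = tx("c", "chr1", "+", [(0, 300)])
        assert filter_expression([c], fpkm_of({"c": (1.9, 1.9)})) == []
        assert filter_expression([c], fpkm_of({"c": (2.0, 0.0)})) == [c]

    def test_missing_candidate_raises_with_ids(self):
        c = tx("absent", "chr1", "+", [(0, 300)])
        with pytest.raises(KeyError, match="absent"):
            filter_expression([c], fpkm_of({"other": (1.0, 1.0)}))


class TestSingleExonProximity:
    def test_same_strand_gap_within_window_discarded(self):
        c = tx("c", "chr1", "+", [(1000, 1200)])
        n = tx("n", "chr1", "+", [(400, 900)])
        assert filter_single_exon_proximity([c], [c, n]) == []

    def test_opposite_strand_neighbor_ignored(self):
        c = tx("c", "chr1", "+", [(1000, 1200)])
        n = tx("n", "chr1", "-", [(400, 900)])
        assert filter_single_exon_proximity([c], [c, n]) == [c]

    def test_gap_boundary_at_window(self):
        c = tx("c", "chr1", "+", [(1000, 1200)])
        at_500 = tx("n", "chr1", "+", [(0, 500)])  # gap exactly 500
        at_501 = tx("n", "chr1", "+", [(0, 499)])  # gap 501
        assert filter_single_exon_proximity([c], [c, at_500]) == []
        assert filter_single_exon_proximity([c], [c, at_501]) == [c]

    def test_multi_exon_candidates_unaffected(self):
        c = tx("c", "chr1", "+", [(1000, 1100), (1300, 1400)])
        n = tx("n", "chr1", "+", [(900, 990)])
        assert filter_single_exon_proximity([c], [c, n]) == [c]

    def test_boundary_agrees_with_brute_force_scan(self, rng):
        for _ in range(200):
            others = [
                tx(f"n{i}", "chr1", "+",
                   [(int(s), int(s) + int(rng.integers(50, 400)))])
                for i, s in enumerate(rng.integers(0, 20000, size=8))
            ]
            s = int(rng.integers(0, 20000))
            c = tx("c", "chr1", "+", [(s, s + 250)])
            kept = filter_single_exon_proximity([c], others + [c])
            gaps = [
                max(0, max(o.span.start, s) - min(o.span.end, s + 250))
                for o in others
            ]
            assert (kept == [c]) == (min(gaps) > 500)


class TestCodingPotential:
    def test_external_scores_rule(self):
        genome = {"chr1": "A" * 1000}
        a = tx("a", "chr1", "+", [(0, 300)])
        b = tx("b", "chr1", "+", [(400, 700)])
        kept = coding_potential_filter(
            [a, b], genome, external_scores={"a": 1.2, "b": -0.5}
        )
        assert [t.id for t in kept] == ["b"]
        kept = coding_potential_filter(
            [a, b], genome, external_scores={"a": 1.2, "b": -0.5},
            pfam_hits=["b"],
        )
        assert kept == []

    def test_surrogate_long_orf_discarded(self, rng):
        # 103-codon ORF (>= 100) embedded in a 350 nt transcript
        from ricelnc.synth import _random_cds

        orf = _random_cds(rng, 102)  # ATG + 102 codons + stop = 312 nt
        seq = "CCC" + orf + "C" * (350 - len(orf) - 3)
        genome = {"chr1": seq}
        c = tx("c", "chr1", "+", [(0, 350)])
        assert longest_orf_codons(seq) >= 100
        assert coding_potential_filter([c], genome) == []

    def test_surrogate_stop_rich_transcript_kept(self):
        # stops in every frame well before codon 100
        seq = ("TAATAGTGA" * 40)[:351]
        genome = {"chr1": seq}
        c = tx("c", "chr1", "+", [(0, 351)])
        # brute-force ORF enumeration confirms no >= 100 codon ORF
        stops = {"TAA", "TAG", "TGA"}
        best = 0
        for f in range(3):
            codons = [seq[i : i + 3] for i in range(f, len(seq) - 2, 3)]
            start = None
            for idx, c3 in enumerate(codons):
                if start is None and c3 == "ATG":
                    start = idx
                elif start is not None and c3 in stops:
                    best = max(best, idx - start)
                    start = None
        assert best < 100
        assert coding_potential_filter(
            [c], genome
        ) == [c]

    def test_minus_strand_uses_reverse_complement(self, rng):
        from ricelnc.synth import _random_cds
        from ricelnc.types import reverse_complement

        orf = _random_cds(rng, 150)
        genome = {"chr1": reverse_complement(orf)}
        c = tx("c", "chr1", "-", [(0, len(orf))])
        assert coding_potential_filter([c], genome) == []


class TestRunIdentification:
    def test_empty_candidates_valid_report(self, bundle):
        kept, report = run_identification(
            [], bundle.annotation, bundle.genome, bundle.fpkm
        )
        assert kept == []
        assert len(report.table) == 0
        assert report.filter_order == FILTER_ORDER

    def test_kept_set_is_subset_and_verdicts_partition(self, bundle, identified):
        lnc, report = identified
        kept_ids = set(t.id for t in lnc)
        assert kept_ids <= set(t.id for t in bundle.candidates)
        assert (report.table["verdict"] == "kept").sum() == len(lnc)
        discarded = report.table[report.table["verdict"] == "discarded"]
        assert (discarded["discarding_filter"] != "").all()
        kept_rows = report.table[report.table["verdict"] == "kept"]
        assert (kept_rows["discarding_filter"] == "").all()

    def test_kept_set_equals_intersection_of_pure_predicates(self, bundle, identified):
        # each filter applied standalone to the full candidate list; the
        # intersection must equal the cascade's kept set (order independence)
        cands = bundle.candidates
        all_tx = list(bundle.annotation) + list(cands)
        survivors = [
            set(t.id for t in filter_strandless(cands)),
            set(t.id for t in filter_sense_overlap(cands, bundle.annotation)),
            set(t.id for t in filter_length(cands)),
            set(t.id for t in filter_expression(cands, bundle.fpkm)),
            set(t.id for t in filter_single_exon_proximity(cands, all_tx)),
            set(t.id for t in coding_potential_filter(cands, bundle.genome)),
        ]
        lnc, _ = identified
        assert set.intersection(*survivors) == set(t.id for t in lnc)
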