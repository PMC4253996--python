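"""Sequence / conservation / overlap statistics."""

import numpy as np
import pytest

from ricelnc.characterize import (
    aligned_fraction,
    au_content,
    conserved_elements,
    exon_stats,
    mean_conservation,
    percent,
    repeat_overlap,
    srna_overlap,
)
from ricelnc.types import ConservationTrack, GenomicInterval, Transcript


def tx(tid, chrom, strand, exons):
    return Transcript(
        tid, tid,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


class TestExonStats:
    def test_two_exon_example(self):
        t = tx("t", "chr1", "+", [(0, 100), (200, 400)])
        s = exon_stats([t])
        assert s.mean_exon_count == 2
        assert s.median_exon_length == 150
        assert s.median_transcript_length == 300
        assert s.spliced_fraction == 1.0

    def test_single_exon_set_spliced_fraction_zero(self):
        s = exon_stats([tx("a", "chr1", "+", [(0, 300)]),
                        tx("b", "chr1", "+", [(500, 900)])])
        assert s.spliced_fraction == 0.0

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            exon_stats([])

    def test_generator_exon_count_target_recovered(self, bundle, lincs):
        s = exon_stats(lincs)
        assert abs(s.mean_exon_count - 2.2) <= 0.3


class TestAuContent:
    @pytest.mark.parametrize(
        "seq, expected",
        [("AUAU", 1.0), ("ATAT", 1.0), ("GCGC", 0.0), ("ATGNNC", 0.5)],
    )
    def test_examples(self, seq, expected):
        assert au_content(seq) == pytest.approx(expected)

    def test_all_n_raises(self):
        with pytest.raises(ValueError):
            au_content("NNNN")

    def test_minus_strand_transcript_uses_transcribed_sense(self):
        # genome AAAA -> minus-strand transcript reads UUUU; A/U content is
        # 1.0 either way, so use an asymmetric check via G/C
        genome = {"chr1": "AAGG"}
        t = tx("t", "chr1", "-", [(0, 4)])
        assert au_content(t, genome) == pytest.approx(0.5)

    def test_planted_au_gap_between_lincrna_and_cds(self, bundle, lincs, mrnas):
        lnc_au = np.mean([au_content(t, bundle.genome) for t in lincs])
        cds_au = np.mean([au_content(t, bundle.genome) for t in mrnas])
        assert lnc_au - cds_au > 0.05


class TestRepeatAndSrnaOverlap:
    def test_transcript_fraction_counts_any_touch(self):
        txs = [tx(f"t{i}", "chr1", "+", [(i * 1000, i * 1000 + 100)])
               for i in range(4)]
        repeats = [GenomicInterval("chr1", 99, 150)]  # 1 bp into t0
        tf, _bf = repeat_overlap(txs, repeats)
        assert tf == pytest.approx(0.25)

    def test_base_fraction_half_covered(self):
        t = tx("t", "chr1", "+", [(0, 100)])
        tf, bf = repeat_overlap([t], [GenomicInterval("chr1", 0, 50)])
        assert (tf, bf) == (1.0, 0.5)

    def test_fragmented_repeats_never_overcount(self):
        t = tx("t", "chr1", "+", [(0, 100)])
        frags = [GenomicInterval("chr1", 0, 30),
                 GenomicInterval("chr1", 20, 50),
                 GenomicInterval("chr1", 40, 50)]
        _, bf = repeat_overlap([t], frags)
        assert bf == pytest.approx(0.5)

    def test_agrees_with_base_set_oracle(self, rng):
        for _ in range(200):
            exons = []
            pos = int(rng.integers(0, 200))
            for _ in range(int(rng.integers(1, 4))):
                ln = int(rng.integers(30, 200))
                exons.append((pos, pos + ln))
                pos += ln + int(rng.integers(20, 100))
            t = tx("t", "chr1", "+", exons)
            reps = []
            for _ in range(int(rng.integers(0, 5))):
                s = int(rng.integers(0, 1200))
                reps.append(GenomicInterval("chr1", s, s + int(rng.integers(10, 300))))
            tf, bf = repeat_overlap([t], reps)
            ebases = set()
            for s, e in exons:
                ebases.update(range(s, e))
            rbases = set()
            for r in reps:
                rbases.update(range(r.start, r.end))
            inter = len(ebases & rbases)
            assert tf == (1.0 if inter else 0.0)
            assert bf == pytest.approx(inter / len(ebases))

    def test_srna_paper_style_fractions(self):
        # 122 of 1,624 -> 7.5%; 44 of 600 -> 7.3% at one decimal
        assert percent(122 / 1624) == 7.5
        assert percent(44 / 600) == 7.3

    def test_srna_counts(self):
        txs = [tx(f"t{i}", "chr1", "+", [(i * 1000, i * 1000 + 100)])
               for i in range(3)]
        count, frac = srna_overlap(txs, [GenomicInterval("chr1", 0, 10)])
        assert (count, frac) == (1, pytest.approx(1 / 3))
        assert srna_overlap(txs, []) == (0, 0.0)

    def test_srna_stranded_mode(self):
        t = tx("t", "chr1", "+", [(0, 100)])
        minus_locus = [GenomicInterval("chr1", 0, 50, "-")]
        assert srna_overlap([t], minus_locus, stranded=True)[0] == 0
        assert srna_overlap([t], minus_locus, stranded=False)[0] == 1


class TestConservation:
    def make_track(self, values):
        return ConservationTrack({"chr1": np.array(values, dtype=float)})

    def test_aligned_fraction(self):
        arr = np.full(200, np.nan)
        arr[:50] = 0.5
        track = self.make_track(arr)
        assert aligned_fraction(
            [GenomicInterval("chr1", 0, 200)], track
        ) == pytest.approx(0.25)
        assert aligned_fraction(
            [GenomicInterval("chr1", 0, 50)], track
        ) == 1.0

    def test_region_beyond_track_is_missing(self):
        track = self.make_track([0.5, 0.5])
        assert aligned_fraction(
            [GenomicInterval("chr1", 0, 4)], track
        ) == pytest.approx(0.5)

    def test_planted_alignment_ordering(self, bundle, lincs, mrnas):
        linc_exons = [e for t in lincs for e in t.exons]
        coding_exons = [e for t in mrnas for e in t.exons]
        assert aligned_fraction(coding_exons, bundle.track) > aligned_fraction(
            linc_exons, bundle.track
        )

    def test_mean_conservation_with_missing(self):
        track = self.make_track([0.2, 0.4, np.nan])
        means = mean_conservation(
            {"f": [GenomicInterval("chr1", 0, 3)]}, track
        )
        assert means["f"] == pytest.approx(0.3)

    def test_all_missing_feature_reported_missing(self):
        track = self.make_track([np.nan, np.nan])
        means = mean_conservation(
            {"f": [GenomicInterval("chr1", 0, 2)]}, track
        )
        assert np.isnan(means["f"])

    def test_means_match_resummation_oracle(self, bundle, rng):
        chrom = "chr1"
        n = bundle.track.chrom_length(chrom)
        features = {}
        for i in range(100):
            s = int(rng.integers(0, n - 500))
            features[f"f{i}"] = [GenomicInterval(chrom, s, s + 300)]
        means = mean_conservation(features, bundle.track)
        for fid, regions in features.items():
            (r,) = regions
            vals = bundle.track.scores(chrom, r.start, r.end)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                assert np.isnan(means[fid])
            else:
                assert means[fid] == pytest.approx(vals.sum() / vals.size)

    def test_conserved_element_examples(self):
        arr = np.concatenate([np.full(10, 0.1), np.full(20, 0.9),
                              np.full(10, 0.1)])
        track = self.make_track(arr)
        (el,) = conserved_elements([GenomicInterval("chr1", 0, 40)], track)
        assert (el.start, el.end) == (10, 30)
        arr14 = np.concatenate([np.full(10, 0.1), np.full(14, 0.9),
                                np.full(10, 0.1)])
        assert conserved_elements(
            [GenomicInterval("chr1", 0, 34)], self.make_track(arr14)
        ) == []

    def test_conserved_elements_match_brute_force_scan(self, rng):
        for _ in range(100):
            arr = np.full(300, np.nan)
            for _ in range(10):
                s = int(rng.integers(0, 280))
                arr[s : s + int(rng.integers(5, 40))] = round(float(rng.random()), 3)
            track = self.make_track(arr)
            got = conserved_elements(
                [GenomicInterval("chr1", 0, 300)], track, 15, 0.8
            )
            # brute-force run scan
            want = []
            run = 0
            for i in range(301):
                ok = i < 300 and not np.isnan(arr[i]) and arr[i] >= 0.8
                if ok:
                    run += 1
                else:
                    if run >= 15:
                        want.append((i - run, i))
                    run = 0
            assert [(e.start, e.end) for e in got] == want


class TestPercent:
    def test_round_half_even_one_decimal(self):
        assert percent(30219 / 39045) == 77.4
        assert percent(0.12345) == 12.3
        # round-half-even at the boundary
        assert percent(0.1205) == 12.0
        assert percent(0.1215) == 12.2
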