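"""Genomic, sequence and conservation characterization of transcript sets.

Covers exon-structure statistics, A/U content of transcribed sequence,
repeat and sRNA-locus overlap, the fraction of residues aligned in a
multiple-genome alignment (a base is "aligned" iff the conservation track
has a score for it), per-feature mean conservation, and detection of short
conserved elements (maximal runs of consecutive bases at or above a score
threshold).

Repeat and sRNA overlap are strand-agnostic by default — repeat annotations
are usually strandless — with a stranded mode for sRNA loci, where the
deriving strand is informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import merge_intervals
from .types import ConservationTrack, GenomicInterval, Transcript


def percent(x: float, decimals: int = 1) -> float:
    """Format a fraction as a percentage, round-half-even at ``decimals``."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x * 100)).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass
class FeatureStats:
    n_transcripts: int
    exon_counts: np.ndarray
    mean_exon_count: float
    median_exon_length: float
    median_transcript_length: float
    spliced_fraction: float


def exon_stats(transcripts: Sequence[Transcript]) -> FeatureStats:
    if not transcripts:
        raise ValueError("exon_stats requires a non-empty transcript set")
    exon_counts = np.array([tx.n_exons for tx in transcripts])
    exon_lengths = np.array(
        [len(e) for tx in transcripts for e in tx.exons]
    )
    tx_lengths = np.array([tx.length for tx in transcripts])
    return FeatureStats(
        n_transcripts=len(transcripts),
        exon_counts=exon_counts,
        mean_exon_count=float(exon_counts.mean()),
        median_exon_length=float(np.median(exon_lengths)),
        median_transcript_length=float(np.median(tx_lengths)),
        spliced_fraction=float((exon_counts >= 2).mean()),
    )


def au_content(seq_or_transcript, genome: Optional[Mapping[str, str]] = None) -> float:
    """(#A + #U) / length of transcribed sequence, N excluded both sides.

    Accepts a raw sequence (DNA or RNA) or a Transcript plus genome, in
    which case the spliced transcript-strand sequence is used.
    """
    if isinstance(seq_or_transcript, Transcript):
        if genome is None:
            raise ValueError("genome required for a Transcript argument")
        seq = seq_or_transcript.spliced_sequence(genome)
    else:
        seq = str(seq_or_transcript)
    seq = seq.upper().replace("U", "T")
    counted = [c for c in seq if c != "N"]
    if not counted:
        raise ValueError("zero-length sequence after N removal")
    at = sum(1 for c in counted if c in "AT")
    return at / len(counted)


def _interval_tree(
    intervals: Iterable[GenomicInterval], stranded: bool
) -> Dict[Tuple[str, str], IntervalTree]:
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for iv in intervals:
        key = (iv.chrom, iv.strand if stranded else ".")
        trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _exon_covered_bases(
    tx: Transcript,
    trees: Dict[Tuple[str, str], IntervalTree],
    stranded: bool,
) -> int:
    pieces: List[Tuple[int, int]] = []
    keys = [(tx.chrom, tx.strand)] if stranded else [(tx.chrom, ".")]
    for key in keys:
        tree = trees.get(key)
        if tree is None:
            continue
        for e in tx.exons:
            for hit in tree.overlap(e.start, e.end):
                pieces.append((max(e.start, hit.begin), min(e.end, hit.end)))
    return sum(e - s for s, e in merge_intervals(pieces))


def repeat_overlap(
    transcripts: Sequence[Transcript], repeats: Sequence[GenomicInterval]
) -> Tuple[float, float]:
    """(fraction of transcripts touching a repeat, fraction of exonic bases
    inside repeats). Strand-agnostic; base fraction uses union semantics so
    fragmented repeat annotations never overcount."""
    if not transcripts:
        return 0.0, 0.0
    trees = _interval_tree(repeats, stranded=False)
    touched = 0
    covered_bases = 0
    total_bases = 0
    for tx in transcripts:
        c = _exon_covered_bases(tx, trees, stranded=False)
        if c > 0:
            touched += 1
        covered_bases += c
        total_bases += tx.length
    return touched / len(transcripts), covered_bases / total_bases


def srna_overlap(
    transcripts: Sequence[Transcript],
    srna_loci: Sequence[GenomicInterval],
    stranded: bool = False,
) -> Tuple[int, float]:
    """Count and fraction of transcripts with >= 1 bp exonic overlap with an
    sRNA locus ("generating sRNAs")."""
    if not transcripts:
        return 0, 0.0
    trees = _interval_tree(srna_loci, stranded=stranded)
    count = sum(
        1
        for tx in transcripts
        if _exon_covered_bases(tx, trees, stranded=stranded) > 0
    )
    return count, count / len(transcripts)


def aligned_fraction(
    regions: Sequence[GenomicInterval], track: ConservationTrack
) -> float:
    """Fraction of region bases carrying a present (non-missing) score.

    Bases beyond the stored track are treated as missing.
    """
    scores = track.region_scores(regions)
    if scores.size == 0:
        raise ValueError("aligned_fraction over an empty region set")
    return float((~np.isnan(scores)).mean())


def mean_conservation(
    features: Mapping[str, Sequence[GenomicInterval]],
    track: ConservationTrack,
) -> pd.Series:
    """Per-feature mean score over present bases (NaN when none present).

    The cumulative distribution over non-missing features is available via
    :func:`conservation_cdf`.
    """
    means = {}
    for fid, regions in features.items():
        scores = track.region_scores(regions)
        present = scores[~np.isnan(scores)]
        means[fid] = float(present.mean()) if present.size else np.nan
    return pd.Series(means, name="mean_cons_score")


def conservation_cdf(means: pd.Series) -> Tuple[np.ndarray, np.ndarray]:
    """Empirical CDF (x, F(x)) over features with a defined mean score."""
    vals = np.sort(means.dropna().to_numpy())
    if vals.size == 0:
        return np.empty(0), np.empty(0)
    return vals, np.arange(1, vals.size + 1) / vals.size


def conserved_elements(
    regions: Sequence[GenomicInterval],
    track: ConservationTrack,
    min_len: int = 15,
    min_score: float = 0.8,
) -> List[GenomicInterval]:
    """Maximal runs of >= min_len consecutive bases with present score
    >= min_score, scanned within each region; sorted, non-overlapping."""
    if min_len <= 0 or min_score <= 0:
        raise ValueError("thresholds must be positive")
    found: List[GenomicInterval] = []
    seen = set()
    for r in regions:
        scores = track.scores(r.chrom, r.start, r.end)
        ok = (~np.isnan(scores)) & (scores >= min_score)
        # run boundaries via diff on the padded boolean mask
        padded = np.concatenate(([False], ok, [False])).astype(int)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                key = (r.chrom, r.start + int(s), r.start + int(e))
                if key not in seen:
                    seen.add(key)
                    found.append(GenomicInterval(*key))
    found.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return found


def exonic_regions(tx: Transcript) -> List[GenomicInterval]:
    return list(tx.exons)


def summarize_sets(
    sets: Mapping[str, Sequence[Transcript]],
    genome: Mapping[str, str],
    repeats: Sequence[GenomicInterval],
    srna_loci: Sequence[GenomicInterval],
    track: ConservationTrack,
) -> pd.DataFrame:
    """One summary row per named transcript set (percentages at 1 decimal)."""
    rows = []
    for name, txs in sets.items():
        if not txs:
            continue
        stats = exon_stats(txs)
        au = float(
            np.mean([au_content(tx, genome) for tx in txs])
        )
        tx_frac, base_frac = repeat_overlap(txs, repeats)
        n_srna, srna_frac = srna_overlap(txs, srna_loci)
        exons = [e for tx in txs for e in tx.exons]
        rows.append(
            {
                "set": name,
                "n": stats.n_transcripts,
                "mean_exon_count": stats.mean_exon_count,
                "median_exon_length": stats.median_exon_length,
                "median_transcript_length": stats.median_transcript_length,
                "spliced_pct": percent(stats.spliced_fraction),
                "mean_au": au,
                "repeat_transcript_pct": percent(tx_frac),
                "repeat_base_pct": percent(base_frac),
                "srna_count": n_srna,
                "srna_pct": percent(srna_frac),
                "aligned_pct": percent(aligned_fraction(exons, track)),
                "mean_cons": float(
                    mean_conservation(
                        {tx.id: tx.exons for tx in txs}, track
                    ).mean()
                ),
            }
        )
    return pd.DataFrame(rows).set_index("set")
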