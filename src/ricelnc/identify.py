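"""lncRNA identification: the filter cascade.

Assembled candidate transcripts are passed through six pure predicates —
strand known, no sense exonic overlap with annotated genes, spliced length
>= 200 nt, expression above the FPKM floor (0.5 for multi-exon, 2 for
single-exon transcripts, taken as the max over samples), single-exon
transcripts not within 500 bp of another same-strand transcript, and no
protein-coding potential. Because every filter is a pure predicate, the
surviving set is order-independent; the report's "first failed filter" is
order-dependent and follows the fixed order above.

Coding potential accepts externally computed classifier scores (discard
score > 0) and protein-domain hit lists; without them, a built-in ORF
surrogate discards transcripts whose longest ATG->stop open reading frame on
the transcript strand (3 forward frames) reaches 100 codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .types import GenomicInterval, Transcript

FILTER_ORDER = (
    "strandless",
    "sense_overlap",
    "length",
    "expression",
    "single_exon_proximity",
    "coding_potential",
)

MIN_LENGTH = 200
FPKM_MULTI = 0.5
FPKM_SINGLE = 2.0
PROXIMITY_WINDOW = 500
ORF_MIN_CODONS = 100

_STOPS = ("TAA", "TAG", "TGA")


def _exon_tree_by_strand(
    transcripts: Iterable[Transcript],
) -> Dict[Tuple[str, str], IntervalTree]:
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for tx in transcripts:
        for e in tx.exons:
            trees.setdefault((e.chrom, e.strand), IntervalTree()).addi(
                e.start, e.end, tx.id
            )
    return trees


def filter_strandless(candidates: Sequence[Transcript]) -> List[Transcript]:
    return [tx for tx in candidates if tx.strand in ("+", "-")]


def _has_sense_overlap(
    tx: Transcript, trees: Dict[Tuple[str, str], IntervalTree]
) -> bool:
    if tx.strand == ".":
        # An unstranded candidate overlaps "in sense" if it touches a known
        # exon on either strand (its orientation cannot exonerate it).
        strands = ("+", "-")
    else:
        strands = (tx.strand,)
    for strand in strands:
        tree = trees.get((tx.chrom, strand))
        if tree is None:
            continue
        for e in tx.exons:
            if tree.overlap(e.start, e.end):
                return True
    return False


def filter_sense_overlap(
    candidates: Sequence[Transcript], known: Sequence[Transcript]
) -> List[Transcript]:
    """Discard candidates with >= 1 bp exonic overlap with a known gene's
    exon on the same strand. Antisense overlap does not discard (those are
    the lncNAT candidates); sense intronic nesting is kept (exon-level rule).
    """
    trees = _exon_tree_by_strand(known)
    return [tx for tx in candidates if not _has_sense_overlap(tx, trees)]


def filter_length(
    candidates: Sequence[Transcript], min_len: int = MIN_LENGTH
) -> List[Transcript]:
    return [tx for tx in candidates if tx.length >= min_len]


def _max_fpkm(tx_id: str, fpkm: pd.DataFrame) -> float:
    return float(fpkm.loc[tx_id].max())


def filter_expression(
    candidates: Sequence[Transcript],
    fpkm: pd.DataFrame,
    multi_threshold: float = FPKM_MULTI,
    single_threshold: float = FPKM_SINGLE,
) -> List[Transcript]:
    missing = [tx.id for tx in candidates if tx.id not in fpkm.index]
    if missing:
        raise KeyError(
            f"candidates absent from expression matrix: {sorted(missing)}"
        )
    kept = []
    for tx in candidates:
        threshold = single_threshold if tx.n_exons == 1 else multi_threshold
        if _max_fpkm(tx.id, fpkm) >= threshold:
            kept.append(tx)
    return kept


def _min_same_strand_gap(
    tx: Transcript, spans: Dict[Tuple[str, str], List[Tuple[int, int, str]]]
) -> Optional[int]:
    """Smallest gap (0 if overlapping) to another same-strand transcript."""
    best: Optional[int] = None
    for s, e, other_id in spans.get((tx.chrom, tx.strand), ()):
        if other_id == tx.id:
            continue
        g = max(0, max(s, tx.span.start) - min(e, tx.span.end))
        if best is None or g < best:
            best = g
    return best


def filter_single_exon_proximity(
    candidates: Sequence[Transcript],
    all_transcripts: Sequence[Transcript],
    window: int = PROXIMITY_WINDOW,
) -> List[Transcript]:
    """Discard single-exon candidates with another same-strand transcript
    overlapping them or within ``window`` bp ("sense direction" read as
    same strand: fragments of one transcript share its strand). Multi-exon
    candidates are unaffected; unstranded neighbors never count as
    same-strand.
    """
    spans: Dict[Tuple[str, str], List[Tuple[int, int, str]]] = {}
    for tx in all_transcripts:
        spans.setdefault((tx.chrom, tx.strand), []).append(
            (tx.span.start, tx.span.end, tx.id)
        )
    kept = []
    for tx in candidates:
        if tx.n_exons > 1:
            kept.append(tx)
            continue
        g = _min_same_strand_gap(tx, spans)
        if g is None or g > window:
            kept.append(tx)
    return kept


def longest_orf_codons(seq: str) -> int:
    """Longest ATG->stop ORF over the 3 forward frames, in codons
    (ATG included, stop excluded). ORFs without an in-frame stop don't count.
    """
    seq = seq.upper().replace("U", "T")
    best = 0
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, (i - start) // 3)
                start = None
    return best


def coding_potential_filter(
    candidates: Sequence[Transcript],
    genome: Mapping[str, str],
    external_scores: Optional[Mapping[str, float]] = None,
    pfam_hits: Optional[Iterable[str]] = None,
    orf_min_codons: int = ORF_MIN_CODONS,
) -> List[Transcript]:
    """Keep non-coding candidates.

    With ``external_scores`` (classifier output), discard score > 0; ids in
    ``pfam_hits`` (protein-domain matches) are additionally discarded. With
    no external table the ORF surrogate applies: discard iff the longest
    forward-frame ORF on the transcript strand reaches ``orf_min_codons``.
    """
    hits = set(pfam_hits) if pfam_hits else set()
    kept = []
    for tx in candidates:
        if tx.id in hits:
            continue
        if external_scores is not None:
            if tx.id not in external_scores:
                raise KeyError(f"no external coding score for {tx.id}")
            if external_scores[tx.id] > 0:
                continue
        elif longest_orf_codons(tx.spliced_sequence(genome)) >= orf_min_codons:
            continue
        kept.append(tx)
    return kept


@dataclass
class FilterReport:
    """Per-transcript verdicts from one cascade run."""

    table: pd.DataFrame
    filter_order: Tuple[str, ...] = FILTER_ORDER

    @property
    def kept_ids(self) -> List[str]:
        return list(self.table.index[self.table["verdict"] == "kept"])

    def discarding_filter(self, tx_id: str) -> str:
        return self.table.loc[tx_id, "discarding_filter"]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# filter_order: {','.join(self.filter_order)}\n")
            self.table.to_csv(fh, sep="\t", index_label="transcript_id")


def run_identification(
    candidates: Sequence[Transcript],
    annotation: Sequence[Transcript],
    genome: Mapping[str, str],
    fpkm: pd.DataFrame,
    external_scores: Optional[Mapping[str, float]] = None,
    pfam_hits: Optional[Iterable[str]] = None,
    min_len: int = MIN_LENGTH,
    multi_threshold: float = FPKM_MULTI,
    single_threshold: float = FPKM_SINGLE,
    window: int = PROXIMITY_WINDOW,
    orf_min_codons: int = ORF_MIN_CODONS,
    disable: Iterable[str] = (),
) -> Tuple[List[Transcript], FilterReport]:
    """Run the full cascade; returns surviving lncRNAs and a FilterReport.

    ``disable`` names filters to skip (used for ablation analyses). The
    report records, per transcript, the first failed filter in the fixed
    order plus the measured values each filter looked at.
    """
    disable = set(disable)
    unknown = disable - set(FILTER_ORDER)
    if unknown:
        raise ValueError(f"unknown filters: {sorted(unknown)}")

    known_trees = _exon_tree_by_strand(annotation)
    all_tx = list(annotation) + list(candidates)
    spans: Dict[Tuple[str, str], List[Tuple[int, int, str]]] = {}
    for tx in all_tx:
        spans.setdefault((tx.chrom, tx.strand), []).append(
            (tx.span.start, tx.span.end, tx.id)
        )
    hits = set(pfam_hits) if pfam_hits else set()

    rows = []
    kept: List[Transcript] = []
    for tx in candidates:
        if tx.id not in fpkm.index:
            raise KeyError(f"candidate absent from expression matrix: {tx.id}")
        max_fpkm = _max_fpkm(tx.id, fpkm)
        min_gap = (
            _min_same_strand_gap(tx, spans) if tx.n_exons == 1 else None
        )
        if external_scores is not None:
            score = external_scores.get(tx.id)
            orf = None
        else:
            score = None
            orf = longest_orf_codons(tx.spliced_sequence(genome))

        failures = {
            "strandless": tx.strand == ".",
            "sense_overlap": _has_sense_overlap(tx, known_trees),
            "length": tx.length < min_len,
            "expression": max_fpkm
            < (single_threshold if tx.n_exons == 1 else multi_threshold),
            "single_exon_proximity": (
                tx.n_exons == 1 and min_gap is not None and min_gap <= window
            ),
            "coding_potential": (
                tx.id in hits
                or (score is not None and score > 0)
                or (orf is not None and orf >= orf_min_codons)
            ),
        }
        first_failed = next(
            (f for f in FILTER_ORDER if f not in disable and failures[f]), ""
        )
        verdict = "kept" if not first_failed else "discarded"
        if verdict == "kept":
            kept.append(tx)
        rows.append(
            {
                "transcript_id": tx.id,
                "verdict": verdict,
                "discarding_filter": first_failed,
                "length_nt": tx.length,
                "n_exons": tx.n_exons,
                "max_fpkm": max_fpkm,
                "min_sense_gap": min_gap if min_gap is not None else -1,
                "coding_score": score if score is not None else float("nan"),
                "orf_codons": orf if orf is not None else -1,
                "pfam_hit": tx.id in hits,
            }
        )
    table = pd.DataFrame(rows).set_index("transcript_id") if rows else pd.DataFrame(
        columns=[
            "verdict",
            "discarding_filter",
            "length_nt",
            "n_exons",
            "max_fpkm",
            "min_sense_gap",
            "coding_score",
            "orf_codons",
            "pfam_hit",
        ]
    )
    return kept, FilterReport(table)
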