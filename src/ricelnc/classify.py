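"""lincRNA / lncNAT classification and lincRNA-neighbor geometry.

An identified lncRNA is a lncNAT when at least one of its exons overlaps an
exon of a non-TE protein-coding mRNA on the opposite strand by >= 1 bp;
otherwise it is a lincRNA. The overlap fraction is the base-union of
antisense-overlapped exonic bases divided by the lncRNA's exonic (spliced)
length, so fragmented mRNA exons never double-count.

Neighbor orientation is purely positional (closest coding gene by span gap
on the same chromosome, ties to the lexicographically smaller gene id):
divergent = head-to-head 5' ends, convergent = tail-to-tail 3' ends,
tandem = same strand, overlapping = span overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .intervals import merge_intervals
from .types import Transcript

_OPPOSITE = {"+": "-", "-": "+"}


@dataclass
class LncRNACall:
    transcript: Transcript
    lnc_class: str  # "lincRNA" | "lncNAT"
    overlap_fraction: float
    closest_gene: Optional[str] = None
    distance: Optional[int] = None  # signed; >0 gene right of lncRNA
    orientation: Optional[str] = None  # divergent|convergent|tandem|overlapping

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction outside [0, 1]")
        if (self.lnc_class == "lncNAT") != (self.overlap_fraction > 0):
            raise ValueError("lncNAT <=> overlap_fraction > 0 violated")


def antisense_overlap_fraction(
    lnc: Transcript, mrna_exon_trees: Dict[Tuple[str, str], IntervalTree]
) -> float:
    """Fraction of lncRNA exonic bases antisense-overlapped by mRNA exons."""
    if lnc.strand not in _OPPOSITE:
        return 0.0
    tree = mrna_exon_trees.get((lnc.chrom, _OPPOSITE[lnc.strand]))
    if tree is None:
        return 0.0
    pieces: List[Tuple[int, int]] = []
    for e in lnc.exons:
        for hit in tree.overlap(e.start, e.end):
            pieces.append((max(e.start, hit.begin), min(e.end, hit.end)))
    if not pieces:
        return 0.0
    covered = sum(e - s for s, e in merge_intervals(pieces))
    return covered / lnc.length


def classify_lnc(
    lncRNAs: Sequence[Transcript], mRNAs: Sequence[Transcript]
) -> List[LncRNACall]:
    """Partition lncRNAs into lincRNA / lncNAT against non-TE mRNA exons.

    ``mRNAs`` should already exclude TE-related mRNAs; any passed with
    biotype TE_mRNA are ignored for the antisense test.
    """
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for m in mRNAs:
        if m.biotype == "TE_mRNA":
            continue
        for e in m.exons:
            trees.setdefault((e.chrom, e.strand), IntervalTree()).addi(
                e.start, e.end, m.id
            )
    calls = []
    for lnc in lncRNAs:
        frac = antisense_overlap_fraction(lnc, trees)
        calls.append(
            LncRNACall(
                lnc,
                "lncNAT" if frac > 0 else "lincRNA",
                frac,
            )
        )
    return calls


def _orientation(lnc: Transcript, gene: Transcript) -> str:
    a, b = lnc.span, gene.span
    if min(a.end, b.end) > max(a.start, b.start):
        return "overlapping"
    if lnc.strand == gene.strand:
        return "tandem"
    gene_left = b.end <= a.start
    # Opposite strands: which ends face each other across the gap?
    if lnc.strand == "+":
        # lnc 5' end is its left edge.
        return "divergent" if gene_left else "convergent"
    return "convergent" if gene_left else "divergent"


def neighbor_orientation(
    lnc: Transcript, coding_genes: Sequence[Transcript]
) -> Tuple[Optional[str], Optional[int], Optional[str]]:
    """Closest coding gene by minimal span gap on the lncRNA's chromosome.

    Returns (gene_id, signed distance, orientation); distance is the gap in
    bases, positive when the gene lies right of the lncRNA, 0 when spans
    overlap. (None, None, None) when the chromosome has no coding gene.
    """
    best: Optional[Tuple[int, str, Transcript]] = None
    for g in coding_genes:
        if g.chrom != lnc.chrom:
            continue
        gp = max(
            0, max(g.span.start, lnc.span.start) - min(g.span.end, lnc.span.end)
        )
        key = (gp, g.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (gp, g.gene_id, g)
    if best is None:
        return None, None, None
    gp, gid, gene = best
    signed = gp if gene.span.start >= lnc.span.start else -gp
    if gp == 0 and min(gene.span.end, lnc.span.end) > max(
        gene.span.start, lnc.span.start
    ):
        signed = 0
    return gid, signed, _orientation(lnc, gene)


def annotate_neighbors(
    calls: Sequence[LncRNACall], coding_genes: Sequence[Transcript]
) -> List[LncRNACall]:
    """Fill closest-gene fields on lincRNA calls (lncNATs get their
    antisense host via the same positional search; orientation for spans
    that overlap is reported as "overlapping")."""
    for call in calls:
        gid, dist, orient = neighbor_orientation(call.transcript, coding_genes)
        call.closest_gene = gid
        call.distance = dist
        call.orientation = orient
    return list(calls)


def calls_to_frame(calls: Sequence[LncRNACall]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": c.transcript.id,
            "lnc_class": c.lnc_class,
            "overlap_fraction": c.overlap_fraction,
            "closest_gene": c.closest_gene or "",
            "distance": c.distance if c.distance is not None else "",
            "orientation": c.orientation or "",
        }
        for c in calls
    ]
    return pd.DataFrame(rows).set_index("transcript_id")
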