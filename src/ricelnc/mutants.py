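"""Mapping insertional-mutant flanking sequence tags (FSTs) to lincRNAs.

Each FST is aligned (exact local alignment, match +1 / mismatch -1 / linear
gap -2, both orientations) against every lincRNA's spliced body sequence and
its 1-kb upstream region. Hits are retained when percent identity (matching
columns / alignment columns x 100) is strictly greater than 90 and the
alignment covers a minimum fraction of the FST (default 0.8 — a pure
identity rule with no coverage floor would accept any ~10 bp perfect
micro-match). A hit is classified internal vs upstream by the genomic
position of the FST's 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import Align

from .types import FSTRecord, GenomicInterval, Transcript, reverse_complement

DATABASES = (
    "affjp",
    "cirad",
    "gsnu",
    "ostid",
    "pfg",
    "rmd",
    "ship",
    "trim",
    "ucd",
)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-2,
    )
    return a


@dataclass(frozen=True)
class UpstreamRegion:
    sequence: str  # 5'->3' on the transcript strand
    interval: GenomicInterval
    truncated: bool


def extract_upstream(
    tx: Transcript, genome: Mapping[str, str], length: int = 1000
) -> Optional[UpstreamRegion]:
    """The promoter-proxy region 5' of a transcript on its own strand.

    For + strand, genomic [start - length, start); for - strand,
    [end, end + length) reverse-complemented. Truncated at chromosome
    boundaries (flagged); None when no upstream base exists.
    """
    chrom_seq = genome[tx.chrom]
    if tx.strand == "-":
        start = tx.span.end
        end = min(len(chrom_seq), start + length)
        truncated = end - start < length
        if end <= start:
            return None
        seq = reverse_complement(chrom_seq[start:end])
    else:
        end = tx.span.start
        start = max(0, end - length)
        truncated = end - start < length
        if end <= start:
            return None
        seq = chrom_seq[start:end]
    return UpstreamRegion(
        seq.upper(), GenomicInterval(tx.chrom, start, end, tx.strand), truncated
    )


@dataclass(frozen=True)
class TargetRegion:
    lnc_id: str
    kind: str  # "internal" | "upstream"
    sequence: str  # 5'->3' on the transcript strand
    transcript: Transcript
    upstream: Optional[UpstreamRegion] = None

    def to_genomic(self, pos: int) -> int:
        """Genomic position of a coordinate on this region's sequence."""
        if self.kind == "internal":
            return self.transcript.spliced_to_genomic(pos)
        iv = self.upstream.interval
        if self.transcript.strand == "-":
            return iv.end - 1 - pos
        return iv.start + pos


def prepare_targets(
    lincRNAs: Sequence[Transcript],
    genome: Mapping[str, str],
    upstream_len: int = 1000,
) -> List[TargetRegion]:
    targets: List[TargetRegion] = []
    for tx in lincRNAs:
        targets.append(
            TargetRegion(tx.id, "internal", tx.spliced_sequence(genome), tx)
        )
        up = extract_upstream(tx, genome, upstream_len)
        if up is not None:
            targets.append(TargetRegion(tx.id, "upstream", up.sequence, tx, up))
    return targets


@dataclass
class MutantHit:
    mutant_id: str
    database: str
    lnc_id: str
    region: str  # "internal" | "upstream"
    identity: float  # percent, (90, 100]
    chrom: str
    align_start: int  # genomic span of the aligned target bases
    align_end: int
    orientation: str  # "+" FST as given, "-" reverse-complemented


@dataclass
class AlignmentStats:
    score: float
    identity: float  # percent
    columns: int
    query_aligned: int  # FST bases inside the alignment
    target_range: Tuple[int, int]  # on the target region sequence
    query_range: Tuple[int, int]


def align_stats(query: str, target: str) -> Optional[AlignmentStats]:
    """Best local alignment of query against target (single orientation)."""
    if not query or not target:
        return None
    aligner = _aligner()
    alignments = aligner.align(target, query)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    columns = aln.length
    if columns == 0:
        return None
    identity = counts.identities / columns * 100.0
    t_blocks, q_blocks = aln.aligned
    t_range = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    q_range = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    q_aligned = q_range[1] - q_range[0]
    return AlignmentStats(
        float(aln.score), identity, columns, q_aligned, t_range, q_range
    )


def gapless_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length sequences aligned column by
    column (no gaps); the identity of the full-length gapless alignment."""
    if len(a) != len(b) or not a:
        raise ValueError("gapless identity requires equal non-empty lengths")
    matches = sum(1 for x, y in zip(a.upper(), b.upper()) if x == y)
    return matches / len(a) * 100.0


def map_fst(
    fst: FSTRecord,
    targets: Sequence[TargetRegion],
    min_identity: float = 90.0,
    min_aligned_frac: float = 0.8,
) -> List[MutantHit]:
    """All retained hits of one FST; a single FST may hit several lincRNAs.

    Identity must exceed ``min_identity`` strictly (90.0 exactly is
    rejected). Hits spanning the body/upstream boundary are classified by
    the 5'-end rule alone. Per (FST, lincRNA) the best-identity hit is kept.
    """
    best: Dict[str, MutantHit] = {}
    fst_rc = reverse_complement(fst.sequence)
    for target in targets:
        for orientation, q in (("+", fst.sequence), ("-", fst_rc)):
            stats = align_stats(q, target.sequence)
            if stats is None:
                continue
            if stats.identity <= min_identity:
                continue
            if stats.query_aligned < min_aligned_frac * len(fst.sequence):
                continue
            # FST 5' end: first aligned query base as given; for the
            # reverse-complemented orientation that's the end of the
            # aligned target stretch.
            if orientation == "+":
                five_prime_target = stats.target_range[0]
            else:
                five_prime_target = stats.target_range[1] - 1
            gpos = target.to_genomic(five_prime_target)
            span = target.transcript.span
            if span.start <= gpos < span.end:
                region = "internal"
            elif target.upstream is not None and (
                target.upstream.interval.start
                <= gpos
                < target.upstream.interval.end
            ):
                region = "upstream"
            else:
                region = target.kind
            g0 = target.to_genomic(stats.target_range[0])
            g1 = target.to_genomic(stats.target_range[1] - 1)
            hit = MutantHit(
                fst.mutant_id,
                fst.database,
                target.lnc_id,
                region,
                stats.identity,
                target.transcript.chrom,
                min(g0, g1),
                max(g0, g1) + 1,
                orientation,
            )
            prev = best.get(target.lnc_id)
            if prev is None or hit.identity > prev.identity:
                best[target.lnc_id] = hit
    return [best[k] for k in sorted(best)]


def map_all(
    fsts: Sequence[FSTRecord],
    targets: Sequence[TargetRegion],
    min_identity: float = 90.0,
    min_aligned_frac: float = 0.8,
) -> List[MutantHit]:
    hits: List[MutantHit] = []
    for fst in sorted(fsts, key=lambda f: f.mutant_id):
        hits.extend(map_fst(fst, targets, min_identity, min_aligned_frac))
    return hits


def tabulate_mutants(hits: Sequence[MutantHit]) -> pd.DataFrame:
    """Per-database counts of distinct mutants and lincRNAs, split by
    internal / upstream insertion region."""
    cols = [
        "mutants_internal",
        "lincRNAs_internal",
        "mutants_upstream",
        "lincRNAs_upstream",
        "mutants_total",
        "lincRNAs_total",
    ]
    data: Dict[str, Dict[str, set]] = {}
    for h in hits:
        d = data.setdefault(
            h.database,
            {
                "mi": set(),
                "li": set(),
                "mu": set(),
                "lu": set(),
                "mt": set(),
                "lt": set(),
            },
        )
        if h.region == "internal":
            d["mi"].add(h.mutant_id)
            d["li"].add(h.lnc_id)
        else:
            d["mu"].add(h.mutant_id)
            d["lu"].add(h.lnc_id)
        d["mt"].add(h.mutant_id)
        d["lt"].add(h.lnc_id)
    rows = []
    for db in sorted(data):
        d = data[db]
        rows.append(
            {
                "database": db,
                "mutants_internal": len(d["mi"]),
                "lincRNAs_internal": len(d["li"]),
                "mutants_upstream": len(d["mu"]),
                "lincRNAs_upstream": len(d["lu"]),
                "mutants_total": len(d["mt"]),
                "lincRNAs_total": len(d["lt"]),
            }
        )
    if not rows:
        return pd.DataFrame(columns=cols).rename_axis("database")
    return pd.DataFrame(rows).set_index("database")
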