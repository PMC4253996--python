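"""Core genomic domain types.

All coordinates are 0-based half-open throughout the package; file readers
convert from each format's native convention on the way in (GTF is 1-based
inclusive, BED/bedGraph already 0-based half-open). Strand is one of
``"+"``, ``"-"`` or ``"."`` (unstranded); unstranded is a first-class value
because the identification cascade's first filter removes strandless
transcripts rather than erroring on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

STRANDS = ("+", "-", ".")

BIOTYPES = ("known_mRNA", "TE_mRNA", "candidate")

_DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def rna(seq: str) -> str:
    """Uppercase a sequence and transcribe T -> U."""
    return seq.upper().replace("T", "U")


def reverse_complement_rna(seq: str) -> str:
    return rna(seq).translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    """An exon-structured transcript; the unit flowing through the cascade.

    Invariants: exons sorted by start, pairwise non-overlapping, sharing the
    transcript's chromosome and strand; the span is exactly the hull of the
    exons. Transcript length is the sum of exon lengths (spliced length).
    """

    id: str
    gene_id: str
    exons: Tuple[GenomicInterval, ...]
    biotype: str = "candidate"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: at least one exon required")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        chrom, strand = exons[0].chrom, exons[0].strand
        prev_end = -1
        for e in exons:
            if e.chrom != chrom or e.strand != strand:
                raise ValueError(
                    f"transcript {self.id}: exons on mixed chrom/strand"
                )
            if e.start < prev_end:
                raise ValueError(
                    f"transcript {self.id}: exons unsorted or overlapping"
                )
            prev_end = e.end
        if self.biotype not in BIOTYPES:
            raise ValueError(
                f"transcript {self.id}: biotype must be one of {BIOTYPES}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        """Spliced length in nt (sum of exon lengths)."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Exonic sequence 5'->3' on the transcript strand.

        Unstranded transcripts return the plus-strand concatenation.
        """
        try:
            chrom_seq = genome[self.chrom]
        except KeyError:
            raise KeyError(
                f"transcript {self.id}: chromosome {self.chrom!r} not in genome"
            ) from None
        if self.span.end > len(chrom_seq):
            raise ValueError(
                f"transcript {self.id}: exon beyond end of {self.chrom} "
                f"({self.span.end} > {len(chrom_seq)})"
            )
        seq = "".join(chrom_seq[e.start : e.end] for e in self.exons)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq.upper()

    def spliced_to_genomic(self, pos: int) -> int:
        """Map a spliced-transcript coordinate to its genomic position."""
        if not 0 <= pos < self.length:
            raise IndexError(f"spliced position {pos} out of range")
        if self.strand == "-":
            pos = self.length - 1 - pos
        for e in self.exons:
            if pos < len(e):
                return e.start + pos
            pos -= len(e)
        raise AssertionError("unreachable")


class ConservationTrack:
    """Per-base conservation scores with explicit missing values.

    Backed by one float array per chromosome; NaN marks unaligned positions.
    Scores, where present, lie in [0, 1].
    """

    def __init__(self, arrays: Optional[Dict[str, np.ndarray]] = None) -> None:
        self._arrays: Dict[str, np.ndarray] = {}
        if arrays:
            for chrom, arr in arrays.items():
                self.set_chrom(chrom, arr)

    def set_chrom(self, chrom: str, arr: np.ndarray) -> None:
        arr = np.asarray(arr, dtype=float)
        present = arr[~np.isnan(arr)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValueError(f"{chrom}: conservation scores outside [0, 1]")
        self._arrays[chrom] = arr

    @property
    def chroms(self) -> List[str]:
        return sorted(self._arrays)

    def chrom_length(self, chrom: str) -> int:
        return len(self._arrays[chrom])

    def scores(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores for [start, end); positions beyond the stored
        track (or on unknown chromosomes) are returned as NaN."""
        n = end - start
        out = np.full(n, np.nan)
        arr = self._arrays.get(chrom)
        if arr is None:
            return out
        lo = max(start, 0)
        hi = min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def region_scores(self, regions: Iterable[GenomicInterval]) -> np.ndarray:
        """Concatenated per-base scores over a set of regions."""
        parts = [self.scores(r.chrom, r.start, r.end) for r in regions]
        if not parts:
            return np.empty(0)
        return np.concatenate(parts)


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3', RNA alphabet, 19-24 nt."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= set("ACGU"):
            raise ValueError(f"miRNA {self.id}: alphabet must be A/C/G/U")
        if not 19 <= len(seq) <= 24:
            raise ValueError(
                f"miRNA {self.id}: length {len(seq)} outside 19-24 nt"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FSTRecord:
    """A flanking sequence tag from an insertional-mutant database."""

    mutant_id: str
    database: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"FST {self.mutant_id}: empty sequence")
        if not set(seq) <= set("ACGTN"):
            raise ValueError(f"FST {self.mutant_id}: alphabet must be A/C/G/T/N")
        if len(seq) < 50:
            raise ValueError(
                f"FST {self.mutant_id}: length {len(seq)} < 50 nt"
            )
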