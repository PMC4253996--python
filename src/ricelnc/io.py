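"""Readers and writers for the pipeline's exchange formats.

GTF is read/written in its native 1-based inclusive convention and converted
to the package's internal 0-based half-open coordinates; BED and bedGraph are
already 0-based half-open. Chromosome names are matched by exact string:
no "chr"-prefix normalization is attempted, and mismatches surface as clear
errors downstream rather than silently empty joins. All writers emit
deterministic ordering so that identical inputs give byte-identical files.
"""

from __future__ import annotations

import re
from collections import OrderedDict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    ConservationTrack,
    FSTRecord,
    GenomicInterval,
    MiRNA,
    Transcript,
)


class GtfParseError(ValueError):
    pass


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path, coordinate_dialect: str = "gtf") -> List[Transcript]:
    """Read a GTF file into Transcripts.

    Exon records sharing a transcript_id are grouped into one Transcript;
    optional ``transcript`` records are used only to validate the declared
    span. ``coordinate_dialect`` is ``"gtf"`` (1-based inclusive, the
    default) or ``"zero_half_open"`` for files already in internal
    coordinates. Output is deterministically ordered by (chrom, start, id).
    """
    if coordinate_dialect not in ("gtf", "zero_half_open"):
        raise ValueError(f"unknown coordinate dialect {coordinate_dialect!r}")
    offset = 1 if coordinate_dialect == "gtf" else 0
    exons: "OrderedDict[str, dict]" = OrderedDict()
    declared_spans: Dict[str, Tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start = int(start_s) - offset
                end = int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if strand not in ("+", "-", "."):
                raise GtfParseError(f"{path}:{lineno}: bad strand {strand!r}")
            attributes = _parse_attributes(attrs)
            tid = attributes.get("transcript_id")
            if tid is None:
                raise GtfParseError(f"{path}:{lineno}: missing transcript_id")
            if feature == "transcript":
                declared_spans[tid] = (start, end)
                continue
            if feature != "exon":
                continue
            gid = attributes.get("gene_id", tid)
            biotype = attributes.get("biotype", "candidate")
            rec = exons.setdefault(
                tid, {"gene_id": gid, "biotype": biotype, "exons": []}
            )
            rec["exons"].append(GenomicInterval(chrom, start, end, strand))
    out: List[Transcript] = []
    for tid, rec in exons.items():
        ex = tuple(sorted(rec["exons"], key=lambda e: e.start))
        tx = Transcript(tid, rec["gene_id"], ex, rec["biotype"])
        if tid in declared_spans:
            s, e = declared_spans[tid]
            if tx.span.start < s or tx.span.end > e:
                raise GtfParseError(
                    f"{path}: transcript {tid}: exon outside declared span"
                )
        out.append(tx)
    out.sort(key=lambda t: (t.chrom, t.span.start, t.id))
    return out


def write_gtf(transcripts: Sequence[Transcript], path) -> None:
    """Write transcripts as GTF exon records (1-based inclusive)."""
    txs = sorted(transcripts, key=lambda t: (t.chrom, t.span.start, t.id))
    with open(path, "w") as fh:
        for tx in txs:
            for e in tx.exons:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.id}"; '
                    f'biotype "{tx.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [
                            tx.chrom,
                            "ricelnc",
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            tx.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_fasta(path) -> Dict[str, str]:
    """FASTA -> {name: uppercased sequence}; duplicate headers error."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA header {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_mirnas(path) -> List[MiRNA]:
    return [MiRNA(name, seq) for name, seq in read_fasta(path).items()]


def read_fsts(path) -> List[FSTRecord]:
    """FSTs from FASTA; database label carried as ``db=<label>`` in the
    description (defaults to "unknown" when absent)."""
    out: List[FSTRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FST id {rec.id!r}")
        seen.add(rec.id)
        m = re.search(r"db=(\S+)", rec.description)
        database = m.group(1) if m else "unknown"
        out.append(FSTRecord(rec.id, database, str(rec.seq)))
    return out


def write_fsts(fsts: Sequence[FSTRecord], path) -> None:
    with open(path, "w") as fh:
        for f in fsts:
            fh.write(f">{f.mutant_id} db={f.database}\n")
            for i in range(0, len(f.sequence), 70):
                fh.write(f.sequence[i : i + 70] + "\n")


def read_bed(path) -> List[GenomicInterval]:
    """BED (0-based half-open); strand taken from column 6 when present."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tfeature_{i}\t0\t{iv.strand}\n"
            )


def read_bedgraph(path, chrom_lengths: Optional[Mapping[str, int]] = None) -> ConservationTrack:
    """bedGraph -> per-base ConservationTrack.

    Positions not covered by any record are missing (NaN). Scores outside
    [0, 1] raise. ``chrom_lengths`` pre-sizes the arrays; otherwise each
    chromosome's track extends to the last covered base.
    """
    records: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, score = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: score {score} outside [0, 1]"
                )
            records.setdefault(chrom, []).append((start, end, score))
    track = ConservationTrack()
    for chrom, recs in records.items():
        length = max(e for _s, e, _v in recs)
        if chrom_lengths and chrom in chrom_lengths:
            length = max(length, chrom_lengths[chrom])
        arr = np.full(length, np.nan)
        for s, e, v in recs:
            arr[s:e] = v
        track.set_chrom(chrom, arr)
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            if chrom not in records:
                track.set_chrom(chrom, np.full(length, np.nan))
    return track


def write_bedgraph(track: ConservationTrack, path) -> None:
    """Write a track as run-length bedGraph records (missing bases omitted)."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            arr = track.scores(chrom, 0, track.chrom_length(chrom))
            n = len(arr)
            i = 0
            while i < n:
                if np.isnan(arr[i]):
                    i += 1
                    continue
                j = i + 1
                while j < n and not np.isnan(arr[j]) and arr[j] == arr[i]:
                    j += 1
                fh.write(f"{chrom}\t{i}\t{j}\t{arr[i]:.6g}\n")
                i = j


def read_expression(path) -> pd.DataFrame:
    """Transcript x sample FPKM matrix from TSV (header row = sample ids).

    Returns a float DataFrame indexed by transcript id. Negative entries and
    duplicate transcript rows raise.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate transcript rows: {dupes}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample columns")
    df = df.astype(float)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    return df


def write_expression(fpkm: pd.DataFrame, path) -> None:
    fpkm.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.17g")
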