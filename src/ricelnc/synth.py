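"""Seeded synthetic-bundle generator with a machine-readable truth table.

Fabricates a toy two-chromosome genome carrying protein-coding genes,
TE-related mRNAs, true lincRNAs and lncNATs, and noise transcripts each of
which violates exactly one identification filter — plus a tissue expression
matrix with controlled specificity, a per-base conservation track, repeat
and sRNA loci, miRNAs with planted decoy sites, and mutated flanking
sequence tags. Every planted fact is recorded in the truth table so each
downstream stage has known answers.

All randomness flows through a single seeded generator: the same
(config, seed) pair reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as rio
from .identify import longest_orf_codons
from .mimicry import build_perfect_site
from .mutants import DATABASES, extract_upstream
from .types import (
    ConservationTrack,
    FSTRecord,
    GenomicInterval,
    MiRNA,
    Transcript,
    reverse_complement,
)

REPRODUCTIVE = (
    "panicle",
    "anther",
    "pistil",
    "seed5DAP",
    "seed10DAP",
    "embryo25DAP",
    "endosperm25DAP",
)
VEGETATIVE = ("callus", "seedling14DAG", "shoot14DAG", "leaf20DAG", "root14DAG")
EXTRA_SAMPLE = "mature_leaf"

NOISE_ROLES = (
    "noise_short",
    "noise_lowFPKM",
    "noise_strandless",
    "noise_single_exon_proximal",
    "noise_coding_orf",
)

# role -> the one cascade filter it is built to fail
ROLE_FILTER = {
    "noise_short": "length",
    "noise_lowFPKM": "expression",
    "noise_strandless": "strandless",
    "noise_single_exon_proximal": "single_exon_proximity",
    "noise_coding_orf": "coding_potential",
}

DEFAULT_MIRNAS = (
    ("osa-miR160", "UGCCUGGCUCCCUGUAUGCCA"),
    ("osa-miR164", "UGGAGAAGCAGGGCACGUGCA"),
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class GeneratorConfig:
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_coding: int = 60
    n_te_mrna: int = 10
    n_lincrna: int = 40
    n_lncnat: int = 20
    n_noise_per_role: int = 15
    n_lncnat_other: int = 4  # lncNATs with broad (category "other") expression
    min_spacing: int = 1500
    # expression design
    on_target_fpkm: Tuple[float, float] = (10.0, 60.0)
    off_target_fpkm: Tuple[float, float] = (0.01, 0.1)
    js_floor: float = 0.5
    anther_weight: float = 3.0  # tissue draw is anther-enriched
    # decoy plantings
    mirnas: Tuple[Tuple[str, str], ...] = DEFAULT_MIRNAS
    decoy_sites_per_mirna: int = 3
    # FST plantings
    n_fst: int = 20
    fst_length: int = 300
    fst_mutation_rate: float = 0.02
    # sequence composition
    lnc_at_fraction: float = 0.62
    background_at_fraction: float = 0.55
    lncnat_overlap_range: Tuple[float, float] = (0.02, 0.30)

    @property
    def samples(self) -> List[str]:
        return list(REPRODUCTIVE) + list(VEGETATIVE) + [EXTRA_SAMPLE]

    @property
    def tissue_groups(self) -> Dict[str, List[str]]:
        return {
            "reproductive": list(REPRODUCTIVE),
            "vegetative": list(VEGETATIVE),
        }


@dataclass
class Bundle:
    config: GeneratorConfig
    seed: int
    genome: Dict[str, str]
    annotation: List[Transcript]
    candidates: List[Transcript]
    fpkm: pd.DataFrame
    track: ConservationTrack
    repeats: List[GenomicInterval]
    srna_loci: List[GenomicInterval]
    mirnas: List[MiRNA]
    fsts: List[FSTRecord]
    truth: pd.DataFrame

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def true_lnc_ids(self) -> List[str]:
        mask = self.truth["planted_role"].isin(["true_lincRNA", "true_lncNAT"])
        return sorted(self.truth.index[mask])

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rio.write_fasta(self.genome, outdir / "genome.fa")
        rio.write_gtf(self.annotation, outdir / "annotation.gtf")
        rio.write_gtf(self.candidates, outdir / "assembled.gtf")
        rio.write_expression(self.fpkm, outdir / "fpkm.tsv")
        rio.write_bedgraph(self.track, outdir / "conservation.bedgraph")
        rio.write_bed(self.repeats, outdir / "repeats.bed")
        rio.write_bed(self.srna_loci, outdir / "srna_loci.bed")
        rio.write_fasta(
            {m.id: m.sequence for m in self.mirnas}, outdir / "mirnas.fa"
        )
        rio.write_fsts(self.fsts, outdir / "fsts.fa")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t")


class PlacementError(RuntimeError):
    pass


def _random_seq(rng: np.random.Generator, length: int, at: float) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(
        np.array(list("ACGT"))[rng.choice(4, size=length, p=p)]
    )


_NON_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_CODON_W = np.array(
    [
        np.prod([{"A": 0.20, "T": 0.20, "C": 0.30, "G": 0.30}[ch] for ch in c])
        for c in _NON_STOP
    ]
)
_CODON_W = _CODON_W / _CODON_W.sum()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.choice(len(_NON_STOP), size=n_codons, p=_CODON_W)
    return "ATG" + "".join(_NON_STOP[i] for i in idx) + "TAA"


def _longest_orf_span(seq: str) -> Tuple[int, int]:
    """(codons, start) of the longest ATG->stop ORF over 3 forward frames."""
    stops = ("TAA", "TAG", "TGA")
    best = (0, -1)
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in stops:
                codons = (i - start) // 3
                if codons > best[0]:
                    best = (codons, start)
                start = None
    return best


def _disrupt_orfs(
    seq: str,
    rng: np.random.Generator,
    allowed: Optional[np.ndarray] = None,
    max_codons: int = 80,
) -> str:
    """Insert in-frame stops until no ORF reaches ``max_codons`` codons.

    ``allowed`` masks positions that may be rewritten (e.g. to protect
    planted decoy sites or bases shared with a host gene).
    """
    s = list(seq)
    if allowed is None:
        allowed = np.ones(len(s), dtype=bool)
    for _ in range(300):
        codons, start = _longest_orf_span("".join(s))
        if codons < max_codons:
            return "".join(s)
        # codon-aligned slots inside the ORF, preferring the middle
        slots = [start + 3 * j for j in range(1, codons)]
        slots.sort(key=lambda p: abs(p - (start + 3 * codons // 2)))
        placed = False
        for p in slots:
            if p + 3 <= len(s) and allowed[p : p + 3].all():
                s[p : p + 3] = "TAA"
                placed = True
                break
        if not placed:
            raise PlacementError(
                "cannot disrupt ORF: no writable codon slot available"
            )
    raise PlacementError("ORF disruption did not converge")


def _split_length(
    rng: np.random.Generator, total: int, k: int, min_part: int
) -> List[int]:
    """Split ``total`` into k parts each >= min_part."""
    if k * min_part > total:
        raise PlacementError(f"cannot split {total} into {k} parts >= {min_part}")
    extra = total - k * min_part
    cuts = np.sort(rng.integers(0, extra + 1, size=k - 1)) if k > 1 else np.array([], dtype=int)
    parts = np.diff(np.concatenate(([0], cuts, [extra]))) + min_part
    return [int(x) for x in parts]


def _make_exons(
    chrom: str, strand: str, start: int, exon_lens: Sequence[int],
    intron_lens: Sequence[int],
) -> Tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + el, strand))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return tuple(exons)


@dataclass
class _Planted:
    tx: Transcript
    role: str
    seq: str  # designed spliced sequence (transcript strand); "" = from genome
    tissue: str = ""
    category: str = ""
    decoy: List[Tuple[str, int, int]] = field(default_factory=list)
    fst: List[Tuple[str, str]] = field(default_factory=list)


def _write_spliced(
    arrays: Dict[str, np.ndarray],
    tx: Transcript,
    seq: str,
    claimed: Dict[str, np.ndarray],
    skip_claimed: bool = False,
    claim: bool = False,
) -> None:
    arr = arrays[tx.chrom]
    cl = claimed[tx.chrom]
    for i, base in enumerate(seq):
        g = tx.spliced_to_genomic(i)
        if skip_claimed and cl[g]:
            continue
        arr[g] = base if tx.strand != "-" else _COMP[base]
        if claim:
            cl[g] = True


def _read_spliced(arrays: Dict[str, np.ndarray], tx: Transcript) -> str:
    arr = arrays[tx.chrom]
    seq = "".join(
        "".join(arr[e.start : e.end]) for e in tx.exons
    )
    if tx.strand == "-":
        seq = reverse_complement(seq)
    return seq


def generate(config: Optional[GeneratorConfig] = None, seed: int = 42) -> Bundle:
    """Generate the full synthetic bundle; deterministic for (config, seed)."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    grouped = list(REPRODUCTIVE) + list(VEGETATIVE)
    tissue_w = np.array(
        [cfg.anther_weight if t == "anther" else 1.0 for t in grouped]
    )
    tissue_w = tissue_w / tissue_w.sum()

    # ----- placement jobs ---------------------------------------------------
    jobs: List[str] = (
        ["coding"] * cfg.n_coding
        + ["TE_mRNA"] * cfg.n_te_mrna
        + ["true_lincRNA"] * cfg.n_lincrna
        + ["noise_short"] * cfg.n_noise_per_role
        + ["noise_lowFPKM"] * cfg.n_noise_per_role
        + ["noise_strandless"] * cfg.n_noise_per_role
        + ["noise_coding_orf"] * cfg.n_noise_per_role
    )
    rng.shuffle(jobs)

    margin = 6000
    counters: Dict[str, int] = {}
    planted: List[_Planted] = []
    coding_txs: List[Transcript] = []

    def next_id(prefix: str) -> str:
        n = counters.get(prefix, 0) + 1
        counters[prefix] = n
        return f"{prefix}_{n:04d}"

    def draw_tissue() -> str:
        return grouped[rng.choice(len(grouped), p=tissue_w)]

    def specific_expression(tissue: str) -> Dict[str, float]:
        vals = {
            s: float(rng.uniform(*cfg.off_target_fpkm)) for s in cfg.samples
        }
        vals[tissue] = float(rng.uniform(*cfg.on_target_fpkm))
        return vals

    group_of = {t: "reproductive" for t in REPRODUCTIVE}
    group_of.update({t: "vegetative" for t in VEGETATIVE})

    expression: Dict[str, Dict[str, float]] = {}

    # pass 1: draw each feature's structure, sequence and expression
    pending: List[dict] = []
    for j, job in enumerate(jobs):
        chrom = chroms[j % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        rec: dict = {"job": job, "chrom": chrom, "reserve": 0, "tissue": "",
                     "category": "", "biotype": "candidate"}
        if job in ("coding", "TE_mRNA", "noise_coding_orf"):
            if job == "noise_coding_orf":
                n_codons = int(rng.integers(110, 200))
                n_ex = 2
            else:
                n_codons = int(rng.integers(150, 400))
                n_ex = int(rng.integers(2, 6))
            utr5 = _random_seq(rng, int(rng.integers(40, 90)), 0.5)
            utr3 = _random_seq(rng, int(rng.integers(50, 110)), 0.5)
            seq = utr5 + _random_cds(rng, n_codons) + utr3
            # genomic-last exon >= 320 so lncNAT overlaps fit inside it
            if len(seq) >= 320 + 80 * max(n_ex - 1, 1):
                exon_lens = _split_length(
                    rng, len(seq) - 320, max(n_ex - 1, 1), 80
                ) + [320]
            else:
                exon_lens = [len(seq)]
            if job == "noise_coding_orf":
                tid = next_id("NOISE_ORF")
                expr = {s: float(rng.uniform(1, 5)) for s in cfg.samples}
            else:
                tid = next_id("GENE" if job == "coding" else "TEG")
                rec["biotype"] = (
                    "known_mRNA" if job == "coding" else "TE_mRNA"
                )
                if job == "coding":
                    rec["reserve"] = 3000  # room for a possible lncNAT tail
                med = 19.0 if job == "coding" else 4.0
                expr = {
                    s: float(np.exp(rng.normal(np.log(med), 0.6)))
                    for s in cfg.samples
                }
        elif job == "true_lincRNA":
            L = int(np.clip(np.exp(rng.normal(np.log(850), 0.45)), 250, 3000))
            k = max(1, min(int(rng.geometric(1 / 2.2)), 6, L // 80))
            exon_lens = _split_length(rng, L, k, 60)
            seq = _disrupt_orfs(_random_seq(rng, L, cfg.lnc_at_fraction), rng)
            tid = next_id("LINC")
            rec["tissue"] = draw_tissue()
            rec["category"] = group_of[rec["tissue"]]
            expr = specific_expression(rec["tissue"])
        elif job == "noise_short":
            L = int(rng.integers(120, 200))
            exon_lens = _split_length(rng, L, 2, 50)
            seq = _disrupt_orfs(_random_seq(rng, L, 0.5), rng)
            tid = next_id("NOISE_SHORT")
            expr = {s: float(rng.uniform(1, 5)) for s in cfg.samples}
        elif job in ("noise_lowFPKM", "noise_strandless"):
            L = int(rng.integers(300, 900))
            exon_lens = _split_length(rng, L, 2, 80)
            seq = _disrupt_orfs(_random_seq(rng, L, 0.5), rng)
            if job == "noise_strandless":
                strand = "."
                tid = next_id("NOISE_NS")
                expr = {s: float(rng.uniform(1, 5)) for s in cfg.samples}
            else:
                tid = next_id("NOISE_LOW")
                expr = {s: float(rng.uniform(0.05, 0.3)) for s in cfg.samples}
        else:
            raise AssertionError(job)
        intron_lens = [
            int(rng.integers(80, 400)) for _ in range(len(exon_lens) - 1)
        ]
        rec.update(
            tid=tid,
            strand=strand,
            exon_lens=exon_lens,
            intron_lens=intron_lens,
            footprint=sum(exon_lens) + sum(intron_lens),
            seq=seq,
            expr=expr,
        )
        pending.append(rec)

    # pass 2: spread features over the full chromosome length (the spare
    # length is distributed randomly into the inter-feature gaps, so no
    # chromosome ends in a long featureless tail)
    first = 2500
    for chrom in chroms:
        items = [r for r in pending if r["chrom"] == chrom]
        need = sum(
            r["footprint"] + r["reserve"] + cfg.min_spacing for r in items
        )
        slack = cfg.chrom_length - margin - first - need
        if slack < 0:
            raise PlacementError(
                f"genome too small: {chrom} needs {need + first + margin} "
                f"bases but has {cfg.chrom_length}"
            )
        w = rng.random(len(items))
        extras = np.floor(slack * w / w.sum()).astype(int)
        pos = first
        for rec, extra in zip(items, extras):
            rec["start"] = pos
            pos += (
                rec["footprint"] + rec["reserve"] + cfg.min_spacing + int(extra)
            )

    for rec in pending:
        exons = _make_exons(
            rec["chrom"], rec["strand"], rec["start"], rec["exon_lens"],
            rec["intron_lens"],
        )
        tx = Transcript(rec["tid"], rec["tid"], exons, rec["biotype"])
        planted.append(
            _Planted(
                tx, rec["job"], rec["seq"],
                tissue=rec["tissue"], category=rec["category"],
            )
        )
        if rec["job"] == "coding":
            coding_txs.append(tx)
        expression[rec["tid"]] = rec["expr"]

    # ----- lncNATs: antisense over the last exon of coding hosts -----------
    if cfg.n_lncnat > len(coding_txs):
        raise PlacementError("not enough coding genes to host lncNATs")
    host_order = rng.permutation(len(coding_txs))
    nat_hosts = [coding_txs[i] for i in host_order[: cfg.n_lncnat]]
    prox_hosts = [
        coding_txs[i]
        for i in host_order[cfg.n_lncnat : cfg.n_lncnat + cfg.n_noise_per_role]
    ]
    if len(prox_hosts) < cfg.n_noise_per_role:
        raise PlacementError("not enough coding genes to anchor proximal noise")

    nat_other_idx = set(
        rng.choice(cfg.n_lncnat, size=cfg.n_lncnat_other, replace=False).tolist()
    )
    nats: List[_Planted] = []
    for i, host in enumerate(nat_hosts):
        L = int(rng.integers(300, 900))
        frac = float(rng.uniform(cfg.lncnat_overlap_range[0] + 0.02,
                                 cfg.lncnat_overlap_range[1] - 0.02))
        # overlap the genomic-last host exon (built >= 320 bp) and extend
        # rightward into the host's reserved post-gap
        host_exon = host.exons[-1]
        d = int(np.clip(round(frac * L), 2, min(len(host_exon) - 20, int(0.29 * L))))
        strand = "-" if host.strand == "+" else "+"
        two_exon = rng.random() < 0.5
        a_start = host_exon.end - d
        if two_exon:
            e1 = int(rng.integers(d + 60, max(d + 61, L - 80)))
            e1 = min(e1, L - 80)
            intron = int(rng.integers(80, 300))
            exons = (
                GenomicInterval(host.chrom, a_start, a_start + e1, strand),
                GenomicInterval(
                    host.chrom,
                    a_start + e1 + intron,
                    a_start + e1 + intron + (L - e1),
                    strand,
                ),
            )
        else:
            exons = (
                GenomicInterval(host.chrom, a_start, a_start + L, strand),
            )
        tid = next_id("LNCNAT")
        tx = Transcript(tid, tid, exons, "candidate")
        if i in nat_other_idx:
            tissue, category = "", "other"
            expression[tid] = {
                s: float(rng.uniform(4.5, 10)) for s in cfg.samples
            }
        else:
            tissue = draw_tissue()
            category = group_of[tissue]
            expression[tid] = specific_expression(tissue)
        nats.append(
            _Planted(tx, "true_lncNAT", "", tissue=tissue, category=category)
        )

    # ----- single-exon proximal noise: downstream of a same-strand host ----
    for host in prox_hosts:
        L = int(rng.integers(250, 600))
        gap_n = int(rng.integers(50, 450))
        start = host.span.end + gap_n
        exons = (
            GenomicInterval(host.chrom, start, start + L, host.strand),
        )
        tid = next_id("NOISE_PROX")
        tx = Transcript(tid, tid, exons, "candidate")
        planted.append(
            _Planted(
                tx,
                "noise_single_exon_proximal",
                _disrupt_orfs(_random_seq(rng, L, 0.5), rng),
            )
        )
        expression[tid] = {s: float(rng.uniform(4, 20)) for s in cfg.samples}

    # ----- decoy sites into lincRNA bodies ----------------------------------
    mirnas = [MiRNA(name, seq) for name, seq in cfg.mirnas]
    lincs = [p for p in planted if p.role == "true_lincRNA"]
    eligible = [p for p in lincs if len(p.seq) >= 200]
    need = len(mirnas) * cfg.decoy_sites_per_mirna
    if len(eligible) < need:
        raise PlacementError("not enough long lincRNAs to host decoy sites")
    host_idx = rng.choice(len(eligible), size=need, replace=False)
    for k, hi in enumerate(host_idx):
        mir = mirnas[k % len(mirnas)]
        host = eligible[int(hi)]
        site = build_perfect_site(mir).replace("U", "T")
        off = int(rng.integers(50, len(host.seq) - len(site) - 50))
        s = host.seq
        new = s[:off] + site + s[off + len(site) :]
        allowed = np.ones(len(new), dtype=bool)
        allowed[off : off + len(site)] = False
        host.seq = _disrupt_orfs(new, rng, allowed)
        host.decoy.append((mir.id, off, off + len(site)))

    # ----- genome assembly ---------------------------------------------------
    arrays = {
        c: np.array(list(_random_seq(rng, cfg.chrom_length,
                                     cfg.background_at_fraction)))
        for c in chroms
    }
    claimed = {c: np.zeros(cfg.chrom_length, dtype=bool) for c in chroms}
    for p in planted:
        claim = p.role in ("coding", "TE_mRNA")
        _write_spliced(arrays, p.tx, p.seq, claimed, claim=claim)
    # lncNATs: write only their own (unclaimed) bases, then clean ORFs
    for p in nats:
        own = _random_seq(rng, p.tx.length, cfg.lnc_at_fraction)
        _write_spliced(arrays, p.tx, own, claimed, skip_claimed=True)
        seq = _read_spliced(arrays, p.tx)
        shared = np.array(
            [
                claimed[p.tx.chrom][p.tx.spliced_to_genomic(i)]
                for i in range(p.tx.length)
            ]
        )
        # threshold 95 (not the scan default 80): an ORF that long cannot
        # fit wholly inside the host-shared bases, so a writable slot exists
        fixed = _disrupt_orfs(seq, rng, allowed=~shared, max_codons=95)
        if fixed != seq:
            _write_spliced(arrays, p.tx, fixed, claimed, skip_claimed=True)
        p.seq = fixed
    planted.extend(nats)

    genome = {c: "".join(arrays[c]) for c in chroms}

    # sanity: designed candidate sequences are intact on the genome
    for p in planted:
        if p.role in ("coding", "TE_mRNA"):
            continue
        got = p.tx.spliced_sequence(genome)
        if got != p.seq:
            raise PlacementError(
                f"{p.tx.id}: genome write-back mismatch (overlapping features?)"
            )
        if p.role.startswith(("true_", "noise_short", "noise_lowFPKM",
                              "noise_strandless", "noise_single")):
            if longest_orf_codons(got) >= 100:
                raise PlacementError(f"{p.tx.id}: residual long ORF")

    # ----- conservation track -----------------------------------------------
    track_arrays = {c: np.full(cfg.chrom_length, np.nan) for c in chroms}

    def paint(iv: GenomicInterval, p_present: float, mu: float, sd: float) -> None:
        arr = track_arrays[iv.chrom]
        pos = iv.start
        while pos < iv.end:
            chunk = min(int(rng.integers(15, 45)), iv.end - pos)
            if rng.random() < p_present:
                arr[pos : pos + chunk] = float(
                    np.clip(rng.normal(mu, sd), 0.0, 1.0)
                )
            pos += chunk

    # sparse intergenic background first; feature exons overwrite it
    for c in chroms:
        n_blocks = cfg.chrom_length // 2000
        starts = rng.integers(0, cfg.chrom_length - 120, size=n_blocks)
        for s in np.sort(starts)[rng.random(n_blocks) < 0.4]:
            track_arrays[c][s : s + int(rng.integers(40, 120))] = float(
                np.clip(rng.normal(0.22, 0.08), 0.0, 1.0)
            )
    for p in planted:
        if p.role == "coding":
            for e in p.tx.exons:
                paint(e, 0.9, 0.85, 0.08)
        elif p.role == "TE_mRNA":
            for e in p.tx.exons:
                paint(e, 0.12, 0.3, 0.1)
        elif p.role in ("true_lincRNA", "true_lncNAT"):
            for e in p.tx.exons:
                paint(e, 0.25, 0.2, 0.08)
    track = ConservationTrack(track_arrays)

    # ----- repeats and sRNA loci --------------------------------------------
    repeats: List[GenomicInterval] = []
    linc_list = [p for p in planted if p.role == "true_lincRNA"]
    n_rep = max(1, len(linc_list) // 4)
    for p in linc_list[:n_rep]:
        e = p.tx.exons[0]
        w = max(10, len(e) // 3)
        repeats.append(GenomicInterval(e.chrom, e.start, e.start + w))
    for p in planted:
        if p.role == "TE_mRNA":
            e = p.tx.exons[0]
            repeats.append(GenomicInterval(e.chrom, e.start, e.end))
    for _ in range(20):
        c = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, cfg.chrom_length - 600))
        repeats.append(GenomicInterval(c, s, s + int(rng.integers(100, 600))))

    srna_loci: List[GenomicInterval] = []
    n_srna = max(1, round(len(linc_list) * 0.075))
    for p in linc_list[-n_srna:]:
        e = p.tx.exons[-1]
        w = max(20, len(e) // 4)
        srna_loci.append(GenomicInterval(e.chrom, e.end - w, e.end))

    # ----- FSTs --------------------------------------------------------------
    fsts: List[FSTRecord] = []
    fst_hosts = rng.choice(len(linc_list), size=cfg.n_fst, replace=True)
    for k, hi in enumerate(fst_hosts):
        host = linc_list[int(hi)]
        region = "internal" if k % 2 == 0 else "upstream"
        if region == "internal":
            src = host.tx.spliced_sequence(genome)
        else:
            up = extract_upstream(host.tx, genome, 1000)
            src = up.sequence
        flen = min(cfg.fst_length, len(src) - 10)
        if flen < 50:
            region = "upstream"
            src = extract_upstream(host.tx, genome, 1000).sequence
            flen = min(cfg.fst_length, len(src) - 10)
        off = int(rng.integers(0, len(src) - flen + 1))
        frag = list(src[off : off + flen])
        n_mut = int(round(cfg.fst_mutation_rate * flen))
        # keep the ends intact so the planted identity equals the local
        # alignment's identity
        if n_mut:
            sites = rng.choice(np.arange(5, flen - 5), size=n_mut, replace=False)
            for m in sites:
                frag[m] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[m]]
        seq = "".join(frag)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        mid = f"M{k + 1:04d}"
        db = DATABASES[int(rng.integers(len(DATABASES)))]
        fsts.append(FSTRecord(mid, db, seq))
        host.fst.append((mid, region))

    # ----- expression matrix and truth table --------------------------------
    order = sorted(expression)
    fpkm = pd.DataFrame.from_dict(expression, orient="index").loc[order, cfg.samples]
    fpkm.index.name = "transcript_id"

    rows = []
    for p in planted:
        role = p.role
        if role == "coding":
            cls, cat = "", ""
        elif role == "true_lincRNA":
            cls, cat = "lincRNA", p.category
        elif role == "true_lncNAT":
            cls, cat = "lncNAT", p.category
        else:
            cls, cat = "", ""
        rows.append(
            {
                "transcript_id": p.tx.id,
                "planted_role": "coding" if role == "coding" else role,
                "planted_class": cls,
                "planted_category": cat,
                "planted_tissue": p.tissue,
                "planted_decoy_sites": ";".join(
                    f"{m}:{s}-{e}" for m, s, e in p.decoy
                ),
                "planted_fst_targets": ";".join(f"{m}:{r}" for m, r in p.fst),
            }
        )
    truth = pd.DataFrame(rows).set_index("transcript_id").sort_index()
    if truth.index.duplicated().any():
        raise PlacementError("duplicate transcript ids in truth table")

    annotation = sorted(
        (p.tx for p in planted if p.role in ("coding", "TE_mRNA")),
        key=lambda t: (t.chrom, t.span.start, t.id),
    )
    candidates = sorted(
        (p.tx for p in planted if p.role not in ("coding", "TE_mRNA")),
        key=lambda t: (t.chrom, t.span.start, t.id),
    )
    return Bundle(
        cfg,
        seed,
        genome,
        annotation,
        candidates,
        fpkm,
        track,
        repeats,
        srna_loci,
        mirnas,
        fsts,
        truth,
    )


def load_bundle(indir) -> Bundle:
    """Read a written bundle back from disk (truth table included)."""
    indir = Path(indir)
    genome = rio.read_fasta(indir / "genome.fa")
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    truth = pd.read_csv(indir / "truth.tsv", sep="\t", index_col=0).fillna("")
    return Bundle(
        GeneratorConfig(),
        -1,
        genome,
        rio.read_gtf(indir / "annotation.gtf"),
        rio.read_gtf(indir / "assembled.gtf"),
        rio.read_expression(indir / "fpkm.tsv"),
        rio.read_bedgraph(indir / "conservation.bedgraph", chrom_lengths),
        rio.read_bed(indir / "repeats.bed"),
        rio.read_bed(indir / "srna_loci.bed"),
        rio.read_mirnas(indir / "mirnas.fa"),
        rio.read_fsts(indir / "fsts.fa"),
        truth,
    )
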