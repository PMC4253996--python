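"""End-to-end orchestration: identification -> classification ->
characterization -> expression -> mimicry/mutants, from a single config."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import characterize, classify, expression, identify, io as rio, mimicry, mutants
from .synth import REPRODUCTIVE, VEGETATIVE
from .types import Transcript

log = logging.getLogger("ricelnc")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Thresholds default to the published cutoffs: spliced length >= 200 nt,
    FPKM >= 0.5 (multi-exon) / 2 (single-exon), 500 bp single-exon
    proximity window, 100-codon ORF surrogate, >90% FST identity, JS-score
    floor 0.5 for category assignment.
    """

    assembled_gtf: str = ""
    annotation_gtf: str = ""
    genome_fasta: str = ""
    fpkm_tsv: str = ""
    conservation_bedgraph: str = ""
    repeats_bed: str = ""
    srna_bed: str = ""
    mirna_fasta: str = ""
    fst_fasta: str = ""
    cpc_scores_tsv: str = ""
    pfam_hits_txt: str = ""
    min_length: int = 200
    fpkm_multi: float = 0.5
    fpkm_single: float = 2.0
    proximity_window: int = 500
    orf_min_codons: int = 100
    fst_min_identity: float = 90.0
    fst_min_aligned_frac: float = 0.8
    js_floor: float = 0.5
    upstream_length: int = 1000
    n_shuffles: int = 200
    seed: int = 7
    tissue_groups: Dict[str, List[str]] = field(
        default_factory=lambda: {
            "reproductive": list(REPRODUCTIVE),
            "vegetative": list(VEGETATIVE),
        }
    )

    def validate(self) -> None:
        for name in (
            "min_length",
            "fpkm_multi",
            "fpkm_single",
            "proximity_window",
            "orf_min_codons",
            "fst_min_identity",
            "js_floor",
            "upstream_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        seen = set()
        for group, samples in self.tissue_groups.items():
            for s in samples:
                if s in seen:
                    raise ValueError(f"sample {s!r} in two tissue groups")
                seen.add(s)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _load_optional_scores(path: str) -> Optional[Dict[str, float]]:
    if not path:
        return None
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "score"])
    return dict(zip(df["id"].astype(str), df["score"].astype(float)))


def _load_optional_ids(path: str) -> Optional[List[str]]:
    if not path:
        return None
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def run_all(config: PipelineConfig, outdir) -> Dict[str, object]:
    """Run the full pipeline; writes per-stage TSVs plus summary.tsv.

    Returns the in-memory results keyed by stage. Any stage error aborts
    with the stage name and cause.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: Dict[str, object] = {}
    stage = "load_inputs"
    try:
        for name in ("assembled_gtf", "annotation_gtf", "genome_fasta", "fpkm_tsv"):
            p = getattr(config, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"required input {name} missing: {p!r}")
        candidates = rio.read_gtf(config.assembled_gtf)
        annotation = rio.read_gtf(config.annotation_gtf)
        genome = rio.read_fasta(config.genome_fasta)
        fpkm = rio.read_expression(config.fpkm_tsv)
        log.info(
            "thresholds: min_length=%d fpkm=%.2f/%.2f window=%d orf=%d "
            "identity>%.1f js_floor=%.2f",
            config.min_length,
            config.fpkm_multi,
            config.fpkm_single,
            config.proximity_window,
            config.orf_min_codons,
            config.fst_min_identity,
            config.js_floor,
        )

        stage = "identification"
        lnc, report = identify.run_identification(
            candidates,
            annotation,
            genome,
            fpkm,
            external_scores=_load_optional_scores(config.cpc_scores_tsv),
            pfam_hits=_load_optional_ids(config.pfam_hits_txt),
            min_len=config.min_length,
            multi_threshold=config.fpkm_multi,
            single_threshold=config.fpkm_single,
            window=config.proximity_window,
            orf_min_codons=config.orf_min_codons,
        )
        report.to_tsv(outdir / "filter_report.tsv")
        rio.write_gtf(lnc, outdir / "lncrna.gtf")
        results["lncRNAs"] = lnc
        results["filter_report"] = report

        stage = "classification"
        mrnas = [t for t in annotation if t.biotype == "known_mRNA"]
        calls = classify.classify_lnc(lnc, mrnas)
        classify.annotate_neighbors(calls, mrnas)
        call_frame = classify.calls_to_frame(calls)
        call_frame.to_csv(outdir / "classification.tsv", sep="\t")
        results["calls"] = calls

        stage = "characterization"
        sets = {
            "lincRNA": [c.transcript for c in calls if c.lnc_class == "lincRNA"],
            "lncNAT": [c.transcript for c in calls if c.lnc_class == "lncNAT"],
            "mRNA": mrnas,
            "TE_mRNA": [t for t in annotation if t.biotype == "TE_mRNA"],
        }
        repeats = rio.read_bed(config.repeats_bed) if config.repeats_bed else []
        srna = rio.read_bed(config.srna_bed) if config.srna_bed else []
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        track = (
            rio.read_bedgraph(config.conservation_bedgraph, chrom_lengths)
            if config.conservation_bedgraph
            else None
        )
        if track is not None:
            char = characterize.summarize_sets(sets, genome, repeats, srna, track)
            char.to_csv(outdir / "characterization.tsv", sep="\t")
            results["characterization"] = char

        stage = "expression"
        lnc_ids = [t.id for t in lnc]
        spec = expression.specificity_table(fpkm.loc[lnc_ids])
        spec.to_csv(outdir / "specificity.tsv", sep="\t", float_format="%.6f")
        cats = expression.categorize(
            lnc_ids, fpkm, config.tissue_groups, config.js_floor
        )
        cat_frame = pd.DataFrame(
            [
                {
                    "transcript_id": c.transcript_id,
                    "category": c.category,
                    "tissue": c.tissue,
                    "js_score": c.js_score,
                }
                for c in cats
            ]
        ).set_index("transcript_id")
        cat_frame.to_csv(outdir / "categories.tsv", sep="\t", float_format="%.6f")
        results["categories"] = cats

        lincs = sets["lincRNA"]
        if lincs and mrnas:
            corr = expression.neighbor_correlation(
                lincs,
                mrnas,
                fpkm,
                chrom_lengths,
                n_shuffles=config.n_shuffles,
                seed=config.seed,
            )
            results["correlation"] = corr
            pd.DataFrame(
                [
                    {
                        "mean_rho": corr.mean_rho,
                        "n_pairs": corr.n_pairs,
                        "n_excluded": corr.n_excluded,
                        "shuffle_mean": corr.shuffle_mean,
                        "shuffle_sd": corr.shuffle_sd,
                        "n_shuffles": config.n_shuffles,
                    }
                ]
            ).to_csv(outdir / "neighbor_correlation.tsv", sep="\t", index=False)

        stage = "mimicry"
        if config.mirna_fasta:
            mirnas = rio.read_mirnas(config.mirna_fasta)
            seqs = {t.id: t.spliced_sequence(genome) for t in lnc}
            sites = mimicry.scan_all(seqs, mirnas)
            pd.DataFrame(
                [
                    {
                        "lnc_id": s.lnc_id,
                        "mirna_id": s.mirna_id,
                        "start": s.start,
                        "end": s.end,
                        "bulge_after": s.bulge_after,
                        "mismatches": s.mismatches,
                        "wobbles": s.wobbles,
                    }
                    for s in sites
                ]
            ).to_csv(outdir / "decoy_sites.tsv", sep="\t", index=False)
            results["decoy_sites"] = sites

        stage = "mutants"
        if config.fst_fasta:
            fsts = rio.read_fsts(config.fst_fasta)
            targets = mutants.prepare_targets(
                lincs, genome, config.upstream_length
            )
            hits = mutants.map_all(
                fsts,
                targets,
                config.fst_min_identity,
                config.fst_min_aligned_frac,
            )
            pd.DataFrame(
                [
                    {
                        "mutant_id": h.mutant_id,
                        "database": h.database,
                        "lnc_id": h.lnc_id,
                        "region": h.region,
                        "identity": round(h.identity, 1),
                        "chrom": h.chrom,
                        "align_start": h.align_start,
                        "align_end": h.align_end,
                        "orientation": h.orientation,
                    }
                    for h in hits
                ]
            ).to_csv(outdir / "mutant_hits.tsv", sep="\t", index=False)
            mutants.tabulate_mutants(hits).to_csv(
                outdir / "mutant_table.tsv", sep="\t"
            )
            results["mutant_hits"] = hits

        stage = "summary"
        n_linc = len(sets["lincRNA"])
        n_nat = len(sets["lncNAT"])
        cat_counts = pd.Series(
            [c.category for c in cats]
        ).value_counts().to_dict()
        summary = {
            "n_candidates": len(candidates),
            "n_lncRNA": len(lnc),
            "n_lincRNA": n_linc,
            "n_lncNAT": n_nat,
            "n_reproductive": cat_counts.get("reproductive", 0),
            "n_vegetative": cat_counts.get("vegetative", 0),
            "n_other": cat_counts.get("other", 0),
            "pct_lincRNA": characterize.percent(
                n_linc / len(lnc) if lnc else 0.0
            ),
            "n_decoy_sites": len(results.get("decoy_sites", [])),
            "n_mutant_hits": len(results.get("mutant_hits", [])),
        }
        pd.Series(summary, name="value").to_csv(
            outdir / "summary.tsv", sep="\t", header=True, index_label="metric"
        )
        results["summary"] = summary
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
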