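"""Expression-level statistics: tissue specificity, categorization,
set comparisons, and lincRNA-neighbor expression correlation.

The tissue-specificity score of a transcript is 1 - sqrt(JSD(p, e_t))
maximized over tissues t, where p is the transcript's expression profile
normalized to a distribution, e_t the perfectly tissue-specific unit
profile, and JSD the Jensen-Shannon divergence with base-2 entropy
(so scores lie in [0, 1], reaching 1 exactly for single-tissue expression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy import stats

from .types import GenomicInterval, Transcript


@dataclass
class SpecificityResult:
    transcript_id: str
    p: np.ndarray  # normalized expression distribution
    scores: np.ndarray  # per-tissue specificity scores
    js_score: float  # max over tissues
    tissue: str  # argmax tissue


def js_specificity(
    vector: Sequence[float], tissues: Optional[Sequence[str]] = None,
    transcript_id: str = "",
) -> SpecificityResult:
    """Jensen-Shannon tissue-specificity of one expression vector.

    Scale-invariant and permutation-equivariant in tissues; an all-zero
    vector has undefined specificity and raises.
    """
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("expression vector must be 1-D with >= 2 tissues")
    if (v < 0).any():
        raise ValueError("negative expression values")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero expression vector: specificity undefined")
    if tissues is None:
        tissues = [f"t{i}" for i in range(v.size)]
    p = v / total
    scores = np.empty(v.size)
    for t in range(v.size):
        e_t = np.zeros(v.size)
        e_t[t] = 1.0
        scores[t] = 1.0 - jensenshannon(p, e_t, base=2)
    best = int(np.argmax(scores))
    return SpecificityResult(
        transcript_id, p, scores, float(scores[best]), str(tissues[best])
    )


def specificity_table(fpkm: pd.DataFrame) -> pd.DataFrame:
    """JS score and argmax tissue per transcript (all-zero rows get NaN)."""
    rows = []
    for tid, row in fpkm.iterrows():
        v = row.to_numpy(dtype=float)
        if v.sum() == 0:
            rows.append({"transcript_id": tid, "js_score": np.nan, "tissue": ""})
            continue
        res = js_specificity(v, fpkm.columns, tid)
        rows.append(
            {"transcript_id": tid, "js_score": res.js_score, "tissue": res.tissue}
        )
    return pd.DataFrame(rows).set_index("transcript_id")


@dataclass
class CategoryAssignment:
    transcript_id: str
    category: str  # reproductive | vegetative | other
    tissue: str
    js_score: float


def categorize(
    transcript_ids: Sequence[str],
    fpkm: pd.DataFrame,
    tissue_groups: Mapping[str, Sequence[str]],
    js_floor: float = 0.5,
) -> List[CategoryAssignment]:
    """Assign each transcript to the group of its most specific tissue.

    Only samples named in ``tissue_groups`` participate (the groups must
    partition the samples used); a transcript whose maximal specificity
    score falls below ``js_floor`` — or with no expression in the grouped
    samples — is "other".
    """
    tissue_to_group: Dict[str, str] = {}
    for group, samples in tissue_groups.items():
        for s in samples:
            if s in tissue_to_group:
                raise ValueError(f"sample {s!r} assigned to two groups")
            tissue_to_group[s] = group
    missing = [s for s in tissue_to_group if s not in fpkm.columns]
    if missing:
        raise KeyError(f"grouped samples absent from matrix: {sorted(missing)}")
    used = [s for s in fpkm.columns if s in tissue_to_group]
    sub = fpkm.loc[list(transcript_ids), used]
    out = []
    for tid, row in sub.iterrows():
        v = row.to_numpy(dtype=float)
        if v.sum() == 0:
            out.append(CategoryAssignment(tid, "other", "", float("nan")))
            continue
        res = js_specificity(v, used, tid)
        if res.js_score >= js_floor:
            out.append(
                CategoryAssignment(
                    tid, tissue_to_group[res.tissue], res.tissue, res.js_score
                )
            )
        else:
            out.append(CategoryAssignment(tid, "other", res.tissue, res.js_score))
    return out


def summary_expression(
    fpkm: pd.DataFrame, ids: Sequence[str], how: str = "max"
) -> pd.Series:
    """Per-transcript summary FPKM: max across samples by default (a
    cross-sample mean would erase tissue-specific transcripts)."""
    sub = fpkm.loc[list(ids)]
    if how == "max":
        return sub.max(axis=1)
    if how == "mean":
        return sub.mean(axis=1)
    raise ValueError(f"unknown summary {how!r}")


def expression_summary(
    sets: Mapping[str, Sequence[str]],
    fpkm: pd.DataFrame,
    how: str = "max",
    test: str = "rank",
) -> Tuple[pd.Series, pd.DataFrame]:
    """Median summary FPKM per set plus pairwise two-sample location tests.

    ``test="rank"`` uses the Mann-Whitney U test (FPKM is heavy-tailed);
    ``test="ttest"`` uses Welch's t-test.
    """
    summaries = {}
    for name, ids in sets.items():
        if len(ids) == 0:
            raise ValueError(f"set {name!r} is empty")
        summaries[name] = summary_expression(fpkm, ids, how)
    medians = pd.Series(
        {name: float(s.median()) for name, s in summaries.items()},
        name="median_fpkm",
    )
    names = list(sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x, y = summaries[a].to_numpy(), summaries[b].to_numpy()
            if test == "rank":
                p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
            elif test == "ttest":
                p = stats.ttest_ind(x, y, equal_var=False).pvalue
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append({"set_a": a, "set_b": b, "p_value": float(p)})
    return medians, pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    mean_rho: float
    n_pairs: int
    n_excluded: int
    shuffle_mean: float
    shuffle_sd: float
    shuffle_means: np.ndarray


def _rank_rows(mat: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, mat)


def _pairwise_spearman(
    lnc_ranks: np.ndarray, gene_ranks: np.ndarray
) -> Tuple[float, int, int]:
    """Mean Spearman rho over row pairs; constant rows excluded, counted."""
    rhos = []
    excluded = 0
    for x, y in zip(lnc_ranks, gene_ranks):
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            excluded += 1
            continue
        rhos.append(float(np.corrcoef(x, y)[0, 1]))
    mean = float(np.mean(rhos)) if rhos else float("nan")
    return mean, len(rhos), excluded


def _closest_gene_index(
    starts: np.ndarray, ends: np.ndarray, s: int, e: int
) -> int:
    gaps = np.maximum(0, np.maximum(starts - e, s - ends))
    return int(np.argmin(gaps))


def neighbor_correlation(
    lincRNAs: Sequence[Transcript],
    coding_genes: Sequence[Transcript],
    fpkm: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> CorrelationResult:
    """Mean Spearman correlation between each lincRNA and its closest coding
    gene, against a positional-shuffle control.

    Each shuffle reassigns every lincRNA to a uniformly random intergenic
    placement (gene bodies excluded) on a length-weighted random chromosome,
    recomputes closest genes, and recomputes the mean correlation; the
    control mean and sd over shuffles are returned. Deterministic for a
    fixed seed.
    """
    if not lincRNAs or not coding_genes:
        raise ValueError("need at least one lincRNA and one coding gene")
    rng = np.random.default_rng(seed)
    genes_by_chrom: Dict[str, List[Transcript]] = {}
    for g in coding_genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    arrs = {
        c: (
            np.array([g.span.start for g in gs]),
            np.array([g.span.end for g in gs]),
            [g.id for g in gs],
        )
        for c, gs in genes_by_chrom.items()
    }
    rank_cache: Dict[str, np.ndarray] = {}

    def ranks(tid: str) -> np.ndarray:
        if tid not in rank_cache:
            rank_cache[tid] = stats.rankdata(fpkm.loc[tid].to_numpy(dtype=float))
        return rank_cache[tid]

    def mean_rho_for(placements: List[Tuple[str, int, int]]) -> Tuple[float, int, int]:
        lnc_r, gene_r = [], []
        for (chrom, s, e), lnc in zip(placements, lincRNAs):
            starts, ends, ids = arrs[chrom]
            gid = ids[_closest_gene_index(starts, ends, s, e)]
            lnc_r.append(ranks(lnc.id))
            gene_r.append(ranks(gid))
        return _pairwise_spearman(np.array(lnc_r), np.array(gene_r))

    observed_placements = [
        (t.chrom, t.span.start, t.span.end) for t in lincRNAs
    ]
    # restrict to chromosomes that carry coding genes
    for chrom, _s, _e in observed_placements:
        if chrom not in arrs:
            raise ValueError(f"no coding gene on chromosome {chrom!r}")
    mean_rho, n_pairs, n_excl = mean_rho_for(observed_placements)

    chroms = [c for c in sorted(chrom_lengths) if c in arrs]
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    def random_intergenic(length: int) -> Tuple[str, int, int]:
        for _ in range(10_000):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            limit = chrom_lengths[chrom] - length
            if limit <= 0:
                continue
            s = int(rng.integers(0, limit))
            e = s + length
            starts, ends, _ = arrs[chrom]
            if (np.maximum(0, np.maximum(starts - e, s - ends)) == 0).any():
                continue  # overlaps a gene body
            return chrom, s, e
        raise RuntimeError("could not place shuffled lincRNA intergenic")

    shuffle_means = np.empty(n_shuffles)
    for k in range(n_shuffles):
        placements = [
            random_intergenic(t.span.end - t.span.start) for t in lincRNAs
        ]
        shuffle_means[k], _, _ = mean_rho_for(placements)
    valid = shuffle_means[~np.isnan(shuffle_means)]
    return CorrelationResult(
        mean_rho=mean_rho,
        n_pairs=n_pairs,
        n_excluded=n_excl,
        shuffle_mean=float(valid.mean()) if valid.size else float("nan"),
        shuffle_sd=float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
        shuffle_means=shuffle_means,
    )
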