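"""miRNA decoy (endogenous target mimic) site prediction.

A decoy site is a stretch of lncRNA that pairs the full miRNA antiparallel
except for a short unpaired bulge on the target side opposite the miRNA's
expected cleavage region. The default rules: a 3-nt bulge placed between the
pairing partners of miRNA positions p and p+1 for p in {9, 10, 11} (i.e. the
bulge sits opposite miRNA positions 9-12 from the 5' end), perfect
Watson-Crick pairing at miRNA positions 2-8 (the seed), at most 3 combined
mismatches + G:U wobbles elsewhere, and no other insertions or deletions.
All constants are parameters of :class:`DecoyRules` so published rule
variants are expressible.

The scan is exhaustive over every window of length |miRNA| + bulge; for each
window the best admissible bulge placement (fewest mismatches + wobbles,
then 5'-most bulge) is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import MiRNA, reverse_complement_rna, rna

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class DecoyRules:
    bulge_len: int = 3
    # bulge allowed between miRNA positions p and p+1, p in this inclusive range
    bulge_after_min: int = 9
    bulge_after_max: int = 11
    seed_start: int = 2  # miRNA positions requiring perfect pairing, inclusive
    seed_end: int = 8
    max_mismatch_wobble: int = 3
    gu_is_wobble: bool = True  # False treats G:U as a full match


@dataclass
class DecoySite:
    lnc_id: str
    start: int  # on the spliced transcript, 0-based
    end: int  # half-open; end - start == len(miRNA) + bulge_len
    mirna_id: str
    bulge_after: int  # miRNA position p; bulge between partners of p and p+1
    bulge_len: int
    mismatches: int
    wobbles: int
    diagram: str


def _pair_class(site_nt: str, mir_nt: str, rules: DecoyRules) -> str:
    pair = (site_nt, mir_nt)
    if pair in WATSON_CRICK:
        return "match"
    if pair in WOBBLE:
        return "match" if not rules.gu_is_wobble else "wobble"
    return "mismatch"


def _evaluate_window(
    window: str, mir: str, p: int, rules: DecoyRules
) -> Optional[Tuple[int, int, str]]:
    """Evaluate one (window, bulge placement); None if inadmissible.

    Returns (mismatches, wobbles, diagram). Window length must equal
    len(mir) + bulge_len; the site is read 5'->3' and pairs the miRNA
    antiparallel, so window position 0 pairs miRNA position n.
    """
    n = len(mir)
    b = rules.bulge_len
    mismatches = wobbles = 0
    top = []  # site 5'->3'
    mid = []
    bot = []  # miRNA 3'->5'
    k = 0
    for i in range(n, 0, -1):  # miRNA positions, 3' to 5'
        site_nt = window[k]
        mir_nt = mir[i - 1]
        cls = _pair_class(site_nt, mir_nt, rules)
        in_seed = rules.seed_start <= i <= rules.seed_end
        if in_seed:
            if cls != "match" or (site_nt, mir_nt) in WOBBLE:
                return None
        elif cls == "wobble":
            wobbles += 1
        elif cls == "mismatch":
            mismatches += 1
        top.append(site_nt)
        mid.append({"match": "|", "wobble": "o", "mismatch": " "}[cls])
        bot.append(mir_nt)
        k += 1
        if i - 1 == p:  # bulge between positions p+1 and p (we just did p+1)
            top.extend(window[k : k + b])
            mid.extend(" " * b)
            bot.extend("-" * b)
            k += b
    if mismatches + wobbles > rules.max_mismatch_wobble:
        return None
    diagram = (
        "site  5' " + "".join(top) + " 3'\n"
        "         " + "".join(mid) + "\n"
        "miRNA 3' " + "".join(bot) + " 5'"
    )
    return mismatches, wobbles, diagram


def predict_decoy_sites(
    lnc_seq: str,
    mirna: MiRNA,
    rules: DecoyRules = DecoyRules(),
    lnc_id: str = "",
) -> List[DecoySite]:
    """Scan a spliced lncRNA sequence for decoy sites of one miRNA.

    DNA input is transcribed automatically. Overlapping windows are all
    reported; within one window the best admissible bulge placement wins.
    """
    if len(mirna) < 19:
        raise ValueError(f"miRNA {mirna.id}: shorter than 19 nt")
    seq = rna(lnc_seq)
    mir = mirna.sequence
    n, b = len(mir), rules.bulge_len
    wlen = n + b
    sites: List[DecoySite] = []
    placements = [
        p
        for p in range(rules.bulge_after_min, rules.bulge_after_max + 1)
        if 1 <= p < n
    ]
    for s in range(0, len(seq) - wlen + 1):
        window = seq[s : s + wlen]
        best: Optional[Tuple[Tuple[int, int], int, int, int, str]] = None
        for p in placements:
            res = _evaluate_window(window, mir, p, rules)
            if res is None:
                continue
            mm, wb, diagram = res
            key = (mm + wb, p)
            if best is None or key < best[0]:
                best = (key, p, mm, wb, diagram)
        if best is not None:
            _, p, mm, wb, diagram = best
            sites.append(
                DecoySite(
                    lnc_id, s, s + wlen, mirna.id, p, b, mm, wb, diagram
                )
            )
    return sites


def scan_all(
    sequences: Dict[str, str],
    mirnas: Sequence[MiRNA],
    rules: DecoyRules = DecoyRules(),
) -> List[DecoySite]:
    """Scan every lncRNA against every miRNA; deterministic ordering."""
    out: List[DecoySite] = []
    for lnc_id in sorted(sequences):
        for mir in sorted(mirnas, key=lambda m: m.id):
            out.extend(
                predict_decoy_sites(sequences[lnc_id], mir, rules, lnc_id)
            )
    return out


def build_perfect_site(
    mirna: MiRNA, bulge_seq: str = "CUC", bulge_after: int = 10
) -> str:
    """Construct an exact-mimic site: full antiparallel complement of the
    miRNA with ``bulge_seq`` inserted between the pairing partners of miRNA
    positions ``bulge_after`` and ``bulge_after + 1`` (RNA alphabet)."""
    rc = reverse_complement_rna(mirna.sequence)
    cut = len(mirna) - bulge_after
    return rc[:cut] + rna(bulge_seq) + rc[cut:]


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition
    (Altschul-Erikson: random Eulerian walk on the transition multigraph)."""
    seq = seq.upper()
    if len(seq) < 3:
        return seq
    edges: Dict[str, List[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    # choose a random last edge into the terminal vertex for each non-terminal
    # vertex, forming a tree into seq[-1]; then shuffle the rest (Eulerian).
    last = seq[-1]
    vertices = list(edges)
    for _attempt in range(1000):
        lasts = {}
        for v in vertices:
            if v == last:
                continue
            lasts[v] = edges[v][int(rng.integers(len(edges[v])))]
        # check the chosen last-edges form a tree rooted at `last`
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last:
                if cur not in lasts:
                    ok = False
                    break
                cur = lasts[cur]
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        remaining: Dict[str, List[str]] = {}
        for v, targets in edges.items():
            pool = list(targets)
            if v in lasts:
                pool.remove(lasts[v])
            rng.shuffle(pool)
            if v in lasts:
                pool.append(lasts[v])
            remaining[v] = pool
        out = [seq[0]]
        cur = seq[0]
        counters = {v: 0 for v in remaining}
        for _ in range(len(seq) - 1):
            nxt = remaining[cur][counters[cur]]
            counters[cur] += 1
            out.append(nxt)
            cur = nxt
        return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian walk")
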