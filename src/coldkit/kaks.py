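"""NG86-style Ka/Ks estimation and duplication-class analysis.

The estimator follows the classical Nei–Gojobori (1986) counting approach:
synonymous and nonsynonymous *sites* per codon are the fractions of single-base
mutations that preserve the amino acid (mutations to stop codons excluded from
the denominator), *differences* between two codons are averaged over all
minimal mutational pathways that avoid stop codons, and the resulting
proportions are corrected for multiple hits with the one-parameter
(Jukes–Cantor) distance d = -3/4 ln(1 - 4p/3). Under purifying selection
Ka/Ks < 1; Ka/Ks > 1 indicates positive selection.

Duplication classes are assigned from a gene map and homolog pair list:
pairs inside a collinear block (found with a greedy monotone-chain extractor,
a deliberate simplification of MCScanX-style chaining) are whole-genome/
segmental duplicates, remaining same-chromosome pairs within a small order-gap
are tandem duplicates, and everything else is dispersed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CODON_NEIGHBORS",
    "KaKsEstimate",
    "CollinearBlock",
    "ng86_sites",
    "ng86_pair",
    "estimate_pairs",
    "detect_tandem",
    "chain_collinear",
    "classify_duplications",
    "selection_summary",
]

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


def _neighbors(codon: str) -> list[tuple[str, bool]]:
    """All single-base sense-codon mutants of ``codon`` with synonymy flags."""
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            out.append((mut, _AA[mut] == _AA[codon]))
    return out


CODON_NEIGHBORS: dict[str, list[tuple[str, bool]]] = {c: _neighbors(c) for c in SENSE_CODONS}


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one sense codon.

    Per position, the synonymous fraction is the share of the single-base
    mutations that preserve the amino acid, with mutations to stop codons
    excluded from the denominator. The two counts always sum to 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    if codon not in _AA:
        raise ValueError(f"not a valid codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            tot += 1
            syn += _AA[mut] == _AA[codon]
        s += syn / tot if tot else 0.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Mean synonymous/nonsynonymous difference counts between two codons.

    Averages over all minimal mutational pathways whose intermediates are
    sense codons; if every pathway passes through a stop codon (rare), falls
    back to averaging over all minimal pathways.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if a in STOP_CODONS or b in STOP_CODONS:
                nd += 1  # stop-crossing fallback step counted nonsynonymous
            elif _AA[a] == _AA[b]:
                sd += 1
            else:
                nd += 1
    n = len(usable)
    return sd / n, nd / n


def _jukes_cantor(p: float) -> float:
    """One-parameter multiple-hit correction; inf when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsEstimate:
    pair_id: str
    ka: float | None
    ks: float | None
    ratio: float | None
    undefined_reason: str | None = None
    # diagnostics
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0


def _split_codons(seq: str, label: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{label}: length {len(seq)} not divisible by 3")
    if len(seq) < 3:
        raise ValueError(f"{label}: need at least one codon")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"{label}: internal stop codon {c} at codon {i}")
        if c not in _AA:
            raise ValueError(f"{label}: invalid codon {c!r} at codon {i}")
    return codons


def ng86_pair(seq1: str, seq2: str, pair_id: str = "pair") -> KaKsEstimate:
    """NG86 Ka, Ks and their ratio for one gapless in-frame codon alignment.

    Sites are averaged over the two sequences. The ratio is undefined when
    Ks = 0 or when either proportion is saturated (p >= 3/4, infinite
    correction), mirroring pairs for which a ratio cannot be obtained.
    """
    cod1 = _split_codons(seq1, "seq1")
    cod2 = _split_codons(seq2, "seq2")
    if len(cod1) != len(cod2):
        raise ValueError("sequences differ in codon count")
    s1 = n1 = s2 = n2 = 0.0
    sd = nd = 0.0
    for a, b in zip(cod1, cod2):
        sa, na = ng86_sites(a)
        sb, nb = ng86_sites(b)
        s1 += sa
        n1 += na
        s2 += sb
        n2 += nb
        if a != b:
            d_s, d_n = _codon_differences(a, b) if a <= b else _codon_differences(b, a)
            sd += d_s
            nd += d_n
    S = (s1 + s2) / 2.0
    N = (n1 + n2) / 2.0
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    est = KaKsEstimate(
        pair_id=pair_id, ka=None, ks=None, ratio=None,
        syn_sites=S, nonsyn_sites=N, syn_diffs=sd, nonsyn_diffs=nd,
    )
    if math.isinf(ks) or math.isinf(ka):
        est.undefined_reason = "saturated"
        est.ka = None if math.isinf(ka) else ka
        est.ks = None if math.isinf(ks) else ks
        return est
    est.ka, est.ks = ka, ks
    if ks == 0.0:
        est.undefined_reason = "Ks=0"
    else:
        est.ratio = ka / ks
    return est


def estimate_pairs(pairs: dict[str, tuple[str, str]]) -> pd.DataFrame:
    """Run :func:`ng86_pair` over ``{pair_id: (seq_a, seq_b)}``."""
    rows = []
    for pid, (a, b) in pairs.items():
        e = ng86_pair(a, b, pid)
        rows.append((pid, e.ka, e.ks, e.ratio, e.undefined_reason,
                     e.syn_sites, e.nonsyn_sites, e.syn_diffs, e.nonsyn_diffs))
    return pd.DataFrame(
        rows,
        columns=["pair_id", "ka", "ks", "ratio", "undefined_reason",
                 "syn_sites", "nonsyn_sites", "syn_diffs", "nonsyn_diffs"],
    )


# ---------------------------------------------------------------------------
# Duplication classification
# ---------------------------------------------------------------------------

@dataclass
class CollinearBlock:
    block_id: str
    chrom_a: str
    chrom_b: str
    orientation: int                      # +1 parallel, -1 antiparallel
    anchors: list[str] = field(default_factory=list)  # pair ids in chain order


def _gene_index(gene_map: pd.DataFrame) -> dict[str, tuple[str, int]]:
    idx = {}
    for row in gene_map.itertuples():
        if row.gene_id in idx:
            raise ValueError(f"duplicate gene id {row.gene_id}")
        idx[row.gene_id] = (row.chromosome, int(row.order_index))
    return idx


def _anchor_table(gene_map: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Map homolog pairs onto (canonical chromosome pair, order, order)."""
    gidx = _gene_index(gene_map)
    rows = []
    for row in pairs.itertuples():
        for g in (row.gene_a, row.gene_b):
            if g not in gidx:
                raise KeyError(f"gene {g!r} absent from gene map")
        (ca, oa), (cb, ob) = gidx[row.gene_a], gidx[row.gene_b]
        if (cb, ob) < (ca, oa):  # canonical orientation for determinism
            (ca, oa), (cb, ob) = (cb, ob), (ca, oa)
        rows.append((row.pair_id, ca, oa, cb, ob))
    return pd.DataFrame(rows, columns=["pair_id", "chrom_a", "order_a", "chrom_b", "order_b"])


def detect_tandem(
    gene_map: pd.DataFrame,
    pairs: pd.DataFrame,
    max_gap: int = 10,
    blocks: list[CollinearBlock] | None = None,
) -> set[str]:
    """Pair ids that are tandem duplicates.

    A pair is tandem iff both genes lie on one chromosome within ``max_gap``
    order indices and the pair is not an anchor of any collinear block.
    """
    in_block = set()
    for blk in blocks or []:
        in_block.update(blk.anchors)
    anchors = _anchor_table(gene_map, pairs)
    out = set()
    for row in anchors.itertuples():
        if row.pair_id in in_block:
            continue
        if row.chrom_a == row.chrom_b and abs(row.order_a - row.order_b) <= max_gap:
            out.add(row.pair_id)
    return out


def _longest_chain(
    anchors: list[tuple[str, int, int]], orientation: int, max_gap: int
) -> list[int]:
    """Longest chain strictly monotone in both coordinates, gaps <= max_gap.

    ``anchors`` are (pair_id, a, b) sorted by (a, b); with orientation -1 the
    b coordinate must strictly decrease. O(n^2) dynamic programme; ties break
    toward the earliest predecessor for determinism.
    """
    n = len(anchors)
    best = [1] * n
    prev = [-1] * n
    for j in range(n):
        _, aj, bj = anchors[j]
        for i in range(j):
            _, ai, bi = anchors[i]
            if ai >= aj or aj - ai > max_gap:
                continue
            db = (bj - bi) * orientation
            if db <= 0 or db > max_gap:
                continue
            if best[i] + 1 > best[j]:
                best[j] = best[i] + 1
                prev[j] = i
    end = int(np.argmax(best))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def chain_collinear(
    gene_map: pd.DataFrame,
    pairs: pd.DataFrame,
    min_anchors: int = 5,
    max_anchor_gap: int = 25,
) -> list[CollinearBlock]:
    """Greedy extraction of collinear blocks from homolog anchors.

    Per chromosome pair, anchors are sorted by the first chromosome's order;
    the longest strictly monotone chain (parallel or antiparallel) with
    successive order gaps <= ``max_anchor_gap`` on both chromosomes is
    extracted and removed, repeating until no chain reaches ``min_anchors``.
    """
    table = _anchor_table(gene_map, pairs)
    blocks: list[CollinearBlock] = []
    counter = itertools.count(1)
    for (ca, cb), grp in table.groupby(["chrom_a", "chrom_b"], sort=True):
        remaining = sorted(
            ((r.pair_id, r.order_a, r.order_b) for r in grp.itertuples()),
            key=lambda x: (x[1], x[2], x[0]),
        )
        while len(remaining) >= min_anchors:
            cand = []
            for orient in (1, -1):
                idx = _longest_chain(remaining, orient, max_anchor_gap)
                cand.append((len(idx), orient == 1, orient, idx))
            cand.sort(reverse=True)  # longest chain; prefer parallel on ties
            length, _, orient, idx = cand[0]
            if length < min_anchors:
                break
            blocks.append(
                CollinearBlock(
                    block_id=f"block{next(counter):03d}",
                    chrom_a=ca, chrom_b=cb, orientation=orient,
                    anchors=[remaining[i][0] for i in idx],
                )
            )
            picked = set(idx)
            remaining = [a for i, a in enumerate(remaining) if i not in picked]
    return blocks


def classify_duplications(
    gene_map: pd.DataFrame,
    pairs: pd.DataFrame,
    blocks: list[CollinearBlock] | None = None,
    max_tandem_gap: int = 10,
) -> pd.DataFrame:
    """Assign each homolog pair to wgd_segmental / tandem / dispersed.

    Block membership takes precedence over tandem adjacency.
    """
    if blocks is None:
        blocks = chain_collinear(gene_map, pairs)
    block_of = {}
    for blk in blocks:
        for pid in blk.anchors:
            block_of[pid] = blk.block_id
    tandem = detect_tandem(gene_map, pairs, max_gap=max_tandem_gap, blocks=blocks)
    rows = []
    for pid in pairs["pair_id"]:
        if pid in block_of:
            rows.append((pid, "wgd_segmental", block_of[pid]))
        elif pid in tandem:
            rows.append((pid, "tandem", None))
        else:
            rows.append((pid, "dispersed", None))
    return pd.DataFrame(rows, columns=["pair_id", "duplication_class", "block_id"])


def selection_summary(estimates: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Per-duplication-class selection tallies and mean Ka/Ks.

    Counts partition each class into ratio < 1 (purifying), ratio > 1
    (positive), ratio = 1 and undefined; the mean is over defined ratios only.
    """
    merged = calls.merge(estimates[["pair_id", "ratio"]], on="pair_id", how="left")
    rows = []
    for cls, grp in merged.groupby("duplication_class", sort=True):
        r = grp["ratio"]
        defined = r.dropna()
        rows.append((
            cls, len(grp),
            int((defined < 1).sum()), int((defined > 1).sum()),
            int((defined == 1).sum()), int(r.isna().sum()),
            float(defined.mean()) if len(defined) else float("nan"),
        ))
    return pd.DataFrame(
        rows,
        columns=["duplication_class", "n_pairs", "n_ratio_lt1", "n_ratio_gt1",
                 "n_ratio_eq1", "n_undefined", "mean_ratio"],
    )
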