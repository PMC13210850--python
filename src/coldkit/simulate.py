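"""Synthetic-data generators with embedded ground truth.

Every downstream stage of the pipeline (tolerance scoring, tissue-specificity
indexing, the cold-induction screen, qPCR quantification, promoter scanning and
Ka/Ks duplication analysis) can be exercised on data produced here, with the
planted truth recorded in a :class:`TruthBundle` so recovery can be checked
exactly.

All generators take an explicit integer ``seed`` and never touch global random
state; identical seeds and parameters reproduce identical outputs.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .promoters import (
    IUPAC_CODES,
    MotifDictionary,
    reverse_complement,
    scan_promoter,
)
from .kaks import CODON_NEIGHBORS, SENSE_CODONS

__all__ = [
    "LatentCultivar",
    "TruthBundle",
    "gen_physiology",
    "gen_expression_atlas",
    "gen_cold_timecourse",
    "gen_qpcr_cts",
    "gen_promoters",
    "gen_cds_pairs",
    "gen_gene_map",
    "sample_sheet_from_columns",
    "write_fasta",
    "write_truth_json",
]


@dataclass(frozen=True)
class LatentCultivar:
    """A cultivar with its latent cold tolerance theta in [0, 1]."""

    cultivar_id: str
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0,1], got {self.theta}")


@dataclass
class TruthBundle:
    """Ground truth planted by the generators.

    Only the fields relevant to a given generator are populated.
    """

    latent_cultivars: list[LatentCultivar] = field(default_factory=list)
    specific_genes: dict[str, list[str]] = field(default_factory=dict)
    silent_genes: list[str] = field(default_factory=list)
    induced_genes: set[str] = field(default_factory=set)
    induction_log2fc: float | None = None
    motif_positions: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    omega_true: dict[str, float] = field(default_factory=dict)
    realized_substitutions: dict[str, tuple[int, int]] = field(default_factory=dict)
    duplication_truth: dict[str, str] = field(default_factory=dict)
    true_fold: dict[tuple[str, float], float] = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    return np.random.default_rng(int(seed))


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Physiological indicator panel
# ---------------------------------------------------------------------------

#: indicator -> (direction, baseline, amplitude). Baselines/amplitudes are on
#: enzyme-activity (U g^-1) or metabolite (mg g^-1, nmol g^-1) scales; direction
#: +1 means the indicator rises with tolerance under stress, -1 that it falls
#: (lipid-peroxidation marker MDA accumulates in sensitive cultivars).
INDICATOR_PARAMS: dict[str, tuple[int, float, float]] = {
    "SOD": (1, 150.0, 1.0),
    "POD": (1, 300.0, 0.9),
    "soluble_sugar": (1, 12.0, 1.2),
    "soluble_protein": (1, 8.0, 0.9),
    "MDA": (-1, 18.0, 1.0),
}

INDICATOR_DIRECTIONS: dict[str, int] = {k: v[0] for k, v in INDICATOR_PARAMS.items()}


def _logistic(x: np.ndarray | float, steepness: float = 4.0) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-steepness * (np.asarray(x, dtype=float) - 0.5)))


def gen_physiology(
    n_cultivars: int,
    timepoints: Sequence[float] = (0, 1, 3, 5, 7),
    n_replicates: int = 5,
    noise_cv: float = 0.1,
    seed: int = 0,
    thetas: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Simulate a cold-stress physiological panel for a set of cultivars.

    Five indicators (SOD, POD, soluble sugar, soluble protein, MDA) are driven
    by a latent tolerance ``theta`` per cultivar: under stress (timepoint > 0)
    positive-direction indicator means increase strictly with theta and MDA
    decreases strictly. At day 0 all cultivars share the indicator baseline.
    Replicate noise is multiplicative log-normal with coefficient of variation
    ``noise_cv``.

    Returns a long-format table with columns
    (cultivar, variable, timepoint, replicate, value) and the truth bundle
    holding the latent thetas (evenly spaced on [0, 1] unless ``thetas`` is
    given).
    """
    if n_cultivars < 3:
        raise ValueError("n_cultivars must be >= 3")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if len(timepoints) == 0:
        raise ValueError("at least one timepoint required")
    if thetas is None:
        thetas = np.linspace(0.0, 1.0, n_cultivars)
    else:
        thetas = np.asarray(thetas, dtype=float)
        if len(thetas) != n_cultivars:
            raise ValueError("thetas length must equal n_cultivars")

    rng = _rng(seed)
    cultivars = [LatentCultivar(f"cv{i + 1:02d}", float(th)) for i, th in enumerate(thetas)]
    t_max = max(timepoints)
    rows = []
    for variable, (direction, base, amp) in INDICATOR_PARAMS.items():
        for cv_obj in cultivars:
            g = _logistic(cv_obj.theta if direction > 0 else 1.0 - cv_obj.theta)
            for t in timepoints:
                stress = (t / t_max) if t_max > 0 else 0.0
                mean = base * (1.0 + amp * stress * g)
                noise = _lognormal_noise(rng, noise_cv, n_replicates)
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        (cv_obj.cultivar_id, variable, float(t), rep, mean * noise[rep - 1])
                    )
    table = pd.DataFrame(
        rows, columns=["cultivar", "variable", "timepoint", "replicate", "value"]
    )
    return table, TruthBundle(latent_cultivars=cultivars)


# ---------------------------------------------------------------------------
# Tissue expression atlas
# ---------------------------------------------------------------------------

DEFAULT_TISSUES = ("root", "stem", "leaf", "flower", "stolon", "flower_pedicel")


def gen_expression_atlas(
    n_genes: int,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    n_specific_per_tissue: int = 10,
    n_silent: int = 4,
    seed: int = 0,
    leakage: float = 0.02,
    specific_level: float = 200.0,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Simulate a genes x tissues abundance atlas (TPM-like units).

    Plants ``n_specific_per_tissue`` tissue-specific genes per tissue (dominant
    tissue at ``specific_level`` with fractional ``leakage`` elsewhere, so the
    true tau index is (1 - leakage) > 0.8 for the defaults), ``n_silent``
    all-zero genes, and broad log-normal background for the remainder.
    """
    tissues = list(tissues)
    n_planted = n_specific_per_tissue * len(tissues) + n_silent
    if n_planted > n_genes:
        raise ValueError(
            f"planted genes ({n_planted}) exceed n_genes ({n_genes}); requests overlap"
        )
    if not 0.0 <= leakage < 1.0:
        raise ValueError("leakage must be in [0,1)")
    rng = _rng(seed)
    gene_ids = [f"gene{i + 1:04d}" for i in range(n_genes)]
    mat = np.zeros((n_genes, len(tissues)))
    truth = TruthBundle()
    idx = 0
    for j, tissue in enumerate(tissues):
        ids = gene_ids[idx : idx + n_specific_per_tissue]
        truth.specific_genes[tissue] = ids
        for g in range(idx, idx + n_specific_per_tissue):
            level = rng.lognormal(math.log(specific_level), 0.3)
            mat[g, :] = leakage * level
            mat[g, j] = level
        idx += n_specific_per_tissue
    truth.silent_genes = gene_ids[idx : idx + n_silent]
    idx += n_silent  # silent rows stay zero
    for g in range(idx, n_genes):
        base = rng.lognormal(math.log(20.0), 1.0)
        sigma = rng.uniform(0.05, 0.8)
        mat[g, :] = base * rng.lognormal(0.0, sigma, size=len(tissues))
    matrix = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=tissues)
    return matrix, truth


# ---------------------------------------------------------------------------
# Cold time course
# ---------------------------------------------------------------------------

def gen_cold_timecourse(
    n_genes: int,
    n_induced: int = 8,
    induction_log2fc: float = 2.0,
    timepoints: Sequence[float] = (0, 12, 24),
    n_replicates: int = 3,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Simulate a cold-stress time course with transient induction.

    Induced genes follow an increase-then-decrease trajectory: mean abundance
    at the second timepoint equals baseline x 2**induction_log2fc, and at
    later timepoints baseline x 2**(induction_log2fc / 2) (between baseline
    and peak). Non-induced genes have constant means. Columns are named
    ``t{timepoint}_r{replicate}``.
    """
    if n_induced > n_genes:
        raise ValueError("n_induced must be <= n_genes")
    if induction_log2fc < 0:
        raise ValueError("induction_log2fc must be >= 0")
    if len(timepoints) < 2:
        raise ValueError("need at least baseline and one stress timepoint")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = _rng(seed)
    gene_ids = [f"gene{i + 1:04d}" for i in range(n_genes)]
    induced_idx = rng.choice(n_genes, size=n_induced, replace=False)
    induced = set(np.array(gene_ids)[induced_idx])
    baseline = rng.lognormal(math.log(30.0), 0.8, size=n_genes)
    peak = 2.0 ** induction_log2fc
    late = 2.0 ** (induction_log2fc / 2.0)
    cols, data = [], []
    for k, t in enumerate(timepoints):
        if k == 0:
            fold = np.ones(n_genes)
        else:
            f = peak if k == 1 else late
            fold = np.where(np.isin(np.arange(n_genes), induced_idx), f, 1.0)
        for rep in range(1, n_replicates + 1):
            cols.append(f"t{t:g}_r{rep}")
            data.append(baseline * fold * _lognormal_noise(rng, noise_cv, n_genes))
    matrix = pd.DataFrame(
        np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"), columns=cols
    )
    truth = TruthBundle(induced_genes=induced, induction_log2fc=float(induction_log2fc))
    return matrix, truth


def sample_sheet_from_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Parse ``t{timepoint}_r{replicate}`` column names into a sample sheet."""
    rows = []
    for col in matrix.columns:
        if not col.startswith("t") or "_r" not in col:
            raise ValueError(f"cannot parse sample column name: {col!r}")
        t_part, r_part = col[1:].split("_r")
        rows.append((col, float(t_part), int(r_part)))
    return pd.DataFrame(rows, columns=["sample", "timepoint", "replicate"])


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def gen_qpcr_cts(
    cultivars: Sequence[str],
    timepoints: Sequence[float],
    true_fold: Mapping[tuple[str, float], float],
    n_bio: int = 3,
    n_tech: int = 3,
    ct_sd: float = 0.0,
    seed: int = 0,
    target_gene: str = "target",
    reference_gene: str = "StActin",
    reference_ct: float = 20.0,
    calibrator_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with a condition-independent reference gene.

    The target's true ``delta Ct`` at condition (cultivar, timepoint) is
    ``calibrator_delta_ct - log2(true_fold)``, so the 2^-ddCt pipeline recovers
    ``true_fold`` relative to the first timepoint exactly when ``ct_sd`` is 0
    (provided ``true_fold`` is 1 at that calibrator timepoint). Gaussian
    measurement noise of ``ct_sd`` cycles is added per technical replicate.
    """
    if n_bio < 1 or n_tech < 1:
        raise ValueError("replicate counts must be >= 1")
    if ct_sd < 0:
        raise ValueError("ct_sd must be >= 0")
    for key, f in true_fold.items():
        if f <= 0:
            raise ValueError(f"true_fold must be > 0, got {f} at {key}")
    rng = _rng(seed)
    rows = []
    for cv in cultivars:
        for t in timepoints:
            fold = float(true_fold.get((cv, t), 1.0))
            delta = calibrator_delta_ct - math.log2(fold)
            for bio in range(1, n_bio + 1):
                for tech in range(1, n_tech + 1):
                    ref_ct = reference_ct + rng.normal(0.0, ct_sd) if ct_sd else reference_ct
                    tgt_ct = (
                        reference_ct + delta + (rng.normal(0.0, ct_sd) if ct_sd else 0.0)
                    )
                    sample = f"{cv}_t{t:g}_b{bio}"
                    rows.append((sample, cv, float(t), target_gene, "target", bio, tech, tgt_ct))
                    rows.append(
                        (sample, cv, float(t), reference_gene, "reference", bio, tech, ref_ct)
                    )
    return pd.DataFrame(
        rows,
        columns=["sample", "cultivar", "timepoint", "gene", "role", "bio_rep", "tech_rep", "ct"],
    )


# ---------------------------------------------------------------------------
# Promoter sequences with planted cis-elements
# ---------------------------------------------------------------------------

def _concretize(pattern: str, rng: np.random.Generator) -> str:
    """Replace IUPAC degeneracies with concrete bases, uniformly at random."""
    return "".join(
        b if b in "ACGT" else rng.choice(sorted(IUPAC_CODES[b])) for b in pattern
    )


def gen_promoters(
    n_promoters: int,
    length: int = 2000,
    dictionary: MotifDictionary | None = None,
    plant_spec: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    gc: float = 0.4,
    seed: int = 0,
    avoid_background_hits: bool = False,
    max_clean_iterations: int = 60,
) -> tuple[dict[str, str], TruthBundle]:
    """Simulate promoter sequences with optionally planted cis-elements.

    Background bases are i.i.d. at the stated GC content. ``plant_spec`` maps
    promoter ids (``prom0001`` ...) to (element name, strand) requests; each
    planted instance is a concretized dictionary pattern, reverse-complemented
    for minus-strand plants, inserted at a recorded non-overlapping position.
    With ``avoid_background_hits`` the background is rejection-resampled until
    it contains no dictionary match outside the planted positions.
    """
    if n_promoters < 1 or length < 1:
        raise ValueError("counts must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0,1)")
    plant_spec = dict(plant_spec or {})
    if (plant_spec or avoid_background_hits) and dictionary is None:
        raise ValueError("a dictionary is required to plant or exclude motifs")
    rng = _rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    truth = TruthBundle()
    for i in range(n_promoters):
        pid = f"prom{i + 1:04d}"
        seq = rng.choice(bases, size=length, p=probs)
        planted: list[tuple[str, int, str, str]] = []  # (element, start, strand, motif)
        occupied: list[tuple[int, int]] = []
        for element, strand in plant_spec.get(pid, []):
            if element not in dictionary.entries:
                raise KeyError(f"unknown element {element!r}")
            pattern = dictionary.entries[element].patterns[0]
            if len(pattern) > length:
                raise ValueError(f"motif {element!r} longer than promoter")
            motif = _concretize(pattern, rng)
            if strand == "-":
                motif = reverse_complement(motif)
            elif strand != "+":
                raise ValueError(f"strand must be '+' or '-', got {strand!r}")
            for _ in range(1000):
                start = int(rng.integers(0, length - len(motif) + 1))
                if all(start + len(motif) <= a or start >= b for a, b in occupied):
                    break
            else:
                raise ValueError(f"could not place motif {element!r} without overlap")
            occupied.append((start, start + len(motif)))
            seq[start : start + len(motif)] = list(motif)
            planted.append((element, start, strand, motif))
        if avoid_background_hits:
            seq = _scrub_background(seq, dictionary, occupied, rng, probs, bases,
                                    max_clean_iterations, pid, planted)
        truth.motif_positions[pid] = [(e, s, st) for e, s, st, _ in planted]
        promoters[pid] = "".join(seq)
    return promoters, truth


def _scrub_background(seq, dictionary, occupied, rng, probs, bases, max_iter, pid, planted):
    """Redraw background windows until no unplanted dictionary match remains."""
    for _ in range(max_iter):
        hits = scan_promoter("".join(seq), dictionary)
        stray = [
            h
            for h in hits.itertuples()
            if not any(a <= h.position < b for a, b in occupied)
        ]
        if not stray:
            # planted instances may still be matched; that is expected
            return seq
        for h in stray:
            end = h.position + len(h.match)
            for pos in range(h.position, end):
                if not any(a <= pos < b for a, b in occupied):
                    seq[pos] = rng.choice(bases, p=probs)
    raise RuntimeError(f"could not scrub background hits from {pid}")


# ---------------------------------------------------------------------------
# Codon-pair evolution at a specified Ka/Ks
# ---------------------------------------------------------------------------

def gen_cds_pairs(
    n_pairs: int,
    n_codons: int,
    omega: float,
    t: float,
    seed: int = 0,
) -> tuple[dict[str, tuple[str, str]], TruthBundle]:
    """Evolve descendant coding sequences from random ancestors.

    Each codon evolves independently under a continuous-time substitution
    process with equal base exchangeabilities in which every nonsynonymous
    single-base change is scaled by ``omega`` relative to synonymous changes;
    paths through stop codons are disallowed. The overall rate is calibrated so
    the expected number of substitutions per codon (at the ancestral
    composition) is ``t``. The true nonsynonymous/synonymous *rate* ratio is
    therefore exactly ``omega``, which the NG86 estimator should recover.

    Returns ``{pair_id: (ancestor, descendant)}`` plus a truth bundle with the
    planted omega and realized (synonymous, nonsynonymous) substitution counts.
    """
    if omega < 0 or t < 0:
        raise ValueError("omega and t must be >= 0")
    if n_pairs < 1 or n_codons < 1:
        raise ValueError("counts must be positive")
    rng = _rng(seed)
    sense = list(SENSE_CODONS)
    # per-codon total rate (unnormalized): syn neighbors weight 1, nonsyn weight omega
    rate_of = {
        c: sum(1.0 if syn else omega for _, syn in CODON_NEIGHBORS[c]) for c in sense
    }
    mean_rate = float(np.mean([rate_of[c] for c in sense]))
    if mean_rate == 0:
        raise ValueError("substitution process has zero total rate")
    scale = 1.0 / mean_rate  # expected substitutions per codon per unit t
    pairs: dict[str, tuple[str, str]] = {}
    truth = TruthBundle()
    for p in range(n_pairs):
        pid = f"pair{p + 1:04d}"
        anc = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
        der = list(anc)
        n_syn = n_nonsyn = 0
        for i in range(n_codons):
            clock = 0.0
            codon = der[i]
            while True:
                total = rate_of[codon] * scale
                if total == 0:
                    break
                clock += rng.exponential(1.0 / total)
                if clock > t:
                    break
                neigh = CODON_NEIGHBORS[codon]
                weights = np.array([1.0 if syn else omega for _, syn in neigh])
                j = int(rng.choice(len(neigh), p=weights / weights.sum()))
                nxt, syn = neigh[j]
                if syn:
                    n_syn += 1
                else:
                    n_nonsyn += 1
                codon = nxt
            der[i] = codon
        pairs[pid] = ("".join(anc), "".join(der))
        truth.omega_true[pid] = float(omega)
        truth.realized_substitutions[pid] = (n_syn, n_nonsyn)
    return pairs, truth


# ---------------------------------------------------------------------------
# Gene maps with planted duplication structure
# ---------------------------------------------------------------------------

def gen_gene_map(
    n_chromosomes: int,
    genes_per_chr: int,
    tandem_arrays: Sequence[tuple[int, int, int]] = (),
    collinear_blocks: Sequence[tuple[int, int, int, int]] = (),
    n_dispersed: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Simulate a gene map plus homolog pairs with known duplication classes.

    ``tandem_arrays`` entries are (chromosome index, start order index, size):
    the array's genes are declared mutual homologs, giving C(size, 2) tandem
    pairs at adjacent order indices. ``collinear_blocks`` entries are
    (chrA, chrB, length, offset): genes at orders offset..offset+length-1 on
    both chromosomes are paired in order, forming a collinear block of
    ``length`` anchors. ``n_dispersed`` decoy pairs are added across
    chromosome pairs unused by any block.
    """
    if n_chromosomes < 1 or genes_per_chr < 2:
        raise ValueError("need >= 1 chromosome with >= 2 genes")
    rng = _rng(seed)
    chroms = [f"chr{c + 1:02d}" for c in range(n_chromosomes)]
    records = []
    for c, chrom in enumerate(chroms):
        for i in range(genes_per_chr):
            start = 500 + i * 3000
            records.append(
                (f"g{c + 1:02d}_{i + 1:03d}", chrom, i, start, start + 2000,
                 "+" if rng.random() < 0.5 else "-")
            )
    gene_map = pd.DataFrame(
        records, columns=["gene_id", "chromosome", "order_index", "start", "end", "strand"]
    )
    by_pos = {
        (row.chromosome, row.order_index): row.gene_id for row in gene_map.itertuples()
    }

    used: set[tuple[int, int]] = set()  # (chrom index, order index) occupied by plants
    pairs: list[tuple[str, str, str]] = []
    truth = TruthBundle()
    counter = itertools.count(1)

    def claim(c: int, i: int, what: str) -> str:
        if c >= n_chromosomes or i >= genes_per_chr or i < 0:
            raise ValueError(f"{what} does not fit on chromosome {c}")
        if (c, i) in used:
            raise ValueError(f"overlapping planted structures at chr {c}, index {i}")
        used.add((c, i))
        return by_pos[(chroms[c], i)]

    for c, start, size in tandem_arrays:
        if size < 2:
            raise ValueError("tandem array size must be >= 2")
        members = [claim(c, start + k, "tandem array") for k in range(size)]
        for a, b in itertools.combinations(members, 2):
            pid = f"hp{next(counter):04d}"
            pairs.append((pid, a, b))
            truth.duplication_truth[pid] = "tandem"

    block_chrom_pairs: set[tuple[int, int]] = set()
    for ca, cb, length, offset in collinear_blocks:
        if ca == cb:
            raise ValueError("collinear blocks must span two distinct chromosomes")
        block_chrom_pairs.add(tuple(sorted((ca, cb))))
        for k in range(length):
            a = claim(ca, offset + k, "collinear block")
            b = claim(cb, offset + k, "collinear block")
            pid = f"hp{next(counter):04d}"
            pairs.append((pid, a, b))
            truth.duplication_truth[pid] = "wgd_segmental"

    free_chrom_pairs = [
        (a, b)
        for a in range(n_chromosomes)
        for b in range(a + 1, n_chromosomes)
        if (a, b) not in block_chrom_pairs
    ]
    if n_dispersed and not free_chrom_pairs:
        raise ValueError("no chromosome pair free of blocks for dispersed decoys")
    for d in range(n_dispersed):
        for _ in range(1000):
            ca, cb = free_chrom_pairs[int(rng.integers(0, len(free_chrom_pairs)))]
            ia = int(rng.integers(0, genes_per_chr))
            ib = int(rng.integers(0, genes_per_chr))
            if (ca, ia) not in used and (cb, ib) not in used:
                break
        else:
            raise ValueError("could not place dispersed decoy")
        a = claim(ca, ia, "dispersed decoy")
        b = claim(cb, ib, "dispersed decoy")
        pid = f"hp{next(counter):04d}"
        pairs.append((pid, a, b))
        truth.duplication_truth[pid] = "dispersed"

    pairs_df = pd.DataFrame(pairs, columns=["pair_id", "gene_a", "gene_b"])
    return gene_map, pairs_df, truth


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str] | Mapping[str, tuple[str, str]], path) -> None:
    """Write sequences (or (ancestor, descendant) pairs) to a FASTA file."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for name, value in sequences.items():
        if isinstance(value, tuple):
            records.append(SeqRecord(Seq(value[0]), id=f"{name}_a", description=""))
            records.append(SeqRecord(Seq(value[1]), id=f"{name}_b", description=""))
        else:
            records.append(SeqRecord(Seq(value), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_truth_json(truth: TruthBundle, path) -> None:
    d = asdict(truth)
    d["induced_genes"] = sorted(d["induced_genes"])
    d["true_fold"] = {f"{cv}|{t:g}": f for (cv, t), f in truth.true_fold.items()}
    d["realized_substitutions"] = {k: list(v) for k, v in truth.realized_substitutions.items()}
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, default=str)
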