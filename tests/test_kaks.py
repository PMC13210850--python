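"""NG86 estimator against brute-force enumeration; duplication classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import coldkit as ck
from coldkit.kaks import (
    SENSE_CODONS,
    STOP_CODONS,
    chain_collinear,
    classify_duplications,
    detect_tandem,
    ng86_pair,
    ng86_sites,
    selection_summary,
)
from Bio.Data.CodonTable import unambiguous_dna_by_id

_AA = dict(unambiguous_dna_by_id[1].forward_table)


def brute_force_sites(codon):
    """Enumerate all 9 single-base mutants directly from the code table."""
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            tot += 1
            syn += _AA[mut] == _AA[codon]
        s += syn / tot if tot else 0.0
    return s, 3.0 - s


class TestSites:
    def test_phe_ttt(self):
        """TTT: only TTC at position 3 is synonymous -> (1/3, 8/3)."""
        s, n = ng86_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_gly_ggg_fourfold(self):
        s, n = ng86_sites("GGG")
        assert (s, n) == (pytest.approx(1.0), pytest.approx(2.0))

    def test_all_sense_codons_sum_to_three_and_match_enumeration(self):
        for codon in SENSE_CODONS:
            s, n = ng86_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)
            bs, bn = brute_force_sites(codon)
            assert s == pytest.approx(bs, abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")


class TestPairEstimates:
    def test_identical_sequences_undefined_ratio(self):
        est = ng86_pair("ATGGCT" * 10, "ATGGCT" * 10)
        assert est.ka == 0.0 and est.ks == 0.0
        assert est.ratio is None
        assert est.undefined_reason == "Ks=0"

    def test_single_synonymous_difference_hand_computed(self):
        """One GAA<->GAG (Glu<->Glu) difference in 100 codons: Ka=0 and
        Ks equals the Jukes-Cantor-corrected p_s from hand-counted sites."""
        base = "GAA" * 100
        mutated = "GAG" + "GAA" * 99
        est = ng86_pair(base, mutated)
        # per-codon sites: pos3 of GAA has 1/3 syn (GAG), GAG has 2/3 (GAA,GAT? no:
        # GAG third-position mutants GAA(syn), GAC(Asp), GAT(Asp) -> 1/3)
        s_gaa = brute_force_sites("GAA")[0]
        s_gag = brute_force_sites("GAG")[0]
        S = (100 * s_gaa + 99 * s_gaa + s_gag) / 2
        ps = 1.0 / S
        expected_ks = -0.75 * math.log(1 - 4 * ps / 3)
        assert est.ka == 0.0
        assert est.ks == pytest.approx(expected_ks, abs=1e-12)
        assert est.ratio == 0.0

    def test_symmetry(self):
        pairs, _ = ck.gen_cds_pairs(5, 60, 0.8, 0.4, seed=13)
        for a, b in pairs.values():
            ea, eb = ng86_pair(a, b), ng86_pair(b, a)
            assert ea.ka == pytest.approx(eb.ka)
            assert ea.ks == pytest.approx(eb.ks)

    def test_site_totals_sum_to_sequence_length(self):
        est = ng86_pair("ATGGCTAAA", "ATGGCTAAA")
        assert est.syn_sites + est.nonsyn_sites == pytest.approx(9.0)

    def test_frame_and_length_validation(self):
        with pytest.raises(ValueError):
            ng86_pair("ATGG", "ATGG")
        with pytest.raises(ValueError):
            ng86_pair("ATG", "ATGATG")
        with pytest.raises(ValueError, match="stop"):
            ng86_pair("TAAATG", "TAAATG")

    def test_omega_recovery_small(self):
        """Scaled-down recovery check (the full-size one runs in acceptance)."""
        pairs, _ = ck.gen_cds_pairs(40, 500, 0.3, 0.2, seed=14)
        est = ck.estimate_pairs(pairs)
        assert est.ratio.mean() == pytest.approx(0.3, abs=0.07)


class TestTandem:
    def test_different_chromosomes_not_tandem(self, tiny_gene_map):
        gene_map, pairs, truth = tiny_gene_map
        block_pairs = {p for p, c in truth.duplication_truth.items()
                       if c == "wgd_segmental"}
        tandem = detect_tandem(gene_map, pairs)
        assert not tandem & block_pairs

    def test_adjacent_pair_is_tandem(self):
        gene_map, pairs, _ = ck.gen_gene_map(1, 10, tandem_arrays=[(0, 0, 2)], seed=1)
        assert detect_tandem(gene_map, pairs) == set(pairs.pair_id)

    def test_gap_threshold(self):
        gene_map, _, _ = ck.gen_gene_map(1, 30, seed=2)
        ids = gene_map.gene_id.tolist()
        pairs = pd.DataFrame({"pair_id": ["near", "far"],
                              "gene_a": [ids[0], ids[0]],
                              "gene_b": [ids[10], ids[11]]})
        assert detect_tandem(gene_map, pairs, max_gap=10) == {"near"}

    def test_unknown_gene_errors(self, tiny_gene_map):
        gene_map, pairs, _ = tiny_gene_map
        bad = pd.DataFrame({"pair_id": ["x"], "gene_a": ["nope"], "gene_b": ["nada"]})
        with pytest.raises(KeyError):
            detect_tandem(gene_map, bad)


def brute_force_longest_chain(anchors, max_gap):
    """Exhaustive search over all subsequences for the longest valid chain."""
    best = 0
    n = len(anchors)
    order = sorted(range(n), key=lambda i: (anchors[i][0], anchors[i][1]))
    for r in range(1, n + 1):
        for combo in itertools.combinations(order, r):
            a = [anchors[i][0] for i in combo]
            b = [anchors[i][1] for i in combo]
            if all(0 < a2 - a1 <= max_gap for a1, a2 in zip(a, a[1:])):
                for sign in (1, -1):
                    db = [(b2 - b1) * sign for b1, b2 in zip(b, b[1:])]
                    if all(0 < d <= max_gap for d in db):
                        best = max(best, r)
    return best


class TestCollinear:
    def test_planted_block_recovered(self, tiny_gene_map):
        gene_map, pairs, truth = tiny_gene_map
        blocks = chain_collinear(gene_map, pairs)
        assert len(blocks) == 1
        expected = {p for p, c in truth.duplication_truth.items() if c == "wgd_segmental"}
        assert set(blocks[0].anchors) == expected

    def test_below_min_anchors_no_block(self):
        gene_map, pairs, _ = ck.gen_gene_map(
            3, 30, collinear_blocks=[(0, 1, 4, 5)], seed=3
        )
        assert chain_collinear(gene_map, pairs, min_anchors=5) == []
        assert len(chain_collinear(gene_map, pairs, min_anchors=4)) == 1

    def test_antiparallel_block_found(self):
        """A descending-order block (inversion) still chains."""
        gene_map, _, _ = ck.gen_gene_map(2, 30, seed=4)
        a_ids = gene_map[gene_map.chromosome == "chr01"].sort_values("order_index")
        b_ids = gene_map[gene_map.chromosome == "chr02"].sort_values("order_index")
        pairs = pd.DataFrame({
            "pair_id": [f"p{i}" for i in range(5)],
            "gene_a": a_ids.gene_id.iloc[5:10].tolist(),
            "gene_b": b_ids.gene_id.iloc[14:9:-1].tolist(),
        })
        blocks = chain_collinear(gene_map, pairs)
        assert len(blocks) == 1 and len(blocks[0].anchors) == 5
        assert blocks[0].orientation == -1

    def test_chain_length_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            n = int(rng.integers(5, 13))
            anchors = [(int(a), int(b)) for a, b in
                       zip(rng.choice(50, n, replace=False), rng.integers(0, 50, n))]
            gene_map, _, _ = ck.gen_gene_map(2, 50, seed=trial)
            a_side = gene_map[gene_map.chromosome == "chr01"].set_index("order_index")
            b_side = gene_map[gene_map.chromosome == "chr02"].set_index("order_index")
            rows = []
            for i, (a, b) in enumerate(anchors):
                rows.append((f"p{i}", a_side.loc[a, "gene_id"], b_side.loc[b, "gene_id"]))
            pairs = pd.DataFrame(rows, columns=["pair_id", "gene_a", "gene_b"])
            blocks = chain_collinear(gene_map, pairs, min_anchors=2, max_anchor_gap=25)
            got = max((len(b.anchors) for b in blocks), default=1)
            expected = brute_force_longest_chain(anchors, max_gap=25)
            assert got == max(expected, 1), f"trial {trial}: {anchors}"


class TestClassification:
    def test_planted_tallies_exact(self):
        gene_map, pairs, truth = ck.gen_gene_map(
            6, 80, tandem_arrays=[(0, 10, 3)],
            collinear_blocks=[(1, 2, 5, 20), (3, 4, 5, 40)],
            n_dispersed=5, seed=9,
        )
        calls = classify_duplications(gene_map, pairs)
        got = calls.set_index("pair_id")["duplication_class"].to_dict()
        assert got == truth.duplication_truth
        tally = calls.duplication_class.value_counts()
        assert (tally["wgd_segmental"], tally["tandem"], tally["dispersed"]) == (10, 3, 5)

    def test_block_precedence_over_tandem(self):
        """Same-chromosome pairs at adjacent order indices that also chain
        into a collinear block are called wgd_segmental, not tandem."""
        gene_map, _, _ = ck.gen_gene_map(1, 30, seed=5)
        ids = gene_map.sort_values("order_index").gene_id.tolist()
        pairs = pd.DataFrame({
            "pair_id": [f"p{i}" for i in range(5)],
            "gene_a": [ids[2 * i] for i in range(5)],
            "gene_b": [ids[2 * i + 1] for i in range(5)],
        })
        assert detect_tandem(gene_map, pairs) == set(pairs.pair_id)  # adjacent
        calls = classify_duplications(gene_map, pairs)
        assert set(calls.duplication_class) == {"wgd_segmental"}

    def test_all_dispersed_without_structure(self):
        gene_map, _, _ = ck.gen_gene_map(3, 20, seed=6)
        by_chr = {c: g.gene_id.tolist() for c, g in gene_map.groupby("chromosome")}
        pairs = pd.DataFrame({
            "pair_id": ["d1", "d2"],
            "gene_a": [by_chr["chr01"][0], by_chr["chr02"][3]],
            "gene_b": [by_chr["chr02"][10], by_chr["chr03"][15]],
        })
        calls = classify_duplications(gene_map, pairs)
        assert set(calls.duplication_class) == {"dispersed"}


class TestSelectionSummary:
    def test_counts_and_means(self):
        est = pd.DataFrame({
            "pair_id": ["a", "b", "c", "d"],
            "ratio": [0.2, 0.4, 1.5, None],
        })
        calls = pd.DataFrame({
            "pair_id": ["a", "b", "c", "d"],
            "duplication_class": ["wgd_segmental"] * 2 + ["tandem", "tandem"],
            "block_id": [None] * 4,
        })
        summ = selection_summary(est, calls).set_index("duplication_class")
        assert summ.loc["wgd_segmental", "mean_ratio"] == pytest.approx(0.3)
        assert summ.loc["wgd_segmental", "n_ratio_lt1"] == 2
        assert summ.loc["tandem", "n_ratio_gt1"] == 1
        assert summ.loc["tandem", "n_undefined"] == 1
        assert summ.n_pairs.sum() == 4
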