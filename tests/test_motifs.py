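"""Consensus discovery and RBP motif enrichment statistics."""

import numpy as np
import pytest

from oracles import fisher_two_sided_exact

from circmotif.model import JunctionSequence, ModelError, MotifRecord, MotifTable
from circmotif.motifs import (
    circularize,
    discover_consensus,
    enrichment_compare,
    enrichment_compare_tiled,
    run_standard_comparisons,
    scan_motif_table,
)


def _js(seq, off, sid="s"):
    return JunctionSequence(seq=seq, junction_offset=off, origin="BSJ",
                            source_id=sid)


def _brute_force_consensus(seqs, k, min_prev):
    """Independent oracle: enumerate every junction-spanning k-mer of every
    sequence and vote."""
    from collections import Counter

    votes = Counter()
    for js in seqs:
        kmers = set()
        for s in range(len(js.seq) - k + 1):
            if s < js.junction_offset < s + k:
                kmers.add(js.seq[s : s + k])
        votes.update(kmers)
    ok = {m: c / len(seqs) for m, c in votes.items() if c / len(seqs) >= min_prev}
    if not ok:
        return None
    best_prev = max(ok.values())
    return min(m for m, p in ok.items() if p == best_prev)


class TestDiscoverConsensus:
    def test_identical_sequences_give_maximal_spanning_kmer(self):
        seqs = [_js("ACGTACGTGG" + "TTCCAACCGG", 10, f"s{i}") for i in range(5)]
        res = discover_consensus(seqs, k_min=4, k_max=6, min_prevalence=0.5)
        assert res.prevalence == 1.0
        assert res.k == 6  # ties broken toward the larger k
        # and the winner must really span the junction in every sequence
        assert len(res.carrier_ids) == 5

    def test_matches_brute_force_enumeration_on_random_sequences(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for trial in range(20):
            seqs = [
                _js("".join(bases[rng.integers(0, 4, 50)]), 25, f"s{i}")
                for i in range(5)
            ]
            res = discover_consensus(seqs, k_min=4, k_max=4, min_prevalence=0.2)
            oracle = _brute_force_consensus(seqs, 4, 0.2)
            assert res.consensus == oracle

    def test_result_invariant_to_sequence_order(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        seqs = [
            _js("".join(bases[rng.integers(0, 4, 40)]), 20, f"s{i}")
            for i in range(8)
        ]
        a = discover_consensus(seqs, 4, 8, 0.25)
        b = discover_consensus(seqs[::-1], 4, 8, 0.25)
        assert (a.consensus, a.k, a.prevalence) == (b.consensus, b.k, b.prevalence)

    def test_no_kmer_reaching_prevalence_gives_empty_with_diagnostic(self):
        seqs = [_js("AAAAAAAAAA" + "TTTTTTTTTT", 10),
                _js("CCCCCCCCCC" + "GGGGGGGGGG", 10, "s2")]
        res = discover_consensus(seqs, 5, 8, min_prevalence=0.9)
        assert res.empty and "prevalence" in res.diagnostic

    def test_empty_class_rejected(self):
        with pytest.raises(ModelError):
            discover_consensus([], 5, 8, 0.5)


class TestScanMotifTable:
    def test_all_n_pattern_present_everywhere(self):
        motifs = MotifTable([MotifRecord("m", "X", "NNNN")])
        pres = scan_motif_table({"a": "ACGTA", "b": "TTT"}, motifs)
        assert bool(pres.loc["a", "m"]) is True
        assert bool(pres.loc["b", "m"]) is False  # shorter than pattern

    def test_empty_motif_table_gives_empty_matrix(self):
        pres = scan_motif_table({"a": "ACGT"}, MotifTable([]))
        assert pres.shape == (1, 0)

    def test_carriers_only(self, default_dataset):
        from circmotif.junctions import JunctionWindow, build_bsj_sequence

        ds = default_dataset
        motifs = MotifTable([MotifRecord("m", "SRSF10", ds.manifest["motif"])])
        seqs = {
            cj.junction_id: build_bsj_sequence(
                ds.genome, ds.models[cj.transcript_id], cj, JunctionWindow(25)
            ).seq
            for cj in ds.junctions
            if cj.dependency_class == "rbm20_dependent"
        }
        pres = scan_motif_table(seqs, motifs)
        carriers = set(ds.manifest["carriers_dependent"])
        # every manifest carrier must show presence; non-carriers may only
        # show it through a non-junction (within-exon) occurrence
        assert carriers <= set(pres.index[pres["m"]])


class TestEnrichment:
    def test_identical_counts_give_or_one_p_one(self):
        motifs = MotifTable([MotifRecord("m", "X", "AAA")])
        rows = enrichment_compare(
            {"a1": "AAAT", "a2": "TTTT"}, {"b1": "AAAT", "b2": "TTTT"}, motifs
        )
        assert rows[0].odds_ratio == 1.0
        assert rows[0].p_value == 1.0

    def test_p_equals_exact_hypergeometric_tail_sum(self):
        # table (8,2;1,9) checked against the exact rational enumeration
        motifs = MotifTable([MotifRecord("m", "X", "AAA")])
        set_a = {f"a{i}": ("AAA" if i < 8 else "TTT") for i in range(10)}
        set_b = {f"b{i}": ("AAA" if i < 1 else "TTT") for i in range(10)}
        (row,) = enrichment_compare(set_a, set_b, motifs)
        assert (row.count_a, row.count_b) == (8, 1)
        expected = float(fisher_two_sided_exact(8, 2, 1, 9))
        assert row.p_value == pytest.approx(expected, abs=1e-12)

    def test_swapping_sets_inverts_odds_ratio_and_preserves_p(self):
        motifs = MotifTable([MotifRecord("m", "X", "AAA")])
        set_a = {f"a{i}": ("AAA" if i < 7 else "TTT") for i in range(9)}
        set_b = {f"b{i}": ("AAA" if i < 2 else "TTT") for i in range(11)}
        (fwd,) = enrichment_compare(set_a, set_b, motifs)
        (rev,) = enrichment_compare(set_b, set_a, motifs)
        assert rev.odds_ratio == pytest.approx(1.0 / fwd.odds_ratio)
        assert rev.p_value == fwd.p_value

    def test_zero_cells_use_haldane_anscombe(self):
        motifs = MotifTable([MotifRecord("m", "X", "AAA")])
        set_a = {f"a{i}": "AAA" for i in range(5)}
        set_b = {f"b{i}": "TTT" for i in range(5)}
        (row,) = enrichment_compare(set_a, set_b, motifs)
        assert row.odds_ratio == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))

    def test_empty_set_rejected(self):
        motifs = MotifTable([MotifRecord("m", "X", "AAA")])
        with pytest.raises(ModelError):
            enrichment_compare({}, {"b": "AAA"}, motifs)

    def test_planted_junction_motif_ranks_first_by_q(self, default_dataset):
        from circmotif.junctions import JunctionWindow, build_bsj_sequence

        ds = default_dataset
        windows = {
            cj.junction_id: build_bsj_sequence(
                ds.genome, ds.models[cj.transcript_id], cj, JunctionWindow(25)
            ).seq
            for cj in ds.junctions
        }
        ttn = {k: v for k, v in windows.items() if k.startswith("TTN_SYN")}
        other = {k: v for k, v in windows.items() if not k.startswith("TTN_SYN")}
        rows = enrichment_compare(ttn, other, ds.motif_table)
        best = min(rows, key=lambda r: (r.q_value, r.p_value))
        assert best.rbp_name == "SRSF10"
        assert best.q_value < 0.05


class TestStandardComparisons:
    def test_five_comparisons_emitted(self, default_dataset):
        ds = default_dataset
        reports = run_standard_comparisons(
            ds.genome, ds.models, ds.junctions, ds.motif_table, "TTN_SYN"
        )
        assert set(reports) == {
            "bsj_dependent_vs_independent",
            "bsj_ttn_vs_nonttn",
            "circ_ttn_vs_nonttn",
            "circ_ttn_vs_linear_mrna",
            "exons_included_vs_excluded",
        }
        for rows in reports.values():
            assert len(rows) == len(ds.motif_table)
            assert all(0 <= r.q_value <= 1 for r in rows)

    def test_missing_dependency_class_is_an_error(self, default_dataset):
        ds = default_dataset
        dep_only = [c for c in ds.junctions if c.dependency_class == "rbm20_dependent"]
        with pytest.raises(ModelError, match="rbm20_independent"):
            run_standard_comparisons(
                ds.genome, ds.models, dep_only, ds.motif_table, "TTN_SYN"
            )

    def test_circularize_wraps_junction(self):
        assert circularize("ACGTT", 3) == "ACGTTACG"
        # a motif split across the circle origin becomes findable
        assert "TTAC" in circularize("ACGTT", 3)

    def test_tiled_comparison_counts_tiles_not_sequences(self):
        motifs = MotifTable([MotifRecord("m", "X", "AAA")])
        long_with = "T" * 600 + "AAA" + "T" * 600
        rows = enrichment_compare_tiled({"a": long_with}, {"b": "T" * 1300}, motifs)
        (row,) = rows
        assert row.total_a == 3 and row.total_b == 3
        assert row.count_a == 1 and row.count_b == 0
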