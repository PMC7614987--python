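"""Fisher test, BH adjustment, scoring, inference and propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcgo.corpus import CorrespondenceMatrix
from dcgo.inference import (
    AnnotationRecord,
    AnnotationTable,
    bh_adjust,
    fisher_one_sided,
    hypergeom_strength,
    infer_annotations,
    propagate_annotations,
    read_annotation_table,
    rescale_scores,
    write_annotation_table,
)

from conftest import make_dag, random_annotation_table, random_dag


def tail_oracle(k, K, n, N):
    """Exhaustive hypergeometric upper-tail sum from binomial coefficients."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    ) / denom


class TestFisherOneSided:
    @pytest.mark.parametrize(
        "k,K,n,N,expected",
        [
            (0, 5, 5, 10, 1.0),
            (5, 5, 5, 10, 1 / 252),
            (4, 8, 6, 20, 5320 / 38760),
        ],
    )
    def test_known_tails(self, k, K, n, N, expected):
        assert fisher_one_sided(k, K, n, N) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "k,K,n,N",
        [(3, 2, 5, 10), (1, 11, 5, 10), (1, 5, 11, 10), (0, 0, 0, 0), (-1, 2, 2, 4)],
    )
    def test_inconsistent_counts_rejected(self, k, K, n, N):
        with pytest.raises(ValueError):
            fisher_one_sided(k, K, n, N)

    def test_matches_oracle_small_universes(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        assert fisher_one_sided(k, K, n, N) == pytest.approx(
                            tail_oracle(k, K, n, N), rel=1e-9, abs=1e-12
                        )


class TestBHAdjust:
    @pytest.mark.parametrize(
        "ps,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.04, 0.05], [0.015, 0.05, 0.05]),
            ([1.0], [1.0]),
        ],
    )
    def test_hand_derived_step_up(self, ps, expected):
        assert bh_adjust(ps) == pytest.approx(expected)

    def test_never_below_raw_p(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(size=50).tolist()
        assert all(a >= p for a, p in zip(bh_adjust(ps), ps))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_empty_input(self):
        assert bh_adjust([]) == []

    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
        seed=st.integers(0, 2**16),
    )
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_permutation_invariance(self, ps, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(ps))
        adjusted = bh_adjust(ps)
        permuted_adjusted = bh_adjust([ps[i] for i in perm])
        for pos, i in enumerate(perm):
            assert permuted_adjusted[pos] == pytest.approx(adjusted[i], rel=1e-12)


class TestHypergeomStrength:
    def test_zero_at_expectation(self):
        assert hypergeom_strength(2, 10, 20, 100) == 0.0

    def test_direct_formula(self):
        expected = 6 / math.sqrt(20 * 0.1 * 0.9 * 80 / 99)
        assert hypergeom_strength(8, 10, 20, 100) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_sigma_zero(self):
        assert hypergeom_strength(5, 5, 5, 5) == 0.0
        assert hypergeom_strength(0, 1, 0, 1) == 0.0


class TestRescaleScores:
    @pytest.mark.parametrize(
        "ss,expected",
        [
            ([2, 5, 11], [1.0, 34.0, 100.0]),
            ([7], [100.0]),
            ([0, 10], [1.0, 100.0]),
        ],
    )
    def test_min_max_mapping(self, ss, expected):
        assert rescale_scores(ss) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rescale_scores([])


def flat_matrix(cells, N, domain_type="other"):
    """CorrespondenceMatrix from {(term, domain): (k, K, n)} entries."""
    k = {pair: v[0] for pair, v in cells.items()}
    K = {}
    n = {}
    for (t, d), (_, Kv, nv) in cells.items():
        K[t] = Kv
        n[d] = nv
    return CorrespondenceMatrix(
        term_ids=sorted(K), domain_ids=sorted(n), k=k, K=K, n=n, N=N,
        domain_type=domain_type,
    )


class TestInferAnnotations:
    def test_planted_pair_retained(self):
        # domain D on 10/40 proteins, term t on 9 of those 10 and 2 of 30
        dag = make_dag({"t": []})
        matrix = flat_matrix({("t", "D"): (9, 11, 10)}, N=40)
        p = fisher_one_sided(9, 11, 10, 40)
        assert p == pytest.approx(tail_oracle(9, 11, 10, 40), rel=1e-9)
        assert p < 1e-5
        table = infer_annotations(matrix, dag, fdr_threshold=0.01)
        assert ("D", "t") in table.records
        rec = table.records[("D", "t")]
        assert rec.origin == "direct"
        assert rec.fdr < 0.01
        assert 1.0 <= rec.score <= 100.0

    def test_all_zero_cells_give_empty_table(self):
        dag = make_dag({"t": []})
        matrix = CorrespondenceMatrix(
            term_ids=["t"], domain_ids=["D"], k={}, K={"t": 3}, n={"D": 4}, N=10
        )
        table = infer_annotations(matrix, dag)
        assert len(table) == 0

    def test_single_insignificant_pair(self):
        dag = make_dag({"t": []})
        matrix = flat_matrix({("t", "D"): (1, 2, 5)}, N=10)
        assert fisher_one_sided(1, 2, 5, 10) > 0.05
        table = infer_annotations(matrix, dag, fdr_threshold=0.05)
        assert len(table) == 0

    def test_propagation_applied_to_direct_hits(self, chain_dag):
        matrix = flat_matrix({("c", "D"): (8, 8, 8)}, N=40)
        table = infer_annotations(matrix, chain_dag, fdr_threshold=0.01)
        assert {t for _, t in table.records} == {"a", "b", "c"}
        assert table.records[("D", "a")].origin == "propagated"


class TestPropagateAnnotations:
    def make_table(self, entries):
        table = AnnotationTable()
        for term, score in entries:
            table.add(
                AnnotationRecord(
                    domain_id="D", domain_type="other", term_id=term,
                    term_name=term, p=1e-6, fdr=1e-5, s=score / 10,
                    score=score, origin="direct",
                )
            )
        return table

    def test_single_path_inheritance(self, chain_dag):
        out = propagate_annotations(self.make_table([("c", 50.0)]), chain_dag)
        assert out.records[("D", "b")].score == 50.0
        assert out.records[("D", "a")].score == 50.0
        assert out.records[("D", "b")].origin == "propagated"

    def test_max_rule_at_common_parent(self):
        dag = make_dag({"a": [], "b": ["a"], "c": ["a"]})
        out = propagate_annotations(self.make_table([("b", 40.0), ("c", 70.0)]), dag)
        assert out.records[("D", "a")].score == 70.0

    def test_diamond_closure_size(self, diamond_dag):
        out = propagate_annotations(self.make_table([("d", 30.0)]), diamond_dag)
        assert len(out) == 4
        assert all(rec.score == 30.0 for rec in out.records.values())

    def test_direct_record_keeps_max_score(self, chain_dag):
        table = self.make_table([("c", 80.0), ("b", 20.0)])
        out = propagate_annotations(table, chain_dag)
        rec = out.records[("D", "b")]
        assert rec.origin == "direct"
        assert rec.score == 80.0

    def test_unknown_term_named_in_error(self, chain_dag):
        with pytest.raises(KeyError, match="zzz"):
            propagate_annotations(self.make_table([("zzz", 10.0)]), chain_dag)

    @pytest.mark.parametrize("seed", range(20))
    def test_closure_and_monotone_invariants(self, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, int(rng.integers(4, 25)))
        table = random_annotation_table(rng, dag)
        out = propagate_annotations(table, dag)
        keys = set(out.records)
        for d, t in keys:
            for anc in dag.ancestors(t):
                assert (d, anc) in keys
                assert out.records[(d, anc)].score >= out.records[(d, t)].score


class TestTableSerialization:
    def test_round_trip(self, tmp_path, chain_dag):
        matrix = flat_matrix({("c", "D"): (8, 8, 8), ("b", "E"): (9, 12, 9)}, N=40)
        table = infer_annotations(matrix, chain_dag, fdr_threshold=0.05,
                                  ontology_name="toy")
        path = tmp_path / "table.tsv"
        write_annotation_table(table, path)
        back = read_annotation_table(path)
        assert set(back.records) == set(table.records)
        for key, rec in table.records.items():
            other = back.records[key]
            assert other.p == rec.p
            assert other.fdr == rec.fdr
            assert other.score == rec.score
            assert other.origin == rec.origin
        assert back.metadata["ontology"] == "toy"

    def test_deterministic_bytes(self, tmp_path, chain_dag):
        matrix = flat_matrix({("c", "D"): (8, 8, 8)}, N=40)
        table = infer_annotations(matrix, chain_dag, fdr_threshold=0.05)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_annotation_table(table, p1)
        write_annotation_table(table, p2)
        assert p1.read_bytes() == p2.read_bytes()
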