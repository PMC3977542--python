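import numpy as np
import pytest

from aptamotif.alphabet import (
    make_composite_alphabet,
    parse_pattern,
    pattern_to_brackets,
    pattern_to_iupac,
)
from aptamotif.preprocess import SequenceRecord
from aptamotif.search import (
    DISTINCT,
    PSSM,
    MergedNode,
    SearchParams,
    build_pssm,
    _SeqMatrix,
    _weights_vector,
    check_integrity,
    find_members,
    loop_propensity,
    merge_step,
    search_motifs,
    total_information,
)
from aptamotif.structures import StructureEnsemble, boltzmann_weights
from aptamotif.suffixtree import build_loop_tree, build_tree

from .conftest import random_records
from .oracles import brute_force_search, occurrences, substring_members, tally_pssm


class TestCompositeAlphabet:
    @pytest.mark.parametrize("deg,size", [(1, 4), (2, 10), (3, 14), (4, 15)])
    def test_sizes(self, deg, size):
        assert len(make_composite_alphabet(deg)) == size

    def test_singletons_first_then_deterministic(self):
        chars = make_composite_alphabet(2)
        assert chars[:4] == [frozenset(b) for b in "ACGT"]
        assert chars == make_composite_alphabet(2)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            make_composite_alphabet(5)

    def test_pattern_notation_round_trip(self):
        pat = parse_pattern("[AG]G[AG]TGGTCCGGG")
        assert pattern_to_iupac(pat) == "RGRTGGTCCGGG"
        assert pattern_to_brackets(pat) == "[AG]G[AG]TGGTCCGGG"
        assert parse_pattern("RGRTGGTCCGGG") == pat


class TestNodeMerging:
    def test_worked_search_examples(self, fig1_records):
        tree = build_tree(fig1_records, max_depth=5)
        # A[CG]CA reaches s1 and s3; [CT]A[GT] reaches all three
        assert find_members(tree, parse_pattern("A[CG]CA")).tolist() == [0, 2]
        assert find_members(tree, parse_pattern("[CT]A[GT]")).tolist() == [0, 1, 2]

    def test_merge_step_dead_branch(self, fig1_records):
        tree = build_tree(fig1_records, max_depth=5)
        merged = merge_step([tree.root], frozenset("T"))
        merged2 = merge_step(merged.nodes, frozenset("T"))  # no "TT" anywhere
        assert merged2.nodes == []
        assert merged2.members.size == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_member_query_equals_direct_scan(self, seed):
        rng = np.random.default_rng(seed)
        records = random_records(rng, 12, max_len=25)
        tree = build_tree(records, max_depth=5)
        chars = make_composite_alphabet(2)
        for _ in range(30):
            pattern = tuple(
                chars[rng.integers(0, len(chars))]
                for _ in range(rng.integers(1, 5))
            )
            expected = sorted(substring_members(records, pattern))
            assert find_members(tree, pattern).tolist() == expected


class TestInformation:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 0.0),
            ((1, 0, 0, 0), 2.0),
            ((0.5, 0.5, 0, 0), 1.0),
        ],
    )
    def test_analytic_values(self, column, expected):
        assert total_information(column) == pytest.approx(expected)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            total_information((-0.1, 0.5, 0.3, 0.3))

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            col = rng.dirichlet(np.ones(4))
            assert 0 <= total_information(col) <= 2 + 1e-12


class TestPSSMAndIntegrity:
    def _matrix(self, records):
        tree = build_tree(records, max_depth=8)
        m = _SeqMatrix(tree)
        return m, _weights_vector(m, "READS")

    def test_single_occurrence_support(self):
        records = [SequenceRecord(0, "ACCA", 1)]
        m, w = self._matrix(records)
        pssm = build_pssm(parse_pattern("A[CG]CA"), np.array([0]), m, w)
        assert pssm.support[1] == frozenset("C")
        assert np.allclose(pssm.columns.sum(axis=1), 1)

    def test_two_occurrences_split_column(self):
        records = [SequenceRecord(0, "ACCA", 1), SequenceRecord(1, "AGCA", 1)]
        m, w = self._matrix(records)
        pssm = build_pssm(parse_pattern("A[CG]CA"), np.array([0, 1]), m, w)
        assert pssm.columns[1].tolist() == pytest.approx([0, 0.5, 0.5, 0])

    def test_identical_occurrences_are_unit_vectors(self):
        records = [SequenceRecord(0, "TACCAT", 2), SequenceRecord(1, "GACCAG", 3)]
        m, w = self._matrix(records)
        pssm = build_pssm(parse_pattern("ACCA"), np.array([0, 1]), m, w)
        assert np.allclose(np.sort(pssm.columns, axis=1)[:, -1], 1.0)

    def test_integrity_examples(self):
        pat = parse_pattern("A[CG]CA")
        good = PSSM(
            np.array([[1, 0, 0, 0], [0, 0.5, 0.5, 0], [0, 1, 0, 0], [1, 0, 0, 0]]),
            [frozenset("A"), frozenset("CG"), frozenset("C"), frozenset("A")],
        )
        assert check_integrity(pat, good)
        bad = PSSM(
            good.columns,
            [frozenset("A"), frozenset("C"), frozenset("C"), frozenset("A")],
        )
        assert not check_integrity(pat, bad)
        single = parse_pattern("ACCA")
        unit = PSSM(
            np.eye(4)[[0, 1, 1, 0]],
            [frozenset("A"), frozenset("C"), frozenset("C"), frozenset("A")],
        )
        assert check_integrity(single, unit)


class TestSearchMotifs:
    def test_overlong_max_len_rejected(self, fig1_records):
        tree = build_tree(fig1_records, max_depth=5)
        with pytest.raises(ValueError):
            search_motifs(tree, SearchParams(min_len=1, max_len=6, min_pos_info=0))

    def test_full_coverage_golden_hits(self, fig1_records):
        tree = build_tree(fig1_records, max_depth=5)
        params = SearchParams(
            min_len=3, max_len=4, min_coverage=1.0, min_pos_info=0.0
        )
        hits = {h.pattern for h in search_motifs(tree, params)}
        # [CT]AG occurs in all three inserts with support exactly {C,T},A,G
        assert parse_pattern("[CT]AG") in hits
        # [CT]A[GT] fails formal integrity: T is never seen at the last position
        assert parse_pattern("[CT]A[GT]") not in hits

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        records = random_records(rng, int(rng.integers(3, 10)), max_len=18)
        params = SearchParams(
            min_len=int(rng.integers(1, 3)),
            max_len=int(rng.integers(3, 5)),
            min_coverage=float(rng.choice([0.3, 0.5, 0.8])),
            coverage_basis="READS" if seed % 2 else DISTINCT,
            min_pos_info=float(rng.choice([0.0, 0.5, 1.0])),
            min_avg_info=float(rng.choice([0.0, 0.8])),
            max_degeneracy=2,
        )
        tree = build_tree(records, max_depth=params.max_len)
        expected = brute_force_search(records, params)
        got = {h.pattern: h for h in search_motifs(tree, params)}
        assert set(got) == set(expected)
        for pat, exp in expected.items():
            hit = got[pat]
            assert sorted(hit.matched_serials.tolist()) == exp["members"]
            assert hit.coverage == pytest.approx(exp["coverage"])
            assert np.allclose(hit.pssm.columns, exp["columns"])

    def test_gap_mode_agrees_with_brute_force(self):
        rng = np.random.default_rng(77)
        records = random_records(rng, 8, max_len=16)
        params = SearchParams(
            min_len=2,
            max_len=4,
            min_coverage=0.5,
            min_pos_info=1.0,
            gap_max_info=0.4,
            max_degeneracy=2,
        )
        tree = build_tree(records, max_depth=4)
        expected = brute_force_search(records, params)
        got = {h.pattern for h in search_motifs(tree, params)}
        assert got == set(expected)

    def test_emitted_pssm_revalidates_against_raw_inserts(self):
        rng = np.random.default_rng(202)
        records = random_records(rng, 8, max_len=20)
        params = SearchParams(
            min_len=2, max_len=4, min_coverage=0.4, min_pos_info=0.0
        )
        tree = build_tree(records, max_depth=4)
        m = _SeqMatrix(tree)
        w = _weights_vector(m, params.coverage_basis)
        hits = search_motifs(tree, params)
        assert hits, "expected at least one hit"
        for hit in hits:
            rescan = build_pssm(hit.pattern, hit.matched_serials, m, w)
            assert np.allclose(hit.pssm.columns, rescan.columns)
            assert hit.pssm.support == rescan.support

    def test_hit_ordering(self):
        rng = np.random.default_rng(303)
        records = random_records(rng, 6, max_len=15)
        tree = build_tree(records, max_depth=4)
        hits = search_motifs(
            tree, SearchParams(min_len=1, max_len=4, min_coverage=0.5, min_pos_info=0)
        )
        lengths = [len(h.pattern) for h in hits]
        assert lengths == sorted(lengths, reverse=True)


def _loop_tree_two_weights():
    """Two records whose planted loops have ensemble weights 0.6/0.8 at 'GTA'."""
    recs = [SequenceRecord(0, "ACGTACG", 1), SequenceRecord(1, "TCGTACT", 1)]

    def ens(seq, p_loop):
        # two structures: one exposing positions 2-5 as a loop, one fully paired
        e = StructureEnsemble(seq, [("((...))", -1.0), ("(.(.).)", -1.0)])
        e.probabilities = [p_loop, 1 - p_loop]
        return e

    ensembles = {0: ens("ACGTACG", 0.6), 1: ens("TCGTACT", 0.8)}
    return build_loop_tree(recs, ensembles, max_depth=5)


class TestLoopPropensity:
    def test_count_weighted_mean(self):
        tree = _loop_tree_two_weights()
        node = tree.lookup("GTA")
        merged = MergedNode([node], node.members, dict(node.weights))
        assert loop_propensity(merged, tree) == pytest.approx(0.7)

    def test_requires_loop_mode(self, fig1_records):
        tree = build_tree(fig1_records, max_depth=5)
        node = tree.lookup("A")
        merged = MergedNode([node], node.members, {0: 1.0})
        with pytest.raises(ValueError):
            loop_propensity(merged, tree)
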