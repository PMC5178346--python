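"""Count accumulation strategies, backtracking, restriction, and the matrices."""

import numpy as np
import pandas as pd
import pytest

from envotag.errors import InputError, UnknownTermError
from envotag.ontology import OntologyGraph, OntologyTerm
from envotag.termspace import (
    TermEvidence,
    accumulate_counts,
    apply_restriction,
    backtrack,
    normalize_rows,
    sample_matrix,
    unannotated_rows,
)


def _ev(q, rid, text, pubmed=None, counts=None):
    return TermEvidence(q, rid, text, pubmed, counts or {})


class TestAccumulateCounts:
    def test_duplicate_text_flat_vs_unique_isolation(self):
        evidence = [
            _ev("C1", "r1", "lake sediment", "P1", {"E:3": 1}),
            _ev("C1", "r2", "lake sediment", "P1", {"E:3": 1}),
        ]
        assert accumulate_counts(evidence, "flat") == {"C1": {"E:3": 2}}
        assert accumulate_counts(evidence, "unique_isolation") == {"C1": {"E:3": 1}}
        assert accumulate_counts(evidence, "unique_pubmed_unique_isolation") == {
            "C1": {"E:3": 1}
        }

    def test_same_text_distinct_pubmed_pairs_stay(self):
        evidence = [
            _ev("C1", "r1", "lake sediment", "P1", {"E:3": 1}),
            _ev("C1", "r2", "lake sediment", "P2", {"E:3": 1}),
        ]
        assert accumulate_counts(evidence, "unique_pubmed_unique_isolation") == {
            "C1": {"E:3": 2}
        }
        assert accumulate_counts(evidence, "unique_isolation") == {"C1": {"E:3": 1}}

    def test_single_row_identical_under_all_strategies(self):
        evidence = [_ev("C1", "r1", "soil", None, {"E:5": 2})]
        outs = {
            s: accumulate_counts(evidence, s)
            for s in ("flat", "unique_isolation", "unique_pubmed_unique_isolation")
        }
        assert all(o == {"C1": {"E:5": 2}} for o in outs.values())

    def test_dedup_is_per_query(self):
        evidence = [
            _ev("C1", "r1", "soil", None, {"E:5": 1}),
            _ev("C2", "r2", "soil", None, {"E:5": 1}),
        ]
        out = accumulate_counts(evidence, "unique_isolation")
        assert out == {"C1": {"E:5": 1}, "C2": {"E:5": 1}}

    def test_whitespace_trimmed_before_dedup(self):
        evidence = [
            _ev("C1", "r1", "  soil ", None, {"E:5": 1}),
            _ev("C1", "r2", "soil", None, {"E:5": 1}),
        ]
        assert accumulate_counts(evidence, "unique_isolation") == {"C1": {"E:5": 1}}

    def test_unknown_strategy(self):
        with pytest.raises(InputError):
            accumulate_counts([], "tfidf")

    def test_unique_isolation_never_exceeds_flat(self, toy):
        """Element-wise: unique_isolation counts <= flat counts."""
        import json

        ds, _ = toy
        expected = json.loads(ds.expected_counts.read_text())
        for per_query in expected.values():
            for term, c in per_query["unique_isolation"].items():
                assert c <= per_query["flat"][term]


class TestBacktrack:
    def test_fixture_propagation(self, mini_graph):
        out = backtrack({"E:3": 1, "E:5": 1}, mini_graph)
        assert out == {"E:3": 1, "E:5": 1, "E:2": 1, "E:1": 2}

    def test_root_only_unchanged(self, mini_graph):
        assert backtrack({"E:1": 4}, mini_graph) == {"E:1": 4}

    def test_diamond_not_double_counted(self, diamond_graph):
        out = backtrack({"D:X": 1}, diamond_graph)
        assert out == {"D:X": 1, "D:Y": 1, "D:Z": 1, "D:W": 1}

    def test_unknown_term_named(self, mini_graph):
        with pytest.raises(UnknownTermError, match="E:99"):
            backtrack({"E:99": 1}, mini_graph)

    def test_never_decreases_and_total_grows(self, mini_graph):
        before = {"E:3": 2, "E:4": 5}
        after = backtrack(before, mini_graph)
        for t, c in before.items():
            assert after[t] >= c
        assert sum(after.values()) >= sum(before.values())

    def test_tree_root_receives_total_tag_count(self, mini_graph):
        counts = {"E:3": 2, "E:4": 1, "E:5": 3}
        after = backtrack(counts, mini_graph)
        assert after["E:1"] == sum(counts.values())

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_transitive_closure_oracle_on_random_dags(self, trial):
        import random

        rng = random.Random(40 + trial)
        n = rng.randint(2, 50)
        terms = {
            f"T:{i}": OntologyTerm(
                f"T:{i}", str(i),
                parents=[f"T:{j}" for j in range(i) if rng.random() < 0.2],
            )
            for i in range(n)
        }
        graph = OntologyGraph(terms)
        counts = {f"T:{i}": rng.randint(1, 5) for i in rng.sample(range(n), k=min(8, n))}
        got = backtrack(counts, graph)
        # oracle: brute-force reachability by DFS over all is_a paths
        expect = dict(counts)
        for t, c in counts.items():
            reached, stack = set(), list(terms[t].parents)
            while stack:
                p = stack.pop()
                if p not in reached:
                    reached.add(p)
                    stack.extend(terms[p].parents)
            for p in reached:
                expect[p] = expect.get(p, 0) + c
        assert got == expect


class TestApplyRestriction:
    def test_removes_non_descendants(self, mini_graph):
        assert apply_restriction({"E:3": 2, "E:5": 1}, mini_graph, "E:2") == {"E:3": 2}

    def test_root_keeps_everything(self, mini_graph):
        counts = {"E:3": 2, "E:5": 1}
        assert apply_restriction(counts, mini_graph, "E:1") == counts

    def test_can_remove_everything(self, mini_graph):
        assert apply_restriction({"E:5": 1}, mini_graph, "E:4") == {}

    def test_unknown_root(self, mini_graph):
        with pytest.raises(UnknownTermError):
            apply_restriction({"E:3": 1}, mini_graph, "E:99")


class TestNormalizeRows:
    def test_equal_split(self):
        S = normalize_rows({"C1": {"E:3": 1, "E:5": 1}}, ["C1"])
        assert list(S.loc["C1"]) == [0.5, 0.5]

    def test_single_term_row(self):
        S = normalize_rows({"C1": {"E:4": 3}}, ["C1"])
        assert S.loc["C1", "E:4"] == 1.0

    def test_zero_rows_kept_and_reported(self):
        S = normalize_rows({"C1": {"E:3": 1}, "C2": {}}, ["C1", "C2"])
        assert unannotated_rows(S) == ["C2"]
        assert S.loc["C2"].sum() == 0

    def test_term_columns_lexicographic(self):
        S = normalize_rows({"C1": {"E:5": 1, "E:2": 1, "E:10": 1}}, ["C1"])
        assert list(S.columns) == sorted(S.columns)

    def test_negative_count_rejected(self):
        with pytest.raises(InputError):
            normalize_rows({"C1": {"E:3": -1}}, ["C1"])

    def test_nonzero_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        raw = {
            f"C{j}": {f"E:{k}": int(rng.integers(0, 9)) for k in range(6)}
            for j in range(20)
        }
        S = normalize_rows(raw, list(raw))
        sums = S.sum(axis=1)
        for s in sums:
            assert s == 0 or abs(s - 1.0) < 1e-9


class TestSampleMatrix:
    def test_symmetric_weights(self):
        S = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["C1", "C2"],
                         columns=["E:3", "E:5"])
        F = pd.DataFrame([[2.0, 2.0]], index=["Z"], columns=["C1", "C2"])
        N = sample_matrix(F, S)
        assert list(N.loc["Z"]) == [0.5, 0.5]

    def test_weighted_composition(self):
        S = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["C1", "C2"],
                         columns=["E:3", "E:5"])
        F = pd.DataFrame([[1.0, 3.0]], index=["Z"], columns=["C1", "C2"])
        N = sample_matrix(F, S)
        assert list(N.loc["Z"]) == [0.25, 0.75]

    def test_zero_sample_row_warns_and_stays_zero(self):
        S = pd.DataFrame([[1.0]], index=["C1"], columns=["E:3"])
        F = pd.DataFrame([[0.0], [2.0]], index=["Z1", "Z2"], columns=["C1"])
        with pytest.warns(UserWarning, match="Z1"):
            N = sample_matrix(F, S)
        assert N.loc["Z1", "E:3"] == 0 and N.loc["Z2", "E:3"] == 1.0

    def test_sequence_set_mismatch_listed(self):
        S = pd.DataFrame([[1.0]], index=["C1"], columns=["E:3"])
        F = pd.DataFrame([[1.0]], index=["Z"], columns=["C9"])
        with pytest.raises(InputError, match="C9"):
            sample_matrix(F, S)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_double_loop_oracle(self, trial):
        """N equals the element-wise brute-force sum over random instances."""
        rng = np.random.default_rng(trial)
        n_samples, n_seqs, n_terms = 5, 4, 6
        raw = rng.integers(0, 5, size=(n_seqs, n_terms)).astype(float)
        S = pd.DataFrame(raw, index=[f"C{j}" for j in range(n_seqs)],
                         columns=[f"E:{k}" for k in range(n_terms)])
        sums = S.sum(axis=1)
        S.loc[sums > 0] = S.loc[sums > 0].div(sums[sums > 0], axis=0)
        F = pd.DataFrame(rng.integers(0, 10, size=(n_samples, n_seqs)).astype(float),
                         index=[f"Z{i}" for i in range(n_samples)], columns=S.index)
        N = sample_matrix(F, S)
        for i in range(n_samples):
            raw_row = [
                sum(F.iat[i, j] * S.iat[j, k] for j in range(n_seqs))
                for k in range(n_terms)
            ]
            total = sum(raw_row)
            expect = [v / total if total else 0.0 for v in raw_row]
            assert np.allclose(N.iloc[i].to_numpy(), expect, atol=1e-12)
            if total:
                assert abs(N.iloc[i].sum() - 1.0) < 1e-9
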