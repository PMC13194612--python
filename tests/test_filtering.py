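"""Subtractive filter cascade: stage rules, oracle equivalence, monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probiotarget import synthetic
from probiotarget.filtering import (
    AnnotationTable,
    CascadeConfig,
    ProteinRecord,
    cluster_redundant,
    filter_essential,
    filter_human_nonhomologous,
    localization_consensus,
    pairwise_identity,
    run_cascade,
)


def make_table(rows: dict[str, dict], hits: list[dict] | None = None) -> AnnotationTable:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "protein_id"
    hits_df = pd.DataFrame(
        hits or [], columns=["protein_id", "evalue", "identity_pct", "coverage_pct"]
    )
    return AnnotationTable(df, hits_df)


class TestClusterRedundant:
    def test_identical_sequences_collapse(self):
        prots = [ProteinRecord(f"p{i}", "MKTAYIAKQR") for i in range(3)]
        clusters, reps = cluster_redundant(prots, 0.7)
        assert len(clusters) == 1 and len(reps) == 1

    def test_disjoint_sequences_stay_apart(self):
        prots = [ProteinRecord("a", "AAAAAAAA"), ProteinRecord("b", "CCCCCCCC")]
        clusters, _ = cluster_redundant(prots, 0.7)
        assert len(clusters) == 2

    def test_threshold_straddles_pair_identity(self):
        """100-mer vs a 25-substitution copy: identity 0.75 by position count."""
        rng = np.random.default_rng(7)
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        mutated = list(base)
        for pos in rng.choice(100, size=25, replace=False):
            mutated[pos] = "W" if mutated[pos] != "W" else "Y"
        pair = [ProteinRecord("a", base), ProteinRecord("b", "".join(mutated))]
        assert pairwise_identity(base, "".join(mutated)) == pytest.approx(0.75)
        assert len(cluster_redundant(pair, 0.70)[0]) == 1
        assert len(cluster_redundant(pair, 0.80)[0]) == 2

    def test_representative_is_longest_founder(self):
        prots = [ProteinRecord("short", "MKTAYI"), ProteinRecord("long", "MKTAYIAKQR")]
        _, reps = cluster_redundant(prots, 0.5)
        assert reps[0].id == "long"

    def test_empty_input(self):
        assert cluster_redundant([], 0.7) == ([], [])

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(
            st.text(alphabet="ACDEG", min_size=5, max_size=20), min_size=1, max_size=12
        ),
        st.sampled_from([0.4, 0.6, 0.8]),
    )
    def test_brute_force_oracle_equivalence(self, seqs, threshold):
        """Greedy clustering matches an independent all-pairs reimplementation."""
        prots = [ProteinRecord(f"p{i:02d}", s) for i, s in enumerate(seqs)]
        clusters, _ = cluster_redundant(prots, threshold)

        # independent oracle: precompute the full identity matrix, then
        # assign longest-first against founders
        ident = {
            (a.id, b.id): pairwise_identity(a.sequence, b.sequence)
            for a in prots
            for b in prots
        }
        ordered = sorted(prots, key=lambda p: (-len(p.sequence), p.id))
        oracle: list[list[str]] = []
        for p in ordered:
            for cl in oracle:
                if ident[(p.id, cl[0])] >= threshold:
                    cl.append(p.id)
                    break
            else:
                oracle.append([p.id])
        got = [[m.id for m in c] for c in clusters]
        assert got == oracle

    def test_union_of_clusters_is_input(self):
        spec = synthetic.SyntheticSpec(
            seed=5, n_proteins=10, length_range=(30, 60),
            redundancy_groups=[(3, 0.9), (2, 1.0)],
        )
        prots, _ = synthetic.generate_proteome(spec)
        clusters, _ = cluster_redundant(prots, 0.7)
        assert sorted(m.id for c in clusters for m in c) == sorted(p.id for p in prots)


class TestFilterEssential:
    def test_threshold_rule_with_inclusive_boundary(self):
        table = make_table(
            {
                "a": {"essentiality_score": 0.30},
                "b": {"essentiality_score": 0.24},
                "c": {"essentiality_score": 0.10},
            }
        )
        trace = filter_essential(table, ["a", "b", "c"])
        assert trace.retained_ids == ("a", "b")
        assert "c" in trace.reasons

    def test_missing_score_strict_vs_fail(self):
        table = make_table({"a": {"essentiality_score": np.nan}})
        with pytest.raises(ValueError):
            filter_essential(table, ["a"])
        trace = filter_essential(table, ["a"], missing="fail")
        assert trace.retained_ids == ()


def loc_row(psortb=("cytoplasmic", 9.0), cello="cytoplasmic", deeploc=("cytoplasmic", 0.9)):
    return {
        "psortb_call": psortb[0],
        "psortb_score": psortb[1],
        "cello2go_call": cello,
        "cello2go_reliability": 0.9,
        "deeplocpro_call": deeploc[0],
        "deeplocpro_prob": deeploc[1],
    }


class TestLocalizationConsensus:
    def test_unanimous_cytoplasmic_retained(self):
        table = make_table({"a": loc_row()})
        assert localization_consensus(table, ["a"]).retained_ids == ("a",)

    def test_low_confidence_vote_does_not_count(self):
        # PSORTb cytoplasmic but below 7.5; the other tools say membrane
        table = make_table(
            {"a": loc_row(psortb=("cytoplasmic", 5.0), cello="membrane",
                          deeploc=("membrane", 0.9))}
        )
        trace = localization_consensus(table, ["a"])
        assert trace.retained_ids == ()

    def test_two_of_three_majority_retained(self):
        table = make_table(
            {"a": loc_row(deeploc=("membrane", 0.9))}
        )
        assert localization_consensus(table, ["a"]).retained_ids == ("a",)

    def test_no_tool_reporting_removed_with_reason(self):
        table = make_table({"a": {"essentiality_score": 0.5}})
        trace = localization_consensus(table, ["a"])
        assert trace.reasons["a"] == "no_tool_report"


class TestHumanHomology:
    def test_no_hits_retained(self):
        table = make_table({"a": {}})
        assert filter_human_nonhomologous(table, ["a"]).retained_ids == ("a",)

    def test_strong_hit_removed(self):
        table = make_table(
            {"a": {}}, hits=[{"protein_id": "a", "evalue": 1e-10,
                              "identity_pct": 60.0, "coverage_pct": 80.0}]
        )
        trace = filter_human_nonhomologous(table, ["a"])
        assert trace.reasons["a"] == "significant_human_hit"

    def test_low_identity_and_coverage_not_significant(self):
        table = make_table(
            {"a": {}}, hits=[{"protein_id": "a", "evalue": 1e-10,
                              "identity_pct": 25.0, "coverage_pct": 20.0}]
        )
        assert filter_human_nonhomologous(table, ["a"]).retained_ids == ("a",)

    def test_any_combination_mode_is_stricter(self):
        table = make_table(
            {"a": {}}, hits=[{"protein_id": "a", "evalue": 1e-10,
                              "identity_pct": 25.0, "coverage_pct": 20.0}]
        )
        trace = filter_human_nonhomologous(table, ["a"], combine="any")
        assert trace.retained_ids == ()

    def test_malformed_hit_rows_error(self):
        table = make_table(
            {"a": {}}, hits=[{"protein_id": "a", "evalue": "bad",
                              "identity_pct": 60.0, "coverage_pct": 80.0}]
        )
        with pytest.raises(ValueError):
            filter_human_nonhomologous(table, ["a"])


@pytest.fixture(scope="module")
def synthetic_cascade_inputs():
    spec = synthetic.SyntheticSpec(
        seed=11, n_proteins=30, length_range=(40, 80),
        redundancy_groups=[(3, 1.0), (2, 0.95)],
        filter_pass_rates={"essential": 0.5, "cytoplasmic": 0.7, "nonhomologous": 0.5},
    )
    prots, _ = synthetic.generate_proteome(spec)
    ann, hits, truth = synthetic.generate_annotations(spec, prots)
    return prots, AnnotationTable(ann, hits), truth


class TestRunCascade:
    def test_final_count_matches_generator_truth(self, synthetic_cascade_inputs):
        prots, table, truth = synthetic_cascade_inputs
        result = run_cascade(prots, table)
        reps = {p.id for p in (c[0] for c in result.clusters)}
        expected = truth[
            truth["essential"] & truth["cytoplasmic"] & truth["nonhomologous"]
        ]["protein_id"]
        expected = {pid for pid in expected if pid in reps}
        assert set(result.candidate_ids) == expected

    def test_empty_proteome(self):
        table = make_table({})
        result = run_cascade([], table)
        assert result.traces == [] and result.candidate_ids == ()

    def test_permissive_config_keeps_non_redundant_set(self, synthetic_cascade_inputs):
        prots, table, _ = synthetic_cascade_inputs
        config = CascadeConfig(
            essentiality_threshold=-1.0, min_localization_votes=0,
            evalue_cut=-1.0,  # nothing can be significant
        )
        result = run_cascade(prots, table, config)
        reps = {c[0].id for c in result.clusters}
        assert set(result.candidate_ids) == reps

    def test_retained_set_never_grows(self, synthetic_cascade_inputs):
        prots, table, _ = synthetic_cascade_inputs
        result = run_cascade(prots, table)
        sizes = [tr.n_in for tr in result.traces] + [len(result.candidate_ids)]
        assert sizes == sorted(sizes, reverse=True)
        for prev, nxt in zip(result.traces, result.traces[1:]):
            assert set(nxt.input_ids) == set(prev.retained_ids)

    @pytest.mark.parametrize("threshold", [0.0, 0.1, 0.24, 0.5, 0.9])
    def test_essentiality_threshold_monotonicity(self, synthetic_cascade_inputs, threshold):
        prots, table, _ = synthetic_cascade_inputs
        ids = [p.id for p in prots]
        low = filter_essential(table, ids, threshold=threshold)
        high = filter_essential(table, ids, threshold=threshold + 0.05)
        assert set(high.retained_ids) <= set(low.retained_ids)
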