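import numpy as np
import pytest

from sigstrat.cohort_stats import (
    assign_subgroups,
    association_test,
    geneset_tally,
    pairwise_interactions,
    prevalence_table,
    read_gmt,
    union_cooccurrence,
)

from conftest import make_record
from oracles import fisher_two_sided


def sample_with(sid, genes, vclass="missense"):
    return [
        make_record(sample_id=sid, gene=g, pos=100_000 + 1000 * i, variant_class=vclass)
        for i, g in enumerate(genes)
    ]


class TestSubgroups:
    def test_four_way_labelling(self):
        records = (
            sample_with("A", ["ARID1A"])
            + sample_with("B", ["PIK3CA"])
            + sample_with("C", ["ARID1A", "PIK3CA"])
            + sample_with("D", ["OTHER"])
        )
        labels = {l.sample_id: l.label for l in assign_subgroups(records)}
        assert labels == {"A": "ARID1A", "B": "PIK3CA", "C": "Double hit", "D": "Undetermined"}

    def test_silent_variants_do_not_toggle_membership(self):
        records = sample_with("A", ["ARID1A"], vclass="silent") + sample_with("A", ["OTHER"])
        (label,) = assign_subgroups(records)
        assert label.label == "Undetermined"

    def test_labels_partition_cohort(self, small_cohort):
        records, truth = small_cohort
        labels = assign_subgroups(records)
        assert len(labels) == len(truth.sample_ids)
        assert {l.sample_id for l in labels} == set(truth.sample_ids)

    def test_generator_truth_recovered(self, small_cohort):
        records, truth = small_cohort
        for l in assign_subgroups(records):
            assert l.label == truth.subgroup[l.sample_id]


class TestPrevalence:
    def test_27_of_55_rounds_to_49_1(self):
        records = []
        for i in range(55):
            genes = ["ARID1A", "FILLER"] if i < 27 else ["FILLER"]
            records += sample_with(f"S{i:02d}", genes)
        prev = prevalence_table(records)
        row = prev["gene_prevalence"].set_index("gene").loc["ARID1A"]
        assert row["n_mutated"] == 27
        assert round(100 * row["prevalence"], 1) == 49.1

    def test_zero_prevalence_for_unmutated_cohort(self):
        prev = prevalence_table(sample_with("A", ["X"], vclass="silent"))
        assert prev["gene_prevalence"].empty

    def test_union_ratio_reports_both_counts(self):
        records = []
        for i in range(10):
            genes = (["ARID1A"] if i < 6 else []) + (["PIK3CA"] if 4 <= i < 9 else [])
            records += sample_with(f"S{i}", genes or ["FILLER"])
        u = union_cooccurrence(records)
        assert u["n_both"] == 2  # samples 4, 5
        assert u["n_union"] == 9
        assert u["ratio_both_over_union"] == pytest.approx(2 / 9)


class TestPairwiseInteractions:
    def _cohort(self, set_a, set_b, n):
        records = []
        for i in range(n):
            genes = (["GA"] if i in set_a else []) + (["GB"] if i in set_b else [])
            records += sample_with(f"S{i:03d}", genes or ["FILLER"])
        return records

    def test_identical_sets_co_occur(self):
        mutated = set(range(10))
        records = self._cohort(mutated, mutated, 20)
        (res,) = [r for r in pairwise_interactions(records) if {r.gene_a, r.gene_b} == {"GA", "GB"}]
        assert res.direction == "co-occurring"
        assert np.isinf(res.odds_ratio)
        assert res.n_co_events == 10
        assert res.p_value == pytest.approx(fisher_two_sided(10, 0, 0, 10), abs=1e-10)

    def test_disjoint_sets_mutually_exclusive(self):
        records = self._cohort(set(range(10)), set(range(10, 20)), 20)
        (res,) = [r for r in pairwise_interactions(records) if {r.gene_a, r.gene_b} == {"GA", "GB"}]
        assert res.direction == "mutually exclusive"
        assert res.p_value == pytest.approx(fisher_two_sided(0, 10, 10, 0), abs=1e-10)

    def test_counts_sum_to_cohort_size(self):
        records = self._cohort(set(range(8)), set(range(5, 17)), 30)
        (res,) = [r for r in pairwise_interactions(records) if {r.gene_a, r.gene_b} == {"GA", "GB"}]
        assert res.n_both + res.n_only_a + res.n_only_b + res.n_neither == 30

    def test_symmetric_under_gene_relabelling(self):
        records = self._cohort(set(range(8)), set(range(5, 17)), 30)
        swapped = []
        for rec in records:
            gene = {"GA": "GB", "GB": "GA"}.get(rec.gene, rec.gene)
            swapped.append(make_record(sample_id=rec.sample_id, gene=gene, pos=rec.pos))
        (a,) = [r for r in pairwise_interactions(records) if {r.gene_a, r.gene_b} == {"GA", "GB"}]
        (b,) = [r for r in pairwise_interactions(swapped) if {r.gene_a, r.gene_b} == {"GA", "GB"}]
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.n_both == b.n_both

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(0)
        n_samples, n_genes = 40, 120
        presence = rng.uniform(size=(n_samples, n_genes)) < 0.5
        records = []
        for i in range(n_samples):
            genes = [f"G{j:03d}" for j in np.where(presence[i])[0]] or ["FILLER"]
            records += sample_with(f"S{i:03d}", genes)
        results = [r for r in pairwise_interactions(records) if "FILLER" not in (r.gene_a, r.gene_b)]
        frac = np.mean([r.direction != "none" for r in results])
        # Fisher is conservative under the null; 0.05 plus Monte-Carlo slack
        assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / len(results))


class TestAssociationTest:
    def test_identical_flags_give_minimal_p(self):
        a = [True] * 8 + [False] * 8
        odds, p = association_test(a, a)
        assert np.isinf(odds)
        assert p == pytest.approx(fisher_two_sided(8, 0, 0, 8), abs=1e-12)

    def test_constant_flag_degenerate_margin(self):
        odds, p = association_test([True] * 10, [True] * 5 + [False] * 5)
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.uniform(size=25) < 0.4
            b = rng.uniform(size=25) < 0.6
            _, p = association_test(a, b)
            t = [
                int(np.sum(a & b)), int(np.sum(a & ~b)),
                int(np.sum(~a & b)), int(np.sum(~a & ~b)),
            ]
            assert p == pytest.approx(fisher_two_sided(*t), abs=1e-10)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            association_test([True], [True, False])


class TestGeneSets:
    def test_fraction_of_samples_hitting_set(self):
        records = sample_with("A", ["X1"]) + sample_with("B", ["Y1"]) + sample_with("C", ["Z1"])
        df = geneset_tally(records, {"XY": ["X1", "Y1"], "Z": ["Z1"], "none": ["Q"]})
        frac = dict(zip(df["gene_set"], df["fraction"]))
        assert frac == {"XY": pytest.approx(2 / 3), "Z": pytest.approx(1 / 3), "none": 0.0}

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("PI3K\tdesc\tPIK3CA\tAKT1\nNOTCH\tdesc\tNOTCH1\n")
        sets = read_gmt(path)
        assert sets == {"PI3K": ["PIK3CA", "AKT1"], "NOTCH": ["NOTCH1"]}
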