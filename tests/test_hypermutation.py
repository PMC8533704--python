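import numpy as np
import pytest

from sigstrat.hypermutation import (
    ApobecResult,
    KataegisConfig,
    RainfallPoint,
    apobec_enrichment,
    apobec_positive,
    call_kataegis,
    intermutation_distances,
    optimal_segmentation,
    segment_distances,
)
from sigstrat.synthetic_cohort import CohortSpec, KataegisCluster, generate_cohort

from conftest import make_record
from oracles import best_segmentation_cost


def snv_at(pos, chrom="chr1", sample="S1", **kw):
    return make_record(sample_id=sample, chrom=chrom, pos=pos, **kw)


class TestIntermutationDistances:
    def test_simple_sequence(self):
        pts = intermutation_distances([snv_at(p) for p in (100_000, 100_500, 101_000)])
        assert np.isnan(pts[0].distance)
        assert [p.distance for p in pts[1:]] == [500.0, 500.0]

    def test_single_mutation_has_no_distance(self):
        (pt,) = intermutation_distances([snv_at(100_000)])
        assert np.isnan(pt.distance)

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(0)
        recs = [snv_at(int(p), chrom=f"chr{1 + i % 2}") for i, p in enumerate(rng.integers(1_000, 9_000_000, 50))]
        a = intermutation_distances(recs)
        order = rng.permutation(len(recs))
        b = intermutation_distances([recs[i] for i in order])
        assert [(p.chrom, p.pos) for p in a] == [(p.chrom, p.pos) for p in b]
        np.testing.assert_array_equal(
            np.nan_to_num([p.distance for p in a], nan=-1),
            np.nan_to_num([p.distance for p in b], nan=-1),
        )

    def test_ties_get_zero_distance(self):
        pts = intermutation_distances([snv_at(100_000), snv_at(100_000, sample="S2")])
        assert pts[1].distance == 0.0


class TestSegmentation:
    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(2, 13))
            x = np.concatenate(
                [rng.normal(3.5, 0.3, n // 2), rng.normal(2.0, 0.3, n - n // 2)]
            )
            rng.shuffle(x) if rng.uniform() < 0.3 else None
            for penalty in (0.5, 1.0, 2.0):
                segs = optimal_segmentation(x, penalty)
                cost = sum(
                    float(np.sum((x[a : b + 1] - x[a : b + 1].mean()) ** 2)) + penalty
                    for a, b in segs
                )
                assert cost == pytest.approx(best_segmentation_cost(x, penalty), abs=1e-9)

    def test_positive_penalty_required(self):
        with pytest.raises(ValueError):
            optimal_segmentation(np.ones(5), 0.0)


def background(chrom="chr1", start=3_000_000, spacing=300_000, n=20, sample="S1"):
    return [snv_at(start + i * spacing, chrom=chrom, sample=sample) for i in range(n)]


class TestKataegisCalls:
    def test_isolated_six_point_cluster_detected(self):
        cluster = [snv_at(1_000_000 + i * 500) for i in range(6)]
        foci = call_kataegis(cluster + background())
        assert len(foci) == 1
        (f,) = foci
        assert f.n_mutations == 6
        assert f.start == 1_000_000 and f.end == 1_002_500
        assert f.mean_distance <= 1000

    def test_five_point_cluster_below_minimum(self):
        cluster = [snv_at(1_000_000 + i * 500) for i in range(5)]
        assert call_kataegis(cluster + background()) == []

    def test_spacing_above_1000_not_kataegis(self):
        cluster = [snv_at(1_000_000 + i * 1100) for i in range(6)]
        assert call_kataegis(cluster + background()) == []

    def test_reported_segments_satisfy_rule_post_hoc(self):
        rng = np.random.default_rng(2)
        recs = [snv_at(int(p)) for p in np.sort(rng.integers(10_000, 9_000_000, 300))]
        pts = intermutation_distances(recs)
        for seg in segment_distances(pts):
            if seg.is_kataegis:
                assert seg.n_mutations >= 6 and seg.mean_distance <= 1000

    def test_planted_clusters_recovered_from_generator(self):
        plan = (
            KataegisCluster(0, "chr1", 6, 400.0),
            KataegisCluster(1, "chr2", 8, 400.0),
            KataegisCluster(2, "chr3", 10, 400.0),
        )
        records, truth = generate_cohort(CohortSpec.kataegis_study(seed=13, plan=plan))
        foci = call_kataegis(records)
        assert len(foci) == 3
        for sid, chrom, start, end, n in truth.kataegis_intervals:
            overlapping = [
                f for f in foci if f.chrom == chrom and f.start <= end and f.end >= start
            ]
            assert len(overlapping) == 1

    def test_null_cohort_rarely_produces_foci(self):
        # uniform placement below one mutation per 10 kb, no planted clusters
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            pts = []
            for chrom in ("chr1", "chr2", "chr3"):
                pos = np.sort(rng.integers(1, 10_000_000, 600))
                d = np.diff(pos).astype(float)
                pts.extend(
                    RainfallPoint("cohort", chrom, int(p), float("nan") if i == 0 else d[i - 1])
                    for i, p in enumerate(pos)
                )
            if any(s.is_kataegis for s in segment_distances(pts)):
                hits += 1
        assert hits <= 5  # 0 foci in >= 95% of null cohorts

    def test_empty_input(self):
        assert call_kataegis([]) == []

    def test_per_sample_mode_keeps_samples_separate(self):
        cluster_a = [snv_at(1_000_000 + i * 500, sample="A") for i in range(3)]
        cluster_b = [snv_at(1_001_500 + i * 500, sample="B") for i in range(3)]
        pooled = call_kataegis(cluster_a + cluster_b + background(sample="A"))
        per_sample = call_kataegis(
            cluster_a + cluster_b + background(sample="A"), KataegisConfig(per_sample=True)
        )
        assert len(pooled) == 1  # interleaved samples merge into one run
        assert per_sample == []  # neither sample alone reaches six mutations


def tcw_context():
    return "G" * 19 + "TCA" + "CGGCGGCGG" + "G" * 10


def non_tcw_context():
    return "G" * 19 + "GCA" + "TCACC" + "G" * 14


class TestApobecEnrichment:
    def test_constructed_enrichment_of_four(self):
        # every mutated C in tCw; each window holds 4 c's and 1 tcw
        recs = [
            make_record(pos=100_000 + i, ref_allele="C", alt_allele="T", context41=tcw_context())
            for i in range(10)
        ]
        res = apobec_enrichment(recs)
        assert (res.mut_tcw, res.mut_c) == (10, 10)
        assert res.background_c == 4 * res.background_tcw
        assert res.enrichment == pytest.approx(4.0)
        assert res.is_positive

    def test_null_proportion_gives_e_of_one(self):
        recs = [make_record(pos=100_000, ref_allele="C", alt_allele="T", context41=tcw_context())]
        recs += [
            make_record(pos=100_010 + i, ref_allele="C", alt_allele="T", context41=non_tcw_context())
            for i in range(3)
        ]
        res = apobec_enrichment(recs)
        assert (res.mut_tcw, res.mut_c) == (1, 4)
        assert res.enrichment == pytest.approx(1.0)
        assert not res.is_positive

    def test_guanine_reference_counts_on_opposite_strand(self):
        from sigstrat.motifs import revcomp

        rec_c = make_record(pos=100_000, ref_allele="C", alt_allele="T", context41=tcw_context())
        rec_g = make_record(
            pos=100_001, ref_allele="G", alt_allele="A", context41=revcomp(tcw_context())
        )
        a = apobec_enrichment([rec_c])
        b = apobec_enrichment([rec_g])
        assert (a.mut_tcw, a.mut_c, a.background_c, a.background_tcw) == (
            b.mut_tcw, b.mut_c, b.background_c, b.background_tcw,
        )

    def test_only_c_to_a_is_undefined_under_restriction(self):
        recs = [make_record(pos=100_000, ref_allele="C", alt_allele="A", context41=tcw_context())]
        with pytest.warns(UserWarning, match="undefined"):
            res = apobec_enrichment(recs)
        assert np.isnan(res.enrichment) and not res.is_positive
        widened = apobec_enrichment(recs, restrict_substitutions=False)
        assert widened.mut_c == 1

    def test_duplication_invariance(self):
        recs = [
            make_record(pos=100_000, ref_allele="C", alt_allele="T", context41=tcw_context()),
            make_record(pos=100_050, ref_allele="C", alt_allele="G", context41=non_tcw_context()),
        ]
        a = apobec_enrichment(recs)
        b = apobec_enrichment(recs + recs)
        assert b.mut_c == 2 * a.mut_c and b.background_c == 2 * a.background_c
        assert b.enrichment == pytest.approx(a.enrichment)

    def test_classification_rule_is_strict_at_two(self):
        assert not apobec_positive(2.0)
        assert apobec_positive(2.01)
        assert not apobec_positive(float("nan"))
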