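import numpy as np
import pytest

from sigstrat.denovo_signatures import (
    MutationalSignatureModel,
    SignatureResults,
    explained_variance,
    match_to_reference,
    nmf_factorize,
    residual_sum_of_squares,
    select_rank,
)
from sigstrat.io_formats import ReferenceSignatureSet
from sigstrat.spectrum import build_spectra, spectra_matrix
from sigstrat.synthetic_cohort import CohortSpec, generate_cohort, make_true_signatures


def _cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


@pytest.fixture(scope="module")
def study_matrix():
    records, truth = generate_cohort(CohortSpec.signature_study(seed=21))
    V = spectra_matrix(build_spectra([r for r in records if r.is_snv]))
    return V.to_numpy(dtype=float), truth


class TestFactorize:
    def test_exact_rank_one_input_reconstructs(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, 96)
        h = rng.uniform(1, 5, 12)
        V = np.outer(w, h)
        run = nmf_factorize(V, 1, seed=1, max_iter=2000, tol=1e-12)
        assert residual_sum_of_squares(V, run.W, run.H) < 1e-6 * np.sum(V**2)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        V = rng.poisson(5.0, (96, 10)).astype(float) + 0.1
        r1 = nmf_factorize(V, 3, seed=42)
        r2 = nmf_factorize(V, 3, seed=42)
        np.testing.assert_array_equal(r1.W, r2.W)
        np.testing.assert_array_equal(r1.H, r2.H)

    def test_w_columns_normalized(self):
        rng = np.random.default_rng(4)
        V = rng.poisson(5.0, (96, 8)).astype(float) + 0.1
        run = nmf_factorize(V, 2, seed=0)
        np.testing.assert_allclose(run.W.sum(axis=0), 1.0, atol=1e-8)
        assert (run.W >= 0).all() and (run.H >= 0).all()

    def test_recovers_well_separated_signatures(self, study_matrix):
        V, truth = study_matrix
        best = min(
            (nmf_factorize(V, 3, seed=s) for s in range(5)), key=lambda r: r.objective
        )
        S = truth.true_signatures
        used = set()
        for j in range(3):
            cosines = [
                (_cosine(S[:, j], best.W[:, i]), i) for i in range(3) if i not in used
            ]
            c, i = max(cosines)
            used.add(i)
            assert c > 0.95

    def test_objective_monotone_in_iterations(self):
        rng = np.random.default_rng(9)
        V = rng.poisson(4.0, (96, 6)).astype(float) + 0.1
        objs = [
            nmf_factorize(V, 2, seed=5, max_iter=n, tol=0.0).objective
            for n in (10, 20, 40, 80, 160)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_permutation_invariance_with_shared_init(self):
        rng = np.random.default_rng(6)
        V = rng.poisson(5.0, (96, 9)).astype(float) + 0.1
        W0 = rng.uniform(0.01, 1, (96, 3))
        H0 = rng.uniform(0.01, 1, (3, 9))
        perm = rng.permutation(9)
        base = nmf_factorize(V, 3, W0=W0, H0=H0)
        permuted = nmf_factorize(V[:, perm], 3, W0=W0, H0=H0[:, perm])
        np.testing.assert_allclose(permuted.W, base.W, atol=1e-8)
        np.testing.assert_allclose(permuted.H, base.H[:, perm], atol=1e-8)

    def test_scale_covariance(self):
        rng = np.random.default_rng(7)
        V = rng.poisson(5.0, (96, 7)).astype(float) + 0.1
        a = nmf_factorize(V, 2, seed=11)
        b = nmf_factorize(10.0 * V, 2, seed=11)
        np.testing.assert_allclose(a.W, b.W, rtol=1e-6, atol=1e-10)
        np.testing.assert_allclose(10.0 * a.H, b.H, rtol=1e-6, atol=1e-8)

    def test_input_validation(self):
        V = np.abs(np.random.default_rng(0).normal(size=(96, 4)))
        with pytest.raises(ValueError):
            nmf_factorize(V, 5)  # k > n
        V[:, 0] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            nmf_factorize(V, 2)
        with pytest.raises(ValueError):
            nmf_factorize(np.full((96, 3), np.nan), 1)

    def test_comparable_fit_to_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(13)
        S = make_true_signatures(1)
        H = rng.uniform(0, 50, (3, 15))
        V = rng.poisson(S @ H).astype(float) + 1e-3
        mine = min(
            (nmf_factorize(V, 3, seed=s, max_iter=1000, tol=1e-9) for s in range(3)),
            key=lambda r: r.objective,
        )
        best_sk = np.inf
        for s in range(3):
            sk = sklearn.NMF(
                n_components=3, solver="mu", beta_loss="kullback-leibler",
                init="random", random_state=s, max_iter=1000, tol=1e-9,
            )
            Wsk = sk.fit_transform(V)
            from sigstrat.denovo_signatures import _kl_divergence

            best_sk = min(best_sk, _kl_divergence(V, Wsk @ sk.components_ + 1e-12))
        assert mine.objective <= best_sk * 1.05 + 1.0


class TestExplainedVariance:
    def test_perfect_reconstruction_is_100(self):
        V = np.random.default_rng(0).uniform(1, 3, (96, 4))
        assert explained_variance(V, V, np.eye(4)) == pytest.approx(100.0)

    def test_zero_reconstruction_is_0(self):
        V = np.ones((96, 4))
        assert explained_variance(V, np.zeros((96, 2)), np.zeros((2, 4))) == 0.0

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(8)
        V = rng.uniform(0, 5, (96, 6))
        W = rng.uniform(0, 1, (96, 2))
        H = rng.uniform(0, 3, (2, 6))
        direct = 100.0 * (1.0 - ((V - W @ H) ** 2).sum() / (V**2).sum())
        assert explained_variance(V, W, H) == pytest.approx(max(min(direct, 100.0), 0.0))

    def test_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            explained_variance(np.zeros((96, 3)), np.zeros((96, 1)), np.zeros((1, 3)))


class TestRankSelection:
    def test_three_signature_cohort_selects_rank_three(self, study_matrix):
        V, _ = study_matrix
        sel = select_rank(V, n_restarts=30, seed=2)
        assert sel.chosen_rank == 3
        assert sel.cophenetic[3] > 0.95

    def test_single_signature_cohort_is_unstable_above_rank_one(self):
        rng = np.random.default_rng(1)
        sig = make_true_signatures(2)[:, 0]
        V = np.column_stack([rng.multinomial(200, sig) for _ in range(30)]).astype(float)
        with pytest.warns(UserWarning, match="no rank >= 2"):
            sel = select_rank(V, n_restarts=30, seed=3)
        assert sel.chosen_rank == 1
        assert all(sel.cophenetic[k] <= 0.95 for k in (2, 3, 4))

    def test_restart_floor_enforced(self):
        with pytest.raises(ValueError):
            select_rank(np.ones((96, 5)), n_restarts=5)


class TestReferenceMatching:
    def test_exact_members_match_with_cosine_one(self, reference_set):
        W = reference_set.matrix[:, :2]
        matches = match_to_reference(W, reference_set)
        assert [(m[1], round(m[2], 6)) for m in matches] == [
            (reference_set.names[0], 1.0),
            (reference_set.names[1], 1.0),
        ]

    def test_orthogonal_signatures_unmatched(self):
        refs = ReferenceSignatureSet(
            names=["only_first_half"],
            matrix=np.concatenate([np.full((48, 1), 1 / 48), np.zeros((48, 1))]),
        )
        W = np.concatenate([np.zeros((48, 1)), np.full((48, 1), 1 / 48)])
        ((_, name, cosine),) = match_to_reference(W, refs)
        assert name is None and cosine == pytest.approx(0.0)

    def test_perturbed_references_still_match(self, reference_set):
        rng = np.random.default_rng(5)
        W = reference_set.matrix.copy()
        W = W * (1 + 0.05 * rng.uniform(-1, 1, W.shape))
        W = np.abs(W) / np.abs(W).sum(axis=0)
        matches = match_to_reference(W, reference_set)
        assert [m[1] for m in matches] == reference_set.names
        assert all(m[2] > 0.98 for m in matches)


class TestModelSurface:
    def test_fit_returns_results_with_statistics(self, study_matrix):
        V, _ = study_matrix
        model = MutationalSignatureModel(V)
        res = model.fit(rank=3, seed=1, n_restarts=2)
        assert isinstance(res, SignatureResults)
        assert res.signatures_frame().shape == (96, 3)
        assert res.exposures_frame().shape == (3, V.shape[1])
        summary = res.summary()
        assert summary.attrs["rank"] == 3
        assert 0 <= summary.attrs["explained_variance"] <= 100
        np.testing.assert_allclose(summary["exposure_fraction"].sum(), 1.0)

    def test_rank_selection_summary_table(self, study_matrix):
        V, _ = study_matrix
        sel = MutationalSignatureModel(V).select_rank(rank_range=(1, 3), n_restarts=15, seed=0)
        df = sel.summary()
        assert list(df["rank"]) == [1, 2, 3]
        assert df["chosen"].sum() == 1
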