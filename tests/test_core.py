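"""The MCIA solver: weights, first axis, deflation, full sequential run."""

import numpy as np
import pytest

from mcia import (
    MciaConfig,
    compute_table_weights,
    deflate,
    generate_bundle,
    nsc_triplet,
    run_mcia,
    solve_first_axis,
)
from mcia.errors import RankError

from conftest import (
    criterion_value,
    dominant_eigpair_oracle,
    identity_triplet,
    pooled_operator,
    random_triplets,
)


def renamed(t, name):
    from dataclasses import replace
    return replace(t, name=name, X=t.X.copy())


class TestTableWeights:
    def test_uniform_is_all_ones(self, rng):
        tables = random_triplets(rng, 6, [5, 7, 9])
        np.testing.assert_array_equal(compute_table_weights(tables, "uniform"), [1, 1, 1])

    def test_identical_tables_get_equal_inverse_weights(self, rng):
        tables = random_triplets(rng, 6, [8])
        pair = [tables[0], renamed(tables[0], "T2")]
        w = compute_table_weights(pair, "inverse_first_eigenvalue")
        assert w[0] == pytest.approx(w[1], rel=1e-12)

    def test_inverse_weight_scales_as_inverse_square_of_table_scale(self, rng):
        t = random_triplets(rng, 6, [8])[0]
        from dataclasses import replace
        alpha = 2.5
        scaled = replace(t, X=alpha * t.X)
        w = compute_table_weights([t], "inverse_first_eigenvalue")[0]
        w_scaled = compute_table_weights([scaled], "inverse_first_eigenvalue")[0]
        assert w_scaled == pytest.approx(w / alpha**2, rel=1e-10)


class TestFirstAxis:
    def test_single_table_identity_metrics_reduces_to_svd(self, rng):
        X = rng.normal(size=(7, 5))
        X -= X.mean(axis=0)
        t = identity_triplet(X)
        v, us, lam = solve_first_axis([t])
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        assert lam == pytest.approx(s[0] ** 2, rel=1e-10)
        np.testing.assert_allclose(np.abs(v), np.abs(U[:, 0]), atol=1e-8)

    def test_duplicated_table_doubles_lambda_keeps_axis(self, rng):
        tables = random_triplets(rng, 6, [10])
        v1, _, lam1 = solve_first_axis(tables)
        pair = [tables[0], renamed(tables[0], "T2")]
        v2, _, lam2 = solve_first_axis(pair)
        assert lam2 == pytest.approx(2 * lam1, rel=1e-10)
        np.testing.assert_allclose(v2, v1, atol=1e-8)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_dense_eigendecomposition_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        tables = random_triplets(rng, 6, [4, 6, 5])
        weights = rng.uniform(0.5, 2.0, size=3)
        v, us, lam = solve_first_axis(tables, weights)
        S = pooled_operator(tables, weights)
        v_o, lam_o = dominant_eigpair_oracle(S, tables[0].D_diag)
        assert lam == pytest.approx(lam_o, rel=1e-8)
        np.testing.assert_allclose(v, v_o, atol=1e-8)

    def test_auxiliary_axes_are_q_normalized_covariance_directions(self, rng):
        tables = random_triplets(rng, 8, [6, 9])
        v, us, lam = solve_first_axis(tables)
        d = tables[0].D_diag
        for t, u in zip(tables, us):
            assert u @ (t.Q_diag * u) == pytest.approx(1.0, abs=1e-10)
            a = t.X.T @ (d * v)
            np.testing.assert_allclose(u, a / np.sqrt(a @ (t.Q_diag * a)), atol=1e-10)

    def test_sign_rule_largest_entry_positive(self, rng):
        tables = random_triplets(rng, 7, [5, 5])
        v, _, _ = solve_first_axis(tables)
        assert v[np.argmax(np.abs(v))] > 0

    def test_zero_operator_errors(self):
        t = identity_triplet(np.zeros((4, 3)))
        with pytest.raises(RankError):
            solve_first_axis([t])


class TestDeflate:
    def test_score_direction_annihilated(self, rng):
        tables = random_triplets(rng, 6, [8, 12])
        v, us, _ = solve_first_axis(tables)
        out = deflate(tables, us)
        for t, u in zip(out, us):
            assert np.linalg.norm(t.X @ (t.Q_diag * u)) < 1e-10

    def test_idempotent(self, rng):
        tables = random_triplets(rng, 6, [8])
        v, us, _ = solve_first_axis(tables)
        once = deflate(tables, us)
        twice = deflate(once, us)
        np.testing.assert_allclose(once[0].X, twice[0].X, atol=1e-14)

    def test_rank_drops_by_exactly_one(self, rng):
        tables = random_triplets(rng, 7, [12])
        v, us, _ = solve_first_axis(tables)
        before = np.linalg.matrix_rank(tables[0].X, tol=1e-9)
        after = np.linalg.matrix_rank(deflate(tables, us)[0].X, tol=1e-9)
        assert before - after == 1


class TestRunMcia:
    def test_orthonormality_constraints(self, rng):
        tables = random_triplets(rng, 8, [10, 14, 12])
        res = run_mcia(tables, MciaConfig(n_axes=5))
        d = res.D_diag
        V = res.synthetic_scores
        gram = V.T @ (d[:, None] * V)
        np.testing.assert_allclose(np.diag(gram), 1.0, atol=1e-10)
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
        for t in tables:
            U = res.aux_axes[t.name]
            gu = U.T @ (t.Q_diag[:, None] * U)
            np.testing.assert_allclose(np.diag(gu), 1.0, atol=1e-10)
            np.testing.assert_allclose(gu - np.diag(np.diag(gu)), 0.0, atol=1e-8)

    def test_eigenvalues_nonincreasing_and_conserved(self, rng):
        tables = random_triplets(rng, 9, [7, 11])
        res = run_mcia(tables, MciaConfig(n_axes=6))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        np.testing.assert_allclose(
            res.pseudo_eigenvalues.sum(axis=0), res.eigenvalues, atol=1e-8
        )

    def test_rank_bound_enforced(self, rng):
        tables = random_triplets(rng, 5, [8])
        with pytest.raises(RankError, match="rank"):
            run_mcia(tables, MciaConfig(n_axes=5))

    def test_default_axis_count(self, rng):
        tables = random_triplets(rng, 6, [9])
        assert run_mcia(tables).n_axes == 5
        tables = random_triplets(rng, 14, [20])
        assert run_mcia(tables).n_axes == 10

    def test_single_table_identity_metrics_reproduces_svd_ordination(self, rng):
        X = rng.normal(size=(8, 6))
        X -= X.mean(axis=0)
        res = run_mcia([identity_triplet(X)], MciaConfig(n_axes=4))
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        scores = res.synthetic_scores * np.sqrt(res.eigenvalues)[None, :]
        svd_scores = U[:, :4] * s[:4][None, :]
        for h in range(4):
            diff = min(
                np.abs(scores[:, h] - svd_scores[:, h]).max(),
                np.abs(scores[:, h] + svd_scores[:, h]).max(),
            )
            assert diff < 1e-8

    def test_criterion_beats_random_candidates(self):
        rng = np.random.default_rng(7)
        tables = random_triplets(rng, 6, [5, 8, 7])
        v, us, lam = solve_first_axis(tables)
        weights = np.ones(3)
        best = criterion_value(tables, weights, v)
        assert best == pytest.approx(lam, rel=1e-10)
        d = tables[0].D_diag
        for _ in range(1000):
            cand = rng.normal(size=len(d))
            cand = cand / np.sqrt(cand @ (d * cand))
            assert criterion_value(tables, weights, cand) <= best + 1e-12

    def test_two_table_first_eigenvalue_matches_coinertia_oracle(self, rng):
        tables = random_triplets(rng, 6, [9, 7])
        res = run_mcia(tables, MciaConfig(n_axes=2))
        S = pooled_operator(tables, [1.0, 1.0])
        _, lam_o = dominant_eigpair_oracle(S, tables[0].D_diag)
        assert res.eigenvalues[0] == pytest.approx(lam_o, rel=1e-8)
        d = tables[0].D_diag
        cross = res.table_scores["T1"][:, 0] @ (d * res.table_scores["T2"][:, 0])
        # co-structured inputs: NSC profiles of the same random scheme stay
        # positively covariant on the first axis
        assert np.isfinite(cross)

    def test_determinism_bit_identical(self, rng):
        tables = random_triplets(rng, 7, [10, 12])
        r1 = run_mcia(tables, MciaConfig(n_axes=4))
        r2 = run_mcia(tables, MciaConfig(n_axes=4))
        assert np.array_equal(r1.synthetic_scores, r2.synthetic_scores)
        assert np.array_equal(r1.eigenvalues, r2.eigenvalues)
        for name in r1.table_names:
            assert np.array_equal(r1.table_scores[name], r2.table_scores[name])

    def test_sample_permutation_equivariance(self, rng):
        from dataclasses import replace
        tables = random_triplets(rng, 8, [9, 11])
        res = run_mcia(tables, MciaConfig(n_axes=3))
        perm = rng.permutation(8)
        permuted = [
            replace(
                t,
                X=t.X[perm],
                row_weights=t.row_weights[perm],
                D_diag=t.D_diag[perm],
                sample_ids=[t.sample_ids[i] for i in perm],
            )
            for t in tables
        ]
        res_p = run_mcia(permuted, MciaConfig(n_axes=3))
        np.testing.assert_allclose(res_p.eigenvalues, res.eigenvalues, atol=1e-10)
        for h in range(3):
            a, b = res.synthetic_scores[perm, h], res_p.synthetic_scores[:, h]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_planted_clusters_separate_on_first_two_axes(self):
        bundle = generate_bundle()  # default spec, seed 1
        tables = [nsc_triplet(t) for t in bundle.tables]
        res = run_mcia(tables, MciaConfig(n_axes=2))
        Z = res.synthetic_scores
        labels = bundle.cluster_labels
        centroids = np.stack([Z[labels == c].mean(axis=0) for c in range(3)])
        within = np.mean([
            np.linalg.norm(Z[labels == c] - centroids[c], axis=1).mean() for c in range(3)
        ])
        for a in range(3):
            for b in range(a + 1, 3):
                assert np.linalg.norm(centroids[a] - centroids[b]) > 4 * within
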