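import numpy as np
import pytest

import drugrepo as dr
from drugrepo.pmf import PMFConfig, sample_negative_pairs


def matrix_from_pairs(n, m, pairs):
    return dr.InteractionMatrix(
        drugs=[f"d{i}" for i in range(n)],
        targets=[f"t{j}" for j in range(m)],
        observed=set(pairs),
    )


def als_oracle(R_dense, mask, d, reg, n_sweeps=200):
    """Alternating ridge regressions on the masked entries, run to
    convergence: an independent route to the same objective."""
    rng = np.random.default_rng(99)
    n, m = R_dense.shape
    U = rng.normal(0, 0.1, (n, d))
    V = rng.normal(0, 0.1, (m, d))
    for _ in range(n_sweeps):
        for i in range(n):
            js = np.nonzero(mask[i])[0]
            A = V[js].T @ V[js] + reg * np.eye(d)
            U[i] = np.linalg.solve(A, V[js].T @ R_dense[i, js])
        for j in range(m):
            iis = np.nonzero(mask[:, j])[0]
            A = U[iis].T @ U[iis] + reg * np.eye(d)
            V[j] = np.linalg.solve(A, U[iis].T @ R_dense[iis, j])
    return U, V


class TestPMFFit:
    def test_zero_positive_regularized_shrinks_to_zero(self):
        # a matrix must have >=1 observed pair, so use one positive but
        # dominate the loss with heavy regularization: scores collapse
        R = matrix_from_pairs(4, 4, [(0, 0)])
        cfg = PMFConfig(latent_dim=2, reg_u=50.0, reg_v=50.0, learn_rate=0.005,
                        max_iter=400, tol=0.0, seed=1)
        f = dr.pmf_fit(R, cfg)
        assert np.abs(dr.predict_scores(f)).max() < 1e-3

    def test_planted_rank1_matches_als_oracle(self):
        # exact rank-1 binary block: R = outer(u, v) with 0/1 u, v
        u = np.array([1, 1, 1, 1, 1, 0, 0, 0])
        v = np.array([1, 1, 1, 1, 0, 0])
        S = np.outer(u, v)
        pairs = [(i, j) for i in range(8) for j in range(6) if S[i, j] == 1]
        R = matrix_from_pairs(8, 6, pairs)
        cfg = PMFConfig(latent_dim=1, reg_u=1e-3, reg_v=1e-3, learn_rate=0.02,
                        max_iter=4000, tol=1e-12, seed=3, neg_ratio=1.0)
        f = dr.pmf_fit(R, cfg)
        scores = dr.predict_scores(f)
        rmse = np.sqrt(np.mean([(1.0 - scores[i, j]) ** 2 for i, j in pairs]))
        assert rmse <= 0.05
        # independent ALS oracle on the same supervision
        mask = np.zeros((8, 6), bool)
        dense = np.zeros((8, 6))
        for i, j in pairs:
            mask[i, j] = True
            dense[i, j] = 1.0
        neg = sample_negative_pairs((8, 6), set(pairs), len(pairs), np.random.default_rng(7))
        for i, j in neg:
            mask[i, j] = True
        Uo, Vo = als_oracle(dense, mask, 1, 1e-3)
        rmse_oracle = np.sqrt(np.mean([(1.0 - (Uo @ Vo.T)[i, j]) ** 2 for i, j in pairs]))
        assert abs(rmse - rmse_oracle) < 0.05

    def test_same_seed_bit_identical(self, planted_dti):
        cfg = PMFConfig(max_iter=30, seed=42)
        f1 = dr.pmf_fit(planted_dti.R, cfg)
        f2 = dr.pmf_fit(planted_dti.R, cfg)
        assert np.array_equal(f1.U, f2.U)
        assert np.array_equal(f1.V, f2.V)
        assert f1.final_objective == f2.final_objective

    def test_objective_finite_and_factors_finite(self, planted_dti):
        f = dr.pmf_fit(planted_dti.R, PMFConfig(max_iter=50, seed=0))
        assert np.isfinite(f.final_objective)

    def test_objective_monotone_under_small_steps(self):
        # track the objective across iteration budgets: non-increasing
        R = matrix_from_pairs(6, 5, [(0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (5, 1)])
        objs = [
            dr.pmf_fit(R, PMFConfig(latent_dim=3, learn_rate=1e-3, max_iter=k,
                                    tol=0.0, seed=2)).final_objective
            for k in (1, 5, 20, 80, 200)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_row_permutation_invariance(self, planted_dti):
        """Permuting drug rows and un-permuting U recovers identical scores."""
        R = planted_dti.R
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(R.drugs))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        R_perm = dr.InteractionMatrix(
            drugs=[R.drugs[p] for p in perm],
            targets=list(R.targets),
            observed={(int(inv[i]), j) for i, j in R.observed},
        )
        cfg = PMFConfig(max_iter=40, seed=9)
        s = dr.predict_scores(dr.pmf_fit(R, cfg))
        s_perm = dr.predict_scores(dr.pmf_fit(R_perm, cfg))
        for row, drug in enumerate(R_perm.drugs):
            np.testing.assert_array_equal(s_perm[row], s[R.drug_index(drug)])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PMFConfig(latent_dim=0)
        with pytest.raises(ValueError):
            PMFConfig(max_iter=0)
        with pytest.raises(ValueError):
            PMFConfig(learn_rate=-1.0)


class TestPredictScores:
    def test_zero_factors_zero_scores(self):
        f = dr.LatentFactors(U=np.zeros((3, 2)), V=np.zeros((4, 2)),
                             config=PMFConfig(latent_dim=2), final_objective=0.0)
        assert not dr.predict_scores(f).any()

    def test_dot_product_identity(self):
        f = dr.LatentFactors(U=np.full((1, 1), 2.0), V=np.full((1, 1), 3.0),
                             config=PMFConfig(latent_dim=1), final_objective=0.0)
        assert dr.predict_scores(f)[0, 0] == 6.0

    def test_heldout_positives_outscore_negatives(self, planted_dti):
        f = dr.pmf_fit(planted_dti.R, PMFConfig(seed=4))
        s = dr.predict_scores(f)
        pos = np.mean([s[i, j] for i, j in planted_dti.hidden_positives])
        neg = np.mean([s[i, j] for i, j in planted_dti.eval_negatives])
        assert pos > neg


class TestRankCandidates:
    def setup_method(self):
        self.R = matrix_from_pairs(3, 1, [(0, 0)])

    def test_k_zero_empty(self):
        s = np.array([[0.9], [0.9], [0.1]])
        assert dr.rank_candidates(s, self.R, "t0", 0) == []

    def test_tie_break_by_drug_id(self):
        s = np.array([[0.1], [0.9], [0.9]])
        out = dr.rank_candidates(s, self.R, "t0", 2)
        assert out == ["d1", "d2"]

    def test_exclusion_of_known_binders(self):
        s = np.array([[9.9], [0.5], [0.4]])
        out = dr.rank_candidates(s, self.R, "t0", 3, exclude={"d0"})
        assert out == ["d1", "d2"]

    def test_unknown_target_errors(self):
        with pytest.raises(KeyError):
            dr.rank_candidates(np.zeros((3, 1)), self.R, "nope", 1)

    def test_hidden_strong_association_rank1(self):
        # block structure: drugs d00-d09 bind t0-t4, d10-d29 bind t5-t9;
        # d00's (d00, t0) edge is withheld -> it must resurface at rank 1
        pairs = [(i, j) for i in range(10) for j in range(5)]
        pairs += [(i, j) for i in range(10, 30) for j in range(5, 10)]
        pairs.remove((0, 0))
        R = matrix_from_pairs(30, 10, pairs)
        s = dr.predict_scores(dr.pmf_fit(R, PMFConfig(latent_dim=4, seed=1)))
        known = R.known_drugs_for("t0")
        ranked = dr.rank_candidates(s, R, "t0", 3, exclude=known)
        col_order = sorted(
            (d for d in R.drugs if d not in known),
            key=lambda d: (-s[R.drug_index(d), 0], d),
        )
        assert ranked == col_order[:3]
        assert ranked[0] == "d0"


class TestHeldoutAUC:
    def scores_for(self, ps, ns):
        n = len(ps) + len(ns)
        s = np.array(ps + ns).reshape(n, 1)
        pos = [(i, 0) for i in range(len(ps))]
        neg = [(len(ps) + i, 0) for i in range(len(ns))]
        return s, pos, neg

    def test_perfect_separation(self):
        s, p, n = self.scores_for([1.0, 1.0], [0.0, 0.0])
        assert dr.heldout_auc(s, p, n) == 1.0

    def test_all_ties_half(self):
        s, p, n = self.scores_for([0.5, 0.5], [0.5])
        assert dr.heldout_auc(s, p, n) == 0.5

    def test_enumerated_example(self):
        s, p, n = self.scores_for([0.8, 0.3], [0.5, 0.1])
        assert dr.heldout_auc(s, p, n) == 0.75

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        ps = rng.normal(size=13)
        ns = rng.normal(size=17)
        # duplicate a value to exercise the tie convention
        ns[0] = ps[0]
        s, p, n = self.scores_for(list(ps), list(ns))
        wins = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in ps for b in ns
        )
        assert dr.heldout_auc(s, p, n) == pytest.approx(wins / (13 * 17), abs=1e-15)

    def test_empty_hidden_set_errors(self):
        with pytest.raises(ValueError):
            dr.heldout_auc(np.zeros((2, 2)), [], [(0, 0)])


class TestLatentFactorsIO:
    def test_save_load_roundtrip_exact(self, tmp_path, planted_dti):
        f = dr.pmf_fit(planted_dti.R, PMFConfig(max_iter=20, seed=8))
        p = tmp_path / "factors.tsv"
        f.save(p)
        g = dr.LatentFactors.load(p)
        assert np.array_equal(f.U, g.U)
        assert np.array_equal(f.V, g.V)
        assert g.config == f.config
        assert g.final_objective == f.final_objective


class TestNegativeSampling:
    def test_excludes_observed_and_distinct(self, rng):
        obs = {(0, 0), (1, 1)}
        neg = sample_negative_pairs((3, 3), obs, 5, rng)
        assert len(neg) == len(set(neg)) == 5
        assert not (set(neg) & obs)

    def test_oversampling_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_negative_pairs((2, 2), {(0, 0)}, 4, rng)
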