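import numpy as np
import pandas as pd
import pytest
from scipy import stats

from painet.network_inference import (
    default_penalty_grid,
    extract_network,
    fit_lfdr,
    partial_correlations,
    ridge_precision,
    select_penalty,
    sparsify,
    spearman_pairwise,
)
from painet.synthetic import SyntheticSpec, generate_dyads, sample_precision


def sample_null_correlations(rng, k, size):
    """Draw from the null density of a sample correlation at k df:
    (1+r)/2 ~ Beta((k-1)/2, (k-1)/2)."""
    return 2 * rng.beta((k - 1) / 2, (k - 1) / 2, size) - 1


class TestSpearmanPairwise:
    def test_complete_data_reduces_to_plain_spearman(self, matrix_factory):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 5, (50, 4)).astype(float)
        m = matrix_factory(vals.tolist())
        corr = spearman_pairwise(m).r.to_numpy()
        expected = stats.spearmanr(vals).statistic
        np.testing.assert_allclose(corr, expected, atol=1e-12)

    def test_matches_per_pair_brute_force_under_missingness(self, matrix_factory):
        rng = np.random.default_rng(1)
        vals = rng.integers(1, 5, (80, 4)).astype(float)
        vals[rng.random(vals.shape) < 0.25] = np.nan
        m = matrix_factory(
            [[None if np.isnan(v) else v for v in row] for row in vals]
        )
        out = spearman_pairwise(m)
        for i in range(4):
            for j in range(i + 1, 4):
                both = ~(np.isnan(vals[:, i]) | np.isnan(vals[:, j]))
                expected = stats.spearmanr(vals[both, i], vals[both, j]).statistic
                assert out.r.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_pairwise_matrix_can_be_indefinite(self, matrix_factory):
        # crafted missingness: pairwise correlations mutually inconsistent
        a = [1, 2, 3, 4, 1, 2, 3, 4]
        rows = []
        for idx, v in enumerate(a):
            # item pairs observed on disjoint subject blocks
            if idx < 4:
                rows.append([v, v, None, 5 - v])
            else:
                rows.append([v, None, 5 - v, v])
        extra = [[1, 1, 1, None], [4, 4, 4, None], [2, None, 4, 2], [3, None, 2, 3]]
        m = matrix_factory(rows + extra)
        r = spearman_pairwise(m).r.to_numpy()
        assert np.linalg.eigvalsh(r).min() < -1e-8

    def test_all_missing_item_is_an_error(self, matrix_factory):
        m = matrix_factory([[1, None], [2, None], [3, None]])
        with pytest.raises(ValueError, match="IT2"):
            spearman_pairwise(m)


class TestRidgePrecision:
    def test_identity_input_with_identity_target_is_fixed_point(self):
        for lam in (1e-3, 0.5, 10.0):
            est = ridge_precision(np.eye(5), lam, target=np.eye(5))
            np.testing.assert_allclose(est.omega, np.eye(5), atol=1e-10)

    def test_small_penalty_limit_matches_matrix_inverse(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        est = ridge_precision(r, 1e-8, target=np.zeros((2, 2)))
        expected = np.array([[4 / 3, -2 / 3], [-2 / 3, 4 / 3]])
        np.testing.assert_allclose(est.omega, expected, atol=1e-4)

    def test_estimating_equation_residual_on_random_instances(self):
        rng = np.random.default_rng(2)
        worst = 0.0
        for _ in range(100):
            p = int(rng.integers(3, 10))
            r = rng.standard_normal((p, p))
            r = (r + r.T) / 2
            lam = float(rng.uniform(0.05, 2.0))
            est = ridge_precision(r, lam)
            resid = np.linalg.inv(est.omega) - r - lam * (est.omega - est.target)
            worst = max(worst, float(np.linalg.norm(resid)))
            assert np.linalg.eigvalsh(est.omega)[0] > 0
        assert worst < 1e-8

    def test_indefinite_input_still_yields_positive_definite(self):
        r = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        assert np.linalg.eigvalsh(r).min() < 0
        est = ridge_precision(r, 0.5)
        assert np.linalg.eigvalsh(est.omega)[0] > 0

    def test_large_penalty_shrinks_toward_target_inverse(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((5, 5))
        r = a @ a.T / 5
        t = np.eye(5)
        dists = [
            np.linalg.norm(ridge_precision(r, lam, target=t).omega - t)
            for lam in (1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(d1 > d2 for d1, d2 in zip(dists, dists[1:]))

    def test_nonpositive_penalty_rejected(self):
        with pytest.raises(ValueError):
            ridge_precision(np.eye(3), 0.0)


class TestPenaltySelection:
    def test_identity_selects_first_grid_point(self):
        lam, path = select_penalty(np.eye(4), target=np.eye(4))
        assert lam == default_penalty_grid()[0]
        np.testing.assert_allclose(path["kappa"], 1.0, atol=1e-9)

    def test_two_digit_loss_accepted_at_boundary(self):
        # kappa = 100 <-> exactly 2 digits lost
        assert np.log10(100.0) == 2.0

    def test_selected_lambda_is_smallest_compliant_on_noisy_data(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((50, 20))
        r = np.corrcoef(z.T)
        grid = np.logspace(-6, 1, 60)
        lam, path = select_penalty(r, grid=grid, max_digits=2.0)
        below = path[path["lam"] < lam]
        assert (below["digits_lost"] > 2.0).all()
        sel = path[path["lam"] == lam].iloc[0]
        assert sel["digits_lost"] <= 2.0

    def test_unattainable_bound_reports_minimum(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((10, 20))
        r = np.corrcoef(z.T)  # rank-deficient
        with pytest.raises(ValueError, match="digits"):
            select_penalty(r, grid=np.logspace(-9, -8, 5), max_digits=2.0)


class TestPartialCorrelations:
    def test_diagonal_precision_has_no_edges(self):
        est = ridge_precision(np.eye(4), 0.1)
        assert (partial_correlations(est)["rho"] == 0).all()

    def test_two_by_two_definition(self):
        est = ridge_precision(np.eye(2), 0.1)
        object.__setattr__(est, "omega", np.array([[1.0, -0.5], [-0.5, 1.0]]))
        out = partial_correlations(est)
        assert out["rho"].iloc[0] == pytest.approx(0.5)

    def test_matches_regression_residual_oracle(self):
        # partial corr of (0,1) given rest == corr of residuals from
        # regressing each on the remaining variables
        rng = np.random.default_rng(6)
        z = rng.standard_normal((5000, 4))
        z[:, 1] += 0.5 * z[:, 0] + 0.3 * z[:, 2]
        sigma = np.cov(z.T)
        omega = np.linalg.inv(sigma)
        d = np.sqrt(np.diag(omega))
        rho01 = -omega[0, 1] / (d[0] * d[1])
        rest = z[:, 2:]
        proj = rest @ np.linalg.lstsq(rest, z[:, :2], rcond=None)[0]
        resid = z[:, :2] - proj
        expected = np.corrcoef(resid.T)[0, 1]
        assert rho01 == pytest.approx(expected, abs=1e-6)


class TestLfdr:
    def test_null_only_sample_recovers_eta0_near_one(self):
        rng = np.random.default_rng(7)
        vals = sample_null_correlations(rng, k=50, size=2000)
        fit = fit_lfdr(vals)
        assert fit.eta0 >= 0.95

    def test_mixture_recovers_null_proportion(self):
        rng = np.random.default_rng(8)
        nulls = sample_null_correlations(rng, k=100, size=1800)
        alts = rng.choice([-0.6, 0.6], size=200)
        fit = fit_lfdr(np.concatenate([nulls, alts]))
        assert fit.eta0 == pytest.approx(0.9, abs=0.05)

    def test_fit_invariant_to_sign_flip(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate(
            [sample_null_correlations(rng, k=80, size=500), [0.5, -0.4, 0.6]]
        )
        f1 = fit_lfdr(vals)
        f2 = fit_lfdr(-vals)
        assert f1.eta0 == pytest.approx(f2.eta0, abs=1e-4)
        assert f1.k_df == pytest.approx(f2.k_df, rel=1e-3)

    def test_posterior_monotone_in_absolute_value(self):
        rng = np.random.default_rng(10)
        vals = np.concatenate(
            [sample_null_correlations(rng, k=60, size=800),
             rng.choice([-0.5, 0.5], 80)]
        )
        fit = fit_lfdr(vals)
        grid = np.linspace(0, 0.95, 100)
        post = fit.posterior_present(grid)
        assert (np.diff(post) >= -1e-12).all()

    def test_degenerate_identical_values_flagged(self):
        fit = fit_lfdr(np.zeros(50))
        assert fit.degenerate and fit.eta0 == 1.0

    def test_mixture_density_integrates_to_one(self):
        rng = np.random.default_rng(11)
        fit = fit_lfdr(sample_null_correlations(rng, k=40, size=400))
        grid = np.linspace(-1 + 1e-9, 1 - 1e-9, 20001)
        area = np.trapezoid(fit.mixture_density(grid), grid)
        assert area == pytest.approx(1.0, abs=1e-3)


class TestSparsify:
    def _edges(self, rhos):
        return pd.DataFrame(
            {
                "item_i": [f"A{i}" for i in range(len(rhos))],
                "item_j": [f"B{i}" for i in range(len(rhos))],
                "rho": rhos,
            }
        )

    def test_degenerate_fit_retains_nothing(self):
        fit = fit_lfdr(np.zeros(50))
        out = sparsify(self._edges([0.1, 0.9]), fit)
        assert not out["retained"].any()

    def test_zero_retention_keeps_everything(self):
        rng = np.random.default_rng(12)
        fit = fit_lfdr(sample_null_correlations(rng, k=40, size=400))
        out = sparsify(self._edges([0.0, 0.2, 0.8]), fit, retention=0.0)
        assert out["retained"].all()

    def test_inclusive_threshold(self):
        rng = np.random.default_rng(13)
        vals = np.concatenate(
            [sample_null_correlations(rng, k=60, size=900),
             rng.choice([-0.5, 0.5], 100)]
        )
        fit = fit_lfdr(vals)
        edges = self._edges([0.3])
        post = fit.posterior_present(np.array([0.3]))[0]
        out = sparsify(edges, fit, retention=post)
        assert bool(out["retained"].iloc[0])


class TestEndToEnd:
    def test_permutation_equivariance(self, matrix_factory):
        truth = sample_precision(8, 0.25, 0.35, seed=20)
        spec = SyntheticSpec(p=8, n=400, missing_rate=0.0, seed=21)
        d = generate_dyads(truth, truth, spec, include_retest=False)
        m = d.get("child", "test")
        res = extract_network(m)
        perm = ["IT5", "IT2", "IT8", "IT1", "IT3", "IT7", "IT4", "IT6"]
        m2 = matrix_factory(
            m.data[perm].to_numpy().tolist(), items=perm
        )
        res2 = extract_network(m2)

        def edge_map(res):
            return {
                frozenset((r.item_i, r.item_j)): pytest.approx(r.rho, abs=1e-9)
                for r in res.edges.itertuples()
            }

        assert edge_map(res) == edge_map(res2)

    def test_recovery_on_one_generous_seed(self):
        truth = sample_precision(20, 0.1, 0.4, seed=1)
        spec = SyntheticSpec(p=20, n=1000, seed=1001, missing_rate=0.05)
        d = generate_dyads(truth, truth, spec, include_retest=False)
        res = extract_network(d.get("child", "test"))
        idx = {it: i for i, it in enumerate(d.catalog.item_ids)}
        found = {
            tuple(sorted((idx[r.item_i], idx[r.item_j])))
            for r in res.retained_edges.itertuples()
        }
        true = set(truth.edges)
        assert len(found & true) / len(true) >= 0.8
        assert len(found & true) / max(len(found), 1) >= 0.8
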