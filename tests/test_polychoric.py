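"""Polychoric estimation against independent oracles and its invariances."""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import ndtri

from sympmix.polychoric import (
    DegenerateItemError,
    ThresholdSet,
    average_offdiagonal,
    contingency_table,
    estimate_pair,
    nearest_pd,
    pair_log_likelihood,
    polychoric_matrix,
    rectangle_probabilities,
    thresholds_from_margins,
)
from sympmix.synthetic import GeneratorConfig, generate


def grid_search_rho(table, tau_i, tau_j, lo=-0.9995, hi=0.9995, step=2e-4):
    """Brute-force ML oracle: exhaustive scan of the likelihood over rho."""
    grid = np.arange(lo, hi + step / 2, step)
    lls = np.array([pair_log_likelihood(r, tau_i, tau_j, table) for r in grid])
    return float(grid[np.argmax(lls)])


def discretized_bivariate_table(rho, cutpoints, n, rng):
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    x = np.searchsorted(cutpoints, z[:, 0])
    y = np.searchsorted(cutpoints, z[:, 1])
    k = cutpoints.size + 1
    return contingency_table(x, y, k, k)


class TestThresholdsFromMargins:
    def test_median_split(self):
        assert thresholds_from_margins([500, 500]).tau == pytest.approx([0.0])

    def test_inverse_normal_of_cumulative_proportion(self):
        tau = thresholds_from_margins([159, 841]).tau
        assert tau == pytest.approx([ndtri(0.159)], abs=1e-10)
        assert tau[0] == pytest.approx(-0.9986, abs=5e-4)

    def test_normal_quartiles(self):
        tau = thresholds_from_margins([250, 250, 250, 250]).tau
        assert tau == pytest.approx([-0.6745, 0.0, 0.6745], abs=1e-4)

    def test_zero_count_category_collapsed(self):
        # empty middle category: same thresholds as the collapsed margin
        with_gap = thresholds_from_margins([300, 0, 700]).tau
        collapsed = thresholds_from_margins([300, 700]).tau
        assert with_gap == pytest.approx(collapsed)

    def test_degenerate_item_flagged(self):
        with pytest.raises(DegenerateItemError):
            thresholds_from_margins([0, 1000, 0])


class TestPairLogLikelihood:
    def test_cell_probabilities_sum_to_one(self):
        tau_i = ThresholdSet(np.array([-1.0, -0.2, 0.4, 1.1, 1.9]))
        tau_j = ThresholdSet(np.array([-0.5, 0.3, 1.5]))
        for rho in (-0.85, -0.3, 0.0, 0.45, 0.9):
            probs = rectangle_probabilities(rho, tau_i, tau_j)
            assert probs.sum() == pytest.approx(1.0, abs=1e-10)
            assert (probs >= 0).all()

    def test_independence_factorizes(self):
        tau_i = ThresholdSet(np.array([-0.7, 0.2]))
        tau_j = ThresholdSet(np.array([0.1, 0.8]))
        probs = rectangle_probabilities(0.0, tau_i, tau_j)
        from scipy.special import ndtr

        pi = np.diff(np.concatenate(([0], ndtr(tau_i.tau), [1])))
        pj = np.diff(np.concatenate(([0], ndtr(tau_j.tau), [1])))
        assert probs == pytest.approx(np.outer(pi, pj), abs=1e-12)

    def test_matches_adaptive_quadrature_oracle(self):
        rho = 0.3
        tau_i = ThresholdSet(np.array([-0.8, 0.5]))
        tau_j = ThresholdSet(np.array([-0.2, 0.9]))
        table = np.array([[30, 10, 5], [12, 25, 9], [4, 11, 20]], dtype=float)

        def density(y, x):
            det = 1.0 - rho**2
            return np.exp(-(x * x - 2 * rho * x * y + y * y) / (2 * det)) / (
                2 * np.pi * np.sqrt(det)
            )

        ai, cj = tau_i.extended, tau_j.extended
        ll = 0.0
        for r in range(3):
            for c in range(3):
                prob = integrate.dblquad(
                    density,
                    max(ai[r], -8),
                    min(ai[r + 1], 8),
                    lambda _: max(cj[c], -8),
                    lambda _: min(cj[c + 1], 8),
                    epsabs=1e-12,
                )[0]
                ll += table[r, c] * np.log(prob)
        assert pair_log_likelihood(rho, tau_i, tau_j, table) == pytest.approx(ll, abs=1e-6)


class TestEstimatePair:
    def test_independence_table_estimates_zero(self):
        row = np.array([200.0, 300.0, 500.0])
        col = np.array([400.0, 350.0, 250.0])
        table = np.outer(row, col) / row.sum()
        assert abs(estimate_pair(table)) < 1e-3

    def test_perfect_association_hits_boundary(self):
        table = np.array([[50.0, 0.0], [0.0, 50.0]])
        est = estimate_pair(table, full_output=True)
        assert est.boundary
        assert est.rho == pytest.approx(1.0, abs=1e-4)

    def test_recovers_true_rho_and_matches_grid_search(self):
        rng = np.random.default_rng(2024)
        cut = np.array([-1.0, -0.4, 0.1, 0.6, 1.2])
        table = discretized_bivariate_table(0.5, cut, 10_000, rng)
        rho_hat = estimate_pair(table)
        assert rho_hat == pytest.approx(0.5, abs=0.03)
        tau_i = thresholds_from_margins(table.sum(axis=1))
        tau_j = thresholds_from_margins(table.sum(axis=0))
        assert rho_hat == pytest.approx(grid_search_rho(table, tau_i, tau_j), abs=1e-3)

    @pytest.mark.parametrize("true_rho", [-0.8, -0.3, 0.0, 0.3, 0.8])
    def test_consistency_at_large_n(self, true_rho):
        rng = np.random.default_rng(int(abs(true_rho) * 100) + 7)
        cut = np.array([-0.9, -0.2, 0.5, 1.3])
        table = discretized_bivariate_table(true_rho, cut, 100_000, rng)
        assert estimate_pair(table) == pytest.approx(true_rho, abs=0.01)

    def test_invariant_to_monotone_category_relabeling(self):
        # merging/relabeling by a strictly increasing map only re-indexes
        # the table; the two-step estimate is unchanged
        rng = np.random.default_rng(5)
        cut = np.array([-0.5, 0.5])
        table = discretized_bivariate_table(0.4, cut, 5_000, rng)
        rho_orig = estimate_pair(table)
        padded = np.zeros((5, 5))
        padded[np.ix_([0, 2, 4], [0, 2, 4])] = table  # relabel 0,1,2 -> 0,2,4
        assert estimate_pair(padded) == pytest.approx(rho_orig, abs=1e-9)


class TestPolychoricMatrix:
    def test_single_factor_population_value(self, single_factor_data):
        rho = polychoric_matrix(single_factor_data).rho
        off = rho[np.triu_indices(12, k=1)]
        assert np.abs(off - 0.49).max() < 0.05  # n = 5,000

    def test_symmetry_exact(self, single_factor_data):
        rho = polychoric_matrix(single_factor_data).rho
        assert np.array_equal(rho, rho.T)

    def test_permuted_columns_destroy_association(self, single_factor_data):
        rng = np.random.default_rng(0)
        values = single_factor_data.values[:10_000].copy()
        for j in range(values.shape[1]):
            rng.shuffle(values[:, j])
        rho = polychoric_matrix(values).rho
        off = rho[np.triu_indices(12, k=1)]
        assert np.abs(off).mean() < 0.03

    def test_degenerate_items_dropped_with_warning(self):
        values = np.random.default_rng(1).integers(0, 4, size=(300, 4))
        values[:, 2] = 1  # constant item
        with pytest.warns(UserWarning, match="degenerate"):
            pm = polychoric_matrix(values)
        assert pm.rho.shape == (3, 3)
        assert pm.dropped_items == [2]


class TestNearestPd:
    def test_identity_unchanged(self):
        assert np.array_equal(nearest_pd(np.eye(5)), np.eye(5))

    def test_pd_input_returned_as_is(self):
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert np.abs(nearest_pd(R) - R).max() == 0.0

    def test_singular_input_repaired(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        fixed = nearest_pd(R)
        assert fixed[0, 1] < 1.0
        assert np.linalg.eigvalsh(fixed).min() > 0
        assert np.diag(fixed) == pytest.approx([1.0, 1.0])


class TestAverageOffdiagonal:
    @pytest.mark.parametrize(
        "matrix, expected",
        [
            (np.eye(4), 0.0),
            (np.full((3, 3), 0.5) + 0.5 * np.eye(3), 0.5),
            (
                np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]]),
                0.4,
            ),
        ],
    )
    def test_arithmetic(self, matrix, expected):
        assert average_offdiagonal(matrix) == pytest.approx(expected)
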