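"""WABA decomposition identities, the r-to-z comparison, nulls and ACE."""

import numpy as np
import pandas as pd
import pytest

from pleioscope.errors import ValidationError
from pleioscope.partition import (
    ace_max_correlation,
    compare_rB_rW,
    critical_z,
    partition_all,
    partition_pair,
    pseudo_strain_null,
    sign_adjust,
    zscore_rB_vs_rW,
)

from conftest import hierarchical_pair


class TestPartitionPair:
    def test_decomposition_identity_random_data(self, rng):
        for _ in range(50):
            J = rng.integers(3, 10)
            n = rng.integers(3, 15)
            x, y, groups = hierarchical_pair(rng, J=int(J), n_per=int(n),
                                             rho_w=rng.uniform(-0.8, 0.8),
                                             rho_b=rng.uniform(-0.8, 0.8))
            p = partition_pair(x, y, groups)
            lhs = (p.eta_b_x * p.eta_b_y * p.r_b
                   + p.eta_w_x * p.eta_w_y * p.r_w)
            assert abs(lhs - p.r_total) < 1e-10
            assert abs(p.eta_b_x**2 + p.eta_w_x**2 - 1) < 1e-10
            assert abs(p.eta_b_y**2 + p.eta_w_y**2 - 1) < 1e-10

    def test_rb_matches_weighted_group_mean_correlation(self, rng):
        x, y, groups = hierarchical_pair(rng, J=7, n_per=13)
        p = partition_pair(x, y, groups)
        # brute force: correlation of group means, weighted by group size
        mx = np.array([x[groups == j].mean() for j in range(7)])
        my = np.array([y[groups == j].mean() for j in range(7)])
        w = np.array([(groups == j).sum() for j in range(7)], dtype=float)
        mxc = mx - np.average(mx, weights=w)
        myc = my - np.average(my, weights=w)
        r_wtd = (np.sum(w * mxc * myc)
                 / np.sqrt(np.sum(w * mxc**2) * np.sum(w * myc**2)))
        assert p.r_b == pytest.approx(r_wtd, abs=1e-12)

    def test_identical_group_means_gives_zero_eta_b(self, rng):
        x, y, groups = hierarchical_pair(rng, J=5, n_per=20)
        # remove all between-group signal on both traits
        for j in range(5):
            x[groups == j] -= x[groups == j].mean()
            y[groups == j] -= y[groups == j].mean()
        p = partition_pair(x, y, groups)
        assert p.eta_b_x == pytest.approx(0.0, abs=1e-12)
        assert p.eta_b_y == pytest.approx(0.0, abs=1e-12)
        assert p.r_total == pytest.approx(p.r_w, abs=1e-10)

    def test_two_balanced_groups_have_unit_rb(self, rng):
        x = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10)])
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(-3, 1, 10)])
        groups = np.repeat([0, 1], 10)
        p = partition_pair(x, y, groups)
        assert abs(p.r_b) == pytest.approx(1.0, abs=1e-12)

    def test_single_group_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValidationError):
            partition_pair(x, x + 1, np.zeros(10, dtype=int))

    def test_zero_within_variance_rejected(self):
        groups = np.repeat([0, 1], 5)
        x = groups.astype(float)  # constant within each group
        y = np.arange(10, dtype=float)
        with pytest.raises(ValidationError, match="within-group"):
            partition_pair(x, y, groups, names=("flat", "y"))

    def test_rw_invariant_to_per_strain_constants(self, rng):
        x, y, groups = hierarchical_pair(rng, J=6, n_per=15)
        p0 = partition_pair(x, y, groups)
        shifts = rng.normal(0, 10, 6)
        p1 = partition_pair(x + shifts[groups], y, groups)
        assert p1.r_w == pytest.approx(p0.r_w, abs=1e-12)

    def test_rb_invariant_to_within_mean_zero_noise(self, rng):
        x, y, groups = hierarchical_pair(rng, J=6, n_per=15)
        p0 = partition_pair(x, y, groups)
        noise = rng.normal(0, 3, len(x))
        for j in range(6):
            noise[groups == j] -= noise[groups == j].mean()
        p1 = partition_pair(x + noise, y, groups)
        assert p1.r_b == pytest.approx(p0.r_b, abs=1e-12)


class TestCompare:
    def test_critical_z_at_printed_cutoff(self):
        # Bonferroni 0.01 over 5,645 pairs; printed as 4.63
        assert critical_z(0.01, 5645) == pytest.approx(4.63, abs=0.01)

    def test_equal_components_give_zero_z(self, rng):
        x, y, groups = hierarchical_pair(rng, J=8, n_per=20)
        p = partition_pair(x, y, groups)
        p.r_b = p.r_w = 0.4
        z, _, sig = compare_rB_rW(p)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert not sig

    def test_z_formula_worked_example(self):
        # r_B=0.5, r_W=0.1, J=374, N=300000 -> z ~ 8.64
        z = zscore_rB_vs_rW(0.5, 0.1, 374, 300_000)
        assert z == pytest.approx(8.64, abs=0.01)

    def test_sign_adjustment_penalizes_opposite_signs(self):
        rb, rw = sign_adjust(-0.5, 0.3)
        assert rb == -0.5 and rw == 0.3
        rb, rw = sign_adjust(-0.5, -0.3)
        assert rb == 0.5 and rw == 0.3

    def test_degenerate_unit_correlation_capped(self, rng):
        x, y, groups = hierarchical_pair(rng, J=8, n_per=20)
        p = partition_pair(x, y, groups)
        p.r_b, p.r_w = 1.0, 0.2
        z, _, _ = compare_rB_rW(p)
        assert np.isfinite(z)


class TestPartitionAll:
    def test_pair_counts_are_within_type_combinations(self, small_cross):
        _, _, _, cells, _ = small_cross
        part = partition_all(cells)
        assert len(part) == 10  # C(5,2) for the single simulated cell type
        assert set(part["cell_type"]) == {"large"}

    def test_types_with_single_trait_contribute_no_pairs(self, rng):
        df = pd.DataFrame({
            "strain": np.repeat(["a", "b", "c"], 30),
            "cell_type": "unbudded",
            "u001": rng.normal(size=90),
        })
        assert partition_all(df).empty

    def test_matches_partition_pair(self, small_cross):
        _, _, _, cells, _ = small_cross
        part = partition_all(cells).set_index(["trait_x", "trait_y"])
        p = partition_pair(cells["l001"].to_numpy(), cells["l003"].to_numpy(),
                           cells["strain"].to_numpy())
        row = part.loc[("l001", "l003")]
        assert row["r_w"] == pytest.approx(p.r_w, abs=1e-12)
        assert row["r_b"] == pytest.approx(p.r_b, abs=1e-12)
        assert row["eta_b_x"] == pytest.approx(p.eta_b_x, abs=1e-12)


class TestPseudoStrainNull:
    def test_group_size_multiset_preserved(self, small_cross):
        _, _, _, cells, _ = small_cross
        null = pseudo_strain_null(cells, seed=1)
        assert (null["n_strains"] == cells["strain"].nunique()).all()
        assert (null["n_cells"] == len(cells)).all()

    def test_fixed_seed_reproducible(self, small_cross):
        _, _, _, cells, _ = small_cross
        a = pseudo_strain_null(cells, seed=7)
        b = pseudo_strain_null(cells, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_null_z_scores_calibrated(self, small_cross):
        _, _, _, cells, _ = small_cross
        null = pseudo_strain_null(cells, seed=3, n_reps=5)
        # across permutations, z should be roughly standard normal
        assert abs(null["z"].mean()) < 0.6
        assert 0.5 < null["z"].std() < 2.0
        assert not null["significant"].any()


class TestAce:
    def test_identity_relation_is_maximal(self, rng):
        x = rng.normal(size=500)
        res = ace_max_correlation(x, x.copy())
        assert res.correlation >= 0.999

    def test_result_at_least_pearson(self, rng):
        x = rng.normal(size=2000)
        y = 0.6 * x + 0.8 * rng.normal(size=2000)
        res = ace_max_correlation(x, y)
        assert res.correlation >= abs(np.corrcoef(x, y)[0, 1]) - 0.02

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValidationError):
            ace_max_correlation(rng.normal(size=10), rng.normal(size=10))
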