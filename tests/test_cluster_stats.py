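"""Watershed-proxy clustering and association statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from olfcluster.cluster_stats import (
    ContingencyTable,
    associate,
    chi_square,
    cluster_landscape,
    contingency,
    rel_diff,
    spearman_by_group,
)


def _flat_grid(rows, cols, d=2):
    return np.zeros((rows, cols)), np.zeros((rows, cols, d))


class TestClusterLandscape:
    def test_flat_landscape_single_cluster(self):
        heights, weights = _flat_grid(4, 6)
        bmus = np.array([[0, 0], [1, 2], [3, 5]])
        a = cluster_landscape(heights, bmus, weights)
        assert a.k == 1
        assert np.array_equal(a.subject_labels, [1, 1, 1])

    def test_one_ridge_column_cannot_split_a_torus(self):
        """Flood fill by hand: a single high column wraps around, one basin."""
        heights, weights = _flat_grid(6, 8)
        heights[:, 3] = 10.0
        bmus = np.array([[0, 0], [0, 6]])
        a = cluster_landscape(heights, bmus, weights, threshold_quantile=0.5)
        assert a.k == 1

    def test_two_ridge_columns_make_two_clusters(self):
        """Two full high columns cut the torus into exactly two basins."""
        heights, weights = _flat_grid(6, 8)
        heights[:, 3] = 10.0
        heights[:, 7] = 10.0
        # make the two valleys distinct in weight space
        weights[:, 0:3] = 0.0
        weights[:, 4:7] = 5.0
        bmus = np.array([[0, 0], [0, 1], [0, 5], [2, 6], [1, 2]])
        a = cluster_landscape(heights, bmus, weights, threshold_quantile=0.5)
        assert a.k == 2
        labels = a.subject_labels
        assert labels[0] == labels[1] == labels[4]
        assert labels[2] == labels[3] != labels[0]
        # ids ordered by descending subject count
        assert np.sum(labels == 1) >= np.sum(labels == 2)

    def test_ridge_bmu_attached_to_nearest_valley(self):
        heights, weights = _flat_grid(6, 8)
        heights[:, 3] = 10.0
        heights[:, 7] = 10.0
        weights[:, 0:3] = 0.0
        weights[:, 4:7] = 5.0
        weights[:, 3] = 4.8  # ridge units near the second valley
        bmus = np.array([[0, 0], [0, 1], [0, 5], [0, 3]])
        a = cluster_landscape(heights, bmus, weights, threshold_quantile=0.5)
        assert a.subject_labels[3] == a.subject_labels[2]

    def test_small_basins_merged(self):
        heights, weights = _flat_grid(8, 10)
        heights[:] = 10.0
        heights[0:2, 0:2] = 0.0  # 4-unit basin, below min_basin_units
        heights[4:7, 4:8] = 0.0  # 12-unit basin
        weights[0:2, 0:2] = 1.0
        weights[4:7, 4:8] = 1.2
        bmus = np.array([[0, 0], [5, 5]])
        a = cluster_landscape(
            heights, bmus, weights, threshold_quantile=0.2, min_basin_units=5
        )
        assert a.k == 1

    def test_partition_invariant_under_toroidal_roll(self, rng):
        heights = rng.uniform(size=(7, 9))
        weights = rng.normal(size=(7, 9, 3))
        bmus = np.column_stack([rng.integers(0, 7, 30), rng.integers(0, 9, 30)])
        base = cluster_landscape(heights, bmus, weights).subject_labels
        for shift in [(2, 0), (0, 4), (3, 5)]:
            h2 = np.roll(heights, shift, axis=(0, 1))
            w2 = np.roll(weights, shift, axis=(0, 1))
            b2 = (bmus + shift) % (7, 9)
            rolled = cluster_landscape(h2, b2, w2).subject_labels
            # same partition up to label permutation
            from sklearn.metrics import adjusted_rand_score

            assert adjusted_rand_score(base, rolled) == 1.0


def _table(data, rows=None, cols=None):
    return ContingencyTable(observed=pd.DataFrame(data, index=rows, columns=cols))


class TestChiSquare:
    def test_two_by_two_closed_form(self):
        chi2, df, p = chi_square(_table([[10, 20], [20, 10]]))
        # n(ad - bc)^2 / (r1 r2 c1 c2) = 60 * 90000 / 810000
        assert chi2 == pytest.approx(6.667, abs=5e-4)
        assert df == 1

    def test_random_tables_match_closed_form(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 50, size=4)
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            chi2, df, _ = chi_square(_table([[a, b], [c, d]]))
            assert chi2 == pytest.approx(expected, abs=1e-9)

    def test_nine_by_three_has_df_16(self, rng):
        counts = rng.integers(5, 40, size=(9, 3))
        _, df, _ = chi_square(_table(counts))
        assert df == 16

    def test_null_table(self):
        # observed equals its own expected counts (independent margins)
        chi2, _, p = chi_square(_table([[10, 20], [20, 40]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            chi_square(_table([[0, 0], [5, 5]]))


class TestRelDiff:
    def test_worked_cells(self):
        # margins give expected [[10, 30],[10,30]]... use an explicit table
        t = _table([[10, 30], [10, 30]])
        assert np.allclose(rel_diff(t).to_numpy(), 0.0)

    def test_exp_10_obs_30_gives_minus_one(self):
        # construct margins so one cell has expected 10 but observed 30
        t = _table([[30, 10], [0, 20]])
        exp = t.expected.to_numpy()
        assert exp[0, 0] == pytest.approx(20.0)
        # direct formula on a synthetic pair instead: (10 - 30) / 20 = -1
        obs, expected = 30.0, 10.0
        assert (expected - obs) / (0.5 * (expected + obs)) == -1.0

    def test_zero_observed_is_extreme(self):
        t = _table([[0, 10], [10, 0]])
        rd = rel_diff(t)
        assert rd.iloc[0, 0] == pytest.approx(2.0)  # obs 0, exp 5
        assert np.all(rd.to_numpy() <= 2) and np.all(rd.to_numpy() >= -2)

    def test_sign_convention_flag_flips(self, rng):
        t = _table(rng.integers(1, 30, size=(4, 3)))
        assert np.allclose(
            rel_diff(t, "obs_minus_exp").to_numpy(), -rel_diff(t, "exp_minus_obs").to_numpy()
        )

    def test_antisymmetry_and_range(self, rng):
        """Swapping observed and expected flips the sign; range is [-2, 2]."""
        for _ in range(50):
            obs = rng.integers(0, 40, size=(3, 3)).astype(float)
            exp = rng.integers(0, 40, size=(3, 3)).astype(float)
            denom = 0.5 * (obs + exp)
            ok = denom > 0
            fwd = np.where(ok, (exp - obs) / np.where(ok, denom, 1), 0.0)
            rev = np.where(ok, (obs - exp) / np.where(ok, denom, 1), 0.0)
            assert np.allclose(fwd, -rev)
            assert np.all(np.abs(fwd) <= 2)


class TestContingency:
    def test_shape_and_margins(self, small_cohort, rng):
        clusters = rng.integers(1, 4, size=len(small_cohort))
        t = contingency(small_cohort, clusters)
        assert t.observed.shape == (9, 3)
        assert t.grand_total == len(small_cohort)
        assert np.array_equal(t.row_totals.to_numpy(), t.observed.sum(axis=1).to_numpy())
        assert abs(t.expected.to_numpy().sum() - t.grand_total) < 1e-9

    def test_excluding_healthy_drops_one_row(self, small_cohort, rng):
        clusters = rng.integers(1, 4, size=len(small_cohort))
        t = contingency(small_cohort, clusters, exclude=["Healthy"])
        assert t.observed.shape == (8, 3)
        assert "Healthy" not in t.observed.index

    def test_empty_after_exclusion_rejected(self):
        frame = pd.DataFrame({"etiology": ["Healthy", "Healthy"]})
        with pytest.raises(ValueError, match="empty"):
            contingency(frame, np.array([1, 2]), exclude=["Healthy"])


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,rho",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (3, 1, 2), -0.5),  # 1 - 6*(4+1+1)/(3*8) = -0.5
            ((1, 2, 3), (3, 2, 1), -1.0),
        ],
    )
    def test_worked_examples(self, x, y, rho):
        frame = pd.DataFrame({"thr": x, "disc": x, "ident": y})
        out = spearman_by_group(frame)
        row = out[(out["group"] == "all") & (out["pair"] == "thr/ident")]
        assert row["rho"].iloc[0] == pytest.approx(rho)

    def test_groups_below_minimum_omitted(self, caplog):
        frame = pd.DataFrame(
            {
                "thr": [1, 2, 3, 4, 5, 6],
                "disc": [1, 2, 3, 4, 5, 6],
                "ident": [2, 3, 1, 6, 5, 4],
                "etiology": ["A", "A", "A", "A", "B", "B"],
            }
        )
        with caplog.at_level("WARNING"):
            out = spearman_by_group(frame, grouping="etiology")
        assert set(out["group"]) == {"all", "A"}

    def test_matches_scipy_on_cohort(self, small_cohort):
        out = spearman_by_group(small_cohort)
        row = out[(out["group"] == "all") & (out["pair"] == "disc/ident")]
        ref, _ = spearmanr(small_cohort["disc"], small_cohort["ident"])
        assert row["rho"].iloc[0] == pytest.approx(ref)


def test_planted_association_is_detected(small_cohort, features):
    """Etiology-profile coupling yields a strongly significant chi-square."""
    from olfcluster.cluster_stats import cluster_landscape
    from olfcluster.esom import Esom

    X = features.to_numpy()
    som = Esom(rows=10, cols=15, epochs=10, random_state=4).fit(X)
    _, _, Us = som.landscape(X)
    a = cluster_landscape(Us, som.bmus(X), som.weights_)
    result = associate(small_cohort.loc[features.index], a.subject_labels)
    assert result.p < 1e-6
    assert result.df == (len(small_cohort["etiology"].unique()) - 1) * (a.k - 1)
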