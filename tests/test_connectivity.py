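"""Parcel/seed connectivity extraction, PCA reduction, session averaging."""

import numpy as np
import pandas as pd
import pytest

from adhdconn.connectivity import (
    average_sessions,
    pairwise_correlations,
    parcel_mean_timecourses,
    pca_reduce,
    seed_connectivity_vector,
)
from adhdconn.constants import PAIR_NAMES
from adhdconn.synthetic_data import Scan4D, make_brain_template, simulate_cohort, simulate_scan


@pytest.fixture(scope="module")
def scan_and_template(small_config_module=None):
    from adhdconn.synthetic_data import GeneratorConfig

    config = GeneratorConfig(
        n_subjects={"SiteA": {"TD": 1}},
        grid_dims=(14, 14, 8),
        parcel_size=(2, 2, 2),
        n_seeds=20,
        T=40,
        rng_seed=11,
    )
    template = make_brain_template(config)
    scan = simulate_scan(simulate_cohort(config)[0], template, config)
    return scan, template


class TestParcelMeans:
    def test_identical_voxel_series_pass_through(self, scan_and_template):
        scan, template = scan_and_template
        data = np.zeros_like(scan.data)
        series = np.sin(np.linspace(0, 6, scan.T))
        for code in range(1, 6):
            data[template.parcel_labels == code] = series * code
        modified = Scan4D(data, scan.tr, scan.mask, scan.motion_params)
        tcs = parcel_mean_timecourses(modified, template.parcel_labels)
        for j in range(5):
            assert np.allclose(tcs[:, j], series * (j + 1))

    def test_two_voxel_parcel_average(self):
        data = np.zeros((2, 1, 1, 5))
        a = np.arange(5.0)
        b = np.arange(5.0) * 3
        data[0, 0, 0] = a
        data[1, 0, 0] = b
        labels = np.ones((2, 1, 1), dtype=int)
        # remaining 4 parcels live on a padded grid
        data = np.pad(data, ((0, 8), (0, 0), (0, 0), (0, 0)))
        labels = np.pad(labels, ((0, 8), (0, 0), (0, 0)))
        for code in range(2, 6):
            labels[code * 2 - 2, 0, 0] = code
        scan = Scan4D(data, 1.0, labels > 0, np.zeros((5, 0)))
        tcs = parcel_mean_timecourses(scan, labels)
        assert np.allclose(tcs[:, 0], (a + b) / 2)

    def test_matches_bruteforce_loop(self, scan_and_template):
        scan, template = scan_and_template
        tcs = parcel_mean_timecourses(scan, template.parcel_labels)
        for code in range(1, 6):
            coords = np.argwhere(template.parcel_labels == code)
            for t in range(scan.T):
                manual = np.mean([scan.data[tuple(c) + (t,)] for c in coords])
                assert tcs[t, code - 1] == pytest.approx(manual, abs=1e-12)

    def test_empty_parcel_named_in_error(self, scan_and_template):
        scan, template = scan_and_template
        labels = template.parcel_labels.copy()
        labels[labels == 3] = 0
        with pytest.raises(ValueError, match="PL"):
            parcel_mean_timecourses(scan, labels)


class TestPairwiseCorrelations:
    def test_five_columns_give_ten_canonical_pairs(self, rng):
        vec = pairwise_correlations(rng.normal(size=(30, 5)))
        assert len(vec.values) == 10
        assert vec.pair_labels == PAIR_NAMES

    def test_duplicated_columns_correlate_perfectly(self, rng):
        col = rng.normal(size=50)
        tcs = np.column_stack([col, col, rng.normal(size=50)])
        vec = pairwise_correlations(tcs, labels=("a", "b", "c"))
        assert vec.values[0] == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        y = np.array([2.0, 1.0, 3.0, 5.0])
        z = np.array([0.0, 1.0, 0.0, 2.0])

        def hand_r(a, b):
            am, bm = a - a.mean(), b - b.mean()
            return float(am @ bm / np.sqrt((am @ am) * (bm @ bm)))

        vec = pairwise_correlations(np.column_stack([x, y, z]), labels=("x", "y", "z"))
        assert vec.values == pytest.approx([hand_r(x, y), hand_r(x, z), hand_r(y, z)])

    def test_zero_variance_column_rejected(self, rng):
        tcs = np.column_stack([rng.normal(size=20), np.full(20, 2.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            pairwise_correlations(tcs, labels=("a", "b"))

    def test_invariant_to_affine_rescaling(self, rng):
        tcs = rng.normal(size=(40, 5))
        scaled = tcs.copy()
        scaled[:, 2] = 3.5 * scaled[:, 2] - 7.0
        assert np.allclose(
            pairwise_correlations(tcs).values,
            pairwise_correlations(scaled).values,
        )


class TestSeedConnectivity:
    def test_pair_count_is_n_choose_2(self, scan_and_template):
        scan, template = scan_and_template
        vec = seed_connectivity_vector(scan, template.seed_coords, radius=1)
        n = len(template.seed_coords)
        assert len(vec.values) == n * (n - 1) // 2

    def test_264_seeds_give_34716_pairs(self):
        from adhdconn.synthetic_data import GeneratorConfig

        config = GeneratorConfig(
            n_subjects={"S": {"TD": 1}}, n_seeds=264, T=10, rng_seed=1
        )
        template = make_brain_template(config)
        scan = simulate_scan(simulate_cohort(config)[0], template, config)
        vec = seed_connectivity_vector(scan, template.seed_coords, radius=0)
        assert len(vec.values) == 264 * 263 // 2 == 34716

    def test_two_seeds_single_pair_radius_zero(self, scan_and_template):
        scan, template = scan_and_template
        seeds = template.seed_coords[:2]
        vec = seed_connectivity_vector(scan, seeds, radius=0)
        a = scan.data[tuple(seeds[0])]
        b = scan.data[tuple(seeds[1])]
        assert len(vec.values) == 1
        assert vec.values[0] == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_seed_outside_mask_rejected(self, scan_and_template):
        scan, template = scan_and_template
        with pytest.raises(ValueError, match="outside mask"):
            seed_connectivity_vector(scan, np.array([[0, 0, 0]]), radius=0)


class TestPCA:
    def test_requested_component_count(self, rng):
        red = pca_reduce(rng.normal(size=(30, 40)), k=10)
        assert red.scores.shape == (30, 10)
        assert red.loadings.shape == (40, 10)

    def test_rank_one_input_fully_explained(self, rng):
        u = rng.normal(size=25)
        v = rng.normal(size=8)
        red = pca_reduce(np.outer(u, v), k=3)
        total = red.explained_variance.sum()
        assert red.explained_variance[0] / total == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(20, 6))
        red = pca_reduce(X, k=6)
        assert np.allclose(red.reconstruct(), X, atol=1e-8)

    def test_scores_centered_with_nonincreasing_variance(self, rng):
        red = pca_reduce(rng.normal(size=(50, 12)), k=8)
        assert np.allclose(red.scores.mean(axis=0), 0.0, atol=1e-10)
        variances = red.scores.var(axis=0)
        assert (np.diff(variances) <= 1e-10).all()

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_reduce(rng.normal(size=(5, 3)), k=4)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(30, 6))
        a = pca_reduce(X, k=4)
        b = pca_reduce(X.copy(), k=4)
        assert np.allclose(a.loadings, b.loadings)
        for i in range(4):
            j = np.argmax(np.abs(a.loadings[:, i]))
            assert a.loadings[j, i] > 0


class TestSessionAveraging:
    def test_identical_sessions_unchanged(self):
        rows = pd.DataFrame(
            {"subject_id": ["s1", "s1"], "f1": [0.5, 0.5], "f2": [1.0, 1.0]}
        )
        out = average_sessions(rows)
        assert out.loc[0, "f1"] == 0.5 and len(out) == 1

    def test_two_session_mean(self):
        rows = pd.DataFrame({"subject_id": ["s1", "s1"], "f": [0.2, 0.4]})
        assert average_sessions(rows)["f"].iloc[0] == pytest.approx(0.3)

    def test_three_sessions_match_loop_oracle(self, rng):
        values = rng.normal(size=(3, 4))
        rows = pd.DataFrame(values, columns=list("abcd"))
        rows.insert(0, "subject_id", "s1")
        out = average_sessions(rows)
        for j, col in enumerate("abcd"):
            assert out[col].iloc[0] == pytest.approx(sum(values[:, j]) / 3)

    def test_missing_feature_rejected(self):
        rows = pd.DataFrame({"subject_id": ["s1", "s1"], "f": [0.2, np.nan]})
        with pytest.raises(ValueError):
            average_sessions(rows)
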