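"""Generator invariants: geometry, counts, correlation recovery, planting."""

import numpy as np
import pandas as pd
import pytest

from adhdconn.constants import M1_CORR_MEANS, PAIR_INDEX, PARCELS, corr_matrix_from_pairs
from adhdconn.preprocess import detrend_poly
from adhdconn.synthetic_data import (
    GeneratorConfig,
    SizingError,
    make_brain_template,
    nearest_correlation,
    records_to_frame,
    simulate_cohort,
    simulate_connectivity,
    simulate_scan,
)


class TestTemplate:
    def test_invariants_on_default_grid(self):
        config = GeneratorConfig(rng_seed=3)
        tpl = make_brain_template(config)
        mask = tpl.brain_mask
        seen = np.zeros_like(mask, dtype=bool)
        for code in range(1, len(PARCELS) + 1):
            vox = tpl.parcel_labels == code
            assert vox.sum() >= 8
            assert not (vox & seen).any(), "parcels overlap"
            assert (vox <= mask).all(), "parcel outside mask"
            seen |= vox
        assert tpl.periphery.any() and (tpl.periphery <= mask).all()
        assert tpl.csf_region.any() and (tpl.csf_region <= mask).all()
        assert len(tpl.seed_coords) == config.n_seeds
        for coord in tpl.seed_coords:
            assert mask[tuple(coord)]

    def test_deterministic_given_seed(self):
        config = GeneratorConfig(rng_seed=9)
        a = make_brain_template(config)
        b = make_brain_template(config)
        assert np.array_equal(a.parcel_labels, b.parcel_labels)
        assert np.array_equal(a.seed_coords, b.seed_coords)

    def test_too_small_grid_raises_sizing_error(self):
        config = GeneratorConfig(grid_dims=(6, 6, 4), n_seeds=264)
        with pytest.raises(SizingError):
            make_brain_template(config)


class TestCohort:
    def test_counts_match_config_exactly(self):
        config = GeneratorConfig(n_subjects={"S": {"TD": 50, "COMBINED": 50}}, rng_seed=0)
        records = simulate_cohort(config)
        counts = pd.Series([r.diagnosis for r in records]).value_counts()
        assert counts["TD"] == 50 and counts["COMBINED"] == 50 and len(records) == 100

    def test_full_missingness_site(self):
        config = GeneratorConfig(
            n_subjects={"S": {"TD": 20}}, iq_missing_rate={"S": 1.0}, rng_seed=0
        )
        frame = records_to_frame(simulate_cohort(config))
        assert frame[["iq_verbal", "iq_performance", "iq_full2", "iq_full4"]].isna().all().all()

    def test_iq_group_means_recovered(self):
        # Monte-Carlo check: group sample means within 3 SE of the targets.
        config = GeneratorConfig(
            n_subjects={"S": {"TD": 500, "COMBINED": 500}},
            iq_mean_td=110.0,
            iq_mean_adhd=100.0,
            iq_sd=10.0,
            iq_missing_rate=0.0,
            site_iq_offset_sd=0.0,
            rng_seed=42,
        )
        frame = records_to_frame(simulate_cohort(config))
        se = np.sqrt(10.0**2 + 3.0**2) / np.sqrt(500)
        td = frame.loc[frame.dx == "TD", "iq_verbal"].mean()
        adhd = frame.loc[frame.dx == "COMBINED", "iq_verbal"].mean()
        assert abs(td - 110.0) < 3 * se
        assert abs(adhd - 100.0) < 3 * se
        assert adhd < td

    def test_cohort_reproducible(self):
        config = GeneratorConfig(n_subjects={"S": {"TD": 30, "INATTENTIVE": 10}}, rng_seed=5)
        a = records_to_frame(simulate_cohort(config))
        b = records_to_frame(simulate_cohort(config))
        pd.testing.assert_frame_equal(a, b)


class TestScans:
    def test_scan_bit_identical_given_seed(self, small_config, small_template):
        records = simulate_cohort(small_config)
        a = simulate_scan(records[0], small_template, small_config)
        b = simulate_scan(records[0], small_template, small_config)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.motion_params, b.motion_params)

    def test_masked_out_voxels_zero(self, small_config, small_template):
        records = simulate_cohort(small_config)
        scan = simulate_scan(records[0], small_template, small_config)
        assert np.all(scan.data[~small_template.brain_mask] == 0)
        assert np.all(np.isfinite(scan.data))

    def test_no_motion_null_case(self):
        # variance_multiplier irrelevant at n_motion_voxels=0: periphery and
        # interior background voxels share the same variance profile.
        config = GeneratorConfig(
            n_subjects={"S": {"TD": 1}},
            n_motion_voxels=0,
            variance_multiplier=1.0,
            drift_linear=0.0,
            drift_quadratic=0.0,
            rng_seed=2,
        )
        tpl = make_brain_template(config)
        scan = simulate_scan(simulate_cohort(config)[0], tpl, config)
        background = tpl.brain_mask & (tpl.parcel_labels == 0)
        periph_var = scan.data[tpl.periphery & background].var(axis=-1).mean()
        inner_var = scan.data[background & ~tpl.periphery].var(axis=-1).mean()
        assert periph_var == pytest.approx(inner_var, rel=0.1)

    def test_high_target_correlation_recovered(self):
        # One subject, corr(DM, DL) target 0.9, long scan: sample correlation
        # of parcel means within the Fisher-z sampling bound +-0.1.
        pairs = np.zeros(10)
        pairs[PAIR_INDEX["DM,DL"]] = 0.9
        target = corr_matrix_from_pairs(pairs)
        config = GeneratorConfig(
            n_subjects={"S": {"TD": 1}},
            subtype_corr={"TD": target},
            corr_sd=0.0,
            T=500,
            rng_seed=8,
        )
        tpl = make_brain_template(config)
        scan = simulate_scan(simulate_cohort(config)[0], tpl, config)
        dm = detrend_poly(scan.data[tpl.parcel_labels == 2].mean(axis=0)[:, None])
        dl = detrend_poly(scan.data[tpl.parcel_labels == 5].mean(axis=0)[:, None])
        r = np.corrcoef(dm.ravel(), dl.ravel())[0, 1]
        assert abs(r - 0.9) < 0.1

    def test_motion_planting_variance(self):
        config = GeneratorConfig(
            n_subjects={"S": {"TD": 1}},
            n_motion_voxels=15,
            variance_multiplier=5.0,
            rng_seed=4,
        )
        tpl = make_brain_template(config)
        scan = simulate_scan(simulate_cohort(config)[0], tpl, config)
        variances = scan.data[tpl.brain_mask].var(axis=-1, ddof=1)
        planted = np.zeros_like(tpl.brain_mask)
        for coord in scan.motion_voxels:
            planted[tuple(coord)] = True
        planted_var = scan.data[planted].var(axis=-1, ddof=1)
        others = scan.data[tpl.brain_mask & ~planted].var(axis=-1, ddof=1)
        assert planted_var.min() > np.percentile(others, 95)

    def test_unknown_diagnosis_has_no_target(self, small_config, small_template):
        records = simulate_cohort(small_config)
        record = records[0]
        config = small_config.with_updates(
            subtype_corr={"COMBINED": small_config.subtype_corr["COMBINED"]}
        )
        with pytest.raises(KeyError):
            simulate_scan(record, small_template, config)


class TestCorrelationModel:
    def test_nearest_correlation_projects_to_psd(self, rng):
        base = corr_matrix_from_pairs(M1_CORR_MEANS["OVERALL"])
        noise = rng.normal(0, 0.5, size=(5, 5))
        broken = np.clip(base + (noise + noise.T) / 2, -0.999, 0.999)
        np.fill_diagonal(broken, 1.0)
        fixed = nearest_correlation(broken)
        assert np.allclose(np.diag(fixed), 1.0)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-10
        assert np.allclose(fixed, fixed.T)

    def test_combined_row_group_mean(self):
        # Cohort generated from the ADHD-combined targets: the mean sampled
        # DM,DL correlation sits near the 0.084 group target.
        config = GeneratorConfig(
            n_subjects={"S": {"COMBINED": 500}}, T=150, rng_seed=21
        )
        records = simulate_cohort(config)
        conn = simulate_connectivity(config, records)
        mean_dm_dl = conn["DM,DL"].mean()
        assert abs(mean_dm_dl - 0.084) < 0.03

    def test_fast_path_reproducible(self, small_config):
        records = simulate_cohort(small_config)
        a = simulate_connectivity(small_config, records)
        b = simulate_connectivity(small_config, records)
        pd.testing.assert_frame_equal(a, b)
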