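"""Group summaries and the multinomial / logistic association models."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from adhdconn.association import (
    pairwise_logistic_models,
    subtype_association_models,
    subtype_correlation_summary,
)
from adhdconn.constants import PAIR_NAMES
from adhdconn.phenotypes import prepare_phenotypes
from adhdconn.synthetic_data import (
    GeneratorConfig,
    records_to_frame,
    simulate_cohort,
    simulate_connectivity,
)


def _cohort(counts, seed, null=False, corr_sd=0.18):
    config = GeneratorConfig(n_subjects=counts, rng_seed=seed, corr_sd=corr_sd)
    if null:
        td = config.subtype_corr["TD"]
        config = config.with_updates(
            subtype_corr={dx: td for dx in config.subtype_corr},
            iq_mean_adhd=config.iq_mean_td,
        )
    records = simulate_cohort(config)
    conn = simulate_connectivity(config, records)
    pheno = prepare_phenotypes(records_to_frame(records))
    return conn, pheno, pheno["dx"].to_numpy()


class TestSummary:
    def test_hand_computed_three_subject_group(self):
        values = np.array([[0.1] * 10, [0.2] * 10, [0.6] * 10])
        features = pd.DataFrame(values, columns=list(PAIR_NAMES))
        out = subtype_correlation_summary(features, ["TD", "TD", "TD"])
        assert out.loc[("TD", "mean"), "VL,DM"] == pytest.approx(0.3)
        assert out.loc[("TD", "sd"), "VL,DM"] == pytest.approx(np.std([0.1, 0.2, 0.6], ddof=1))

    def test_identical_vectors_zero_sd(self):
        features = pd.DataFrame(np.full((4, 10), 0.25), columns=list(PAIR_NAMES))
        out = subtype_correlation_summary(features, ["TD", "TD", "COMBINED", "COMBINED"])
        assert (out.xs("sd", level="stat") == 0).all().all()

    def test_sparse_group_omitted_with_warning(self):
        features = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 10)) / 10,
                                columns=list(PAIR_NAMES))
        with pytest.warns(RuntimeWarning):
            out = subtype_correlation_summary(features, ["TD", "TD", "COMBINED"])
        assert "COMBINED" not in out.index.get_level_values("group")

    def test_generator_parameters_recovered(self):
        # Means within +-0.03 of the group targets on a 500-per-group cohort.
        conn, _, y = _cohort({"S": {"TD": 500, "COMBINED": 500}}, seed=3)
        out = subtype_correlation_summary(conn, y)
        from adhdconn.constants import M1_CORR_MEANS

        for group in ("TD", "COMBINED"):
            means = out.loc[(group, "mean")].to_numpy()
            assert np.abs(means - M1_CORR_MEANS[group]).max() < 0.03

    def test_overall_row_mean_pl_al(self):
        # Cohort generated from the overall-sample targets: PL,AL mean near 0.450.
        config = GeneratorConfig(
            n_subjects={"S": {"TD": 500}},
            rng_seed=6,
        )
        from adhdconn.constants import M1_CORR_MEANS, corr_matrix_from_pairs

        config = config.with_updates(
            subtype_corr={"TD": corr_matrix_from_pairs(M1_CORR_MEANS["OVERALL"])}
        )
        records = simulate_cohort(config)
        conn = simulate_connectivity(config, records)
        out = subtype_correlation_summary(conn, ["TD"] * len(records))
        assert out.loc[("TD", "mean"), "PL,AL"] == pytest.approx(0.450, abs=0.03)


def _neg_loglik_multinomial(beta, X, onehot):
    """Three-level multinomial NLL with TD as reference (flat params)."""
    p = X.shape[1]
    b = beta.reshape(2, p)
    eta = np.column_stack([np.zeros(len(X)), X @ b[0], X @ b[1]])
    return -np.sum(eta[onehot] - np.log(np.exp(eta).sum(axis=1)))


def _oracle_lr_pvalue(x_pair, y_codes):
    """From-scratch LR test: two nested fits via scipy.optimize."""
    n = len(y_codes)
    onehot = (np.arange(3)[None, :] == y_codes[:, None])
    X_full = np.column_stack([np.ones(n), x_pair])
    X_base = np.ones((n, 1))
    res_full = optimize.minimize(
        _neg_loglik_multinomial, np.zeros(4), args=(X_full, onehot), method="BFGS"
    )
    res_base = optimize.minimize(
        _neg_loglik_multinomial, np.zeros(2), args=(X_base, onehot), method="BFGS"
    )
    lr = 2.0 * (res_base.fun - res_full.fun)
    return stats.chi2.sf(max(lr, 0.0), df=2)


class TestMultinomialModels:
    def test_model1_matches_from_scratch_likelihood_ratio(self):
        conn, pheno, y = _cohort(
            {"S": {"TD": 40, "COMBINED": 30, "INATTENTIVE": 30}}, seed=11
        )
        out = subtype_association_models(conn, pheno, y)
        x = conn["DM,DL"].to_numpy()
        x = (x - x.mean()) / x.std()
        codes = np.array([{"TD": 0, "COMBINED": 1, "INATTENTIVE": 2}[v] for v in y])
        oracle = _oracle_lr_pvalue(x, codes)
        assert out.loc["DM,DL", "model1"] == pytest.approx(oracle, abs=1e-4)

    def test_planted_dm_dl_effect_detected(self):
        # Group means 0.168 (TD) vs 0.084 (combined) at n=600: Model 1
        # flags the DM,DL pair while clearly null pairs stay moderate.
        conn, pheno, y = _cohort(
            {"S": {"TD": 300, "COMBINED": 180, "INATTENTIVE": 120}}, seed=12
        )
        out = subtype_association_models(conn, pheno, y)
        assert out.loc["DM,DL", "model1"] < 0.05

    def test_constant_pair_flagged(self):
        conn, pheno, y = _cohort(
            {"S": {"TD": 20, "COMBINED": 15, "INATTENTIVE": 15}}, seed=13
        )
        conn["DM,DL"] = 0.1
        out = subtype_association_models(conn, pheno, y)
        assert np.isnan(out.loc["DM,DL", "model1"])
        assert out.loc["DM,DL", "model1_flag"] == "non-identifiable"

    def test_missing_outcome_level_rejected(self):
        conn, pheno, y = _cohort({"S": {"TD": 20, "COMBINED": 20}}, seed=14)
        with pytest.raises(ValueError):
            subtype_association_models(conn, pheno, y)


class TestLogisticModels:
    def test_planted_negative_effect_sign_recovered(self):
        # The combined group's lower DM,DL correlation should surface as a
        # negative ADHD coefficient in nearly every replicate.
        signs = []
        for seed in range(12):
            conn, pheno, y = _cohort(
                {"S": {"TD": 150, "COMBINED": 150}}, seed=100 + seed
            )
            out = pairwise_logistic_models(
                conn, pheno, (y != "TD").astype(int)
            )
            signs.append(out.loc["DM,DL", "coef"] < 0)
        assert np.mean(signs) >= 0.95

    def test_type_one_error_near_nominal(self):
        # Label permutation: ~5% of replicates significant at alpha=0.05.
        hits = []
        rng = np.random.default_rng(0)
        conn, pheno, y = _cohort({"S": {"TD": 120, "COMBINED": 80}}, seed=55, null=True)
        binary = (y != "TD").astype(int)
        for _ in range(100):
            perm = rng.permutation(len(binary))
            out = pairwise_logistic_models(conn, pheno, binary[perm])
            hits.append(out.loc["DM,DL", "pvalue"] < 0.05)
        assert 0.0 <= np.mean(hits) <= 0.12

    def test_degenerate_input_flags_without_crash(self):
        conn = pd.DataFrame(
            np.random.default_rng(1).normal(size=(3, 10)) / 10, columns=list(PAIR_NAMES)
        )
        pheno = pd.DataFrame(
            {
                "age": [8.0, 9.0, 10.0],
                "iq_composite": [100.0, 105.0, 96.0],
                "gender": ["M", "F", "M"],
                "handedness": ["R", "R", "L"],
            }
        )
        out = pairwise_logistic_models(conn, pheno, [0, 1, 1])
        assert len(out) == 10  # every pair reported, flags set as needed

    def test_site_adjustment_keeps_directions(self):
        conn, pheno, y = _cohort(
            {"SiteA": {"TD": 100, "COMBINED": 100}, "SiteB": {"TD": 100, "COMBINED": 100}},
            seed=77,
        )
        binary = (y != "TD").astype(int)
        plain = pairwise_logistic_models(conn, pheno, binary)
        adjusted = pairwise_logistic_models(conn, pheno, binary, adjust_site=True)
        # the planted DM,DL direction survives site adjustment
        assert np.sign(plain.loc["DM,DL", "coef"]) == np.sign(adjusted.loc["DM,DL", "coef"])
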