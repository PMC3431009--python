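"""End-to-end orchestration: simulate -> preprocess -> features -> models.

``run_pipeline`` wires every stage into one reproducible run: it simulates
a cohort and its scans, applies the temporal preprocessing, extracts the
motor-network, CUR and seed-based feature families (averaging sessions
within subject), prepares covariates, splits off an internal test set,
trains the three classifier stages, combines them by majority vote, scores
everything with the hierarchical competition rule, and runs the
association analyses.  All artifacts are written under an output directory
with a SHA-256 manifest; rerunning with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import io as adio
from .connectivity import (
    average_sessions,
    pairwise_correlations,
    parcel_mean_timecourses,
    pca_reduce,
    seed_connectivity_vector,
)
from .constants import IQ_COLUMNS, PAIR_NAMES
from .cur import cur_covariance_vector, peripheral_fraction
from .evaluation import permutation_pvalue, score_report, split_cohort
from .models import fit_random_forest_pipeline, fit_two_stage_gbm, majority_vote
from .phenotypes import prepare_phenotypes
from .preprocess import preprocess_scan
from .synthetic_data import (
    GeneratorConfig,
    make_brain_template,
    records_to_frame,
    simulate_cohort,
    simulate_scan,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    detrend_order: int = 2
    band: tuple[float, float] | None = (0.01, 0.1)
    use_motion_confounds: bool = True
    cur_c: int = 20
    cur_rank: int | None = None
    cur_ranking: str = "leverage"
    k_pca: int = 10
    seed_radius: int = 1
    #: internal test-set size; None picks 184 for study-sized cohorts,
    #: else ~24% of the cohort
    n_test: int | None = None
    split_seed: int = 0
    model_seed: int = 0
    rf_params: dict = field(default_factory=dict)
    gbm_params: dict = field(default_factory=dict)
    ensemble: tuple[str, ...] = ("rf_parcel", "gbm_cur", "gbm_seed")
    tiebreak: str = "gbm_cur"
    write_scans: bool = False
    run_association: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        gen = d["generator"]
        gen["subtype_corr"] = {
            k: np.asarray(v).tolist() for k, v in gen["subtype_corr"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        if "subtype_corr" in gen:
            gen["subtype_corr"] = {
                k: np.asarray(v, dtype=float) for k, v in gen["subtype_corr"].items()
            }
        for key in ("grid_dims", "parcel_size"):
            if key in gen:
                gen[key] = tuple(gen[key])
        if "n_subjects" in gen:
            gen["n_subjects"] = {
                site: {dx: int(n) for dx, n in row.items()}
                for site, row in gen["n_subjects"].items()
            }
        d["generator"] = GeneratorConfig(**gen)
        for key in ("band", "ensemble"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _motion_summary(motion: np.ndarray) -> np.ndarray:
    """Collapse the T x p nuisance table to per-parameter SDs."""
    return np.asarray(motion).std(axis=0, ddof=1)


def _extract_subject_features(record, template, config: RunConfig, outdir: Path):
    """Per-session extraction, returning one row per family per session."""
    parcel_rows, cur_rows, seed_rows, motion_rows = [], [], [], []
    for session in range(record.n_sessions):
        scan = simulate_scan(record, template, config.generator, session=session)
        if config.write_scans:
            scan_dir = outdir / "scans"
            scan_dir.mkdir(exist_ok=True)
            adio.save_scan(
                scan,
                scan_dir / f"{record.subject_id}_ses-{session}.nii.gz",
                motion_path=scan_dir / f"{record.subject_id}_ses-{session}_motion.tsv",
            )
        clean = preprocess_scan(
            scan,
            detrend_order=config.detrend_order,
            band=config.band,
            use_motion_confounds=config.use_motion_confounds,
        )
        tcs = parcel_mean_timecourses(clean, template.parcel_labels)
        conn = pairwise_correlations(tcs, subject_id=record.subject_id)
        parcel_rows.append([record.subject_id, *conn.values])

        vec, sel = cur_covariance_vector(
            clean,
            c=config.cur_c,
            rank_k=config.cur_rank,
            ranking=config.cur_ranking,
        )
        frac = peripheral_fraction(sel, template)
        cur_rows.append([record.subject_id, *vec, frac])

        seed_conn = seed_connectivity_vector(
            clean, template.seed_coords, radius=config.seed_radius,
            subject_id=record.subject_id,
        )
        seed_rows.append([record.subject_id, *seed_conn.values])
        motion_rows.append([record.subject_id, *_motion_summary(scan.motion_params)])
    return parcel_rows, cur_rows, seed_rows, motion_rows


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline; returns the run report (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    gen.validate()

    template = make_brain_template(gen)
    records = simulate_cohort(gen)
    if len(records) < 8:
        raise ValueError("cohort too small to split and train")
    logger.info("simulated cohort of %d subjects", len(records))

    pheno_raw = records_to_frame(records)
    pheno = prepare_phenotypes(pheno_raw)

    n_c = config.cur_c
    cur_cols = [
        f"cov_{i:02d}_{j:02d}" for i in range(n_c) for j in range(i, n_c)
    ]
    n_seeds = len(template.seed_coords)
    seed_cols = [
        f"seed{i:03d},seed{j:03d}"
        for i in range(n_seeds)
        for j in range(i + 1, n_seeds)
    ]
    parcel_rows, cur_rows, seed_rows, motion_rows = [], [], [], []
    for record in records:
        pr, cr, sr, mr = _extract_subject_features(record, template, config, outdir)
        parcel_rows += pr
        cur_rows += cr
        seed_rows += sr
        motion_rows += mr

    parcel_df = average_sessions(
        pd.DataFrame(parcel_rows, columns=["subject_id", *PAIR_NAMES])
    )
    cur_df = average_sessions(
        pd.DataFrame(cur_rows, columns=["subject_id", *cur_cols, "peripheral_fraction"])
    )
    seed_df = average_sessions(
        pd.DataFrame(seed_rows, columns=["subject_id", *seed_cols])
    )
    n_motion = len(motion_rows[0]) - 1
    motion_df = average_sessions(
        pd.DataFrame(
            motion_rows,
            columns=["subject_id", *(f"motion_sd_{i:02d}" for i in range(n_motion))],
        )
    )

    # align phenotypes to the (sorted) feature tables
    pheno = pheno.set_index("subject_id").loc[parcel_df["subject_id"]].reset_index()
    truth = pheno["dx"].tolist()
    subject_ids = parcel_df["subject_id"].tolist()

    # cross-subject reductions (stacked feature matrices)
    k_cur = min(config.k_pca, len(records), len(cur_cols))
    cur_pca = pca_reduce(cur_df[cur_cols].to_numpy(), k=k_cur)
    cur_pc_cols = [f"cur_pc{i + 1}" for i in range(k_cur)]
    cur_scores = pd.DataFrame(cur_pca.scores, columns=cur_pc_cols)

    k_seed = min(config.k_pca, len(records), len(seed_cols))
    seed_pca = pca_reduce(seed_df[seed_cols].to_numpy(), k=k_seed)
    seed_pc_cols = [f"seed_pc{i + 1}" for i in range(k_seed)]
    seed_scores = pd.DataFrame(seed_pca.scores, columns=seed_pc_cols)

    demo_all_iq = ["age", "gender", "site", "handedness", *IQ_COLUMNS, "iq_composite"]
    demo_composite = ["age", "gender", "site", "handedness", "iq_composite"]

    table_rf = pd.concat(
        [parcel_df[list(PAIR_NAMES)].reset_index(drop=True), pheno[demo_all_iq]], axis=1
    )
    table_cur = pd.concat([cur_scores, pheno[demo_composite]], axis=1)
    motion_cols = [c for c in motion_df.columns if c != "subject_id"]
    table_seed = pd.concat(
        [seed_scores, motion_df[motion_cols].reset_index(drop=True), pheno[demo_composite]],
        axis=1,
    )

    n = len(records)
    n_test = config.n_test
    if n_test is None:
        n_test = 184 if n >= 400 else max(2, int(round(0.24 * n)))
    train_idx, test_idx = split_cohort(n, n_test=n_test, seed=config.split_seed)
    y = np.asarray(truth)
    ids = np.asarray(subject_ids)

    models = {}
    models["rf_parcel"] = fit_random_forest_pipeline(
        table_rf.iloc[train_idx],
        y[train_idx],
        required_columns=list(PAIR_NAMES) + demo_composite,
        seed=config.model_seed,
        source="rf_parcel",
        **config.rf_params,
    )
    models["gbm_cur"] = fit_two_stage_gbm(
        table_cur.iloc[train_idx],
        y[train_idx],
        seed=config.model_seed + 1,
        source="gbm_cur",
        **config.gbm_params,
    )
    models["gbm_seed"] = fit_two_stage_gbm(
        table_seed.iloc[train_idx],
        y[train_idx],
        seed=config.model_seed + 2,
        source="gbm_seed",
        **config.gbm_params,
    )

    tables = {"rf_parcel": table_rf, "gbm_cur": table_cur, "gbm_seed": table_seed}
    predictions = {}
    reports = {}
    for name in config.ensemble:
        pred = models[name].predict(tables[name].iloc[test_idx], ids[test_idx])
        predictions[name] = pred
        reports[name] = score_report(y[test_idx], pred.labels).to_dict()

    ensemble_pred = majority_vote(list(predictions.values()), tiebreak_source=config.tiebreak)
    reports["ensemble"] = score_report(y[test_idx], ensemble_pred.labels).to_dict()
    baseline_labels = ["TD"] * len(test_idx)
    reports["baseline_all_td"] = score_report(y[test_idx], baseline_labels).to_dict()
    reports["ensemble"]["permutation_pvalue"] = permutation_pvalue(
        y[test_idx], ensemble_pred.labels, n_perm=500, seed=config.split_seed
    )

    association_report = {}
    if config.run_association:
        try:
            summary = assoc.subtype_correlation_summary(parcel_df, truth)
            summary.to_csv(outdir / "association_summary.csv")
            pvals = assoc.subtype_association_models(parcel_df, pheno, truth)
            pvals.to_csv(outdir / "association_multinomial.csv")
            logistic = assoc.pairwise_logistic_models(
                parcel_df, pheno, ["0" if t == "TD" else "1" for t in truth]
            )
            logistic.to_csv(outdir / "association_logistic.csv")
            association_report = {
                "summary_csv": "association_summary.csv",
                "multinomial_csv": "association_multinomial.csv",
                "logistic_csv": "association_logistic.csv",
                "dm_dl_model1_p": float(pvals.loc["DM,DL", "model1"]),
            }
        except ValueError as exc:
            association_report = {"skipped": str(exc)}

    # artifacts
    adio.save_template(template, outdir / "template")
    adio.save_phenotypes(pheno_raw, outdir / "phenotypes.csv")
    adio.save_phenotypes(pheno, outdir / "phenotypes_prepared.csv")
    parcel_df.to_csv(outdir / "features_parcel.csv", index=False)
    cur_df.to_csv(outdir / "features_cur.csv", index=False)
    motion_df.to_csv(outdir / "features_motion.csv", index=False)
    pd.concat([pd.Series(subject_ids, name="subject_id"), cur_scores, seed_scores], axis=1).to_csv(
        outdir / "features_components.csv", index=False
    )
    pred_frame = pd.DataFrame({"subject_id": ids[test_idx], "truth": y[test_idx]})
    for name, pred in predictions.items():
        pred_frame[name] = pred.labels
    pred_frame["ensemble"] = ensemble_pred.labels
    pred_frame.to_csv(outdir / "predictions.csv", index=False)

    report = {
        "config_hash": config.config_hash(),
        "n_subjects": n,
        "n_train": len(train_idx),
        "n_test": len(test_idx),
        "scores": reports,
        "association": association_report,
        "seeds": {
            "generator": gen.rng_seed,
            "split": config.split_seed,
            "model": config.model_seed,
        },
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    manifest = {
        "config_hash": config.config_hash(),
        "files": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
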