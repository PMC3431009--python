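"""Synthetic resting-state fMRI cohorts with known ground truth.

This module generates phenotype records and 4D BOLD-like scans whose
statistical structure mirrors the ADHD-200 training release closely enough
that every downstream stage of the diagnosis pipeline — temporal
preprocessing, motor-network connectivity, CUR voxel selection, classifiers,
scoring and association models — can be exercised end to end without any
imaging data download.

The generative model, per subject:

1.  A subject-level 5x5 inter-parcel correlation matrix is drawn by adding
    Gaussian jitter (SD ``corr_sd``) to the diagnosis group's target matrix
    on the correlation scale, then projecting to the nearest valid
    correlation matrix if the jitter breaks positive semi-definiteness.
    Jittering on the correlation scale keeps group means equal to the
    targets by construction.
2.  Five latent parcel signals are drawn as a stationary AR(1) Gaussian
    process (unit variance, lag-one coefficient ``ar_coef``) whose
    cross-correlation equals the subject matrix, giving the slow,
    temporally smooth character of resting BOLD fluctuations.
3.  Every voxel of a parcel receives that parcel's latent signal plus white
    voxel noise (SD ``voxel_noise_sd``); remaining brain voxels receive
    unit-variance white noise.  A linear+quadratic scanner drift with
    subject-jittered amplitude is added across the brain.
4.  ``n_motion_voxels`` voxels drawn from the mask periphery and CSF
    compartment are overwritten with heavy-tailed (Student-t, 3 df) motion
    time courses rescaled to ``variance_multiplier`` times the baseline
    voxel variance; when ``shared_direction`` is set they share a
    cohort-level component, emulating a common population direction of head
    motion.
5.  A T x 36 nuisance table of smooth AR(1) "motion parameters" is emitted
    with each scan.

Phenotypes reproduce the consortium's site-imbalanced class prevalence,
per-site gender/age distributions, the TD-vs-ADHD IQ gap, and per-site IQ
missingness.

Everything is deterministic given ``GeneratorConfig.rng_seed``: identical
config and seed give bit-identical cohorts and scans.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .constants import (
    ADHD_SUBTYPES,
    AGE_RANGE,
    DX_LEVELS,
    IQ_COLUMNS,
    M1_CORR_MEANS,
    PARCELS,
    SITE_TABLE,
    corr_matrix_from_pairs,
    default_site_counts,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SizingError",
    "GeneratorConfig",
    "BrainTemplate",
    "SubjectRecord",
    "Scan4D",
    "make_brain_template",
    "simulate_cohort",
    "simulate_scan",
    "simulate_connectivity",
    "records_to_frame",
    "nearest_correlation",
]

# Distinct RNG stream tags so template, cohort and per-scan draws never
# overlap even though they share one user-facing seed.
_STREAM_TEMPLATE = 3
_STREAM_COHORT = 5
_STREAM_MOTION_COURSE = 7
_STREAM_SITE = 11
_STREAM_SCAN = 101
_STREAM_FASTCONN = 211


class SizingError(ValueError):
    """Grid too small for the requested template geometry."""


def _default_subtype_corr() -> dict[str, np.ndarray]:
    """Default target matrices: published group means per diagnosis.

    No separate summary exists for the (rare) hyperactive/impulsive
    subtype, so it falls back to the overall-sample matrix.
    """
    return {
        "TD": corr_matrix_from_pairs(M1_CORR_MEANS["TD"]),
        "COMBINED": corr_matrix_from_pairs(M1_CORR_MEANS["COMBINED"]),
        "INATTENTIVE": corr_matrix_from_pairs(M1_CORR_MEANS["INATTENTIVE"]),
        "HYPERACTIVE": corr_matrix_from_pairs(M1_CORR_MEANS["OVERALL"]),
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Defaults encode the study conditions the pipeline was built for: site x
    subtype counts mirroring the training release, group target correlation
    matrices from the published summaries, a ~10-point composite-IQ gap
    between TD and ADHD children, and between-subject correlation jitter
    sized so observed per-pair SDs land near the published ~0.2.
    """

    #: site -> {diagnosis -> count}
    n_subjects: dict[str, dict[str, int]] = field(default_factory=default_site_counts)
    #: diagnosis -> 5x5 target correlation matrix for the parcel signals
    subtype_corr: dict[str, np.ndarray] = field(default_factory=_default_subtype_corr)
    #: between-subject SD of each pairwise correlation (correlation scale)
    corr_sd: float = 0.18
    T: int = 150
    tr: float = 2.0
    #: white-noise SD added to each parcel voxel (latent signal SD is 1)
    voxel_noise_sd: float = 0.2
    #: scanner drift amplitudes over normalised time in [-1, 1]
    drift_linear: float = 1.0
    drift_quadratic: float = 0.5
    #: lag-one autocorrelation of the latent parcel signals
    ar_coef: float = 0.3
    iq_mean_td: float = 110.0
    iq_mean_adhd: float = 100.0
    iq_sd: float = 13.0
    #: scalar rate applied to every site, or a site -> rate mapping
    iq_missing_rate: float | dict[str, float] = 0.1
    #: SD of the per-site additive IQ offset (site effect)
    site_iq_offset_sd: float = 2.0
    #: relative SD of the per-site scan-noise scale factor
    site_noise_sd: float = 0.05
    grid_dims: tuple[int, int, int] = (20, 20, 10)
    #: size of each cuboid parcel in voxels
    parcel_size: tuple[int, int, int] = (3, 3, 2)
    n_seeds: int = 264
    n_motion_voxels: int = 20
    variance_multiplier: float = 8.0
    shared_direction: bool = True
    n_motion_params: int = 36
    n_sessions: int = 1
    rng_seed: int = 0

    def validate(self) -> None:
        for site, row in self.n_subjects.items():
            for dx, n in row.items():
                if dx not in DX_LEVELS:
                    raise ValueError(f"unknown diagnosis {dx!r} for site {site!r}")
                if n < 0:
                    raise ValueError(f"negative count for {site}/{dx}")
        for dx, mat in self.subtype_corr.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (5, 5):
                raise ValueError(f"subtype_corr[{dx!r}] must be 5x5")
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ValueError(f"subtype_corr[{dx!r}] not symmetric")
            if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
                raise ValueError(f"subtype_corr[{dx!r}] diagonal must be 1")
            if np.linalg.eigvalsh(mat).min() < -1e-8:
                raise ValueError(f"subtype_corr[{dx!r}] not positive semi-definite")
        for name in ("corr_sd", "voxel_noise_sd", "iq_sd", "site_iq_offset_sd", "site_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for rate in self._missing_rates().values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("iq_missing_rate must lie in [0, 1]")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not -1 < self.ar_coef < 1:
            raise ValueError("ar_coef must lie in (-1, 1)")
        if self.variance_multiplier < 0 or self.n_motion_voxels < 0:
            raise ValueError("motion parameters must be non-negative")

    def _missing_rates(self) -> dict[str, float]:
        if isinstance(self.iq_missing_rate, dict):
            return dict(self.iq_missing_rate)
        return {site: float(self.iq_missing_rate) for site in self.n_subjects}

    def with_updates(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class BrainTemplate:
    """Spatial layout shared by every subject of a synthetic cohort.

    ``parcel_labels`` codes the five M1 parcels 1..5 in canonical order;
    ``periphery`` marks mask voxels within one voxel (Chebyshev) of the mask
    boundary and ``csf_region`` a small central ventricle-like compartment —
    together they form the candidate pool for planted motion voxels.
    """

    grid_dims: tuple[int, int, int]
    brain_mask: np.ndarray
    parcel_labels: np.ndarray
    seed_coords: np.ndarray  # (n_seeds, 3) integer voxel coordinates
    csf_region: np.ndarray
    periphery: np.ndarray

    def validate(self) -> None:
        mask = self.brain_mask.astype(bool)
        if self.parcel_labels.shape != mask.shape:
            raise ValueError("parcel label grid does not match mask")
        for code, name in enumerate(PARCELS, start=1):
            vox = self.parcel_labels == code
            if not vox.any():
                raise ValueError(f"parcel {name} is empty")
            if (vox & ~mask).any():
                raise ValueError(f"parcel {name} extends outside the brain mask")
        if (self.parcel_labels[~mask] != 0).any():
            raise ValueError("parcel labels present outside the mask")
        if (self.csf_region & ~mask).any():
            raise ValueError("CSF region outside mask")
        if (self.periphery & ~mask).any():
            raise ValueError("periphery outside mask")
        for coord in self.seed_coords:
            if not mask[tuple(coord)]:
                raise ValueError(f"seed {coord} outside mask")

    def parcel_voxels(self, code: int) -> np.ndarray:
        return self.parcel_labels == code


@dataclass
class SubjectRecord:
    """Phenotypes for one subject; ``iq`` uses NaN for missing measures."""

    subject_id: str
    index: int
    site: str
    age: float
    gender: str
    handedness: str
    iq: dict[str, float]
    diagnosis: str
    n_sessions: int = 1


@dataclass
class Scan4D:
    """One session's BOLD-like data on the template grid, plus nuisance table.

    ``motion_voxels`` records the planted motion-artifact coordinates when
    the scan came from the simulator — ground truth for motion-detection
    diagnostics, absent (None) for loaded real data.
    """

    data: np.ndarray  # (nx, ny, nz, T)
    tr: float
    mask: np.ndarray
    motion_params: np.ndarray  # (T, n_motion_params)
    motion_voxels: np.ndarray | None = None

    @property
    def T(self) -> int:
        return self.data.shape[-1]

    def masked_matrix(self) -> np.ndarray:
        """Return the T x V matrix of in-mask voxel time courses."""
        return self.data[self.mask.astype(bool)].T

    def with_masked_matrix(self, mat: np.ndarray) -> "Scan4D":
        """Rebuild a scan from a T x V in-mask matrix (out-of-mask = 0)."""
        data = np.zeros_like(self.data)
        data[self.mask.astype(bool)] = mat.T
        return Scan4D(
            data=data,
            tr=self.tr,
            mask=self.mask,
            motion_params=self.motion_params,
            motion_voxels=self.motion_voxels,
        )


# ---------------------------------------------------------------------------
# correlation utilities


def nearest_correlation(mat: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``eps`` and the diagonal renormalised to 1 —
    a single-pass spectral projection, adequate for the mild indefiniteness
    produced by jittering an already-valid matrix.
    """
    mat = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(mat)
    if w.min() >= 0:
        out = mat.copy()
    else:
        w = np.clip(w, eps, None)
        out = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(out), eps, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _jitter_correlation(target: np.ndarray, corr_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Subject-level correlation matrix: target + symmetric Gaussian jitter."""
    p = target.shape[0]
    noise = np.zeros_like(target)
    iu = np.triu_indices(p, k=1)
    noise[iu] = rng.normal(0.0, corr_sd, size=len(iu[0]))
    noise = noise + noise.T
    jittered = np.clip(target + noise, -0.999, 0.999)
    np.fill_diagonal(jittered, 1.0)
    if np.linalg.eigvalsh(jittered).min() < 0:
        logger.debug("jittered correlation matrix not PSD; projecting")
        jittered = nearest_correlation(jittered)
    return jittered


def _ar1_mvnormal(rng: np.random.Generator, corr: np.ndarray, T: int, phi: float) -> np.ndarray:
    """Stationary AR(1) Gaussian series, T x p, unit variance, cross-corr ``corr``."""
    p = corr.shape[0]
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(p))
    innov = rng.standard_normal((T, p)) @ chol.T
    out = np.empty((T, p))
    out[0] = innov[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, T):
        out[t] = phi * out[t - 1] + scale * innov[t]
    return out


# ---------------------------------------------------------------------------
# template


def _ellipsoid_mask(dims: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = dims
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = max(cx, 0.5), max(cy, 0.5), max(cz, 0.5)
    x, y, z = np.ogrid[:nx, :ny, :nz]
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def make_brain_template(config: GeneratorConfig) -> BrainTemplate:
    """Build the shared brain template for a cohort.

    An ellipsoidal brain mask is carved into the grid; the periphery is the
    1-voxel-thick rind of the mask, a small central block plays the role of
    CSF/ventricles, five disjoint cuboid parcels are placed in the interior,
    and ``n_seeds`` distinct in-mask voxels are sampled as reference seeds.
    Deterministic given ``config.rng_seed``.

    Raises
    ------
    SizingError
        If the grid cannot hold five disjoint parcels of ``parcel_size``
        (each at least 8 voxels) or ``n_seeds`` distinct mask voxels.
    """
    config.validate()
    dims = tuple(int(d) for d in config.grid_dims)
    if any(d < 3 for d in dims):
        raise SizingError(f"grid {dims} too small for a brain mask")
    mask = _ellipsoid_mask(dims)

    struct = np.ones((3, 3, 3), dtype=bool)  # Chebyshev neighbourhood
    interior = ndimage.binary_erosion(mask, structure=struct)
    periphery = mask & ~interior

    # central ventricle-like CSF block, clipped to the interior
    nx, ny, nz = dims
    csf = np.zeros(dims, dtype=bool)
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    csf[max(cx - 1, 0) : cx + 2, max(cy - 1, 0) : cy + 2, max(cz - 1, 0) : cz + 1] = True
    csf &= interior

    # place five disjoint cuboid parcels in interior \ (csf dilated by 1)
    px, py, pz = config.parcel_size
    if px * py * pz < 8:
        raise SizingError("parcel_size must contain at least 8 voxels")
    blocked = ndimage.binary_dilation(csf, structure=struct)
    labels = np.zeros(dims, dtype=np.int16)
    placed = 0
    for ix in range(0, nx - px + 1):
        for iy in range(0, ny - py + 1):
            for iz in range(0, nz - pz + 1):
                if placed == len(PARCELS):
                    break
                region = (slice(ix, ix + px), slice(iy, iy + py), slice(iz, iz + pz))
                if interior[region].all() and not blocked[region].any():
                    placed += 1
                    labels[region] = placed
                    # keep a 1-voxel gap between parcels
                    blockmask = np.zeros(dims, dtype=bool)
                    blockmask[region] = True
                    blocked |= ndimage.binary_dilation(blockmask, structure=struct)
    if placed < len(PARCELS):
        raise SizingError(
            f"grid {dims} holds only {placed} of {len(PARCELS)} parcels "
            f"of size {config.parcel_size}"
        )

    mask_coords = np.argwhere(mask)
    if config.n_seeds > len(mask_coords):
        raise SizingError(
            f"requested {config.n_seeds} seeds but mask has only "
            f"{len(mask_coords)} voxels"
        )
    rng = np.random.default_rng([config.rng_seed, _STREAM_TEMPLATE])
    pick = rng.choice(len(mask_coords), size=config.n_seeds, replace=False)
    seeds = mask_coords[np.sort(pick)]

    template = BrainTemplate(
        grid_dims=dims,
        brain_mask=mask,
        parcel_labels=labels,
        seed_coords=seeds,
        csf_region=csf,
        periphery=periphery,
    )
    template.validate()
    return template


# ---------------------------------------------------------------------------
# cohort phenotypes


def _site_params(site: str) -> dict:
    info = SITE_TABLE.get(site)
    if info is None:
        return {"male_pct": 62, "age_mean": 11.4, "age_sd": 3.3}
    return info


def _site_unit(config: GeneratorConfig, site: str) -> float:
    """Deterministic standard-normal draw attached to a site name."""
    key = zlib.crc32(site.encode("utf-8")) % (2**31)
    rng = np.random.default_rng([config.rng_seed, _STREAM_SITE, key])
    return float(rng.standard_normal())


def simulate_cohort(config: GeneratorConfig) -> list[SubjectRecord]:
    """Draw phenotype records for every configured site x subtype cell.

    Counts match the config exactly; ages and gender follow per-site
    distributions; the four IQ measures scatter around a subject-level
    latent IQ whose mean is ``iq_mean_td`` or ``iq_mean_adhd`` (plus a
    site offset), and each measure is missing independently at the site's
    configured rate.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, _STREAM_COHORT])
    rates = config._missing_rates()
    records: list[SubjectRecord] = []
    idx = 0
    for site in sorted(config.n_subjects):
        params = _site_params(site)
        site_iq_offset = config.site_iq_offset_sd * _site_unit(config, site)
        rate = rates.get(site, 0.0)
        row = config.n_subjects[site]
        for dx in DX_LEVELS:
            for _ in range(int(row.get(dx, 0))):
                age = float(
                    np.clip(
                        rng.normal(params["age_mean"], params["age_sd"]),
                        AGE_RANGE[0],
                        AGE_RANGE[1],
                    )
                )
                gender = "M" if rng.random() < params["male_pct"] / 100.0 else "F"
                handedness = "R" if rng.random() < 0.9 else "L"
                mean_iq = config.iq_mean_td if dx == "TD" else config.iq_mean_adhd
                latent_iq = rng.normal(mean_iq + site_iq_offset, config.iq_sd)
                iq = {}
                for col in IQ_COLUMNS:
                    value = latent_iq + rng.normal(0.0, 3.0)
                    missing = rng.random() < rate
                    iq[col] = np.nan if missing else float(value)
                records.append(
                    SubjectRecord(
                        subject_id=f"sub-{idx:05d}",
                        index=idx,
                        site=site,
                        age=age,
                        gender=gender,
                        handedness=handedness,
                        iq=iq,
                        diagnosis=dx,
                        n_sessions=config.n_sessions,
                    )
                )
                idx += 1
    return records


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records (one row per subject, NaN = missing IQ)."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "site": r.site,
            "age": r.age,
            "gender": r.gender,
            "handedness": r.handedness,
        }
        row.update({col: r.iq.get(col, np.nan) for col in IQ_COLUMNS})
        row["dx"] = r.diagnosis
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scans


def _shared_motion_course(config: GeneratorConfig) -> np.ndarray:
    """Cohort-level heavy-tailed motion time course (normalised t, 3 df)."""
    rng = np.random.default_rng([config.rng_seed, _STREAM_MOTION_COURSE])
    return rng.standard_t(df=3, size=config.T) / np.sqrt(3.0)


def simulate_scan(
    subject: SubjectRecord,
    template: BrainTemplate,
    config: GeneratorConfig,
    session: int = 0,
) -> Scan4D:
    """Simulate one session's 4D scan for a subject.

    See the module docstring for the generative model.  Deterministic given
    ``(config.rng_seed, subject.index, session)``; out-of-mask voxels are
    exactly zero.
    """
    config.validate()
    try:
        target = np.asarray(config.subtype_corr[subject.diagnosis], dtype=float)
    except KeyError:
        raise KeyError(
            f"no subtype_corr entry for diagnosis {subject.diagnosis!r}"
        ) from None
    rng = np.random.default_rng(
        [config.rng_seed, _STREAM_SCAN, subject.index, session]
    )
    T = config.T
    mask = template.brain_mask.astype(bool)
    site_factor = max(1.0 + config.site_noise_sd * _site_unit(config, subject.site), 0.1)

    subj_corr = _jitter_correlation(target, config.corr_sd, rng)
    latent = _ar1_mvnormal(rng, subj_corr, T, config.ar_coef)

    data = np.zeros(template.grid_dims + (T,), dtype=float)
    background = mask & (template.parcel_labels == 0)
    data[background] = rng.normal(0.0, site_factor, size=(int(background.sum()), T))
    for code in range(1, len(PARCELS) + 1):
        vox = template.parcel_labels == code
        n_vox = int(vox.sum())
        data[vox] = latent[:, code - 1] + rng.normal(
            0.0, config.voxel_noise_sd, size=(n_vox, T)
        )

    tau = np.linspace(-1.0, 1.0, T)
    a1 = config.drift_linear * rng.normal(1.0, 0.25)
    a2 = config.drift_quadratic * rng.normal(1.0, 0.25)
    data[mask] += a1 * tau + a2 * tau**2

    pick = np.empty((0, 3), dtype=int)
    if config.n_motion_voxels > 0:
        pool = np.argwhere(template.periphery | template.csf_region)
        n_plant = min(config.n_motion_voxels, len(pool))
        pick = pool[rng.choice(len(pool), size=n_plant, replace=False)]
        shared = _shared_motion_course(config)
        w = 0.7 if config.shared_direction else 0.0
        target_sd = np.sqrt(config.variance_multiplier) * site_factor
        for coord in pick:
            own = rng.standard_t(df=3, size=T) / np.sqrt(3.0)
            raw = w * shared + np.sqrt(1.0 - w**2) * own
            sd = raw.std()
            if sd < 1e-12:  # pragma: no cover - degenerate draw
                raw = rng.standard_normal(T)
                sd = raw.std()
            data[tuple(coord)] = raw / sd * target_sd

    # smooth AR(1) nuisance table standing in for realignment parameters
    innov = rng.normal(0.0, 0.1, size=(T, config.n_motion_params))
    motion = np.empty_like(innov)
    motion[0] = innov[0]
    for t in range(1, T):
        motion[t] = 0.9 * motion[t - 1] + innov[t]

    return Scan4D(
        data=data,
        tr=config.tr,
        mask=mask,
        motion_params=motion,
        motion_voxels=pick,
    )


# ---------------------------------------------------------------------------
# parcel-level fast path


def simulate_connectivity(
    config: GeneratorConfig, records: list[SubjectRecord]
) -> pd.DataFrame:
    """Sample each subject's 10-vector of parcel correlations directly.

    Shortcut past the voxel stage: draws the subject-level jittered
    correlation matrix and the T-sample latent AR(1) series exactly as
    ``simulate_scan`` does, then returns the sample correlations of the
    latent signals themselves.  Distributionally this matches the full
    scan -> preprocess -> parcel-mean route up to the (small) voxel-noise
    attenuation and band-pass degrees-of-freedom loss, at a tiny fraction
    of the cost — useful for calibration studies with many replicates.
    """
    from .constants import PAIR_NAMES  # local to avoid clutter at module top

    config.validate()
    rows = []
    iu = np.triu_indices(len(PARCELS), k=1)
    for r in records:
        target = np.asarray(config.subtype_corr[r.diagnosis], dtype=float)
        rng = np.random.default_rng(
            [config.rng_seed, _STREAM_FASTCONN, r.index]
        )
        subj_corr = _jitter_correlation(target, config.corr_sd, rng)
        latent = _ar1_mvnormal(rng, subj_corr, config.T, config.ar_coef)
        sample = np.corrcoef(latent.T)
        rows.append([r.subject_id, *sample[iu]])
    return pd.DataFrame(rows, columns=["subject_id", *PAIR_NAMES])
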