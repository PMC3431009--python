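"""Shared vocabulary and reference summaries for the ADHD-200-style cohort.

The five primary-motor (M1) parcels follow the dorsomedial-to-ventrolateral
organisation of the motor homunculus:

* ``VL`` ventrolateral (oro-motor function)
* ``DM`` dorsomedial (trunk / lower limbs)
* ``PL`` posterior lateral
* ``AL`` anterior lateral
* ``DL`` dorsolateral (upper limbs)

The canonical pair ordering is the row-major upper triangle of the parcel
order above — the same column order used in published group summaries of the
ADHD-200 training sample — so feature vectors produced anywhere in the
package line up with those tables.

``M1_CORR_MEANS`` / ``M1_CORR_SDS`` hold the published group-level means and
between-subject SDs of the 10 inter-parcel Pearson correlations for the
overall sample, typically developing controls, ADHD-combined and
ADHD-inattentive groups.  The synthetic generator uses them as its default
targets.  ``SITE_TABLE`` holds per-site sample sizes, training subtype
prevalences (the fully withheld Brown sample is excluded), gender balance
and age distributions, so default synthetic cohorts reproduce the
consortium's site imbalance.
"""

from __future__ import annotations

import numpy as np

#: Canonical M1 parcel order; integer label codes are 1-based in this order.
PARCELS: tuple[str, ...] = ("VL", "DM", "PL", "AL", "DL")

#: Unordered parcel pairs, row-major upper triangle of ``PARCELS``.
PAIRS: tuple[tuple[str, str], ...] = tuple(
    (PARCELS[i], PARCELS[j])
    for i in range(len(PARCELS))
    for j in range(i + 1, len(PARCELS))
)

#: Pair names in the canonical ordering, e.g. ``"VL,DM"``.
PAIR_NAMES: tuple[str, ...] = tuple(f"{a},{b}" for a, b in PAIRS)

#: Diagnosis levels. TD = typically developing control.
DX_LEVELS: tuple[str, ...] = ("TD", "COMBINED", "HYPERACTIVE", "INATTENTIVE")
ADHD_SUBTYPES: tuple[str, ...] = ("COMBINED", "HYPERACTIVE", "INATTENTIVE")

#: IQ measure columns carried by phenotype tables (verbal, performance and
#: two full-scale variants, mirroring the mixture of WISC/WASI instruments).
IQ_COLUMNS: tuple[str, ...] = ("iq_verbal", "iq_performance", "iq_full2", "iq_full4")

# Group-level mean inter-parcel correlations (canonical pair order).
M1_CORR_MEANS: dict[str, np.ndarray] = {
    "OVERALL": np.array(
        [0.115, 0.344, 0.183, 0.277, -0.002, 0.272, 0.146, 0.450, 0.229, 0.187]
    ),
    "TD": np.array(
        [0.134, 0.349, 0.192, 0.284, -0.007, 0.279, 0.168, 0.456, 0.241, 0.179]
    ),
    "COMBINED": np.array(
        [0.084, 0.349, 0.192, 0.281, 0.008, 0.289, 0.084, 0.469, 0.210, 0.171]
    ),
    "INATTENTIVE": np.array(
        [0.103, 0.317, 0.185, 0.249, -0.015, 0.266, 0.120, 0.449, 0.239, 0.175]
    ),
}

# Between-subject SDs of the same correlations.
M1_CORR_SDS: dict[str, np.ndarray] = {
    "OVERALL": np.array(
        [0.206, 0.184, 0.204, 0.191, 0.189, 0.207, 0.201, 0.182, 0.205, 0.187]
    ),
    "TD": np.array(
        [0.207, 0.182, 0.203, 0.188, 0.183, 0.205, 0.200, 0.174, 0.201, 0.189]
    ),
    "COMBINED": np.array(
        [0.209, 0.173, 0.198, 0.185, 0.196, 0.201, 0.194, 0.174, 0.201, 0.198]
    ),
    "INATTENTIVE": np.array(
        [0.210, 0.183, 0.191, 0.203, 0.187, 0.213, 0.199, 0.187, 0.201, 0.148]
    ),
}


def corr_matrix_from_pairs(values) -> np.ndarray:
    """Assemble a 5x5 correlation matrix from a 10-vector in canonical order."""
    values = np.asarray(values, dtype=float)
    if values.shape != (10,):
        raise ValueError(f"expected 10 pairwise values, got shape {values.shape}")
    p = len(PARCELS)
    mat = np.eye(p)
    iu = np.triu_indices(p, k=1)
    mat[iu] = values
    mat[(iu[1], iu[0])] = values
    return mat


def pairs_from_corr_matrix(mat: np.ndarray) -> np.ndarray:
    """Extract the canonical 10-vector from a 5x5 correlation matrix."""
    mat = np.asarray(mat, dtype=float)
    iu = np.triu_indices(len(PARCELS), k=1)
    return mat[iu].copy()


#: Index of a named pair within the canonical 10-vector.
PAIR_INDEX: dict[str, int] = {name: i for i, name in enumerate(PAIR_NAMES)}

# Per-site demographics of the training release: total released N, subtype
# percentages among training (non-withheld) subjects, percent male, and the
# age mean/SD.  Brown is omitted (entirely withheld).
SITE_TABLE: dict[str, dict] = {
    "Peking": {
        "n": 245,
        "subtype_pct": {"TD": 47, "COMBINED": 12, "HYPERACTIVE": 0, "INATTENTIVE": 20},
        "male_pct": 71,
        "age_mean": 11.70,
        "age_sd": 1.96,
    },
    "KKI": {
        "n": 94,
        "subtype_pct": {"TD": 65, "COMBINED": 17, "HYPERACTIVE": 1, "INATTENTIVE": 5},
        "male_pct": 60,
        "age_mean": 10.22,
        "age_sd": 1.34,
    },
    "NeuroImage": {
        "n": 73,
        "subtype_pct": {"TD": 32, "COMBINED": 25, "HYPERACTIVE": 8, "INATTENTIVE": 1},
        "male_pct": 59,
        "age_mean": 17.64,
        "age_sd": 3.05,
    },
    "NYU": {
        "n": 263,
        "subtype_pct": {"TD": 38, "COMBINED": 29, "HYPERACTIVE": 1, "INATTENTIVE": 17},
        "male_pct": 65,
        "age_mean": 11.45,
        "age_sd": 2.91,
    },
    "Oregon": {
        "n": 113,
        "subtype_pct": {"TD": 37, "COMBINED": 20, "HYPERACTIVE": 2, "INATTENTIVE": 11},
        "male_pct": 54,
        "age_mean": 9.10,
        "age_sd": 1.25,
    },
    "Pitt": {
        "n": 98,
        "subtype_pct": {"TD": 91, "COMBINED": 0, "HYPERACTIVE": 0, "INATTENTIVE": 0},
        "male_pct": 54,
        "age_mean": 15.08,
        "age_sd": 2.78,
    },
    "WashU": {
        "n": 61,
        "subtype_pct": {"TD": 100, "COMBINED": 0, "HYPERACTIVE": 0, "INATTENTIVE": 0},
        "male_pct": 54,
        "age_mean": 11.47,
        "age_sd": 3.88,
    },
}

#: Plausible age range for a paediatric/young-adult cohort (years).
AGE_RANGE: tuple[float, float] = (7.0, 26.0)


def default_site_counts(scale: float = 1.0) -> dict[str, dict[str, int]]:
    """Per-site x subtype subject counts mirroring the training release.

    ``scale`` shrinks (or grows) every cell proportionally, rounding to the
    nearest integer, so small smoke-test cohorts retain the site imbalance.
    """
    counts: dict[str, dict[str, int]] = {}
    for site, info in SITE_TABLE.items():
        row = {
            dx: int(round(info["n"] * pct / 100.0 * scale))
            for dx, pct in info["subtype_pct"].items()
        }
        counts[site] = row
    return counts
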