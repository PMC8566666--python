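"""Synthetic multi-site, two-class cohorts with planted connectivity signal.

Subjects are zero-mean Gaussian ROI time series. The two diagnostic classes
share a base covariance built from a random sparse partial-correlation
structure; the ASD class additionally perturbs the covariance entries among a
small set of signal regions by +/- ``effect_size`` (alternating signs, then
re-projected to SPD). Per-subject heterogeneity is a small random symmetric
covariance perturbation; acquisition sites differ by a multiplicative
variance scaling, mimicking scanner/protocol gain differences without
touching the correlation structure that carries the class signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .data_io import RoiTimeSeries

_SPD_FLOOR = 1e-6


@dataclass
class SyntheticSpec:
    """Study-condition knobs for cohort generation.

    Defaults describe the standard test cohort: 16 ROIs, 100 subjects per
    class over 3 sites, T=150 timepoints, covariance effect 0.4 planted among
    four signal regions.
    """

    n_subjects_per_class: int = 100
    n_rois: int = 16
    n_timepoints: int = 150
    signal_regions: tuple[int, ...] = (2, 5, 9, 12)
    effect_size: float = 0.4
    n_sites: int = 3
    site_shift: float = 0.1
    subject_noise: float = 0.05
    ar_coefficient: float = 0.0  # optional AR(1) temporal smoothing, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if any(not 0 <= r < self.n_rois for r in self.signal_regions):
            raise ValueError("signal_regions must lie in [0, n_rois)")
        if self.n_subjects_per_class < 1 or self.n_sites < 1:
            raise ValueError("need at least one subject per class and one site")


def _project_spd(m: np.ndarray, floor: float = _SPD_FLOOR) -> np.ndarray:
    """Eigenvalue clipping at ``floor``; raises if the input is wildly broken."""
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    if not np.isfinite(w).all():
        raise ValueError("SPD projection failed: non-finite eigenvalues")
    return (v * np.clip(w, floor, None)) @ v.T


def _base_covariance(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random sparse partial-correlation structure, inverted and normalized
    to unit diagonal."""
    prec = np.eye(n)
    for i, j in combinations(range(n), 2):
        if rng.random() < 0.15:
            val = rng.uniform(0.1, 0.3) * rng.choice([-1.0, 1.0])
            prec[i, j] = prec[j, i] = val
    w = np.linalg.eigvalsh(prec).min()
    if w < 0.1:
        prec += (0.1 - w) * np.eye(n)
    cov = np.linalg.inv(prec)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def class_covariances(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(ASD covariance, HC covariance): shared base plus the planted block."""
    base = _base_covariance(spec.n_rois, rng)
    delta = np.zeros_like(base)
    for idx, (i, j) in enumerate(combinations(sorted(spec.signal_regions), 2)):
        sign = 1.0 if idx % 2 == 0 else -1.0
        delta[i, j] = delta[j, i] = sign * spec.effect_size
    cov_hc = _project_spd(base)
    cov_asd = _project_spd(base + delta)
    return cov_asd, cov_hc


def generate_cohort(spec: SyntheticSpec) -> tuple[list[RoiTimeSeries], dict]:
    """Emit the cohort and a ground-truth record.

    Subjects alternate sites round-robin within each class so every site sees
    both classes (needed by leave-one-site-out). All randomness flows from
    ``spec.seed``; identical specs give bit-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    cov_asd, cov_hc = class_covariances(spec, rng)
    site_factors = 1.0 + spec.site_shift * np.linspace(-1.0, 1.0, spec.n_sites)

    cohort: list[RoiTimeSeries] = []
    for label, class_cov in (("ASD", cov_asd), ("HC", cov_hc)):
        for s in range(spec.n_subjects_per_class):
            site_idx = s % spec.n_sites
            noise = rng.standard_normal((spec.n_rois, spec.n_rois))
            subj_cov = class_cov + spec.subject_noise * 0.5 * (noise + noise.T)
            subj_cov = _project_spd(subj_cov) * site_factors[site_idx]
            chol = np.linalg.cholesky(subj_cov)
            z = rng.standard_normal((spec.n_timepoints, spec.n_rois))
            if spec.ar_coefficient > 0:
                for t in range(1, spec.n_timepoints):
                    z[t] = spec.ar_coefficient * z[t - 1] + np.sqrt(
                        1.0 - spec.ar_coefficient**2
                    ) * z[t]
            signal = z @ chol.T
            cohort.append(
                RoiTimeSeries(
                    subject_id=f"{label.lower()}_{s:04d}",
                    site=f"site_{site_idx}",
                    diagnosis=label,
                    signal=signal,
                    atlas_name=f"synthetic{spec.n_rois}",
                )
            )
    ground_truth = {
        "cov_asd": cov_asd,
        "cov_hc": cov_hc,
        "signal_regions": tuple(sorted(spec.signal_regions)),
        "site_factors": site_factors,
        "spec": spec,
    }
    return cohort, ground_truth


# ---------------------------------------------------------------------------
# Hand-checkable worked example
# ---------------------------------------------------------------------------

# 4-ROI class means chosen so the pairwise row distances are sqrt(2), sqrt(5)
# and sqrt(8): small enough to verify the KNN template by hand.
ASD_MEAN = np.array(
    [
        [0.0, 1.0, 0.0, 0.0],
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 2.0],
        [0.0, 0.0, 2.0, 0.0],
    ]
)
HC_MEAN = np.array(
    [
        [1.0, 0.5, 0.0, 0.0],
        [0.5, 1.0, 0.5, 0.0],
        [0.0, 0.5, 1.0, 0.5],
        [0.0, 0.0, 0.5, 1.0],
    ]
)

# symmetric perturbations with zero class mean (+d, -d per pair of subjects)
_DELTA_A = np.array(
    [
        [0.0, 0.2, 0.0, 0.1],
        [0.2, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.2],
        [0.1, 0.0, 0.2, 0.0],
    ]
)
_DELTA_B = np.array(
    [
        [0.0, 0.0, 0.3, 0.0],
        [0.0, 0.0, 0.1, 0.0],
        [0.3, 0.1, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0],
    ]
)


def generate_worked_example() -> dict:
    """Deterministic 4-ROI, 8-subject toy cohort of connectivity matrices.

    The class means of the returned matrices equal :data:`ASD_MEAN` /
    :data:`HC_MEAN` exactly (subjects come in +delta / -delta pairs), so
    template construction on this example is fully hand-checkable.
    """
    from .connectivity import ConnectivityMatrix

    subjects = []
    for label, mean in (("ASD", ASD_MEAN), ("HC", HC_MEAN)):
        for i, delta in enumerate((_DELTA_A, -_DELTA_A, _DELTA_B, -_DELTA_B)):
            subjects.append(
                ConnectivityMatrix(f"{label.lower()}_toy_{i}", "tangent", mean + delta)
            )
    return {
        "subjects": subjects,
        "labels": ["ASD"] * 4 + ["HC"] * 4,
        "asd_mean": ASD_MEAN.copy(),
        "hc_mean": HC_MEAN.copy(),
    }
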