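"""Per-subject functional-connectivity features.

Three feature kinds are supported: Pearson correlation, Ledoit-Wolf shrunk
covariance, and tangent-space embedding of covariances at an affine-invariant
geometric-mean reference. Covariances (SPD by shrinkage) are the input to the
tangent embedding; the reference is fitted on training subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import ledoit_wolf as _sk_ledoit_wolf

from .data_io import RoiTimeSeries

_SYM_TOL = 1e-10


@dataclass
class ConnectivityMatrix:
    """An N x N symmetric feature matrix for one subject."""

    subject_id: str
    kind: str  # "correlation" | "covariance" | "tangent"
    values: np.ndarray
    shrinkage: float | None = None  # Ledoit-Wolf alpha, covariance kind only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"subject {self.subject_id}: connectivity must be square")
        if not np.isfinite(v).all():
            raise ValueError(f"subject {self.subject_id}: non-finite connectivity values")
        if np.abs(v - v.T).max() > _SYM_TOL:
            raise ValueError(f"subject {self.subject_id}: connectivity not symmetric")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class TangentReference:
    """Reference point for tangent embedding: the mean covariance G and its
    inverse square root (the whitener) G^{-1/2}."""

    mean_cov: np.ndarray
    whitener: np.ndarray
    fitted_on: list[str] = field(default_factory=list)
    mean_kind: str = "geometric"


def _check_spd(m: np.ndarray, what: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if np.abs(m - m.T).max() > 1e-8:
        raise ValueError(f"{what}: matrix not symmetric")
    w = np.linalg.eigvalsh(m)
    if w.min() <= 0:
        raise ValueError(f"{what}: matrix not positive definite (min eigenvalue {w.min():.3g})")
    return 0.5 * (m + m.T)


def _spd_pow(m: np.ndarray, power: float) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    return (v * w**power) @ v.T


def _sym_logm(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    if w.min() <= 0:
        raise ValueError("matrix logarithm requires a positive-definite argument")
    return (v * np.log(w)) @ v.T


def _sym_expm(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    return (v * np.exp(w)) @ v.T


def ledoit_wolf_covariance(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Ledoit-Wolf shrunk covariance (1-a) S + a (tr S / N) I of the de-meaned
    signal; the shrinkage intensity a in [0, 1] is chosen by the Ledoit-Wolf
    oracle formula, which makes the estimate well-conditioned (SPD for a > 0)
    even when T < N."""
    x = ts.signal
    if not np.isfinite(x).all():
        raise ValueError(f"subject {ts.subject_id}: non-finite signal")
    cov, alpha = _sk_ledoit_wolf(x - x.mean(axis=0), assume_centered=True)
    cov = 0.5 * (cov + cov.T)
    return ConnectivityMatrix(ts.subject_id, "covariance", cov, shrinkage=float(alpha))


def pearson_correlation(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation matrix with unit diagonal; fails on zero-variance ROIs."""
    x = ts.signal
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"subject {ts.subject_id}: zero-variance ROI(s) {dead.tolist()}, "
            "correlation undefined"
        )
    corr = np.corrcoef(x, rowvar=False)
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(ts.subject_id, "correlation", corr)


def fit_tangent_reference(
    covs: list[ConnectivityMatrix],
    mean_kind: str = "geometric",
    tol: float = 1e-6,
    max_iter: int = 50,
) -> TangentReference:
    """Fit the tangent-space reference point on TRAINING covariances.

    ``geometric``: affine-invariant (Karcher) mean by fixed-point iteration
    G <- G^{1/2} exp( mean_i log(G^{-1/2} C_i G^{-1/2}) ) G^{1/2},
    initialized at the Euclidean mean, until the Frobenius norm of the update
    step drops below ``tol``. ``euclidean``: the arithmetic mean.
    """
    if not covs:
        raise ValueError("need at least one covariance to fit a tangent reference")
    mats = [_check_spd(c.values, f"subject {c.subject_id}") for c in covs]
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("covariances have inconsistent sizes")
    stack = np.stack(mats)

    g = stack.mean(axis=0)
    if mean_kind == "euclidean":
        pass
    elif mean_kind == "geometric":
        for it in range(max_iter):
            g_isqrt = _spd_pow(g, -0.5)
            g_sqrt = _spd_pow(g, 0.5)
            whitened = g_isqrt @ stack @ g_isqrt
            logs = np.stack([_sym_logm(w) for w in whitened])
            step = logs.mean(axis=0)
            g = g_sqrt @ _sym_expm(step) @ g_sqrt
            g = 0.5 * (g + g.T)
            if np.linalg.norm(step, "fro") < tol:
                break
        else:
            raise RuntimeError(
                f"geometric mean did not converge in {max_iter} fixed-point iterations"
            )
    else:
        raise ValueError(f"unknown tangent mean kind {mean_kind!r}")

    whitener = _spd_pow(g, -0.5)
    return TangentReference(
        mean_cov=g,
        whitener=whitener,
        fitted_on=[c.subject_id for c in covs],
        mean_kind=mean_kind,
    )


def tangent_embed(cov: ConnectivityMatrix, ref: TangentReference) -> ConnectivityMatrix:
    """Project an SPD covariance to the tangent space at the reference:
    logm(G^{-1/2} C G^{-1/2}). Zero matrix iff C equals the reference."""
    c = _check_spd(cov.values, f"subject {cov.subject_id}")
    t = _sym_logm(ref.whitener @ c @ ref.whitener.T)
    return ConnectivityMatrix(cov.subject_id, "tangent", 0.5 * (t + t.T))


def tangent_unembed(tangent: ConnectivityMatrix, ref: TangentReference) -> ConnectivityMatrix:
    """Inverse of :func:`tangent_embed`: G^{1/2} expm(T) G^{1/2}."""
    g_sqrt = _spd_pow(ref.mean_cov, 0.5)
    c = g_sqrt @ _sym_expm(tangent.values) @ g_sqrt
    return ConnectivityMatrix(tangent.subject_id, "covariance", 0.5 * (c + c.T))
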