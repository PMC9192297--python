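"""Riemannian potato: covariance-based outlier gating of EEG epochs.

Each 2 s epoch is summarized by its channel covariance matrix, a point on
the manifold of symmetric positive-definite (SPD) matrices.  Clean EEG
epochs cluster around a reference covariance (the Fréchet mean under the
affine-invariant metric); artifact-contaminated epochs sit far from it.
The "potato" is the acceptance region: an epoch whose z-scored log
geodesic distance from the reference exceeds a threshold is labeled
abnormal.

The affine-invariant geodesic distance between SPD matrices A and B is

    delta(A, B) = || logm(A^{-1/2} B A^{-1/2}) ||_F
                = sqrt( sum_i log^2 lambda_i ),

with lambda_i the eigenvalues of A^{-1} B.  It is invariant under any
congruence C -> W^T C W with invertible W, so the gate does not depend on
channel scaling or linear remixing.  The Fréchet (geometric) mean is
computed by the standard fixed-point iteration in the tangent space at
the current estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg as sla

from .io import Recording, segment_epochs

__all__ = [
    "SPDMatrix",
    "PotatoModel",
    "epoch_covariance",
    "riemann_distance",
    "riemann_mean",
    "fit_potato",
    "apply_potato",
    "partition_record",
]

#: z-score assigned when the geodesic distance to the reference is zero
#: (log distance is -inf); keeps downstream arithmetic finite.
Z_FLOOR = -10.0

#: below this, the log-distance spread carries no outlier evidence and
#: nothing is flagged.
SIGMA_DEGENERATE = 1e-12


@dataclass
class SPDMatrix:
    """A symmetric positive-definite matrix (µV² for covariances)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("SPD matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("matrix is not symmetric (tolerance 1e-10)")
        v = 0.5 * (v + v.T)
        lam_min = float(np.linalg.eigvalsh(v)[0])
        if lam_min <= 0:
            raise ValueError(
                f"matrix is not positive definite (min eigenvalue {lam_min:g})"
            )
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class PotatoModel:
    """Fitted potato: reference mean plus log-distance statistics.

    An epoch with covariance C is abnormal iff
    ``(log delta(reference, C) - mu_logd) / sigma_logd > z_threshold``
    (strict inequality; a point exactly on the threshold is normal).
    """

    reference: SPDMatrix
    mu_logd: float
    sigma_logd: float
    z_threshold: float = 2.5
    n_fit: int = 0

    def __post_init__(self) -> None:
        if self.sigma_logd < 0:
            raise ValueError("sigma_logd must be >= 0")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


def epoch_covariance(epoch_data: np.ndarray, shrinkage: float = 1e-3) -> SPDMatrix:
    """Shrunk sample covariance of one epoch.

    Rows are channels.  The sample covariance C of the row-demeaned data
    is blended toward a scaled identity:
    ``(1 - lambda) C + lambda (tr C / n) I``.  A small shrinkage keeps
    the 10x10 estimate from 512 samples safely positive definite even
    for linearly dependent channels.
    """
    x = np.asarray(epoch_data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 channels")
    n_ch, n_s = x.shape
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must be in [0, 1]")
    if n_s < n_ch and shrinkage == 0:
        raise ValueError(
            f"{n_s} samples < {n_ch} channels: covariance singular "
            "without shrinkage"
        )
    xc = x - x.mean(axis=1, keepdims=True)
    c = (xc @ xc.T) / n_s
    c = (1.0 - shrinkage) * c + shrinkage * (np.trace(c) / n_ch) * np.eye(n_ch)
    return SPDMatrix(c)


def _vals(m: SPDMatrix | np.ndarray) -> np.ndarray:
    return m.values if isinstance(m, SPDMatrix) else np.asarray(m, dtype=float)


def riemann_distance(a: SPDMatrix, b: SPDMatrix) -> float:
    """Affine-invariant geodesic distance between two SPD matrices."""
    av, bv = _vals(a), _vals(b)
    if av.shape != bv.shape:
        raise ValueError(f"dimension mismatch: {av.shape} vs {bv.shape}")
    # eigenvalues of A^{-1} B via the generalized problem B v = lam A v
    lam = sla.eigvalsh(bv, av)
    if np.any(lam <= 0):
        raise ValueError("inputs are not both positive definite")
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def _sqrtm_spd(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, q = np.linalg.eigh(v)
    if lam[0] <= 0:
        raise ValueError("matrix is not positive definite")
    s = np.sqrt(lam)
    return (q * s) @ q.T, (q / s) @ q.T  # sqrt and inverse sqrt


def _logm_sym(v: np.ndarray) -> np.ndarray:
    lam, q = np.linalg.eigh(v)
    return (q * np.log(lam)) @ q.T


def _expm_sym(v: np.ndarray) -> np.ndarray:
    lam, q = np.linalg.eigh(v)
    return (q * np.exp(lam)) @ q.T


def riemann_mean(
    covs: Sequence[SPDMatrix],
    tol: float = 1e-8,
    max_iter: int = 50,
    weights: np.ndarray | None = None,
) -> SPDMatrix:
    """Fréchet (Karcher) mean of SPD matrices under the affine metric.

    Fixed-point iteration: map all matrices to the tangent space at the
    current estimate M, average, and map back:
    ``M <- M^{1/2} exp(mean_i log(M^{-1/2} C_i M^{-1/2})) M^{1/2}``,
    stopping when the tangent mean's Frobenius norm drops below ``tol``.
    Initialized at the arithmetic mean.  Warns and returns the best
    iterate on non-convergence.
    """
    if len(covs) == 0:
        raise ValueError("cannot average an empty set of matrices")
    mats = [_vals(c) for c in covs]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("matrices must share a common dimension")
    if weights is None:
        w = np.full(len(mats), 1.0 / len(mats))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    m = sum(wi * mi for wi, mi in zip(w, mats))
    # damped fixed-point iteration: halve the step whenever the tangent
    # norm grows, which keeps widely spread sets (artifact outliers)
    # from oscillating
    nu, prev_norm = 1.0, np.inf
    for _ in range(max_iter):
        s, s_inv = _sqrtm_spd(m)
        tangent = sum(
            wi * _logm_sym(s_inv @ ci @ s_inv) for wi, ci in zip(w, mats)
        )
        norm = np.linalg.norm(tangent, "fro")
        if norm < tol:
            break
        if norm > prev_norm:
            nu /= 2.0
        else:
            nu = min(1.0, 1.2 * nu)
        prev_norm = norm
        m = s @ _expm_sym(nu * tangent) @ s.T
    else:
        warnings.warn(
            f"Frechet mean did not converge in {max_iter} iterations "
            f"(residual {norm:.2e})",
            RuntimeWarning,
        )
    return SPDMatrix(0.5 * (m + m.T))


def fit_potato(
    covs: Sequence[SPDMatrix],
    z_threshold: float = 2.5,
    refit_iters: int = 10,
    mean_tol: float = 1e-8,
    mean_max_iter: int = 250,
) -> PotatoModel:
    """Fit the potato by an iterative trimmed Fréchet-mean estimate.

    Starting from all epochs as inliers: compute the Fréchet mean and the
    mean/sd of log geodesic distances on the current inliers, flag epochs
    with z > z_threshold, and repeat until the inlier set is stable (at
    most ``refit_iters`` rounds).  If the log-distance spread collapses
    (all covariances essentially identical) nothing is flagged.
    """
    n = len(covs)
    if n < 8:
        raise ValueError(f"need at least 8 epochs to fit a potato, got {n}")
    inliers = np.ones(n, dtype=bool)
    mu = sigma = 0.0
    reference = None
    for _ in range(refit_iters):
        reference = riemann_mean([covs[i] for i in np.flatnonzero(inliers)],
                                 tol=mean_tol, max_iter=mean_max_iter)
        d = np.array([riemann_distance(reference, c) for c in covs])
        with np.errstate(divide="ignore"):
            logd = np.log(d)
        fit_logd = logd[inliers]
        fit_logd = fit_logd[np.isfinite(fit_logd)]
        if fit_logd.size < 2:
            break
        mu = float(fit_logd.mean())
        sigma = float(fit_logd.std())
        if sigma < SIGMA_DEGENERATE:
            inliers = np.ones(n, dtype=bool)
            sigma = 0.0
            break
        z = (logd - mu) / sigma
        z[~np.isfinite(logd)] = Z_FLOOR
        new_inliers = z <= z_threshold
        if not new_inliers.any():
            raise ValueError("degenerate fit: every epoch flagged as outlier")
        if np.array_equal(new_inliers, inliers):
            break
        inliers = new_inliers
    return PotatoModel(
        reference=reference,
        mu_logd=mu,
        sigma_logd=sigma,
        z_threshold=z_threshold,
        n_fit=int(inliers.sum()),
    )


def apply_potato(model: PotatoModel, cov: SPDMatrix) -> tuple[float, str]:
    """Score one covariance against a fitted potato.

    Returns ``(z, label)`` with label "abnormal" iff z strictly exceeds
    the model threshold.  Zero distance (the reference itself) maps to
    the finite z floor.
    """
    cv = _vals(cov)
    if cv.shape != model.reference.values.shape:
        raise ValueError(
            f"dimension mismatch: {cv.shape} vs {model.reference.values.shape}"
        )
    d = riemann_distance(model.reference, cov)
    if model.sigma_logd < SIGMA_DEGENERATE:
        z = Z_FLOOR
    elif d == 0:
        z = Z_FLOOR
    else:
        z = (np.log(d) - model.mu_logd) / model.sigma_logd
        z = max(z, Z_FLOOR)
    label = "abnormal" if z > model.z_threshold else "normal"
    return float(z), label


def partition_record(
    recording: Recording,
    channels: Sequence[str] | None = None,
    z_threshold: float = 2.5,
    shrinkage: float = 1e-3,
    epoch_s: float = 2.0,
) -> tuple[list[str], np.ndarray, PotatoModel]:
    """Label every epoch of a recording normal/abnormal with one potato.

    The potato is fit unsupervised on all epochs of the record jointly
    (no class information), using the given channel subset (default: all
    channels of the recording).

    Returns ``(labels, z_scores, model)`` with one entry per epoch.
    """
    epochs = segment_epochs(recording, epoch_s)
    chans = list(channels) if channels is not None else list(recording.channel_names)
    covs = []
    for ep in epochs:
        idx = [ep.channel_names.index(c) for c in chans]
        covs.append(epoch_covariance(ep.data[idx], shrinkage=shrinkage))
    model = fit_potato(covs, z_threshold=z_threshold)
    labels, zs = [], np.empty(len(covs))
    for i, c in enumerate(covs):
        z, lab = apply_potato(model, c)
        zs[i] = z
        labels.append(lab)
    return labels, zs, model
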