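"""Common spatial patterns (CSP) for two-class and one-vs-rest filtering.

CSP finds spatial filters w maximizing the variance ratio
w' R_A w / w' R_B w between two classes of trials via joint
diagonalization: whiten the composite covariance R_A + R_B with
P = eps^{-1/2} U0', diagonalize the whitened class-A covariance
P R_A P' = U diag(lambda) U', and take W = U' P. Because whitening sends
R_A + R_B to the identity, the class eigenvalues are complementary
(lambda_A + lambda_B = 1), so filters at both ends of the spectrum are
discriminative. Per-trial features are log normalized variances of the
projected rows. The one-vs-rest extension trains one filter set per
class against the pooled rest and concatenates the feature blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

from .signals import Trial

__all__ = [
    "SpatialFilterBank",
    "class_covariance",
    "whitening_matrix",
    "csp_filters",
    "csp_log_variance",
    "ovr_csp",
]

#: Ridge added (relative to mean eigenvalue) when a composite covariance
#: is numerically rank-deficient.
_REG_SCALE = 1e-10


def class_covariance(trials: Sequence[Trial] | Sequence[np.ndarray]) -> np.ndarray:
    """Average trace-normalized covariance ``mean_i X_i X_i' / tr(X_i X_i')``.

    Trace normalization makes the estimate invariant to per-trial
    amplitude scaling, the standard convention for CSP.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    mats = [t.x if isinstance(t, Trial) else np.asarray(t, dtype=float) for t in trials]
    n_ch = mats[0].shape[0]
    acc = np.zeros((n_ch, n_ch))
    for x in mats:
        if x.shape[0] != n_ch:
            raise ValueError(
                f"inconsistent channel counts: {x.shape[0]} vs {n_ch}"
            )
        c = x @ x.T
        tr = np.trace(c)
        if tr <= 0:
            raise ValueError("degenerate trial with zero power")
        acc += c / tr
    acc /= len(mats)
    return (acc + acc.T) / 2.0  # exact symmetry


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude entry positive (determinism)."""
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


def whitening_matrix(r_sum: np.ndarray, flag: list | None = None) -> np.ndarray:
    """Whitener ``P = eps^{-1/2} U0'`` of a symmetric PSD matrix.

    Satisfies ``P @ r_sum @ P.T == I``. Near-singular input (an
    eigenvalue at or below numerical tolerance) is ridge-regularized by
    ``1e-10 * trace/N`` on the diagonal; if ``flag`` is passed, the
    string ``"regularized"`` is appended to it when this happens.
    """
    r_sum = np.asarray(r_sum, dtype=float)
    n = r_sum.shape[0]
    evals, evecs = linalg.eigh(r_sum)
    tol = max(np.max(np.abs(evals)), 1.0) * np.finfo(float).eps * n
    if np.min(evals) <= tol:
        r_sum = r_sum + (_REG_SCALE * np.trace(r_sum) / n + tol) * np.eye(n)
        evals, evecs = linalg.eigh(r_sum)
        if flag is not None:
            flag.append("regularized")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], _fix_signs(evecs[:, order])
    return (evecs / np.sqrt(evals)).T


def csp_filters(r_a: np.ndarray, r_b: np.ndarray) -> np.ndarray:
    """Spatial filter matrix ``W = U' P`` for class covariances R_A, R_B.

    Rows are ordered by descending eigenvalue of the whitened class-A
    covariance, i.e. the first filters maximize class-A variance and the
    last maximize class-B variance.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if r_a.shape != r_b.shape or r_a.shape[0] != r_a.shape[1]:
        raise ValueError("covariances must be square and identically sized")
    p = whitening_matrix(r_a + r_b)
    s_a = p @ r_a @ p.T
    evals, evecs = linalg.eigh((s_a + s_a.T) / 2.0)
    order = np.argsort(evals)[::-1]
    u = _fix_signs(evecs[:, order])
    return u.T @ p


def csp_log_variance(trial: Trial | np.ndarray, w: np.ndarray) -> np.ndarray:
    """Log normalized variance features of a CSP-projected trial.

    ``f_p = log(var(z_p) / sum_q var(z_q))`` with ``Z = W X``; the
    normalization makes the features invariant to global trial scaling
    and the exponentials of the features sum to one.
    """
    x = trial.x if isinstance(trial, Trial) else np.asarray(trial, dtype=float)
    if w.shape[1] != x.shape[0]:
        raise ValueError(
            f"filter matrix expects {w.shape[1]} channels, trial has {x.shape[0]}"
        )
    z = w @ x
    v = z.var(axis=1)
    total = v.sum()
    if total <= 0:
        raise ValueError("degenerate trial: zero variance after projection")
    return np.log(v / total)


@dataclass
class SpatialFilterBank:
    """Per-class one-vs-rest CSP projections plus training metadata."""

    filters_per_class: list[np.ndarray]
    classes: list[int]
    n_channels: int
    n_filters: int  # rows retained per class matrix

    def transform(self, trial: Trial | np.ndarray) -> np.ndarray:
        """Concatenated log-variance feature blocks, one per class (length
        ``n_classes * n_filters``)."""
        return np.concatenate(
            [csp_log_variance(trial, w) for w in self.filters_per_class]
        )

    def feature_blocks(self, trial: Trial | np.ndarray) -> list[np.ndarray]:
        return [csp_log_variance(trial, w) for w in self.filters_per_class]


def ovr_csp(
    trials: Sequence[Trial],
    n_classes: int = 4,
    n_filters: int | None = None,
) -> SpatialFilterBank:
    """Fit one-vs-rest CSP filter banks on labelled trials.

    For each class k, CSP is computed between the class-k trials and the
    pooled remaining trials. By default all N filters per class are
    retained, so a trial maps to a spatial feature vector of length
    ``n_classes * N``; pass ``n_filters=2m`` to keep only the m most
    discriminative filters from each end of the eigenvalue spectrum.
    """
    labels = sorted({t.label for t in trials})
    expected = list(range(n_classes))
    if labels != expected:
        missing = sorted(set(expected) - set(labels))
        raise ValueError(f"classes {missing} absent from training labels")
    n_ch = trials[0].n_channels
    filters: list[np.ndarray] = []
    for k in expected:
        in_class = [t for t in trials if t.label == k]
        rest = [t for t in trials if t.label != k]
        r_a = class_covariance(in_class)
        r_b = class_covariance(rest)
        w = csp_filters(r_a, r_b)
        if n_filters is not None and n_filters < n_ch:
            m = n_filters // 2
            keep = list(range(m)) + list(range(n_ch - (n_filters - m), n_ch))
            w = w[keep]
        filters.append(w)
    return SpatialFilterBank(filters, expected, n_ch, filters[0].shape[0])
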