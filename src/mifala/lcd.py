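"""Local characteristic-scale decomposition (LCD) into intrinsic scale components.

LCD is an adaptive, extrema-driven decomposition in the empirical-mode
family. A signal is split into intrinsic scale components (ISCs) plus a
residue,

    x(t) = sum_p ISC_p(t) + u_n(t),

where each ISC oscillates symmetrically about a local mean built from
its extrema (no "riding waves") and components are extracted from the
highest local frequency downward. Each candidate component is refined by
sifting: repeatedly subtracting the extrema-based local mean curve until
a Cauchy-style standard-deviation criterion

    SD = sum_t |h_k(t) - h_{k-1}(t)|^2 / h_{k-1}(t)^2

falls below a threshold. For EEG classification the first few ISCs of
selected sensorimotor channels are summarized by log sub-band powers in
the 8-30 Hz range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

__all__ = [
    "SiftConfig",
    "ISCDecomposition",
    "MonotoneSignalError",
    "local_extrema",
    "local_mean_curve",
    "compute_sd",
    "sift_isc",
    "lcd_decompose",
    "isc_feature_vector",
]


class MonotoneSignalError(ValueError):
    """Raised when a signal has too few extrema to define a local mean."""


@dataclass
class SiftConfig:
    """Sifting controls.

    sd_threshold : stop sifting once SD drops below this (0.3 is the
        conventional range for Cauchy-type sifting criteria).
    max_sift_iters : hard cap on sifting iterations per component.
    max_components : number of ISCs to extract before everything left
        becomes the residue; 3 keeps the decomposition cheap while
        capturing the dominant EEG rhythms.
    baseline_ratio : weight ``a`` mixing the straight-line value L_k and
        the extremum X_k into the local-mean control point
        ``a*L_k + (1-a)*X_k``; 0.5 is the standard choice.
    """

    sd_threshold: float = 0.3
    max_sift_iters: int = 30
    max_components: int = 3
    baseline_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.max_components < 1:
            raise ValueError("max_components must be at least 1")
        if not 0 < self.baseline_ratio < 1:
            raise ValueError("baseline_ratio must lie in (0, 1)")
        if self.max_sift_iters < 1:
            raise ValueError("max_sift_iters must be at least 1")


@dataclass
class ISCDecomposition:
    """Ordered intrinsic scale components plus residue for one signal."""

    components: list[np.ndarray]
    residue: np.ndarray
    sd_trace: list[list[float]] = field(default_factory=list)
    max_iters_hit: list[bool] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for c in self.components:
            out += c
        return out

    def to_matrix(self) -> np.ndarray:
        """Rows ISC_1..ISC_n then the residue, for delimited-text export."""
        return np.vstack(self.components + [self.residue])


class SDResult(NamedTuple):
    value: float
    n_skipped: int


def local_extrema(x: np.ndarray) -> np.ndarray:
    """Indices of strict-ish interior extrema, plateaus collapsed to centers.

    A plateau bounded by a rise on one side and a fall on the other (or
    vice versa) counts as a single extremum at its middle sample.
    """
    x = np.asarray(x, dtype=float)
    d = np.diff(x)
    # signs of nonzero slopes, with plateaus inheriting the previous slope
    idx: list[int] = []
    nz = np.nonzero(d)[0]
    if nz.size < 2:
        return np.array([], dtype=int)
    prev_i = nz[0]
    prev_s = np.sign(d[prev_i])
    for i in nz[1:]:
        s = np.sign(d[i])
        if s != prev_s:
            # extremum spans samples prev_i+1 .. i (plateau center)
            idx.append((prev_i + 1 + i) // 2)
            prev_s = s
        prev_i = i
    return np.asarray(idx, dtype=int)


def _control_points(
    x: np.ndarray, ext: np.ndarray, a: float
) -> tuple[np.ndarray, np.ndarray]:
    """Local-mean control points at extrema, with mirrored end extrema.

    For consecutive extrema (tau_{k-1}, X_{k-1}), (tau_k, X_k),
    (tau_{k+1}, X_{k+1}) the control value at tau_k is
    ``a*L_k + (1-a)*X_k`` where L_k is the value at tau_k of the chord
    joining the neighbouring extrema. The boundary extrema are handled
    by mirror extension of the two nearest extrema about each end.
    """
    tau = ext.astype(float)
    X = x[ext]
    # mirror the two nearest extrema about each endpoint of the index axis
    tau_ext = np.concatenate(([2 * tau[0] - tau[1]], tau, [2 * tau[-1] - tau[-2]]))
    X_ext = np.concatenate(([X[1]], X, [X[-2]]))
    L = X_ext[:-2] + (X_ext[2:] - X_ext[:-2]) * (
        (tau_ext[1:-1] - tau_ext[:-2]) / (tau_ext[2:] - tau_ext[:-2])
    )
    ctrl = a * L + (1 - a) * X
    return tau, ctrl


def local_mean_curve(x: np.ndarray, baseline_ratio: float = 0.5) -> np.ndarray:
    """Extrema-based local-mean (baseline) curve of ``x``.

    Control points at each extremum are joined by linear interpolation
    and extended to the signal ends with the boundary control values.
    Raises :class:`MonotoneSignalError` for signals with fewer than 3
    extrema, which have no oscillation to demodulate.
    """
    x = np.asarray(x, dtype=float)
    ext = local_extrema(x)
    if ext.size < 3:
        raise MonotoneSignalError(
            f"need at least 3 local extrema, found {ext.size}"
        )
    tau, ctrl = _control_points(x, ext, baseline_ratio)
    t = np.arange(x.size, dtype=float)
    return np.interp(t, tau, ctrl)


def compute_sd(h_k: np.ndarray, h_km1: np.ndarray) -> SDResult:
    """Sifting stop statistic between consecutive iterates.

    ``SD = sum_t |h_k - h_km1|^2 / h_km1^2``. Samples where the previous
    iterate is zero are undefined and skipped; the count of skipped
    terms is returned alongside the value.
    """
    h_k = np.asarray(h_k, dtype=float)
    h_km1 = np.asarray(h_km1, dtype=float)
    if h_k.shape != h_km1.shape:
        raise ValueError("iterates must have identical shapes")
    nz = h_km1 != 0.0
    n_skipped = int(h_km1.size - np.count_nonzero(nz))
    diff = h_k[nz] - h_km1[nz]
    value = float(np.sum((diff * diff) / (h_km1[nz] * h_km1[nz])))
    return SDResult(value, n_skipped)


def sift_isc(
    x: np.ndarray, cfg: SiftConfig | None = None
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Extract one ISC from ``x`` by iterative local-mean subtraction.

    Returns ``(isc, remainder, sd_trace)`` with ``isc + remainder == x``
    by construction. Iteration stops when SD drops below
    ``cfg.sd_threshold`` or after ``cfg.max_sift_iters`` passes.
    """
    cfg = cfg or SiftConfig()
    x = np.asarray(x, dtype=float)
    h = x - local_mean_curve(x, cfg.baseline_ratio)  # first sift
    sd_trace: list[float] = []
    for _ in range(cfg.max_sift_iters - 1):
        try:
            mean = local_mean_curve(h, cfg.baseline_ratio)
        except MonotoneSignalError:
            break
        h_next = h - mean
        sd = compute_sd(h_next, h).value
        sd_trace.append(sd)
        h = h_next
        if sd < cfg.sd_threshold:
            break
    return h, x - h, sd_trace


def lcd_decompose(x: np.ndarray, cfg: SiftConfig | None = None) -> ISCDecomposition:
    """Full LCD of a 1-D signal into up to ``cfg.max_components`` ISCs.

    Components come out highest-local-frequency first; decomposition
    stops early when the remainder runs out of extrema (fewer than 3),
    in which case it becomes the residue. A signal that is monotone or
    constant from the start yields zero components.
    """
    cfg = cfg or SiftConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("signal too short to decompose (need >= 10 samples)")
    components: list[np.ndarray] = []
    traces: list[list[float]] = []
    hit_flags: list[bool] = []
    residue = x.copy()
    for _ in range(cfg.max_components):
        if local_extrema(residue).size < 3:
            break
        isc, residue, trace = sift_isc(residue, cfg)
        components.append(isc)
        traces.append(trace)
        hit_flags.append(bool(trace) and trace[-1] >= cfg.sd_threshold)
    return ISCDecomposition(components, residue, traces, hit_flags)


def isc_feature_vector(
    isc: np.ndarray,
    fs: float,
    n_features: int = 20,
    band: tuple[float, float] = (8.0, 30.0),
    power_floor: float = 1e-12,
) -> np.ndarray:
    """Log sub-band power descriptor of one ISC.

    The Welch power spectral density is integrated over ``n_features``
    equal-width sub-bands spanning ``band`` (8-30 Hz by default, the
    mu/beta range whose event-related power changes carry the motor
    imagery information) and log10-transformed with a floor of
    ``power_floor`` so all-zero components stay finite.
    """
    isc = np.asarray(isc, dtype=float)
    if isc.size < 2 * n_features:
        raise ValueError(
            f"ISC of {isc.size} samples too short for {n_features} features"
        )
    freqs, psd = sps.welch(isc, fs=fs, nperseg=min(isc.size, 256))
    edges = np.linspace(band[0], band[1], n_features + 1)
    out = np.empty(n_features)
    for i in range(n_features):
        hi_inclusive = i == n_features - 1
        sel = (freqs >= edges[i]) & (
            (freqs <= edges[i + 1]) if hi_inclusive else (freqs < edges[i + 1])
        )
        out[i] = np.log10(max(float(np.sum(psd[sel])), power_floor))
    return out
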