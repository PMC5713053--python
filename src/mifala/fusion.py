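"""Channel augmentation and serial fusion of spectral and spatial features.

The feature construction stacks the raw channels with the intrinsic
scale components of a few sensorimotor channels (by default 3 ISCs each
for C3, C4 and Cz, turning 22 channels into 31 augmented "channels"),
extracts a frequency-domain block F1 (log sub-band powers of each ISC,
K components x P bands) and a spatial block F2 (one-vs-rest CSP
log-variances over the augmented channels, 4N values), and serially
fuses them: every constituent sub-vector is scaled to unit Euclidean
norm and the blocks are concatenated,

    F = [f_11/||f_11||, ..., f_1K/||f_1K||, f^1/||f^1||, ..., f^4/||f^4||].

With the defaults (K=9 ISCs, P=20 bands, N=31 augmented channels) the
fused vector has K*P + 4N = 304 entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .csp import SpatialFilterBank, ovr_csp
from .lcd import SiftConfig, lcd_decompose, isc_feature_vector
from .signals import Trial

__all__ = [
    "DEFAULT_LCD_CHANNELS",
    "FeatureVector",
    "augment_channels",
    "extract_f1",
    "serial_fuse",
    "FeatureExtractor",
]

DEFAULT_LCD_CHANNELS = ("C3", "C4", "Cz")


@dataclass
class FeatureVector:
    """Fused feature vector with its block structure."""

    f1_block: np.ndarray
    f2_block: np.ndarray
    fused: np.ndarray
    #: name -> (start, stop) into ``fused`` for every normalized sub-vector
    block_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)


def _channel_index(trial: Trial, name: str) -> int:
    if trial.channel_names is None:
        raise ValueError("trial has no channel names; cannot resolve " + name)
    try:
        return trial.channel_names.index(name)
    except ValueError as exc:
        raise ValueError(f"channel {name!r} not present in trial") from exc


def _decompose_channels(
    trial: Trial, lcd_channels: Sequence[str], cfg: SiftConfig
) -> list[tuple[str, list[np.ndarray]]]:
    """Per selected channel: exactly ``cfg.max_components`` ISC rows.

    If the decomposition terminates early (signal runs out of extrema)
    the missing components are zero rows, keeping K fixed so feature
    dimensions never depend on the data.
    """
    out = []
    for name in lcd_channels:
        row = trial.x[_channel_index(trial, name)]
        dec = lcd_decompose(row, cfg)
        comps = list(dec.components)
        while len(comps) < cfg.max_components:
            comps.append(np.zeros_like(row))
        out.append((name, comps[: cfg.max_components]))
    return out


def augment_channels(
    trial: Trial,
    lcd_channels: Sequence[str] = DEFAULT_LCD_CHANNELS,
    cfg: SiftConfig | None = None,
) -> Trial:
    """Stack the original channels with per-channel ISC rows.

    Output row order is the n original channels followed by the ISCs in
    channel-major order (C3-ISC1..3, C4-ISC1..3, Cz-ISC1..3 with the
    defaults); ISC rows are named ``"<channel>.isc<p>"``.
    """
    cfg = cfg or SiftConfig()
    if not lcd_channels:
        return trial
    rows = [trial.x]
    names = list(trial.channel_names or [])
    for name, comps in _decompose_channels(trial, lcd_channels, cfg):
        rows.append(np.vstack(comps))
        names.extend(f"{name}.isc{p + 1}" for p in range(cfg.max_components))
    return Trial(np.vstack(rows), trial.label, names or None)


def extract_f1(
    trial: Trial,
    lcd_channels: Sequence[str] = DEFAULT_LCD_CHANNELS,
    cfg: SiftConfig | None = None,
    fs: float = 250.0,
    n_features: int = 20,
) -> np.ndarray:
    """Frequency-domain block: P log sub-band powers per ISC, concatenated.

    With 3 channels x 3 ISCs x 20 bands this is the length-180 F1 block.
    """
    cfg = cfg or SiftConfig()
    parts = []
    for _, comps in _decompose_channels(trial, lcd_channels, cfg):
        for comp in comps:
            parts.append(isc_feature_vector(comp, fs, n_features))
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def _normalize_blocks(
    v: np.ndarray, block_len: int, label: str
) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    if v.size % block_len:
        raise ValueError(
            f"{label} length {v.size} is not a multiple of sub-vector length {block_len}"
        )
    out = v.astype(float).copy()
    spans = []
    for i in range(v.size // block_len):
        sl = slice(i * block_len, (i + 1) * block_len)
        nrm = np.linalg.norm(out[sl])
        if nrm == 0:
            raise ValueError(f"zero-norm sub-vector {label}[{i}]")
        out[sl] /= nrm
        spans.append((f"{label}{i + 1}", sl.start, sl.stop))
    return out, spans


def serial_fuse(
    f1: np.ndarray, f2: np.ndarray, p: int = 20, n_classes: int = 4
) -> FeatureVector:
    """Serially fuse the spectral and spatial blocks.

    ``f1`` is treated as K sub-vectors of length ``p`` (one per ISC) and
    ``f2`` as ``n_classes`` sub-vectors (one per one-vs-rest filter
    set); each sub-vector is divided by its Euclidean norm, then all are
    concatenated F1-first.
    """
    f1 = np.asarray(f1, dtype=float).ravel()
    f2 = np.asarray(f2, dtype=float).ravel()
    if f1.size == 0 or f2.size == 0:
        raise ValueError("both feature blocks must be non-empty")
    if not (np.all(np.isfinite(f1)) and np.all(np.isfinite(f2))):
        raise ValueError("feature blocks must be finite")
    if f2.size % n_classes:
        raise ValueError(
            f"spatial block length {f2.size} not divisible by {n_classes} classes"
        )
    f1n, spans1 = _normalize_blocks(f1, p, "f1_")
    f2n, spans2 = _normalize_blocks(f2, f2.size // n_classes, "f2_class")
    fused = np.concatenate([f1n, f2n])
    bounds = {name: (a, b) for name, a, b in spans1}
    bounds.update({name: (a + f1n.size, b + f1n.size) for name, a, b in spans2})
    return FeatureVector(f1n, f2n, fused, bounds)


@dataclass
class FeatureExtractor:
    """Fitted CSP-LCD feature pipeline: augment -> F1 + F2 -> fuse.

    The one-vs-rest CSP bank is estimated from training trials only
    (``fit``); LCD and band powers are per-trial operations with no
    fitted state, so ``transform`` can be applied to held-out trials
    without leakage.
    """

    lcd_channels: Sequence[str] = DEFAULT_LCD_CHANNELS
    sift: SiftConfig = field(default_factory=SiftConfig)
    fs: float = 250.0
    n_band_features: int = 20
    n_classes: int = 4
    n_csp_filters: int | None = None
    bank: SpatialFilterBank | None = None

    def fit(self, trials: Sequence[Trial]) -> "FeatureExtractor":
        augmented = [augment_channels(t, self.lcd_channels, self.sift) for t in trials]
        self.bank = ovr_csp(augmented, self.n_classes, self.n_csp_filters)
        return self

    def transform_one(self, trial: Trial) -> FeatureVector:
        if self.bank is None:
            raise RuntimeError("FeatureExtractor must be fitted before transform")
        # decompose once, reuse the ISC rows for both F1 and the augmentation
        decs = _decompose_channels(trial, self.lcd_channels, self.sift)
        f1 = np.concatenate(
            [
                isc_feature_vector(comp, self.fs, self.n_band_features)
                for _, comps in decs
                for comp in comps
            ]
        )
        aug = np.vstack([trial.x] + [np.vstack(comps) for _, comps in decs])
        f2 = self.bank.transform(aug)
        return serial_fuse(f1, f2, self.n_band_features, self.n_classes)

    def transform(self, trials: Sequence[Trial]) -> np.ndarray:
        """Feature matrix (n_trials x D) of fused vectors."""
        return np.vstack([self.transform_one(t).fused for t in trials])

    def fit_transform(self, trials: Sequence[Trial]) -> np.ndarray:
        return self.fit(trials).transform(trials)

    def feature_names(self) -> list[str]:
        """One name per fused entry: block, channel/class, index."""
        if self.bank is None:
            raise RuntimeError("FeatureExtractor must be fitted first")
        names = []
        for ch in self.lcd_channels:
            for p in range(self.sift.max_components):
                for b in range(self.n_band_features):
                    names.append(f"f1.{ch}.isc{p + 1}.band{b + 1}")
        for k in self.bank.classes:
            for j in range(self.bank.n_filters):
                names.append(f"f2.class{k}.filt{j + 1}")
        return names
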