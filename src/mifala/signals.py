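"""Preprocessing and synthetic motor-imagery EEG generation.

Motor imagery modulates sensorimotor rhythms (mu/beta, roughly 8-30 Hz)
over central electrodes; the standard preprocessing for classification
is a band-pass to that range followed by extraction of a short epoch
from each cued trial. This module provides that preprocessing, the
in-memory containers for recordings and epoched trials, a reproducible
synthetic 4-class generator with class-dependent spatial covariance,
and plain-text trial persistence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "RawRecording",
    "Trial",
    "SyntheticConfig",
    "bandpass_filter",
    "notch_filter",
    "epoch_extract",
    "generate_synthetic_mi",
    "save_trials",
    "load_trials",
    "read_edf",
    "generate_synthetic_features",
]

#: Sensorimotor-area electrode labels used for the informative channels
#: of synthetic recordings, in priority order. The first three (C3, C4,
#: Cz) are the conventional hand/foot imagery sites and are the default
#: targets for per-channel time-frequency decomposition downstream.
SENSORIMOTOR_LABELS = (
    "C3", "C4", "Cz", "FC3", "FC4", "FCz", "CP3", "CP4", "CPz",
    "C1", "C2", "C5", "C6", "CP1", "CP2", "FC1", "FC2",
)


@dataclass
class RawRecording:
    """A continuous multi-channel recording with cue events.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel labels, one per row of ``data``.
    events : list of (int, int)
        ``(onset_sample, class_label)`` pairs; onsets are 0-based sample
        indices of the imagery cue.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one channel name per data row required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")


@dataclass
class Trial:
    """One epoched trial: a channels x samples matrix plus class label."""

    x: np.ndarray
    label: int
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("trial matrix must be 2-D (channels x samples)")
        if self.x.shape[1] < 2:
            raise ValueError("trial must contain at least 2 samples")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("trial contains non-finite samples")
        if self.channel_names is not None and len(self.channel_names) != self.x.shape[0]:
            raise ValueError("one channel name per trial row required")

    @property
    def n_channels(self) -> int:
        return self.x.shape[0]

    @property
    def n_samples(self) -> int:
        return self.x.shape[1]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic 4-class motor-imagery generator.

    ``snr`` is the ratio of class-dependent rhythm power to background
    noise power, averaged over the informative channels.
    """

    n_trials_per_class: int = 100
    n_channels: int = 22
    n_informative_channels: int = 4
    fs: float = 250.0
    epoch_seconds: float = 1.0
    snr: float = 2.0
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative_channels > self.n_channels:
            raise ValueError("n_informative_channels must not exceed n_channels")
        if self.n_informative_channels < 1 or self.n_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.fs <= 0 or self.epoch_seconds <= 0:
            raise ValueError("fs and epoch_seconds must be positive")
        if self.n_trials_per_class < 1:
            raise ValueError("need at least one trial per class")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_seconds))

    def channel_names(self) -> list[str]:
        """Informative channels get sensorimotor labels; the rest are numbered."""
        names: list[str] = []
        for i in range(self.n_channels):
            if i < self.n_informative_channels and i < len(SENSORIMOTOR_LABELS):
                names.append(SENSORIMOTOR_LABELS[i])
            else:
                names.append(f"ch{i:02d}")
        return names

    def class_loadings(self) -> np.ndarray:
        """Deterministic per-class rhythm amplitude on each channel.

        Returns an (n_classes, n_channels) array ``A``; class k adds
        ``A[k, c] * s(t)`` to channel c, where ``s`` is a unit-variance
        band-limited rhythm. Each class boosts a different informative
        channel (cyclically), giving distinct spatial covariances, and
        the loadings are scaled so that the mean rhythm power over the
        informative channels equals ``snr`` (background noise has unit
        variance).
        """
        n_inf = self.n_informative_channels
        base = np.zeros((self.n_classes, self.n_channels))
        for k in range(self.n_classes):
            for c in range(n_inf):
                boost = 2.0 if c == k % n_inf else 1.0
                base[k, c] = boost
        # mean squared loading over informative channels -> snr
        for k in range(self.n_classes):
            p = np.mean(base[k, :n_inf] ** 2)
            base[k] *= np.sqrt(self.snr / p)
        return base

    def class_covariance(self, k: int) -> np.ndarray:
        """Population covariance of class ``k`` trials: I + a_k a_k^T."""
        a = self.class_loadings()[k]
        return np.eye(self.n_channels) + np.outer(a, a)


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low: float = 8.0,
    high: float = 30.0,
    order: int = 5,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth band-pass along the last axis.

    Defaults to the 8-30 Hz mu/beta band with a 5th-order design. Offline
    analysis uses forward-backward (zero-phase) filtering; set
    ``zero_phase=False`` for the causal single-pass variant used when
    samples must be processed as they arrive.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band [{low}, {high}] Hz must lie inside (0, fs/2)")
    if x.shape[-1] < 3 * order:
        raise ValueError(
            f"signal too short for order-{order} filter: {x.shape[-1]} samples"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def notch_filter(x: np.ndarray, fs: float, freq: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Narrow notch (IIR) to suppress power-line interference."""
    b, a = sps.iirnotch(freq, q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float), axis=-1)


def epoch_extract(
    rec: RawRecording, t_start_s: float = 2.5, t_end_s: float = 3.5
) -> list[Trial]:
    """Cut one trial per event from a recording.

    The window ``[onset + t_start_s, onset + t_end_s)`` is half-open and
    expressed relative to each event onset; the 2.5-3.5 s default targets
    the early-imagery period of a cue-paced paradigm.
    """
    if t_end_s <= t_start_s:
        raise ValueError("t_end_s must exceed t_start_s")
    n_total = rec.data.shape[1]
    n_win = int(round((t_end_s - t_start_s) * rec.fs))
    trials: list[Trial] = []
    for onset, label in rec.events:
        i0 = onset + int(round(t_start_s * rec.fs))
        i1 = i0 + n_win
        if i0 < 0 or i1 > n_total:
            raise ValueError(
                f"epoch [{i0}, {i1}) outside recording of {n_total} samples"
            )
        trials.append(
            Trial(rec.data[:, i0:i1].copy(), int(label), list(rec.channel_names))
        )
    return trials


def _rhythm(rng: np.random.Generator, n: int, fs: float, n_sines: int = 4) -> np.ndarray:
    """Unit-variance band-limited rhythm: sum of sinusoids in 8-30 Hz."""
    t = np.arange(n) / fs
    freqs = rng.uniform(8.0, 30.0, size=n_sines)
    phases = rng.uniform(0.0, 2 * np.pi, size=n_sines)
    s = np.sum(np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]), axis=0)
    sd = s.std()
    if sd < 1e-12:  # pathological phase cancellation
        s = np.sin(2 * np.pi * 10.0 * t)
        sd = s.std()
    return s / sd


def generate_synthetic_mi(cfg: SyntheticConfig) -> list[Trial]:
    """Generate balanced, labelled synthetic motor-imagery trials.

    Each trial is unit-variance white Gaussian noise on every channel
    plus a shared band-limited rhythm loaded onto the informative
    channels with class-dependent amplitudes (see
    :meth:`SyntheticConfig.class_loadings`). Class-conditional
    covariance is therefore ``I + a_k a_k^T``. Trials are interleaved
    across classes (labels 0,1,...,K-1,0,1,...) and fully reproducible
    from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    names = cfg.channel_names()
    loadings = cfg.class_loadings()
    n = cfg.n_samples
    trials: list[Trial] = []
    for _ in range(cfg.n_trials_per_class):
        for k in range(cfg.n_classes):
            noise = rng.standard_normal((cfg.n_channels, n))
            s = _rhythm(rng, n, cfg.fs)
            x = noise + loadings[k][:, None] * s[None, :]
            trials.append(Trial(x, k, list(names)))
    return trials


def generate_synthetic_features(
    n_per_class: int = 100,
    n_informative: int = 6,
    n_noise: int = 24,
    n_classes: int = 4,
    separation: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature-level benchmark for wrapper feature selection.

    Returns ``(X, y)`` where the first ``n_informative`` columns carry
    class-dependent means (distinct +/-``separation`` sign patterns per
    class over unit-variance Gaussian noise) and the remaining
    ``n_noise`` columns are pure standard-normal distractors. Selecting
    exactly the informative columns is the planted ground truth.
    """
    rng = np.random.default_rng(seed)
    # distinct sign patterns per class: bits of (k+1) cycled over columns
    means = np.zeros((n_classes, n_informative))
    for k in range(n_classes):
        for j in range(n_informative):
            means[k, j] = separation * (1.0 if ((k + 1) >> (j % 3)) & 1 else -1.0)
    n = n_per_class * n_classes
    y = np.tile(np.arange(n_classes), n_per_class)
    x = rng.standard_normal((n, n_informative + n_noise))
    x[:, :n_informative] += means[y]
    return x, y


# ---------------------------------------------------------------------------
# Plain-text persistence: one delimited matrix per trial + a labels file.
# ---------------------------------------------------------------------------

_TRIAL_FMT = "%.17e"  # full double precision -> exact decimal round-trip


def save_trials(trials: Sequence[Trial], directory: str | Path) -> None:
    """Write trials as ``trial_<i>.txt`` matrices plus ``labels.txt``.

    Values are written with 17 significant digits so that reloading
    reproduces the doubles bit-for-bit. Channel names, if present, go in
    a ``channels.txt`` sidecar (shared across trials).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "labels.txt", "w") as fh:
        fh.write("trial_id\tlabel\n")
        for i, tr in enumerate(trials):
            np.savetxt(directory / f"trial_{i:04d}.txt", tr.x, fmt=_TRIAL_FMT)
            fh.write(f"{i}\t{tr.label}\n")
    if trials and trials[0].channel_names is not None:
        (directory / "channels.txt").write_text(
            "\n".join(trials[0].channel_names) + "\n"
        )


def load_trials(directory: str | Path) -> list[Trial]:
    """Inverse of :func:`save_trials`."""
    directory = Path(directory)
    labels: dict[int, int] = {}
    with open(directory / "labels.txt") as fh:
        header = fh.readline()
        if not header.startswith("trial_id"):
            raise ValueError("labels.txt missing 'trial_id\\tlabel' header")
        for line in fh:
            if line.strip():
                tid, lab = line.split()
                labels[int(tid)] = int(lab)
    names: list[str] | None = None
    ch_file = directory / "channels.txt"
    if ch_file.exists():
        names = ch_file.read_text().split()
    trials = []
    for tid in sorted(labels):
        x = np.loadtxt(directory / f"trial_{tid:04d}.txt", ndmin=2)
        trials.append(Trial(x, labels[tid], list(names) if names else None))
    return trials


def read_edf(path: str | Path, event_map: dict[str, int] | None = None) -> RawRecording:
    """Load an EDF/GDF recording into a :class:`RawRecording`.

    Requires the optional ``mne`` dependency. Annotations are mapped to
    integer class labels via ``event_map`` (annotation description ->
    label); unmapped annotations are dropped.
    """
    try:
        import mne  # noqa: PLC0415 -- optional dependency
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF/GDF files requires the optional 'mne' dependency"
        ) from exc
    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events: list[tuple[int, int]] = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        key = str(desc)
        if event_map is not None and key in event_map:
            events.append((int(round(onset * raw.info["sfreq"])), event_map[key]))
        elif event_map is None and re.fullmatch(r"\d+", key):
            events.append((int(round(onset * raw.info["sfreq"])), int(key)))
    return RawRecording(data, float(raw.info["sfreq"]), list(raw.ch_names), events)
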