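"""End-to-end orchestration: preprocess -> features -> select -> classify.

A single :class:`PipelineConfig` describes every stage (band-pass,
epoch window, LCD, CSP, FA-LA selection, SRDA) and the whole run is a
deterministic function of (trials, config). All fitted state — the CSP
filter bank, the selected feature mask, the classifier — is estimated
on training data only and applied unchanged to held-out test data.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .fa_la import FaLaConfig, SelectionResult, run_fa_la, stratified_split
from .fusion import DEFAULT_LCD_CHANNELS, FeatureExtractor
from .lcd import SiftConfig
from .signals import Trial, bandpass_filter
from .srda import Metrics, evaluate, fit_srda, predict_srda

__all__ = ["PipelineConfig", "CVReport", "run_pipeline", "cross_validate"]

logger = logging.getLogger("mifala")


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    band_low: float = 8.0
    band_high: float = 30.0
    filter_order: int = 5
    epoch_start_s: float = 2.5
    epoch_end_s: float = 3.5
    fs: float = 250.0
    lcd_channels: tuple[str, ...] = DEFAULT_LCD_CHANNELS
    sift: SiftConfig = field(default_factory=SiftConfig)
    n_band_features: int = 20
    n_classes: int = 4
    n_csp_filters: int | None = None
    selection: FaLaConfig = field(default_factory=FaLaConfig)
    srda_alpha: float = 0.01
    test_fraction: float = 0.25
    cv_folds: int = 10
    seed: int = 0
    apply_bandpass: bool = True
    select_features: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "sift" in raw and isinstance(raw["sift"], dict):
            raw["sift"] = SiftConfig(**raw["sift"])
        if "selection" in raw and isinstance(raw["selection"], dict):
            raw["selection"] = FaLaConfig(**raw["selection"])
        if "lcd_channels" in raw:
            raw["lcd_channels"] = tuple(raw["lcd_channels"])
        return cls(**raw)

    def extractor(self) -> FeatureExtractor:
        return FeatureExtractor(
            lcd_channels=self.lcd_channels,
            sift=self.sift,
            fs=self.fs,
            n_band_features=self.n_band_features,
            n_classes=self.n_classes,
            n_csp_filters=self.n_csp_filters,
        )


@dataclass
class CVReport:
    """Aggregated cross-validation outcome."""

    fold_metrics: list[Metrics]
    selected_counts: list[int]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([m.accuracy for m in self.fold_metrics])

    @property
    def kappas(self) -> np.ndarray:
        return np.array([m.kappa for m in self.fold_metrics])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.fold_metrics) > 1 else 0.0

    @property
    def mean_kappa(self) -> float:
        return float(self.kappas.mean())


def _preprocess(trials: Sequence[Trial], cfg: PipelineConfig) -> list[Trial]:
    if not cfg.apply_bandpass:
        return list(trials)
    try:
        return [
            Trial(
                bandpass_filter(t.x, cfg.fs, cfg.band_low, cfg.band_high, cfg.filter_order),
                t.label,
                t.channel_names,
            )
            for t in trials
        ]
    except ValueError as exc:
        raise PipelineError("preprocess", str(exc)) from exc


def _check_labels(trials: Sequence[Trial], cfg: PipelineConfig, stage: str) -> None:
    present = {t.label for t in trials}
    missing = set(range(cfg.n_classes)) - present
    if missing:
        raise PipelineError(stage, f"classes {sorted(missing)} missing from data")


def run_pipeline(
    trials: Sequence[Trial],
    cfg: PipelineConfig,
    train_idx: np.ndarray | None = None,
    test_idx: np.ndarray | None = None,
) -> tuple[Metrics, SelectionResult | None]:
    """One train/test run of the full chain.

    Without explicit index arrays the trials are split stratified with
    ``cfg.test_fraction`` held out. Feature extraction (CSP bank), FA-LA
    selection and the final SRDA fit all see training trials only; the
    selected mask and classifier are then applied to the test trials.
    """
    labels = np.array([t.label for t in trials])
    if train_idx is None or test_idx is None:
        rng = np.random.default_rng(cfg.seed)
        try:
            train_idx, test_idx = stratified_split(labels, cfg.test_fraction, rng)
        except ValueError as exc:
            raise PipelineError("split", str(exc)) from exc
    train = [trials[i] for i in train_idx]
    test = [trials[i] for i in test_idx]
    _check_labels(train, cfg, "split")

    train = _preprocess(train, cfg)
    test = _preprocess(test, cfg)

    try:
        extractor = cfg.extractor().fit(train)
        x_train = extractor.transform(train)
        x_test = extractor.transform(test)
    except ValueError as exc:
        raise PipelineError("features", str(exc)) from exc
    y_train = labels[train_idx]
    y_test = labels[test_idx]
    logger.info("feature dimension D = %d", x_train.shape[1])

    selection: SelectionResult | None = None
    if cfg.select_features:
        sel_cfg = cfg.selection
        if sel_cfg.seed != cfg.seed:
            sel_cfg = FaLaConfig(**{**asdict(sel_cfg), "seed": cfg.seed})
        try:
            selection = run_fa_la(x_train, y_train, sel_cfg)
        except ValueError as exc:
            raise PipelineError("selection", str(exc)) from exc
        mask = selection.mask
        logger.info(
            "FA-LA selected %d / %d features (best val accuracy %.3f)",
            selection.selected_count, mask.size, selection.best_accuracy,
        )
    else:
        mask = np.ones(x_train.shape[1], dtype=bool)

    try:
        model = fit_srda(x_train[:, mask], y_train, cfg.srda_alpha)
    except ValueError as exc:
        raise PipelineError("classify", str(exc)) from exc
    pred = predict_srda(model, x_test[:, mask])
    metrics = evaluate(y_test, pred, cfg.n_classes)
    logger.info("test accuracy %.4f, kappa %.4f", metrics.accuracy, metrics.kappa)
    return metrics, selection


def _stratified_folds(
    labels: np.ndarray, folds: int, seed: int
) -> list[np.ndarray]:
    """Deterministic stratified fold assignment: within each class the
    (seed-shuffled) trials are dealt round-robin to folds."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=int)
    for k in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == k))
        assignment[idx] = np.arange(idx.size) % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def cross_validate(
    trials: Sequence[Trial], cfg: PipelineConfig, folds: int | None = None
) -> CVReport:
    """Stratified k-fold evaluation of the full pipeline.

    Every fitted quantity (CSP bank, mask, classifier) is re-estimated
    inside each training fold; the fold test sets partition the data.
    """
    folds = folds or cfg.cv_folds
    labels = np.array([t.label for t in trials])
    _, counts = np.unique(labels, return_counts=True)
    if np.min(counts) < folds:
        raise PipelineError(
            "cv", f"need at least {folds} trials per class, have {np.min(counts)}"
        )
    fold_idx = _stratified_folds(labels, folds, cfg.seed)
    all_idx = np.arange(labels.size)
    metrics_list: list[Metrics] = []
    sel_counts: list[int] = []
    for f, test_idx in enumerate(fold_idx):
        train_idx = np.setdiff1d(all_idx, test_idx)
        logger.info("fold %d/%d: %d train, %d test", f + 1, folds, train_idx.size, test_idx.size)
        m, sel = run_pipeline(trials, cfg, train_idx=train_idx, test_idx=test_idx)
        metrics_list.append(m)
        sel_counts.append(sel.selected_count if sel is not None else -1)
    return CVReport(metrics_list, sel_counts)
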