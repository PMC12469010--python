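"""Subject-wise evaluation: stratified splits, confusion matrices, metrics.

Splitting is at subject granularity — all of a subject's feature rows follow
their subject — so no individual contributes to both train and test sets.
Within each class, subjects are shuffled with a seeded generator and a
round-half-up prefix of size ``fraction * n_class`` is assigned to training,
with at least one train and one test subject enforced per class.

Metrics use autism (ASD) as the positive class. Metrics with a zero
denominator are reported as missing (None), never silently 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ArgumentError, DataError, DegenerateClassError, SubbandFLDAError
from .features import FeatureMatrix, extract_features, stack_features, zscore_apply, zscore_fit
from .flda import FisherLDA, FisherLDAResults
from .shrinkage import denoise
from .signal_io import ASD, NORMAL, CohortManifest, SignalRecord, load_cohort
from .swt import band_of_level, db4_filters, swt_decompose


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, exhaustive train/test partition of subject IDs."""

    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    fraction: float
    seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        train, test = set(self.train_subjects), set(self.test_subjects)
        if train & test:
            raise DataError(f"train/test overlap: {sorted(train & test)}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def subject_wise_split(
    subjects: Mapping[str, str] | Sequence[tuple[str, str]],
    fraction: float = 0.7,
    seed: int = 42,
    *,
    stratified: bool = True,
) -> SplitPlan:
    """Deterministic subject-wise stratified split.

    ``subjects`` maps subject ID -> class label (or is a sequence of such
    pairs). Per class, IDs are sorted, shuffled by a generator seeded with
    ``seed``, and the first ``round(fraction * n_class)`` (half-up) go to
    training; every class keeps at least one subject on each side.
    """
    pairs = list(subjects.items()) if isinstance(subjects, Mapping) else list(subjects)
    if not 0.0 < fraction < 1.0:
        raise ArgumentError(f"fraction must be in (0, 1), got {fraction}")
    by_class: dict[str, list[str]] = {}
    for sid, label in pairs:
        by_class.setdefault(label, []).append(str(sid))
    if len(set(sid for sid, _ in pairs)) != len(pairs):
        raise DataError("duplicate subject IDs")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    groups = by_class.items() if stratified else [("all", [s for s, _ in pairs])]
    for label, ids in sorted(groups):
        if len(ids) < 2:
            raise DegenerateClassError(
                f"class {label!r} has {len(ids)} subject(s); need >= 2 to stratify"
            )
        ids = sorted(ids)
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        n_train = _round_half_up(fraction * len(ids))
        n_train = min(max(n_train, 1), len(ids) - 1)  # >= 1 subject on each side
        train.extend(shuffled[:n_train])
        test.extend(shuffled[n_train:])
    return SplitPlan(
        train_subjects=tuple(sorted(train)),
        test_subjects=tuple(sorted(test)),
        fraction=fraction,
        seed=seed,
        stratified=stratified,
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary counts with ASD as the positive class."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FN", "FP", "TN"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be >= 0")
        if self.total == 0:
            raise ArgumentError("confusion matrix must count at least one item")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    def to_dict(self) -> dict:
        return {"TP": self.TP, "FN": self.FN, "FP": self.FP, "TN": self.TN}


@dataclass(frozen=True)
class MetricsReport:
    """Derived rates in [0, 1]; None where the denominator is zero."""

    accuracy: float | None
    specificity: float | None
    recall: float | None
    precision: float | None
    f1: float | None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
        }


def confusion(y_true, y_pred, *, positive: str = ASD, negative: str = NORMAL) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with the given positive class (default ASD)."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ArgumentError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    valid = {positive, negative}
    seen = set(y_true) | set(y_pred)
    if not seen <= valid:
        raise ArgumentError(f"labels {sorted(seen - valid)} outside {sorted(valid)}")
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred == negative)))
    fp = int(np.sum((y_true == negative) & (y_pred == positive)))
    tn = int(np.sum((y_true == negative) & (y_pred == negative)))
    return ConfusionMatrix(TP=tp, FN=fn, FP=fp, TN=tn)


def _safe_div(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, specificity, recall, precision and F1 from counts."""
    precision = _safe_div(cm.TP, cm.TP + cm.FP)
    recall = _safe_div(cm.TP, cm.TP + cm.FN)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=_safe_div(cm.TP + cm.TN, cm.total),
        specificity=_safe_div(cm.TN, cm.TN + cm.FP),
        recall=recall,
        precision=precision,
        f1=f1,
    )


@dataclass
class LevelResult:
    """Everything the pipeline produced for one decomposition level."""

    level: int
    band: str
    confusion: ConfusionMatrix
    metrics: MetricsReport
    model: FisherLDAResults
    n_train_rows: int
    n_test_rows: int


@dataclass
class PipelineReport:
    """Per-level results plus the split and config hash of the run."""

    levels: dict[int, LevelResult]
    split: SplitPlan
    config_hash: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j in sorted(self.levels):
            r = self.levels[j]
            rows.append(
                {
                    "level": r.level,
                    "band": r.band,
                    **r.confusion.to_dict(),
                    **r.metrics.to_dict(),
                    "n_train_rows": r.n_train_rows,
                    "n_test_rows": r.n_test_rows,
                    "seed": self.seed,
                    "config_hash": self.config_hash,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "format_version": "1",
            "seed": self.seed,
            "config_hash": self.config_hash,
            "split": {
                "train_subjects": list(self.split.train_subjects),
                "test_subjects": list(self.split.test_subjects),
                "fraction": self.split.fraction,
                "seed": self.split.seed,
            },
            "levels": {
                str(j): {
                    "band": r.band,
                    "confusion": r.confusion.to_dict(),
                    "metrics": r.metrics.to_dict(),
                    "n_train_rows": r.n_train_rows,
                    "n_test_rows": r.n_test_rows,
                }
                for j, r in sorted(self.levels.items())
            },
        }

    def save(self, json_path: str | Path, csv_path: str | Path | None = None) -> None:
        Path(json_path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)


def evaluate_pipeline(
    cohort: CohortManifest | Sequence[SignalRecord],
    config: PipelineConfig | None = None,
    *,
    root: str | Path | None = None,
) -> PipelineReport:
    """Run the full pipeline on a cohort and score it per level.

    Stages: read records -> SWT decomposition (db4, J levels) -> shrinkage
    denoising -> per-level detail features -> subject-wise stratified split ->
    z-normalization fit on training rows -> Fisher LDA fit on training rows ->
    prediction on held-out subjects -> confusion matrix and metrics per level.

    ``cohort`` is either a manifest (with ``root`` for relative paths) or a
    sequence of in-memory records.
    """
    if config is None:
        config = PipelineConfig()
    if isinstance(cohort, CohortManifest):
        records = load_cohort(
            cohort, root if root is not None else ".", exclude=config.exclude_channels
        )
    else:
        records = list(cohort)
    if not records:
        raise DataError("empty cohort")

    bank = db4_filters()
    per_level_parts: dict[int, list[FeatureMatrix]] = {j: [] for j in config.levels}
    for rec in records:
        try:
            dec = swt_decompose(rec, config.J, bank)
            dec = denoise(dec, config.threshold)
            feats = extract_features(
                dec,
                rec,
                levels=config.levels,
                profile=config.band_profile,
                epoch_samples=config.epoch_samples,
            )
        except SubbandFLDAError as exc:
            raise type(exc)(f"[subject {rec.subject_id}] {exc}") from exc
        for j, fm in feats.items():
            per_level_parts[j].append(fm)

    subjects = {rec.subject_id: rec.class_label for rec in records}
    split = subject_wise_split(subjects, config.split_fraction, config.seed)

    level_results: dict[int, LevelResult] = {}
    for j in config.levels:
        fm = stack_features(per_level_parts[j])
        train = fm.select_subjects(split.train_subjects)
        test = fm.select_subjects(split.test_subjects)
        model = FisherLDA(train.X, train.y).fit(ridge=config.ridge)
        y_pred = model.predict(test.X)
        cm = confusion(test.y, y_pred)
        band = band_of_level(j, records[0].fs, profile=config.band_profile)[2]
        level_results[j] = LevelResult(
            level=j,
            band=band,
            confusion=cm,
            metrics=metrics(cm),
            model=model,
            n_train_rows=train.n_rows,
            n_test_rows=test.n_rows,
        )
    return PipelineReport(
        levels=level_results,
        split=split,
        config_hash=config.hash(),
        seed=config.seed,
    )
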