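"""Sub-band feature matrices from denoised detail coefficients.

A feature row is one time sample of a level's detail-coefficient matrix: 15
channel values, labeled with the record's class and subject. Rows from many
subjects are stacked into cohort-level matrices, and z-normalization is fit
on training rows only and applied unchanged to test rows (no leakage).

An optional epoch-averaging mode is provided (non-default): rows become
within-epoch means of the coefficient matrix over fixed-length windows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, DegenerateFeatureError, ShapeError
from .signal_io import SignalRecord
from .swt import SWTDecomposition, band_of_level


@dataclass
class FeatureMatrix:
    """Per-level feature rows with class and subject labels."""

    level: int
    band: str
    X: np.ndarray
    y: np.ndarray
    subject_of_row: np.ndarray
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        self.subject_of_row = np.asarray(self.subject_of_row)
        if self.X.ndim != 2:
            raise ShapeError("X must be 2-D [rows, channels]")
        if not (len(self.y) == self.X.shape[0] == len(self.subject_of_row)):
            raise ShapeError(
                f"row-label mismatch: X has {self.X.shape[0]} rows, "
                f"y {len(self.y)}, subjects {len(self.subject_of_row)}"
            )

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def select_subjects(self, subjects: Iterable[str]) -> "FeatureMatrix":
        """Rows belonging to the given subject IDs (order preserved)."""
        subjects = set(subjects)
        mask = np.array([s in subjects for s in self.subject_of_row])
        return replace(
            self,
            X=self.X[mask],
            y=self.y[mask],
            subject_of_row=self.subject_of_row[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: channel-named columns plus class and subject."""
        cols = list(self.channel_labels) or [f"ch{i}" for i in range(self.n_channels)]
        df = pd.DataFrame(self.X, columns=cols)
        df["class"] = self.y
        df["subject"] = self.subject_of_row
        return df


@dataclass(frozen=True)
class NormalizationStats:
    """Per-column mean and standard deviation fitted on training rows."""

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "fitted_on": self.fitted_on,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(
            mean=np.asarray(d["mean"], dtype=np.float64),
            sd=np.asarray(d["sd"], dtype=np.float64),
            fitted_on=int(d["fitted_on"]),
        )


def extract_features(
    dec: SWTDecomposition,
    rec: SignalRecord | None = None,
    levels: Sequence[int] = (3, 4, 6),
    *,
    profile: str = "paper",
    epoch_samples: int | None = None,
) -> dict[int, FeatureMatrix]:
    """Per-level feature matrices from a decomposition's detail coefficients.

    ``rec`` supplies class/subject metadata when the decomposition was built
    from a bare array; decompositions built from a :class:`SignalRecord`
    already carry it. Each requested level yields the original-length slice of
    that level's detail matrix; with ``epoch_samples`` set, rows are averaged
    within consecutive windows of that many samples instead.
    """
    subject = rec.subject_id if rec is not None else dec.subject_id
    label = rec.class_label if rec is not None else dec.class_label
    channels = tuple(rec.channel_labels if rec is not None else dec.channel_labels)
    fs = rec.fs if rec is not None else dec.source_fs

    out: dict[int, FeatureMatrix] = {}
    for j in levels:
        if not 1 <= j <= dec.levels:
            raise ArgumentError(f"level {j} not present in decomposition (J={dec.levels})")
        X = dec.detail(j)
        if epoch_samples is not None:
            if epoch_samples < 1:
                raise ArgumentError(f"epoch_samples must be >= 1, got {epoch_samples}")
            n_epochs = X.shape[0] // epoch_samples
            if n_epochs == 0:
                raise ArgumentError("epoch_samples longer than the record")
            X = (
                X[: n_epochs * epoch_samples]
                .reshape(n_epochs, epoch_samples, X.shape[1])
                .mean(axis=1)
            )
        n = X.shape[0]
        band = band_of_level(j, fs or 256.0, profile=profile)[2]
        out[j] = FeatureMatrix(
            level=j,
            band=band,
            X=X.copy(),
            y=np.full(n, label, dtype=object),
            subject_of_row=np.full(n, subject, dtype=object),
            channel_labels=channels,
        )
    return out


def stack_features(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate same-level feature matrices from several subjects."""
    if not parts:
        raise ArgumentError("nothing to stack")
    level = parts[0].level
    band = parts[0].band
    channels = parts[0].channel_labels
    for p in parts[1:]:
        if p.level != level:
            raise ShapeError(f"mixed levels in stack: {level} vs {p.level}")
        if p.n_channels != parts[0].n_channels:
            raise ShapeError("mixed channel counts in stack")
    return FeatureMatrix(
        level=level,
        band=band,
        X=np.vstack([p.X for p in parts]),
        y=np.concatenate([p.y for p in parts]),
        subject_of_row=np.concatenate([p.subject_of_row for p in parts]),
        channel_labels=channels,
    )


def zscore_fit(train: FeatureMatrix | np.ndarray) -> NormalizationStats:
    """Per-column mean/sd over training rows (population sd, denominator n)."""
    X = train.X if isinstance(train, FeatureMatrix) else np.asarray(train, dtype=np.float64)
    if X.size == 0:
        raise ArgumentError("cannot fit normalization on an empty matrix")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population (ddof=0), documented
    # constant columns can carry rounding-level sd; treat those as degenerate too
    zero = np.nonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(mean)))[0]
    if zero.size:
        raise DegenerateFeatureError(
            f"zero-variance feature column(s) {zero.tolist()}; cannot z-normalize"
        )
    return NormalizationStats(mean=mean, sd=sd, fitted_on=X.shape[0])


def zscore_apply(
    stats: NormalizationStats, M: FeatureMatrix | np.ndarray
) -> FeatureMatrix | np.ndarray:
    """Apply train-fitted stats columnwise: ``(X - mean) / sd``."""
    X = M.X if isinstance(M, FeatureMatrix) else np.asarray(M, dtype=np.float64)
    if X.shape[1] != stats.mean.shape[0]:
        raise ShapeError(
            f"matrix has {X.shape[1]} columns, stats expect {stats.mean.shape[0]}"
        )
    Z = (X - stats.mean) / stats.sd
    if isinstance(M, FeatureMatrix):
        return replace(M, X=Z)
    return Z
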