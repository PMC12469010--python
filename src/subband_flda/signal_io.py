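"""Reading and writing multi-channel EEG matrices with metadata sidecars.

Data files are delimited numeric matrices (CSV/TSV/whitespace), rows = time
samples, columns = channels. A JSON sidecar carries subject ID, class label,
sampling rate and ordered channel labels from the 10-20 system. A cohort is
described by a JSON manifest listing one entry per subject.

By default channel O2 is excluded from analysis (treated as a grounding
channel in the source recordings); the exclusion list is configuration, not
a hard-coded electrophysiological claim.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ShapeError, SignalParseError

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"

#: Class labels used throughout the pipeline; ASD is the positive class.
ASD = "ASD"
NORMAL = "NORMAL"
CLASS_LABELS = (ASD, NORMAL)

#: Channel montage of the source recordings (10-20 system); O2 excluded by default.
DEFAULT_CHANNELS_16 = (
    "FP1", "F3", "F7", "T3", "T5", "O1", "C4", "FP2",
    "FZ", "F4", "F8", "C3", "CZ", "PZ", "OZ", "O2",
)
DEFAULT_EXCLUDE = frozenset({"O2"})
DEFAULT_CHANNELS_15 = tuple(c for c in DEFAULT_CHANNELS_16 if c not in DEFAULT_EXCLUDE)


@dataclass
class SignalRecord:
    """One subject's multi-channel EEG plus metadata.

    ``data`` is a float64 matrix of shape [n_samples, n_channels] in
    microvolt-scale arbitrary units.
    """

    subject_id: str
    class_label: str
    fs: float
    channel_labels: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.class_label not in CLASS_LABELS:
            raise DataError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        if not self.fs > 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ShapeError(f"data must be 2-D [samples, channels], got ndim={self.data.ndim}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise DataError("record must have at least one sample and one channel")
        if self.data.shape[1] != len(self.channel_labels):
            raise ShapeError(
                f"{self.data.shape[1]} data columns but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise DataError("channel labels must be unique")
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise DataError(
                f"non-finite value at sample {bad[0]}, channel "
                f"{self.channel_labels[bad[1]]}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class ManifestEntry:
    subject_id: str
    class_label: str
    data_path: str
    sidecar_path: str


@dataclass
class CohortManifest:
    """Index of a cohort directory: one (data file, sidecar) pair per subject."""

    entries: list[ManifestEntry] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.class_label] = counts.get(e.class_label, 0) + 1
        return counts

    def validate(self, root: Path | None = None) -> None:
        ids = [e.subject_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate subject_id in manifest")
        for e in self.entries:
            for p in (e.data_path, e.sidecar_path):
                path = Path(p) if root is None else Path(root) / p
                if not path.exists():
                    raise DataError(f"manifest references missing file: {path}")


def _sniff_delimiter(path: Path) -> str | None:
    """Return ',' / '\\t' for delimited files, None for whitespace."""
    with open(path) as fh:
        first = fh.readline()
    if "," in first:
        return ","
    if "\t" in first:
        return "\t"
    return None  # whitespace-separated


def _parse_matrix(path: Path) -> np.ndarray:
    """Parse a delimited numeric matrix, reporting the location of bad cells."""
    delim = _sniff_delimiter(path)
    try:
        df = pd.read_csv(
            path, header=None, dtype=str,
            sep=delim if delim is not None else r"\s+",
            engine="python" if delim is None else "c",
        )
    except Exception as exc:  # malformed structure (ragged rows etc.)
        raise SignalParseError(f"{path}: {exc}") from exc
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise SignalParseError(
            f"{path}: non-numeric or non-finite cell at row {r + 1}, column {c + 1} "
            f"(value {df.iat[r, c]!r})"
        )
    return values


def read_signal(
    path: str | Path,
    meta: Mapping | str | Path,
    *,
    transpose: bool = False,
    exclude: Iterable[str] | None = DEFAULT_EXCLUDE,
) -> SignalRecord:
    """Read a delimited EEG matrix plus metadata into a :class:`SignalRecord`.

    Parameters
    ----------
    path
        Delimited numeric matrix, rows = time samples, columns = channels
        (set ``transpose=True`` for the opposite orientation).
    meta
        Mapping with keys ``subject_id``, ``class_label``, ``fs``,
        ``channel_labels``, or a path to a JSON sidecar with those keys.
    exclude
        Channel labels dropped after reading; default drops O2. Pass ``None``
        or an empty set to keep all channels.
    """
    path = Path(path)
    if not isinstance(meta, Mapping):
        with open(meta) as fh:
            meta = json.load(fh)
    values = _parse_matrix(path)
    if transpose:
        values = values.T
    rec = SignalRecord(
        subject_id=str(meta["subject_id"]),
        class_label=str(meta["class_label"]).upper(),
        fs=float(meta.get("fs", 256.0)),
        channel_labels=tuple(meta["channel_labels"]),
        data=values,
    )
    if exclude:
        rec = drop_channels(rec, exclude)
    return rec


def drop_channels(rec: SignalRecord, exclude: Iterable[str]) -> SignalRecord:
    """Return a copy of ``rec`` without the channels named in ``exclude``.

    Unknown labels are ignored with a logged warning; excluding every channel
    is an error. Channel order of the survivors is preserved.
    """
    exclude = set(exclude)
    unknown = exclude - set(rec.channel_labels)
    if unknown:
        logger.warning(
            "drop_channels: labels %s not present in record %s; ignored",
            sorted(unknown), rec.subject_id,
        )
    keep = [i for i, lab in enumerate(rec.channel_labels) if lab not in exclude]
    if not keep:
        raise DataError("drop_channels would remove every channel")
    if len(keep) == rec.n_channels:
        return replace(rec, data=rec.data.copy())
    return replace(
        rec,
        channel_labels=tuple(rec.channel_labels[i] for i in keep),
        data=rec.data[:, keep].copy(),
    )


def write_signal(
    rec: SignalRecord,
    data_path: str | Path,
    sidecar_path: str | Path | None = None,
    *,
    delimiter: str = ",",
    fmt: str = "%.17g",
) -> tuple[Path, Path]:
    """Write ``rec`` as a delimited matrix plus JSON sidecar; returns both paths."""
    data_path = Path(data_path)
    if sidecar_path is None:
        sidecar_path = data_path.with_suffix(".json")
    sidecar_path = Path(sidecar_path)
    np.savetxt(data_path, rec.data, delimiter=delimiter, fmt=fmt)
    sidecar = {
        "format_version": FORMAT_VERSION,
        "subject_id": rec.subject_id,
        "class_label": rec.class_label,
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")
    return data_path, sidecar_path


def save_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "format_version": FORMAT_VERSION,
        "records": [vars(e) for e in manifest.entries],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    return path


def load_manifest(path: str | Path, *, validate: bool = True) -> CohortManifest:
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    entries = [ManifestEntry(**{k: e[k] for k in
                                ("subject_id", "class_label", "data_path", "sidecar_path")})
               for e in payload["records"]]
    manifest = CohortManifest(entries=entries)
    if validate:
        manifest.validate(root=path.parent)
    return manifest


def load_cohort(
    manifest: CohortManifest,
    root: str | Path,
    *,
    exclude: Iterable[str] | None = DEFAULT_EXCLUDE,
) -> list[SignalRecord]:
    """Read every record referenced by a manifest (paths relative to ``root``)."""
    root = Path(root)
    records = []
    for e in manifest.entries:
        rec = read_signal(root / e.data_path, root / e.sidecar_path, exclude=exclude)
        if rec.subject_id != e.subject_id or rec.class_label != e.class_label:
            raise DataError(
                f"manifest/sidecar mismatch for {e.subject_id}: sidecar says "
                f"{rec.subject_id}/{rec.class_label}"
            )
        records.append(rec)
    return records
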