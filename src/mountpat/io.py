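"""Reading and writing segments, manifests and feature matrices.

Segment files are delimited numeric text (rows = time samples, columns =
channels), comma or tab separated, with an optional single header line of
channel labels (auto-detected: if the first line does not parse as
numbers, it is taken as the header).  A dataset manifest is a delimited
table with columns ``path``, ``label`` and optional ``subject``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EEGSegment

__all__ = [
    "read_segment",
    "read_manifest",
    "load_dataset",
    "write_features",
    "read_features",
    "ingest_edf",
]


def _sniff_delimiter(line: str) -> str:
    try:
        return csv.Sniffer().sniff(line, delimiters=",\t; ").delimiter
    except csv.Error:
        return ","


def read_segment(
    path: str | Path,
    label=None,
    subject_id=None,
    sampling_rate_hz: float | None = None,
) -> EEGSegment:
    """Read one epoch from a delimited text file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"segment file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    tokens = [t for t in first.strip().split(delim) if t]
    try:
        [float(t) for t in tokens]
        header = None
        labels = None
    except ValueError:
        header = 0
        labels = tokens
    frame = pd.read_csv(path, sep=delim, header=header)
    data = frame.to_numpy(dtype=float)
    return EEGSegment(
        data=data,
        channel_labels=list(labels) if labels else [],
        label=label,
        subject_id=subject_id,
        sampling_rate_hz=sampling_rate_hz,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a dataset manifest.

    Each row must name an existing segment file and a non-empty label; the
    ``subject`` column is optional.  Paths are resolved relative to the
    manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    with open(path) as fh:
        first = fh.readline()
    manifest = pd.read_csv(path, sep=_sniff_delimiter(first))
    if "path" not in manifest.columns or "label" not in manifest.columns:
        raise ValueError("manifest needs 'path' and 'label' columns")
    if "subject" not in manifest.columns:
        manifest["subject"] = None
    base = path.parent
    resolved = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"manifest row points to missing file: {p}")
        if pd.isna(row["label"]) or str(row["label"]) == "":
            raise ValueError(f"empty label for segment {p}")
        resolved.append(str(p))
    manifest = manifest.copy()
    manifest["path"] = resolved
    return manifest


def load_dataset(
    manifest: pd.DataFrame | str | Path,
) -> tuple[list[EEGSegment], np.ndarray, np.ndarray | None]:
    """Load all segments of a manifest; enforce a consistent channel count."""
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    segments = []
    nc = None
    for _, row in manifest.iterrows():
        seg = read_segment(
            row["path"],
            label=row["label"],
            subject_id=None if pd.isna(row["subject"]) else row["subject"],
        )
        if nc is None:
            nc = seg.n_channels
        elif seg.n_channels != nc:
            raise ValueError(
                f"channel-count mismatch: {row['path']} has "
                f"{seg.n_channels} channels, expected {nc}"
            )
        segments.append(seg)
    labels = np.asarray([s.label for s in segments])
    subjects = np.asarray([s.subject_id for s in segments], dtype=object)
    if all(s is None for s in subjects.tolist()):
        subjects = None
    return segments, labels, subjects


def write_features(
    path: str | Path, features: np.ndarray, labels: np.ndarray
) -> None:
    """Write a feature matrix as delimited text, final column = label."""
    features = np.asarray(features)
    frame = pd.DataFrame(features)
    frame["label"] = np.asarray(labels)
    frame.to_csv(path, index=False)


def read_features(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`write_features`."""
    frame = pd.read_csv(path)
    labels = frame.pop("label").to_numpy()
    return frame.to_numpy(dtype=float), labels


def ingest_edf(
    path: str | Path,
    epoch_length_s: float,
    out_dir: str | Path,
    label=None,
) -> pd.DataFrame:
    """Slice an EDF recording into fixed-length epoch files plus a manifest.

    Thin wrapper over MNE's EDF reader (install the ``edf`` extra); no
    filtering or resampling is applied — raw samples are written as-is.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF ingestion needs the 'mne' package (pip install mountpat[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T  # (samples, channels)
    sfreq = float(raw.info["sfreq"])
    epoch_len = int(round(epoch_length_s * sfreq))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    n_epochs = data.shape[0] // epoch_len
    header = ",".join(raw.ch_names)
    for e in range(n_epochs):
        chunk = data[e * epoch_len : (e + 1) * epoch_len]
        seg_path = out / f"{Path(path).stem}_epoch{e:04d}.csv"
        np.savetxt(
            seg_path, chunk, delimiter=",", fmt="%.10g", header=header, comments=""
        )
        rows.append({"path": str(seg_path), "label": label, "subject": None})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
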