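"""Domain types, the recording file format, and dataset assembly.

A *recording* is one subject walking for ~1 minute under one emotion
condition with the accelerometer at one wear site, sampled at 5 Hz as
(x, y, z) acceleration triples in m/s².  Recordings are stored in a
long-form delimited text format (one row per sample) with the header

    subject_id,site,emotion,sample_index,x,y,z

optionally preceded by a comment line ``# sampling_rate=5``.  The format
is deliberately plain text: transparent, diff-able, and round-trips
exactly (floats are written with shortest-repr precision).
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, FormatError, IntegrityError, VocabularyError

logger = logging.getLogger(__name__)

SITES: tuple[str, ...] = ("wrist", "ankle")
EMOTIONS: tuple[str, ...] = ("neutral", "happy", "angry")

#: Classification tasks mapped to their class sets (the benchmark grid:
#: every pairwise contrast plus the full three-way problem).
TASKS: Mapping[str, tuple[str, ...]] = {
    "neutral_vs_angry": ("neutral", "angry"),
    "neutral_vs_happy": ("neutral", "happy"),
    "happy_vs_angry": ("happy", "angry"),
    "three_class": ("neutral", "happy", "angry"),
}

_COLUMNS = ["subject_id", "site", "emotion", "sample_index", "x", "y", "z"]


@dataclass(frozen=True)
class TriaxialRecording:
    """One subject-condition triaxial acceleration time series.

    Parameters
    ----------
    subject_id
        Opaque participant identifier.
    site
        Wear site, ``"wrist"`` or ``"ankle"``.
    emotion
        Condition label, ``"neutral"``, ``"happy"`` or ``"angry"``.
    samples
        Array of shape (n, 3): ordered (x, y, z) triples in m/s².
    sampling_rate
        Samples per second (the bracelet records at 5).
    """

    subject_id: str
    site: str
    emotion: str
    samples: np.ndarray
    sampling_rate: float = 5.0

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise VocabularyError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.emotion not in EMOTIONS:
            raise VocabularyError(
                f"unknown emotion {self.emotion!r}; expected one of {EMOTIONS}"
            )
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3 or samples.shape[0] < 1:
            raise IntegrityError(
                f"samples must be a non-empty (n, 3) array, got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise IntegrityError(
                f"non-finite sample in recording ({self.subject_id}, {self.site}, {self.emotion})"
            )
        if not self.sampling_rate > 0:
            raise IntegrityError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.shape[0]

    def axis(self, name: str) -> np.ndarray:
        """Return one axis ('x', 'y' or 'z') as a 1-D array."""
        return self.samples[:, "xyz".index(name)]


@dataclass(frozen=True)
class Segment:
    """A fixed-width window of a (filtered) recording, with provenance."""

    source: TriaxialRecording
    window_index: int
    data: np.ndarray  # (windowsize, 3)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 3:
            raise IntegrityError(f"segment data must be (n, 3), got {data.shape}")
        object.__setattr__(self, "data", data)

    def __len__(self) -> int:
        return self.data.shape[0]

    def axis(self, name: str) -> np.ndarray:
        return self.data[:, "xyz".index(name)]


@dataclass(frozen=True)
class LabelledDataset:
    """Per-segment feature rows restricted to one task at one wear site.

    ``X`` holds one 114-feature row per segment (columns named per the
    feature inventory), ``y`` the emotion labels, and ``meta`` the
    provenance columns (subject_id, emotion, window_index) in the same
    row order.
    """

    task: str
    site: str
    X: pd.DataFrame
    y: np.ndarray
    meta: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise VocabularyError(f"unknown task {self.task!r}")
        classes = set(TASKS[self.task])
        labels, counts = np.unique(self.y, return_counts=True)
        bad = set(labels) - classes
        if bad:
            raise VocabularyError(f"labels {sorted(bad)} outside task {self.task!r} classes")
        for lab, cnt in zip(labels, counts):
            if cnt < 2:
                raise IntegrityError(f"class {lab!r} has {cnt} row(s); need >= 2")

    @property
    def classes(self) -> tuple[str, ...]:
        return TASKS[self.task]

    def __len__(self) -> int:
        return len(self.y)


def _parse_sampling_rate(text: str) -> float | None:
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if body.startswith("sampling_rate"):
            try:
                return float(body.split("=", 1)[1])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"malformed sampling_rate header: {line!r}") from exc
    return None


def read_recordings(path: str | Path) -> list[TriaxialRecording]:
    """Read recordings from one long-form delimited text file.

    One :class:`TriaxialRecording` is returned per distinct
    (subject_id, site, emotion) group, samples ordered by sample_index.
    The sampling rate is taken from a ``# sampling_rate=...`` header
    line if present, else defaults to 5 samples/s.
    """
    path = Path(path)
    text = path.read_text()
    rate = _parse_sampling_rate(text) or 5.0
    df = pd.read_csv(io.StringIO(text), comment="#", float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")
    for col in ("x", "y", "z", "sample_index"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric value in column {col!r} of {path}") from exc
    bad_sites = set(df["site"]) - set(SITES)
    if bad_sites:
        raise VocabularyError(f"unknown site token(s) {sorted(bad_sites)} in {path}")
    bad_emotions = set(df["emotion"]) - set(EMOTIONS)
    if bad_emotions:
        raise VocabularyError(f"unknown emotion token(s) {sorted(bad_emotions)} in {path}")

    recordings = []
    for (subject, site, emotion), group in df.groupby(
        ["subject_id", "site", "emotion"], sort=True
    ):
        group = group.sort_values("sample_index")
        idx = group["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise IntegrityError(
                f"sample_index not contiguous from 0 for group ({subject}, {site}, {emotion})"
            )
        recordings.append(
            TriaxialRecording(
                subject_id=str(subject),
                site=site,
                emotion=emotion,
                samples=group[["x", "y", "z"]].to_numpy(),
                sampling_rate=rate,
            )
        )
    return recordings


def write_recordings(recordings: Sequence[TriaxialRecording], path: str | Path) -> Path:
    """Write recordings to one delimited text file; re-reading reproduces them.

    Rows are sorted by (subject_id, site, emotion, sample_index) so output
    is deterministic regardless of input order.
    """
    if not recordings:
        raise IntegrityError("cannot write an empty collection of recordings")
    rates = {rec.sampling_rate for rec in recordings}
    if len(rates) != 1:
        raise IntegrityError(f"recordings mix sampling rates {sorted(rates)}")
    frames = []
    for rec in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "site": rec.site,
                    "emotion": rec.emotion,
                    "sample_index": np.arange(len(rec)),
                    "x": rec.samples[:, 0],
                    "y": rec.samples[:, 1],
                    "z": rec.samples[:, 2],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["subject_id", "site", "emotion", "sample_index"], kind="stable")
    path = Path(path)
    rate = rates.pop()
    rate_str = f"{int(rate)}" if rate == int(rate) else repr(rate)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate={rate_str}\n")
        df.to_csv(fh, index=False)
    return path


def assemble_task(
    feature_table: pd.DataFrame, task: str, site: str, feature_names: Sequence[str]
) -> LabelledDataset:
    """Restrict a per-segment feature table to one task's classes at one site.

    ``feature_table`` carries the provenance columns subject_id / site /
    emotion / window_index plus one column per feature.  Rows are ordered
    deterministically by (subject_id, emotion, window_index).  A task class
    with no rows raises :class:`CoverageError` naming the class.
    """
    if task not in TASKS:
        raise VocabularyError(f"unknown task {task!r}")
    if site not in SITES:
        raise VocabularyError(f"unknown site {site!r}")
    classes = TASKS[task]
    sub = feature_table[
        (feature_table["site"] == site) & (feature_table["emotion"].isin(classes))
    ]
    for cls in classes:
        if not (sub["emotion"] == cls).any():
            raise CoverageError(f"task {task!r} at site {site!r}: class {cls!r} absent")
    sub = sub.sort_values(["subject_id", "emotion", "window_index"], kind="stable")
    return LabelledDataset(
        task=task,
        site=site,
        X=sub[list(feature_names)].reset_index(drop=True),
        y=sub["emotion"].to_numpy(),
        meta=sub[["subject_id", "emotion", "window_index"]].reset_index(drop=True),
    )
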