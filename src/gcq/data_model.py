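"""Core data model: trials, labels, montages and the on-disk dataset layout.

The atomic unit is a :class:`Trial` — one channels × samples matrix with a
sampling rate and named channels.  Self-assessment scores (valence and
arousal, each rated 1–9) are cut at 4.5 into the four quadrant classes of
the dimensional emotion model:

====== ======= ======= =========
class  arousal valence name
====== ======= ======= =========
1      < 4.5   < 4.5   LALV
2      ≥ 4.5   < 4.5   HALV
3      < 4.5   ≥ 4.5   LAHV
4      ≥ 4.5   ≥ 4.5   HAHV
====== ======= ======= =========

A score of exactly 4.5 counts as "high" on both axes.

The reference montage is the standard 32-electrode 10–20 layout used by the
DEAP recordings, partitioned into six brain areas (left/right frontal,
left/right central–temporal, left/right parieto-occipital).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_NAMES",
    "REFERENCE_CHANNELS",
    "REFERENCE_MONTAGE",
    "LabelRecord",
    "MontageMap",
    "MontageReport",
    "RecordingSet",
    "Trial",
    "ValidationError",
    "LoadError",
    "assign_class",
    "parse_montage_text",
    "read_deap_arrays",
    "read_recording_set",
    "validate_montage",
    "write_recording_set",
]


class ValidationError(ValueError):
    """Raised when a value violates a data-model invariant."""


class LoadError(RuntimeError):
    """Raised when an on-disk dataset cannot be read consistently."""


CLASS_NAMES = {1: "LALV", 2: "HALV", 3: "LAHV", 4: "HAHV"}

#: Canonical channel order of the 32-electrode reference montage.
REFERENCE_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Midline electrodes belong to neither hemisphere and to no area.
_REFERENCE_EXCLUDED: tuple[str, ...] = ("Oz", "Pz", "Fz", "Cz")

_REFERENCE_AREAS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("Area 1", ("Fp1", "AF3", "F3", "FC5", "F7")),
    ("Area 2", ("Fp2", "AF4", "F4", "FC6", "F8")),
    ("Area 3", ("FC1", "CP1", "C3", "T7")),
    ("Area 4", ("FC2", "CP2", "C4", "T8")),
    ("Area 5", ("CP5", "P3", "PO3", "O1", "P7")),
    ("Area 6", ("CP6", "P4", "PO4", "O2", "P8")),
)


def assign_class(valence: float, arousal: float) -> int:
    """Map a (valence, arousal) score pair to emotion class 1–4.

    Low means < 4.5 and high means ≥ 4.5 on both axes, so the boundary
    score 4.5 is high.

    Raises
    ------
    ValidationError
        If either score falls outside [1, 9]; the message names the axis.
    """
    for axis, score in (("valence", valence), ("arousal", arousal)):
        if not np.isfinite(score) or not 1.0 <= score <= 9.0:
            raise ValidationError(
                f"{axis} score {score!r} outside the valid range [1, 9]"
            )
    high_v = valence >= 4.5
    high_a = arousal >= 4.5
    if high_a:
        return 4 if high_v else 2
    return 3 if high_v else 1


@dataclass(frozen=True)
class LabelRecord:
    """Per-trial self-assessment scores and the derived emotion class."""

    subject_id: str
    trial_id: str
    valence: float
    arousal: float
    class_id: int = field(default=0)

    def __post_init__(self) -> None:
        derived = assign_class(self.valence, self.arousal)
        if self.class_id == 0:
            object.__setattr__(self, "class_id", derived)
        elif self.class_id != derived:
            raise ValidationError(
                f"class_id {self.class_id} inconsistent with scores "
                f"(valence={self.valence}, arousal={self.arousal} → {derived})"
            )


@dataclass(frozen=True)
class Trial:
    """One multichannel recording: channels × samples at a fixed rate."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if data.ndim != 2:
            raise ValidationError(f"trial data must be 2-D, got shape {data.shape}")
        if data.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"{data.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(data)):
            raise ValidationError("trial data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def reorder(self, channel_order: Sequence[str]) -> "Trial":
        """Return a copy with channels permuted into ``channel_order``."""
        index = {name: i for i, name in enumerate(self.channel_names)}
        missing = [c for c in channel_order if c not in index]
        if missing:
            raise ValidationError(
                f"trial {self.subject_id}/{self.trial_id} missing channel(s): "
                + ", ".join(missing)
            )
        rows = [index[c] for c in channel_order]
        return Trial(
            data=self.data[rows],
            fs=self.fs,
            channel_names=tuple(channel_order),
            subject_id=self.subject_id,
            trial_id=self.trial_id,
        )


@dataclass(frozen=True)
class MontageMap:
    """Partition of a channel set into named brain areas.

    ``excluded`` lists channels deliberately left out of every area (the
    reference montage excludes the four midline electrodes, which belong
    to neither hemisphere); they are still recorded and used in
    32-channel mode, but never averaged into an area.
    """

    area_names: tuple[str, ...]
    areas: tuple[tuple[str, ...], ...]
    channel_order: tuple[str, ...]
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "area_names", tuple(self.area_names))
        object.__setattr__(self, "areas", tuple(tuple(a) for a in self.areas))
        object.__setattr__(self, "channel_order", tuple(self.channel_order))
        object.__setattr__(self, "excluded", tuple(self.excluded))
        if len(self.area_names) != len(self.areas):
            raise ValidationError("area_names and areas length mismatch")

    @property
    def assignment(self) -> dict[str, int]:
        """Channel label → area index (first assignment wins on duplicates)."""
        out: dict[str, int] = {}
        for i, members in enumerate(self.areas):
            for ch in members:
                out.setdefault(ch, i)
        return out

    @property
    def area_sizes(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.areas)


REFERENCE_MONTAGE = MontageMap(
    area_names=tuple(name for name, _ in _REFERENCE_AREAS),
    areas=tuple(members for _, members in _REFERENCE_AREAS),
    channel_order=REFERENCE_CHANNELS,
    excluded=_REFERENCE_EXCLUDED,
)


@dataclass(frozen=True)
class MontageReport:
    """Result of checking a montage against a channel set."""

    passed: bool
    unassigned: tuple[str, ...]
    duplicates: tuple[str, ...]
    unknown: tuple[str, ...]
    area_sizes: tuple[int, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "PASS" if self.passed else "FAIL"
        parts = [f"montage check: {status}", f"area sizes: {list(self.area_sizes)}"]
        if self.unassigned:
            parts.append("unassigned: " + ", ".join(self.unassigned))
        if self.duplicates:
            parts.append("duplicated: " + ", ".join(self.duplicates))
        if self.unknown:
            parts.append("not in channel set: " + ", ".join(self.unknown))
        return "; ".join(parts)


def validate_montage(
    channel_names: Sequence[str], montage: MontageMap
) -> MontageReport:
    """Check that ``montage`` partitions ``channel_names`` exactly.

    The check passes iff every channel is assigned to exactly one area or
    is deliberately excluded, and every area member exists in the channel
    set (no omission, no overlap, no stray labels).
    """
    channels = list(channel_names)
    seen: dict[str, int] = {}
    duplicates: list[str] = []
    unknown: list[str] = []
    for members in montage.areas + (montage.excluded,):
        for ch in members:
            if ch in seen:
                if ch not in duplicates:
                    duplicates.append(ch)
            seen[ch] = seen.get(ch, 0) + 1
            if ch not in channels and ch not in unknown:
                unknown.append(ch)
    unassigned = [ch for ch in channels if ch not in seen]
    passed = not unassigned and not duplicates and not unknown
    return MontageReport(
        passed=passed,
        unassigned=tuple(unassigned),
        duplicates=tuple(duplicates),
        unknown=tuple(unknown),
        area_sizes=montage.area_sizes,
    )


def parse_montage_text(text: str) -> MontageMap:
    """Parse a plain-text montage config.

    Each non-empty, non-comment line reads ``Area name: Ch1 Ch2 ...`` (commas
    allowed between labels).  Channel order defaults to order of appearance.
    """
    names: list[str] = []
    areas: list[tuple[str, ...]] = []
    order: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValidationError(f"montage line missing ':' separator: {line!r}")
        name, _, rest = line.partition(":")
        members = tuple(tok for tok in re.split(r"[\s,]+", rest.strip()) if tok)
        if not members:
            raise ValidationError(f"montage area {name.strip()!r} has no channels")
        names.append(name.strip())
        areas.append(members)
        order.extend(members)
    if not areas:
        raise ValidationError("montage config contains no areas")
    return MontageMap(tuple(names), tuple(areas), tuple(order))


@dataclass
class RecordingSet:
    """A dataset: trials, their labels, and manifest metadata."""

    trials: list[Trial]
    labels: list[LabelRecord]
    name: str = "unnamed"
    fs: float = 128.0
    montage_id: str = "reference-32"

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.labels):
            raise ValidationError(
                f"{len(self.trials)} trials but {len(self.labels)} labels"
            )
        for trial, label in zip(self.trials, self.labels):
            if (trial.subject_id, trial.trial_id) != (
                label.subject_id,
                label.trial_id,
            ):
                raise ValidationError(
                    f"trial/label id mismatch: {trial.subject_id}/{trial.trial_id}"
                    f" vs {label.subject_id}/{label.trial_id}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.labels],
                "trial_id": [r.trial_id for r in self.labels],
                "valence": [r.valence for r in self.labels],
                "arousal": [r.arousal for r in self.labels],
                "class_id": [r.class_id for r in self.labels],
            }
        )


# ---------------------------------------------------------------------------
# On-disk layout
#
# One directory per dataset:
#   manifest.txt       key = value lines: name, fs, montage
#   labels.csv         header subject_id,trial_id,valence,arousal
#   trials/<subject_id>__<trial_id>.npy   channels × samples array
# ---------------------------------------------------------------------------


def write_recording_set(recordings: RecordingSet, path: str | Path) -> Path:
    """Write a :class:`RecordingSet` in the canonical directory layout."""
    root = Path(path)
    (root / "trials").mkdir(parents=True, exist_ok=True)
    manifest = (
        f"name = {recordings.name}\n"
        f"fs = {recordings.fs}\n"
        f"montage = {recordings.montage_id}\n"
    )
    (root / "manifest.txt").write_text(manifest)
    recordings.labels_frame().drop(columns=["class_id"]).to_csv(
        root / "labels.csv", index=False
    )
    for trial in recordings.trials:
        np.save(root / "trials" / f"{trial.subject_id}__{trial.trial_id}.npy",
                trial.data)
    return root


def _read_manifest(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_recording_set(
    path: str | Path, montage: MontageMap = REFERENCE_MONTAGE
) -> RecordingSet:
    """Read the canonical dataset layout back into a :class:`RecordingSet`.

    Every trial is validated and its channels permuted into the montage's
    canonical order.  Label rows with out-of-range or missing scores are
    rejected and counted in the raised error / log.
    """
    root = Path(path)
    manifest_path = root / "manifest.txt"
    if not manifest_path.exists():
        raise LoadError(f"no manifest.txt under {root}")
    manifest = _read_manifest(manifest_path)
    fs = float(manifest.get("fs", 128.0))

    labels_path = root / "labels.csv"
    if not labels_path.exists():
        raise LoadError(f"no labels.csv under {root}")
    table = pd.read_csv(labels_path, dtype={"subject_id": str, "trial_id": str})

    trials: list[Trial] = []
    labels: list[LabelRecord] = []
    n_rejected = 0
    for row in table.itertuples(index=False):
        sid, tid = str(row.subject_id), str(row.trial_id)
        try:
            label = LabelRecord(sid, tid, float(row.valence), float(row.arousal))
        except (ValidationError, TypeError) as exc:
            logger.warning("rejecting label row %s/%s: %s", sid, tid, exc)
            n_rejected += 1
            continue
        trial_path = root / "trials" / f"{sid}__{tid}.npy"
        if not trial_path.exists():
            raise LoadError(f"missing trial file {trial_path} for {sid}/{tid}")
        data = np.load(trial_path)
        try:
            trial = Trial(
                data=data,
                fs=fs,
                channel_names=montage.channel_order,
                subject_id=sid,
                trial_id=tid,
            )
        except ValidationError as exc:
            raise LoadError(f"invalid trial {sid}/{tid} in {trial_path}: {exc}")
        trials.append(trial)
        labels.append(label)
    if n_rejected:
        logger.warning("rejected %d label row(s) with invalid scores", n_rejected)
    return RecordingSet(
        trials=trials,
        labels=labels,
        name=manifest.get("name", root.name),
        fs=fs,
        montage_id=manifest.get("montage", "reference-32"),
    )


def read_deap_arrays(
    data: np.ndarray,
    labels: np.ndarray,
    subject_id: str,
    fs: float = 128.0,
    montage: MontageMap = REFERENCE_MONTAGE,
) -> RecordingSet:
    """Adapter for one subject in the DEAP array layout.

    ``data`` is trials × channels × samples (40 × 40 × 8064 for the
    preprocessed release) and ``labels`` is trials × 4 with valence and
    arousal in the first two columns.  Only the first 32 channel rows are
    EEG; any extra peripheral-sensor rows are dropped with a warning.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if data.ndim != 3:
        raise LoadError(f"expected trials × channels × samples, got {data.shape}")
    if labels.shape[0] != data.shape[0] or labels.shape[1] < 2:
        raise LoadError(
            f"labels shape {labels.shape} inconsistent with data {data.shape}"
        )
    n_eeg = len(montage.channel_order)
    if data.shape[1] > n_eeg:
        logger.warning(
            "dropping %d non-EEG channel row(s) beyond the first %d",
            data.shape[1] - n_eeg, n_eeg,
        )
        data = data[:, :n_eeg, :]
    elif data.shape[1] < n_eeg:
        raise LoadError(
            f"only {data.shape[1]} channels present; montage needs {n_eeg}"
        )
    trials = []
    records = []
    for t in range(data.shape[0]):
        tid = f"t{t + 1:02d}"
        trials.append(
            Trial(data[t], fs, montage.channel_order, subject_id, tid)
        )
        records.append(
            LabelRecord(subject_id, tid, float(labels[t, 0]), float(labels[t, 1]))
        )
    return RecordingSet(trials, records, name=f"deap-{subject_id}", fs=fs)
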