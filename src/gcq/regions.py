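"""Electrode combination: collapse 32 channels into 6 area averages.

Each brain area's signal is the unweighted arithmetic mean of its member
channels at every sample.  Averaging is linear, so it commutes with the
(linear) wavelet band reconstruction; decompose-then-combine and
combine-then-decompose give the same result, and the latter is offered as
a fast path by callers that only need area signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import MontageMap, REFERENCE_MONTAGE, Trial, ValidationError

__all__ = ["AreaTrial", "combine"]


@dataclass(frozen=True)
class AreaTrial:
    """Area-averaged signals: 6 × samples, in montage area order."""

    data: np.ndarray
    area_names: tuple[str, ...]
    fs: float
    subject_id: str = ""
    trial_id: str = ""
    band: str = "all"

    @property
    def n_areas(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def combine(
    trial: Trial, montage: MontageMap = REFERENCE_MONTAGE, band: str = "all"
) -> AreaTrial:
    """Average channels within each montage area.

    Output rows follow the montage's area order; the sample count is
    preserved.  Raises if any area member is missing from the trial.
    """
    index = {name: i for i, name in enumerate(trial.channel_names)}
    rows = np.empty((len(montage.areas), trial.n_samples))
    for a, (area_name, members) in enumerate(zip(montage.area_names, montage.areas)):
        missing = [ch for ch in members if ch not in index]
        if missing:
            raise ValidationError(
                f"channel(s) {', '.join(missing)} of {area_name} missing "
                f"from trial {trial.subject_id}/{trial.trial_id}"
            )
        rows[a] = trial.data[[index[ch] for ch in members]].mean(axis=0)
    return AreaTrial(
        data=rows,
        area_names=montage.area_names,
        fs=trial.fs,
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        band=band,
    )
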