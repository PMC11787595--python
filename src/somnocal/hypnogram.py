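"""Hypnogram container: ordered 30-s sleep-stage epochs.

Stages follow AASM nomenclature: W (wake), N1/N2 (light non-REM),
N3 (slow-wave sleep), R (REM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STAGES = ("W", "N1", "N2", "N3", "R")
SLEEP_STAGES = ("N1", "N2", "N3", "R")
EPOCH_SECONDS = 30.0
EPOCHS_PER_MINUTE = 2

__all__ = ["Hypnogram", "STAGES", "SLEEP_STAGES", "EPOCH_SECONDS"]


@dataclass
class Hypnogram:
    """A night of 30-s stage epochs between lights off and lights on.

    ``epochs`` is an ordered sequence of stage labels; with the default
    8-h sleep opportunity that is 960 epochs.  ``lights_off`` is a clock
    label ("23:00"); all within-night times are minutes from lights off.
    """

    epochs: np.ndarray
    lights_off: str = "23:00"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype="U2")
        bad = set(np.unique(self.epochs)) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        if len(self.epochs) == 0:
            raise ValueError("hypnogram must contain at least one epoch")

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def duration_min(self) -> float:
        return len(self.epochs) * EPOCH_SECONDS / 60.0

    def stage_epoch_counts(self) -> dict[str, int]:
        """Epoch count per stage, zeros included."""
        return {s: int(np.sum(self.epochs == s)) for s in STAGES}

    def stage_minutes(self) -> dict[str, float]:
        return {s: c * EPOCH_SECONDS / 60.0 for s, c in self.stage_epoch_counts().items()}

    def minute_stages(self) -> np.ndarray:
        """Stage of each whole minute, or '' where the two constituent
        epochs disagree (the 60-s continuity rule for stage-specific EE)."""
        n_min = len(self.epochs) // EPOCHS_PER_MINUTE
        pairs = self.epochs[: n_min * EPOCHS_PER_MINUTE].reshape(n_min, EPOCHS_PER_MINUTE)
        same = pairs[:, 0] == pairs[:, 1]
        out = np.where(same, pairs[:, 0], "")
        return out.astype("U2")
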