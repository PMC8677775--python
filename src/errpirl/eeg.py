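"""EEG recording container and plain-text bundle I/O.

Recordings carry 16 EEG channels in a fixed fronto-central montage plus 3
EOG channels, sampled at 512 Hz, with event markers (motion onset, joystick
release, trial end).  On-disk format is a documented CSV bundle (one CSV per
signal block + a JSON event sidecar); channel order in outputs matches the
montage below exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["EEG_CHANNELS", "EOG_CHANNELS", "SAMPLE_RATE", "EEGRecording"]

EEG_CHANNELS: tuple[str, ...] = (
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4",
    "C3", "C1", "Cz", "C2", "C4",
    "CP3", "CP1", "CPz", "CP2", "CP4",
)
EOG_CHANNELS: tuple[str, ...] = ("EOG1", "EOG2", "EOG3")
SAMPLE_RATE = 512.0

EVENT_KINDS = ("motion_onset", "release", "trial_end")


@dataclass
class EEGRecording:
    """Multichannel EEG/EOG segment (microvolts) with event markers."""

    sample_rate: float
    eeg: np.ndarray  # (16, n_samples)
    eog: np.ndarray  # (3, n_samples)
    events: List[Tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, float)
        self.eog = np.asarray(self.eog, float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.eeg.shape[0] != len(EEG_CHANNELS):
            raise ValueError(f"expected {len(EEG_CHANNELS)} EEG channels")
        if self.eog.shape[0] != len(EOG_CHANNELS):
            raise ValueError(f"expected {len(EOG_CHANNELS)} EOG channels")
        if self.eeg.shape[1] != self.eog.shape[1]:
            raise ValueError("EEG and EOG must share the sample axis")
        dur = self.duration
        for t, kind in self.events:
            if not 0 <= t <= dur:
                raise ValueError(f"event {kind!r} at {t} s outside recording span")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def event_time(self, kind: str) -> Optional[float]:
        for t, k in self.events:
            if k == kind:
                return t
        return None

    def copy_with(self, eeg: np.ndarray) -> "EEGRecording":
        return EEGRecording(self.sample_rate, eeg, self.eog.copy(), list(self.events))

    # -- bundle I/O ---------------------------------------------------------

    def save_bundle(self, directory: str | Path, stem: str = "recording") -> None:
        """Write ``<stem>_eeg.csv``, ``<stem>_eog.csv``, ``<stem>_events.json``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.eeg.T, columns=list(EEG_CHANNELS)).to_csv(
            directory / f"{stem}_eeg.csv", index=False
        )
        pd.DataFrame(self.eog.T, columns=list(EOG_CHANNELS)).to_csv(
            directory / f"{stem}_eog.csv", index=False
        )
        meta = {
            "sample_rate": self.sample_rate,
            "events": [{"time": float(t), "kind": k} for t, k in self.events],
        }
        (directory / f"{stem}_events.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load_bundle(cls, directory: str | Path, stem: str = "recording") -> "EEGRecording":
        directory = Path(directory)
        eeg = pd.read_csv(directory / f"{stem}_eeg.csv")[list(EEG_CHANNELS)].to_numpy().T
        eog = pd.read_csv(directory / f"{stem}_eog.csv")[list(EOG_CHANNELS)].to_numpy().T
        meta = json.loads((directory / f"{stem}_events.json").read_text())
        events = [(float(e["time"]), str(e["kind"])) for e in meta["events"]]
        return cls(float(meta["sample_rate"]), eeg, eog, events)
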