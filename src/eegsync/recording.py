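"""The in-memory container for one subject's multichannel EEG."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Recording:
    """One subject's EEG: a channels × time matrix in µV plus metadata.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``, physical units µV.
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered 10-20 electrode names, one per row of ``samples``.
    subject_id
        Unique identifier within a cohort.
    group
        ``"IA"`` (internet-addiction) or ``"HC"`` (healthy control).
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str = "s0"
    group: str = "HC"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels × time)")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channel rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples")
        if self.group not in ("IA", "HC"):
            raise ValueError(f"group must be 'IA' or 'HC', got {self.group!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, samples: np.ndarray) -> "Recording":
        """Same metadata, new sample matrix (e.g. a band-limited copy)."""
        return Recording(
            samples=samples,
            fs=self.fs,
            channel_labels=self.channel_labels,
            subject_id=self.subject_id,
            group=self.group,
        )
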