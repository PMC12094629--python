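"""A 32-channel 10-20 montage with approximate planar electrode positions.

Positions are schematic top-view coordinates on a unit head disc (x: left
negative, y: nose positive).  They are used only to give the synthetic
volume-conduction mixing a distance structure and to group electrodes into
scalp regions; no forward modelling is implied.
"""

from __future__ import annotations

import numpy as np

#: Ordered channel labels for the default 32-electrode cap.
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "POz",
    "O1", "Oz", "O2",
)

#: Schematic (x, y) position per label, unit head radius.
POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fpz": (0.00, 1.00), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.43, 0.55), "Fz": (0.00, 0.50),
    "F4": (0.43, 0.55), "F8": (0.81, 0.59),
    "FT7": (-0.95, 0.31), "FC3": (-0.50, 0.27), "FCz": (0.00, 0.25),
    "FC4": (0.50, 0.27), "FT8": (0.95, 0.31),
    "T7": (-1.00, 0.00), "C3": (-0.50, 0.00), "Cz": (0.00, 0.00),
    "C4": (0.50, 0.00), "T8": (1.00, 0.00),
    "TP7": (-0.95, -0.31), "CP3": (-0.50, -0.27), "CPz": (0.00, -0.25),
    "CP4": (0.50, -0.27), "TP8": (0.95, -0.31),
    "P7": (-0.81, -0.59), "P3": (-0.43, -0.55), "Pz": (0.00, -0.50),
    "P4": (0.43, -0.55), "P8": (0.81, -0.59),
    "POz": (0.00, -0.75),
    "O1": (-0.31, -0.95), "Oz": (0.00, -1.00), "O2": (0.31, -0.95),
}

FRONTAL = ("Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8")
OCCIPITAL = ("O1", "Oz", "O2", "POz", "P3", "Pz", "P4")


def distance_matrix(labels: tuple[str, ...] = CHANNELS_32) -> np.ndarray:
    """Pairwise Euclidean distances between electrode positions."""
    pts = np.array([POSITIONS[lab] for lab in labels])
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))
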