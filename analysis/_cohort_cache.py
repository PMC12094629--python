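"""Shared helper for the analysis scripts: build (or reload) the study cohort.

The full 92-subject connectivity computation takes a minute or two, so the
tensors are cached as an .npz under scratch/ after the first run; delete
scratch/ to force regeneration.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from eegsync.connectivity import ConnectivityTensor
from eegsync.experiments import make_separable_cohort
from eegsync.synthetic import study_couplings  # noqa: F401  (re-export)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

COHORT_SEED = 20260927
STRENGTH_RATIO = 2.0  # the study-style contrast: IA twice the HC strength
STRENGTH_HC = 1.0


def get_cohort(force: bool = False):
    """(config, {metric: tensor}, labels) for the study-style cohort."""
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cache = SCRATCH / "cohort_tensors.npz"
    config, _, _ = (None, None, None)
    if cache.exists() and not force:
        data = np.load(cache, allow_pickle=False)
        labels = data["labels"].astype(str)
        meta = {
            "subject_ids": tuple(data["subject_ids"].astype(str)),
            "groups": tuple(labels),
            "band_names": tuple(data["band_names"].astype(str)),
            "channel_labels": tuple(data["channel_labels"].astype(str)),
        }
        tensors = {
            m: ConnectivityTensor(values=data[m], metric=m.upper(), **meta)
            for m in ("pli", "wpli")
        }
        from eegsync.synthetic import SyntheticConfig

        config = SyntheticConfig(
            fs=250.0, duration=30.0, seed=COHORT_SEED,
            couplings=study_couplings(STRENGTH_HC, STRENGTH_RATIO),
        )
        return config, tensors, labels
    config, tensors, labels = make_separable_cohort(
        COHORT_SEED, ratio=STRENGTH_RATIO, strength_hc=STRENGTH_HC,
    )
    np.savez_compressed(
        cache,
        pli=tensors["pli"].values,
        wpli=tensors["wpli"].values,
        labels=labels,
        subject_ids=np.array(tensors["pli"].subject_ids),
        band_names=np.array(tensors["pli"].band_names),
        channel_labels=np.array(tensors["pli"].channel_labels),
    )
    return config, tensors, labels
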