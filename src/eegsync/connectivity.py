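"""Phase-lag connectivity: analytic signal, PLI and WPLI, and the cohort tensor.

The phase lag index (PLI) of two channels a, b with instantaneous phases
φ_a(t), φ_b(t) is

    PLI = | ⟨ sign( sin(Δφ(t)) ) ⟩_t |,   Δφ = φ_a − φ_b,

the absolute time-average of the sign of the phase difference's sine: 0 when
phase leads and lags balance (or coincide at Δφ ∈ {0, π}, where the sine
vanishes), 1 when one channel consistently leads the other.  Because a
shared source seen through instantaneous (zero-lag) volume conduction
produces Δφ ∈ {0, π}, PLI discounts it by construction.

The weighted PLI (WPLI) weights each sample by the magnitude of the
imaginary cross-component I(t) = Im{ z_a(t) · z̄_b(t) } of the two analytic
signals:

    WPLI = | ⟨ I(t) ⟩_t | / ⟨ |I(t)| ⟩_t ,

which down-weights samples with near-zero lag, where PLI's sign flips are
driven by noise.  Both metrics lie in [0, 1] and are invariant to rescaling
either channel.

`connectivity_tensor` runs the full per-subject pipeline (broadband +
notch filtering, artifact rejection, per-band filtering, per-segment
analytic signal with edge trimming, duration-weighted aggregation) and
returns a subjects × bands × channel-pairs array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .bands import BandSpec, CANONICAL_BANDS
from .preprocess import (
    CleanSegments,
    broadband_clean,
    fir_bandpass,
    reject_artifacts,
)
from .recording import Recording

__all__ = [
    "analytic_signal",
    "PhasePairSeries",
    "phase_pair",
    "pli",
    "wpli",
    "ConnectivityTensor",
    "connectivity_tensor",
    "pair_index",
]

METRICS = ("pli", "wpli")


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Complex analytic signal z(t) = x(t) + i·x̂(t) along the last axis.

    Uses the frequency-domain construction (negative frequencies zeroed,
    positive doubled); the real part of the result equals the input to
    machine precision.  Input should be band-limited and mean-removed;
    the instantaneous phase is ``np.angle`` of the result.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to analytic_signal")
    if x.shape[-1] < 64:
        raise ValueError(
            f"series of {x.shape[-1]} samples too short for a stable "
            "analytic signal (need >= 64)"
        )
    return hilbert(x, axis=-1)


@dataclass
class PhasePairSeries:
    """Per-sample phase relationship of one channel pair.

    ``dphi`` is the wrapped phase difference φ_a − φ_b in (−π, π];
    ``imag_cross`` is Im{z_a · z̄_b}, whose sign agrees with sin(Δφ)
    wherever both are nonzero and whose magnitude carries the WPLI weights.
    """

    dphi: np.ndarray
    imag_cross: np.ndarray

    def __post_init__(self) -> None:
        self.dphi = np.asarray(self.dphi, dtype=float).ravel()
        self.imag_cross = np.asarray(self.imag_cross, dtype=float).ravel()
        if self.dphi.size != self.imag_cross.size:
            raise ValueError("dphi and imag_cross length mismatch")
        if self.dphi.size < 1:
            raise ValueError("empty phase-pair series")

    @property
    def n(self) -> int:
        return self.dphi.size

    @classmethod
    def from_phases(cls, dphi: np.ndarray) -> "PhasePairSeries":
        """Build from a phase-difference series alone (unit amplitudes)."""
        dphi = np.asarray(dphi, dtype=float)
        return cls(dphi=dphi, imag_cross=np.sin(dphi))


def phase_pair(za: np.ndarray, zb: np.ndarray) -> PhasePairSeries:
    """Pair series from two analytic signals of equal length."""
    za = np.asarray(za)
    zb = np.asarray(zb)
    if za.shape != zb.shape:
        raise ValueError("analytic signals must have equal shape")
    cross = za * np.conj(zb)
    dphi = np.angle(cross)
    return PhasePairSeries(dphi=dphi, imag_cross=cross.imag)


def pli(pair: PhasePairSeries) -> float:
    """Phase lag index: |mean sign(sin Δφ)| ∈ [0, 1].

    Samples with sin(Δφ) exactly 0 (no lead or lag) contribute 0 to the
    average — they are counted in N but push the index toward 0.
    """
    return float(np.abs(np.mean(np.sign(np.sin(pair.dphi)))))


def wpli(pair: PhasePairSeries) -> float:
    """Weighted phase lag index: |⟨I⟩| / ⟨|I|⟩ ∈ [0, 1].

    A pair with identically zero imaginary cross-component (pure zero-lag
    relationship, e.g. volume conduction of a single source) has an
    undefined 0/0 ratio; it is reported as 0 — no detectable lagged
    coupling — with a warning.
    """
    denom = float(np.mean(np.abs(pair.imag_cross)))
    if denom == 0.0:
        warnings.warn(
            "WPLI denominator is zero (pure zero-lag pair); returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.abs(np.mean(pair.imag_cross)) / denom)


def pair_index(n_channels: int) -> list[tuple[int, int]]:
    """Ordered unordered-pair index: (i, j) with i < j, row-major."""
    return [(i, j) for i in range(n_channels - 1)
            for j in range(i + 1, n_channels)]


def _pairwise_metrics(
    Z: np.ndarray, metrics: Sequence[str]
) -> dict[str, np.ndarray]:
    """PLI/WPLI for all channel pairs of one analytic-signal block.

    ``Z`` is channels × time (complex).  Returns condensed vectors in
    ``pair_index`` order.  Vectorized per anchor channel; this is the hot
    loop of the cohort pipeline.
    """
    n = Z.shape[0]
    npairs = n * (n - 1) // 2
    out = {m: np.empty(npairs) for m in metrics}
    k = 0
    for i in range(n - 1):
        cross_im = (Z[i] * np.conj(Z[i + 1:])).imag  # (n-i-1, T)
        stop = k + cross_im.shape[0]
        if "pli" in out:
            out["pli"][k:stop] = np.abs(np.sign(cross_im).mean(axis=1))
        if "wpli" in out:
            num = np.abs(cross_im.mean(axis=1))
            den = np.abs(cross_im).mean(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
            out["wpli"][k:stop] = w
        k = stop
    return out


@dataclass
class ConnectivityTensor:
    """Subjects × bands × channel-pairs connectivity values in [0, 1].

    Only the upper triangle (i < j over the channel-label ordering) is
    stored; the metric is symmetric by construction.
    """

    values: np.ndarray
    metric: str
    subject_ids: tuple[str, ...]
    groups: tuple[str, ...]
    band_names: tuple[str, ...]
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_pairs = len(self.channel_labels) * (len(self.channel_labels) - 1) // 2
        expect = (len(self.subject_ids), len(self.band_names), n_pairs)
        if self.values.shape != expect:
            raise ValueError(
                f"values shape {self.values.shape} != expected {expect}"
            )

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pair_index(len(self.channel_labels))

    @property
    def pair_labels(self) -> list[tuple[str, str]]:
        labs = self.channel_labels
        return [(labs[i], labs[j]) for i, j in self.pairs]

    @property
    def n_features(self) -> int:
        return self.values.shape[1] * self.values.shape[2]

    def feature_matrix(self) -> np.ndarray:
        """Subjects × (band, pair) flattened feature matrix."""
        return self.values.reshape(self.values.shape[0], -1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: subject_id, group, band, chan_a, chan_b, value."""
        rows = []
        plabs = self.pair_labels
        for s, (sid, grp) in enumerate(zip(self.subject_ids, self.groups)):
            for b, band in enumerate(self.band_names):
                vals = self.values[s, b]
                rows.append(pd.DataFrame({
                    "subject_id": sid,
                    "group": grp,
                    "band": band,
                    "chan_a": [p[0] for p in plabs],
                    "chan_b": [p[1] for p in plabs],
                    "value": vals,
                }))
        return pd.concat(rows, ignore_index=True)


def subject_connectivity(
    recording: Recording,
    metrics: Sequence[str] = METRICS,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    amp_threshold: float = 100.0,
    min_segment: float = 10.0,
    edge_trim: float = 1.0,
    segments: CleanSegments | None = None,
) -> dict[str, np.ndarray]:
    """Band × pair connectivity for one subject, all requested metrics.

    Runs broadband (1–60 Hz) + notch filtering and artifact rejection,
    then per band: FIR band-pass of the continuous series, analytic signal
    per clean segment, ``edge_trim`` seconds discarded at each segment end
    (filter/Hilbert transients), per-segment metrics combined as a
    duration-weighted mean.
    """
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}; choose from {METRICS}")
    clean = broadband_clean(recording)
    if segments is None:
        segments = reject_artifacts(
            clean, amp_threshold=amp_threshold, min_segment=min_segment
        )
    if segments.excluded or not segments.intervals:
        raise ValueError(
            f"subject {recording.subject_id!r} has no usable clean segment"
            + (f" ({segments.reason})" if segments.reason else "")
        )
    fs = recording.fs
    trim = int(round(edge_trim * fs))
    n_ch = recording.n_channels
    npairs = n_ch * (n_ch - 1) // 2
    out = {m: np.empty((len(bands), npairs)) for m in metrics}
    for b, band in enumerate(bands):
        xb = fir_bandpass(clean.samples, fs, band.f_low, band.f_high)
        acc = {m: np.zeros(npairs) for m in metrics}
        total_w = 0.0
        for start, end in segments.intervals:
            seg = xb[:, start:end]
            seg = seg - seg.mean(axis=1, keepdims=True)
            if seg.shape[1] - 2 * trim < 64:
                continue
            Z = analytic_signal(seg)[:, trim:seg.shape[1] - trim]
            w = Z.shape[1] / fs
            vals = _pairwise_metrics(Z, metrics)
            for m in metrics:
                acc[m] += w * vals[m]
            total_w += w
        if total_w == 0.0:
            raise ValueError(
                f"subject {recording.subject_id!r}: all clean segments too "
                "short after edge trimming"
            )
        for m in metrics:
            out[m][b] = acc[m] / total_w
    return out


def connectivity_tensor(
    cohort: Iterable[Recording],
    metric: str | Sequence[str] = "pli",
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    amp_threshold: float = 100.0,
    min_segment: float = 10.0,
    edge_trim: float = 1.0,
) -> ConnectivityTensor | dict[str, ConnectivityTensor]:
    """Connectivity tensor(s) for a cohort of recordings.

    With a single metric name returns one :class:`ConnectivityTensor`;
    with a sequence, a dict keyed by metric (the expensive per-subject
    pipeline is shared).  All subjects must share channel labels.
    """
    single = isinstance(metric, str)
    metrics = (metric,) if single else tuple(metric)
    recs = list(cohort)
    if not recs:
        raise ValueError("empty cohort")
    labels = recs[0].channel_labels
    for r in recs:
        if r.channel_labels != labels:
            raise ValueError(
                f"subject {r.subject_id!r} has different channel labels"
            )
    per_subject = [
        subject_connectivity(
            r, metrics=metrics, bands=bands, amp_threshold=amp_threshold,
            min_segment=min_segment, edge_trim=edge_trim,
        )
        for r in recs
    ]
    band_names = tuple(b.name for b in bands)
    sids = tuple(r.subject_id for r in recs)
    grps = tuple(r.group for r in recs)
    tensors = {
        m: ConnectivityTensor(
            values=np.stack([ps[m] for ps in per_subject]),
            metric=m.upper(),
            subject_ids=sids,
            groups=grps,
            band_names=band_names,
            channel_labels=labels,
        )
        for m in metrics
    }
    return tensors[metric] if single else tensors
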