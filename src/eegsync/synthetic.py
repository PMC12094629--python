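"""Two-group synthetic EEG cohorts with planted phase-lag coupling.

Every downstream stage (filtering, PLI/WPLI, feature selection,
classification) is exercised against cohorts generated here, because the
study population this package emulates — resting-state EEG from an
internet-addiction (IA) group and healthy controls (HC) — has no public
recordings.  The generator plants a known ground truth:

* each channel carries 1/f (pink) background noise;
* each :class:`CouplingSpec` adds a shared narrowband source to one
  channel pair, the second channel receiving it delayed by
  ``phase_lag / (2π f_center)`` seconds — a frequency-consistent phase
  offset within the band — and scaled by the group's strength;
* a symmetric, diagonally dominant zero-lag mixing matrix with
  distance-decaying off-diagonal entries is applied last, emulating
  volume conduction (which must NOT register as phase-lag connectivity).

Sources are band-pass-filtered Gaussian noise, not sinusoids, so the
instantaneous phase is nondegenerate.  Group differences are planted by
giving IA subjects a different coupling strength than HC subjects,
mirroring the frontal-delta / occipital-gamma pattern in which the IA
group shows the stronger synchronization.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .bands import get_band
from .montage import CHANNELS_32, distance_matrix
from .preprocess import fir_bandpass
from .recording import Recording

__all__ = [
    "CouplingSpec",
    "SyntheticConfig",
    "generate_subject",
    "generate_cohort",
    "study_couplings",
    "pink_noise",
    "mixing_matrix",
]


@dataclass(frozen=True)
class CouplingSpec:
    """One planted phase-lag coupling between a channel pair in one band.

    ``phase_lag`` (radians) must be nonzero and not ±π: a coupling at
    exactly zero or π lag has no imaginary cross-spectral component and is
    invisible to PLI/WPLI by design.  ``strength_hc`` / ``strength_ia``
    are source amplitudes as multiples of the background noise SD.
    """

    pair: tuple[str, str]
    band: str
    phase_lag: float
    strength_hc: float
    strength_ia: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", tuple(self.pair))
        if len(self.pair) != 2 or self.pair[0] == self.pair[1]:
            raise ValueError(f"pair must be two distinct labels, got {self.pair}")
        get_band(self.band)  # raises on unknown band
        lag = float(self.phase_lag)
        if not np.isfinite(lag) or lag == 0.0 or abs(abs(lag) - np.pi) < 1e-12 \
                or not -np.pi < lag < np.pi:
            raise ValueError(
                "phase_lag must lie in (−π, π) excluding 0 and ±π "
                f"(got {self.phase_lag})"
            )
        for s in (self.strength_hc, self.strength_ia):
            if not np.isfinite(s) or s < 0:
                raise ValueError(f"strengths must be finite and >= 0, got {s}")

    def strength(self, group: str) -> float:
        return self.strength_ia if group == "IA" else self.strength_hc


@dataclass
class SyntheticConfig:
    """Full generative specification of a two-group cohort.

    Defaults match the emulated study design where stated — 42 IA and 50 HC
    subjects on a 32-channel cap — while the sampling rate and duration
    default to desk-scale values (250 Hz, 60 s) rather than the study's
    1000 Hz × 5 min; both are overridable.
    """

    n_ia: int = 42
    n_hc: int = 50
    channel_labels: tuple[str, ...] = CHANNELS_32
    fs: float = 250.0
    duration: float = 60.0
    couplings: tuple[CouplingSpec, ...] = ()
    mixing_spread: float = 0.3
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.couplings = tuple(self.couplings)
        if self.n_ia < 2 or self.n_hc < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.fs < 120.0:
            raise ValueError(
                f"fs={self.fs} Hz violates Nyquist for the 60-Hz band edge "
                "(need >= 120 Hz)"
            )
        if self.duration < 10.0:
            raise ValueError("duration must be at least 10 s")
        if self.mixing_spread < 0:
            raise ValueError("mixing_spread must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for c in self.couplings:
            band = get_band(c.band)
            if self.fs < 2 * band.f_high:
                raise ValueError(
                    f"fs={self.fs} Hz violates Nyquist for band {c.band!r} "
                    f"(upper edge {band.f_high} Hz)"
                )
            for lab in c.pair:
                if lab not in self.channel_labels:
                    raise ValueError(f"coupling channel {lab!r} not in montage")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def to_manifest(self) -> dict:
        """JSON-serializable echo of the full configuration."""
        d = asdict(self)
        d["channel_labels"] = list(self.channel_labels)
        d["couplings"] = [
            {**asdict(c), "pair": list(c.pair)} for c in self.couplings
        ]
        return d


def pink_noise(rng: np.random.Generator, shape: tuple[int, int],
               exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent Gaussian noise, unit SD per row, via spectral shaping."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _fractional_delay(x: np.ndarray, delay_samples: float) -> np.ndarray:
    """Circular fractional delay via a frequency-domain phase ramp."""
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(n)
    spec *= np.exp(-2j * np.pi * freqs * delay_samples)
    return np.fft.irfft(spec, n=n, axis=-1)


def mixing_matrix(
    labels: tuple[str, ...],
    spread: float,
    length_scale: float = 0.4,
) -> np.ndarray:
    """Symmetric zero-lag volume-conduction mixing, unit diagonal.

    Off-diagonal leakage decays as a Gaussian of inter-electrode distance
    with the given length scale (head-radius units) and is normalized so
    the largest off-diagonal row sum equals ``spread`` — every channel's
    own signal stays dominant for spread < 1.
    """
    if spread == 0:
        return np.eye(len(labels))
    d = distance_matrix(labels)
    K = np.exp(-(d ** 2) / (2 * length_scale ** 2))
    np.fill_diagonal(K, 0.0)
    row_max = K.sum(axis=1).max()
    return np.eye(len(labels)) + (spread / row_max) * K


def _band_source(rng: np.random.Generator, n: int, fs: float,
                 band_name: str, edge_margin: float = 0.2) -> np.ndarray:
    """Unit-RMS narrowband Gaussian source (band-passed white noise).

    The source occupies the central part of the band: each edge is pulled
    in by ``edge_margin`` of the bandwidth, so a source planted in one
    analysis band does not bleed lagged energy into its neighbours through
    the finite filter transitions.
    """
    band = get_band(band_name)
    width = band.f_high - band.f_low
    lo = band.f_low + edge_margin * width
    hi = band.f_high - edge_margin * width
    # generate with 2 s padding per side, crop after filtering
    pad = int(round(2 * fs))
    raw = rng.standard_normal(n + 2 * pad)
    s = fir_bandpass(raw, fs, lo, hi)[pad:pad + n]
    rms = np.sqrt(np.mean(s ** 2))
    return s / (rms if rms > 0 else 1.0)


def generate_subject(
    config: SyntheticConfig, group: str, subject_seed: int | np.random.SeedSequence
) -> Recording:
    """One subject's recording under the config's generative model.

    Deterministic for a fixed ``(config, group, subject_seed)``.
    """
    if group not in ("IA", "HC"):
        raise ValueError(f"group must be 'IA' or 'HC', got {group!r}")
    rng = np.random.default_rng(subject_seed)
    n = config.n_samples
    labels = config.channel_labels
    x = config.noise_sd * pink_noise(rng, (config.n_channels, n))
    idx = {lab: i for i, lab in enumerate(labels)}
    for c in config.couplings:
        amp = c.strength(group) * config.noise_sd
        if amp == 0:
            continue
        source = _band_source(rng, n, config.fs, c.band)
        f_center = get_band(c.band).center
        delay = c.phase_lag / (2 * np.pi * f_center) * config.fs  # samples
        x[idx[c.pair[0]]] += amp * source
        x[idx[c.pair[1]]] += amp * _fractional_delay(source, delay)
    M = mixing_matrix(labels, config.mixing_spread)
    x = M @ x
    return Recording(
        samples=x, fs=config.fs, channel_labels=labels, group=group
    )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[Recording], dict]:
    """All n_ia + n_hc recordings plus the ground-truth manifest.

    Per-subject seeds are derived from the master seed and the subject
    index through :class:`numpy.random.SeedSequence`, so the cohort is
    reproducible and individual subjects can be regenerated independently.
    """
    recordings: list[Recording] = []
    for i in range(config.n_ia + config.n_hc):
        group = "IA" if i < config.n_ia else "HC"
        ss = np.random.SeedSequence([int(config.seed), i])
        rec = generate_subject(config, group, ss)
        rec.subject_id = f"{group.lower()}{i:03d}"
        recordings.append(rec)
    manifest = {
        "config": config.to_manifest(),
        "subjects": [
            {"subject_id": r.subject_id, "group": r.group}
            for r in recordings
        ],
        "planted_couplings": [
            {
                "pair": list(c.pair),
                "band": c.band,
                "phase_lag": c.phase_lag,
                "strength_hc": c.strength_hc,
                "strength_ia": c.strength_ia,
            }
            for c in config.couplings
        ],
    }
    return recordings, manifest


def study_couplings(
    strength_hc: float = 1.0,
    ratio: float = 2.0,
    lag: float = np.pi / 4,
) -> tuple[CouplingSpec, ...]:
    """The default planted pattern emulating the reported group contrast.

    Frontal delta-band pairs and occipital-weighted gamma-band pairs,
    each stronger in the IA group by ``ratio``; lags default to π/4, far
    from both PLI blind spots (0 and π).
    """
    ia = strength_hc * ratio
    mk = lambda pair, band: CouplingSpec(  # noqa: E731
        pair=pair, band=band, phase_lag=lag,
        strength_hc=strength_hc, strength_ia=ia,
    )
    return (
        mk(("F3", "F4"), "delta"),
        mk(("Fp1", "Fz"), "delta"),
        mk(("F7", "F8"), "delta"),
        mk(("O1", "O2"), "gamma1"),
        mk(("POz", "Oz"), "gamma1"),
        mk(("P3", "O1"), "gamma3"),
    )
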