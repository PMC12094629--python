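"""Canonical EEG frequency bands.

The analysis partitions 1–60 Hz into eight bands: the classical delta,
theta and alpha bands, a split beta (12–21, 21–30 Hz) and a three-way
split gamma (30–40, 40–50, 50–60 Hz).  Band-limited copies of a recording
are produced by zero-phase FIR filtering at these edges before phase
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got ({self.f_low}, {self.f_high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)


CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta1", 12.0, 21.0),
    BandSpec("beta2", 21.0, 30.0),
    BandSpec("gamma1", 30.0, 40.0),
    BandSpec("gamma2", 40.0, 50.0),
    BandSpec("gamma3", 50.0, 60.0),
)

BAND_BY_NAME: dict[str, BandSpec] = {b.name: b for b in CANONICAL_BANDS}


def get_band(name: str) -> BandSpec:
    """Look up a canonical band by name; raise with the valid names otherwise."""
    try:
        return BAND_BY_NAME[name]
    except KeyError:
        raise ValueError(
            f"unknown band {name!r}; canonical bands are "
            f"{sorted(BAND_BY_NAME)}"
        ) from None
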