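"""Canonical frequency-band definitions.

The default band set is the eight-band scheme common in resting-state EEG
work on auditory phantom perception: delta through gamma, spanning the
2-44 Hz passband of the preprocessing stage.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi] in Hz (edges inclusive)."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )

    def contains(self, f: float) -> bool:
        return self.f_lo <= f <= self.f_hi


#: The canonical eight bands (Hz). LOW_BANDS/HIGH_BANDS partition them for
#: cross-frequency coupling analyses.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 3.5),
    BandDefinition("theta", 4.0, 7.5),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 12.0),
    BandDefinition("beta1", 13.0, 18.0),
    BandDefinition("beta2", 18.5, 21.0),
    BandDefinition("beta3", 21.5, 30.0),
    BandDefinition("gamma", 30.5, 44.0),
)

LOW_BANDS = ("delta", "theta", "alpha1", "alpha2")
HIGH_BANDS = ("beta1", "beta2", "beta3", "gamma")

_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


def get_band(name: str) -> BandDefinition:
    """Look up a canonical band by name."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known: {sorted(_BY_NAME)}"
        ) from None
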