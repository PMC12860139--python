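"""Health-state space: monthly-migraine-day (MMD) severity bands.

The model classifies patients into six disjoint bands of monthly migraine
days.  The first three bands (<15 MMD) are episodic migraine (EM), the last
three (>=15 MMD) chronic migraine (CM), following the International Headache
Society cut-off of 15 MMD.  Band display labels follow the transition-table
convention ("20-24", "24+") while the underlying integer ranges are kept
disjoint (20-23, >=24).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class MmdBand:
    """One severity band of monthly migraine days.

    Parameters
    ----------
    label : str
        Display label, e.g. ``"4-9"`` or ``"24+"``.
    lower : int
        Smallest integer MMD in the band.
    upper : int or None
        Largest integer MMD in the band; ``None`` for the unbounded top band.
    """

    label: str
    lower: int
    upper: int | None

    @property
    def is_chronic(self) -> bool:
        """True for chronic-migraine bands (>=15 MMD)."""
        return self.lower >= 15

    def contains(self, mmd_int: int) -> bool:
        if mmd_int < self.lower:
            return False
        return self.upper is None or mmd_int <= self.upper

    @property
    def midpoint(self) -> float:
        if self.upper is None:
            raise ValueError(f"band {self.label!r} is unbounded")
        return (self.lower + self.upper) / 2.0


#: The six model states, ordered from least to most severe.
BANDS: tuple[MmdBand, ...] = (
    MmdBand("0-3", 0, 3),
    MmdBand("4-9", 4, 9),
    MmdBand("10-14", 10, 14),
    MmdBand("15-19", 15, 19),
    MmdBand("20-24", 20, 23),
    MmdBand("24+", 24, None),
)

BAND_LABELS: tuple[str, ...] = tuple(b.label for b in BANDS)
N_BANDS: int = len(BANDS)

#: Representative MMD value per band used for expected-MMD summaries:
#: band midpoints, with the unbounded top band represented by 26 days.
DEFAULT_BAND_VALUES: tuple[float, ...] = (1.5, 6.5, 12.0, 17.0, 21.5, 26.0)

_LABEL_TO_INDEX = {b.label: i for i, b in enumerate(BANDS)}


def band_index(label: str) -> int:
    """Index of a band given its display label."""
    try:
        return _LABEL_TO_INDEX[label]
    except KeyError:
        raise KeyError(
            f"unknown band label {label!r}; expected one of {BAND_LABELS}"
        ) from None


def band_of_mmd(mmd: float) -> MmdBand:
    """Map a (possibly fractional) MMD count to its severity band.

    Fractional values are rounded half-up to an integer day count before
    banding; anything rounding to >=24 falls in the open-ended top band.

    Raises
    ------
    ValueError
        If ``mmd`` is negative or not finite.
    """
    if not math.isfinite(mmd):
        raise ValueError(f"MMD must be finite, got {mmd!r}")
    if mmd < 0:
        raise ValueError(f"MMD must be non-negative, got {mmd!r}")
    mmd_int = math.floor(mmd + 0.5)  # round half-up; bands are integer days
    for band in BANDS:
        if band.contains(mmd_int):
            return band
    raise AssertionError("bands must cover all non-negative integers")


def band_index_of_mmd(mmd: float) -> int:
    """Index (0..5) of the band containing ``mmd``."""
    return band_index(band_of_mmd(mmd).label)
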