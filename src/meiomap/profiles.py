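"""Binned, strand-resolved coverage containers.

All coverage in this package lives on a symmetric 20-bp grid around a
hotspot center: bin ``l`` covers ``[w*(l - 1/2), w*(l + 1/2))`` bp relative
to the center (lower-closed), where ``w`` is the bin width.  Index 0 of the
arrays corresponds to bin ``-m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_BIN_WIDTH = 20


@dataclass
class StrandProfile:
    """Per-strand binned coverage around one hotspot center.

    Parameters
    ----------
    crick, watson
        Per-bin read coverage on each strand, equal length ``2*m + 1``.
    bin_width
        Bin width in bp (20 by default).
    origin
        Genomic coordinate of the hotspot center, used only for I/O.
    """

    crick: np.ndarray
    watson: np.ndarray
    bin_width: int = DEFAULT_BIN_WIDTH
    origin: float = 0.0
    chrom: str = field(default="chrS")

    def __post_init__(self) -> None:
        self.crick = np.asarray(self.crick, dtype=float)
        self.watson = np.asarray(self.watson, dtype=float)
        if self.crick.shape != self.watson.shape or self.crick.ndim != 1:
            raise ValueError("crick and watson must be 1-D arrays of equal length")
        if len(self.crick) % 2 != 1:
            raise ValueError("profiles must have an odd number of bins (symmetric grid)")

    @property
    def m(self) -> int:
        """Half-width of the grid in bins."""
        return (len(self.crick) - 1) // 2

    @property
    def span(self) -> int:
        """Half-width of the grid in bp."""
        return self.m * self.bin_width

    def bin_centers(self) -> np.ndarray:
        """Bin midpoints in bp relative to the hotspot center."""
        return np.arange(-self.m, self.m + 1) * self.bin_width

    def mirrored(self) -> "StrandProfile":
        """Reflect coordinates and swap strands (left/right flip)."""
        return replace(self, crick=self.watson[::-1].copy(), watson=self.crick[::-1].copy())

    def total(self) -> np.ndarray:
        """Strand-summed coverage."""
        return self.crick + self.watson

    def scaled(self, a: float) -> "StrandProfile":
        return replace(self, crick=self.crick * a, watson=self.watson * a)


def check_same_binning(profiles) -> None:
    """Raise ValueError unless all profiles share bin width and grid size."""
    first = profiles[0]
    for p in profiles[1:]:
        if p.bin_width != first.bin_width or len(p.crick) != len(first.crick):
            raise ValueError("profiles do not share binning")


def sum_profiles(profiles) -> StrandProfile:
    """Total coverage over a hotspot set (the aggregate the solver consumes)."""
    check_same_binning(profiles)
    crick = np.sum([p.crick for p in profiles], axis=0)
    watson = np.sum([p.watson for p in profiles], axis=0)
    return StrandProfile(crick, watson, bin_width=profiles[0].bin_width)
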