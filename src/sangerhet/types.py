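"""Core record types shared across the package.

Everything downstream operates on a :class:`ChromatogramTrace`: the four
per-nucleotide fluorescence intensity arrays of a Sanger run, the base calls
made by the sequencer, and the scan index of each called base's peak. Variant
records (:class:`SnpCall`, :class:`IndelCall`) carry the caller's evidence so
reports can be audited by eye against the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

BASES = ("A", "C", "G", "T")


class TraceFormatError(ValueError):
    """A trace file is unreadable, truncated, or missing a required record."""


class EmptyTraceError(TraceFormatError):
    """A trace file contains no called bases or no sample points."""


class DegenerateFeatureError(ValueError):
    """Feature extraction hit a zero denominator; treat position as non-SNP."""


@dataclass
class ChromatogramTrace:
    """Four-channel chromatogram with base calls anchored to scan positions.

    Scan indices and base indices are 0-based throughout the library; text
    reports convert base positions to 1-based on output.
    """

    sample_id: str
    channels: dict[str, np.ndarray]
    called_bases: str
    peak_scans: np.ndarray

    def __post_init__(self) -> None:
        if set(self.channels) != set(BASES):
            raise ValueError(f"channels must be exactly {BASES}")
        self.channels = {b: np.asarray(self.channels[b], dtype=float) for b in BASES}
        self.peak_scans = np.asarray(self.peak_scans, dtype=int)
        n = self.length_scans
        for b in BASES:
            if self.channels[b].ndim != 1 or len(self.channels[b]) != n:
                raise ValueError("all four channel arrays must have equal length")
            if np.any(self.channels[b] < 0):
                raise ValueError(f"negative intensities in channel {b}")
        if len(self.called_bases) != len(self.peak_scans):
            raise ValueError("called_bases and peak_scans must have equal length")
        if len(self.peak_scans):
            if np.any(np.diff(self.peak_scans) <= 0):
                raise ValueError("peak_scans must be strictly increasing")
            if self.peak_scans[0] < 0 or self.peak_scans[-1] >= n:
                raise ValueError("peak_scans out of range")
        bad = set(self.called_bases) - set(BASES) - {"N"}
        if bad:
            raise ValueError(f"called_bases contains invalid letters {bad}")

    @property
    def length_scans(self) -> int:
        return len(self.channels["A"])

    @property
    def n_bases(self) -> int:
        return len(self.called_bases)


@dataclass(frozen=True)
class PeakGeometry:
    """One wave: left-bottom (L), middle-top (M) and right-bottom (R) points.

    ``resolved`` is False when the wave had no local maximum of its own
    (merged into a neighbouring identical base's peak) and the geometry is a
    window-spanning fallback; such flank points are not measurements.
    """

    channel: str
    L: tuple[int, float]
    M: tuple[int, float]
    R: tuple[int, float]
    resolved: bool = True

    def __post_init__(self) -> None:
        if not (self.L[0] < self.M[0] < self.R[0]):
            raise ValueError("wave points must satisfy L.x < M.x < R.x")
        if self.M[1] < self.L[1] or self.M[1] < self.R[1]:
            raise ValueError("M must be the highest point of the wave")

    @property
    def height(self) -> float:
        return self.M[1]

    @property
    def half_extent(self) -> float:
        """Sum of the two vertical half-extents |yM-yL| + |yM-yR|."""
        return abs(self.M[1] - self.L[1]) + abs(self.M[1] - self.R[1])


@dataclass(frozen=True)
class BasePositionFeatures:
    """The three double-peak features at one called-base position.

    horizontal_distance: scans between the two apices.
    height_ratio: primary apex height over secondary apex height (>= 1).
    halfwave_width_ratio: ratio of the summed vertical half-extents.
    """

    horizontal_distance: float
    height_ratio: float
    halfwave_width_ratio: float
    base_index: int
    primary_base: str
    secondary_base: str

    def __post_init__(self) -> None:
        vals = (self.horizontal_distance, self.height_ratio, self.halfwave_width_ratio)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("features must be finite")
        if self.height_ratio < 1.0:
            raise ValueError("height_ratio must be >= 1 (primary is taller)")


@dataclass(frozen=True)
class NoisyWaveRule:
    """Thresholds defining a 'noisy wave' near a candidate SNP.

    A spurious wave counts as noisy when its height exceeds
    ``height_fraction`` of the secondary peak's height AND its vertical
    half-extent exceeds ``width_fraction`` of the secondary's.
    """

    height_fraction: float = 0.70
    width_fraction: float = 0.50
    window_bases: int = 2

    def __post_init__(self) -> None:
        for f in (self.height_fraction, self.width_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must lie in (0, 1)")


@dataclass(frozen=True)
class SnpCall:
    base_index: int
    primary_base: str
    secondary_base: str
    score: float
    grade: int
    noisy_count: int

    def __post_init__(self) -> None:
        if not 1.0 <= self.score <= 100.0:
            raise ValueError("score out of [1, 100]")
        if not 1 <= self.grade <= 6:
            raise ValueError("grade out of 1..6")


@dataclass(frozen=True)
class IndelCall:
    """A heterozygous InDel: signed size m, '+' = the primary (top-peak)
    allele carries the extra bases relative to the secondary allele."""

    size_m: int
    start_index: int
    matchability: float
    allele_long: str
    allele_short: str

    def __post_init__(self) -> None:
        if not 1 <= abs(self.size_m) <= 30:
            raise ValueError("|m| must lie in 1..30")
        if not 0.0 <= self.matchability <= 1.0:
            raise ValueError("matchability out of [0, 1]")

    @property
    def sign(self) -> str:
        return "+" if self.size_m > 0 else "-"


@dataclass(frozen=True)
class DoublePeakRegion:
    """A stretch of base positions dominated by continuous double peaks.

    ``secondary_seq`` uses 'N' at positions inside the region where no
    secondary peak was resolvable (the two alleles share a base there).
    """

    start_index: int
    end_index: int
    primary_seq: str
    secondary_seq: str

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("start_index must be <= end_index")
        n = self.end_index - self.start_index + 1
        if len(self.primary_seq) != n or len(self.secondary_seq) != n:
            raise ValueError("sequence lengths must equal region length")


@dataclass
class VariantReport:
    sample_id: str
    snp_calls: list[SnpCall] = field(default_factory=list)
    indel_call: Optional[IndelCall] = None
    allele_sequences: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        pos = [c.base_index for c in self.snp_calls]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("snp_calls must be sorted by unique base position")
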