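"""Wave location and double-peak feature extraction.

At every called-base position the four denoised channels are examined. The
channel carrying the most intensity at the called peak scan is the primary
peak (the called base); the strongest genuine wave on the remaining channels
is the secondary peak when it clears a floor fraction of the primary — the
signature of the second allele at a heterozygous site. Three features
summarise the double peak: the horizontal distance between apices, the apex
height ratio, and the half-wave width ratio
(|y1-y2| + |y1-y3|) / (|y4-y5| + |y4-y6|) built from the vertical
half-extents of the two waves.

Two artefacts of real traces shape the implementation. Consecutive
identical bases merge into one broad wave with no interior local maximum at
the flanking positions, so the primary wave falls back to a window-spanning
geometry when no apex is resolvable. And the rising tail of a neighbouring
base's peak carries noise bumps that are local maxima but not waves; a
genuine wave must have a vertical half-extent that is a sizeable fraction of
its height (``prominence_fraction``). Denoised channels are piecewise
constant over 2**levels-scan blocks, so apices arrive as plateaus; the
plateau centre is taken as the apex scan.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .types import (
    BASES,
    BasePositionFeatures,
    ChromatogramTrace,
    DegenerateFeatureError,
    NoisyWaveRule,
    PeakGeometry,
)

#: minimum half-extent/height for a local maximum to count as a wave
PROMINENCE_FRACTION = 0.25


class MalformedPositionError(ValueError):
    """No signal on any channel at a base position."""


def median_peak_spacing(trace: ChromatogramTrace) -> float:
    """Median scan distance between consecutive called-base peaks."""
    if trace.n_bases < 2:
        return float(trace.length_scans)
    return float(np.median(np.diff(trace.peak_scans)))


def default_search_halfwidth(trace: ChromatogramTrace) -> int:
    """Half the median inter-peak spacing, floored at 2 scans."""
    return max(2, int(round(median_peak_spacing(trace) / 2.0)))


def _plateaus(signal: np.ndarray, lo: int, hi: int):
    """Yield (start, end, value) runs of equal value intersecting [lo, hi]."""
    n = len(signal)
    i = max(lo, 0)
    while i > 0 and signal[i - 1] == signal[i]:
        i -= 1
    while i <= hi:
        j = i
        while j + 1 < n and signal[j + 1] == signal[j]:
            j += 1
        yield i, j, signal[i]
        i = j + 1


def locate_wave(
    channel_signal: np.ndarray, center_scan: int, search_halfwidth: int
) -> Optional[PeakGeometry]:
    """Locate the highest wave within ``center_scan ± search_halfwidth``.

    M is the centre of the highest local-maximum plateau in the window; L and
    R are the nearest local minima (or window edges) on either side. Returns
    None when the window holds no positive local maximum or the wave cannot
    be given distinct L < M < R points.
    """
    signal = np.asarray(channel_signal, dtype=float)
    n = len(signal)
    if search_halfwidth < 2:
        raise ValueError("search_halfwidth must be >= 2")
    if not 0 <= center_scan < n:
        raise ValueError("center_scan outside signal")
    lo = max(0, center_scan - search_halfwidth)
    hi = min(n - 1, center_scan + search_halfwidth)

    best = None
    for s, e, v in _plateaus(signal, lo, hi):
        left_ok = s == 0 or signal[s - 1] < v
        right_ok = e == n - 1 or signal[e + 1] < v
        if left_ok and right_ok and v > 0:
            apex = (s + e) // 2
            if lo <= apex <= hi and (best is None or v > best[0]):
                best = (v, apex, s, e)
    if best is None:
        return None
    v, apex, s, e = best

    # walk down each flank to the nearest local minimum; the wave's support
    # is wider than the apex-search window, so the walk may leave it
    flo = max(0, apex - 2 * search_halfwidth)
    fhi = min(n - 1, apex + 2 * search_halfwidth)
    k = s
    while k > flo and signal[k - 1] <= signal[k]:
        k -= 1
    left = (k, float(signal[k]))
    k = e
    while k < fhi and signal[k + 1] <= signal[k]:
        k += 1
    right = (k, float(signal[k]))
    if not (left[0] < apex < right[0]):
        return None
    return PeakGeometry(channel="?", L=left, M=(apex, float(v)), R=right)


def _fallback_wave(
    signal: np.ndarray, center: int, halfwidth: int
) -> Optional[PeakGeometry]:
    """Window-spanning geometry for a merged peak with no interior apex."""
    n = len(signal)
    lo = max(0, center - halfwidth)
    hi = min(n - 1, center + halfwidth)
    v = float(signal[center])
    if v <= 0 or not (lo < center < hi):
        return None
    return PeakGeometry(
        channel="?",
        L=(lo, min(float(signal[lo]), v)),
        M=(center, v),
        R=(hi, min(float(signal[hi]), v)),
        resolved=False,
    )


def is_genuine_wave(
    geom: PeakGeometry, prominence_fraction: float = PROMINENCE_FRACTION
) -> bool:
    """True when the wave rises well clear of its flanks (not a tail bump)."""
    return geom.half_extent >= prominence_fraction * geom.height


def _genuine_waves_at(
    trace: ChromatogramTrace,
    base_index: int,
    search_halfwidth: int,
    prominence_fraction: float = PROMINENCE_FRACTION,
) -> dict[str, PeakGeometry]:
    """Genuine waves per channel around a called-base position."""
    center = int(trace.peak_scans[base_index])
    out: dict[str, PeakGeometry] = {}
    for b in BASES:
        g = locate_wave(trace.channels[b], center, search_halfwidth)
        if g is not None and is_genuine_wave(g, prominence_fraction):
            out[b] = PeakGeometry(channel=b, L=g.L, M=g.M, R=g.R)
    return out


def _wave_at(
    trace: ChromatogramTrace, channel: str, center: int, halfwidth: int
) -> Optional[PeakGeometry]:
    g = locate_wave(trace.channels[channel], center, halfwidth)
    if g is None:
        g = _fallback_wave(trace.channels[channel], center, halfwidth)
    if g is None:
        return None
    return PeakGeometry(channel=channel, L=g.L, M=g.M, R=g.R, resolved=g.resolved)


def primary_secondary(
    trace: ChromatogramTrace,
    base_index: int,
    search_halfwidth: Optional[int] = None,
    floor_fraction: float = 0.10,
) -> tuple[PeakGeometry, Optional[PeakGeometry]]:
    """Primary and secondary wave at a called-base position.

    Channels are ranked by their intensity at the called peak scan (ties
    broken by fixed channel order A < C < G < T): the strongest is the
    primary, the runner-up the secondary when it clears ``floor_fraction``
    of the primary. Ranking by at-scan intensity rather than in-window wave
    height keeps the rising tails of neighbouring peaks from outranking the
    signal that is actually present at this base's migration time. Each
    wave's geometry is the highest local maximum in the search window, or a
    window-spanning fallback when adjacent identical bases merged the apex
    away. Should the located geometries come out height-inverted, the roles
    are swapped so the primary is never the lower wave.
    """
    if search_halfwidth is None:
        search_halfwidth = default_search_halfwidth(trace)
    center = int(trace.peak_scans[base_index])
    vals = {b: float(trace.channels[b][center]) for b in BASES}
    primary_channel = max(BASES, key=lambda b: vals[b])  # max is stable: A<C<G<T
    primary = _wave_at(trace, primary_channel, center, search_halfwidth)
    if primary is None:
        raise MalformedPositionError(
            f"no signal on any channel at base index {base_index}"
        )
    rest = [b for b in BASES if b != primary_channel]
    secondary_channel = max(rest, key=lambda b: vals[b])
    secondary: Optional[PeakGeometry] = None
    if vals[secondary_channel] >= floor_fraction * vals[primary_channel] > 0:
        secondary = _wave_at(trace, secondary_channel, center, search_halfwidth)
    if secondary is not None and secondary.height < floor_fraction * primary.height:
        secondary = None
    if secondary is not None and secondary.height > primary.height:
        primary, secondary = secondary, primary
    return primary, secondary


def extract_features(
    primary: PeakGeometry, secondary: PeakGeometry, base_index: int
) -> BasePositionFeatures:
    """Compute the three double-peak features from two wave geometries."""
    y1 = primary.M[1]
    y4 = secondary.M[1]
    if y4 == 0:
        raise DegenerateFeatureError("secondary peak height is zero")
    sec_extent = secondary.half_extent
    if sec_extent == 0:
        raise DegenerateFeatureError("secondary half-wave extent is zero")
    distance = float(abs(primary.M[0] - secondary.M[0]))
    height_ratio = abs(y1) / abs(y4)
    width_ratio = primary.half_extent / sec_extent
    return BasePositionFeatures(
        horizontal_distance=distance,
        height_ratio=height_ratio,
        halfwave_width_ratio=width_ratio,
        base_index=base_index,
        primary_base=primary.channel,
        secondary_base=secondary.channel,
    )


def features_with_fallback(
    primary: PeakGeometry, secondary: PeakGeometry, base_index: int
) -> Optional[BasePositionFeatures]:
    """Double-peak features, robust to merged apices.

    When a wave has no resolvable apex of its own (adjacent identical bases
    merged it into a broad shoulder) its half-extent is not measurable and
    the printed width-ratio formula degenerates. For Gaussian waves of equal
    width rising from baseline the half-extent is proportional to the
    height, so the height ratio substitutes for the width ratio in that
    case. Returns None when no usable features exist at the position.
    """
    if secondary.height == 0:
        return None
    measurable = (
        primary.resolved
        and secondary.resolved
        and primary.half_extent >= PROMINENCE_FRACTION * primary.height
        and secondary.half_extent >= PROMINENCE_FRACTION * secondary.height
    )
    if measurable:
        try:
            return extract_features(primary, secondary, base_index)
        except DegenerateFeatureError:
            return None
    height_ratio = primary.height / secondary.height
    return BasePositionFeatures(
        horizontal_distance=float(abs(primary.M[0] - secondary.M[0])),
        height_ratio=height_ratio,
        halfwave_width_ratio=height_ratio,
        base_index=base_index,
        primary_base=primary.channel,
        secondary_base=secondary.channel,
    )


def count_noisy_waves(
    trace: ChromatogramTrace,
    base_index: int,
    secondary: PeakGeometry,
    rule: NoisyWaveRule = NoisyWaveRule(),
    search_halfwidth: Optional[int] = None,
) -> int:
    """Count spurious waves around a candidate SNP position.

    A genuine wave within ``rule.window_bases`` called positions is noisy
    when its height exceeds ``rule.height_fraction`` of the secondary peak's
    height and its half-wave extent exceeds ``rule.width_fraction`` of the
    secondary's. Each position's own primary wave is the legitimate sequence
    signal and never counts, nor does the secondary itself at ``base_index``.
    """
    if search_halfwidth is None:
        search_halfwidth = default_search_halfwidth(trace)
    h_cut = rule.height_fraction * secondary.height
    w_cut = rule.width_fraction * secondary.half_extent
    lo = max(0, base_index - rule.window_bases)
    hi = min(trace.n_bases - 1, base_index + rule.window_bases)
    seen: set[tuple[str, int]] = set()
    count = 0
    for j in range(lo, hi + 1):
        waves = _genuine_waves_at(trace, j, search_halfwidth)
        if not waves:
            continue
        center = int(trace.peak_scans[j])
        prim_channel = max(
            BASES, key=lambda b: float(trace.channels[b][center])
        )
        for b, g in waves.items():
            if b == prim_channel:
                continue
            if j == base_index and b == secondary.channel:
                continue
            key = (b, g.M[0])
            if key in seen:
                continue
            seen.add(key)
            if g.height > h_cut and g.half_extent > w_cut:
                count += 1
    return count
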