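"""Heterozygous InDel detection by stepwise allelic base alignment.

Downstream of a heterozygous insertion/deletion the two alleles of a diploid
amplicon are frame-shifted against each other, so nearly every base position
shows a double peak. The region of continuous double peaks is split into two
call streams — the primary (top-peak) and secondary (lower-peak) base at each
position — and the secondary stream is slid against the primary by every
offset m in ±1..±max_size. The matchability (identity fraction over the
scored overlap) peaks at the true InDel size; the sign of the winning m says
which allele carries the extra bases ('+' = the primary allele does).

Base transposition tolerance: where the two allele peaks are nearly equal the
basecaller may swap which is primary, corrupting both comparisons that trace
position takes part in. A mismatch may therefore be repaired by swapping the
primary/secondary calls at one position of the comparison, provided every
already-scored comparison involving that position still matches after the
swap; each position can be swapped at most once.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import peaks as _peaks
from .types import ChromatogramTrace, DoublePeakRegion, IndelCall
from .wavelet import denoise_trace


class InsufficientOverlapError(ValueError):
    """Fewer than the minimum scoreable positions at the requested offset."""


MIN_OVERLAP = 5


def find_double_peak_region(
    trace: ChromatogramTrace,
    min_run: int = 8,
    *,
    floor_fraction: float = 0.40,
    max_gap: int = 4,
    search_halfwidth: Optional[int] = None,
) -> Optional[DoublePeakRegion]:
    """Find the stretch of base positions dominated by double peaks.

    Positions where the two alleles share a base show a single peak even
    inside a genuine InDel tail, so double-peak positions are chained
    allowing single-peak gaps of at most ``max_gap``; the chain with the most
    double-peak positions wins and must contain at least ``min_run`` of them.
    Gap positions enter ``secondary_seq`` as 'N'.
    """
    if search_halfwidth is None:
        search_halfwidth = _peaks.default_search_halfwidth(trace)
    prim: list[str] = []
    sec: list[Optional[str]] = []
    for i in range(trace.n_bases):
        try:
            p, s = _peaks.primary_secondary(trace, i, search_halfwidth, floor_fraction)
        except _peaks.MalformedPositionError:
            prim.append("N")
            sec.append(None)
            continue
        prim.append(p.channel)
        sec.append(s.channel if s is not None else None)

    marked = [i for i, s in enumerate(sec) if s is not None]
    if not marked:
        return None
    chains: list[list[int]] = [[marked[0]]]
    for i in marked[1:]:
        if i - chains[-1][-1] <= max_gap + 1:
            chains[-1].append(i)
        else:
            chains.append([i])
    best = max(chains, key=len)
    if len(best) < min_run:
        return None
    start, end = best[0], best[-1]
    primary_seq = "".join(prim[start : end + 1])
    secondary_seq = "".join(
        s if s is not None else "N" for s in sec[start : end + 1]
    )
    return DoublePeakRegion(
        start_index=start,
        end_index=end,
        primary_seq=primary_seq,
        secondary_seq=secondary_seq,
    )


def _pairs(length: int, m: int) -> list[tuple[int, int]]:
    """(secondary index, primary index) comparisons at offset m."""
    k = abs(m)
    if m > 0:
        return [(j, j + k) for j in range(length - k)]
    return [(j + k, j) for j in range(length - k)]


def matchability(
    primary_seq: str,
    secondary_seq: str,
    m: int,
    allow_transposition: bool = True,
) -> float:
    """Identity fraction between the call streams at offset ``m``.

    Positive m: the secondary stream lags the primary (the primary allele
    carries m extra bases); negative m the converse. Positions where either
    call is 'N' are not scored. Raises InsufficientOverlapError when fewer
    than five positions can be scored.
    """
    if not 1 <= abs(m) <= 30:
        raise ValueError("|m| must lie in 1..30")
    L = len(primary_seq)
    if len(secondary_seq) != L:
        raise ValueError("call streams must have equal length")
    P = list(primary_seq)
    S = list(secondary_seq)
    pairs = [
        (i_s, i_p)
        for i_s, i_p in _pairs(L, m)
        if S[i_s] != "N" and P[i_p] != "N"
    ]
    if len(pairs) < MIN_OVERLAP:
        raise InsufficientOverlapError(
            f"only {len(pairs)} scoreable positions at offset {m}"
        )
    consumed: set[int] = set()
    scored: list[tuple[int, int]] = []
    matches = 0
    for i_s, i_p in pairs:
        if S[i_s] == P[i_p]:
            matches += 1
        elif allow_transposition:
            prev = scored[-1] if scored else None
            for t in (i_p, i_s):
                # miscalled positions are isolated: never swap a position
                # adjacent to one already swapped, or repairs could cascade
                # into wholesale stream exchange
                if t in consumed or (t - 1) in consumed or (t + 1) in consumed:
                    continue
                P[t], S[t] = S[t], P[t]
                # the swap must repair this comparison, keep the previous
                # scored comparison matching, and not break any earlier
                # comparison the swapped position takes part in
                ok = S[i_s] == P[i_p]
                if ok and prev is not None:
                    ok = S[prev[0]] == P[prev[1]]
                if ok:
                    ok = all(S[a] == P[b] for a, b in scored if t in (a, b))
                if ok:
                    consumed.add(t)
                    matches += 1
                    break
                P[t], S[t] = S[t], P[t]  # undo
        scored.append((i_s, i_p))
    return matches / len(pairs)


def _merge_alleles(region: DoublePeakRegion, m: int) -> tuple[str, str]:
    """Region-level long/short allele strings for the winning offset."""
    P, S = region.primary_seq, region.secondary_seq
    L = len(P)
    k = abs(m)
    if m > 0:
        long_seq = P
        short = [
            S[j] if S[j] != "N" else P[j + k] for j in range(L - k)
        ]
        short_seq = "".join(short)
    else:
        long_chars = []
        for j in range(L):
            c = S[j]
            if c == "N" and j >= k:
                c = P[j - k]
            long_chars.append(c)
        long_seq = "".join(long_chars)
        short_seq = P[: L - k]
    return long_seq, short_seq


def find_indel(
    region: DoublePeakRegion,
    max_size: int = 30,
    *,
    accept: float = 0.80,
    allow_transposition: bool = True,
) -> Optional[IndelCall]:
    """Search m in ±1..±max_size for the offset of maximal matchability.

    Ties break toward smaller |m|, then positive sign. Returns None when the
    best matchability falls below ``accept`` or no offset leaves enough
    overlap to score.
    """
    best: Optional[tuple[float, int]] = None
    for size in range(1, max_size + 1):
        for m in (size, -size):
            try:
                score = matchability(
                    region.primary_seq, region.secondary_seq, m, allow_transposition
                )
            except InsufficientOverlapError:
                continue
            if best is None or score > best[0]:
                best = (score, m)
    if best is None or best[0] < accept:
        return None
    score, m = best
    long_seq, short_seq = _merge_alleles(region, m)
    return IndelCall(
        size_m=m,
        start_index=region.start_index,
        matchability=score,
        allele_long=long_seq,
        allele_short=short_seq,
    )


def resolve_alleles(
    trace: ChromatogramTrace, call: IndelCall, region: DoublePeakRegion
) -> tuple[str, str]:
    """Full-length allele sequences: shared prefix plus the deconvolved tails."""
    if call.start_index != region.start_index:
        raise ValueError("call was not produced from this region")
    expected_long, expected_short = _merge_alleles(region, call.size_m)
    if (call.allele_long, call.allele_short) != (expected_long, expected_short):
        raise ValueError("call alleles inconsistent with region")
    prefix = trace.called_bases[: region.start_index]
    return prefix + call.allele_long, prefix + call.allele_short


def detect_indel(
    trace: ChromatogramTrace,
    *,
    levels: int = 3,
    min_run: int = 8,
    max_size: int = 30,
    accept: float = 0.80,
    floor_fraction: float = 0.40,
    max_gap: int = 4,
) -> tuple[Optional[DoublePeakRegion], Optional[IndelCall], Optional[tuple[str, str]]]:
    """Denoise, locate the double-peak region, and call the InDel end to end."""
    dn = denoise_trace(trace, levels)
    region = find_double_peak_region(
        dn, min_run, floor_fraction=floor_fraction, max_gap=max_gap
    )
    if region is None:
        return None, None, None
    call = find_indel(region, max_size, accept=accept)
    if call is None:
        return region, None, None
    alleles = resolve_alleles(dn, call, region)
    return region, call, alleles
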