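"""Synthetic diploid Sanger chromatograms with known planted variants.

Each allele is rendered as a train of Gaussian peaks, one per base, on the
channel of that base, apex on a regular scan grid (both alleles co-migrate by
base count from the primer, so the j-th base of either allele sits at the
j-th grid position). The two allele signals are summed 50:50; at a
heterozygous SNP the variant channel is further scaled by the allele ratio,
and for a heterozygous InDel the whole second allele is scaled by an
amplification-imbalance ratio so the primary/secondary identity of the two
call streams is stable, as it is in real traces. Linear channel crosstalk
and uniform baseline noise complete the model; mobility shifts, dye blobs
and polymerase slippage are deliberately not modelled.

Downstream of a planted InDel the two alleles are frame-shifted, so nearly
every position shows a double peak — the phenomenon the InDel caller keys on.
Base calls and peak scans are emitted from the noise-free primary-allele
grid. A truth manifest accompanies every trace so callers can be scored.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import BASES, ChromatogramTrace

SCF_MAGIC = b".scf"


class SimSpecError(ValueError):
    """The simulation spec is internally inconsistent."""


@dataclass
class TraceSimSpec:
    """Parameters of one synthetic diploid trace.

    het_snps: list of (base_index, alt_base, allele_ratio in (0, 1]).
    het_indel: optional (start_index, bases, sign); sign '+' plants the extra
    bases on the primary (louder) allele, '-' on the secondary one.
    """

    n_bases: int
    peak_spacing: int = 12
    peak_sigma: float = 4.0
    primary_height: float = 1000.0
    noise_uniform_max: float = 50.0
    crosstalk_fraction: float = 0.02
    het_snps: list[tuple[int, str, float]] = field(default_factory=list)
    het_indel: Optional[tuple[int, str, str]] = None
    indel_allele_ratio: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bases < 1:
            raise SimSpecError("n_bases must be >= 1")
        if self.peak_spacing <= 2:
            raise SimSpecError("peaks must be resolvable (peak_spacing > 2)")
        seen = set()
        for idx, alt, ratio in self.het_snps:
            if not 0 <= idx < self.n_bases:
                raise SimSpecError(f"SNP index {idx} out of range")
            if alt not in BASES:
                raise SimSpecError(f"invalid alt base {alt!r}")
            if not 0 < ratio <= 1:
                raise SimSpecError("allele_ratio must lie in (0, 1]")
            if idx in seen:
                raise SimSpecError(f"duplicate SNP index {idx}")
            seen.add(idx)
        if self.het_indel is not None:
            start, bases, sign = self.het_indel
            if not 0 < start < self.n_bases:
                raise SimSpecError("indel start out of range")
            if not bases or len(bases) > 30 or set(bases) - set(BASES):
                raise SimSpecError("indel bases must be 1..30 letters of ACGT")
            if sign not in "+-":
                raise SimSpecError("indel sign must be '+' or '-'")
            if not 0 < self.indel_allele_ratio <= 1:
                raise SimSpecError("indel_allele_ratio must lie in (0, 1]")
            for idx, _, _ in self.het_snps:
                if idx >= start:
                    raise SimSpecError(
                        "SNP overlaps the double-peak tail of the InDel"
                    )


@dataclass(frozen=True)
class TruthManifest:
    snp_truth: list[tuple[int, str, str, float]]
    indel_truth: Optional[tuple[int, int, str, str, str]]  # start, size, sign, long, short


def _render(seq: str, weights: np.ndarray, spacing: int, sigma: float,
            height: float, offset: int, length: int) -> dict[str, np.ndarray]:
    channels = {b: np.zeros(length) for b in BASES}
    x = np.arange(length, dtype=float)
    reach = int(np.ceil(4 * sigma))
    for j, b in enumerate(seq):
        apex = offset + j * spacing
        lo, hi = max(0, apex - reach), min(length, apex + reach + 1)
        channels[b][lo:hi] += (
            height * weights[j] * np.exp(-((x[lo:hi] - apex) ** 2) / (2 * sigma**2))
        )
    return channels


def simulate_trace(spec: TraceSimSpec) -> tuple[ChromatogramTrace, TruthManifest]:
    """Render a synthetic trace and its truth manifest (seed-reproducible)."""
    rng = np.random.default_rng(spec.seed)
    B = "".join(rng.choice(list(BASES), size=spec.n_bases))
    # ensure planted SNP alt differs from the reference base
    b_list = list(B)
    for idx, alt, _ in spec.het_snps:
        if b_list[idx] == alt:
            others = [c for c in BASES if c != alt]
            b_list[idx] = others[int(rng.integers(len(others)))]
    allele1 = "".join(b_list)

    snp_truth: list[tuple[int, str, str, float]] = []
    indel_truth: Optional[tuple[int, int, str, str, str]] = None

    if spec.het_indel is not None:
        start, bases, sign = spec.het_indel
        k = len(bases)
        if sign == "+":
            a1 = allele1[:start] + bases + allele1[start:]
            a1 = a1[: spec.n_bases] if len(a1) > spec.n_bases else a1
            # keep called length == n_bases: truncate the tail of allele1
            allele1 = a1
            allele2 = allele1[:start] + allele1[start + k :]
            long_a, short_a = allele1, allele2
        else:
            allele2 = allele1[:start] + bases + allele1[start:]
            long_a, short_a = allele2, allele1
        weights2 = np.full(len(allele2), 0.5 * spec.indel_allele_ratio)
        indel_truth = (start, k, sign, long_a, short_a)
    else:
        a2 = list(allele1)
        for idx, alt, _ in spec.het_snps:
            a2[idx] = alt
        allele2 = "".join(a2)
        weights2 = np.full(len(allele2), 0.5)
        for idx, alt, ratio in spec.het_snps:
            weights2[idx] = 0.5 * ratio
            snp_truth.append((idx, allele1[idx], alt, ratio))

    weights1 = np.full(len(allele1), 0.5)
    offset = spec.peak_spacing
    max_len = max(len(allele1), len(allele2))
    length = 2 * offset + max_len * spec.peak_spacing

    ch1 = _render(allele1, weights1, spec.peak_spacing, spec.peak_sigma,
                  spec.primary_height, offset, length)
    ch2 = _render(allele2, weights2, spec.peak_spacing, spec.peak_sigma,
                  spec.primary_height, offset, length)
    channels = {b: ch1[b] + ch2[b] for b in BASES}

    if spec.crosstalk_fraction > 0:
        total = sum(channels.values())
        channels = {
            b: s + spec.crosstalk_fraction * (total - s) for b, s in channels.items()
        }
    if spec.noise_uniform_max > 0:
        for b in BASES:
            channels[b] = channels[b] + rng.uniform(
                0.0, spec.noise_uniform_max, size=length
            )

    called = allele1[: spec.n_bases]
    peak_scans = offset + spec.peak_spacing * np.arange(len(called))
    trace = ChromatogramTrace(
        sample_id=f"sim-{spec.seed}",
        channels=channels,
        called_bases=called,
        peak_scans=peak_scans,
    )
    return trace, TruthManifest(snp_truth=snp_truth, indel_truth=indel_truth)


# --- SCF v3 writing -------------------------------------------------------


def _delta_encode(arr: np.ndarray) -> np.ndarray:
    d = arr.astype(np.uint16)
    for _ in range(2):
        d = d - np.concatenate(([np.uint16(0)], d[:-1]))
    return d


def delta_decode_u16(arr: np.ndarray) -> np.ndarray:
    """Invert the SCF double-delta encoding (modulo 2**16)."""
    x = arr.astype(np.uint64)
    for _ in range(2):
        x = np.cumsum(x) & 0xFFFF
    return x.astype(np.uint16)


def write_scf(trace: ChromatogramTrace, path) -> None:
    """Write a trace as an SCF v3 file (16-bit samples)."""
    n_samples = trace.length_scans
    n_bases = trace.n_bases
    comments = f"NAME={trace.sample_id}\n".encode()
    samples_offset = 128
    sample_bytes = 4 * n_samples * 2
    bases_offset = samples_offset + sample_bytes
    bases_bytes = n_bases * 12
    comments_offset = bases_offset + bases_bytes
    header = struct.pack(
        ">4s I I I I I I I I 4s I I I I 18I",
        SCF_MAGIC,
        n_samples,
        samples_offset,
        n_bases,
        0,
        0,
        bases_offset,
        len(comments),
        comments_offset,
        b"3.00",
        2,
        0,
        0,
        comments_offset + len(comments),
        *([0] * 18),
    )
    body = bytearray()
    for b in BASES:
        vals = np.clip(np.round(trace.channels[b]), 0, 65535).astype(np.uint16)
        body += _delta_encode(vals).astype(">u2").tobytes()
    body += trace.peak_scans.astype(">u4").tobytes()
    body += b"\x00" * (4 * n_bases)  # per-channel probabilities
    body += trace.called_bases.encode()
    body += b"\x00" * (3 * n_bases)  # spare
    body += comments
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(bytes(body))


# --- benchmark generation -------------------------------------------------

DEFAULT_MIX = {"null": 0.2, "snp": 0.4, "indel": 0.4}
_SNP_RATIOS = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def benchmark_specs(
    n_traces: int, variant_mix: Optional[dict] = None, seed: int = 0
) -> list[TraceSimSpec]:
    """Deterministic list of trace specs spanning the benchmark conditions."""
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    mix = dict(DEFAULT_MIX)
    if variant_mix:
        mix.update(variant_mix)
    noise = float(mix.get("noise", 50.0))
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_traces)
    n_null = int(round(mix["null"] * n_traces))
    n_snp = int(round(mix["snp"] * n_traces))
    specs = []
    for i in range(n_traces):
        s = int(child_seeds[i])
        if i < n_null:
            specs.append(
                TraceSimSpec(n_bases=120, noise_uniform_max=noise, seed=s)
            )
        elif i < n_null + n_snp:
            ratios = [
                _SNP_RATIOS[(i + j) % len(_SNP_RATIOS)] for j in range(3)
            ]
            alts = [BASES[(i + j) % 4] for j in range(3)]
            specs.append(
                TraceSimSpec(
                    n_bases=120,
                    noise_uniform_max=noise,
                    het_snps=[
                        (30, alts[0], ratios[0]),
                        (60, alts[1], ratios[1]),
                        (90, alts[2], ratios[2]),
                    ],
                    seed=s,
                )
            )
        else:
            j = i - n_null - n_snp
            size = j % 30 + 1
            sign = "+" if j % 2 == 0 else "-"
            local = np.random.default_rng(s)
            bases = "".join(local.choice(list(BASES), size=size))
            specs.append(
                TraceSimSpec(
                    n_bases=120,
                    noise_uniform_max=noise,
                    het_indel=(40, bases, sign),
                    seed=s,
                )
            )
    return specs


def make_benchmark(
    n_traces: int,
    out_dir,
    variant_mix: Optional[dict] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a benchmark of SCF traces plus a truth manifest TSV.

    The same (n_traces, mix, seed) always produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(benchmark_specs(n_traces, variant_mix, seed)):
        trace, truth = simulate_trace(spec)
        name = f"trace_{i:04d}.scf"
        write_scf(trace, out / name)
        kind = (
            "indel" if spec.het_indel else "snp" if spec.het_snps else "null"
        )
        rows.append(
            {
                "trace": name,
                "kind": kind,
                "seed": spec.seed,
                "noise": spec.noise_uniform_max,
                "snp_indices": ",".join(str(t[0]) for t in truth.snp_truth),
                "snp_ratios": ",".join(f"{t[3]:g}" for t in truth.snp_truth),
                "indel_start": truth.indel_truth[0] if truth.indel_truth else "",
                "indel_size": truth.indel_truth[1] if truth.indel_truth else "",
                "indel_sign": truth.indel_truth[2] if truth.indel_truth else "",
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False, lineterminator="\n")
    return manifest
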