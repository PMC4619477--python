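"""Chromatogram file reading and plain-text report writing.

ABI (.ab1) containers are read through Biopython's abi parser; the analyzed
(processed) data channels DATA9-12 are used, with the channel-to-base mapping
taken from the FWO_1 field-order record rather than assumed. SCF v2/v3 files
are decoded directly (header, sample matrix, base section) since no installed
library handles SCF. Readers either return a trace satisfying every
ChromatogramTrace invariant or raise a typed error.

Reports are deterministic TSV text: identical input always produces
byte-identical output (LF endings, fixed float formatting). Base positions
are 1-based in reports, 0-based everywhere in the library.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from . import __version__
from .simulate import SCF_MAGIC, delta_decode_u16
from .types import (
    BASES,
    ChromatogramTrace,
    EmptyTraceError,
    TraceFormatError,
    VariantReport,
)


def _clean_bases(raw: bytes | str) -> str:
    if isinstance(raw, bytes):
        raw = raw.decode("ascii", errors="replace")
    return "".join(c if c in BASES else "N" for c in raw.upper())


def read_ab1(path) -> ChromatogramTrace:
    """Read an ABI .ab1 trace (analyzed channels, base calls, peak scans)."""
    from Bio import SeqIO

    try:
        record = SeqIO.read(str(path), "abi")
    except (ValueError, struct.error, OSError) as exc:
        raise TraceFormatError(f"not a readable ABI file: {path}: {exc}") from exc
    raw = record.annotations.get("abif_raw", {})
    for tag in ("DATA9", "DATA10", "DATA11", "DATA12", "FWO_1"):
        if tag not in raw:
            raise TraceFormatError(f"ABI file missing record {tag}: {path}")
    order = raw["FWO_1"]
    if isinstance(order, bytes):
        order = order.decode("ascii")
    if sorted(order) != sorted(BASES):
        raise TraceFormatError(f"ABI field order record invalid: {order!r}")
    channels = {}
    for i, base in enumerate(order):
        data = np.asarray(raw[f"DATA{9 + i}"], dtype=float)
        channels[base] = np.clip(data, 0.0, None)
    pbas = raw.get("PBAS2", raw.get("PBAS1"))
    ploc = raw.get("PLOC2", raw.get("PLOC1"))
    if pbas is None or ploc is None:
        missing = "PBAS" if pbas is None else "PLOC"
        raise TraceFormatError(f"ABI file missing record {missing}: {path}")
    called = _clean_bases(pbas)
    if not called:
        raise EmptyTraceError(f"ABI file has zero called bases: {path}")
    try:
        return ChromatogramTrace(
            sample_id=record.id if record.id not in ("", "<unknown id>") else Path(path).stem,
            channels=channels,
            called_bases=called,
            peak_scans=np.asarray(ploc, dtype=int),
        )
    except ValueError as exc:
        raise TraceFormatError(f"ABI records inconsistent: {path}: {exc}") from exc


def read_scf(path) -> ChromatogramTrace:
    """Read an SCF v2 or v3 trace file."""
    try:
        blob = Path(path).read_bytes()
    except OSError as exc:
        raise TraceFormatError(f"cannot read {path}: {exc}") from exc
    if len(blob) < 128:
        raise TraceFormatError(f"file too short to be SCF: {path}")
    (
        magic,
        n_samples,
        samples_offset,
        n_bases,
        _lclip,
        _rclip,
        bases_offset,
        comments_size,
        comments_offset,
        version,
        sample_size,
        _code_set,
        _priv_size,
        _priv_offset,
    ) = struct.unpack(">4s 8I 4s 4I", blob[:56])
    if magic != SCF_MAGIC:
        raise TraceFormatError(f"bad SCF magic {magic!r}: {path}")
    try:
        major = int(version[:1])
    except ValueError:
        raise TraceFormatError(f"unparseable SCF version {version!r}")
    if major not in (2, 3):
        raise TraceFormatError(f"unsupported SCF version {version!r}: {path}")
    if n_samples == 0 or n_bases == 0:
        raise EmptyTraceError(f"SCF file has no samples or no bases: {path}")
    if sample_size not in (1, 2):
        raise TraceFormatError(f"invalid SCF sample size {sample_size}")

    dt = np.dtype(">u2" if sample_size == 2 else "u1")
    try:
        if major == 3:
            need = 4 * n_samples * sample_size
            chunk = blob[samples_offset : samples_offset + need]
            if len(chunk) < need:
                raise TraceFormatError(f"truncated SCF sample section: {path}")
            mat = np.frombuffer(chunk, dtype=dt).reshape(4, n_samples)
            if sample_size == 2:
                mat = np.vstack([delta_decode_u16(row) for row in mat])
            else:
                dec = []
                for row in mat:
                    x = row.astype(np.uint64)
                    for _ in range(2):
                        x = np.cumsum(x) & 0xFF
                    dec.append(x.astype(np.uint8))
                mat = np.vstack(dec)
            channels = {b: mat[i].astype(float) for i, b in enumerate(BASES)}
            need_b = 12 * n_bases
            bchunk = blob[bases_offset : bases_offset + need_b]
            if len(bchunk) < need_b:
                raise TraceFormatError(f"truncated SCF base section: {path}")
            peaks = np.frombuffer(bchunk[: 4 * n_bases], dtype=">u4").astype(int)
            calls = bchunk[8 * n_bases : 9 * n_bases]
        else:  # v2: interleaved samples, 12-byte base records
            need = 4 * n_samples * sample_size
            chunk = blob[samples_offset : samples_offset + need]
            if len(chunk) < need:
                raise TraceFormatError(f"truncated SCF sample section: {path}")
            mat = np.frombuffer(chunk, dtype=dt).reshape(n_samples, 4).T
            channels = {b: mat[i].astype(float) for i, b in enumerate(BASES)}
            need_b = 12 * n_bases
            bchunk = blob[bases_offset : bases_offset + need_b]
            if len(bchunk) < need_b:
                raise TraceFormatError(f"truncated SCF base section: {path}")
            rec = np.frombuffer(bchunk, dtype=np.uint8).reshape(n_bases, 12)
            peaks = rec[:, :4].copy().view(">u4").ravel().astype(int)
            calls = bytes(rec[:, 8])
        sample_id = Path(path).stem
        if comments_size:
            comments = blob[comments_offset : comments_offset + comments_size]
            for line in comments.decode("ascii", errors="replace").splitlines():
                if line.startswith("NAME="):
                    sample_id = line[5:].strip() or sample_id
        return ChromatogramTrace(
            sample_id=sample_id,
            channels=channels,
            called_bases=_clean_bases(calls),
            peak_scans=peaks,
        )
    except TraceFormatError:
        raise
    except ValueError as exc:
        raise TraceFormatError(f"SCF contents invalid: {path}: {exc}") from exc


def read_trace(path) -> ChromatogramTrace:
    """Dispatch on extension: .ab1 via the ABI reader, everything else SCF."""
    if str(path).lower().endswith(".ab1"):
        return read_ab1(path)
    return read_scf(path)


def write_report(report: VariantReport, path, json_sidecar: bool = False) -> None:
    """Write a variant report as deterministic TSV (optionally + JSON).

    Columns -- SNP rows: position (1-based), primary base, secondary base,
    score (2 decimals), grade, noisy-wave count. INDEL row: start position
    (1-based), size |m|, sign ('+' = top-peak allele carries the extra
    bases), matchability (4 decimals). Allele rows carry the two resolved
    allele sequences.
    """
    lines = [
        f"# sangerhet v{__version__}",
        f"# sample: {report.sample_id}",
        "# base positions are 1-based",
    ]
    if not report.snp_calls and report.indel_call is None:
        lines.append("# no variants detected")
    if report.snp_calls:
        lines.append("SNP\tposition\tprimary\tsecondary\tscore\tgrade\tnoisy_waves")
        for c in report.snp_calls:
            lines.append(
                f"SNP\t{c.base_index + 1}\t{c.primary_base}\t{c.secondary_base}"
                f"\t{c.score:.2f}\t{c.grade}\t{c.noisy_count}"
            )
    if report.indel_call is not None:
        c = report.indel_call
        lines.append("INDEL\tstart\tsize\tsign\tmatchability")
        lines.append(
            f"INDEL\t{c.start_index + 1}\t{abs(c.size_m)}\t{c.sign}"
            f"\t{c.matchability:.4f}"
        )
    if report.allele_sequences is not None:
        long_a, short_a = report.allele_sequences
        lines.append(f"ALLELE_LONG\t{long_a}")
        lines.append(f"ALLELE_SHORT\t{short_a}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    if json_sidecar:
        doc = {
            "sample_id": report.sample_id,
            "tool_version": __version__,
            "snp_calls": [
                {
                    "position": c.base_index + 1,
                    "primary": c.primary_base,
                    "secondary": c.secondary_base,
                    "score": round(c.score, 2),
                    "grade": c.grade,
                    "noisy_waves": c.noisy_count,
                }
                for c in report.snp_calls
            ],
            "indel_call": (
                None
                if report.indel_call is None
                else {
                    "start": report.indel_call.start_index + 1,
                    "size": abs(report.indel_call.size_m),
                    "sign": report.indel_call.sign,
                    "matchability": round(report.indel_call.matchability, 4),
                }
            ),
            "allele_sequences": (
                list(report.allele_sequences) if report.allele_sequences else None
            ),
        }
        with open(str(path) + ".json", "w", newline="\n") as fh:
            json.dump(doc, fh, sort_keys=True, indent=1)
            fh.write("\n")
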