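"""Shared fixtures: simulated traces, the scoring model, and an ABIF writer.

The ABIF writer exists only so the ABI reader can be exercised without
binary fixtures: it packs a minimal, standards-conformant ABIF container
(header, directory, DATA9-12 / FWO_1 / PBAS2 / PLOC2 / PCON2 tags) that
Biopython's independent abi parser accepts.
"""

from __future__ import annotations

import struct

import numpy as np
import pytest

from sangerhet import simulate as sim, snpnet


@pytest.fixture(scope="session")
def model():
    return snpnet.default_model()


@pytest.fixture(scope="session")
def snp_trace():
    """Trace with three planted heterozygous SNPs at moderate noise."""
    spec = sim.TraceSimSpec(
        n_bases=120,
        het_snps=[(30, "A", 0.8), (60, "C", 0.8), (90, "G", 0.8)],
        seed=7,
    )
    return sim.simulate_trace(spec)


@pytest.fixture(scope="session")
def indel_trace():
    """Trace with a planted 3-base insertion on the primary allele."""
    spec = sim.TraceSimSpec(n_bases=120, het_indel=(40, "ACG", "+"), seed=11)
    return sim.simulate_trace(spec)


@pytest.fixture(scope="session")
def null_trace():
    """Homozygous trace, zero noise and crosstalk."""
    spec = sim.TraceSimSpec(
        n_bases=120, noise_uniform_max=0.0, crosstalk_fraction=0.0, seed=3
    )
    return sim.simulate_trace(spec)


def write_abif(path, channels, called_bases, peak_scans, field_order="GATC"):
    """Pack a minimal ABIF container readable by Bio.SeqIO's abi parser.

    ``channels`` maps base letter to intensity array; DATA9-12 are laid out
    in ``field_order`` order, mirroring how real ABI files permute channels.
    """
    n = len(called_bases)
    tags = []
    for i, base in enumerate(field_order):
        data = np.asarray(channels[base]).astype(">h").tobytes()
        tags.append((b"DATA", 9 + i, 4, 2, len(channels[base]), data))
    tags += [
        (b"FWO_", 1, 2, 1, 4, field_order.encode()),
        (b"PBAS", 2, 2, 1, n, called_bases.encode()),
        (b"PLOC", 2, 4, 2, n, np.asarray(peak_scans).astype(">h").tobytes()),
        (b"PCON", 2, 2, 1, n, bytes([40] * n)),
    ]
    entries = []
    pos = 128
    blobs = b""
    for name, number, etype, esize, nelem, data in tags:
        dsize = len(data)
        if dsize > 4:
            entries.append((name, number, etype, esize, nelem, dsize, pos, None))
            blobs += data
            pos += dsize
        else:
            packed = data + b"\x00" * (4 - dsize)
            entries.append((name, number, etype, esize, nelem, dsize, None, packed))
    dir_offset = pos
    dirbytes = b""
    for name, number, etype, esize, nelem, dsize, off, packed in entries:
        head = struct.pack(">4sIHHII", name, number, etype, esize, nelem, dsize)
        if packed is None:
            dirbytes += head + struct.pack(">I", off) + b"\x00" * 4
        else:
            dirbytes += head + packed + b"\x00" * 4
    header = b"ABIF" + struct.pack(">H", 101)
    header += struct.pack(
        ">4sIHHII", b"tdir", 1, 1023, 28, len(entries), len(entries) * 28
    ) + struct.pack(">II", dir_offset, 0)
    header += b"\x00" * (128 - len(header))
    with open(path, "wb") as fh:
        fh.write(header + blobs + dirbytes)
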