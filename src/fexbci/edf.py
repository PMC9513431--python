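"""Minimal EDF writer for continuous multichannel recordings.

The pipeline only *imports* EDF (via :func:`fexbci.synthdata.read_edf_epochs`,
which uses MNE); this writer exists so synthetic continuous recordings can be
exported for interoperability tests and demos.  It emits plain EDF: one
256-byte global header, one 256-byte header block per signal, then int16
little-endian data records.  Signals are quantised to the 16-bit range over
a symmetric physical range, so the round trip is exact only to the
quantisation step (physical_max / 32767).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_edf"]


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field '{s}' exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, data: np.ndarray, fs: float,
              ch_names: list[str], physical_dim: str = "uV") -> Path:
    """Write a (C, T) microvolt array as an EDF file with 1 s data records.

    ``fs`` must be a positive integer (samples per 1 s record) and T a
    multiple of fs; trailing samples are zero-padded into a final record.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError(f"data must be (C, T), got {data.shape}")
    C, T = data.shape
    if len(ch_names) != C:
        raise ValueError(f"{len(ch_names)} names for {C} channels")
    spr = int(round(fs))
    if spr <= 0 or abs(fs - spr) > 1e-9:
        raise ValueError(f"fs must be a positive integer Hz, got {fs}")
    n_records = int(np.ceil(T / spr))
    padded = np.zeros((C, n_records * spr))
    padded[:, :T] = data

    pmax = float(np.abs(padded).max())
    pmax = max(pmax, 1e-6)
    dmax = 32767
    scale = dmax / pmax
    digital = np.clip(np.round(padded * scale), -dmax, dmax).astype("<i2")

    header = b"".join([
        _field(0, 8), _field("synthetic", 80), _field("fexbci", 80),
        _field("01.01.00", 8), _field("00.00.00", 8),
        _field(256 * (C + 1), 8), _field("", 44),
        _field(n_records, 8), _field(1, 8), _field(C, 4),
    ])
    per_signal = [
        b"".join(_field(n, 16) for n in ch_names),
        b"".join(_field("", 80) for _ in range(C)),
        b"".join(_field(physical_dim, 8) for _ in range(C)),
        b"".join(_field(f"{-pmax:.6g}"[:8], 8) for _ in range(C)),
        b"".join(_field(f"{pmax:.6g}"[:8], 8) for _ in range(C)),
        b"".join(_field(-dmax, 8) for _ in range(C)),
        b"".join(_field(dmax, 8) for _ in range(C)),
        b"".join(_field("", 80) for _ in range(C)),
        b"".join(_field(spr, 8) for _ in range(C)),
        b"".join(_field("", 32) for _ in range(C)),
    ]
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        for block in per_signal:
            fh.write(block)
        for r in range(n_records):
            sl = digital[:, r * spr:(r + 1) * spr]
            fh.write(sl.tobytes())
    return path
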