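"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Covers the subset of the standard that cell-cycle panels actually use:
HEADER offsets, delimited TEXT segment, binary DATA in list mode with
$DATATYPE F (float32), D (float64) or I (unsigned integers of $PnB bits),
both byte orders, and $PnE log-amplification de-scaling
(``value = f2 · 10^(f1 · x / $PnR)``) so stored log-scale parameters come
back on a linear scale.  Writing always emits float32, little-endian,
linear ($PnE = "0,0").
"""

from __future__ import annotations

import struct

import numpy as np
import pandas as pd

from .events import EventTable

__all__ = ["read_fcs", "write_fcs"]


def _parse_text(blob: bytes) -> dict[str, str]:
    delim = blob[:1].decode("latin-1")
    # split on the delimiter; doubled delimiters (escapes) are not used here
    parts = blob.decode("latin-1").strip(delim).split(delim)
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs(path, mapping: dict[str, str] | None = None) -> EventTable:
    """Read an FCS 3.x file into an :class:`EventTable` (linear scale).

    ``mapping`` renames instrument parameter names ($PnN) to canonical
    channel roles, e.g. ``{"UV 440-W": "dna_width"}``.  An unmapped name is
    kept verbatim.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r}")
    text_start, text_end = int(raw[10:18]), int(raw[18:26])
    data_start, data_end = int(raw[26:34]), int(raw[34:42])
    text = _parse_text(raw[text_start:text_end + 1])
    if data_start == 0:
        data_start = int(text["$BEGINDATA"])
        data_end = int(text["$ENDDATA"])

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    if text.get("$MODE", "L").upper() != "L":
        raise ValueError("only list mode ($MODE L) is supported")
    datatype = text["$DATATYPE"].upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    bits = [int(text[f"$P{i}B"]) for i in range(1, n_par + 1)]
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise ValueError("integer data requires uniform $PnB of 16 or 32")
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise ValueError(f"unsupported $DATATYPE {datatype!r}")

    data = np.frombuffer(raw[data_start:data_end + 1],
                         dtype=dtype, count=n_par * n_tot)
    data = data.reshape(n_tot, n_par).astype(float)

    columns = {}
    for i in range(1, n_par + 1):
        name = text.get(f"$P{i}N", f"P{i}").strip()
        values = data[:, i - 1]
        f1, _, f2 = text.get(f"$P{i}E", "0,0").partition(",")
        f1, f2 = float(f1), float(f2 or 0)
        if f1 > 0:  # log-amplified: de-log per keyword metadata
            decades, scale = f1, (f2 if f2 > 0 else 1.0)
            rng = float(text.get(f"$P{i}R", 1024))
            values = scale * 10.0 ** (decades * values / rng)
        if mapping and name in mapping:
            name = mapping[name]
        columns[name] = values
    meta = {"source": str(path), "fcs_version": version,
            "n_events": n_tot, "text": text}
    return EventTable(pd.DataFrame(columns), metadata=meta)


def write_fcs(path, events: EventTable, extra_text: dict | None = None) -> None:
    """Write an :class:`EventTable` as FCS 3.1 (float32, little-endian, linear)."""
    data = events.data.to_numpy(dtype=np.float32)
    n_tot, n_par = data.shape
    payload = data.astype("<f4").tobytes()

    text: dict[str, str] = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(events.channels, start=1):
        rng = float(np.nanmax(data[:, i - 1])) if n_tot else 1.0
        text[f"$P{i}N"] = str(name)
        text[f"$P{i}B"] = "32"
        text[f"$P{i}E"] = "0,0"
        text[f"$P{i}R"] = f"{max(rng, 1.0):.0f}"
    if extra_text:
        text.update({str(k): str(v) for k, v in extra_text.items()})

    # iterate because the TEXT segment length depends on the data offsets
    header_len = 58
    delim = "/"
    data_start = None
    for _ in range(3):
        guess = data_start or 0
        t = dict(text)
        t["$BEGINDATA"] = str(guess)
        t["$ENDDATA"] = str(guess + len(payload) - 1)
        blob = delim + delim.join(f"{k}{delim}{v}" for k, v in t.items()) + delim
        new_start = header_len + len(blob)
        if new_start == data_start:
            break
        data_start = new_start
    text_bytes = blob.encode("latin-1")
    data_end = data_start + len(payload) - 1
    header = (f"FCS3.1    {header_len:>8d}{header_len + len(text_bytes) - 1:>8d}"
              f"{data_start:>8d}{data_end:>8d}{0:>8d}{0:>8d}").encode("ascii")
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header + text_bytes + payload)
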