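"""Minimal FCS 3.0 writer/reader for cytometry-style export.

Object tables are exported as list-mode FCS 3.0 files with one event per
object and one parameter per selected numeric column, stored as 32-bit
little-endian floats (``$DATATYPE F``, ``$MODE L``, ``$BYTEORD 1,2,3,4``).
Float storage is deliberate: corrected FRET can be negative and the
coefficients live in [0, 1], neither of which survives integer channels.

Only the features this package needs are implemented: primary TEXT and
DATA segments, no ANALYSIS segment, no next data set.  The reader exists
for round-trip verification and covers the same subset.
"""

from __future__ import annotations

import os

import numpy as np

_DELIM = "/"


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        sval = str(value).replace(_DELIM, "\\")  # delimiter not escapable in-values; substitute
        parts.append(f"{key}{_DELIM}{sval}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(path: str | os.PathLike, data: np.ndarray, parameter_names: list[str]) -> None:
    """Write an (n_events, n_params) float array as an FCS 3.0 file.

    An empty table (0 events) still produces a valid file.
    """
    data = np.asarray(data, dtype="<f4")
    if data.ndim != 2:
        raise ValueError("data must be 2-D: events x parameters")
    n_events, n_params = data.shape
    if n_params != len(parameter_names):
        raise ValueError("one parameter name required per column")

    ranges = []
    for j in range(n_params):
        col = data[:, j]
        hi = float(np.nanmax(col)) if n_events else 1.0
        ranges.append(max(1, int(np.ceil(abs(hi))) + 1))

    header_len = 58  # "FCS3.0" + 4 spaces + 6 x 8-char offsets
    data_bytes = data.tobytes(order="C")
    # TEXT length depends on the offsets printed inside it; iterate to fixpoint
    text_start = 256
    data_start = data_end = 0
    text = b""
    for _ in range(3):
        keywords = {
            "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
            "$BEGINDATA": str(data_start),
            "$ENDDATA": str(data_end),
            "$BYTEORD": "1,2,3,4",
            "$DATATYPE": "F",
            "$MODE": "L",
            "$NEXTDATA": "0",
            "$TOT": str(n_events),
            "$PAR": str(n_params),
        }
        for j, name in enumerate(parameter_names, start=1):
            keywords[f"$P{j}N"] = name
            keywords[f"$P{j}B"] = "32"
            keywords[f"$P{j}E"] = "0,0"
            keywords[f"$P{j}R"] = str(ranges[j - 1])
        text = _text_segment(keywords)
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(data_bytes) - 1 if data_bytes else 0

    header = (
        b"FCS3.0    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_start if data_bytes else 0:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    with open(os.fspath(path), "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_start - header_len))
        fh.write(text)
        fh.write(data_bytes)


def read_fcs(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    """Read back an FCS 3.0 file written by :func:`write_fcs`."""
    with open(os.fspath(path), "rb") as fh:
        raw = fh.read()
    if not raw.startswith(b"FCS3.0"):
        raise ValueError("not an FCS 3.0 file")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start:text_end + 1].decode("ascii")
    delim = text[0]
    fields = text[1:].split(delim)
    kw = {fields[i]: fields[i + 1] for i in range(0, len(fields) - 1, 2)}
    n_events = int(kw["$TOT"])
    n_params = int(kw["$PAR"])
    names = [kw[f"$P{j}N"] for j in range(1, n_params + 1)]
    if n_events == 0:
        return np.zeros((0, n_params), dtype=np.float32), names
    data_start = int(kw["$BEGINDATA"])
    data_end = int(kw["$ENDDATA"])
    buf = raw[data_start:data_end + 1]
    data = np.frombuffer(buf, dtype="<f4").reshape(n_events, n_params)
    return data.copy(), names
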