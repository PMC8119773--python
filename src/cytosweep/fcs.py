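"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Covers the subset of the standard needed for event matrices: one list-mode
DATA segment of float (``$DATATYPE F``/``D``) or unsigned integer
(``$DATATYPE I``, uniform ``$PnB`` of 16/32/64 bits) values, little- or
big-endian ``$BYTEORD``, with the ``$PnE`` log/linear decoding applied to
integer data when declared.  Spillover/compensation keywords are read into
the metadata dict but never applied.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .exceptions import FormatError

_DELIM = "/"


def write_fcs(path, values, channels) -> None:
    """Write an events x channels matrix as a minimal FCS 3.1 file.

    Data are stored as little-endian float32 list mode with linear
    (``0,0``) amplification keywords.
    """
    values = np.asarray(values, dtype=np.float32)
    n, p = values.shape
    if p != len(channels):
        raise ValueError("channel count does not match matrix width")
    data = values.astype("<f4").tobytes()

    def text_segment(begin_data, end_data):
        kw = {
            "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
            "$BEGINDATA": str(begin_data), "$ENDDATA": str(end_data),
            "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
            "$NEXTDATA": "0", "$PAR": str(p), "$TOT": str(n),
        }
        for i, name in enumerate(channels, start=1):
            kw[f"$P{i}N"] = str(name)
            kw[f"$P{i}B"] = "32"
            kw[f"$P{i}E"] = "0,0"
            kw[f"$P{i}R"] = str(int(max(np.max(values[:, i - 1]), 1)) + 1
                               if n else 262144)
        parts = [_DELIM]
        for k, v in kw.items():
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("ascii")

    # fixed-point iteration for the offsets (digit counts can shift them)
    begin_text = 58
    begin_data, end_data = 0, 0
    for _ in range(4):
        text = text_segment(begin_data, end_data)
        new_begin = begin_text + len(text)
        new_end = new_begin + len(data) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = text_segment(begin_data, end_data)
    end_text = begin_text + len(text) - 1

    header = b"FCS3.1    " + b"".join(
        f"{v:>8d}".encode("ascii")
        for v in (begin_text, end_text,
                  begin_data if begin_data <= 99999999 else 0,
                  end_data if end_data <= 99999999 else 0, 0, 0))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


def read_fcs(path):
    """Read an FCS 3.0/3.1 list-mode file.

    Returns
    -------
    (values, channels, metadata)
        ``values`` is an events x channels float64 array with ``$PnE``
        decoding applied to integer data; ``channels`` the ``$PnN`` names;
        ``metadata`` the raw TEXT keyword dict.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 58:
        raise FormatError(f"{path}: too short for an FCS header")
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS"):
        raise FormatError(f"{path}: bad magic {version!r}, not an FCS file")
    try:
        begin_text = int(raw[10:18])
        end_text = int(raw[18:26])
        begin_data_hdr = int(raw[26:34])
        end_data_hdr = int(raw[34:42])
    except ValueError as exc:
        raise FormatError(f"{path}: unparsable header offsets") from exc
    if not (0 < begin_text < end_text < len(raw)):
        raise FormatError(f"{path}: TEXT segment offsets out of range")

    text = raw[begin_text:end_text + 1].decode("latin-1")
    delim = text[0]
    # standard escaping doubles the delimiter inside values; split on single
    # delimiters by temporarily protecting doubled ones
    sentinel = "\x00"
    parts = text.strip(delim).replace(delim + delim, sentinel).split(delim)
    parts = [p.replace(sentinel, delim) for p in parts]
    if len(parts) % 2:
        parts = parts[:-1]
    meta = {parts[i].strip().upper(): parts[i + 1]
            for i in range(0, len(parts), 2)}

    def require(key):
        if key not in meta:
            raise FormatError(f"{path}: missing required keyword {key}")
        return meta[key]

    if require("$MODE").strip().upper() != "L":
        raise FormatError(f"{path}: only list-mode ($MODE L) is supported")
    n_par = int(require("$PAR"))
    n_tot = int(require("$TOT"))
    dtype_code = require("$DATATYPE").strip().upper()
    byteord = require("$BYTEORD").strip()
    if byteord.startswith("1"):
        endian = "<"
    elif byteord.startswith("4") or byteord.startswith("2"):
        endian = ">"
    else:
        raise FormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    begin_data = int(meta.get("$BEGINDATA", begin_data_hdr) or begin_data_hdr)
    end_data = int(meta.get("$ENDDATA", end_data_hdr) or end_data_hdr)
    if begin_data <= 0:
        raise FormatError(f"{path}: no DATA segment offset")

    channels = []
    bits = []
    for i in range(1, n_par + 1):
        channels.append(meta.get(f"$P{i}N", f"P{i}").strip())
        bits.append(int(meta.get(f"$P{i}B", "32")))
    if dtype_code == "F":
        dt = np.dtype(f"{endian}f4")
    elif dtype_code == "D":
        dt = np.dtype(f"{endian}f8")
    elif dtype_code == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32, 64):
            raise FormatError(
                f"{path}: integer data requires uniform $PnB of 16/32/64")
        dt = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {dtype_code!r}")

    nbytes = n_tot * n_par * dt.itemsize
    segment = raw[begin_data:begin_data + nbytes]
    if len(segment) < nbytes:
        raise FormatError(
            f"{path}: DATA segment truncated "
            f"({len(segment)} bytes, expected {nbytes})")
    values = np.frombuffer(segment, dtype=dt).reshape(n_tot, n_par)
    values = values.astype(np.float64)

    if dtype_code == "I":
        # $PnE "f1,f2": stored x decodes to f2 * 10^(f1 * x / $PnR)
        for i in range(n_par):
            pne = meta.get(f"$P{i + 1}E", "0,0").split(",")
            f1 = float(pne[0]) if pne[0] else 0.0
            f2 = float(pne[1]) if len(pne) > 1 and pne[1] else 0.0
            if f1 > 0:
                rng = float(meta.get(f"$P{i + 1}R", "1024"))
                scale = f2 if f2 > 0 else 1.0
                values[:, i] = scale * 10.0 ** (f1 * values[:, i] / rng)
    return values, channels, meta
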