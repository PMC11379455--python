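"""Minimal FCS 3.0/3.1 reader and writer.

Flow Cytometry Standard files hold a fixed-width ASCII HEADER with byte
offsets, a delimited TEXT segment of ``$KEY value`` pairs, and a binary DATA
segment of events x parameters. This module supports the subset of the
standard that cytometry acquisition software actually emits for list-mode
data: ``$MODE L`` with ``$DATATYPE`` F (float32), D (float64) or I (unsigned
integers of 8/16/32/64 bits), either byte order.

Reading returns the event matrix with one display name per channel, taken
from ``$PnS`` (stain/antigen name) when present and falling back to ``$PnN``
(the short channel name) otherwise. Writing always emits FCS 3.1, float32,
little-endian.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyFcsError, FcsFormatError

_HEADER_LEN = 58  # 10-byte version id + six 8-byte offset fields

_DTYPES = {
    ("F", 32): "f4",
    ("D", 64): "f8",
    ("I", 8): "u1",
    ("I", 16): "u2",
    ("I", 32): "u4",
    ("I", 64): "u8",
}


@dataclass
class FcsFile:
    """Parsed FCS content: the event matrix plus raw TEXT keywords."""

    matrix: np.ndarray  # n_events x n_channels, float64
    short_names: list[str] = field(default_factory=list)  # $PnN
    stain_names: list[str | None] = field(default_factory=list)  # $PnS or None
    keywords: dict[str, str] = field(default_factory=dict)

    @property
    def channel_names(self) -> list[str]:
        """Display names: $PnS when present, else $PnN."""
        return [
            s if s else n for s, n in zip(self.stain_names, self.short_names)
        ]


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Doubled delimiters escape a literal delimiter inside a value; split on
    # single occurrences only.
    sentinel = b"\x00\x01\x02"
    parts = body.replace(delim + delim, sentinel).split(delim)
    parts = [p.replace(sentinel, delim) for p in parts]
    if len(parts) % 2 != 0:
        parts = parts[:-1]  # trailing junk after the last pair
    out: dict[str, str] = {}
    for key, value in zip(parts[::2], parts[1::2]):
        out[key.decode("utf-8", "replace").strip().upper()] = value.decode(
            "utf-8", "replace"
        ).strip()
    return out


def _offsets(header_field: str) -> int:
    try:
        return int(header_field.strip() or "0")
    except ValueError as exc:
        raise FcsFormatError(f"non-numeric HEADER offset {header_field!r}") from exc


def read_fcs_file(path: str | os.PathLike) -> FcsFile:
    """Read an FCS 3.0/3.1 file in full (matrix, names, keywords)."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < _HEADER_LEN:
        raise FcsFormatError(f"{path}: file shorter than an FCS header")
    version = data[:10].decode("ascii", "replace")
    if not version.startswith("FCS3."):
        raise FcsFormatError(
            f"{path}: unsupported or corrupt FCS version id {version!r}"
        )
    text_begin = _offsets(data[10:18].decode("ascii", "replace"))
    text_end = _offsets(data[18:26].decode("ascii", "replace"))
    data_begin = _offsets(data[26:34].decode("ascii", "replace"))
    data_end = _offsets(data[34:42].decode("ascii", "replace"))
    if text_begin <= 0 or text_end <= text_begin or text_end >= len(data):
        raise FcsFormatError(f"{path}: TEXT segment offsets out of range")
    kw = _parse_text_segment(data[text_begin : text_end + 1])

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"].upper()
        mode = kw["$MODE"].upper()
        byteord = kw["$BYTEORD"]
    except KeyError as exc:
        raise FcsFormatError(f"{path}: missing required keyword {exc}") from exc
    if n_tot == 0:
        raise EmptyFcsError(f"{path}: file declares zero events ($TOT=0)")
    if mode != "L":
        raise FcsFormatError(f"{path}: only list mode ($MODE L) is supported")

    # Large files store 0 in the header and the real offsets in TEXT.
    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    bits = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise FcsFormatError(f"{path}: mixed $PnB widths are not supported")
    key = (datatype, bits.pop())
    if key not in _DTYPES:
        raise FcsFormatError(
            f"{path}: unsupported $DATATYPE/$PnB combination {key}"
        )
    endian = "<" if byteord.startswith("1") else ">"
    dtype = np.dtype(endian + _DTYPES[key])

    need = n_tot * n_par * dtype.itemsize
    seg = data[data_begin : data_begin + need]
    if len(seg) < need:
        raise FcsFormatError(
            f"{path}: DATA segment truncated "
            f"(need {need} bytes, found {len(seg)})"
        )
    matrix = (
        np.frombuffer(seg, dtype=dtype)
        .reshape(n_tot, n_par)
        .astype(np.float64)
    )

    short = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    stain = [kw.get(f"$P{i}S") or None for i in range(1, n_par + 1)]
    return FcsFile(matrix=matrix, short_names=short, stain_names=stain, keywords=kw)


def read_fcs(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    """Read an FCS file, returning (events x channels matrix, channel names).

    Channel names prefer ``$PnS`` over ``$PnN``. Raises
    :class:`~cytobinary.errors.FcsFormatError` on malformed files and
    :class:`~cytobinary.errors.EmptyFcsError` when ``$TOT`` is zero.
    """
    parsed = read_fcs_file(path)
    return parsed.matrix, parsed.channel_names


def write_fcs(
    path: str | os.PathLike,
    matrix: np.ndarray,
    short_names: list[str],
    stain_names: list[str | None] | None = None,
    extra_keywords: dict[str, str] | None = None,
) -> None:
    """Write an FCS 3.1 file (list mode, float32, little-endian).

    ``short_names`` populate ``$PnN``; ``stain_names`` (optional, may contain
    None entries) populate ``$PnS``.
    """
    matrix = np.asarray(matrix, dtype=np.float32)
    if matrix.ndim != 2:
        raise FcsFormatError("event matrix must be 2-D (events x channels)")
    n_tot, n_par = matrix.shape
    if n_par != len(short_names):
        raise FcsFormatError("channel name count does not match matrix width")
    if stain_names is not None and len(stain_names) != n_par:
        raise FcsFormatError("stain name count does not match matrix width")

    payload = matrix.tobytes(order="C")
    delim = "/"

    def escape(value: str) -> str:
        return value.replace(delim, delim + delim)

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(short_names, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(max(1.0, float(np.max(matrix[:, i - 1], initial=0.0)) + 1)))
        if stain_names is not None and stain_names[i - 1]:
            kw[f"$P{i}S"] = str(stain_names[i - 1])
    if extra_keywords:
        kw.update({k.upper(): str(v) for k, v in extra_keywords.items()})

    # $BEGINDATA/$ENDDATA depend on the TEXT length, which depends on the
    # digits of those offsets; fix by iterating until stable.
    begin_data, end_data = 0, 0
    for _ in range(8):
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        text = delim + delim.join(
            escape(k) + delim + escape(v) for k, v in sorted(kw.items())
        ) + delim
        text_bytes = text.encode("utf-8")
        text_begin = _HEADER_LEN
        text_end = text_begin + len(text_bytes) - 1
        new_begin = text_end + 1
        new_end = new_begin + len(payload) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end

    header = "FCS3.1    " + "".join(
        f"{v:>8d}" for v in (text_begin, text_end, begin_data, end_data, 0, 0)
    )
    buf = io.BytesIO()
    buf.write(header.encode("ascii"))
    buf.write(text_bytes)
    buf.write(payload)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())
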