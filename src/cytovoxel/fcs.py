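"""Minimal Flow Cytometry Standard (FCS) reader and writer.

Supports the list-mode subset that covers FCS 2.0/3.0/3.1 files as produced
by common acquisition software and by :func:`write_fcs` itself:

* ``$DATATYPE`` ``F`` (float32), ``D`` (float64) or ``I`` (fixed-width
  unsigned integers, common bit widths);
* ``$MODE L`` (list mode);
* ``$BYTEORD`` ``1,2,3,4`` (little endian) or ``4,3,2,1`` (big endian).

The writer emits FCS 3.1 with float32 data and is the round-trip partner used
by the test-suite oracles. Analysis segments, multiple datasets
(``$NEXTDATA`` != 0) and bit-packed integer data are out of scope.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

from .core import EmptySampleError, EventMatrix, FCSParseError, TransformState

__all__ = ["read_fcs", "write_fcs"]

_REQUIRED_KEYWORDS = ("$TOT", "$PAR", "$DATATYPE", "$MODE", "$BYTEORD")


def _parse_text_segment(raw: bytes, offset: int) -> dict[str, str]:
    if not raw:
        raise FCSParseError(f"empty TEXT segment at offset {offset}")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    # strip leading/trailing delimiter; FCS allows escaped delimiters by
    # doubling, which we do not attempt to resolve beyond simple splitting.
    parts = body.strip(delim).split(delim)
    if len(parts) < 2:
        raise FCSParseError(f"TEXT segment at offset {offset} has no key/value pairs")
    if len(parts) % 2 == 1:
        parts = parts[:-1]
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs(path: str | Path) -> EventMatrix:
    """Read one FCS file into an :class:`EventMatrix` (transform state raw).

    Channel names are taken from ``$PnN`` (falling back to ``$PnS``); sample
    and batch ids default to the file stem and are assigned downstream from
    the metadata table.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FCSParseError(f"{path}: file truncated at offset {len(blob)} (header incomplete)")
    version = blob[:6].decode("latin-1", errors="replace")
    if not version.startswith("FCS"):
        raise FCSParseError(f"{path}: bad magic {version!r} at offset 0")

    def _header_int(lo: int, hi: int) -> int:
        field = blob[lo:hi].decode("latin-1").strip()
        try:
            return int(field) if field else 0
        except ValueError:
            raise FCSParseError(f"{path}: non-numeric header field at offset {lo}") from None

    text_start, text_end = _header_int(10, 18), _header_int(18, 26)
    data_start, data_end = _header_int(26, 34), _header_int(34, 42)
    if text_end <= text_start:
        raise FCSParseError(f"{path}: invalid TEXT offsets at header offset 10")
    text = _parse_text_segment(blob[text_start : text_end + 1], text_start)

    missing = [k for k in _REQUIRED_KEYWORDS if k not in text]
    if missing:
        raise FCSParseError(f"{path}: missing required keywords {missing}")

    # FCS 3.x stores large-data offsets in TEXT when header fields are zero.
    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    if data_end <= data_start:
        raise FCSParseError(f"{path}: invalid DATA offsets ({data_start}, {data_end})")

    n_events = int(text["$TOT"])
    n_par = int(text["$PAR"])
    if n_events == 0:
        raise EmptySampleError(f"{path}: file declares zero events")
    if text["$MODE"].upper() != "L":
        raise FCSParseError(f"{path}: unsupported $MODE {text['$MODE']!r} (only list mode)")

    byteord = text["$BYTEORD"].replace(" ", "")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FCSParseError(f"{path}: unsupported $BYTEORD {text['$BYTEORD']!r}")

    datatype = text["$DATATYPE"].upper()
    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32, 64):
            raise FCSParseError(f"{path}: unsupported mixed/unusual $PnB widths {sorted(set(bits))}")
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise FCSParseError(f"{path}: unsupported $DATATYPE {datatype!r}")

    raw = blob[data_start : data_end + 1]
    needed = n_events * n_par * dtype.itemsize
    if len(raw) < needed:
        raise FCSParseError(
            f"{path}: DATA segment at offset {data_start} holds {len(raw)} bytes, need {needed}"
        )
    values = np.frombuffer(raw[:needed], dtype=dtype).reshape(n_events, n_par).astype(np.float64)
    if not np.isfinite(values).all():
        raise FCSParseError(f"{path}: non-finite values in DATA segment at offset {data_start}")

    names = []
    for i in range(1, n_par + 1):
        name = text.get(f"$P{i}N") or text.get(f"$P{i}S") or f"P{i}"
        names.append(name)

    return EventMatrix(
        values=values,
        marker_names=names,
        sample_id=path.stem,
        batch_id=text.get("$SRC", ""),
        transform_state=TransformState.RAW,
    )


def write_fcs(
    em: EventMatrix,
    path: str | Path,
    extra_keywords: dict[str, str] | None = None,
) -> Path:
    """Write an event matrix as a single-dataset FCS 3.1 file (float32)."""
    if em.n_cells == 0:
        raise EmptySampleError("refusing to write an FCS file with zero events")
    path = Path(path)
    data = np.ascontiguousarray(em.values, dtype="<f4").tobytes()

    keywords: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$TOT": str(em.n_cells),
        "$PAR": str(em.n_markers),
    }
    for i, name in enumerate(em.marker_names, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(1.0, float(np.ceil(em.values[:, i - 1].max() + 1)))))
    if em.batch_id:
        keywords["$SRC"] = em.batch_id
    if extra_keywords:
        keywords.update(extra_keywords)

    delim = "/"
    header_len = 58
    # Two-pass layout: offsets depend on the TEXT length which embeds offsets.
    for _ in range(3):
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in keywords.items()) + delim
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(data) - 1
        keywords["$BEGINDATA"] = str(data_start)
        keywords["$ENDDATA"] = str(data_end)

    buf = io.BytesIO()
    header = (
        f"FCS3.1    "
        f"{text_start:>8d}{text_end:>8d}"
        f"{data_start:>8d}{data_end:>8d}"
        f"{0:>8d}{0:>8d}"
    )
    buf.write(header.encode("ascii"))
    buf.write(text.encode("latin-1"))
    buf.write(data)
    path.write_bytes(buf.getvalue())
    return path
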