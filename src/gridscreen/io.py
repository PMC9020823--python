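"""Reading and writing screen data.

Event data arrive either as FCS 3.0/3.1 list-mode files (one per well) or as
delimited text with a channel-name header row.  Plate maps are CSV/TSV with
columns ``well_id, plate_id, read_order, role, drug, concentration`` (optional
``row``/``col``; inferred from the well id like ``"B07"`` when absent).

The FCS reader implemented here covers the common list-mode subset produced
by autosampling cytometers: a single dataset per file, ``$MODE L`` and
``$DATATYPE`` F, D or I, with either byte order.
"""

from __future__ import annotations

import csv
import io as _stdio
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ChannelError,
    EventTable,
    FileFormatError,
    Screen,
    TransformError,
    ValidationError,
    WellRecord,
    ZeroEventsError,
)

__all__ = [
    "read_fcs_well",
    "read_event_text",
    "write_event_text",
    "read_platemap",
    "write_platemap",
    "apply_transform",
    "read_screen",
    "write_screen",
    "well_position",
]

PLATEMAP_COLUMNS = ("well_id", "plate_id", "read_order", "role", "drug",
                    "concentration")


# ---------------------------------------------------------------------------
# FCS parsing
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FileFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Escaped delimiters (doubled) are rare in practice; split then re-join
    # empty fields produced by doubling.
    parts = body.split(delim)
    fields: list[str] = []
    for p in parts:
        if fields and p == b"":
            # doubled delimiter → literal delimiter inside previous field
            fields[-1] += delim
        else:
            fields.append(p)
    if len(fields) % 2 == 1:
        fields = fields[:-1]
    out: dict[str, str] = {}
    for k, v in zip(fields[0::2], fields[1::2]):
        out[k.decode("utf-8", "replace").strip().upper()] = v.decode(
            "utf-8", "replace").strip()
    return out


def read_fcs_well(path: str | Path,
                  channel_filter: Sequence[str] | None = None) -> EventTable:
    """Read one FCS 3.0/3.1 list-mode file into an :class:`EventTable`.

    Parameters
    ----------
    path : path to the FCS file.
    channel_filter : optional list of channel names ($PnN) to keep, in the
        requested order.

    Raises
    ------
    FileFormatError : not an FCS 3.0/3.1 file or unsupported layout.
    ZeroEventsError : the file declares zero events.
    ChannelError : a requested channel is absent.
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise FileFormatError(f"cannot read {path}: {exc}") from exc
    if len(raw) < 58:
        raise FileFormatError(f"{path}: too short to be an FCS file")
    version = raw[0:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FileFormatError(f"{path}: unsupported version {version!r}")

    def _offset(a: int, b: int) -> int:
        txt = raw[a:b].decode("ascii", "replace").strip() or "0"
        try:
            return int(txt)
        except ValueError as exc:
            raise FileFormatError(f"{path}: bad header offset {txt!r}") from exc

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    text = _parse_text_segment(raw[text_start:text_end + 1])
    if data_start == 0 or data_end == 0:
        data_start = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))
    n_par = int(text.get("$PAR", "0"))
    n_tot = int(text.get("$TOT", "0"))
    if n_par < 1:
        raise FileFormatError(f"{path}: $PAR missing or < 1")
    if n_tot < 1:
        raise ZeroEventsError(f"{path}: file contains zero events")
    if data_start <= 0 or data_end <= 0:
        raise FileFormatError(f"{path}: no DATA segment offsets")
    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FileFormatError(f"{path}: only list mode ($MODE L) supported")

    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if len(set(bits)) != 1:
        raise FileFormatError(f"{path}: mixed $PnB widths unsupported")
    nbytes = bits[0] // 8
    endian = "<" if little else ">"
    if datatype == "F":
        if nbytes != 4:
            raise FileFormatError(f"{path}: $DATATYPE F requires 32-bit $PnB")
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        if nbytes != 8:
            raise FileFormatError(f"{path}: $DATATYPE D requires 64-bit $PnB")
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        dtype = np.dtype(f"{endian}u{nbytes}")
    else:
        raise FileFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    names = []
    for i in range(1, n_par + 1):
        name = text.get(f"$P{i}N") or text.get(f"$P{i}S") or f"P{i}"
        names.append(name)

    expected = n_tot * n_par * nbytes
    seg = raw[data_start:data_start + expected]
    if len(seg) < expected:
        raise FileFormatError(f"{path}: DATA segment truncated")
    data = np.frombuffer(seg, dtype=dtype).astype(np.float64)
    events = data.reshape(n_tot, n_par)
    table = EventTable(events, tuple(names))
    if channel_filter is not None:
        table = table.select_channels(channel_filter)
    return table


# ---------------------------------------------------------------------------
# Delimited-text event files
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") and \
        "\t" in first_line else ","


def read_event_text(path: str | Path,
                    channel_filter: Sequence[str] | None = None) -> EventTable:
    """Read a delimited event file (header row of channel names)."""
    path = Path(path)
    try:
        with open(path, "r", newline="") as fh:
            first = fh.readline()
    except OSError as exc:
        raise FileFormatError(f"cannot read {path}: {exc}") from exc
    if not first.strip():
        raise FileFormatError(f"{path}: empty file")
    sep = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] == 0:
        raise ZeroEventsError(f"{path}: no events")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FileFormatError(f"{path}: non-numeric event data") from exc
    table = EventTable(values, tuple(str(c) for c in df.columns))
    if channel_filter is not None:
        table = table.select_channels(channel_filter)
    return table


def write_event_text(table: EventTable, path: str | Path,
                     sep: str = ",") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(sep.join(table.channel_names) + "\n")
        np.savetxt(fh, table.events, delimiter=sep, fmt="%.9g")


# ---------------------------------------------------------------------------
# Plate maps
# ---------------------------------------------------------------------------

_WELL_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def well_position(well_id: str) -> tuple[int, int]:
    """Map a well id like ``"B07"`` to 1-based (row, col)."""
    m = _WELL_RE.match(well_id.strip())
    if not m:
        raise ValidationError(f"cannot parse well id {well_id!r}")
    letters, digits = m.group(1).upper(), m.group(2)
    row = 0
    for ch in letters:
        row = row * 26 + (ord(ch) - ord("A") + 1)
    return row, int(digits)


def _split_concentration(raw: str) -> tuple[float, str]:
    raw = str(raw).strip()
    if not raw or raw.lower() in ("nan", "na"):
        return 0.0, ""
    m = re.match(r"^([-+0-9.eE]+)\s*(.*)$", raw)
    if not m:
        raise ValidationError(f"cannot parse concentration {raw!r}")
    return float(m.group(1)), m.group(2).strip()


def read_platemap(path: str | Path) -> Screen:
    """Read a plate-map CSV/TSV into a :class:`Screen` (wells without events).

    Required columns: ``well_id, plate_id, read_order, role, drug,
    concentration``.  Validation rejects missing columns, duplicate
    (plate, well) pairs, duplicate read orders within a plate, and negative
    controls that name a drug.
    """
    path = Path(path)
    try:
        with open(path, "r", newline="") as fh:
            first = fh.readline()
    except OSError as exc:
        raise FileFormatError(f"cannot read {path}: {exc}") from exc
    sep = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in PLATEMAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"plate map missing columns: {missing}")
    wells = []
    for _, rec in df.iterrows():
        conc, unit = _split_concentration(rec["concentration"])
        if "row" in df.columns and "col" in df.columns and rec["row"]:
            row, col = int(rec["row"]), int(rec["col"])
        else:
            row, col = well_position(rec["well_id"])
        wells.append(WellRecord(
            well_id=str(rec["well_id"]).strip(),
            plate_id=str(rec["plate_id"]).strip(),
            row=row, col=col,
            read_order=int(rec["read_order"]),
            role=str(rec["role"]).strip(),
            drug=str(rec["drug"]).strip(),
            concentration=conc, concentration_unit=unit,
        ))
    return Screen(wells)


def write_platemap(screen: Screen, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(list(PLATEMAP_COLUMNS) + ["row", "col"])
        for w in screen.wells:
            conc = f"{w.concentration:g}"
            if w.concentration_unit:
                conc += f" {w.concentration_unit}"
            wr.writerow([w.well_id, w.plate_id, w.read_order, w.role,
                         w.drug, conc, w.row, w.col])


# ---------------------------------------------------------------------------
# Screens on disk: plate_map.csv + events/<plate>/<well>.csv
# ---------------------------------------------------------------------------

def write_screen(screen: Screen, directory: str | Path) -> None:
    """Write plate map + one delimited event file per well."""
    directory = Path(directory)
    write_platemap(screen, directory / "plate_map.csv")
    for w in screen.wells:
        if w.events is not None:
            write_event_text(w.events,
                             directory / "events" / w.plate_id / f"{w.well_id}.csv")


def read_screen(directory: str | Path,
                channel_filter: Sequence[str] | None = None) -> Screen:
    """Read a screen directory written by :func:`write_screen`.

    Event files may be delimited text (``.csv``/``.tsv``/``.txt``) or FCS
    (``.fcs``), located at ``events/<plate_id>/<well_id>.<ext>``.
    """
    directory = Path(directory)
    screen = read_platemap(directory / "plate_map.csv")
    wells = []
    for w in screen.wells:
        base = directory / "events" / w.plate_id
        table = None
        for ext, reader in ((".csv", read_event_text), (".tsv", read_event_text),
                            (".txt", read_event_text), (".fcs", read_fcs_well)):
            p = base / f"{w.well_id}{ext}"
            if p.exists():
                table = reader(p, channel_filter)
                break
        if table is None:
            raise FileFormatError(f"no event file for well {w.sample_id}")
        w.events = table
        wells.append(w)
    return Screen(wells)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def apply_transform(table: EventTable, cofactor: float) -> EventTable:
    """Arcsinh-transform intensities: x -> asinh(x / cofactor).

    The transform is opt-in (raw intensities are the default everywhere) and
    may be applied at most once per table.
    """
    if cofactor <= 0:
        raise TransformError("cofactor must be > 0")
    if table.transform_state != "none":
        raise TransformError(f"table already transformed: {table.transform_state}")
    return EventTable(np.arcsinh(table.events / cofactor),
                      table.channel_names,
                      transform_state=f"arcsinh({cofactor:g})")
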