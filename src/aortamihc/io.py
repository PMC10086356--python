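"""Input/output: cell tables (CSV), geometry (JSON), ground truth (JSON)
and per-slide FCS 3.1 export.

Cell tables are plain CSV, one row per segmented cell, with provenance
recorded as ``#``-prefixed header lines.  The FCS export mirrors the
flow-style analysis route of the source workflow: one FCS 3.1 file per
slide with x/y positions and one channel per marker, list-mode float32
data, little-endian.  A matching reader is provided for round-trip
verification (no installed library reads/writes FCS in this stack).
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import ALL_MARKERS
from .simulate import GroundTruth, PlantedTLS

REQUIRED_COLUMNS = ("cell_id", "slide_id", "tile_id", "x_um", "y_um")
NUMERIC_COLUMNS = ("x_um", "y_um") + ALL_MARKERS


class CellTableError(ValueError):
    pass


# --------------------------------------------------------------------------
def write_cell_table(cells: pd.DataFrame, path, provenance: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        cells.to_csv(fh, index=False, float_format="%.8g")


def read_cell_table(path) -> pd.DataFrame:
    """Read a cell table, validating required columns and numeric fields.

    Unknown extra columns are preserved untouched.  A malformed numeric
    entry raises :class:`CellTableError` naming the file line.
    """
    path = Path(path)
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
            else:
                break
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableError(f"cell table {path.name}: missing column(s) {missing}")
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            line_no = n_header + 2 + row  # header comments + column row + 1-based
            raise CellTableError(
                f"cell table {path.name}, line {line_no}: malformed value "
                f"{df[col].iloc[row]!r} in column {col!r}"
            )
        df[col] = vals
    return df


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        slide_id=d["slide_id"],
        tls=[
            PlantedTLS(
                tls_id=t["tls_id"],
                slide_id=t["slide_id"],
                center_x_um=t["center_x_um"],
                center_y_um=t["center_y_um"],
                n_b=t["n_b"],
                n_t=t["n_t"],
                member_ids=tuple(t["member_ids"]),
                has_germinal_center=t["has_germinal_center"],
            )
            for t in d["tls"]
        ],
    )


# --------------------------------------------------------------------------
# FCS 3.1 (list mode, float32, little-endian)
def export_fcs(
    cells: pd.DataFrame,
    path,
    markers: tuple[str, ...] = ALL_MARKERS,
    markers_masked: tuple[str, ...] = (),
) -> None:
    """Write one FCS 3.1 file: parameters x_um, y_um and one channel per
    non-masked marker; event count equals cell count."""
    if len(cells) == 0:
        raise CellTableError("export_fcs: empty cell table")
    channels = ["x_um", "y_um"] + [m for m in markers if m not in markers_masked]
    data = cells[channels].to_numpy(dtype="<f4")
    n_events, n_par = data.shape
    data_bytes = data.tobytes()

    def build_text(begin_data: int, end_data: int) -> bytes:
        kw = {
            "$BEGINANALYSIS": "0",
            "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0",
            "$BEGINDATA": str(begin_data),
            "$ENDDATA": str(end_data),
            "$BYTEORD": "1,2,3,4",
            "$DATATYPE": "F",
            "$MODE": "L",
            "$NEXTDATA": "0",
            "$TOT": str(n_events),
            "$PAR": str(n_par),
        }
        for i, ch in enumerate(channels, start=1):
            kw[f"$P{i}N"] = ch
            kw[f"$P{i}B"] = "32"
            kw[f"$P{i}E"] = "0,0"
            kw[f"$P{i}R"] = str(int(np.ceil(max(1.0, float(np.nanmax(data[:, i - 1]))))))
        text = "/" + "".join(f"{k}/{v}/" for k, v in kw.items())
        return text.encode("ascii")

    header_len = 58  # 6 version + 4 spaces + 6 x 8-char offsets
    begin_text = header_len
    # offsets depend on TEXT length; iterate to a fixed point
    begin_data = end_data = 0
    for _ in range(3):
        text = build_text(begin_data, end_data)
        new_begin = begin_text + len(text)
        new_end = new_begin + len(data_bytes) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = build_text(begin_data, end_data)
    end_text = begin_text + len(text) - 1

    header = b"FCS3.1    " + b"".join(
        f"{v:>8d}".encode("ascii")
        for v in (begin_text, end_text, begin_data, end_data, 0, 0)
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)


def read_fcs(path) -> pd.DataFrame:
    """Minimal FCS reader for files written by :func:`export_fcs`."""
    raw = Path(path).read_bytes()
    if not raw.startswith(b"FCS3"):
        raise CellTableError("not an FCS file")
    begin_text = int(raw[10:18])
    end_text = int(raw[18:26])
    text = raw[begin_text : end_text + 1].decode("ascii")
    delim = text[0]
    tokens = text.strip(delim).split(delim)
    kw = dict(zip(tokens[::2], tokens[1::2]))
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    begin_data = int(kw["$BEGINDATA"])
    end_data = int(kw["$ENDDATA"])
    if kw["$DATATYPE"] != "F" or kw["$BYTEORD"] != "1,2,3,4":
        raise CellTableError("unsupported FCS data layout")
    n_vals = n_par * n_tot
    data = struct.unpack(f"<{n_vals}f", raw[begin_data : begin_data + 4 * n_vals])
    assert end_data >= begin_data
    arr = np.asarray(data, dtype=np.float32).reshape(n_tot, n_par)
    names = [kw[f"$P{i}N"] for i in range(1, n_par + 1)]
    return pd.DataFrame(arr, columns=names)
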