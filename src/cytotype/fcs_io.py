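"""Reading pre-gated FCS files and merging samples into one EventTable.

Contains a minimal FCS 3.0/3.1 codec (list-mode, float or integer data,
little- or big-endian) sufficient for pre-gated single-cell exports plus
the fixture files written by :mod:`cytotype.synthetic`.  Channel selection
keeps fluorescence *area* channels (names ending in ``-A``) mapped to panel
marker names; forward/side-scatter area channels are carried along as
optional extra columns but never enter downstream mathematics.
"""

from __future__ import annotations

import logging
import struct
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import EventTable

log = logging.getLogger(__name__)

__all__ = [
    "read_fcs",
    "write_fcs",
    "read_fcs_folder",
    "subsample",
    "write_table",
    "read_table",
]


class FcsError(ValueError):
    pass


# ----------------------------------------------------------------------
# low-level codec
# ----------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    """Decode a TEXT segment: delimiter-separated key/value pairs.

    A delimiter inside a value is escaped by doubling; empty split tokens
    therefore stand for literal delimiters and are re-joined.
    """
    delim = raw[0:1].decode("latin-1")
    body = raw[1:].decode("latin-1")
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    # a doubled delimiter inside a value splits into an empty token; re-join
    merged: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "":
            if i + 2 < len(parts):
                tok += delim + parts[i + 2]
                i += 2
            else:
                tok += delim
                i += 1
        merged.append(tok)
        i += 1
    return {k.strip().upper(): v for k, v in zip(merged[0::2], merged[1::2])}


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[dict]]:
    """Read one FCS 3.0/3.1 file.

    Returns
    -------
    data
        ``(n_events, n_channels)`` float64 array.
    channels
        Per-channel dicts with keys ``name`` ($PnN), ``stain`` ($PnS, may
        be ``None``) and ``range`` ($PnR, may be ``None``).
    """
    path = Path(path)
    try:
        blob = path.read_bytes()
    except OSError as exc:
        raise FcsError(f"cannot read FCS file {path}: {exc}") from exc
    if len(blob) < 58 or not blob[:3] == b"FCS":
        raise FcsError(f"{path} is not an FCS file")
    version = blob[:10].decode("ascii", "replace").strip()
    if not version.startswith("FCS3"):
        raise FcsError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        return int(blob[lo:hi].decode("ascii").strip() or 0)

    text_beg, text_end = _offset(10, 18), _offset(18, 26)
    data_beg, data_end = _offset(26, 34), _offset(34, 42)
    text = _parse_text_segment(blob[text_beg:text_end + 1])

    if data_beg == 0:
        data_beg = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_code = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    channels = []
    widths = []
    for i in range(1, n_par + 1):
        channels.append(
            {
                "name": text.get(f"$P{i}N", f"P{i}"),
                "stain": text.get(f"$P{i}S"),
                "range": text.get(f"$P{i}R"),
            }
        )
        widths.append(int(text.get(f"$P{i}B", 32)))

    raw = blob[data_beg:data_end + 1]
    if dtype_code == "F":
        arr = np.frombuffer(raw[: 4 * n_par * n_tot], dtype=f"{order}f4")
    elif dtype_code == "D":
        arr = np.frombuffer(raw[: 8 * n_par * n_tot], dtype=f"{order}f8")
    elif dtype_code == "I":
        w = widths[0]
        if len(set(widths)) != 1 or w not in (16, 32):
            raise FcsError(f"{path}: unsupported mixed/odd integer widths")
        arr = np.frombuffer(raw[: (w // 8) * n_par * n_tot], dtype=f"{order}u{w // 8}")
    else:
        raise FcsError(f"{path}: unsupported $DATATYPE {dtype_code!r}")
    if arr.size < n_par * n_tot:
        raise FcsError(f"{path}: truncated DATA segment")
    data = np.asarray(arr, dtype=np.float64).reshape(n_tot, n_par)
    return data, channels


def write_fcs(
    path: str | Path,
    data: np.ndarray,
    channel_names: Sequence[str],
    stain_names: Sequence[str] | None = None,
) -> None:
    """Write a minimal valid FCS 3.1 file (list mode, float32, little-endian)."""
    data = np.asarray(data, dtype=np.float32)
    n_tot, n_par = data.shape
    if len(channel_names) != n_par:
        raise FcsError("channel_names length does not match data columns")
    delim = "/"
    kw: list[tuple[str, str]] = [
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$BYTEORD", "1,2,3,4"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
    ]
    for i, name in enumerate(channel_names, start=1):
        kw += [
            (f"$P{i}N", str(name)),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(1.0, np.nanmax(data[:, i - 1], initial=1.0)) * 2))),
        ]
        if stain_names is not None and stain_names[i - 1]:
            kw.append((f"$P{i}S", str(stain_names[i - 1])))

    data_bytes = data.astype("<f4").tobytes()
    header_len = 58
    # iterate: TEXT length depends on the offsets printed inside it
    begin_data = header_len + 1000
    for _ in range(8):
        text = delim + delim.join(
            f"{k}{delim}{v}" for k, v in
            kw + [("$BEGINDATA", str(begin_data)),
                  ("$ENDDATA", str(begin_data + len(data_bytes) - 1))]
        ) + delim
        new_begin = header_len + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    text_bytes = text.encode("latin-1")
    text_beg = header_len
    text_end = text_beg + len(text_bytes) - 1
    data_end = begin_data + len(data_bytes) - 1

    def fmt(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # fall back to TEXT-segment offsets
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fmt(text_beg) + fmt(text_end)
    header += fmt(begin_data if data_end < 10**8 else 0)
    header += fmt(data_end if data_end < 10**8 else 0)
    header += fmt(0) + fmt(0)
    Path(path).write_bytes(header + text_bytes + data_bytes)


# ----------------------------------------------------------------------
# folder -> EventTable
# ----------------------------------------------------------------------

_SCATTER_PREFIXES = ("FSC", "SSC")


def _classify_channels(
    channels: list[dict], marker_map: Mapping[str, str] | None
) -> tuple[dict[str, int], dict[str, int]]:
    """Split area channels into panel markers and scatter extras.

    Channel identity prefers the stain label ($PnS) over the detector name
    ($PnN), since panels are keyed by stain.  ``marker_map`` maps either
    label to the marker name; when ``None``, every non-scatter ``-A``
    channel becomes a marker named after its label minus the ``-A`` suffix.
    """
    markers: dict[str, int] = {}
    scatter: dict[str, int] = {}
    for idx, ch in enumerate(channels):
        label = ch["stain"] or ch["name"]
        name = ch["name"] or ""
        is_area = label.endswith("-A") or name.endswith("-A")
        if not is_area:
            continue
        base = label[:-2] if label.endswith("-A") else label
        if base.upper().startswith(_SCATTER_PREFIXES) or name.upper().startswith(_SCATTER_PREFIXES):
            scatter[label] = idx
            continue
        if marker_map is None:
            markers[base] = idx
        else:
            for key in (label, name, base):
                if key in marker_map:
                    markers[marker_map[key]] = idx
                    break
    return markers, scatter


def read_fcs_folder(
    folder: str | Path,
    marker_map: Mapping[str, str] | None = None,
    keep_scatter: bool = True,
    sample_meta: pd.DataFrame | None = None,
) -> EventTable:
    """Read every FCS file in ``folder`` and merge into one raw EventTable.

    Each file is one sample (sample id = file stem); files are merged in
    lexicographic filename order with per-sample event counts preserved.

    Parameters
    ----------
    marker_map
        Mapping from instrument channel labels (stain or detector name,
        with or without the ``-A`` suffix) to panel marker names.  ``None``
        keeps all non-scatter area channels under their own labels.
    """
    folder = Path(folder)
    paths = sorted(folder.glob("*.fcs"))
    if not paths:
        raise FcsError(f"no FCS files found in {folder}")
    tables = []
    marker_sets: dict[str, set[str]] = {}
    for p in paths:
        try:
            data, channels = read_fcs(p)
        except FcsError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise FcsError(f"cannot read FCS file {p}: {exc}") from exc
        markers, scat = _classify_channels(channels, marker_map)
        if not markers:
            raise FcsError(f"{p}: no area marker channels matched")
        marker_sets[p.stem] = set(markers)
        names = sorted(markers)
        X = data[:, [markers[m] for m in names]]
        tab = EventTable(
            intensities=X,
            markers=names,
            sample_id=np.repeat(p.stem, len(data)),
            space_tag="raw",
            scatter=data[:, list(scat.values())] if (keep_scatter and scat) else None,
            scatter_names=list(scat) if (keep_scatter and scat) else [],
        )
        tables.append(tab)
    common = set.intersection(*marker_sets.values())
    union = set.union(*marker_sets.values())
    if common != union:
        diff = sorted(union - common)
        detail = "; ".join(
            f"{s} missing {sorted(set(diff) - ms)}"
            for s, ms in marker_sets.items()
            if set(diff) - ms
        )
        raise FcsError(
            "marker channels are asymmetric across files: "
            + ", ".join(diff)
            + (f" ({detail})" if detail else "")
        )
    merged = EventTable.concat(tables)
    if sample_meta is not None:
        merged.sample_meta = sample_meta.reindex(merged.sample_meta.index)
    return merged


def subsample(events: EventTable, n_per_sample: int, seed: int) -> EventTable:
    """Uniform per-sample downsampling without replacement.

    Each sample contributes ``min(n_per_sample, its event count)`` events;
    retained events keep their on-disk order.  Reproducible under ``seed``.
    """
    if n_per_sample < 1:
        raise ValueError("n_per_sample must be >= 1")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for s in events.samples:
        idx = np.flatnonzero(events.sample_id == s)
        if len(idx) > n_per_sample:
            chosen = rng.choice(idx, size=n_per_sample, replace=False)
            idx = np.sort(chosen)
        keep.append(idx)
    return events.select(np.concatenate(keep))


def write_table(events: EventTable, path: str | Path) -> None:
    """Columnar text export: ``sample_id,<marker1>,...`` plus obs columns."""
    events.to_frame().to_csv(path, index=False)


#: per-event annotation columns recognised on re-read even though numeric
OBS_COLUMNS = {"cluster", "final_label", "true_label", "cam_label", "rfm_label",
               "transfer_label"}


def read_table(path: str | Path, space_tag: str = "raw") -> EventTable:
    """Read a table written by :func:`write_table` back into an EventTable."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    num = df.drop(columns="sample_id")
    marker_cols = [
        c for c in num.columns
        if pd.api.types.is_numeric_dtype(num[c]) and c not in OBS_COLUMNS
    ]
    obs_cols = [c for c in num.columns if c not in marker_cols]
    return EventTable(
        intensities=df[marker_cols].to_numpy(dtype=float) if marker_cols else np.empty((len(df), 0)),
        markers=marker_cols,
        sample_id=df["sample_id"].to_numpy(),
        space_tag=space_tag,
        obs=df[obs_cols].reset_index(drop=True) if obs_cols else None,
    )
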