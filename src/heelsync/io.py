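"""File I/O: TRC marker trajectories, force-platform CSV exports, JSON sync
reports and an optional MOT export of the shifted force channel.

TRC is the tab-delimited marker-trajectory format with a standard header
block (DataRate / NumFrames / NumMarkers on lines 2-3, marker names on
line 4, per-axis subheaders on line 5).  The vertical axis defaults to Y,
the TRC convention, and is overridable in config.  Force exports are
delimited text with one vertical-force column per platform; the delimiter
is auto-detected among comma/semicolon/tab and the sampling rate is a
required input because exports may lack a time column.

All indices in reports are 0-based and all times are in seconds; numeric
fields round-trip bit-identically through the paired reader.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .signals import (
    ConfigurationError,
    FormatError,
    HeelSyncError,
    SampledSignal,
    TrialRecord,
)

__all__ = [
    "MarkerTriplet",
    "read_trc",
    "write_trc",
    "read_force_csv",
    "write_force_csv",
    "write_sync_report",
    "read_sync_report",
    "write_mot",
    "load_trial",
]

_AXES = ("x", "y", "z")


class MarkerTriplet(NamedTuple):
    x: SampledSignal
    y: SampledSignal
    z: SampledSignal

    def axis(self, name: str) -> SampledSignal:
        if name not in _AXES:
            raise ConfigurationError(f"vertical axis must be one of {_AXES}, got {name!r}")
        return getattr(self, name)


def read_trc(path: str | Path, start_time: float = 0.0) -> dict[str, MarkerTriplet]:
    """Read a TRC file into one (x, y, z) signal triplet per marker.

    The sampling rate is taken from the DataRate header field; the frame
    count must match the NumFrames declaration.

    Raises
    ------
    FormatError
        On a malformed header (naming the offending line) or a frame-count
        mismatch.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise FormatError(f"{path}: TRC file too short ({len(lines)} lines)")

    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    for key in ("DataRate", "NumFrames", "NumMarkers"):
        if key not in header:
            raise FormatError(f"{path}: line 2 missing TRC header field {key!r}")
    try:
        data_rate = float(header["DataRate"])
        num_frames = int(header["NumFrames"])
        num_markers = int(header["NumMarkers"])
    except ValueError as exc:
        raise FormatError(f"{path}: line 3 has non-numeric header value: {exc}") from exc

    marker_row = lines[3].split("\t")
    markers = [m.strip() for m in marker_row[2:] if m.strip()]
    if len(markers) != num_markers:
        raise FormatError(
            f"{path}: line 4 declares {len(markers)} marker names but header "
            f"says NumMarkers={num_markers}")

    data_rows = [ln for ln in lines[5:] if ln.strip()]
    if len(data_rows) != num_frames:
        raise FormatError(
            f"{path}: header declares NumFrames={num_frames} but file has "
            f"{len(data_rows)} data rows")

    expected_cols = 2 + 3 * num_markers
    data = np.empty((num_frames, 3 * num_markers), dtype=float)
    for r, ln in enumerate(data_rows):
        cells = ln.split("\t")
        if len(cells) < expected_cols:
            raise FormatError(
                f"{path}: data row {r} has {len(cells)} columns, expected {expected_cols}")
        try:
            data[r] = [float(c) for c in cells[2:expected_cols]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in data row {r}: {exc}") from exc

    out: dict[str, MarkerTriplet] = {}
    for m, name in enumerate(markers):
        sigs = {
            ax: SampledSignal(
                data[:, 3 * m + a], data_rate, start_time=start_time,
                label=f"{name}_{ax.upper()}", units="m")
            for a, ax in enumerate(_AXES)
        }
        out[name] = MarkerTriplet(**sigs)
    return out


def write_trc(path: str | Path, markers: Mapping[str, tuple], sampling_rate: float,
              units: str = "m") -> None:
    """Write marker triplets (mapping name -> (x, y, z) arrays) as TRC.

    Values are formatted with 17 significant digits so the paired reader
    recovers the arrays exactly.
    """
    path = Path(path)
    names = list(markers)
    arrays = {n: [np.asarray(a, dtype=float) for a in markers[n]] for n in names}
    n_frames = len(arrays[names[0]][0])
    for n in names:
        if len(arrays[n]) != 3 or any(len(a) != n_frames for a in arrays[n]):
            raise FormatError(f"marker {n!r} must provide three equal-length axis arrays")

    rows = []
    rows.append(f"PathFileType\t4\t(X/Y/Z)\t{path.name}")
    rows.append("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames")
    rows.append(f"{sampling_rate:g}\t{sampling_rate:g}\t{n_frames}\t{len(names)}\t"
                f"{units}\t{sampling_rate:g}\t1\t{n_frames}")
    rows.append("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t")
    rows.append("\t\t" + "\t".join(
        f"X{m + 1}\tY{m + 1}\tZ{m + 1}" for m in range(len(names))))
    for i in range(n_frames):
        cells = [str(i + 1), f"{i / sampling_rate:.17g}"]
        for n in names:
            cells.extend(f"{arrays[n][a][i]:.17g}" for a in range(3))
        rows.append("\t".join(cells))
    path.write_text("\n".join(rows) + "\n")


def read_force_csv(
    path: str | Path,
    column_map: Mapping[str, str],
    sampling_rate: float,
    start_time: float = 0.0,
) -> dict[str, SampledSignal]:
    """Read mapped vertical-force columns from a delimited text export.

    ``column_map`` maps logical platform names to file headers.  The
    delimiter is auto-detected among comma/semicolon/tab; the sampling
    rate is supplied, not inferred.

    Raises
    ------
    ConfigurationError
        If a mapped header is absent (the message lists available headers).
    FormatError
        If a mapped column contains a non-numeric cell (with row number).
    """
    path = Path(path)
    try:
        sample = path.read_text()[:4096]
        try:
            sep = csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
        except csv.Error:
            sep = ","
        df = pd.read_csv(path, sep=sep)
    except (pd.errors.ParserError, OSError) as exc:
        raise FormatError(f"{path}: could not parse force export: {exc}") from exc
    out: dict[str, SampledSignal] = {}
    for logical, header in column_map.items():
        if header not in df.columns:
            raise ConfigurationError(
                f"{path}: mapped header {header!r} not in file; available "
                f"headers: {list(df.columns)}")
        col = pd.to_numeric(df[header], errors="coerce")
        bad = col.index[col.isna() & df[header].notna()]
        if len(bad) or col.isna().any():
            row = int(bad[0]) if len(bad) else int(col.index[col.isna()][0])
            raise FormatError(f"{path}: non-numeric cell in column {header!r}, data row {row}")
        out[logical] = SampledSignal(
            col.to_numpy(dtype=float), sampling_rate, start_time=start_time,
            label=header, units="N")
    return out


def write_force_csv(path: str | Path, columns: Mapping[str, np.ndarray]) -> None:
    """Write force channels (mapping header -> array) as comma-delimited text."""
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# reports


def write_sync_report(result, path: str | Path) -> None:
    """Serialize a SyncResult / TrialFailure / batch dict as a JSON report."""
    path = Path(path)
    payload = result.to_dict() if hasattr(result, "to_dict") else result
    try:
        path.write_text(json.dumps(payload, indent=2) + "\n")
    except OSError as exc:
        raise HeelSyncError(f"cannot write report to {path}: {exc}") from exc


def read_sync_report(path: str | Path) -> dict:
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except OSError as exc:
        raise HeelSyncError(f"cannot read report from {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON report: {exc}") from exc


def write_mot(path: str | Path, signals: Mapping[str, SampledSignal]) -> None:
    """Write signals as an OpenSim storage (MOT) table, time first column.

    All signals must share one clock and rate; intended for handing the
    shifted force channel to downstream musculoskeletal tooling.
    """
    path = Path(path)
    sigs = dict(signals)
    if not sigs:
        raise FormatError("write_mot needs at least one signal")
    first = next(iter(sigs.values()))
    for name, s in sigs.items():
        if s.n_samples != first.n_samples or s.sampling_rate != first.sampling_rate \
                or s.start_time != first.start_time:
            raise FormatError(f"signal {name!r} is not on the shared clock/grid")
    t = first.times()
    lines = [
        path.stem,
        "version=1",
        f"nRows={first.n_samples}",
        f"nColumns={1 + len(sigs)}",
        "inDegrees=no",
        "endheader",
        "time\t" + "\t".join(sigs),
    ]
    for i in range(first.n_samples):
        lines.append("\t".join([f"{t[i]:.17g}"] + [f"{s.values[i]:.17g}" for s in sigs.values()]))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trial assembly


def load_trial(trc_path: str | Path, force_path: str | Path, config) -> TrialRecord:
    """Assemble a TrialRecord from a TRC file and a force export per config."""
    markers = read_trc(trc_path)
    for name in (config.heel_marker_left, config.heel_marker_right):
        if name not in markers:
            raise ConfigurationError(
                f"heel marker {name!r} not in TRC file; markers present: "
                f"{sorted(markers)}")
    forces = read_force_csv(force_path, config.force_columns, config.force_sampling_rate)
    if config.active_platform not in forces:
        raise ConfigurationError(
            f"active_platform {config.active_platform!r} not among mapped force "
            f"columns {sorted(forces)}")
    axis = config.vertical_axis
    return TrialRecord(
        heel_left=markers[config.heel_marker_left].axis(axis),
        heel_right=markers[config.heel_marker_right].axis(axis),
        vgrf=forces,
        laterality_mode=config.laterality_mode,
        evaluated_side=config.evaluated_side,
        active_platform=config.active_platform,
        name=Path(trc_path).stem,
    )
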