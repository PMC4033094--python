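"""On-disk formats: TSV interchange, SNIRF-style HDF5 export, provenance.

TSV is the canonical format — human-diffable and test-friendly.  A
recording TSV has a ``time_s`` column plus one column per
channel-chromophore (``L_HbO``, ``L_Hb``, ...); a trial table TSV has
``onset_s``, ``duration_s``, ``condition``, ``block``.  Every written
recording gets a JSON provenance sidecar (``<name>.provenance.json``)
listing the processing steps and their parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .recording import CHROMOPHORES, HemoRecording, Trial, TrialTable

_FMT_VERSION = "1.0"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".provenance.json")


def _check_overwrite(path: Path, force: bool) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")


def write_trials(trials: TrialTable, path, force: bool = False) -> None:
    path = Path(path)
    _check_overwrite(path, force)
    df = pd.DataFrame(
        [{"onset_s": t.onset, "duration_s": t.duration,
          "condition": t.condition, "block": t.block} for t in trials]
    )
    df.to_csv(path, sep="\t", index=False)


def read_trials(path) -> TrialTable:
    df = pd.read_csv(path, sep="\t")
    required = {"onset_s", "duration_s", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if "block" not in df.columns:
        df["block"] = "restricted"
    return TrialTable(
        Trial(float(r.onset_s), float(r.duration_s), str(r.condition),
              str(r.block))
        for r in df.itertuples()
    )


def write_recording(rec: HemoRecording, path, force: bool = False) -> None:
    """Write a recording TSV plus its provenance sidecar."""
    path = Path(path)
    _check_overwrite(path, force)
    data = {"time_s": rec.times}
    for ch in rec.channels:
        for chromo in CHROMOPHORES:
            data[f"{ch}_{chromo}"] = rec.series[ch][chromo]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                              float_format="%.9g")
    _sidecar(path).write_text(json.dumps(
        {"format": _FMT_VERSION, "rate_hz": rec.rate,
         "steps": rec.provenance}, indent=2))


def read_recording(path) -> HemoRecording:
    """Read a recording TSV (sidecar provenance restored if present)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: timestamps are not strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-4):
        raise ValueError(f"{path}: timestamps are not uniformly spaced")
    rate = 1.0 / dt.mean()
    series: dict[str, dict[str, np.ndarray]] = {}
    for col in df.columns:
        if col == "time_s":
            continue
        if "_" not in col:
            raise ValueError(
                f"{path}: column {col!r} is not of the form "
                "<channel>_<HbO|Hb>"
            )
        ch, chromo = col.rsplit("_", 1)
        if chromo not in CHROMOPHORES:
            raise ValueError(
                f"{path}: column {col!r} has unknown chromophore suffix "
                f"{chromo!r} (expected one of {CHROMOPHORES})"
            )
        series.setdefault(ch, {})[chromo] = df[col].to_numpy(float)
    provenance = []
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        provenance = meta.get("steps", [])
        if "rate_hz" in meta:
            rate = float(meta["rate_hz"])
    return HemoRecording(rate=rate, series=series, provenance=provenance)


def write_snirf(rec: HemoRecording, path, force: bool = False) -> None:
    """Export to a minimal SNIRF-style HDF5 layout (processed Hb data)."""
    path = Path(path)
    _check_overwrite(path, force)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=rec.to_matrix())
        data1.create_dataset("time", data=rec.times)
        for i, (ch, chromo) in enumerate(
            [(ch, c) for ch in rec.channels for c in CHROMOPHORES], start=1
        ):
            ml = data1.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=rec.channels.index(ch) + 1)
            ml.create_dataset("detectorIndex", data=rec.channels.index(ch) + 1)
            ml.create_dataset("dataTypeLabel", data=chromo)
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("LengthUnit", data="s")
        meta.create_dataset("rate_hz", data=rec.rate)
        meta.create_dataset("channels", data=",".join(rec.channels))


def read_snirf(path) -> HemoRecording:
    """Re-import a recording written by :func:`write_snirf`."""
    with h5py.File(path, "r") as f:
        data1 = f["nirs/data1"]
        mat = np.asarray(data1["dataTimeSeries"])
        meta = f["nirs/metaDataTags"]
        rate = float(np.asarray(meta["rate_hz"]))
        raw = meta["channels"][()]
        if isinstance(raw, bytes):
            raw = raw.decode()
        channels = str(raw).split(",")
    series: dict[str, dict[str, np.ndarray]] = {}
    col = 0
    for ch in channels:
        series[ch] = {}
        for chromo in CHROMOPHORES:
            series[ch][chromo] = mat[:, col]
            col += 1
    return HemoRecording(rate=rate, series=series)
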