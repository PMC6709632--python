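"""File formats: CSV for traces/curves/transit times, TIFF for image data.

CSV files are the universal interchange: a header row names the columns
(with units in the names) and values are written with 17 significant
digits, so numeric round-trips are lossless at 64-bit precision. Optional
``# key=value`` comment lines carry metadata such as the sampling interval.
"""

from __future__ import annotations

import json
from typing import Tuple

import numpy as np
import pandas as pd
import tifffile

from .correlator import CorrelationCurve, IntensityTrace
from .errors import FormatError
from .sfcs_pipeline import SFCSCarpet
from .transit_stats import TransitTimeSet

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_curve_csv", "read_curve_csv",
    "write_transit_csv", "read_transit_csv",
    "write_carpet", "read_carpet",
    "write_image_tiff", "read_image_tiff",
    "write_json",
]

_FLOAT_FMT = "%.17g"


def _write_csv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_csv(path, required) -> Tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}' "
                              f"(found {list(df.columns)})")
    return df, meta


def write_trace_csv(path, trace: IntensityTrace) -> None:
    t = (np.arange(1, len(trace) + 1)) * trace.dt
    _write_csv(path, pd.DataFrame({"time_s": t, "intensity": trace.values}),
               meta={"dt_s": repr(trace.dt), **trace.meta})


def read_trace_csv(path) -> IntensityTrace:
    df, meta = _read_csv(path, required=("time_s", "intensity"))
    if "dt_s" in meta:
        dt = float(meta["dt_s"])
    elif len(df) > 1:
        dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
    else:
        raise FormatError(f"{path}: cannot determine the sampling interval")
    return IntensityTrace(df["intensity"].to_numpy(), dt, meta)


def write_curve_csv(path, curve: CorrelationCurve) -> None:
    d = {"lag_s": curve.lags, "G": curve.G}
    if curve.sem is not None:
        d["sem"] = curve.sem
    _write_csv(path, pd.DataFrame(d), meta=curve.meta)


def read_curve_csv(path) -> CorrelationCurve:
    df, meta = _read_csv(path, required=("lag_s", "G"))
    sem = df["sem"].to_numpy() if "sem" in df.columns else None
    return CorrelationCurve(df["lag_s"].to_numpy(), df["G"].to_numpy(),
                            sem, meta)


def write_transit_csv(path, times: TransitTimeSet) -> None:
    d = {"transit_ms": times.times_ms}
    if times.labels is not None:
        d["group"] = times.labels
    _write_csv(path, pd.DataFrame(d))


def read_transit_csv(path) -> TransitTimeSet:
    df, _ = _read_csv(path, required=("transit_ms",))
    labels = df["group"].to_numpy() if "group" in df.columns else None
    return TransitTimeSet(df["transit_ms"].to_numpy(), labels=labels)


def write_carpet(path, carpet: SFCSCarpet) -> None:
    """Write a carpet as TIFF (pixels x cycles) or CSV, by extension."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        data = carpet.intensities
        if np.allclose(data, np.round(data)) and data.max() < 2 ** 16 \
                and data.min() >= 0:
            data = data.astype(np.uint16)
        else:
            data = data.astype(np.float32)
        tifffile.imwrite(
            path, data,
            metadata={"axes": "YX",
                      "scan_frequency_hz": carpet.scan_frequency,
                      "pixel_size_nm": carpet.pixel_size_nm})
    elif path.endswith(".csv"):
        df = pd.DataFrame(carpet.intensities.T)
        df.columns = [f"pixel_{i}" for i in range(carpet.n_pixels)]
        _write_csv(path, df,
                   meta={"scan_frequency_hz": repr(carpet.scan_frequency),
                         "pixel_size_nm": repr(carpet.pixel_size_nm)})
    else:
        raise FormatError(f"unsupported carpet format: {path}")


def read_carpet(path, scan_frequency: float | None = None,
                pixel_size_nm: float | None = None) -> SFCSCarpet:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray().astype(float)
            md = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        freq = scan_frequency or float(md.get("scan_frequency_hz", 0) or 0)
        px = pixel_size_nm or float(md.get("pixel_size_nm", 100.0))
        if not freq:
            raise FormatError(f"{path}: scan frequency not in metadata; "
                              "pass scan_frequency explicitly")
        return SFCSCarpet(data, scan_frequency=freq, pixel_size_nm=px)
    if path.endswith(".csv"):
        df, meta = _read_csv(path, required=())
        cols = [c for c in df.columns if c.startswith("pixel_")]
        if not cols:
            raise FormatError(f"{path}: no pixel_* columns found")
        freq = scan_frequency or float(meta.get("scan_frequency_hz", 0) or 0)
        px = pixel_size_nm or float(meta.get("pixel_size_nm", 100.0))
        if not freq:
            raise FormatError(f"{path}: scan frequency missing")
        return SFCSCarpet(df[cols].to_numpy().T, scan_frequency=freq,
                          pixel_size_nm=px)
    raise FormatError(f"unsupported carpet format: {path}")


def write_image_tiff(path, *channels) -> None:
    data = np.stack([np.asarray(c, dtype=np.float32) for c in channels]) \
        if len(channels) > 1 else np.asarray(channels[0], dtype=np.float32)
    tifffile.imwrite(str(path), data)


def read_image_tiff(path) -> np.ndarray:
    try:
        return tifffile.imread(str(path)).astype(float)
    except Exception as exc:
        raise FormatError(f"{path}: cannot read TIFF ({exc})") from exc


def write_json(path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
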