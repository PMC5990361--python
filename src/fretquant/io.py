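"""Readers and writers for the package's flat file formats.

All formats are plain text (CSV/JSON/YAML) except channel images, which
are TIFF.  Schema violations raise :class:`SchemaError` naming the file
and offending column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SchemaError
from .flim import DecayHistogram, IRF
from .imaging import SpectralImageSet
from .isotherms import TitrationDataset
from .kinetics import KineticTrace


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError("missing required columns", path=str(path),
                          field=",".join(missing))


def read_titration_csv(path) -> TitrationDataset:
    """Tidy titration table: analyte_value, analyte_unit, replicate, ratio."""
    df = pd.read_csv(path)
    _require_columns(df, ["analyte_value", "replicate", "ratio"], path)
    return TitrationDataset.from_dataframe(df)


def write_titration_csv(path, data: TitrationDataset) -> None:
    rows = []
    for i, x in enumerate(data.axis):
        for rep in range(data.responses.shape[1]):
            rows.append({"analyte_value": x, "analyte_unit": data.axis_unit,
                         "replicate": rep + 1, "ratio": data.responses[i, rep]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_kinetics_csv(path) -> list:
    """Kinetic traces: time_s, signal and optional series_conc_uM column."""
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "signal"], path)
    if "series_conc_uM" in df.columns and df["series_conc_uM"].notna().any():
        traces = []
        for conc, sub in df.groupby("series_conc_uM", sort=True):
            traces.append(KineticTrace(time_s=sub["time_s"].to_numpy(),
                                       signal=sub["signal"].to_numpy(),
                                       substrate_conc_uM=float(conc)))
        return traces
    return [KineticTrace(time_s=df["time_s"].to_numpy(),
                         signal=df["signal"].to_numpy())]


def read_decay_csv(path, as_irf: bool = False):
    """TCSPC histogram: bin_start_ns, counts (uniform binning)."""
    df = pd.read_csv(path)
    _require_columns(df, ["bin_start_ns", "counts"], path)
    starts = df["bin_start_ns"].to_numpy(dtype=float)
    if starts.size < 2:
        raise SchemaError("need at least two bins", path=str(path))
    dt = np.diff(starts)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise SchemaError("binning is not uniform", path=str(path),
                          field="bin_start_ns")
    edges = np.append(starts, starts[-1] + dt[0])
    counts = df["counts"].to_numpy(dtype=float)
    if as_irf:
        return IRF.from_histogram(edges, counts)
    return DecayHistogram(bin_edges_ns=edges, counts=counts)


def write_decay_csv(path, h: DecayHistogram) -> None:
    pd.DataFrame({"bin_start_ns": h.bin_edges_ns[:-1],
                  "counts": h.counts}).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    """Cytometry event table with the six channels + condition/replicate."""
    from .cytometry import validate_events

    df = pd.read_csv(path)
    try:
        validate_events(df)
    except SchemaError as exc:
        raise SchemaError(str(exc), path=str(path)) from exc
    return df


def read_image_set(tmr_path, fret_path, sir_path,
                   flatfield_paths: Optional[dict] = None,
                   background: Optional[dict] = None) -> SpectralImageSet:
    """Assemble a channel set from per-channel TIFF files."""
    import tifffile

    channels = {name: tifffile.imread(p).astype(float)
                for name, p in (("tmr", tmr_path), ("fret", fret_path),
                                ("sir", sir_path))}
    flat = None
    if flatfield_paths:
        flat = {ch: tifffile.imread(p).astype(float)
                for ch, p in flatfield_paths.items()}
    return SpectralImageSet(**channels, flatfield=flat, background=background)


def write_image_set(directory, imgs: SpectralImageSet, prefix: str = "") -> dict:
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ch in ("tmr", "fret", "sir"):
        p = directory / f"{prefix}{ch}.tif"
        tifffile.imwrite(p, imgs.channel(ch).astype(np.float32))
        paths[ch] = p
    return paths


def read_mask_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path).astype(np.int32)


def write_fit_report(path, payload: dict) -> None:
    """JSON fit report; numpy types are converted to plain Python."""

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default,
                                     sort_keys=True))
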