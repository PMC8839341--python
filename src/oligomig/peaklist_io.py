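"""Peak-list and report file I/O.

Primary dialect: comma-separated, dot-decimal, UTF-8 CSV with a header row
(columns ``mz,intensity``); a one-column file is read with unit intensities.
MGF is supported for MSn product-ion lists through pyteomics.  All tables
written by the package carry a ``#`` provenance header (tool version, config
hash, seed) that readers skip.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from . import __version__
from .annotation import MassTolerance, PeakList

__all__ = [
    "read_peaklist",
    "write_peaklist_csv",
    "write_peaklist_mgf",
    "write_table",
    "read_table",
    "config_hash",
]


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping, for provenance headers."""
    blob = json.dumps({k: str(v) for k, v in sorted(config.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance_lines(config: Mapping | None, seed: int | None) -> list[str]:
    parts = [f"# oligomig {__version__}"]
    if config is not None:
        parts.append(f"# config_hash {config_hash(config)}")
    if seed is not None:
        parts.append(f"# seed {seed}")
    return parts


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> None:
    """CSV export with a commented provenance header, 6-decimal floats."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for line in _provenance_lines(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _peaklist_from_frame(
    df: pd.DataFrame, instrument: str, source: str, tolerance: MassTolerance | None
) -> PeakList:
    cols = [str(c).strip().lower() for c in df.columns]
    df.columns = cols
    if "mz" in cols:
        mz = df["mz"].to_numpy(float)
        inten = df["intensity"].to_numpy(float) if "intensity" in cols else None
    else:
        mz = df.iloc[:, 0].to_numpy(float)
        inten = df.iloc[:, 1].to_numpy(float) if df.shape[1] > 1 else None
    if inten is None:
        warnings.warn(f"{source}: no intensity column; defaulting intensities to 1.0", stacklevel=2)
        inten = np.ones_like(mz)
    if np.any(inten < 0):
        raise ValueError(f"{source}: negative intensities")
    return PeakList(mz=mz, intensity=inten, instrument=instrument, tolerance=tolerance,
                    metadata={"source": source})


def read_peaklist(
    path: str | Path,
    fmt: str | None = None,
    instrument: str = "generic",
    tolerance: MassTolerance | None = None,
) -> PeakList:
    """Read a centroided peak list from CSV or MGF.

    Format is auto-detected from the extension (``.mgf`` vs anything else =
    CSV) unless *fmt* overrides it.  For MGF, the first ``BEGIN IONS`` block
    is used.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mgf" if path.suffix.lower() == ".mgf" else "csv"
    if fmt == "mgf":
        with _mgf.read(str(path)) as reader:
            try:
                spectrum = next(iter(reader))
            except StopIteration:
                raise ValueError(f"{path}: no spectra in MGF file") from None
        mz = np.asarray(spectrum["m/z array"], float)
        inten = np.asarray(spectrum["intensity array"], float)
        meta = {str(k): str(v) for k, v in spectrum.get("params", {}).items()}
        meta["source"] = str(path)
        return PeakList(mz=mz, intensity=inten, instrument=instrument, tolerance=tolerance,
                        metadata=meta)
    if fmt == "csv":
        try:
            df = pd.read_csv(path, comment="#")
        except Exception as e:
            raise ValueError(f"{path}: cannot parse CSV peak list: {e}") from e
        if df.empty:
            raise ValueError(f"{path}: empty peak list")
        # headerless two-column numeric files: first row was consumed as header
        try:
            float(df.columns[0])
            df = pd.read_csv(path, comment="#", header=None)
        except ValueError:
            pass
        return _peaklist_from_frame(df, instrument, str(path), tolerance)
    raise ValueError(f"unknown peak-list format {fmt!r} (use 'csv' or 'mgf')")


def write_peaklist_csv(
    peaks: PeakList, path: str | Path, config: Mapping | None = None, seed: int | None = None
) -> None:
    df = pd.DataFrame({"mz": peaks.mz, "intensity": peaks.intensity})
    write_table(df, path, config=config, seed=seed)


def write_peaklist_mgf(peaks: PeakList, path: str | Path, title: str = "oligomig") -> None:
    spectrum = {
        "m/z array": np.asarray(peaks.mz, float),
        "intensity array": np.asarray(peaks.intensity, float),
        "params": {"title": title},
    }
    _mgf.write([spectrum], output=str(path), file_mode="w")
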