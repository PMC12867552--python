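"""File formats, run configuration and provenance records.

Epochs come from EDF recordings (via ``mne``, optional), plain CSV (one
column per channel, header row, sampling rate supplied by the caller) or
NPZ archives written by this package.  The NPZ schema is versioned:
arrays ``epochs`` (epochs x samples), scalars ``fs`` and ``seed``,
optional ``levels``/``beta_targets``, plus a ``schema`` field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("rnb")

NPZ_SCHEMA = "rnb-epochs-1"


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass
class RunConfig:
    """Configuration of a command-line run (YAML-loadable)."""

    input: str | None = None
    format: str = "csv"
    channel: str | int = 0
    epoch_s: float = 20.0
    fs: float | None = None
    outdir: str = "."
    seed: int = 0
    verbosity: int = 1
    rnb: dict = field(default_factory=dict)
    bands: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _epochize(x: np.ndarray, fs: float, epoch_s: float) -> list[np.ndarray]:
    n = int(round(epoch_s * fs))
    n_ep = x.size // n
    dropped = x.size - n_ep * n
    if dropped:
        logger.info(
            "dropped %d trailing samples (%.2f s) not filling an epoch",
            dropped,
            dropped / fs,
        )
    return [x[i * n : (i + 1) * n].copy() for i in range(n_ep)]


def _read_csv_column(path: str, channel) -> np.ndarray:
    import pandas as pd

    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(_locate_csv_fault(path, exc)) from exc
    col = channel if isinstance(channel, str) else df.columns[int(channel)]
    if col not in df.columns:
        raise KeyError(f"unknown channel {channel!r}; file has {list(df.columns)}")
    vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    if np.isnan(vals).any():
        bad_row = int(np.flatnonzero(np.isnan(vals))[0])
        raise FormatError(_row_byte_offset(path, bad_row))
    return vals


def _locate_csv_fault(path: str, exc: Exception) -> str:
    return f"malformed CSV {path!r}: {exc}"


def _row_byte_offset(path: str, bad_row: int) -> str:
    """Name the byte offset of the first non-numeric data row."""
    offset = 0
    with open(path, "rb") as fh:
        for i, line in enumerate(fh):
            if i == bad_row + 1:       # +1 for the header line
                return (
                    f"non-numeric value in {path!r} at data row {bad_row} "
                    f"(byte offset {offset})"
                )
            offset += len(line)
    return f"non-numeric value in {path!r} at data row {bad_row}"


def read_epochs(
    path: str,
    format: str | None = None,
    epoch_s: float = 20.0,
    channel: str | int = 0,
    fs: float | None = None,
) -> tuple[list[np.ndarray], float]:
    """Read a recording and cut it into non-overlapping epochs.

    Returns ``(epochs, fs)``; a trailing partial epoch is dropped (and
    logged).  CSV input requires ``fs``; NPZ archives carry their own
    sampling rate and are returned as stored.
    """
    p = Path(path)
    fmt = format or p.suffix.lstrip(".").lower()
    if fmt == "npz":
        with np.load(p) as z:
            if "epochs" not in z or "fs" not in z:
                raise FormatError(f"{path!r} lacks the 'epochs'/'fs' arrays")
            return [np.asarray(e, float) for e in z["epochs"]], float(z["fs"])
    if fmt == "csv":
        if fs is None:
            raise ValueError("CSV input requires an explicit sampling rate (fs)")
        x = _read_csv_column(path, channel)
        return _epochize(x, fs, epoch_s), float(fs)
    if fmt == "edf":
        try:
            import mne
        except ImportError as exc:
            raise ImportError("EDF support requires the optional 'mne' dependency") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        names = raw.ch_names
        name = channel if isinstance(channel, str) else names[int(channel)]
        if name not in names:
            raise KeyError(f"unknown channel {channel!r}; file has {names}")
        x = raw.get_data(picks=[name])[0]
        return _epochize(x, raw.info["sfreq"], epoch_s), float(raw.info["sfreq"])
    raise ValueError(f"unknown format {fmt!r} (expected edf, csv or npz)")


def write_epochs_npz(
    path: str,
    epochs: np.ndarray,
    fs: float,
    seed: int | None = None,
    levels: np.ndarray | None = None,
    beta_targets: np.ndarray | None = None,
) -> None:
    data = {
        "schema": NPZ_SCHEMA,
        "epochs": np.asarray(epochs, float),
        "fs": float(fs),
        "seed": -1 if seed is None else int(seed),
    }
    if levels is not None:
        data["levels"] = np.asarray(levels, float)
    if beta_targets is not None:
        data["beta_targets"] = np.asarray(beta_targets, float)
    np.savez(path, **data)


def write_provenance(path: str, config: dict, seed: int | None) -> None:
    """JSON record sufficient to regenerate an output bit-identically."""
    import rnb

    record = {
        "package": "rnb",
        "version": rnb.__version__,
        "seed": seed,
        "config": config,
        "versions": _lib_versions(),
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)


def _lib_versions() -> dict:
    import numpy
    import pandas
    import scipy

    return {"numpy": numpy.__version__, "scipy": scipy.__version__, "pandas": pandas.__version__}
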