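"""Recording containers, channel filtering, and tabular I/O.

A :class:`Recording` bundles the two channels of a sensillum tip-recording:
the unfiltered DC trace (transepithelial potential plus spikes) and the
high-pass filtered AC trace (spike-emphasizing), together with the sampling
rate, stimulus onset times and experiment metadata.  Recordings are stored
in HDF5 containers with datasets ``/dc`` and ``/ac``; feature and slope
tables are stored as CSV (or read from XLS workbooks in the deposited
layout).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Recording",
    "FEATURE_COLUMNS",
    "derive_ac",
    "write_recording",
    "read_recording",
    "write_feature_table",
    "read_feature_table",
    "read_slope_sheet",
    "read_raw_parameter_sheet",
]

#: canonical feature-table columns, in the order of the deposited raw sheets
FEATURE_COLUMNS = ["latency", "f6ap", "spa", "n_aps_early", "n_aps_llpr"]

# header variants accepted when reading external tables (lower-cased,
# stripped of spaces/underscores/#-signs before lookup)
_COLUMN_ALIASES: Mapping[str, str] = {
    "latency": "latency",
    "latencyms": "latency",
    "f6ap": "f6ap",
    "f6aps": "f6ap",
    "phasicfrequency": "f6ap",
    "spa": "spa",
    "spamv": "spa",
    "sensillumpotentialamplitude": "spa",
    "apsearly": "n_aps_early",
    "napsearly": "n_aps_early",
    "aps1s": "n_aps_early",
    "naps1s": "n_aps_early",
    "apsllpr": "n_aps_llpr",
    "napsllpr": "n_aps_llpr",
    "llpr": "n_aps_llpr",
    "experimentid": "experiment_id",
    "experiment": "experiment_id",
    "id": "experiment_id",
    "animal": "experiment_id",
    "condition": "condition",
    "treatment": "condition",
    "zt": "zt",
    "ztwindow": "zt",
    "stimulationtime": "stimulation_time",
    "stimulationtimemin": "stimulation_time",
    "time": "stimulation_time",
    "timemin": "stimulation_time",
    "slope": "slope",
}

_META_FIELDS = ("animal_id", "condition", "zt_window", "day", "stimulus_duration")


@dataclasses.dataclass
class Recording:
    """Dual-channel tip-recording with stimulus schedule and metadata.

    Parameters
    ----------
    dc:
        Unfiltered channel, millivolts.
    ac:
        High-pass filtered channel, millivolts; same length as ``dc``.
    sampling_rate:
        Samples per second (default 20 kHz).
    stimulus_onsets:
        Stimulus onset times in seconds from recording start, strictly
        increasing and inside the recorded interval.
    meta:
        Free-form metadata; the keys ``animal_id``, ``condition``,
        ``zt_window``, ``day`` and ``stimulus_duration`` are round-tripped
        through the HDF5 container.
    """

    dc: np.ndarray
    ac: np.ndarray
    sampling_rate: float = 20_000.0
    stimulus_onsets: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0)
    )
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dc = np.asarray(self.dc, dtype=np.float64)
        self.ac = np.asarray(self.ac, dtype=np.float64)
        self.stimulus_onsets = np.asarray(self.stimulus_onsets, dtype=np.float64)
        if self.dc.shape != self.ac.shape:
            raise ValueError(
                f"dc and ac must have equal length, got {self.dc.size} and {self.ac.size}"
            )
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.stimulus_onsets.size:
            if np.any(np.diff(self.stimulus_onsets) <= 0):
                raise ValueError("stimulus_onsets must be strictly increasing")
            if self.stimulus_onsets[0] < 0 or self.stimulus_onsets[-1] >= self.duration:
                raise ValueError("stimulus_onsets must lie within [0, duration)")

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.dc.size / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return self.dc.size

    def time_to_index(self, t: float) -> int:
        return int(round(t * self.sampling_rate))


def derive_ac(
    dc: np.ndarray, sampling_rate: float, cutoff: float = 150.0
) -> np.ndarray:
    """High-pass filter the DC channel to obtain the AC (spike) channel.

    Uses a 4th-order Butterworth applied forward-backward (zero phase), so
    spike extrema keep their timing.

    Parameters
    ----------
    dc:
        Input samples.
    sampling_rate:
        Hz; must exceed twice the cutoff.
    cutoff:
        High-pass cutoff frequency in Hz (default 150).
    """
    nyquist = sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(
            f"cutoff must be in (0, Nyquist={nyquist:g} Hz), got {cutoff}"
        )
    sos = signal.butter(4, cutoff, btype="highpass", fs=sampling_rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(dc, dtype=np.float64))


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording to an HDF5 container (datasets /dc, /ac)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("dc", data=rec.dc)
        f.create_dataset("ac", data=rec.ac)
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["stimulus_onsets"] = rec.stimulus_onsets
        for key in _META_FIELDS:
            if key in rec.meta and rec.meta[key] is not None:
                f.attrs[f"meta_{key}"] = rec.meta[key]
        extra = {k: v for k, v in rec.meta.items() if k not in _META_FIELDS}
        for k, v in extra.items():
            if isinstance(v, (str, int, float, bool)):
                f.attrs[f"meta_{k}"] = v
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises ``KeyError`` naming the missing attribute if the container lacks
    ``sampling_rate`` or ``stimulus_onsets``.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for ds in ("dc", "ac"):
            if ds not in f:
                raise KeyError(f"recording container is missing dataset '{ds}'")
        for attr in ("sampling_rate", "stimulus_onsets"):
            if attr not in f.attrs:
                raise KeyError(f"recording container is missing attribute '{attr}'")
        meta = {}
        for k, v in f.attrs.items():
            if k.startswith("meta_"):
                if isinstance(v, bytes):
                    v = v.decode()
                elif isinstance(v, np.generic):
                    v = v.item()
                meta[k[5:]] = v
        return Recording(
            dc=f["dc"][:],
            ac=f["ac"][:],
            sampling_rate=float(f.attrs["sampling_rate"]),
            stimulus_onsets=np.asarray(f.attrs["stimulus_onsets"], dtype=float),
            meta=meta,
        )


# ---------------------------------------------------------------------------
# tabular I/O


def _normalize_header(name: object) -> str:
    s = str(name).strip().lower()
    for ch in (" ", "_", "#", "(", ")", "-", "."):
        s = s.replace(ch, "")
    return s


def _canonical_columns(columns) -> dict:
    """Map raw header names to canonical names where recognized."""
    mapping = {}
    for col in columns:
        key = _normalize_header(col)
        if key in _COLUMN_ALIASES:
            mapping[col] = _COLUMN_ALIASES[key]
        else:
            # slope sheets suffix parameter names with 'slope'
            if key.endswith("slope"):
                base = key[: -len("slope")]
                if base in _COLUMN_ALIASES:
                    mapping[col] = _COLUMN_ALIASES[base]
    return mapping


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-stimulus feature table as CSV, NaN cells as "NaN"."""
    path = Path(path)
    table.to_csv(path, index=False, na_rep="NaN")
    return path


def _read_tabular(path: Path, sheet=0) -> pd.DataFrame:
    if path.suffix.lower() in (".xls", ".xlsx"):
        return pd.read_excel(path, sheet_name=sheet, na_values=["NaN", "nan"])
    return pd.read_csv(path, na_values=["NaN", "nan"])


def read_feature_table(path: str | Path, sheet=0) -> pd.DataFrame:
    """Read a per-stimulus feature table (CSV or XLS).

    Recognizes the canonical export of this package as well as minor header
    variants; "NaN" cells become missing values.  Returns a DataFrame with
    canonical column names; the matched header mapping is stored in
    ``df.attrs["header_mapping"]``.
    """
    path = Path(path)
    df = _read_tabular(path, sheet)
    mapping = _canonical_columns(df.columns)
    recognized = set(mapping.values())
    if not recognized & set(FEATURE_COLUMNS):
        raise ValueError(
            "unrecognized feature-table layout; expected columns like "
            f"{['stimulation_time', 'experiment_id', *FEATURE_COLUMNS]}, "
            f"got {list(df.columns)}"
        )
    df = df.rename(columns=mapping)
    df.attrs["header_mapping"] = mapping
    return df


def read_slope_sheet(path: str | Path, sheet=0) -> pd.DataFrame:
    """Read a per-animal slope table (CSV or XLS 'slopes' sheet).

    Expected layout: one row per experiment with an experiment ID column, a
    condition column, optionally a ZT column, and one slope column per
    response parameter.  Returns canonical columns ``experiment_id``,
    ``condition`` (and ``zt`` when present) plus the recognized parameter
    columns.
    """
    path = Path(path)
    df = _read_tabular(path, sheet)
    mapping = _canonical_columns(df.columns)
    df = df.rename(columns=mapping)
    param_cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    if "condition" not in df.columns or not param_cols:
        raise ValueError(
            "unrecognized slope-sheet layout; expected an experiment ID "
            "column, a condition column, and per-parameter slope columns "
            f"named like {FEATURE_COLUMNS}; got {list(df.columns)}"
        )
    df.attrs["header_mapping"] = mapping
    df.attrs["parameter_columns"] = param_cols
    return df


def read_raw_parameter_sheet(path: str | Path, sheet=0) -> pd.DataFrame:
    """Read a raw per-stimulation parameter sheet in the deposited layout.

    First column: stimulation time in minutes; remaining columns: one per
    experiment ID.  Returns a long-format DataFrame with columns
    ``stimulation_time``, ``experiment_id``, ``value``.
    """
    path = Path(path)
    df = _read_tabular(path, sheet)
    if df.shape[1] < 2:
        raise ValueError(
            "unrecognized raw-parameter layout; expected a stimulation-time "
            "column followed by one column per experiment"
        )
    time_col = df.columns[0]
    long = df.melt(
        id_vars=[time_col], var_name="experiment_id", value_name="value"
    ).rename(columns={time_col: "stimulation_time"})
    long["stimulation_time"] = pd.to_numeric(long["stimulation_time"])
    if (long["stimulation_time"].dropna() < 0).any():
        raise ValueError("stimulation times must be non-negative")
    return long
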