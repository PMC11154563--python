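"""Domain containers and file I/O.

A multichannel PPG recording lives on disk as a plain CSV table (one time
column, one column per LED channel, a pressure column and a displacement
column) plus a JSON sidecar carrying the sampling rate and the per-channel
wavelength metadata.  The packaged clinical table mirrors the study cohort:
56 nephrology-department subjects with laboratory hemoglobin (g/L) and,
where collected, blood pressure, heart rate, creatinine and urea.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import PPGFormatError

__all__ = [
    "MultichannelPPG",
    "SubjectRecord",
    "ClinicalTable",
    "read_ppg",
    "write_ppg",
    "load_clinical_fixture",
    "filter_complete",
]


@dataclass
class MultichannelPPG:
    """A transmissive PPG recording with sensor side-channels.

    Attributes
    ----------
    time : ndarray
        Sample times in seconds on a uniform grid.
    channels : ndarray, shape (n_samples, n_channels)
        Transmitted light intensity per LED channel, arbitrary ADC units.
    wavelengths_nm : ndarray, shape (n_channels,)
        Nominal peak wavelength of each LED (centroid for the broadband one).
    broadband : ndarray of bool, shape (n_channels,)
        Flags the spectrally broad channel.  Exactly one flag is set when the
        record carries the full 8-LED complement.
    pressure : ndarray
        Contact-force trace from the finger-clip pressure sensor (arb. units).
    displacement : ndarray
        LED-to-photodiode distance trace in mm.
    fs_hz : float
        Sampling rate, 500 Hz for the acquisition front end emulated here.
    """

    time: np.ndarray
    channels: np.ndarray
    wavelengths_nm: np.ndarray
    broadband: np.ndarray
    pressure: np.ndarray
    displacement: np.ndarray
    fs_hz: float = 500.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.broadband = np.asarray(self.broadband, dtype=bool)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = self.time.shape[0]
        if self.channels.shape[0] != n or self.pressure.shape[0] != n \
                or self.displacement.shape[0] != n:
            raise ValueError("time, channels, pressure and displacement must share length")
        if self.channels.shape[1] != self.wavelengths_nm.shape[0] \
                or self.channels.shape[1] != self.broadband.shape[0]:
            raise ValueError("per-channel metadata does not match channel count")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if np.any(self.channels < 0):
            raise ValueError("intensities must be non-negative")
        if self.n_channels == 8 and int(self.broadband.sum()) != 1:
            raise ValueError("an 8-channel record must flag exactly one broadband channel")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    def channel_order(self) -> np.ndarray:
        """Channel indices sorted by ascending wavelength, broadband last."""
        narrow = [i for i in range(self.n_channels) if not self.broadband[i]]
        narrow.sort(key=lambda i: self.wavelengths_nm[i])
        broad = [i for i in range(self.n_channels) if self.broadband[i]]
        return np.array(narrow + broad, dtype=int)

    def channel_names(self) -> list[str]:
        return [
            "led_broadband" if self.broadband[i] else f"led_{self.wavelengths_nm[i]:g}nm"
            for i in range(self.n_channels)
        ]


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the clinical table; optional covariates may be missing (None)."""

    id: int
    hemoglobin_g_per_L: float
    gender: str
    age: Optional[float] = None
    diastolic_mmHg: Optional[float] = None
    systolic_mmHg: Optional[float] = None
    heart_rate_bpm: Optional[float] = None
    creatinine_umol_per_L: Optional[float] = None
    urea_mmol_per_L: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.hemoglobin_g_per_L > 0:
            raise ValueError("hemoglobin must be positive")
        if self.gender not in ("male", "female"):
            raise ValueError(f"unknown gender {self.gender!r}")


_FIELD_ALIASES = {
    "hemoglobin": "hemoglobin_g_per_L",
    "creatinine": "creatinine_umol_per_L",
    "urea": "urea_mmol_per_L",
    "heart_rate": "heart_rate_bpm",
}


@dataclass(frozen=True)
class ClinicalTable:
    records: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with missing cells as NaN and gender coded 1=male, 0=female."""
        rows = [dataclasses.asdict(r) for r in self.records]
        df = pd.DataFrame(rows).set_index("id")
        df["gender"] = (df["gender"] == "male").astype(float)
        return df.astype(float)


def _resolve_fields(fields: Sequence[str]) -> list[str]:
    valid = {f.name for f in dataclasses.fields(SubjectRecord)}
    out: list[str] = []
    for name in fields:
        if name == "blood_pressure":
            out.extend(["diastolic_mmHg", "systolic_mmHg"])
            continue
        name = _FIELD_ALIASES.get(name, name)
        if name not in valid:
            raise KeyError(f"unknown clinical field {name!r}")
        out.append(name)
    return out


def filter_complete(table: ClinicalTable, fields: Sequence[str]) -> ClinicalTable:
    """Keep only subjects with every named covariate present.

    ``"blood_pressure"`` expands to both pressure fields; short aliases such as
    ``"creatinine"`` are accepted.  An empty field list returns the table as is.
    """
    names = _resolve_fields(fields)
    kept = tuple(
        r for r in table.records
        if all(getattr(r, name) is not None for name in names)
    )
    return ClinicalTable(kept)


def load_clinical_fixture() -> ClinicalTable:
    """The packaged 56-subject clinical table (hemoglobin in g/L)."""
    with resources.files("ppghb.data").joinpath("clinical_table.csv").open("r") as fh:
        df = pd.read_csv(fh)
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in df.columns:
            v = row[col]
            if col == "gender":
                kwargs[col] = v
            elif col == "id":
                kwargs[col] = int(v)
            else:
                kwargs[col] = None if pd.isna(v) else float(v)
        records.append(SubjectRecord(**kwargs))
    return ClinicalTable(tuple(records))


# --------------------------------------------------------------------------
# signal files: CSV + JSON sidecar

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_ppg(rec: MultichannelPPG, path: str | Path) -> Path:
    """Write a recording as ``<path>.csv``-style table plus JSON sidecar."""
    path = Path(path)
    names = rec.channel_names()
    header = ["time"] + names + ["pressure", "displacement"]
    data = np.column_stack(
        [rec.time, rec.channels, rec.pressure, rec.displacement])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in data:
            w.writerow([f"{v:.10g}" for v in row])
    meta = {
        "fs_hz": rec.fs_hz,
        "channels": [
            {
                "name": names[i],
                "wavelength_nm": float(rec.wavelengths_nm[i]),
                "broadband": bool(rec.broadband[i]),
            }
            for i in range(rec.n_channels)
        ],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_ppg(path: str | Path) -> MultichannelPPG:
    """Read a recording written by :func:`write_ppg`.

    Raises
    ------
    PPGFormatError
        If the sidecar is missing, a required column is absent, or a row is
        ragged / non-numeric (the error names the offending line).
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise PPGFormatError(f"missing metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise PPGFormatError(f"unreadable sidecar {sidecar}: {exc}") from exc

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PPGFormatError(f"{path}: empty file") from None
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise PPGFormatError(
                    f"{path}: line {lineno}: expected {len(header)} cells, got {len(row)}")
            try:
                rows.append([float(v) for v in row])
            except ValueError as exc:
                raise PPGFormatError(f"{path}: line {lineno}: {exc}") from exc
    if not rows:
        raise PPGFormatError(f"{path}: no data rows")
    table = np.asarray(rows, dtype=float)
    cols = {name: table[:, i] for i, name in enumerate(header)}

    chan_meta = meta.get("channels", [])
    required = ["time", "pressure", "displacement"] + [c["name"] for c in chan_meta]
    for name in required:
        if name not in cols:
            raise PPGFormatError(f"{path}: missing column {name!r}")
    channels = np.column_stack([cols[c["name"]] for c in chan_meta])
    return MultichannelPPG(
        time=cols["time"],
        channels=channels,
        wavelengths_nm=np.array([c["wavelength_nm"] for c in chan_meta], dtype=float),
        broadband=np.array([c["broadband"] for c in chan_meta], dtype=bool),
        pressure=cols["pressure"],
        displacement=cols["displacement"],
        fs_hz=float(meta.get("fs_hz", math.nan)),
    )
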