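"""Sensor-log, weather-log and annotation I/O plus stream windowing.

The raw input of the pipeline is a continuous log from a fixed e-nose:
four metal-oxide (MOX) resistances, two electrochemical channels (H2S,
NH3), one photoionization detector (PID), and onboard temperature /
relative humidity, sampled at a nominal 10 s cadence.  This module
validates those logs, slices them into fixed-duration analysis windows
(default 5 min), and maps raw source classes onto the three model
classes used downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical sensor-log column order (External interface)
SENSOR_COLUMNS = [
    "timestamp",
    "mox1_ohm",
    "mox2_ohm",
    "mox3_ohm",
    "mox4_ohm",
    "ec_h2s",
    "ec_nh3",
    "pid",
    "temp_c",
    "rh_pct",
]

MOX_COLUMNS = ["mox1_ohm", "mox2_ohm", "mox3_ohm", "mox4_ohm"]
AUX_COLUMNS = ["ec_h2s", "ec_nh3", "pid"]

WEATHER_COLUMNS = ["timestamp", "temp_c", "rh_pct", "rain_mm", "wind_ms", "wind_deg"]

ANNOTATION_COLUMNS = [
    "sample_id",
    "source_class",
    "odour_conc_oue_m3",
    "start",
    "end",
    "campaign",
    "role",
]

SOURCE_CLASSES = ("Air", "Biogas", "Biofilter", "Sheds")
MODEL_CLASSES = ("Air", "Biogas", "Organic odour")

_MERGE_MAP = {
    "Air": "Air",
    "Biogas": "Biogas",
    "Biofilter": "Organic odour",
    "Sheds": "Organic odour",
    # already-merged labels pass through
    "Organic odour": "Organic odour",
}

#: temperature sanity band, degC
TEMP_BAND = (-40.0, 60.0)


def merge_source_classes(source_class: str) -> str:
    """Map a sampling source class onto its model class.

    Biofilter and shed emissions are chemically similar organic odours and
    are merged into a single 'Organic odour' class; Air and Biogas map to
    themselves.
    """
    try:
        return _MERGE_MAP[source_class]
    except KeyError:
        raise ValueError(
            f"unknown source class {source_class!r}; expected one of {SOURCE_CLASSES}"
        ) from None


@dataclass
class SensorStream:
    """An ordered multi-channel sensor record series at fixed nominal cadence.

    ``data`` holds one row per record with the columns of
    :data:`SENSOR_COLUMNS`; ``cadence_s`` is the nominal sampling period.
    Timestamps are strictly increasing; cadence gaps are flagged (see
    :meth:`gap_mask`), never filled.
    """

    data: pd.DataFrame
    cadence_s: float = 10.0

    def __post_init__(self) -> None:
        missing = [c for c in SENSOR_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"sensor stream missing mandatory columns: {missing}")
        ts = self.data["timestamp"]
        if not pd.api.types.is_datetime64_any_dtype(ts):
            raise TypeError("timestamp column must be datetime64")
        if len(self.data) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be non-decreasing")
        if len(self.data) > 1 and ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing (duplicates found)")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.Series:
        return self.data["timestamp"]

    def gap_mask(self, tolerance: float = 1.5) -> np.ndarray:
        """Boolean mask over inter-record steps exceeding ``tolerance`` x cadence."""
        dt = self.data["timestamp"].diff().dt.total_seconds().to_numpy()[1:]
        return dt > tolerance * self.cadence_s

    def slice(self, start: pd.Timestamp, end: pd.Timestamp) -> pd.DataFrame:
        """Records with start <= timestamp < end."""
        ts = self.data["timestamp"]
        return self.data.loc[(ts >= start) & (ts < end)]


@dataclass
class AnalysisWindow:
    """A fixed-duration slice of a stream, the unit of feature extraction."""

    records: pd.DataFrame
    start: pd.Timestamp
    end: pd.Timestamp
    cadence_s: float
    min_fill: float = 0.8

    @property
    def expected_records(self) -> int:
        return int(round((self.end - self.start).total_seconds() / self.cadence_s))

    @property
    def fill_fraction(self) -> float:
        if self.expected_records == 0:
            return 0.0
        return len(self.records) / self.expected_records

    @property
    def underfilled(self) -> bool:
        return self.fill_fraction < self.min_fill


@dataclass
class TrainingSample:
    """One annotated odour presentation: a window plus its olfactometry value."""

    sample_id: str
    source_class: str
    odour_concentration: float
    start: pd.Timestamp
    end: pd.Timestamp
    campaign: str
    role: str = "train"
    model_class: str = field(init=False)

    def __post_init__(self) -> None:
        self.model_class = merge_source_classes(self.source_class)
        if self.source_class != "Air" and not self.odour_concentration > 0:
            raise ValueError(
                f"sample {self.sample_id}: non-Air class requires positive concentration"
            )
        if self.role not in ("train", "test"):
            raise ValueError(f"role must be 'train' or 'test', got {self.role!r}")


def _validate_sensor_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating physical invariants; return (clean frame, n dropped)."""
    ok = np.ones(len(df), dtype=bool)
    for c in MOX_COLUMNS:
        ok &= df[c].to_numpy() > 0
    rh = df["rh_pct"].to_numpy()
    ok &= (rh >= 0) & (rh <= 100)
    t = df["temp_c"].to_numpy()
    ok &= (t > TEMP_BAND[0]) & (t < TEMP_BAND[1])
    ok &= ~df[SENSOR_COLUMNS[1:]].isna().any(axis=1).to_numpy()
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} malformed sensor record(s)", stacklevel=3)
        logger.warning("dropped %d malformed sensor record(s)", n_dropped)
    return df.loc[ok].reset_index(drop=True), n_dropped


def read_sensor_log(
    path, cadence_s: float = 10.0, column_map: dict[str, str] | None = None
) -> SensorStream:
    """Read a sensor-log CSV into a validated :class:`SensorStream`.

    ``column_map`` renames non-canonical input headers onto
    :data:`SENSOR_COLUMNS`.  Rows violating the physical invariants
    (non-positive resistance, RH outside [0, 100], temperature outside the
    sanity band, missing values) are dropped with a counted warning.
    Non-monotone timestamps are a hard error.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sensor log {path} missing mandatory column(s): {missing}")
    df = df[SENSOR_COLUMNS].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    if len(df) > 1 and not df["timestamp"].is_monotonic_increasing:
        raise ValueError(f"sensor log {path}: timestamps are not monotone increasing")
    df, _ = _validate_sensor_frame(df)
    return SensorStream(df, cadence_s=cadence_s)


def write_sensor_log(stream: SensorStream, path) -> None:
    """Write a stream back to the canonical CSV dialect (ISO-8601 timestamps)."""
    out = stream.data.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False, float_format="%.6f")


def read_weather_log(path) -> pd.DataFrame:
    """Read a 15-min weather-station CSV (used for reporting, not compensation)."""
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather log {path} missing column(s): {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    if not df["timestamp"].is_monotonic_increasing:
        raise ValueError(f"weather log {path}: timestamps are not monotone increasing")
    return df[WEATHER_COLUMNS]


def read_annotations(path) -> list[TrainingSample]:
    """Read the training-sample annotation CSV into :class:`TrainingSample` rows."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} missing column(s): {missing}")
    samples = []
    for row in df.itertuples(index=False):
        samples.append(
            TrainingSample(
                sample_id=str(row.sample_id),
                source_class=row.source_class,
                odour_concentration=float(row.odour_conc_oue_m3),
                start=pd.to_datetime(row.start, utc=True),
                end=pd.to_datetime(row.end, utc=True),
                campaign=str(row.campaign),
                role=row.role,
            )
        )
    return samples


def write_annotations(samples: list[TrainingSample], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "source_class": s.source_class,
            "odour_conc_oue_m3": s.odour_concentration,
            "start": s.start.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "end": s.end.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "campaign": s.campaign,
            "role": s.role,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def segment_stream(
    stream: SensorStream, width_s: float = 300.0, min_fill: float = 0.8
) -> list[AnalysisWindow]:
    """Cut a stream into consecutive non-overlapping windows of ``width_s``.

    Windows are anchored at the first record (not wall-clock boundaries).
    Every record lands in exactly one window; windows holding fewer than
    ``min_fill`` of their expected records are returned flagged
    (``underfilled``) rather than silently dropped.
    """
    if width_s <= 0:
        raise ValueError("window width must be positive")
    if width_s < 2 * stream.cadence_s:
        raise ValueError(
            f"window width {width_s}s shorter than 2 cadence steps "
            f"({2 * stream.cadence_s}s)"
        )
    if len(stream) == 0:
        raise ValueError("cannot segment an empty stream")
    t0 = stream.timestamps.iloc[0]
    offsets = (stream.timestamps - t0).dt.total_seconds().to_numpy()
    idx = np.floor(offsets / width_s).astype(int)
    width = pd.Timedelta(seconds=width_s)
    windows = []
    for k in range(idx.max() + 1):
        start = t0 + k * width
        sel = stream.data.loc[idx == k]
        windows.append(
            AnalysisWindow(
                records=sel.reset_index(drop=True),
                start=start,
                end=start + width,
                cadence_s=stream.cadence_s,
                min_fill=min_fill,
            )
        )
    return windows


def window_for_sample(
    stream: SensorStream, sample: TrainingSample, min_fill: float = 0.8
) -> AnalysisWindow:
    """Extract the analysis window an annotation row points at."""
    recs = stream.slice(sample.start, sample.end)
    return AnalysisWindow(
        records=recs.reset_index(drop=True),
        start=sample.start,
        end=sample.end,
        cadence_s=stream.cadence_s,
        min_fill=min_fill,
    )
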