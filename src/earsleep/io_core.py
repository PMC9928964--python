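"""Recording and hypnogram I/O for the ear-EEG sleep pipeline.

The pipeline's signal container is :class:`RawRecording`: four data
electrodes (EL1, EL2 in the left ear; ER1, ER2 in the right ear), all
recorded against a common left-ear reference electrode, sampled at a
shared rate (250 Hz in the at-home study setup).  Signals live on disk
as EDF (European Data Format), the standard container for PSG/EEG;
hypnograms and study tables are plain CSV.

EDF reading goes through :func:`mne.io.read_raw_edf`; writing uses a
minimal EDF writer in this module (16-bit samples, fixed physical range
of +/-1000 uV, 1 s data records).
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np

logger = logging.getLogger("earsleep")

#: The four data electrodes, fixed order: left ear then right ear.
DATA_CHANNELS = ("EL1", "EL2", "ER1", "ER2")

#: The five sleep stages in the project-wide fixed order, plus the
#: bookkeeping label for epochs the pipeline could not score.
STAGES = ("W", "N1", "N2", "N3", "REM")
UNSCORED = "UNSCORED"
STAGE_ALPHABET = STAGES + (UNSCORED,)

#: Project-wide integer encoding W=0, N1=1, N2=2, N3=3, REM=4.
STAGE_TO_INT = {s: i for i, s in enumerate(STAGES)}

#: Fixed physical range used when writing EDF, comfortably covering the
#: 350 uV amplitude-rejection bound.
EDF_PHYS_RANGE_UV = 1000.0

EPOCH_LEN_S = 30.0


class IOError_(RuntimeError):
    """Labelled I/O failure (missing channel, malformed hypnogram, ...)."""


@dataclass
class RawRecording:
    """A multi-channel ear-EEG recording in microvolts.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (study value: 250).
    channels : dict[str, np.ndarray]
        Ordered map label -> sample vector in uV for exactly the four
        data electrodes ``EL1, EL2, ER1, ER2``.
    meta : dict
        Free-form metadata: ``subject``, ``equipment`` ("custom" or
        "generic"), ``part`` ("A" or "B"), ``night``, ``start_time``.
    """

    fs: float
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if tuple(self.channels) != DATA_CHANNELS:
            raise ValueError(
                f"channels must be exactly {DATA_CHANNELS}, got {tuple(self.channels)}"
            )
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"channel lengths differ: {sorted(lengths)}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def n_epochs(self) -> int:
        """Number of complete 30 s epochs; a trailing partial epoch is dropped."""
        return int(self.n_samples // round(EPOCH_LEN_S * self.fs))

    def as_array(self) -> np.ndarray:
        """(4, n_samples) array in DATA_CHANNELS order."""
        return np.stack([self.channels[c] for c in DATA_CHANNELS])

    def epoch(self, i: int) -> np.ndarray:
        """Samples of epoch ``i`` as a (4, 30*fs) array, half-open window."""
        spe = int(round(EPOCH_LEN_S * self.fs))
        if not 0 <= i < self.n_epochs:
            raise IndexError(f"epoch {i} out of range [0, {self.n_epochs})")
        return self.as_array()[:, i * spe : (i + 1) * spe]

    def copy(self) -> "RawRecording":
        return replace(
            self,
            channels={k: v.copy() for k, v in self.channels.items()},
            meta=dict(self.meta),
        )


@dataclass
class Hypnogram:
    """Sleep-stage labels, one per 30 s epoch.

    ``labels`` is a sequence over W/N1/N2/N3/REM plus UNSCORED for
    epochs rejected by artifact handling.
    """

    labels: tuple[str, ...]
    epoch_len: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        bad = [l for l in self.labels if l not in STAGE_ALPHABET]
        if bad:
            raise ValueError(f"unknown stage label(s): {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    def scored(self) -> np.ndarray:
        """Boolean mask of epochs carrying a real stage (not UNSCORED)."""
        return np.array([l != UNSCORED for l in self.labels])

    def to_int(self) -> np.ndarray:
        """Integer codes W=0..REM=4; UNSCORED becomes -1."""
        return np.array([STAGE_TO_INT.get(l, -1) for l in self.labels])


# ---------------------------------------------------------------------------
# EDF writing (minimal writer: 1 s records, 16-bit, fixed physical range)
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording(rec: RawRecording, path) -> Path:
    """Write a :class:`RawRecording` to an EDF file.

    Samples are quantized to 16 bits over a fixed +/-1000 uV physical
    range; values outside that range are clipped.  Data records are 1 s
    long, so a trailing partial second is dropped (with a warning).
    Subject/equipment/part/night metadata are stored in the EDF
    recording-id header field as ``key=value`` pairs.
    """
    path = Path(path)
    fs_int = int(round(rec.fs))
    if abs(rec.fs - fs_int) > 1e-9:
        raise IOError_(f"EDF writer requires an integer sampling rate, got {rec.fs}")
    n_records = rec.n_samples // fs_int
    if n_records == 0:
        raise IOError_("recording shorter than one EDF data record (1 s); refusing to write")
    if n_records * fs_int < rec.n_samples:
        logger.warning(
            "write_recording: dropping trailing partial second (%d samples)",
            rec.n_samples - n_records * fs_int,
        )

    start = rec.meta.get("start_time") or _dt.datetime(2000, 1, 1, 23, 0, 0)
    rec_id_parts = [
        f"{k}={rec.meta[k]}" for k in ("subject", "equipment", "part", "night") if k in rec.meta
    ]
    rec_id = " ".join(rec_id_parts) if rec_id_parts else "earsleep"

    ns = len(DATA_CHANNELS)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(str(rec.meta.get("subject", "X")), 80),
            _edf_field(rec_id, 80),
            _edf_field(start.strftime("%d.%m.%y"), 8),
            _edf_field(start.strftime("%H.%M.%S"), 8),
            _edf_field(str(256 * (ns + 1)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),  # record duration, seconds
            _edf_field(str(ns), 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_edf_field(c, 16) for c in DATA_CHANNELS),
            b"".join(_edf_field("AgAgCl electrode", 80) for _ in DATA_CHANNELS),
            b"".join(_edf_field("uV", 8) for _ in DATA_CHANNELS),
            b"".join(_edf_field(f"{-EDF_PHYS_RANGE_UV:.0f}", 8) for _ in DATA_CHANNELS),
            b"".join(_edf_field(f"{EDF_PHYS_RANGE_UV:.0f}", 8) for _ in DATA_CHANNELS),
            b"".join(_edf_field("-32768", 8) for _ in DATA_CHANNELS),
            b"".join(_edf_field("32767", 8) for _ in DATA_CHANNELS),
            b"".join(_edf_field("", 80) for _ in DATA_CHANNELS),
            b"".join(_edf_field(str(fs_int), 8) for _ in DATA_CHANNELS),
            b"".join(_edf_field("", 32) for _ in DATA_CHANNELS),
        ]
    )

    # EDF decode convention: physical = (digital - dmin) * gain + pmin,
    # gain = (pmax - pmin) / (dmax - dmin); encode with its exact inverse
    gain = 2 * EDF_PHYS_RANGE_UV / 65535.0
    data = rec.as_array()[:, : n_records * fs_int]
    digital = np.clip(
        np.round((data + EDF_PHYS_RANGE_UV) / gain) - 32768, -32768, 32767
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        for r in range(n_records):
            block = digital[:, r * fs_int : (r + 1) * fs_int]
            fh.write(block.tobytes())  # signal-major within record, EDF layout
    return path


def read_recording(path) -> RawRecording:
    """Read an EDF file into a :class:`RawRecording` (uV units).

    Channel labels are matched case-insensitively to EL1/EL2/ER1/ER2;
    extra channels (triggers etc.) are ignored with a warning.  Missing
    data channels or mixed sampling rates raise :class:`IOError_`.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such file: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    by_upper = {name.upper(): name for name in raw.ch_names}
    missing = [c for c in DATA_CHANNELS if c.upper() not in by_upper]
    if missing:
        raise IOError_(f"EDF {path.name} is missing data channel(s): {', '.join(missing)}")
    extra = [n for n in raw.ch_names if n.upper() not in {c.upper() for c in DATA_CHANNELS}]
    if extra:
        logger.warning("read_recording: ignoring extra channel(s) %s in %s", extra, path.name)

    picks = [by_upper[c.upper()] for c in DATA_CHANNELS]
    data = raw.get_data(picks=picks) * 1e6  # mne returns volts
    channels = {c: data[i] for i, c in enumerate(DATA_CHANNELS)}

    meta: dict = {}
    rec_id = _read_edf_recording_id(path)
    for token in rec_id.split():
        if "=" in token:
            k, _, v = token.partition("=")
            meta[k] = v
    if "night" in meta:
        try:
            meta["night"] = int(meta["night"])
        except ValueError:
            pass
    return RawRecording(fs=float(raw.info["sfreq"]), channels=channels, meta=meta)


def _read_edf_recording_id(path: Path) -> str:
    with open(path, "rb") as fh:
        fh.seek(8 + 80)
        return fh.read(80).decode("ascii", errors="replace").strip()


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

def write_hypnogram(h: Hypnogram, path) -> Path:
    """Write a hypnogram as CSV with header ``epoch,stage`` (0-based epochs).

    The epoch length is recorded in a leading ``# epoch_len_s=`` comment.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# epoch_len_s={h.epoch_len:g}\n")
        w = csv.writer(fh)
        w.writerow(["epoch", "stage"])
        for i, s in enumerate(h.labels):
            w.writerow([i, s])
    return path


def read_hypnogram(path) -> Hypnogram:
    """Read a hypnogram CSV written by :func:`write_hypnogram`.

    Unknown stage symbols raise :class:`IOError_` naming the row.
    The epoch length defaults to 30 s when the header comment is absent.
    """
    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such file: {path}")
    epoch_len = EPOCH_LEN_S
    labels: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "epoch_len_s=" in first:
                epoch_len = float(first.split("epoch_len_s=")[1])
            header_line = fh.readline()
        else:
            header_line = first
        cols = [c.strip() for c in header_line.strip().split(",")]
        if "stage" not in cols:
            raise IOError_(f"{path.name}: missing 'stage' column")
        stage_idx = cols.index("stage")
        for row_no, line in enumerate(fh):
            if not line.strip():
                continue
            fields = [c.strip() for c in line.strip().split(",")]
            stage = fields[stage_idx]
            if stage not in STAGE_ALPHABET:
                raise IOError_(f"{path.name}: unknown stage '{stage}' at row {row_no}")
            labels.append(stage)
    return Hypnogram(labels=tuple(labels), epoch_len=epoch_len)


# ---------------------------------------------------------------------------
# Study table
# ---------------------------------------------------------------------------

STUDY_KEY_COLUMNS = ["subject", "equipment", "part", "recording"]


def write_study_table(df, path) -> Path:
    """Write a study table (one row per recording-night) to CSV."""
    import pandas as pd  # noqa: F401

    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_study_table(path):
    """Read a study table CSV; validates key columns and uniqueness."""
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in STUDY_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path.name}: missing column(s) {missing}")
    if df.duplicated(subset=["subject", "recording"]).any():
        raise IOError_(f"{path.name}: duplicate (subject, recording) pairs")
    return df
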