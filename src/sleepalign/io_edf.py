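"""Reading and writing polysomnography recordings and hypnograms.

EDF/EDF+ recordings are read through :mod:`mne`; the single selected EEG
channel (nominally Fpz-Cz) is returned in microvolts and resampled to the
canonical 100 Hz rate all downstream window sizes assume.  Hypnograms are
accepted either as an EDF+ annotation track or as a two-column CSV
(``epoch_index,stage``), and expanded to one stage outcome per 30-s epoch.

A minimal standard-conformant 16-bit EDF writer is included so the synthetic
generator can emit real files; it writes one signal with 1-s data records.
"""

from __future__ import annotations

import csv
import datetime
import enum
import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

TARGET_RATE_HZ = 100.0
EPOCH_S = 30.0
SAMPLES_PER_EPOCH = 3000


class StageLabel(enum.IntEnum):
    """Five-class AASM sleep stage with fixed integer codes."""

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4


class _DropType:
    """Sentinel for movement / unscored epochs excluded from the dataset."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "DROP"


DROP = _DropType()

# Sleep-EDF annotation dialect plus the bare tokens used by the CSV format.
# The old Sleep-EDF "3"/"4" (Rechtschaffen & Kales S3/S4) both merge into N3
# under the AASM standard.
STAGE_TOKEN_MAP: dict[str, StageLabel | _DropType] = {
    "Sleep stage W": StageLabel.W,
    "Sleep stage 1": StageLabel.N1,
    "Sleep stage 2": StageLabel.N2,
    "Sleep stage 3": StageLabel.N3,
    "Sleep stage 4": StageLabel.N3,
    "Sleep stage R": StageLabel.REM,
    "Sleep stage ?": DROP,
    "Movement time": DROP,
    "W": StageLabel.W,
    "1": StageLabel.N1,
    "2": StageLabel.N2,
    "3": StageLabel.N3,
    "4": StageLabel.N3,
    "R": StageLabel.REM,
    "N1": StageLabel.N1,
    "N2": StageLabel.N2,
    "N3": StageLabel.N3,
    "REM": StageLabel.REM,
    "M": DROP,
    "?": DROP,
}


class ChannelNotFoundError(KeyError):
    pass


class UnknownStageTokenError(ValueError):
    pass


class HypnogramGapError(ValueError):
    pass


@dataclass
class RawRecording:
    """A single-channel recording in microvolts at a known sampling rate."""

    samples: np.ndarray
    sampling_rate: float
    channel_name: str
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size == 0:
            raise ValueError("recording contains no samples")
        if self.start_time < 0:
            raise ValueError("start_time must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def n_epochs(self) -> int:
        return int(self.samples.size // (EPOCH_S * self.sampling_rate))


@dataclass
class HypnogramAnnotation:
    """One scored interval of the hypnogram in source-dialect tokens."""

    onset_s: float
    duration_s: float
    raw_stage: str

    def __post_init__(self):
        if self.onset_s < 0:
            raise ValueError("onset_s must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def map_stage_token(token: str) -> StageLabel | _DropType:
    """Map a source-dialect stage token to a StageLabel or DROP."""
    try:
        return STAGE_TOKEN_MAP[token.strip()]
    except KeyError:
        raise UnknownStageTokenError(
            f"unknown stage token {token!r}; known tokens: "
            f"{sorted(STAGE_TOKEN_MAP)}"
        ) from None


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def load_recording(path, channel: str) -> RawRecording:
    """Load one EEG channel from an EDF/EDF+ file, resampled to 100 Hz.

    Raises FileNotFoundError if the path does not exist and
    ChannelNotFoundError (listing the available channels) if the requested
    channel is absent.  Resampling uses polyphase filtering, which preserves
    band content below the new Nyquist frequency.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    except Exception as exc:
        raise OSError(f"cannot parse EDF file {path}: {exc}") from exc
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {path.name}; available: {raw.ch_names}"
        )
    raw.load_data(verbose="error")
    data_volts = raw.get_data(picks=[channel])[0]
    samples = data_volts * 1e6  # mne returns SI volts; we work in microvolts
    rate = float(raw.info["sfreq"])
    if rate != TARGET_RATE_HZ:
        frac = Fraction(TARGET_RATE_HZ / rate).limit_denominator(10000)
        samples = resample_poly(samples, frac.numerator, frac.denominator)
        rate = TARGET_RATE_HZ
    return RawRecording(samples=samples, sampling_rate=rate, channel_name=channel)


def write_edf(path, recording: RawRecording, *, patient_id: str = "X",
              recording_id: str = "synthetic") -> None:
    """Write a single-signal 16-bit EDF file with 1-s data records.

    The sampling rate must be a positive integer (it is the per-record sample
    count).  A trailing partial record is truncated with a warning.
    """
    rate = recording.sampling_rate
    if rate != int(rate) or rate <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(rate)
    samples = recording.samples
    n_records = samples.size // spr
    if n_records == 0:
        raise ValueError("recording shorter than one data record")
    if samples.size % spr:
        logger.warning("truncating %d trailing samples (partial EDF record)",
                       samples.size % spr)
        samples = samples[:n_records * spr]

    phys_max = float(np.max(np.abs(samples)))
    phys_max = max(phys_max * 1.0001, 1.0)
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((samples - phys_min) * scale + dig_min).astype("<i2")

    def f(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    start = datetime.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join([
        f("0", 8),
        f(patient_id, 80),
        f(recording_id, 80),
        f(start.strftime("%d.%m.%y"), 8),
        f(start.strftime("%H.%M.%S"), 8),
        f(256 * 2, 8),            # header bytes: fixed + one signal block
        f("", 44),
        f(n_records, 8),
        f(1, 8),                  # record duration, seconds
        f(1, 4),                  # number of signals
    ])
    signal_header = b"".join([
        f(recording.channel_name, 16),
        f("", 80),                # transducer
        f("uV", 8),
        f(f"{phys_min:.6g}"[:8], 8),
        f(f"{phys_max:.6g}"[:8], 8),
        f(dig_min, 8),
        f(dig_max, 8),
        f("", 80),                # prefiltering
        f(spr, 8),
        f("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        fh.write(digital.tobytes())


# ---------------------------------------------------------------------------
# hypnogram I/O and expansion
# ---------------------------------------------------------------------------

def read_hypnogram(path) -> list[HypnogramAnnotation]:
    """Read a hypnogram from an EDF+ annotation track or the CSV dialect.

    The CSV dialect is ``epoch_index,stage`` with a header row, one row per
    30-s epoch; consecutive epochs with the same token are merged into one
    annotation.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_hypnogram_csv(path)
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ann = mne.read_annotations(path)
    out = [HypnogramAnnotation(float(o), float(d), str(s))
           for o, d, s in zip(ann.onset, ann.duration, ann.description)]
    _check_sorted_nonoverlapping(out)
    return out


def _read_hypnogram_csv(path: Path) -> list[HypnogramAnnotation]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows or "epoch_index" not in rows[0] or "stage" not in rows[0]:
        raise ValueError(f"{path}: expected CSV header 'epoch_index,stage'")
    tokens: dict[int, str] = {}
    for row in rows:
        tokens[int(row["epoch_index"])] = row["stage"].strip()
    n = max(tokens) + 1
    missing = [i for i in range(n) if i not in tokens]
    if missing:
        raise HypnogramGapError(f"{path}: missing epoch indices {missing[:10]}")
    # merge runs of identical tokens
    out: list[HypnogramAnnotation] = []
    run_start, run_token = 0, tokens[0]
    for i in range(1, n + 1):
        if i == n or tokens[i] != run_token:
            out.append(HypnogramAnnotation(run_start * EPOCH_S,
                                           (i - run_start) * EPOCH_S, run_token))
            if i < n:
                run_start, run_token = i, tokens[i]
    return out


def write_hypnogram_csv(path, labels) -> None:
    """Write per-epoch stage tokens as the two-column CSV dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch_index", "stage"])
        for i, lab in enumerate(labels):
            token = lab.name if isinstance(lab, StageLabel) else str(lab)
            writer.writerow([i, token])


def _check_sorted_nonoverlapping(annotations: list[HypnogramAnnotation]) -> None:
    for a, b in zip(annotations, annotations[1:]):
        if b.onset_s < a.onset_s:
            raise ValueError("annotations not sorted by onset")
        if b.onset_s < a.onset_s + a.duration_s - 1e-9:
            raise ValueError(
                f"overlapping annotations at {b.onset_s:.1f} s"
            )


def expand_hypnogram(annotations: list[HypnogramAnnotation],
                     epoch_s: float = EPOCH_S,
                     total_epochs: int | None = None
                     ) -> list[StageLabel | _DropType]:
    """Expand scored intervals into one outcome per epoch.

    Each annotation of duration D contributes floor(D / epoch_s) consecutive
    labels; a trailing partial epoch is truncated with a warning.  Gaps
    between annotations and unknown tokens are errors.  ``total_epochs``
    defaults to the coverage of the annotations; if larger than the coverage,
    the shortfall is a gap error.
    """
    if not annotations:
        raise ValueError("empty hypnogram")
    _check_sorted_nonoverlapping(annotations)
    origin = annotations[0].onset_s
    outcomes: list[StageLabel | _DropType] = []
    cursor = origin
    for ann in annotations:
        if ann.onset_s > cursor + 1e-9:
            raise HypnogramGapError(
                f"hypnogram gap between {cursor:.1f} s and {ann.onset_s:.1f} s"
            )
        label = map_stage_token(ann.raw_stage)
        n_full = int(ann.duration_s // epoch_s)
        if ann.duration_s % epoch_s > 1e-9:
            logger.warning("truncating trailing partial epoch in annotation at "
                           "%.1f s", ann.onset_s)
        outcomes.extend([label] * n_full)
        cursor = ann.onset_s + ann.duration_s
    if total_epochs is None:
        total_epochs = len(outcomes)
    if len(outcomes) < total_epochs:
        raise HypnogramGapError(
            f"hypnogram covers {len(outcomes)} epochs but {total_epochs} requested "
            f"(gap after {origin + len(outcomes) * epoch_s:.1f} s)"
        )
    return outcomes[:total_epochs]
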