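"""Signal conditioning: median-filter baseline correction, epoching, trimming.

The running median over a short temporal neighbourhood tracks slow baseline
drift (electrode wander, movement) while being insensitive to the oscillatory
EEG content riding on it; subtracting that estimate calibrates the baseline
without distorting the waveform the encoder consumes.  After correction the
signal is cut into 30-s epochs, unscored epochs are dropped, wake far from
the sleep period is trimmed away, and each epoch is z-scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .io_edf import (DROP, SAMPLES_PER_EPOCH, RawRecording, StageLabel,
                     _DropType)

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


class NoSleepError(ValueError):
    pass


@dataclass
class SignalEpoch:
    """One 30-s EEG window (3000 samples at 100 Hz) with its stage label."""

    samples: np.ndarray
    label: StageLabel
    source_epoch_index: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape != (SAMPLES_PER_EPOCH,):
            raise ValueError(
                f"epoch must have {SAMPLES_PER_EPOCH} samples, got {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch contains non-finite samples")


@dataclass
class EpochDataset:
    """Model-ready collection of labelled epochs."""

    epochs: list[SignalEpoch]

    @property
    def stage_counts(self) -> dict[StageLabel, int]:
        counts = {s: 0 for s in StageLabel}
        for ep in self.epochs:
            counts[ep.label] += 1
        return counts

    def signals(self) -> np.ndarray:
        """(n, 3000) array of all epoch signals."""
        return np.stack([ep.samples for ep in self.epochs])

    def labels(self) -> np.ndarray:
        """(n,) array of integer stage codes."""
        return np.array([int(ep.label) for ep in self.epochs])

    def __len__(self):
        return len(self.epochs)

    def subset(self, indices) -> "EpochDataset":
        return EpochDataset([self.epochs[i] for i in indices])


@dataclass
class PreprocessConfig:
    median_window_s: float = 1.0
    wake_margin_epochs: int = 60
    normalize_epochs: bool = True


def median_baseline_correct(signal: np.ndarray, window_s: float = 1.0,
                            sampling_rate: float = 100.0) -> np.ndarray:
    """Subtract the centred running-median baseline from a signal.

    The window (window_s * sampling_rate samples, rounded) must be odd and
    at least 3; edges are handled by reflection.  Subtracting the median
    baseline removes constant offsets exactly and slow drift almost entirely
    while leaving rhythms faster than ~1/window_s largely untouched.
    """
    signal = np.asarray(signal, dtype=np.float64)
    window = int(round(window_s * sampling_rate))
    if window % 2 == 0:
        # a centered window needs an odd sample count; snap up (1.0 s at
        # 100 Hz becomes 101 samples = 1.01 s)
        window += 1
    if window < 3:
        raise ParameterError(
            f"median window must span at least 3 samples, got {window}"
        )
    if signal.size < window:
        raise ParameterError("signal shorter than the median window")
    baseline = median_filter(signal, size=window, mode="reflect")
    return signal - baseline


def trim_peripheral_wake(labels, margin_epochs: int = 60) -> tuple[int, int]:
    """Index range (inclusive) keeping sleep plus a flanking wake margin.

    Returns ``(first, last)`` where ``first = first_sleep - margin`` and
    ``last = last_sleep + margin``, clipped to the valid index range.  Raises
    NoSleepError when no non-wake epoch exists.
    """
    codes = np.array([int(l) for l in labels])
    sleep = np.nonzero(codes != int(StageLabel.W))[0]
    if sleep.size == 0:
        raise NoSleepError("no sleep present: all epochs are wake")
    first = max(int(sleep[0]) - margin_epochs, 0)
    last = min(int(sleep[-1]) + margin_epochs, len(codes) - 1)
    return first, last


def build_dataset(recording: RawRecording, labels,
                  config: PreprocessConfig | None = None) -> EpochDataset:
    """Condition a recording and its per-epoch outcomes into an EpochDataset.

    Applies baseline correction to the full signal, slices 30-s epochs,
    drops DROP outcomes, trims peripheral wake, and (by default) z-scores
    each epoch (constant epochs are left at zero).
    """
    config = config or PreprocessConfig()
    n_epochs = recording.samples.size // SAMPLES_PER_EPOCH
    labels = list(labels)
    if len(labels) != n_epochs:
        raise ValueError(
            f"label list length {len(labels)} != epoch count {n_epochs}"
        )
    corrected = median_baseline_correct(
        recording.samples, config.median_window_s, recording.sampling_rate
    )
    kept: list[tuple[int, StageLabel, np.ndarray]] = []
    for i, lab in enumerate(labels):
        if isinstance(lab, _DropType) or lab is DROP:
            continue
        lab = StageLabel(lab)
        kept.append((i, lab, corrected[i * SAMPLES_PER_EPOCH:(i + 1) * SAMPLES_PER_EPOCH]))
    if not kept:
        raise ValueError("all epochs dropped; nothing to build")
    first, last = trim_peripheral_wake([lab for _, lab, _ in kept],
                                       config.wake_margin_epochs)
    kept = kept[first:last + 1]
    epochs = []
    for src, lab, sig in kept:
        if config.normalize_epochs:
            mu = sig.mean()
            sd = sig.std()
            sig = (sig - mu) / sd if sd > 0 else np.zeros_like(sig)
        epochs.append(SignalEpoch(samples=sig, label=lab, source_epoch_index=src))
    return EpochDataset(epochs)


# ---------------------------------------------------------------------------
# serialization — versioned npz container: columnar labels + raw sample array
# ---------------------------------------------------------------------------

_DATASET_FORMAT_VERSION = 1


def save_epoch_dataset(path, dataset: EpochDataset) -> None:
    np.savez(
        path,
        format_version=_DATASET_FORMAT_VERSION,
        samples=dataset.signals(),
        stage_code=dataset.labels(),
        source_epoch_index=np.array([ep.source_epoch_index for ep in dataset.epochs]),
    )


def load_epoch_dataset(path) -> EpochDataset:
    with np.load(path) as z:
        if int(z["format_version"]) != _DATASET_FORMAT_VERSION:
            raise ValueError(f"unsupported dataset format version {z['format_version']}")
        epochs = [
            SignalEpoch(samples=s, label=StageLabel(int(c)), source_epoch_index=int(i))
            for s, c, i in zip(z["samples"], z["stage_code"], z["source_epoch_index"])
        ]
    return EpochDataset(epochs)
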