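"""Synthetic stage-labelled EEG with the spectral structure of real sleep.

Each stage is generated as a sum of narrow-band oscillators (a few random
frequencies per band, random phases) plus broadband Gaussian noise, with the
stage-characteristic dominant band: relaxed wake is alpha-dominant (8-13 Hz),
N1 theta-dominant (4-8 Hz), N2 theta with amplitude-modulated 12-14 Hz
spindle packets, N3 high-amplitude delta (0.5-4 Hz), and REM low-amplitude
mixed theta with a 2-3 Hz sawtooth component.  A slow sinusoid plus linear
ramp emulates baseline drift so the median-filter calibration has something
to remove.  This is a statistical emulator of stage-dependent band power,
not a physiological EEG model; its purpose is to make the full pipeline
testable and its stages separable by spectral content alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import sawtooth as _sawtooth

from .io_edf import (EPOCH_S, SAMPLES_PER_EPOCH, TARGET_RATE_HZ,
                     HypnogramAnnotation, RawRecording, StageLabel,
                     write_edf, write_hypnogram_csv)
from .preprocess import SignalEpoch

DEFAULT_CHANNEL = "EEG Fpz-Cz"


@dataclass
class StageSpectrum:
    """Band-power parameterization of one stage.

    band_components: (low Hz, high Hz, relative amplitude) triples; the
    component signals are unit-variance before weighting, so relative
    amplitudes compare directly.  amplitude_scale sets the overall microvolt
    scale; broadband_noise_sd is additive white noise in microvolts.
    """

    stage: StageLabel
    band_components: list[tuple[float, float, float]]
    broadband_noise_sd: float
    amplitude_scale: float
    spindles: bool = False
    sawtooth: bool = False

    def __post_init__(self):
        for lo, hi, amp in self.band_components:
            if not (0 < lo < hi < TARGET_RATE_HZ / 2):
                raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist)")
            if amp <= 0:
                raise ValueError("band amplitudes must be positive")

    @property
    def dominant_band(self) -> tuple[float, float]:
        lo, hi, _ = max(self.band_components, key=lambda b: b[2])
        return (lo, hi)


def default_stage_spectra() -> dict[StageLabel, StageSpectrum]:
    """The five stage parameterizations with distinct dominant bands.

    Amplitudes follow the usual clinical picture: deep sleep (N3) shows
    large slow waves, REM is low-amplitude and desynchronized.
    """
    return {
        StageLabel.W: StageSpectrum(
            StageLabel.W, [(8.0, 13.0, 1.0), (18.0, 30.0, 0.35)],
            broadband_noise_sd=8.0, amplitude_scale=30.0),
        StageLabel.N1: StageSpectrum(
            StageLabel.N1, [(4.0, 8.0, 1.0), (8.0, 13.0, 0.3)],
            broadband_noise_sd=8.0, amplitude_scale=35.0),
        StageLabel.N2: StageSpectrum(
            StageLabel.N2, [(4.0, 8.0, 0.8), (12.0, 14.0, 1.0)],
            broadband_noise_sd=8.0, amplitude_scale=45.0, spindles=True),
        StageLabel.N3: StageSpectrum(
            StageLabel.N3, [(0.5, 4.0, 1.0), (4.0, 8.0, 0.25)],
            broadband_noise_sd=10.0, amplitude_scale=80.0),
        StageLabel.REM: StageSpectrum(
            StageLabel.REM, [(4.0, 8.0, 0.9), (2.0, 3.0, 1.0)],
            broadband_noise_sd=8.0, amplitude_scale=25.0, sawtooth=True),
    }


@dataclass
class SimConfig:
    n_epochs_per_stage: int = 20
    seed: int = 0
    drift_amplitude: float = 100.0       # microvolts
    drift_period_s: float = 50.0         # 0.02 Hz
    stage_sequence: list[StageLabel] | None = None


def _band_oscillator(lo: float, hi: float, t: np.ndarray,
                     rng: np.random.Generator, n_components: int = 3) -> np.ndarray:
    """Unit-variance sum of sinusoids at random frequencies within the band."""
    freqs = rng.uniform(lo, hi, n_components)
    phases = rng.uniform(0, 2 * np.pi, n_components)
    sig = np.sum([np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs, phases)],
                 axis=0)
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def generate_epoch(stage: StageLabel, spectra: dict[StageLabel, StageSpectrum],
                   rng: np.random.Generator) -> SignalEpoch:
    """One 30-s labelled epoch drawn from the stage's spectral recipe."""
    spec = spectra[StageLabel(stage)]
    t = np.arange(SAMPLES_PER_EPOCH) / TARGET_RATE_HZ
    signal = np.zeros(SAMPLES_PER_EPOCH)
    for lo, hi, amp in spec.band_components:
        comp = _band_oscillator(lo, hi, t, rng)
        if spec.spindles and lo >= 11.0:
            comp = comp * _spindle_envelope(t, rng)
        if spec.sawtooth and hi <= 3.5:
            f = rng.uniform(lo, hi)
            comp = _sawtooth(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            comp = comp / comp.std()
        signal += amp * comp
    signal = spec.amplitude_scale * signal / max(
        sum(a for _, _, a in spec.band_components), 1.0)
    signal += spec.broadband_noise_sd * rng.standard_normal(SAMPLES_PER_EPOCH)
    return SignalEpoch(samples=signal, label=StageLabel(stage),
                       source_epoch_index=0)


def _spindle_envelope(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Amplitude modulation: 0.5-1 s Gaussian packets, ~8 per 30 s epoch."""
    env = np.full_like(t, 0.15)      # faint background so variance is nonzero
    n_packets = rng.integers(6, 11)
    for _ in range(n_packets):
        center = rng.uniform(0, t[-1])
        width = rng.uniform(0.25, 0.5)   # Gaussian sigma -> ~0.5-1 s packets
        env += np.exp(-0.5 * ((t - center) / width) ** 2)
    return env / max(env.std(), 1e-9)


def generate_recording(config: SimConfig,
                       spectra: dict[StageLabel, StageSpectrum] | None = None,
                       out_dir=None
                       ) -> tuple[RawRecording, list[HypnogramAnnotation]]:
    """Concatenate labelled epochs into a drifting recording plus hypnogram.

    The stage sequence is either explicit or a seeded shuffle of
    n_epochs_per_stage copies of each stage.  When ``out_dir`` is given, the
    recording is written as EDF plus a hypnogram CSV and a manifest.
    """
    spectra = spectra or default_stage_spectra()
    rng = np.random.default_rng(config.seed)
    if config.stage_sequence is not None:
        sequence = [StageLabel(s) for s in config.stage_sequence]
    else:
        if config.n_epochs_per_stage < 1:
            raise ValueError("n_epochs_per_stage must be >= 1")
        sequence = [s for s in StageLabel for _ in range(config.n_epochs_per_stage)]
        rng.shuffle(sequence)
    if not sequence:
        raise ValueError("empty stage sequence")

    epochs = [generate_epoch(s, spectra, rng) for s in sequence]
    samples = np.concatenate([ep.samples for ep in epochs])
    if config.drift_amplitude > 0:
        t = np.arange(samples.size) / TARGET_RATE_HZ
        phase = rng.uniform(0, 2 * np.pi)
        drift = config.drift_amplitude * np.sin(
            2 * np.pi * t / config.drift_period_s + phase)
        drift += 0.5 * config.drift_amplitude * t / t[-1]   # slow linear wander
        samples = samples + drift

    recording = RawRecording(samples=samples, sampling_rate=TARGET_RATE_HZ,
                             channel_name=DEFAULT_CHANNEL)
    annotations = _sequence_to_annotations(sequence)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_edf(out_dir / "recording.edf", recording)
        write_hypnogram_csv(out_dir / "hypnogram.csv", sequence)
        manifest = {
            "seed": config.seed,
            "n_epochs_per_stage": config.n_epochs_per_stage,
            "drift_amplitude": config.drift_amplitude,
            "drift_period_s": config.drift_period_s,
            "n_epochs": len(sequence),
            "channel": DEFAULT_CHANNEL,
        }
        import json

        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return recording, annotations


def _sequence_to_annotations(sequence: list[StageLabel]) -> list[HypnogramAnnotation]:
    """Merge consecutive identical stages into Sleep-EDF dialect annotations."""
    tokens = {StageLabel.W: "Sleep stage W", StageLabel.N1: "Sleep stage 1",
              StageLabel.N2: "Sleep stage 2", StageLabel.N3: "Sleep stage 3",
              StageLabel.REM: "Sleep stage R"}
    out: list[HypnogramAnnotation] = []
    run_start = 0
    for i in range(1, len(sequence) + 1):
        if i == len(sequence) or sequence[i] != sequence[run_start]:
            out.append(HypnogramAnnotation(run_start * EPOCH_S,
                                           (i - run_start) * EPOCH_S,
                                           tokens[sequence[run_start]]))
            run_start = i
    return out
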