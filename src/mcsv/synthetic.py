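"""Seeded generator of annotated multichannel EEG records.

The generator emulates the statistical structure the prediction method
assumes rather than physiologically forward-modelled EEG:

* inter-ictal background: independent per-channel 1/f-coloured noise plus
  narrowband oscillations in the standard delta/theta/alpha/beta/gamma
  bands (one component per band, random phase per channel), over a small
  white sensor-noise floor;
* pre-ictal spans (``[onset - pil_minutes*60, onset)``): gamma-band power
  multiplied by ``preictal_gamma_gain`` and short high-frequency-oscillation
  (HFO) bursts injected near 90 Hz — the high-gamma signature that precedes
  seizures;
* ictal spans: large-amplitude 4 Hz spike-wave-like activity (generated so
  labels partition the record, but excluded from classification);
* optional low-frequency blink transients and broadband muscle bursts;
* 16-bit quantisation of the final samples.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .record import EEGRecord, SeizureAnnotation, TEN_TWENTY_21

__all__ = ["SimulationConfig", "GroundTruth", "simulate_record", "inject_artifacts"]

#: Representative oscillation frequency (Hz) and default amplitude (uV) per band.
BAND_COMPONENTS = {
    "delta": 2.0,
    "theta": 6.0,
    "alpha": 10.0,
    "beta": 20.0,
    "gamma": 40.0,
}
DEFAULT_BAND_POWERS = {"delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 5.0, "gamma": 2.0}

INTERICTAL, PREICTAL, ICTAL = 0, 1, 2


@dataclass
class SimulationConfig:
    """Conditions of a simulated recording.

    ``band_powers`` are oscillation amplitudes in microvolts.  The pre-ictal
    gamma gain must exceed 1 so the planted effect is detectable.
    ``iil_pil_ratio`` is the target inter-ictal : pre-ictal duration ratio
    used by :meth:`balanced` to lay out a record.
    """

    duration: float
    seizure_onsets: list[float]
    n_channels: int = 21
    fs: float = 250.0
    pil_minutes: float = 5.0
    iil_pil_ratio: float = 15.0
    band_powers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_POWERS))
    preictal_gamma_gain: float = 4.0
    artifact_rate: float = 0.0
    quantization_bits: int = 16
    seed: int = 0
    ictal_s: float = 30.0
    noise_scale: float = 5.0
    sensor_noise: float = 0.5
    hfo_freq: float = 90.0
    hfo_burst_s: float = 0.3
    hfo_rate_hz: float = 2.0
    hfo_gain: float = 1.5
    patient_id: str = "sim"

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.preictal_gamma_gain <= 1:
            raise ValueError("preictal_gamma_gain must exceed 1")
        if self.artifact_rate < 0:
            raise ValueError("artifact rate must be >= 0")
        pil_s = self.pil_minutes * 60.0
        onsets = sorted(self.seizure_onsets)
        for t in onsets:
            if not (pil_s < t < self.duration):
                raise ValueError(
                    f"onset {t} s must lie in ({pil_s} s, {self.duration} s): "
                    "the full pre-ictal span must fit inside the record"
                )
        for a, b in zip(onsets, onsets[1:]):
            if b - pil_s < a + self.ictal_s:
                raise ValueError("overlapping pre-ictal/ictal spans")

    @property
    def pil_seconds(self) -> float:
        return self.pil_minutes * 60.0

    @classmethod
    def balanced(cls, pil_minutes: float = 5.0, iil_pil_ratio: float = 15.0, **kw) -> "SimulationConfig":
        """Single-seizure layout whose IIL : PIL durations match the ratio exactly.

        The record is ``IIL | PIL | ictal`` with the seizure at the end, so
        inter-ictal time is exactly ``iil_pil_ratio`` times pre-ictal time.
        """
        pil_s = pil_minutes * 60.0
        ictal_s = kw.pop("ictal_s", 30.0)
        onset = pil_s * (1.0 + iil_pil_ratio)
        return cls(
            duration=onset + ictal_s,
            seizure_onsets=[onset],
            pil_minutes=pil_minutes,
            iil_pil_ratio=iil_pil_ratio,
            ictal_s=ictal_s,
            **kw,
        )


@dataclass
class GroundTruth:
    """Per-sample state labels (0 inter-ictal, 1 pre-ictal, 2 ictal)."""

    labels: np.ndarray
    annotations: list[SeizureAnnotation]
    fs: float

    def state_seconds(self) -> dict[str, float]:
        n = np.bincount(self.labels, minlength=3)
        return {
            "interictal": float(n[INTERICTAL] / self.fs),
            "preictal": float(n[PREICTAL] / self.fs),
            "ictal": float(n[ICTAL] / self.fs),
        }


def _colored_noise(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """1/f-power noise normalised to the requested RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec *= 1.0 / np.sqrt(np.maximum(f, 0.5))
    x = np.fft.irfft(spec, n)
    return x * (rms / max(np.std(x), 1e-12))


def _channel_labels(n: int) -> list[str]:
    if n <= len(TEN_TWENTY_21):
        return TEN_TWENTY_21[:n]
    return TEN_TWENTY_21 + [f"EXT{i}" for i in range(n - len(TEN_TWENTY_21))]


def simulate_record(config: SimulationConfig) -> tuple[EEGRecord, GroundTruth]:
    """Generate one annotated record and its ground truth."""
    rng = np.random.default_rng(config.seed)
    fs, n = config.fs, int(round(config.duration * config.fs))
    t = np.arange(n) / fs
    n_ch = config.n_channels

    labels = np.full(n, INTERICTAL, dtype=np.int8)
    annotations = []
    pil_spans = []
    for onset in sorted(config.seizure_onsets):
        p0 = max(onset - config.pil_seconds, 0.0)
        pil_spans.append((p0, onset))
        labels[int(round(p0 * fs)) : int(round(onset * fs))] = PREICTAL
        offset = min(onset + config.ictal_s, config.duration)
        labels[int(round(onset * fs)) : int(round(offset * fs))] = ICTAL
        if offset > onset:
            annotations.append(SeizureAnnotation(onset, offset, "seiz"))

    preictal = labels == PREICTAL
    ictal = labels == ICTAL
    gamma_amp = config.band_powers.get("gamma", 0.0)
    gain = config.preictal_gamma_gain

    data = np.empty((n_ch, n))
    for c in range(n_ch):
        x = _colored_noise(rng, n, fs, config.noise_scale)
        x += config.sensor_noise * rng.standard_normal(n)
        for band, freq in BAND_COMPONENTS.items():
            amp = config.band_powers.get(band, 0.0) * rng.uniform(0.8, 1.2)
            phase = rng.uniform(0, 2 * math.pi)
            comp = amp * np.sin(2 * math.pi * freq * t + phase)
            if band == "gamma":
                comp = np.where(preictal, gain * comp, comp)
            x += comp
        # Ictal morphology: high-amplitude spike-wave around 4 Hz.
        if ictal.any():
            ph = rng.uniform(0, 2 * math.pi)
            x[ictal] += 80.0 * (
                np.sin(2 * math.pi * 4.0 * t[ictal] + ph)
                + 0.5 * np.sin(2 * math.pi * 8.0 * t[ictal] + 2 * ph)
            )
        data[c] = x

    # HFO-like bursts, shared timing across channels, within pre-ictal spans.
    burst_n = max(int(round(config.hfo_burst_s * fs)), 2)
    env = np.hanning(burst_n)
    for p0, p1 in pil_spans:
        span = p1 - p0
        n_bursts = rng.poisson(config.hfo_rate_hz * span)
        starts = rng.uniform(p0, p1 - config.hfo_burst_s, size=n_bursts)
        for t0 in starts:
            i0 = int(round(t0 * fs))
            seg_t = t[i0 : i0 + burst_n]
            for c in range(n_ch):
                ph = rng.uniform(0, 2 * math.pi)
                data[c, i0 : i0 + burst_n] += (
                    config.hfo_gain * gamma_amp * gain
                    * env[: len(seg_t)]
                    * np.sin(2 * math.pi * config.hfo_freq * seg_t + ph)
                )

    record = EEGRecord(data, fs, _channel_labels(n_ch), config.patient_id, annotations)
    if config.artifact_rate > 0:
        record = inject_artifacts(record, config.artifact_rate, seed=config.seed + 1)

    record.data = quantize(record.data, config.quantization_bits)
    truth = GroundTruth(labels, [a for a in record.annotations], fs)
    return record, truth


def quantize(data: np.ndarray, bits: int) -> np.ndarray:
    """Round samples to a ``2**bits``-step grid spanning the signal range."""
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return data.copy()
    lsb = (hi - lo) / (2**bits - 1)
    return lo + np.round((data - lo) / lsb) * lsb


def inject_artifacts(record: EEGRecord, rate: float, seed: int = 0) -> EEGRecord:
    """Additive artifacts at Poisson-distributed times (``rate`` events/hour).

    Events alternate randomly between low-frequency, high-amplitude blink
    transients on the frontal channels and short broadband muscle bursts on
    a single random channel.  The input record is not modified.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    out = record.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    fs, n = record.fs, record.n_samples
    n_events = rng.poisson(rate * record.duration / 3600.0)
    frontal = [i for i, lab in enumerate(record.channel_labels) if lab.startswith(("Fp", "F"))]
    if not frontal:
        frontal = [0]
    for _ in range(n_events):
        t0 = rng.uniform(0, record.duration)
        i0 = int(t0 * fs)
        if rng.random() < 0.5:  # blink: ~0.7 s monophasic bump, < 2 Hz content
            m = min(int(0.7 * fs), n - i0)
            if m > 2:
                wave = 120.0 * np.hanning(m)
                for c in frontal:
                    out.data[c, i0 : i0 + m] += wave
        else:  # muscle: 0.3 s broadband burst
            m = min(int(0.3 * fs), n - i0)
            if m > 2:
                c = int(rng.integers(0, record.n_channels))
                out.data[c, i0 : i0 + m] += 40.0 * rng.standard_normal(m) * np.hanning(m)
    return out
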