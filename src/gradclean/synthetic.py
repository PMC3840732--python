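"""Synthetic EEG/fMRI recordings with known ground truth.

Emulates the phenomena an artifact-correction pipeline must survive:
periodic slice-epoch artifact waveforms orders of magnitude larger than
the EEG, volume gaps between slice groups carrying a transition
transient, unsynchronised sampling (accumulating sub-sample epoch
jitter), slow artifact amplitude drift, slow baseline wander, and
artifact-free lead-in/lead-out segments.  Every generated sample is
reproducible from the seed, and the clean EEG, pure artifact, true
epoch shifts and true acquisition span are returned alongside the
recording.

The default parameters mirror a standard EPI protocol: 21 slices per
volume with a 144 ms slice period (TR an exact multiple of the slice
time, hence no volume gap), sampled at 250 Hz, with the artifact 100x
the EEG RMS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfftfreq

from .io import Event, Recording

logger = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "GroundTruth", "generate"]

N_HARMONICS = 7
EEG_BANDLIMIT_FRACTION = 0.40  # of the Nyquist frequency
EEG_LOW_CUT_HZ = 1.5  # slower activity is modelled by the baseline wander
ALPHA_FREQ_HZ = 10.0
ALPHA_RMS_FRACTION = 0.10


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic concurrent EEG/fMRI recording.

    Amplitudes are in microvolts, durations in seconds.  The artifact
    waveform repeats once per slice period; ``clock_drift`` accumulates
    a fixed sub-sample offset per epoch, emulating unsynchronised
    scanner and EEG clocks.  ``missing_trigger_indices`` lists epochs
    whose trigger event is dropped from the event list (the artifact is
    still there).
    """

    rate: float = 250.0
    n_channels: int = 4
    pre_duration: float = 10.0
    post_duration: float = 10.0
    n_v: int = 10
    n_s: int = 21
    slice_period: float = 0.144
    volume_gap: float = 0.0
    artifact_amplitude: float = 1000.0
    artifact_waveform: str = "harmonic-stack"  # or "sawtooth-burst"
    amplitude_drift: float = 0.05  # fraction per minute
    amplitude_modulation: float = 0.02  # respiratory-like, peak fraction
    amplitude_modulation_period: float = 3.7  # seconds (~0.27 Hz breathing)
    clock_drift: float = 0.02  # samples accumulated per epoch
    baseline_wander_amplitude: float = 100.0
    baseline_wander_period: float = 20.0
    eeg_amplitude: float = 10.0  # RMS of the 1/f background
    missing_trigger_indices: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        if self.rate <= 0 or self.n_channels < 1:
            raise ValueError("invalid rate or channel count")
        if self.n_v < 1 or self.n_s < 1 or self.slice_period <= 0:
            raise ValueError("inconsistent timing spec")
        if self.volume_gap < 0:
            raise ValueError("volume_gap must be >= 0")
        if self.artifact_waveform not in ("harmonic-stack", "sawtooth-burst"):
            raise ValueError(f"unknown waveform {self.artifact_waveform!r}")

    @property
    def volume_period(self) -> float:
        return self.n_s * self.slice_period + self.volume_gap

    @property
    def n_epochs(self) -> int:
        return self.n_v * self.n_s


@dataclass
class GroundTruth:
    """What the generator knows that a correction pipeline must recover."""

    clean: np.ndarray
    artifact: np.ndarray
    baseline: np.ndarray
    epoch_onsets: np.ndarray  # true (fractional) onset samples
    epoch_shifts: np.ndarray  # fractional part relative to the trigger
    acq_span: tuple = (0, 0)
    channel_gains: np.ndarray = field(default_factory=lambda: np.ones(1))


def _raw_waveform(phase: np.ndarray, kind: str) -> np.ndarray:
    # Hann-gated sine stacks: the burst vanishes (with zero slope) at every
    # slice boundary the way gradient waveforms return to zero between
    # slices, so the acquisition onset and offset are smooth
    w = np.zeros_like(phase)
    if kind == "harmonic-stack":
        # equal harmonic magnitudes: the induced voltage follows dB/dt of
        # the switched gradients, whose spike-like waveform has a flat
        # harmonic envelope; the alternating signs keep the comb flat
        # through the Hann gate below
        for k in range(1, N_HARMONICS + 1):
            w += ((-1) ** k) * np.sin(2 * np.pi * k * phase)
    else:  # sawtooth-burst: band-limited sawtooth shape, gated to a burst
        for k in range(1, N_HARMONICS + 1):
            w += ((-1) ** (k + 1)) * np.sin(2 * np.pi * k * phase) / k
    return w * 0.5 * (1.0 - np.cos(2 * np.pi * phase))


def _waveform(phase: np.ndarray, kind: str) -> np.ndarray:
    """Periodic artifact waveform on phase in cycles, unit peak.

    The gated harmonic stack is odd about mid-epoch, so peak
    normalisation puts it exactly in [-1, 1]: the within-epoch
    peak-to-peak range is 2.
    """
    dense = _raw_waveform(np.linspace(0.0, 1.0, 4096, endpoint=False), kind)
    return _raw_waveform(phase, kind) / float(np.max(np.abs(dense)))


def _one_over_f_noise(
    rng: np.random.Generator, n: int, rate: float, rms: float
) -> np.ndarray:
    """1/f-power-shaped noise, band-limited below half the interpolation
    cutoff so that resampling blocks are lossless on the EEG content."""
    f = rfftfreq(n, d=1.0 / rate)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = 1.0 / np.sqrt(f[nz])  # power ~ 1/f
    amp[f > EEG_BANDLIMIT_FRACTION * rate / 2.0] = 0.0
    amp[f < EEG_LOW_CUT_HZ] = 0.0  # slower content lives in the wander term
    spec = amp * np.exp(2j * np.pi * rng.random(f.size))
    x = irfft(spec, n=n)
    return x * (rms / np.sqrt(np.mean(x ** 2)))


def generate(spec: SyntheticSpec) -> tuple:
    """Generate ``(Recording, GroundTruth)`` for the given spec.

    The recording is exactly ``clean + artifact + baseline wander``;
    'slice' trigger events sit at the rounded true epoch onsets (minus
    any listed missing ones) and ``acq_span`` covers first slice onset
    to last slice end.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate

    pre = int(round(spec.pre_duration * rate))
    post = int(round(spec.post_duration * rate))
    sp = spec.slice_period * rate  # samples, possibly fractional
    vp = spec.volume_period * rate

    # true (fractional) epoch onsets with accumulating clock drift
    onsets = np.empty(spec.n_epochs)
    for v in range(spec.n_v):
        for s in range(spec.n_s):
            e = v * spec.n_s + s
            onsets[e] = pre + v * vp + s * sp + e * spec.clock_drift
    acq_start = pre
    acq_end = int(np.ceil(onsets[-1] + sp))
    n = acq_end + post

    t = np.arange(n) / rate
    baseline = spec.baseline_wander_amplitude * np.sin(
        2 * np.pi * t / spec.baseline_wander_period
        + 2 * np.pi * rng.random())

    # pure artifact: per-epoch evaluation of the periodic waveform
    artifact_shape = np.zeros(n)
    drift_per_sample = spec.amplitude_drift / (60.0 * rate)
    for e, on in enumerate(onsets):
        a = int(np.ceil(on))
        b = min(n, int(np.ceil(on + sp)))
        if b <= a:
            continue
        phase = (np.arange(a, b) - on) / sp
        artifact_shape[a:b] = _waveform(phase, spec.artifact_waveform)
    # volume-transition transient inside each gap
    if spec.volume_gap > 0:
        for v in range(spec.n_v - 1):
            e_last = (v + 1) * spec.n_s - 1
            g0 = int(np.ceil(onsets[e_last] + sp))
            g1 = int(np.ceil(onsets[e_last + 1]))
            if g1 > g0:
                tg = np.arange(g1 - g0) / rate
                artifact_shape[g0:g1] = (
                    1.5 * np.exp(-tg / (0.2 * spec.volume_gap))
                    * np.sin(2 * np.pi * (0.4 * rate / 2.0 *
                                          EEG_BANDLIMIT_FRACTION) * tg))
    drift_env = 1.0 + drift_per_sample * (np.arange(n) - acq_start)
    drift_env[:acq_start] = 1.0
    if spec.amplitude_modulation:
        # respiration modulates the electrode-loop geometry and with it the
        # induced artifact amplitude by a few percent
        drift_env *= 1.0 + spec.amplitude_modulation * np.sin(
            2 * np.pi * t / spec.amplitude_modulation_period
            + 2 * np.pi * rng.random())
    artifact_shape *= drift_env

    gains = 1.0 + 0.5 * (rng.random(spec.n_channels) - 0.5)
    clean = np.empty((spec.n_channels, n))
    alpha_phase = 2 * np.pi * rng.random(spec.n_channels)
    for ch in range(spec.n_channels):
        noise = _one_over_f_noise(rng, n, rate, spec.eeg_amplitude)
        alpha = (np.sqrt(2.0) * ALPHA_RMS_FRACTION * spec.eeg_amplitude
                 * np.sin(2 * np.pi * ALPHA_FREQ_HZ * t + alpha_phase[ch]))
        clean[ch] = noise + alpha
    artifact = spec.artifact_amplitude * np.outer(gains, artifact_shape)
    baseline_all = np.tile(baseline, (spec.n_channels, 1))

    data = clean + artifact + baseline_all

    trigger_lat = np.round(onsets).astype(np.int64)
    events = [
        Event("slice", int(lat))
        for e, lat in enumerate(trigger_lat)
        if e not in set(spec.missing_trigger_indices)
    ]
    rec = Recording(
        data=data,
        rate=rate,
        channel_labels=[f"Ch{c + 1}" for c in range(spec.n_channels)],
        events=events,
        acq_span=(acq_start, acq_end),
    )
    truth = GroundTruth(
        clean=clean,
        artifact=artifact,
        baseline=baseline_all,
        epoch_onsets=onsets,
        epoch_shifts=onsets - trigger_lat,
        acq_span=(acq_start, acq_end),
        channel_gains=gains,
    )
    logger.info("synthetic recording: %d ch x %d samples, %d epochs, "
                "%d events", spec.n_channels, n, spec.n_epochs, len(events))
    return rec, truth
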