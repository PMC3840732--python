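"""Quantitative indicators of artifact-correction quality.

Five indicator families, each computed per channel with summary
statistics across channels:

* **Median imaging artifact** — mean peak-to-peak range over ten
  intervals spanning the acquisition (and the same on the merged
  non-acquisition data as a baseline).
* **RMS ratios** — corrected/unimpaired (1.0 is ideal; above 1 means
  residual artifact, below 1 over-correction) and
  uncorrected/corrected (larger is better).
* **SNR of the corrected signal** — S/(D-S) with S the unimpaired power
  and D the corrected acquisition power; channels with non-positive
  noise power are excluded and counted.
* **Median residual activity** — percentage difference of band activity
  (delta 0.8-4, theta 4-8, alpha 8-12, beta 12-24 Hz) between the
  corrected acquisition and the unimpaired data, median across
  channels.
* **Power density reduction** — dB ratio corrected/original at the
  volume frequency and five slice-frequency harmonics, averaged over
  channels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, rfftfreq

from .io import Recording
from .triggers import estimate_acq_span

logger = logging.getLogger(__name__)

__all__ = [
    "EvalResult",
    "median_imaging_artifact",
    "rms_ratios",
    "snr_corrected",
    "median_residual_activity",
    "power_density_reduction",
    "evaluate",
    "render_report",
    "slice_harmonics",
]

#: interval length for the median imaging artifact, as a multiple of the
#: slice period (the published convention allows 1.10 .. 1.20)
ARTIFACT_INTERVAL_FACTOR = 1.15

#: EEG band edges in Hz (half-open bins [lo, hi))
BANDS = {
    "0.8-4.0 Hz": (0.8, 4.0),
    "4.0-8.0 Hz": (4.0, 8.0),
    "8.0-12.0 Hz": (8.0, 12.0),
    "12.0-24.0 Hz": (12.0, 24.0),
}

RESIDUAL_WINDOW_S = 3.0
N_WINDOWS = 10


@dataclass
class EvalResult:
    """All performance indicators with per-channel detail."""

    label: str = ""
    channels: list = field(default_factory=list)
    median_imaging_artifact: dict = field(default_factory=dict)
    rms_corrected_to_unimpaired: dict = field(default_factory=dict)
    rms_uncorrected_to_corrected: dict = field(default_factory=dict)
    snr_corrected: dict = field(default_factory=dict)
    median_residual_activity: dict = field(default_factory=dict)
    power_density_reduction: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "channels": self.channels,
            "median_imaging_artifact": self.median_imaging_artifact,
            "rms_corrected_to_unimpaired": self.rms_corrected_to_unimpaired,
            "rms_uncorrected_to_corrected": self.rms_uncorrected_to_corrected,
            "snr_corrected": self.snr_corrected,
            "median_residual_activity": self.median_residual_activity,
            "power_density_reduction": self.power_density_reduction,
        }


def _interval_starts(start: int, stop: int, length: int, n: int) -> np.ndarray:
    """``n`` interval start positions linearly spaced over [start, stop)."""
    if stop - start < length:
        raise ValueError("region shorter than one interval")
    last = stop - length
    if stop - start < n * length:
        logger.warning("intervals overlap: region of %d samples, %d "
                       "intervals of %d", stop - start, n, length)
    return np.unique(np.round(np.linspace(start, last, n)).astype(int))


def median_imaging_artifact(
    rec: Recording, slice_period: float, acq_span: tuple
) -> dict:
    """Peak-to-peak artifact amplitude, acquisition vs baseline."""
    a, b = acq_span
    length = int(round(ARTIFACT_INTERVAL_FACTOR * slice_period))
    starts = _interval_starts(a, b, length, N_WINDOWS)

    def mean_range(data: np.ndarray, starts: np.ndarray) -> np.ndarray:
        ranges = [
            data[:, s:s + length].max(axis=1) - data[:, s:s + length].min(axis=1)
            for s in starts
        ]
        return np.mean(ranges, axis=0)

    acq = mean_range(rec.data, starts)
    merged = np.concatenate([rec.data[:, :a], rec.data[:, b:]], axis=1)
    out = {
        "per_channel": acq.tolist(),
        "min": float(acq.min()),
        "max": float(acq.max()),
        "median": float(np.median(acq)),
    }
    if merged.shape[1] >= length:
        bstarts = _interval_starts(0, merged.shape[1], length, N_WINDOWS)
        base = mean_range(merged, bstarts)
        out["baseline"] = {
            "per_channel": base.tolist(),
            "min": float(base.min()),
            "max": float(base.max()),
            "median": float(np.median(base)),
        }
    return out


def _rms(x: np.ndarray, axis=-1) -> np.ndarray:
    x = x - x.mean(axis=axis, keepdims=True)
    return np.sqrt(np.mean(x * x, axis=axis))


def rms_ratios(
    original: np.ndarray, corrected: np.ndarray, unimpaired: np.ndarray
) -> tuple:
    """Both RMS ratio indicators on demeaned per-channel signals.

    Returns ``(corrected_to_unimpaired, uncorrected_to_corrected)``
    dicts with per-channel values and summary statistics.
    """
    r_cu = _rms(corrected) / _rms(unimpaired)
    r_uc = _rms(original) / _rms(corrected)

    def summarize(r):
        return {
            "per_channel": r.tolist(),
            "mean": float(r.mean()),
            "min": float(r.min()),
            "max": float(r.max()),
            "median": float(np.median(r)),
        }

    return summarize(r_cu), summarize(r_uc)


def snr_corrected(corrected_acq: np.ndarray, unimpaired: np.ndarray) -> dict:
    """SNR = S / (D - S) per channel; non-positive noise power excluded."""
    S = _rms(unimpaired) ** 2
    D = _rms(corrected_acq) ** 2
    noise = D - S
    snr = np.where(noise > 0, S / np.where(noise > 0, noise, 1.0), np.nan)
    valid = np.isfinite(snr)
    return {
        "per_channel": [float(v) if np.isfinite(v) else None for v in snr],
        "n_positive": int(valid.sum()),
        "n_excluded": int((~valid).sum()),
        "mean": float(np.nanmean(snr)) if valid.any() else None,
        "median": float(np.nanmedian(snr)) if valid.any() else None,
    }


def _band_activity(data: np.ndarray, rate: float) -> dict:
    """Mean spectral magnitude per EEG band of time-domain-averaged windows."""
    n_ch, n = data.shape
    wlen = int(round(RESIDUAL_WINDOW_S * rate))
    n_win = N_WINDOWS
    if n < wlen:
        raise ValueError("region shorter than one 3 s window")
    if n < n_win * wlen:
        n_win = max(1, n // wlen)
        logger.warning("region only fits %d non-overlapping 3 s windows",
                       n_win)
    starts = np.unique(np.round(np.linspace(0, n - wlen, n_win)).astype(int))
    avg = np.mean([data[:, s:s + wlen] for s in starts], axis=0)
    avg = avg - avg.mean(axis=1, keepdims=True)
    mag = np.abs(rfft(avg, axis=1))
    f = rfftfreq(wlen, d=1.0 / rate)
    out = {}
    for name, (lo, hi) in BANDS.items():
        sel = (f >= lo) & (f < hi)
        out[name] = mag[:, sel].mean(axis=1)
    return out


def median_residual_activity(
    corrected_acq: np.ndarray, unimpaired: np.ndarray, rate: float
) -> dict:
    """Median percentage band-activity difference, acquisition vs baseline."""
    a_corr = _band_activity(corrected_acq, rate)
    a_ni = _band_activity(unimpaired, rate)
    out = {}
    for band in BANDS:
        pd = 100.0 * np.abs(a_corr[band] - a_ni[band]) / a_ni[band]
        out[band] = {
            "per_channel": pd.tolist(),
            "median": float(np.median(pd)),
        }
    return out


def slice_harmonics(
    volume_period_s: float, n_slices: int, n_harmonics: int = 5
) -> tuple:
    """Volume frequency and the first slice-frequency harmonics in Hz."""
    f_vol = 1.0 / volume_period_s
    f_slice = n_slices / volume_period_s
    return f_vol, [f_slice * k for k in range(1, n_harmonics + 1)]


def power_density_reduction(
    original: np.ndarray,
    corrected: np.ndarray,
    slice_freq: float,
    volume_freq: float,
    rate: float,
) -> dict:
    """dB power ratio corrected/original at artifact frequencies.

    Uses the FFT bin nearest each target frequency; the squared
    magnitude ratio in dB is averaged over channels.
    """
    n = original.shape[1]
    f = rfftfreq(n, d=1.0 / rate)
    mo = np.abs(rfft(original - original.mean(axis=1, keepdims=True), axis=1))
    mc = np.abs(rfft(corrected - corrected.mean(axis=1, keepdims=True), axis=1))
    targets = {"volume": volume_freq}
    for k in range(1, 6):
        targets[f"slice_h{k}"] = k * slice_freq
    out = {}
    for name, freq in targets.items():
        b = int(np.argmin(np.abs(f - freq)))
        ratio = mc[:, b] / mo[:, b]
        db = 10.0 * np.log10(ratio ** 2)
        out[name] = {
            "freq_hz": float(f[b]),
            "target_hz": float(freq),
            "per_channel_db": db.tolist(),
            "mean_db": float(db.mean()),
        }
    return out


def evaluate(
    original: Recording,
    corrected: Recording,
    channels=None,
    n_slices_per_volume: int | None = None,
    trigger_label: str = "slice",
    label: str = "",
) -> EvalResult:
    """Run every indicator with a shared acquisition/trigger context.

    ``channels`` restricts the comparison (indices or labels), e.g. to
    leave out ECG/EMG channels.  Slice timing is taken from the
    ``trigger_label`` events of the original recording.
    """
    if channels is None:
        idx = list(range(original.n_channels))
    else:
        idx = [original.channel_labels.index(c) if isinstance(c, str) else int(c)
               for c in channels]
    span = original.acq_span or estimate_acq_span(original)
    if span is None:
        raise ValueError("acquisition span unknown: set acq_span or make it "
                         "detectable")
    a, b = span
    lat = original.event_latencies(trigger_label)
    if lat.size < 2:
        raise ValueError(f"need >= 2 {trigger_label!r} events for timing")
    slice_period = float(np.median(np.diff(lat)))
    f_slice = original.rate / slice_period
    if n_slices_per_volume:
        f_vol = f_slice / n_slices_per_volume
    else:
        f_vol = f_slice

    orig = original.data[idx]
    corr = corrected.data[idx]
    unimp = np.concatenate([corr[:, :a], corr[:, b:]], axis=1)

    res = EvalResult(label=label,
                     channels=[original.channel_labels[i] for i in idx])
    res.median_imaging_artifact = median_imaging_artifact(
        Recording(corr, corrected.rate,
                  [original.channel_labels[i] for i in idx]),
        slice_period, span)
    r_cu, r_uc = rms_ratios(orig[:, a:b], corr[:, a:b], unimp)
    res.rms_corrected_to_unimpaired = r_cu
    res.rms_uncorrected_to_corrected = r_uc
    res.snr_corrected = snr_corrected(corr[:, a:b], unimp)
    res.median_residual_activity = median_residual_activity(
        corr[:, a:b], unimp, original.rate)
    res.power_density_reduction = power_density_reduction(
        orig, corr, f_slice, f_vol, original.rate)
    return res


def render_report(results) -> tuple:
    """Side-by-side summary of one or more labelled results.

    Accepts a list of :class:`EvalResult` (or ``(EvalResult, label)``
    pairs); returns ``(text, json_document)``.
    """
    cols = []
    for item in results:
        if isinstance(item, tuple):
            res, lab = item
            res.label = lab
        else:
            res = item
        cols.append(res)

    rows = [("Median imaging artifact (uV)",
             [f"{c.median_imaging_artifact['median']:.1f}" for c in cols]),
            ("RMS corrected to unimpaired",
             [f"{c.rms_corrected_to_unimpaired['mean']:.3f}" for c in cols]),
            ("RMS uncorrected to corrected",
             [f"{c.rms_uncorrected_to_corrected['mean']:.1f}" for c in cols]),
            ("SNR of corrected",
             [f"{c.snr_corrected['mean']:.2f} ({c.snr_corrected['n_positive']})"
              if c.snr_corrected["mean"] is not None else "n/a"
              for c in cols])]
    for band in BANDS:
        rows.append((f"Residual activity {band}",
                     [f"{c.median_residual_activity[band]['median']:.0f}%"
                      for c in cols]))
    pdr_keys = ["volume"] + [f"slice_h{k}" for k in range(1, 6)]
    for key in pdr_keys:
        freq = cols[0].power_density_reduction[key]["target_hz"]
        rows.append((f"Power density {key} ({freq:.2f} Hz)",
                     [f"{c.power_density_reduction[key]['mean_db']:.0f} dB"
                      for c in cols]))

    name_w = max(len(r[0]) for r in rows)
    col_w = max(12, *(len(c.label or f"run{i}") for i, c in enumerate(cols)))
    header = " " * name_w + "  " + "  ".join(
        (c.label or f"run{i}").rjust(col_w) for i, c in enumerate(cols))
    lines = [header, "-" * len(header)]
    for name, vals in rows:
        lines.append(name.ljust(name_w) + "  "
                     + "  ".join(v.rjust(col_w) for v in vals))
    text = "\n".join(lines)
    doc = json.dumps({"results": [c.as_dict() for c in cols]}, indent=1)
    return text, doc
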