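"""Locating, repairing and synthesising MR acquisition triggers.

Slice-wise template subtraction stands or falls with an accurate list of
slice (or volume) onset times.  This module filters trigger events out of
a recording, classifies them as slice or volume triggers, fills gaps left
by dropped triggers while acknowledging genuine volume gaps, converts
volume triggers into slice triggers, and characterises the dataset as a
whole (:func:`analyze`).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "TriggerSet",
    "find_triggers",
    "find_missing_triggers",
    "add_triggers",
    "generate_slice_triggers",
    "analyze",
    "AnalysisReport",
    "check_setup",
    "estimate_acq_span",
]

#: mean inter-trigger spacing below this (seconds) means slice triggers
SLICE_CLASSIFICATION_THRESHOLD_S = 1.0

#: a slice-trigger gap larger than this multiple of the median spacing is
#: a candidate volume gap
VOLUME_GAP_FACTOR = 1.5

#: a gap counts as k missing periods when within this fraction of k periods
MISSING_GAP_TOLERANCE = 0.20


@dataclass
class TriggerSet:
    """Ordered slice/volume onset latencies with volume/slice bookkeeping.

    ``latencies`` are 0-based sample indices, strictly increasing.  For
    slice triggers with known geometry, ``n_e == n_v * n_s``.
    """

    latencies: np.ndarray
    kind: str = "slice"  # {"slice", "volume"}
    n_v: int | None = None
    n_s: int | None = None
    offset: int = 0
    volume_gap_after: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=np.int64)
    )  # indices e such that a volume gap follows trigger e
    ambiguous_gaps: list = field(default_factory=list)

    def __post_init__(self):
        self.latencies = np.asarray(self.latencies, dtype=np.int64)
        if self.latencies.size and np.any(np.diff(self.latencies) <= 0):
            raise ValueError("trigger latencies must be strictly increasing")
        if (
            self.kind == "slice"
            and self.n_v is not None
            and self.n_s is not None
            and self.n_e != self.n_v * self.n_s
        ):
            raise ValueError(
                f"n_e={self.n_e} inconsistent with n_v*n_s="
                f"{self.n_v * self.n_s}"
            )

    @property
    def n_e(self) -> int:
        return int(self.latencies.size)

    @property
    def median_spacing(self) -> float:
        """Median inter-trigger distance in samples (robust slice period)."""
        if self.n_e < 2:
            raise ValueError("need >= 2 triggers for a spacing estimate")
        return float(np.median(np.diff(self.latencies)))


def find_triggers(
    rec: Recording, event_label: str, trigger_offset: int = 0
) -> TriggerSet:
    """Collect all events named ``event_label`` as a :class:`TriggerSet`.

    All latencies are shifted by ``trigger_offset`` samples.  The set is
    classified as slice triggers when the mean inter-trigger distance is
    below 1.0 s, as volume triggers otherwise.
    """
    lat = rec.event_latencies(event_label)
    if lat.size == 0:
        raise ValueError(f"no events labeled {event_label!r} in recording")
    if lat.size < 2:
        raise ValueError(
            f"only one event labeled {event_label!r}: insufficient triggers "
            "for slice/volume classification"
        )
    lat = lat + int(trigger_offset)
    if np.any(np.diff(lat) <= 0):
        raise ValueError("non-monotone trigger latencies after offset")
    mean_dist_s = float(np.mean(np.diff(lat))) / rec.rate
    kind = "slice" if mean_dist_s < SLICE_CLASSIFICATION_THRESHOLD_S else "volume"
    ts = TriggerSet(latencies=lat, kind=kind, offset=int(trigger_offset))
    if kind == "slice":
        gaps, n_s = _detect_volume_gaps(lat)
        ts.volume_gap_after = gaps
        if n_s is not None:
            ts.n_s = n_s
            if ts.n_e % n_s == 0:
                ts.n_v = ts.n_e // n_s
    logger.info("found %d %s triggers (mean spacing %.3f s)",
                ts.n_e, kind, mean_dist_s)
    return ts


def _detect_volume_gaps(lat: np.ndarray):
    """Find quasi-periodic oversized gaps in a slice-trigger stream.

    Returns ``(gap_indices, n_s)`` where ``gap_indices[i] = e`` means a
    volume gap follows trigger ``e`` (the last slice of a volume), and
    ``n_s`` is the slices-per-volume count implied by the gap period (or
    None when no periodic gaps exist).
    """
    diffs = np.diff(lat)
    if diffs.size < 2:
        return np.array([], dtype=np.int64), None
    med = np.median(diffs)
    cand = np.nonzero(diffs > VOLUME_GAP_FACTOR * med)[0]
    if cand.size == 0:
        return np.array([], dtype=np.int64), None
    if cand.size == 1:
        # a single oversized gap: only a volume gap if it is *not* close to
        # an integer multiple of the period (else it looks like a dropout)
        if _missing_count(diffs[cand[0]], med) is None:
            return cand.astype(np.int64), None
        return np.array([], dtype=np.int64), None
    steps = np.diff(cand)
    n_s = int(np.median(steps))
    # quasi-periodic: most steps agree with the median step
    periodic = np.abs(steps - n_s) <= max(1, round(0.1 * n_s))
    if n_s >= 2 and np.mean(periodic) >= 0.5:
        return cand.astype(np.int64), n_s
    return cand.astype(np.int64), None


def _missing_count(gap: float, period: float) -> int | None:
    """Number of periods k >= 2 the gap spans, or None if ambiguous."""
    k = int(round(gap / period))
    if k >= 2 and abs(gap - k * period) <= MISSING_GAP_TOLERANCE * k * period:
        return k
    return None


def find_missing_triggers(ts: TriggerSet, rec: Recording) -> TriggerSet:
    """Fill dropped triggers in an otherwise periodic trigger stream.

    Gaps close to an integer multiple ``k >= 2`` of the local period are
    filled with ``k - 1`` equally spaced triggers.  For slice triggers,
    recurring oversized last-slice -> first-slice intervals are recognised
    as volume gaps and left alone.  Gaps that are neither are recorded in
    ``ambiguous_gaps`` and not filled.  The operation is idempotent.
    """
    if ts.n_e < 3:
        raise ValueError("need >= 3 triggers to diagnose missing ones")
    lat = ts.latencies
    diffs = np.diff(lat)
    med = float(np.median(diffs))
    gap_after = set()
    if ts.kind == "slice":
        gaps, gap_n_s = _detect_volume_gaps(lat)
        # honour volume gaps only when they recur; a single oversized
        # non-integer gap is ambiguous, not a volume gap
        if gap_n_s is not None or gaps.size >= 2:
            gap_after = set(int(g) for g in gaps)

    out = [int(lat[0])]
    ambiguous = []
    inserted = 0
    for i, d in enumerate(diffs):
        nxt = int(lat[i + 1])
        if i in gap_after or d <= VOLUME_GAP_FACTOR * med:
            out.append(nxt)
            continue
        k = _missing_count(float(d), med)
        if k is None:
            ambiguous.append((int(lat[i]), nxt))
            logger.warning(
                "ambiguous trigger gap %d..%d (%.1f periods): not filled",
                lat[i], nxt, d / med,
            )
            out.append(nxt)
            continue
        fill = np.round(np.linspace(lat[i], nxt, k + 1))[1:-1]
        out.extend(int(x) for x in fill)
        inserted += k - 1
        out.append(nxt)
    if inserted:
        logger.info("inserted %d missing triggers", inserted)
    new = replace(
        ts,
        latencies=np.array(out, dtype=np.int64),
        n_v=None,
        n_s=None,
        ambiguous_gaps=ambiguous,
    )
    if new.kind == "slice":
        gaps, n_s = _detect_volume_gaps(new.latencies)
        new.volume_gap_after = gaps
        new.n_s = n_s
        if n_s is not None and new.n_e % n_s == 0:
            new.n_v = new.n_e // n_s
    return new


def add_triggers(ts: TriggerSet, new_latencies, rec: Recording) -> TriggerSet:
    """Merge manually specified latencies (e.g. dummy-scan onsets) into ``ts``."""
    new_latencies = np.asarray(new_latencies, dtype=np.int64)
    if new_latencies.size == 0:
        return replace(ts, latencies=ts.latencies.copy())
    if np.any((new_latencies < 0) | (new_latencies >= rec.n_samples)):
        raise ValueError("new trigger latency outside recording")
    merged = np.concatenate([ts.latencies, new_latencies])
    if np.unique(merged).size != merged.size:
        raise ValueError("duplicate trigger latency")
    merged.sort()
    return replace(ts, latencies=merged, n_v=None, n_s=None)


def generate_slice_triggers(
    ts: TriggerSet,
    n_slices: int,
    slice_duration: float,
    rel_pos: float = 0.0,
) -> TriggerSet:
    """Expand volume triggers into per-slice triggers.

    Within each volume period, a block of ``n_slices`` triggers spaced
    ``slice_duration`` samples apart is placed according to ``rel_pos``
    (0 = block starts at the volume trigger, 1 = block ends at the next
    volume trigger).  Latencies are rounded to the nearest sample.
    """
    if ts.kind != "volume":
        raise ValueError("generate_slice_triggers needs volume triggers")
    if not 0.0 <= rel_pos <= 1.0:
        raise ValueError("rel_pos must lie in [0, 1]")
    period = ts.median_spacing
    block = n_slices * slice_duration
    if block > period + 0.5:
        raise ValueError(
            f"slice block ({block:.1f} samples) exceeds volume period "
            f"({period:.1f} samples)"
        )
    slack = period - block
    lat = []
    for t in ts.latencies:
        start = t + rel_pos * slack
        for s in range(n_slices):
            lat.append(int(round(start + s * slice_duration)))
    return TriggerSet(
        latencies=np.array(lat, dtype=np.int64),
        kind="slice",
        n_v=ts.n_e,
        n_s=n_slices,
        offset=ts.offset,
    )


# ---------------------------------------------------------------------------
# Dataset analysis
# ---------------------------------------------------------------------------

def estimate_acq_span(
    rec: Recording, window_s: float = 0.1, factor: float = 5.0
) -> tuple | None:
    """Estimate the fMRI acquisition span from artifact amplitude.

    The gradient artifact exceeds EEG by orders of magnitude, so a
    sliding-window standard deviation (window 100 ms) thresholded at
    ``factor`` times the median windowed SD of the first second marks the
    acquisition robustly.  Returns a 0-based half-open interval or None
    when no crossing exists.
    """
    win = max(3, int(round(window_s * rec.rate)))
    x = rec.data - rec.data.mean(axis=1, keepdims=True)
    m1 = uniform_filter1d(x, win, axis=1, mode="nearest")
    m2 = uniform_filter1d(x * x, win, axis=1, mode="nearest")
    sd = np.sqrt(np.maximum(m2 - m1 * m1, 0.0)).max(axis=0)
    first_sec = sd[: max(win, int(rec.rate))]
    thresh = factor * float(np.median(first_sec))
    if thresh <= 0:
        return None
    above = np.nonzero(sd > thresh)[0]
    if above.size == 0:
        return None
    return int(above[0]), int(above[-1]) + 1


def estimate_slice_period_autocorr(
    rec: Recording, ts: TriggerSet, channel: int | None = None
) -> float | None:
    """Estimate the slice period from one volume interval's autocorrelation.

    Takes the data between the first two volume triggers, autocorrelates
    it and reads the slice period off the spacing of the autocorrelation
    maxima.  Returns samples, or None if no usable peaks exist.
    """
    if ts.n_e < 2:
        return None
    a, b = int(ts.latencies[0]), int(ts.latencies[1])
    if channel is None:
        seg_all = rec.data[:, a:b]
        channel = int(np.argmax(seg_all.std(axis=1)))
    x = rec.data[channel, a:b].astype(float)
    x = x - x.mean()
    if x.size < 8 or not np.any(x):
        return None
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    ac /= ac[0]
    # peaks of the autocorrelation; ignore the zero-lag peak
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(ac, height=0.2)
    if peaks.size == 0:
        return None
    if peaks.size == 1:
        return float(peaks[0])
    return float(np.median(np.diff(np.concatenate([[0], peaks]))))


@dataclass
class AnalysisReport:
    """Structured outcome of :func:`analyze` with a plain-text rendering."""

    n_samples: int = 0
    rate: float = 0.0
    duration_s: float = 0.0
    channel_labels: list = field(default_factory=list)
    event_inventory: dict = field(default_factory=dict)
    acq_span: tuple | None = None
    acq_duration_s: float | None = None
    pre_duration_s: float | None = None
    post_duration_s: float | None = None
    trigger_kind: str | None = None
    n_triggers: int | None = None
    spacing_histogram: dict = field(default_factory=dict)
    median_spacing: float | None = None
    missing_trigger_warning: bool = False
    trigger_count_sufficient: bool | None = None
    volume_gaps: list = field(default_factory=list)
    slice_period_samples: float | None = None
    est_n_volumes: int | None = None
    est_n_slices: int | None = None
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["spacing_histogram"] = {str(k): v for k, v in self.spacing_histogram.items()}
        return d

    def as_text(self) -> str:
        L = []
        L.append(f"Samples:        {self.n_samples} ({self.duration_s:.2f} s)")
        L.append(f"Sampling rate:  {self.rate:g} Hz")
        L.append(f"Channels:       {len(self.channel_labels)}")
        L.append("  " + ", ".join(self.channel_labels))
        L.append("Events:")
        for name, cnt in sorted(self.event_inventory.items()):
            L.append(f"  {name!r}: {cnt}")
        if self.acq_span is not None:
            L.append(
                f"fMRI acquisition: samples {self.acq_span[0]}..{self.acq_span[1]}"
                f" ({self.acq_duration_s:.2f} s)"
            )
            L.append(f"  unimpaired before: {self.pre_duration_s:.2f} s,"
                     f" after: {self.post_duration_s:.2f} s")
        else:
            L.append("fMRI acquisition: not detected")
        if self.trigger_kind is not None:
            L.append(f"Triggers: {self.n_triggers} classified as "
                     f"{self.trigger_kind} triggers")
            L.append("  spacing histogram (samples: count): " + ", ".join(
                f"{k}: {v}" for k, v in sorted(self.spacing_histogram.items())))
            if self.volume_gaps:
                L.append(f"  volume gaps detected after {len(self.volume_gaps)}"
                         " triggers")
            if self.slice_period_samples is not None:
                L.append(f"  slice period estimate: "
                         f"{self.slice_period_samples:.2f} samples")
            if self.est_n_volumes is not None:
                L.append(f"  estimated volumes: {self.est_n_volumes}, "
                         f"slices: {self.est_n_slices}")
        for w in self.warnings:
            L.append(f"WARNING: {w}")
        return "\n".join(L)


def analyze(rec: Recording, ts: TriggerSet | None = None) -> AnalysisReport:
    """Characterise a recording: inventory, acquisition span, trigger health."""
    rep = AnalysisReport(
        n_samples=rec.n_samples,
        rate=rec.rate,
        duration_s=rec.duration,
        channel_labels=list(rec.channel_labels),
        event_inventory=dict(Counter(e.label for e in rec.events)),
    )
    span = rec.acq_span or estimate_acq_span(rec)
    if span is not None:
        rep.acq_span = span
        rep.acq_duration_s = (span[1] - span[0]) / rec.rate
        rep.pre_duration_s = span[0] / rec.rate
        rep.post_duration_s = (rec.n_samples - span[1]) / rec.rate

    if ts is not None and ts.n_e >= 2:
        diffs = np.diff(ts.latencies)
        rep.trigger_kind = ts.kind
        rep.n_triggers = ts.n_e
        rep.spacing_histogram = {int(k): int(v) for k, v in
                                 zip(*np.unique(diffs, return_counts=True))}
        med = float(np.median(diffs))
        rep.median_spacing = med
        gaps, n_s = (np.array([], dtype=int), None)
        if ts.kind == "slice":
            gaps, n_s = _detect_volume_gaps(ts.latencies)
            rep.volume_gaps = [int(g) for g in gaps]
            vol_period = None
            if n_s is not None:
                rep.est_n_slices = ts.n_e
                rep.est_n_volumes = int(round(ts.n_e / n_s))
            elif ts.n_s:
                rep.est_n_slices = ts.n_e
                rep.est_n_volumes = int(round(ts.n_e / ts.n_s))
            else:
                rep.est_n_slices = ts.n_e
            # missing triggers: gaps close to >= 2 periods outside volume gaps
            gap_set = set(int(g) for g in gaps)
            for i, d in enumerate(diffs):
                if i not in gap_set and _missing_count(float(d), med):
                    rep.missing_trigger_warning = True
                    rep.warnings.append(
                        f"possible missing trigger between latencies "
                        f"{ts.latencies[i]} and {ts.latencies[i + 1]}")
        else:
            sp = estimate_slice_period_autocorr(rec, ts)
            rep.slice_period_samples = sp
            rep.est_n_volumes = ts.n_e
            if sp:
                rep.est_n_slices = ts.n_e * int(round(med / sp))
        # sufficiency: triggers should roughly cover the acquisition span
        if rep.acq_span is not None:
            expected = (rep.acq_span[1] - rep.acq_span[0]) / med
            rep.trigger_count_sufficient = (expected - ts.n_e) <= 2
            if not rep.trigger_count_sufficient:
                rep.warnings.append(
                    f"only {ts.n_e} triggers for an acquisition spanning "
                    f"~{expected:.0f} trigger periods")
    return rep


def check_setup(rec: Recording, cfg, ts: TriggerSet | None = None) -> list:
    """Sanity-check data + configuration; returns a list of findings.

    An empty list means the setup looks clean.  Findings are plain strings
    (this mirrors a pre-flight check, not an exception path).
    """
    findings = []
    if rec is None or rec.n_samples == 0:
        findings.append("no EEG data provided")
        return findings
    if ts is None or ts.n_e == 0:
        findings.append("triggers not set")
    elif ts.n_e >= 2:
        med = ts.median_spacing
        avg_window = getattr(cfg, "avg_window", None)
        if avg_window is not None and avg_window > ts.n_e:
            findings.append(
                f"averaging window ({avg_window}) exceeds trigger count "
                f"({ts.n_e})")
        if med < 2:
            findings.append("inter-trigger spacing below 2 samples")
    nyq = rec.rate / 2.0
    for attr in ("lp_cutoff_hz", "hp_cutoff_hz"):
        cut = getattr(cfg, attr, None) if cfg is not None else None
        if cut is not None and cut >= nyq:
            findings.append(f"{attr} = {cut:g} Hz is not below Nyquist "
                            f"({nyq:g} Hz)")
    return findings
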