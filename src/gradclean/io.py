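"""EEGLAB dataset I/O and the core :class:`Recording` data model.

A :class:`Recording` is the object every stage of the toolbox transforms:
a channels x samples matrix in microvolts, a sampling rate, channel labels,
a sorted list of trigger :class:`Event` objects and an optional fMRI
acquisition span.  On disk the continuous EEGLAB dataset format is used:
a ``.set`` MAT-file header plus a ``.fdt`` float32 payload (or the data
embedded in the ``.set`` itself).

Internally sample indices are 0-based half-open; EEGLAB's 1-based event
latencies are converted at the I/O boundary.  Data is stored float32 on
disk and promoted to float64 in memory.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.io

logger = logging.getLogger(__name__)

__all__ = ["Event", "Recording", "read_eeglab", "write_eeglab"]


@dataclass(frozen=True)
class Event:
    """A named marker at an integer sample index (0-based)."""

    label: str
    latency: int

    def __post_init__(self):
        object.__setattr__(self, "latency", int(self.latency))


@dataclass
class Recording:
    """A continuous multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Sample values in microvolts (float64 in memory).
    rate : float
        Sampling rate in Hz, > 0.
    channel_labels : list of str
        One label per data row.
    events : list of Event
        Markers sorted by latency (ties keep insertion order).
    acq_span : tuple (start, stop) or None
        0-based half-open sample interval covered by the fMRI acquisition.
    """

    data: np.ndarray
    rate: float
    channel_labels: list = field(default_factory=list)
    events: list = field(default_factory=list)
    acq_span: tuple | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be > 0")
        if not self.channel_labels:
            self.channel_labels = [f"Ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.n_channels} data rows"
            )
        self.events = sorted(
            (Event(e.label, e.latency) for e in self.events),
            key=lambda e: e.latency,
        )
        for e in self.events:
            if not 0 <= e.latency < self.n_samples:
                raise ValueError(
                    f"event {e.label!r} latency {e.latency} outside recording"
                )
        if self.acq_span is not None:
            a, b = self.acq_span
            if not (0 <= a < b <= self.n_samples):
                raise ValueError(f"invalid acq_span {self.acq_span}")
            self.acq_span = (int(a), int(b))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            events=list(self.events),
        )

    def event_latencies(self, label: str) -> np.ndarray:
        """Latencies (sorted, int) of all events with the given label."""
        return np.array(
            [e.latency for e in self.events if e.label == label], dtype=np.int64
        )


# ---------------------------------------------------------------------------
# EEGLAB .set / .fdt
# ---------------------------------------------------------------------------

def write_eeglab(rec: Recording, path: str | os.PathLike) -> None:
    """Write ``rec`` as a continuous EEGLAB dataset (.set + .fdt).

    The sample payload goes to a companion ``.fdt`` file (float32,
    channel-interleaved / column-major as EEGLAB expects); the ``.set``
    holds the MAT5 header struct.  Event latencies are written 1-based.
    The acquisition span, when set, is stored under ``EEG.etc.acq_span``
    (1-based inclusive), which EEGLAB tools ignore gracefully.
    """
    path = os.fspath(path)
    if not path.endswith(".set"):
        path = path + ".set"
    fdt_path = path[:-4] + ".fdt"

    data32 = np.ascontiguousarray(rec.data, dtype="<f4")
    # EEGLAB stores (nbchan, pnts) column-major == (pnts, nbchan) row-major
    data32.T.tofile(fdt_path)

    if rec.events:
        ev_dtype = [("type", object), ("latency", object)]
        ev = np.zeros((1, len(rec.events)), dtype=ev_dtype)
        for i, e in enumerate(rec.events):
            ev[0, i] = (e.label, float(e.latency + 1))
    else:
        ev = np.zeros((0, 0), dtype=[("type", object), ("latency", object)])

    chanlocs = np.zeros((1, rec.n_channels), dtype=[("labels", object)])
    for i, lab in enumerate(rec.channel_labels):
        chanlocs[0, i] = (lab,)

    etc: dict = {}
    if rec.acq_span is not None:
        etc["acq_span"] = np.array(
            [rec.acq_span[0] + 1, rec.acq_span[1]], dtype=float
        )

    eeg = {
        "setname": os.path.basename(path)[:-4],
        "nbchan": float(rec.n_channels),
        "pnts": float(rec.n_samples),
        "trials": 1.0,
        "srate": float(rec.rate),
        "xmin": 0.0,
        "xmax": (rec.n_samples - 1) / rec.rate,
        "data": os.path.basename(fdt_path),
        "chanlocs": chanlocs,
        "event": ev,
        "etc": etc,
    }
    scipy.io.savemat(path, {"EEG": eeg}, appendmat=False)
    logger.info("wrote %s (+%s): %d ch x %d samples, %d events",
                path, os.path.basename(fdt_path), rec.n_channels,
                rec.n_samples, len(rec.events))


def _mat_str(x) -> str:
    if isinstance(x, bytes):
        return x.decode()
    if isinstance(x, np.ndarray):
        return "".join(str(c) for c in x.flat)
    return str(x)


def read_eeglab(path: str | os.PathLike) -> Recording:
    """Read a continuous EEGLAB dataset into a :class:`Recording`.

    Supports sample data embedded in the ``.set`` or referenced as a
    companion ``.fdt`` file.  Event latencies are converted from EEGLAB's
    1-based convention to 0-based integer sample indices.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    mat = scipy.io.loadmat(path, squeeze_me=True, struct_as_record=False,
                           appendmat=False)
    if "EEG" not in mat:
        raise ValueError(f"{path}: no EEG struct found (not an EEGLAB .set?)")
    eeg = mat["EEG"]

    n_ch = int(eeg.nbchan)
    n_samp = int(eeg.pnts)
    trials = int(getattr(eeg, "trials", 1) or 1)
    if trials != 1:
        raise ValueError(f"{path}: epoched datasets (trials={trials}) are "
                         "not supported; only continuous data")

    raw = eeg.data
    if isinstance(raw, (str, bytes)) or (
        isinstance(raw, np.ndarray) and raw.dtype.kind == "U"
    ):
        fdt_path = os.path.join(os.path.dirname(path) or ".", _mat_str(raw))
        if not os.path.exists(fdt_path):
            raise FileNotFoundError(
                f"{path} references missing payload file {fdt_path}"
            )
        flat = np.fromfile(fdt_path, dtype="<f4")
        if flat.size != n_ch * n_samp:
            raise ValueError(
                f"{fdt_path}: payload holds {flat.size} values, header "
                f"promises {n_ch} x {n_samp}"
            )
        data = flat.reshape(n_samp, n_ch).T.astype(np.float64)
    else:
        data = np.asarray(raw, dtype=np.float64)
        if data.ndim == 1:
            data = data[np.newaxis, :]
        if data.shape != (n_ch, n_samp):
            raise ValueError(
                f"{path}: embedded data shape {data.shape} does not match "
                f"header ({n_ch}, {n_samp})"
            )

    labels = []
    chanlocs = getattr(eeg, "chanlocs", None)
    if chanlocs is not None:
        locs = np.atleast_1d(chanlocs)
        if locs.size == n_ch:
            labels = [_mat_str(c.labels) for c in locs.flat]

    events = []
    raw_events = getattr(eeg, "event", None)
    if raw_events is not None:
        for ev in np.atleast_1d(raw_events).flat:
            lab = _mat_str(ev.type)
            lat = int(round(float(np.atleast_1d(ev.latency).flat[0]))) - 1
            events.append(Event(lab, lat))

    acq_span = None
    etc = getattr(eeg, "etc", None)
    if etc is not None and hasattr(etc, "acq_span"):
        a, b = np.asarray(etc.acq_span, dtype=float).ravel()[:2]
        acq_span = (int(a) - 1, int(b))

    return Recording(
        data=data,
        rate=float(eeg.srate),
        channel_labels=labels,
        events=events,
        acq_span=acq_span,
    )


def write_ground_truth(truth: dict, path: str | os.PathLike) -> None:
    """Write a JSON ground-truth sidecar (arrays summarised, not embedded)."""
    ser = {}
    for k, v in truth.items():
        if isinstance(v, np.ndarray):
            ser[k] = v.tolist()
        else:
            ser[k] = v
    with open(path, "w") as fh:
        json.dump(ser, fh)
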