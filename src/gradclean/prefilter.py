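"""Sectionwise high-/low-pass pre-filtering of the raw recording.

Slow baseline fluctuations during fMRI acquisition differ in mean level
from the unimpaired EEG before and after it, so the filter is applied
separately to the pre-, during- and post-acquisition sections.  Three
filter families are offered:

``fir``
    Windowed-sinc (Hamming) linear-phase FIR of order 1000, applied
    zero-phase.
``ideal``
    Brick-wall filter in the frequency domain: the response is exactly
    0.0 in the stop band and 1.0 in the pass band.
``gauss``
    Gaussian-shaped frequency response: the steepest transition with no
    overshoot anywhere.  The response is 0.5 at the cutoff frequency
    (half-amplitude convention).
``custom``
    A user-supplied frequency-response table, interpolated onto the FFT
    grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq
from scipy.signal import filtfilt, firwin

from .io import Recording

logger = logging.getLogger(__name__)

__all__ = ["FilterSpec", "design_filter", "apply_prefilter"]

FIR_ORDER = 1000  # taps = order + 1 (odd, so high-pass stays type I)


@dataclass
class FilterSpec:
    """Specification of a pre-filter.

    At least one of ``hp_cutoff``, ``lp_cutoff`` or ``custom_weights``
    must be set.  ``per_channel_cutoffs`` maps a channel label to an
    ``(hp, lp)`` pair overriding the global cutoffs for that channel.
    ``custom_weights`` is a 2-column array (frequency Hz, gain).
    """

    kind: str = "gauss"  # {"fir", "ideal", "gauss", "custom"}
    hp_cutoff: float | None = None
    lp_cutoff: float | None = None
    per_channel_cutoffs: dict = field(default_factory=dict)
    custom_weights: np.ndarray | None = None
    acquisition_only: bool = False  # leave unimpaired sections untouched

    def validate(self, rate: float) -> None:
        if self.kind not in ("fir", "ideal", "gauss", "custom"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if (
            self.hp_cutoff is None
            and self.lp_cutoff is None
            and self.custom_weights is None
        ):
            raise ValueError("no cutoff frequencies or custom weights given")
        nyq = rate / 2.0
        cutoffs = [self.hp_cutoff, self.lp_cutoff]
        for hp, lp in self.per_channel_cutoffs.values():
            cutoffs += [hp, lp]
        for c in cutoffs:
            if c is not None and not 0.0 < c < nyq:
                raise ValueError(
                    f"cutoff {c:g} Hz outside (0, Nyquist={nyq:g}) Hz")


def _gauss_lp(f: np.ndarray, cutoff: float) -> np.ndarray:
    # exp(-ln2 (f/fc)^2): monotone, overshoot-free, 0.5 at fc
    return np.exp(-np.log(2.0) * (f / cutoff) ** 2)


def _response_on_grid(
    spec: FilterSpec, f: np.ndarray, hp: float | None, lp: float | None
) -> np.ndarray:
    if spec.kind == "custom":
        w = np.asarray(spec.custom_weights, dtype=float)
        return np.interp(f, w[:, 0], w[:, 1])
    h = np.ones_like(f)
    if spec.kind == "ideal":
        if hp is not None:
            h = np.where(f < hp, 0.0, h)
        if lp is not None:
            h = np.where(f > lp, 0.0, h)
    elif spec.kind in ("gauss", "fir"):
        # the fir response returned here is the target; coefficients below
        if hp is not None:
            h = h * (1.0 - _gauss_lp(f, hp))
        if lp is not None:
            h = h * _gauss_lp(f, lp)
    return h


def design_filter(
    spec: FilterSpec, rate: float, n_samples: int,
    hp: float | None = None, lp: float | None = None,
):
    """Design the filter for a section of ``n_samples`` samples.

    Returns ``(freq_response, fir_coefficients)``; the coefficient vector
    is None for frequency-domain kinds.  ``hp``/``lp`` override the
    spec's global cutoffs (used for per-channel settings).
    """
    spec.validate(rate)
    hp = spec.hp_cutoff if hp is None else hp
    lp = spec.lp_cutoff if lp is None else lp
    f = rfftfreq(n_samples, d=1.0 / rate)
    if spec.kind == "fir":
        nyq = rate / 2.0
        taps = None
        if hp is not None and lp is not None:
            taps = firwin(FIR_ORDER + 1, [hp / nyq, lp / nyq],
                          pass_zero=False, window="hamming")
        elif hp is not None:
            taps = firwin(FIR_ORDER + 1, hp / nyq, pass_zero=False,
                          window="hamming")
        elif lp is not None:
            taps = firwin(FIR_ORDER + 1, lp / nyq, pass_zero=True,
                          window="hamming")
        # actual magnitude response of the designed FIR on the grid
        h = np.abs(rfft(taps, n=max(n_samples, taps.size)))[: f.size]
        return h, taps
    return _response_on_grid(spec, f, hp, lp), None


def _filter_section(
    x: np.ndarray, spec: FilterSpec, rate: float,
    hp: float | None, lp: float | None,
) -> np.ndarray:
    """Filter one 1-D section.  Demeans first; restores the mean only for
    a pure low-pass (high-passing removes DC by definition)."""
    if x.size == 0:
        return x
    mean = float(x.mean())
    y = x - mean
    if spec.kind == "fir":
        _, taps = design_filter(spec, rate, x.size, hp=hp, lp=lp)
        pad = min(3 * (taps.size - 1) // 2, x.size - 1)
        y = filtfilt(taps, [1.0], y, padlen=pad)
    elif spec.kind == "ideal":
        # unpadded: zeroing bins is an exact projection (idempotent)
        h, _ = design_filter(spec, rate, x.size, hp=hp, lp=lp)
        y = irfft(rfft(y) * h, n=x.size)
    else:
        # odd-reflection padding on both sides keeps the section edges
        # value-continuous so slow filters settle without transients
        pad = min(x.size - 1, int(round(rate)))
        left = 2 * y[0] - y[pad:0:-1]
        right = 2 * y[-1] - y[-2:-pad - 2:-1]
        ext = np.concatenate([left, y, right])
        n = next_fast_len(int(np.ceil(ext.size * 1.05)))
        bridge = np.linspace(ext[-1], ext[0], n - ext.size + 2)[1:-1]
        ext = np.concatenate([ext, bridge])  # circular continuity
        h, _ = design_filter(spec, rate, n, hp=hp, lp=lp)
        y = irfft(rfft(ext) * h, n=n)[pad:pad + x.size]
    pure_lowpass = hp is None and spec.kind != "custom"
    if pure_lowpass:
        y = y + mean
    return y


def apply_prefilter(rec: Recording, spec: FilterSpec) -> Recording:
    """Apply ``spec`` to each of the three acquisition sections independently.

    Requires ``rec.acq_span``; the sections before, during and after the
    fMRI acquisition are filtered separately because their DC levels
    differ.  With ``spec.acquisition_only`` the unimpaired sections are
    returned untouched.
    """
    if rec.acq_span is None:
        raise ValueError("apply_prefilter requires rec.acq_span to be set")
    spec.validate(rec.rate)
    a, b = rec.acq_span
    out = rec.copy()
    sections = [(a, b)] if spec.acquisition_only else \
        [(0, a), (a, b), (b, rec.n_samples)]
    for ch in range(rec.n_channels):
        label = rec.channel_labels[ch]
        hp, lp = spec.per_channel_cutoffs.get(
            label, (spec.hp_cutoff, spec.lp_cutoff))
        for s0, s1 in sections:
            if s1 - s0 == 0:
                continue
            out.data[ch, s0:s1] = _filter_section(
                rec.data[ch, s0:s1], spec, rec.rate, hp, lp)
    logger.info("prefiltered %d channels (%s, hp=%s, lp=%s) in %d sections",
                rec.n_channels, spec.kind, spec.hp_cutoff, spec.lp_cutoff,
                len(sections))
    return out
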