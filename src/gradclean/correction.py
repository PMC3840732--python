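"""The correction engine: a configurable sequence of per-channel blocks.

Artifact removal is expressed as an ordered list of named blocks (plus
optional user callables) executed per channel, e.g.::

    ["cut", "upsample", "align_slices", "align_subsample",
     "remove_volume_artifact", "template", "obs",
     "downsample", "paste", "lowpass", "anc"]

The engine maintains two signals throughout: the working EEG segment
(successively cleaned) and the reconstructed artifact, which starts at
zero and accumulates everything removed from the data.  Their sum equals
the input over the processed region up to resampling round-off — the
conservation contract every sequence obeys.

Blocks
------
``cut`` / ``paste``
    Isolate the fMRI acquisition span (padded by one epoch) and merge it
    back, sample aligned.
``upsample`` / ``downsample``
    Polyphase FIR interpolation by the configured integer factor with an
    anti-alias/anti-image cutoff at 0.5 relative to the original
    Nyquist.  The fine-rate domain serves artifact estimation; at
    ``downsample`` the accumulated artifact increment is brought back to
    the original rate and subtracted from the retained original segment,
    so conservation holds exactly.
``align_slices``
    Integer-lag epoch alignment (cross-correlation against a reference
    epoch, search range +- one original sample).
``align_subsample``
    Fractional epoch alignment via FFT linear-phase shifts; the shift
    minimising the squared error to the reference epoch is found by
    bisection on [-0.5, +0.5] samples.
``remove_volume_artifact``
    Logistic-weighted subtraction of volume-transition templates next to
    volume gaps; the gap itself is bridged linearly.
``template``
    Build the averaging matrix A (scheme from the config or from a user
    callable), compute the templates N = A . D and subtract them.
``obs``
    Optimal-basis-set PCA on the residual epochs (see
    :mod:`gradclean.postprocess`).
``lowpass`` / ``anc``
    Zero-phase low-pass and adaptive noise cancellation post-processing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq

from . import averaging
from .io import Recording
from .triggers import TriggerSet

logger = logging.getLogger(__name__)

__all__ = [
    "CorrectionConfig",
    "EpochMatrix",
    "ArtifactEstimate",
    "run_sequence",
    "upsample",
    "downsample",
    "fft_shift",
    "logistic_weight",
    "solve_logistic_anchors",
    "compute_template",
]

KNOWN_BLOCKS = (
    "cut", "paste", "upsample", "downsample", "align_slices",
    "align_subsample", "remove_volume_artifact", "template", "obs",
    "lowpass", "anc",
)

#: logistic weight anchors: (position as fraction of slice interval, weight)
LOGISTIC_ANCHORS = ((0.80, 0.50), (0.69, 0.10))


@dataclass
class CorrectionConfig:
    """Configuration of the correction sequence and its blocks."""

    sequence: list = field(default_factory=list)
    upsample_factor: int = 10
    avg_window: int = 30
    avg_matrix: dict = field(default_factory=lambda: {"scheme": "fastr_slice"})
    obs_num_pcs: int | str = "auto"
    obs_segment_fraction: float = 0.25
    obs_coef_smooth: int = 9  # epochs; 1 = strict per-epoch least squares
    lp_cutoff_hz: float | None = 70.0
    hp_cutoff_hz: float | None = None
    exclude_channels: list = field(default_factory=list)
    dont_touch_non_artifact: bool = True
    volume_gap_fill: str = "linear"  # {"zero", "linear"}
    rng_seed: int = 0
    align_reference: int | None = None  # default: middle epoch
    sub_sample_tol: float = 1e-3
    #: moving-average window (epochs) for the estimated fractional shifts,
    #: applied after unwrapping; clock drift is smooth, so this suppresses
    #: estimation noise.  1 = raw per-epoch estimates.
    align_shift_smooth: int = 5
    anc_order: int | None = None
    anc_mu: float | None = None
    guard_fraction: float = 0.10

    def validate(self) -> None:
        names = [b for b in self.sequence if isinstance(b, str)]
        unknown = [b for b in names if b not in KNOWN_BLOCKS]
        if unknown:
            raise ValueError(f"unknown correction block(s): {unknown}")
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if "paste" in names and "cut" not in names:
            raise ValueError("'paste' without preceding 'cut'")
        if "cut" in names and "paste" in names:
            if names.index("cut") > names.index("paste"):
                raise ValueError("'cut' must precede 'paste'")
        if names.count("upsample") != names.count("downsample"):
            raise ValueError("'upsample'/'downsample' must be paired")
        if self.volume_gap_fill not in ("zero", "linear"):
            raise ValueError("volume_gap_fill must be 'zero' or 'linear'")


@dataclass
class EpochMatrix:
    """One channel's data wrapped into slice epochs.

    ``D`` holds one guarded window per epoch: ``guard`` samples, the
    ``n_l``-sample epoch proper, ``guard`` samples.  ``epoch_starts``
    are the (integer) start indices of the epoch proper in the segment.
    """

    D: np.ndarray
    epoch_starts: np.ndarray
    n_l: int
    guard: int = 0

    @property
    def n_e(self) -> int:
        return self.D.shape[0]


@dataclass
class ArtifactEstimate:
    """Accumulated reconstructed artifact, same shape as the recording."""

    data: np.ndarray
    provenance: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Primitive operations (usable standalone and as engine blocks)
# ---------------------------------------------------------------------------

#: relative cutoff of the interpolation anti-alias/anti-image filter,
#: as a fraction of the original Nyquist frequency
INTERP_RELATIVE_CUTOFF = 0.5


def _interp_filter(k: int) -> np.ndarray:
    from scipy.signal import firwin

    # long Kaiser design: passband flat (ripple ~1e-5) below ~0.45 of the
    # original Nyquist, stopband ~100 dB above ~0.55; resample_poly applies
    # its own `up` gain to user-supplied coefficients
    return firwin(128 * k + 1, INTERP_RELATIVE_CUTOFF / k,
                  window=("kaiser", 10.0))


def _odd_reflect(x: np.ndarray, pad: int) -> np.ndarray:
    left = 2.0 * x[0] - x[pad:0:-1]
    right = 2.0 * x[-1] - x[-2:-pad - 2:-1]
    return np.concatenate([left, x, right])


def upsample(x: np.ndarray, k: int) -> np.ndarray:
    """Polyphase FIR interpolation by integer ``k``.

    The anti-image filter cuts off at 0.5 relative to the original
    Nyquist frequency, trading bandwidth for a smooth reconstruction
    between the original samples.  The input is odd-reflected at both
    ends so the filter settles without edge transients."""
    from scipy.signal import resample_poly

    if k < 1:
        raise ValueError("upsample factor must be >= 1")
    if k == 1:
        return x.copy()
    pad = min(x.size - 1, 128)
    y = resample_poly(_odd_reflect(x, pad), k, 1, window=_interp_filter(k))
    return y[k * pad:k * (pad + x.size)]


def downsample(x: np.ndarray, k: int) -> np.ndarray:
    """Inverse of :func:`upsample`: matching low-pass, then every k-th
    sample."""
    from scipy.signal import resample_poly

    if k < 1:
        raise ValueError("downsample factor must be >= 1")
    if k == 1:
        return x.copy()
    pad = min(x.size - k, 128 * k)
    y = resample_poly(_odd_reflect(x, pad), 1, k, window=_interp_filter(k))
    return y[pad // k:pad // k + int(np.ceil(x.size / k))]


def fft_shift(x: np.ndarray, delta: float) -> np.ndarray:
    """Shift ``x`` by ``delta`` samples (content moves later for positive
    ``delta``) by adding a linear phase in the frequency domain."""
    n = x.size
    X = rfft(x)
    f = rfftfreq(n)
    X = X * np.exp(-2j * np.pi * f * delta)
    if n % 2 == 0:
        X[-1] = X[-1].real * np.cos(np.pi * delta)
    return irfft(X, n=n)


def logistic_weight(x, alpha: float, x0: float):
    """Logistic weighting function ``w(x) = 1 / (1 + exp(alpha (x - x0)))``."""
    return 1.0 / (1.0 + np.exp(alpha * (np.asarray(x, dtype=float) - x0)))


def solve_logistic_anchors(anchors=LOGISTIC_ANCHORS):
    """Fix (alpha, x0) of the logistic weight from two (x, w) anchors."""
    (x1, w1), (x2, w2) = anchors
    l1 = np.log(1.0 / w1 - 1.0)
    l2 = np.log(1.0 / w2 - 1.0)
    alpha = (l1 - l2) / (x1 - x2)
    x0 = x1 - l1 / alpha
    return float(alpha), float(x0)


def compute_template(
    em: EpochMatrix,
    A: "averaging.AveragingMatrix",
    gap_fill: str = "zero",
    out_len: int | None = None,
) -> np.ndarray:
    """Template contribution ``N = A . D`` unwrapped onto the segment.

    Consecutive epochs tile the segment; where the next epoch starts
    early the template is truncated, where it starts late (a volume gap)
    the gap is filled with zeros or a linear bridge per ``gap_fill``.
    """
    N_ep = A.apply(em.D)
    starts = np.asarray(em.epoch_starts, dtype=np.int64)
    if out_len is None:
        out_len = int(starts[-1]) + em.n_l
    contrib = np.zeros(out_len)
    g = em.guard
    for e in range(em.n_e):
        c0 = int(starts[e])
        c1 = c0 + em.n_l
        if e + 1 < em.n_e:
            c1 = min(c1, int(starts[e + 1]))
        c1 = min(c1, out_len)
        if c1 <= c0:
            continue
        contrib[c0:c1] = N_ep[e, g:g + (c1 - c0)]
        if e + 1 < em.n_e and int(starts[e + 1]) > c0 + em.n_l:
            g0, g1 = c0 + em.n_l, int(starts[e + 1])
            if gap_fill == "linear" and g1 <= out_len:
                lo = contrib[g0 - 1]
                hi = N_ep[e + 1, g]
                contrib[g0:g1] = np.linspace(lo, hi, g1 - g0 + 2)[1:-1]
            # "zero": leave zeros
    return contrib


def align_slices(
    seg: np.ndarray, em: EpochMatrix, reference: int, max_lag: int
) -> tuple:
    """Integer-lag epoch alignment against a reference epoch.

    Each epoch's start index is shifted by the lag (within ``+-max_lag``
    samples) maximising the cross-correlation of its demeaned window
    with the reference epoch; shifts at the search boundary are clamped.
    Returns ``(EpochMatrix, shifts)`` with the windows re-extracted at
    the shifted starts; ``shifts`` are the applied data shifts (the
    negated lags).
    """
    if em.n_e == 0:
        raise ValueError("empty epoch matrix")
    g = em.guard
    ref = em.D[reference][g:g + em.n_l] if g else em.D[reference]
    ref = ref - ref.mean()
    win = em.n_l
    starts = np.asarray(em.epoch_starts, dtype=np.int64).copy()
    shifts = np.zeros(em.n_e, dtype=np.int64)
    for e in range(em.n_e):
        best, best_lag = -np.inf, 0
        for lag in range(-max_lag, max_lag + 1):
            a = starts[e] + lag
            if a < 0 or a + win > seg.size:
                continue
            w = seg[a:a + win]
            w = w - w.mean()
            c = float(ref @ w)
            if c > best:
                best, best_lag = c, lag
        starts[e] += best_lag
        shifts[e] = -best_lag
    full = em.n_l + 2 * g
    D = np.stack([seg[s - g:s - g + full] for s in starts])
    return EpochMatrix(D, starts, em.n_l, g), shifts


def align_subsample(
    em: EpochMatrix, reference: int, tol: float = 1e-3
) -> tuple:
    """Fractional epoch alignment by FFT linear-phase shifts.

    Per epoch, the shift in ``[-0.5, +0.5]`` samples minimising the
    squared error to the (demeaned) reference epoch is found by
    bisection and applied in the frequency domain.  Returns
    ``(EpochMatrix, shifts)``.
    """
    ref = em.D[reference] - em.D[reference].mean()
    D = np.empty_like(em.D)
    shifts = np.zeros(em.n_e)
    for e in range(em.n_e):
        w = em.D[e] - em.D[e].mean()
        if not np.all(np.isfinite(w)):
            raise ValueError(f"non-finite data in epoch {e}")
        delta = _bisect_shift(w, ref, tol, crop=em.guard)
        shifts[e] = delta
        D[e] = fft_shift(em.D[e], delta) if abs(delta) > tol else em.D[e]
    from dataclasses import replace as _replace

    return _replace(em, D=D), shifts


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class _ChannelState:
    """Mutable per-channel working state threaded through the blocks."""

    def __init__(self, engine: "_Engine", ch: int):
        self.engine = engine
        self.ch = ch
        self.full = engine.rec.data[ch].astype(np.float64).copy()
        self.artifact_full = np.zeros_like(self.full)
        self.seg: np.ndarray | None = None
        self.artifact_seg: np.ndarray | None = None
        self.region: tuple | None = None
        self.factor = 1
        self.epoch_starts: np.ndarray | None = None  # float, segment coords
        self.n_l = 0
        self.guard = 0
        self.pasted = False
        self.integer_shifts: np.ndarray | None = None
        self.subsample_shifts: np.ndarray | None = None
        self.pending_matrix = None
        self._seg0 = self._art0 = self._art0_up = None
        self.log: list = []

    # -- helpers -----------------------------------------------------------

    @property
    def work(self) -> np.ndarray:
        """The array blocks currently operate on."""
        if self.seg is not None:
            return self.seg
        if self.pasted and self.engine.cfg.dont_touch_non_artifact:
            a, b = self.region
            return self.full[a:b]
        return self.full

    @property
    def work_artifact(self) -> np.ndarray:
        if self.seg is not None:
            return self.artifact_seg
        if self.pasted and self.engine.cfg.dont_touch_non_artifact:
            a, b = self.region
            return self.artifact_full[a:b]
        return self.artifact_full

    def int_starts(self) -> np.ndarray:
        return np.round(np.asarray(self.epoch_starts)).astype(np.int64)

    def epochs(self) -> EpochMatrix:
        """Extract the guarded epoch windows from the current segment."""
        starts = self.int_starts()
        g, n_l = self.guard, self.n_l
        win = n_l + 2 * g
        seg = self.seg
        D = np.zeros((starts.size, win))
        for e, s in enumerate(starts):
            a = s - g
            b = a + win
            if a < 0 or b > seg.size:
                raise ValueError(
                    f"epoch {e} window [{a}, {b}) outside segment "
                    f"(len {seg.size}); was 'cut' executed?")
            D[e] = seg[a:b]
        return EpochMatrix(D, starts, n_l, g)

    def tile_bounds(self, e: int) -> tuple:
        """Non-overlapping write-back range of epoch ``e`` in the segment."""
        starts = self.int_starts()
        c0 = int(starts[e])
        c1 = c0 + self.n_l
        if e + 1 < starts.size:
            c1 = min(c1, int(starts[e + 1]))
        return c0, min(c1, self.seg.size)

    def write_tile(self, e: int, window: np.ndarray) -> None:
        """Write a processed guarded window back, central tile only, and
        account the change into the artifact estimate."""
        c0, c1 = self.tile_bounds(e)
        if c1 <= c0:
            return
        g = self.guard
        new = window[g:g + (c1 - c0)]
        self.artifact_seg[c0:c1] += self.seg[c0:c1] - new
        self.seg[c0:c1] = new


class _Engine:
    def __init__(self, rec: Recording, ts: TriggerSet, cfg: CorrectionConfig):
        self.rec = rec
        self.ts = ts
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.rng_seed)
        self.n_l0 = int(round(ts.median_spacing)) if ts.n_e >= 2 else 0
        self._fixed_matrix_cache = None

    # -- epoch bookkeeping --------------------------------------------------

    def acq_bounds(self) -> tuple:
        if self.rec.acq_span is not None:
            return self.rec.acq_span
        return int(self.ts.latencies[0]), int(self.ts.latencies[-1]) + self.n_l0

    def ref_index(self) -> int:
        if self.cfg.align_reference is not None:
            return int(self.cfg.align_reference)
        return self.ts.n_e // 2

    # -- blocks -------------------------------------------------------------

    def block_cut(self, st: _ChannelState) -> None:
        a, b = self.acq_bounds()
        pad = self.n_l0
        r0 = max(0, a - pad)
        r1 = min(st.full.size, b + pad)
        st.region = (r0, r1)
        st.seg = st.full[r0:r1].copy()
        st.artifact_seg = st.artifact_full[r0:r1].copy()
        st.factor = 1
        st.n_l = self.n_l0
        st.guard = max(1, int(round(self.cfg.guard_fraction * self.n_l0)))
        st.epoch_starts = (self.ts.latencies - r0).astype(np.float64)

    def block_paste(self, st: _ChannelState) -> None:
        if st.seg is None or st.region is None:
            raise ValueError("'paste' without preceding 'cut'")
        if st.factor != 1:
            raise ValueError("cannot paste at an altered sampling rate; "
                             "missing 'downsample'?")
        r0, r1 = st.region
        st.full[r0:r1] = st.seg
        st.artifact_full[r0:r1] = st.artifact_seg
        st.seg = None
        st.artifact_seg = None
        st.pasted = True

    def block_upsample(self, st: _ChannelState) -> None:
        k = self.cfg.upsample_factor
        if st.seg is None:
            raise ValueError("'upsample' requires 'cut' first")
        # the resampled domain serves artifact *estimation*; the original
        # segment is kept so 'downsample' can apply the artifact increment
        # at the original rate without round-tripping the data
        st._seg0 = st.seg
        st._art0 = st.artifact_seg
        st.seg = upsample(st.seg, k)
        st.artifact_seg = upsample(st.artifact_seg, k)
        st._art0_up = st.artifact_seg.copy()
        st.factor *= k
        st.n_l *= k
        st.guard *= k
        st.epoch_starts = st.epoch_starts * k

    def block_downsample(self, st: _ChannelState) -> None:
        k = self.cfg.upsample_factor
        if st.seg is None or st.factor % k != 0 or st.factor < k:
            raise ValueError("'downsample' without matching 'upsample'")
        delta_up = st.artifact_seg - st._art0_up
        delta = downsample(delta_up, k)
        st.seg = st._seg0 - delta
        st.artifact_seg = st._art0 + delta
        st._seg0 = st._art0 = st._art0_up = None
        st.factor //= k
        st.n_l //= k
        st.guard //= k
        st.epoch_starts = st.epoch_starts / k

    def block_align_slices(self, st: _ChannelState) -> None:
        em = st.epochs()
        ref = em.D[self.ref_index()]
        ref = ref - ref.mean()
        nref = np.linalg.norm(ref)
        if nref == 0:
            return
        g = st.guard
        ref = ref[g:-g] if g else ref  # guards can hold unrelated content
        max_lag = st.factor  # +- one original sample
        win = st.n_l
        shifts = np.zeros(em.n_e, dtype=np.int64)
        starts = st.int_starts()
        for e in range(em.n_e):
            best, best_lag = -np.inf, 0
            for lag in range(-max_lag, max_lag + 1):
                a = starts[e] + lag
                if a < 0 or a + win > st.seg.size:
                    continue
                w = st.seg[a:a + win]
                w = w - w.mean()
                c = float(ref @ w)
                if c > best:
                    best, best_lag = c, lag
            if abs(best_lag) == max_lag and best_lag != 0:
                logger.debug("channel %d epoch %d: integer shift clamped at "
                             "search boundary (%d)", st.ch, e, best_lag)
            shifts[e] = -best_lag
            st.epoch_starts[e] += best_lag
        st.integer_shifts = shifts
        st.log.append(("align_slices", {"max_abs_shift": int(np.abs(shifts).max())}))

    def block_align_subsample(self, st: _ChannelState) -> None:
        em = st.epochs()
        ref = em.D[self.ref_index()]
        ref = ref - ref.mean()
        tol = self.cfg.sub_sample_tol
        shifts = np.zeros(em.n_e)
        starts = st.int_starts()
        seg0 = st.seg.copy()  # snapshot: windows must not mix shifted tiles
        margin = 3 * st.guard  # wide margin keeps the circular wrap of the
        # applied FFT shift far away from the written tile
        for e in range(em.n_e):
            w = em.D[e]
            w = w - w.mean()
            shifts[e] = _bisect_shift(w, ref, tol, crop=st.guard)
        if self.cfg.align_shift_smooth > 1 and em.n_e > 2:
            from scipy.ndimage import uniform_filter1d

            # the scanner/EEG clock offset drifts smoothly; smooth the
            # estimates in the unwrapped domain (period: one sample) and
            # carry only the noise correction back to the wrapped values
            u = np.unwrap(shifts, period=1.0)
            s = uniform_filter1d(u, int(self.cfg.align_shift_smooth),
                                 mode="nearest")
            shifts = shifts + (s - u)
        for e in range(em.n_e):
            delta = shifts[e]
            if abs(delta) > tol:
                a = max(0, int(starts[e]) - margin)
                b = min(seg0.size, int(starts[e]) + st.n_l + margin)
                shifted = fft_shift(seg0[a:b], delta)
                c0, c1 = st.tile_bounds(e)
                new = shifted[c0 - a:c1 - a]
                st.artifact_seg[c0:c1] += st.seg[c0:c1] - new
                st.seg[c0:c1] = new
        st.subsample_shifts = shifts
        st.log.append(("align_subsample",
                       {"rms_shift": float(np.sqrt(np.mean(shifts ** 2)))}))

    def volume_gap_epochs(self) -> np.ndarray:
        return np.asarray(self.ts.volume_gap_after, dtype=np.int64)

    def block_remove_volume_artifact(self, st: _ChannelState) -> None:
        gaps = self.volume_gap_epochs()
        if gaps.size == 0:
            return
        em = st.epochs()
        alpha, x0 = solve_logistic_anchors()
        n_l, g = st.n_l, st.guard
        # x runs 0 (away from gap) -> 1 (at the gap) across the epoch
        x = (np.arange(n_l) + 0.5) / n_l
        w_before = logistic_weight(x, alpha, x0)
        w_after = w_before[::-1]
        starts = st.int_starts()
        for e in gaps:
            e = int(e)
            if e + 1 >= em.n_e:
                continue
            lo = max(0, e - 4)
            if e - lo < 4:
                logger.warning("channel %d: only %d epochs before volume gap "
                               "at epoch %d", st.ch, e - lo + 1, e)
            tmpl_before = em.D[lo:e + 1, g:g + n_l].mean(axis=0)
            hi = min(em.n_e, e + 6)
            if hi - (e + 1) < 5:
                logger.warning("channel %d: only %d epochs after volume gap "
                               "at epoch %d", st.ch, hi - e - 1, e)
            tmpl_after = em.D[e + 1:hi, g:g + n_l].mean(axis=0)
            for idx, w, tmpl in ((e, w_before, tmpl_before),
                                 (e + 1, w_after, tmpl_after)):
                c0, c1 = st.tile_bounds(idx)
                m = c1 - c0
                if m <= 0:
                    continue
                delta = (w * tmpl)[:m]
                st.artifact_seg[c0:c1] += delta
                st.seg[c0:c1] -= delta
            # bridge the gap itself linearly in the EEG data
            g0 = int(starts[e]) + n_l
            g1 = int(starts[e + 1])
            if g1 > g0:
                lo_v = st.seg[g0 - 1]
                hi_v = st.seg[g1]
                fill = np.linspace(lo_v, hi_v, g1 - g0 + 2)[1:-1]
                st.artifact_seg[g0:g1] += st.seg[g0:g1] - fill
                st.seg[g0:g1] = fill
        st.log.append(("remove_volume_artifact", {"n_gaps": int(gaps.size)}))

    def _build_matrix(self, st: _ChannelState, em: EpochMatrix):
        if st.pending_matrix is not None:
            A = st.pending_matrix
            st.pending_matrix = None
            return A
        spec = dict(self.cfg.avg_matrix)
        scheme = spec.pop("scheme", "fastr_slice")
        window = spec.pop("window", self.cfg.avg_window)
        if scheme == "allen":
            return averaging.build_allen(em.D, block=spec.pop("block", 100),
                                         **spec)
        if scheme == "farm":
            return averaging.build_farm(em.D, window=window, **spec)
        if scheme == "fastr_slice":
            return self._fixed(lambda: averaging.build_fastr_slice(
                em.n_e, window=window))
        if scheme == "fastr_volume":
            return self._fixed(lambda: averaging.build_fastr_volume(
                em.n_e, n_s=spec.pop("n_s", self.ts.n_s), window=window))
        if scheme == "moosmann":
            return self._fixed(lambda: averaging.build_moosmann(
                em.n_e, spec.pop("realign_file"),
                threshold_mm=spec.pop("threshold_mm", 0.8),
                n_s=spec.pop("n_s", self.ts.n_s or 1), window=window))
        if scheme == "corresponding_slice":
            n_s = spec.pop("n_s", self.ts.n_s)
            return self._fixed(lambda: averaging.build_corresponding_slice(
                em.n_e // n_s, n_s))
        raise ValueError(f"unknown averaging scheme {scheme!r}")

    def _fixed(self, builder):
        if self._fixed_matrix_cache is None:
            self._fixed_matrix_cache = builder()
        return self._fixed_matrix_cache

    def block_template(self, st: _ChannelState) -> None:
        em = st.epochs()
        A = self._build_matrix(st, em)
        contrib = compute_template(em, A, self.cfg.volume_gap_fill,
                                   out_len=st.seg.size)
        st.seg -= contrib
        st.artifact_seg += contrib
        st.log.append(("template", {"scheme": A.scheme}))

    def block_obs(self, st: _ChannelState) -> None:
        from .postprocess import OBSConfig, obs_clean

        em = st.epochs()
        cfg = OBSConfig(
            num_pcs=self.cfg.obs_num_pcs,
            segment_fraction=self.cfg.obs_segment_fraction,
            rng_seed=self.cfg.rng_seed + st.ch,
            coef_smooth=self.cfg.obs_coef_smooth,
        )
        cleaned = obs_clean(em, cfg)
        for e in range(em.n_e):
            st.write_tile(e, cleaned.D[e])
        st.log.append(("obs", {}))

    def block_lowpass(self, st: _ChannelState) -> None:
        from .postprocess import lowpass_post

        cutoff = self.cfg.lp_cutoff_hz
        if cutoff is None:
            return
        rate = self.rec.rate * st.factor
        x = st.work
        y = lowpass_post(x, cutoff, rate)
        st.work_artifact[:] += x - y
        x[:] = y
        st.log.append(("lowpass", {"cutoff_hz": cutoff}))

    def block_anc(self, st: _ChannelState) -> None:
        from .postprocess import anc

        x = st.work
        ref = st.work_artifact
        order = self.cfg.anc_order
        if order is None:
            order = max(4, int(round(self.n_l0 * st.factor)))
        y = anc(x, ref, order=order, mu=self.cfg.anc_mu)
        st.work_artifact[:] += x - y
        x[:] = y
        st.log.append(("anc", {"order": order}))

    BLOCKS = {
        "cut": block_cut,
        "paste": block_paste,
        "upsample": block_upsample,
        "downsample": block_downsample,
        "align_slices": block_align_slices,
        "align_subsample": block_align_subsample,
        "remove_volume_artifact": block_remove_volume_artifact,
        "template": block_template,
        "obs": block_obs,
        "lowpass": block_lowpass,
        "anc": block_anc,
    }

    # -- driver -------------------------------------------------------------

    def run_channel(self, ch: int) -> _ChannelState:
        st = _ChannelState(self, ch)
        for blk in self.cfg.sequence:
            if callable(blk):
                out = blk(st)
                if isinstance(out, averaging.AveragingMatrix):
                    st.pending_matrix = out
                continue
            self.BLOCKS[blk](self, st)
        if st.seg is not None:  # sequence ended before 'paste'
            if st.factor != 1:
                raise ValueError("sequence ended at an altered sampling rate")
            self.block_paste(st)
        return st


def run_sequence(
    rec: Recording, ts: TriggerSet, cfg: CorrectionConfig
):
    """Execute the configured block sequence on every channel.

    Returns ``(cleaned, artifact, log)``: the cleaned :class:`Recording`,
    the accumulated :class:`ArtifactEstimate` and a per-channel block
    log.  Channels listed in ``cfg.exclude_channels`` (labels or
    indices) are passed through untouched.
    """
    cfg.validate()
    excluded = set()
    for c in cfg.exclude_channels:
        if isinstance(c, str):
            excluded.add(rec.channel_labels.index(c))
        else:
            excluded.add(int(c))
    engine = _Engine(rec, ts, cfg)
    cleaned = rec.copy()
    artifact = ArtifactEstimate(np.zeros_like(rec.data))
    log = {}
    for ch in range(rec.n_channels):
        if ch in excluded:
            continue
        st = engine.run_channel(ch)
        cleaned.data[ch] = st.full
        artifact.data[ch] = st.artifact_full
        log[rec.channel_labels[ch]] = st.log
    artifact.provenance = [b if isinstance(b, str) else getattr(
        b, "__name__", "callable") for b in cfg.sequence]
    logger.info("correction sequence %s applied to %d/%d channels",
                artifact.provenance, rec.n_channels - len(excluded),
                rec.n_channels)
    return cleaned, artifact, log


def _bisect_shift(w: np.ndarray, ref: np.ndarray, tol: float,
                  max_iter: int = 30, crop: int = 0) -> float:
    """Fractional shift of ``w`` minimising the SSE to ``ref``.

    Bisection on [-0.5, +0.5] samples: the interval is repeatedly halved
    toward the side whose probe point has the smaller SSE, until it is
    narrower than ``tol``.  ``crop`` samples at each end are excluded
    from the SSE so that the circular wrap of the FFT shift cannot bias
    the optimum.
    """
    cache: dict = {}
    sl = slice(crop, w.size - crop) if crop else slice(None)

    def sse(d: float) -> float:
        if d not in cache:
            cache[d] = float(np.sum((fft_shift(w, d)[sl] - ref[sl]) ** 2))
        return cache[d]

    a, b = -0.5, 0.5
    for _ in range(max_iter):
        if b - a < tol:
            break
        m = 0.5 * (a + b)
        q1 = 0.5 * (a + m)
        q3 = 0.5 * (m + b)
        if sse(q1) < sse(q3):
            b = m
        else:
            a = m
    best = min(cache, key=cache.get)
    if sse(0.0) <= cache[best]:
        return 0.0
    return best
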