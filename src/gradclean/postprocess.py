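"""Residual-artifact removal after template subtraction.

Three tools: an optimal-basis-set (OBS) PCA that models what the
averaged templates missed, a zero-phase low-pass for residual
high-frequency spikes, and LMS adaptive noise cancellation (ANC) driven
by the reconstructed artifact as its reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .correction import EpochMatrix

logger = logging.getLogger(__name__)

__all__ = ["OBSConfig", "obs_clean", "lowpass_post", "anc"]

#: smallest cumulative explained-variance fraction for num_pcs='auto'
AUTO_VARIANCE_FRACTION = 0.90


@dataclass
class OBSConfig:
    """Configuration of the OBS-PCA residual cleaner.

    ``num_pcs`` is the number of principal components C forming the
    optimal basis set, or ``'auto'`` to pick the smallest C explaining at
    least 90% of the residual variance.  The PCA is fitted on a seeded
    random subset of ``segment_fraction`` of the epochs so that it does
    not lock onto activity recurring at exact multiples of the epoch.
    """

    num_pcs: int | str = "auto"
    segment_fraction: float = 0.25
    rng_seed: int = 0
    #: moving-average window (epochs) for the per-epoch OBS coefficients;
    #: 1 = strict per-epoch least squares.  The residual artifact evolves
    #: slowly across epochs, so smoothing suppresses the EEG projection
    #: noise in the fits without losing artifact model fidelity.
    coef_smooth: int = 1

    def __post_init__(self):
        if self.num_pcs != "auto":
            self.num_pcs = int(self.num_pcs)
            if self.num_pcs < 1:
                raise ValueError("num_pcs must be >= 1 (or 'auto')")


def obs_clean(em: EpochMatrix, cfg: OBSConfig) -> EpochMatrix:
    """Fit an optimal basis set to the residual epochs and subtract it.

    A temporal PCA is fitted on a random subset of the (demeaned)
    epochs; the strongest C components are least-squares scaled to each
    epoch and subtracted.  The projection never increases an epoch's
    sum of squares.
    """
    D = np.asarray(em.D, dtype=np.float64)
    n_e, n_l = D.shape
    if n_e < 2:
        raise ValueError("OBS needs >= 2 epochs")
    if not np.any(D):
        return replace(em, D=D.copy())

    rng = np.random.default_rng(cfg.rng_seed)
    n_sub = int(round(cfg.segment_fraction * n_e))
    n_sub = min(n_e, max(2, n_sub))
    subset = np.sort(rng.choice(n_e, size=n_sub, replace=False))

    X = D[subset] - D[subset].mean(axis=1, keepdims=True)
    # temporal PCA: components are length-n_l waveforms
    _, svals, Vt = np.linalg.svd(X, full_matrices=False)

    if cfg.num_pcs == "auto":
        var = svals ** 2
        total = var.sum()
        if total == 0:
            return replace(em, D=D.copy())
        cum = np.cumsum(var) / total
        C = int(np.searchsorted(cum, AUTO_VARIANCE_FRACTION) + 1)
    else:
        C = cfg.num_pcs
    if C >= min(n_e, n_l):
        raise ValueError(
            f"num_pcs={C} must be below min(n_epochs, epoch_len)="
            f"{min(n_e, n_l)}")
    C = min(C, Vt.shape[0])
    obs = Vt[:C]  # orthonormal rows

    cleaned = D - D.mean(axis=1, keepdims=True)
    means = D.mean(axis=1, keepdims=True)
    # least-squares scaling == orthogonal projection for orthonormal basis
    coeffs = cleaned @ obs.T
    if cfg.coef_smooth > 1:
        from scipy.ndimage import uniform_filter1d

        coeffs = uniform_filter1d(coeffs, int(cfg.coef_smooth), axis=0,
                                  mode="nearest")
    cleaned = cleaned - coeffs @ obs
    logger.debug("OBS removed %d components (subset of %d/%d epochs)",
                 C, n_sub, n_e)
    return replace(em, D=cleaned + means)


def lowpass_post(x: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass (order 5, applied forward-backward)."""
    nyq = rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff:g} Hz outside (0, {nyq:g}) Hz")
    b, a = butter(5, cutoff / nyq, btype="low")
    return filtfilt(b, a, x)


def anc(
    signal: np.ndarray,
    reference: np.ndarray,
    order: int | None = None,
    mu: float | None = None,
) -> np.ndarray:
    """LMS adaptive noise cancellation.

    An adaptive FIR filter driven by ``reference`` (the reconstructed
    artifact) is iteratively adjusted so its output tracks whatever part
    of ``signal`` is correlated with the reference; that output is
    subtracted.  ``order`` defaults to one slice period (set by the
    caller) and ``mu`` to ``0.01 / (order * var(reference))``, which
    normalises the convergence rate across artifact amplitudes while
    keeping the LMS misadjustment noise well below the EEG level.
    """
    signal = np.asarray(signal, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if reference.shape != signal.shape:
        raise ValueError("reference must have the same length as signal")
    ref_var = float(np.var(reference))
    if ref_var == 0.0:
        logger.warning("ANC reference has zero variance; returning input")
        return signal.copy()
    if order is None:
        order = 32
    order = int(order)
    if mu is None:
        mu = 0.01 / (order * ref_var)

    n = signal.size
    w = np.zeros(order)
    out = signal.copy()
    r = reference - reference.mean()
    for i in range(order - 1, n):
        window = r[i - order + 1:i + 1][::-1]
        y = float(w @ window)
        e = signal[i] - y
        out[i] = e
        w += 2.0 * mu * e * window
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("ANC diverged (non-finite output); "
                                 "reduce mu")
    return out
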