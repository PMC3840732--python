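"""Builders for the epoch-averaging matrix **A**.

The template-generation step of every subtraction algorithm is expressed
as an ``n_e x n_e`` weight matrix A: the artifact template of epoch *e*
is the linear combination ``sum_f A[e, f] * D[f, :]`` of all epochs, so
templates for all epochs are obtained with a single product ``N = A @ D``.
Each published scheme is one recipe for filling A:

* :func:`build_allen` — block-wise averaging with a 0.975 correlation gate
  (averaged artifact subtraction, AAS).
* :func:`build_farm` — per-epoch selection of the best-correlated epochs
  within a sliding window (FARM).
* :func:`build_fastr_slice` — moving average over every second neighbour
  slice (FASTR with slice triggers).
* :func:`build_fastr_volume` — corresponding slices of neighbouring
  volumes (FASTR with volume/section triggers).
* :func:`build_moosmann` — sliding windows that never span a
  super-threshold head movement (realignment-parameter informed).
* :func:`build_corresponding_slice` — corresponding slices across all
  volumes.

Every nonzero row of A sums to 1 (templates are averages) and all
weights are nonnegative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AveragingMatrix",
    "build_allen",
    "build_farm",
    "build_fastr_slice",
    "build_fastr_volume",
    "build_moosmann",
    "build_corresponding_slice",
    "read_realignment_params",
]

#: head radius (mm) used to convert rotations (rad) into arc displacement
HEAD_RADIUS_MM = 50.0


@dataclass
class AveragingMatrix:
    """An ``n_e x n_e`` nonnegative weight matrix with row sums 0 or 1."""

    A: np.ndarray
    scheme: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.float64)
        n, m = self.A.shape
        if n != m:
            raise ValueError("averaging matrix must be square")
        if np.any(self.A < -1e-15):
            raise ValueError("averaging weights must be nonnegative")
        sums = self.A.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-9
        if np.any(bad & (sums != 0.0)):
            raise ValueError("nonzero rows of A must sum to 1")

    @property
    def n_e(self) -> int:
        return self.A.shape[0]

    def apply(self, D: np.ndarray) -> np.ndarray:
        """Template matrix ``N = A @ D``."""
        D = np.asarray(D, dtype=np.float64)
        if D.shape[0] != self.n_e:
            raise ValueError(
                f"data matrix has {D.shape[0]} epochs, A expects {self.n_e}")
        return self.A @ D


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two epochs (0 for degenerate inputs)."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b) / (na * nb)


def build_allen(
    D: np.ndarray, block: int = 100, corr_threshold: float = 0.975
) -> AveragingMatrix:
    """AAS block-wise averaging with a correlation gate.

    Epochs are partitioned into consecutive blocks of ``block`` epochs
    (25 is the published choice for sequences with volume gaps, 100 for
    gap-free sequences).  Within a block the template is seeded with the
    mean of the first five epochs; each remaining epoch is admitted when
    its correlation with the current template exceeds ``corr_threshold``,
    updating the template.  Every row of the block, admitted or not, gets
    uniform weight over the admitted epochs.
    """
    D = np.asarray(D, dtype=np.float64)
    n_e = D.shape[0]
    if block < 5:
        raise ValueError("Allen block size must be >= 5")
    A = np.zeros((n_e, n_e))
    for b0 in range(0, n_e, block):
        b1 = min(b0 + block, n_e)
        idx = list(range(b0, b1))
        seed = idx[: min(5, len(idx))]
        admitted = list(seed)
        template = D[admitted].mean(axis=0)
        for e in idx[len(seed):]:
            if _corr(D[e], template) > corr_threshold:
                admitted.append(e)
                template = D[admitted].mean(axis=0)
        w = 1.0 / len(admitted)
        for e in idx:
            A[e, admitted] = w
    return AveragingMatrix(A, "allen",
                           {"block": block, "corr_threshold": corr_threshold})


def build_farm(
    D: np.ndarray, window: int = 50, n_best: int = 12
) -> AveragingMatrix:
    """FARM: per epoch, average the best-correlated epochs of a window.

    For epoch *e* the ``window`` temporally nearest epochs (excluding *e*
    itself) are candidates; the ``n_best`` with the highest correlation
    to epoch *e* form its template with uniform weights.  Equal
    correlations are broken toward the temporally nearest epoch, then the
    lower index.
    """
    D = np.asarray(D, dtype=np.float64)
    n_e = D.shape[0]
    if window < n_best:
        raise ValueError("window must be >= n_best")
    if n_e < 2:
        raise ValueError("need >= 2 epochs")
    A = np.zeros((n_e, n_e))
    k_best = min(n_best, n_e - 1)
    for e in range(n_e):
        order = sorted(
            (f for f in range(n_e) if f != e),
            key=lambda f: (abs(f - e), f),
        )
        cand = order[: min(window, len(order))]
        ranked = sorted(
            cand, key=lambda f: (-_corr(D[e], D[f]), abs(f - e), f))
        sel = ranked[:k_best]
        A[e, sel] = 1.0 / len(sel)
    return AveragingMatrix(A, "farm", {"window": window, "n_best": n_best})


def build_fastr_slice(n_e: int, window: int = 30) -> AveragingMatrix:
    """FASTR slice-trigger matrix: every second epoch of a +-window/2 hood.

    Row *e* averages every second element of the ordered neighbour list
    ``[e-h, ..., e-1, e+1, ..., e+h]`` with ``h = window // 2`` (15
    epochs for the default window of 30 — only every second slice is
    used so the EEG stays uncorrelated between averaged slices).  Edge
    rows shrink the window symmetrically where possible.
    """
    if n_e < 2:
        raise ValueError("need >= 2 epochs for a sliding-window template")
    h = window // 2
    A = np.zeros((n_e, n_e))
    for e in range(n_e):
        m = min(h, e, n_e - 1 - e)
        if m == 0:  # at the very edge use the one-sided neighbourhood
            m = min(h, max(e, n_e - 1 - e))
            hood = [f for f in range(e - m, e + m + 1)
                    if f != e and 0 <= f < n_e]
        else:
            hood = [f for f in range(e - m, e + m + 1) if f != e]
        sel = hood[::2]
        A[e, sel] = 1.0 / len(sel)
    return AveragingMatrix(A, "fastr_slice", {"window": window})


def build_fastr_volume(
    n_e: int, n_s: int, window: int = 30
) -> AveragingMatrix:
    """FASTR volume/section-trigger matrix: corresponding slices of
    neighbouring volumes within ``window`` volumes, excluding the own
    volume."""
    if n_e % n_s != 0:
        raise ValueError("n_e must be a multiple of n_s")
    n_v = n_e // n_s
    if n_v < 2:
        raise ValueError("need >= 2 volumes to average across volumes")
    h = max(1, window // 2)
    A = np.zeros((n_e, n_e))
    for v in range(n_v):
        vols = [u for u in range(max(0, v - h), min(n_v, v + h + 1)) if u != v]
        w = 1.0 / len(vols)
        for s in range(n_s):
            e = v * n_s + s
            for u in vols:
                A[e, u * n_s + s] = w
    return AveragingMatrix(A, "fastr_volume",
                           {"n_s": n_s, "window": window})


def read_realignment_params(path) -> np.ndarray:
    """Read an SPM-convention realignment parameter file.

    Whitespace-separated text with >= 6 numeric columns per row (3
    translations in mm, 3 rotations in rad), one row per volume.
    """
    params = np.loadtxt(path, ndmin=2)
    if params.shape[1] < 6:
        raise ValueError(
            f"realignment file needs >= 6 columns, got {params.shape[1]}")
    return params[:, :6]


def build_moosmann(
    n_e: int, realign_file, threshold_mm: float = 0.8,
    n_s: int = 1, window: int = 30,
) -> AveragingMatrix:
    """Realignment-parameter informed averaging matrix.

    The per-volume movement is the maximum absolute inter-volume change
    of the six realignment parameters (rotations converted to arc length
    at a 50 mm head radius).  Averaging windows never span a movement
    larger than ``threshold_mm``: the corresponding-slice sliding window
    is restricted to the contiguous run of still volumes containing the
    current one, so the template restarts after each movement.
    """
    params = read_realignment_params(realign_file)
    n_v, rem = divmod(n_e, n_s)
    if rem != 0:
        raise ValueError("n_e must be a multiple of n_s")
    if params.shape[0] != n_v:
        raise ValueError(
            f"realignment file has {params.shape[0]} rows for {n_v} volumes")
    disp = np.abs(np.diff(params, axis=0))
    disp[:, 3:] *= HEAD_RADIUS_MM
    move = disp.max(axis=1)  # movement between volume v and v+1
    boundaries = np.nonzero(move > threshold_mm)[0]  # after volume b

    seg_start = np.zeros(n_v, dtype=int)
    seg_end = np.full(n_v, n_v, dtype=int)
    for b in boundaries:
        seg_end[: b + 1] = np.minimum(seg_end[: b + 1], b + 1)
        seg_start[b + 1:] = np.maximum(seg_start[b + 1:], b + 1)

    h = max(1, window // 2)
    A = np.zeros((n_e, n_e))
    for v in range(n_v):
        lo = max(seg_start[v], v - h)
        hi = min(seg_end[v], v + h + 1)
        vols = [u for u in range(lo, hi) if u != v]
        if not vols:
            vols = [v]  # isolated volume: fall back to its own epochs
            logger.warning("volume %d isolated by movement boundaries; "
                           "template falls back to the volume itself", v)
        w = 1.0 / len(vols)
        for s in range(n_s):
            e = v * n_s + s
            for u in vols:
                A[e, u * n_s + s] = w
    return AveragingMatrix(
        A, "moosmann",
        {"threshold_mm": threshold_mm, "n_s": n_s, "window": window},
    )


def build_corresponding_slice(n_v: int, n_s: int) -> AveragingMatrix:
    """Average corresponding slices across all measured volumes."""
    n_e = n_v * n_s
    A = np.zeros((n_e, n_e))
    w = 1.0 / n_v
    for v in range(n_v):
        for s in range(n_s):
            e = v * n_s + s
            for u in range(n_v):
                A[e, u * n_s + s] = w
    return AveragingMatrix(A, "corresponding_slice",
                           {"n_v": n_v, "n_s": n_s})
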