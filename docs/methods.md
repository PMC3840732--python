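# Methods

This note documents the models, numerical choices and known limitations of
`gradclean`. It is written for users who need to judge what a passing test
suite does — and does not — say about their own recordings.

## Data model and conventions

A `Recording` is a channels × samples float64 matrix in microvolts with a
sampling rate, channel labels, a latency-sorted event list and an optional
fMRI acquisition span. Sample indexing is 0-based half-open everywhere
inside the package; the 1-based event latencies of the EEGLAB on-disk
format are converted at the I/O boundary, and sample data is stored float32
on disk (the `.fdt` payload) but promoted to float64 in memory for the
FFT-heavy processing. Only continuous datasets are supported.

## Trigger analysis and repair

Slice versus volume triggers are told apart by the mean inter-trigger
distance (below 1.0 s ⇒ slice). Missing triggers are diagnosed from gaps
whose length is within ±20% of an integer multiple k ≥ 2 of the median
spacing and filled with k−1 equally spaced events; the 20% tolerance
separates sampling jitter from real dropouts at typical rates. Oversized
gaps recurring quasi-periodically every n_s triggers are volume gaps and
are never filled; a single oversized gap that is not close to an integer
multiple is reported as ambiguous and left alone, because one occurrence
cannot be told apart from a recording glitch.

The acquisition span, when not stored with the dataset, is estimated from a
sliding-window standard deviation (window 100 ms) thresholded at 5× the
median windowed SD of the first second — robust because the artifact
exceeds the EEG by orders of magnitude. For volume triggers the slice
period is estimated from the spacing of maxima in the autocorrelation of
one volume interval.

## Prefiltering

Because the mean level differs between the sections before, during and
after the acquisition, filters are applied per section. Three designs are
offered: a windowed-sinc (Hamming) FIR of order 1000 applied zero-phase; an
ideal frequency-domain filter whose response is exactly 0 in the stop band
(applied without padding, so that it is a true projection: applying it
twice equals applying it once); and a Gaussian frequency response
exp(−ln2·(f/fc)²), the steepest transition with no overshoot anywhere,
with the half-amplitude point at the cutoff — a convention this package
fixes since several are in circulation. Frequency-domain sections are
demeaned, odd-reflected at both ends (so slow filters settle without edge
transients) and padded to a fast FFT length with a linear bridge closing
the circle; the mean is restored only for pure low-passes.

## The correction engine

A correction run is an ordered list of named blocks executed per channel.
Two signals are threaded through the run: the working segment
(successively cleaned) and the reconstructed artifact, initially zero.
Every block that modifies the segment adds its removed content to the
artifact, which makes the conservation contract
`cleaned + artifact == input` hold structurally, and gives the ANC stage
its reference signal for free.

Epoch geometry: from each slice trigger, the epoch length n_l is the median
inter-trigger spacing; a symmetric guard of 10% of n_l on each side gives
alignment headroom and is trimmed at subtraction. Epoch starts follow the
actual trigger latencies; where spacing is shorter than n_l the write-back
tile truncates, where it is longer the remainder falls to the volume-gap
fill rule. The default alignment reference is the middle epoch of the
acquisition (smallest worst-case drift distance to any other epoch).

Resampling: polyphase FIR interpolation by the configured integer factor
(default 10) with the anti-alias/anti-image cutoff at 0.5 of the original
Nyquist — a deliberately conservative cutoff that reconstructs smoothly
between samples. The long Kaiser design (128·k+1 taps, β = 10) keeps the
passband flat to ~1e−5 below 0.45 of the original Nyquist. The fine-rate
domain is used to *estimate* the artifact; at `downsample` the accumulated
artifact increment is brought back to the original rate and subtracted from
the retained original-rate segment. This increment formulation performs
the same subtraction as a literal up-process-down chain but conserves
exactly and never passes the untouched part of the data through the
band-limited interpolation (whose step response would otherwise distort
the abrupt artifact onset at the acquisition boundary).

Alignment: integer lags are found by cross-correlating each epoch (central
part only — the guards may hold unrelated content at the acquisition
edges) against the reference within ± one original sample. Fractional lags
apply the FFT time-shift rule and minimise the squared error to the
reference by bisection on [−0.5, +0.5] samples (terminating below 1e−3
samples, at most 30 halvings); the squared error is evaluated with the
guard samples cropped so the circular wrap of the FFT shift cannot bias
the optimum, and the shift is applied over a 3-guard margin for the same
reason. Because the scanner/EEG clock offset drifts smoothly, the engine
additionally smooths the estimated shifts across epochs (moving average of
5 epochs in the unwrapped domain); this suppresses the EEG-induced
estimation noise without biasing the drift line. The module-level
`align_subsample` operation performs the raw per-epoch estimate.

Volume gaps: gap positions follow from the trigger spacing inequality
between the last slice of one volume and the first of the next. The
transition templates are the averages of the five slice epochs on either
side of the gap, weighted by the logistic w(x) = 1/(1+e^(α(x−x0))) with
α ≈ −19.97 and x0 = 0.80 fixed by the anchors w(0.80) = 0.50 and
w(0.69) = 0.10 (x measured as the fraction of the slice interval toward
the gap; the third point w(0.57) ≈ 1% then follows). The gap itself is
bridged linearly.

Template subtraction: `N = A·D` with any of the averaging-matrix builders.
All builders produce nonnegative weights with nonzero rows summing to 1.
Scheme-specific notes: the block-wise (Allen/AAS) builder seeds each block
template with its first five epochs and admits the rest at Pearson
correlation > 0.975, and a rejected epoch is still corrected with the block
template; the FARM builder picks the 12 best-correlated of the 50 nearest
epochs with ties broken toward the temporally nearest, then the lower
index; the every-second-slice builder takes every second element of the
ordered ±15-epoch neighbour list (15 weights for the default window of
30); the realignment-informed builder converts rotations to arc length at
a 50 mm head radius and restarts templates after any parameter change
above the threshold (0.8 mm default). Sliding schemes exclude the current
epoch from its own template so its EEG is never subtracted from itself.

## Post-processing

OBS-PCA: a temporal PCA is fitted per channel on a seeded random 25%
subset of the residual epochs (a subset, so the basis does not lock onto
activity recurring at exact epoch multiples); the strongest C components
form the optimal basis set, which is least-squares scaled per epoch and
subtracted. `num_pcs='auto'` picks the smallest C whose cumulative
explained variance reaches 0.9. The engine smooths the per-epoch scaling
coefficients across epochs (moving average, default 9 epochs): the
residual artifact amplitude evolves slowly (drift, respiration), while a
strict per-epoch fit also absorbs the epoch's own EEG along the component
shapes — roughly √(C/dof) of the per-epoch EEG energy, which is
substantial because a slice epoch holds only ~14 effective EEG degrees of
freedom. Smoothing averages that noise down while tracking the slow
amplitude changes. The standalone `obs_clean` defaults to strict
least-squares (`coef_smooth=1`), for which the per-epoch sum of squares
never increases.

Low-pass: order-5 Butterworth applied forward-backward (zero phase),
default cutoff 70 Hz.

ANC: an LMS adaptive FIR filter driven by the reconstructed artifact
removes whatever in the signal is still correlated with it. The automatic
order is one slice period; the automatic step size 0.01/(order·var(ref))
normalises convergence across artifact amplitudes while keeping the LMS
misadjustment noise well below the EEG level (converging within a few
hundred samples at typical rates).

## Evaluation indicators

All indicators demean per channel (or use ranges), so constant offsets
never matter. The median imaging artifact uses ten intervals of 1.15× the
slice period (the published convention allows 1.10–1.20; one value is
fixed for determinism) with start positions linearly spaced over the
acquisition, and the same computation on the merged non-acquisition data
as a baseline. Residual band activity averages ten equally spaced 3 s
windows in the time domain before the FFT; band edges {0.8, 4, 8, 12, 24}
Hz are half-open ([lo, hi)) so shared edges are never counted twice; the
median across channels is reported because the percentage differences are
not normally distributed. Power-density reduction reads the FFT bin
nearest each harmonic of the slice frequency (and the volume frequency),
squares the corrected/original magnitude ratio and averages the dB values
over channels. SNR uses S/(D−S) with S from the unimpaired sections;
channels with non-positive noise power are excluded and counted, since a
negative noise power is physically meaningless.

## The synthetic generator

The generator emulates the phenomena the pipeline must survive, with
defaults mirroring a standard EPI protocol: 250 Hz sampling, 21 slices per
volume, a 144 ms slice period with TR an exact multiple of the slice time
(no volume gap; a gap with its own transition transient can be configured),
10 s of artifact-free lead-in and lead-out, and an artifact amplitude of
100× the EEG RMS.

* **Artifact waveform** — a Hann-gated stack of slice-frequency harmonics
  with equal magnitudes and alternating signs. The gate makes the burst
  vanish with zero slope at every slice boundary, the way gradient
  waveforms return to zero between slices; the flat harmonic envelope
  reflects that the induced voltage follows dB/dt of the switched
  gradients, whose spike-like time course has comparable power across the
  first harmonics. The waveform is normalised to unit peak (it is odd
  about mid-epoch, so the within-epoch peak-to-peak range is exactly 2×
  the amplitude), and its 8 comb lines stay below the 0.5-relative
  interpolation cutoff.
* **Amplitude dynamics** — a linear drift (0.05/min) plus a
  respiratory-like sinusoidal modulation (2% peak at ~0.27 Hz), the
  documented reason block-wise templates and OBS exist.
* **Clock drift** — a fixed sub-sample offset accumulating per epoch
  (0.02 samples), emulating unsynchronised scanner and EEG clocks; trigger
  events sit at the rounded true onsets and the fractional truth is
  returned for calibration tests.
* **EEG model** — 1/f-power noise spanning 1.5–50 Hz plus a 10 Hz tone at
  10% of the noise RMS and a per-channel random phase. Activity slower
  than 1.5 Hz is modelled by the separate baseline-wander term (100 µV at
  0.05 Hz), which the 1 Hz high-pass prefilter removes. The 50 Hz upper
  limit keeps the EEG inside the flat passband of the 0.5-relative
  interpolation filter, so resampling is lossless on the EEG content.

What passing tests do *not* show about real data: real gradient artifacts
contain power beyond the interpolation cutoff (the conservative 0.5
relative cutoff then irreversibly smooths part of the artifact shape);
real EEG is not band-limited below half the Nyquist frequency, has
non-stationary spectra, and carries the ballistocardiogram, which this
package does not address; electrode-specific artifact waveforms can
decorrelate across the head in ways a single per-channel template handles
only approximately; and real trigger jitter is not a clean linear drift.
The synthetic validation therefore demonstrates the correctness of the
machinery and its calibration, not a guaranteed quality level on any given
recording.

## Validated configuration and problem sizes

The end-to-end validation (in `tests/test_acceptance.py`) runs the full
block sequence — cut, 10× upsample, integer and sub-sample alignment,
volume-artifact removal, template subtraction, OBS (C = 3), downsample,
paste, 70 Hz low-pass, ANC — with the block-wise averaging matrix
(block 100, gate 0.975) on the default protocol at 10 volumes × 21 slices
× 3 channels. On these conditions the slice-harmonic power drops by more
than 45 dB, the cleaned acquisition-region EEG correlates with the
ground-truth clean EEG at ≥ 0.95 per channel, and conservation holds to
floating-point precision. The sliding-window schemes reach lower
correlations under identical conditions (~0.89 for the 12-of-50 selection)
simply because their templates average fewer epochs and therefore carry
more EEG contamination; this is a property of the schemes, not of the
implementation. Ten volumes keep the whole suite fast while giving every
averaging window its full intended width.

## Known limitations

Ballistocardiogram correction, ICA- and wavelet-based extensions, and
spatial (across-channel) decompositions are out of scope. The engine
applies one identical block sequence to every channel. EEGLAB datasets are
supported in their continuous form only, and ICA fields of the EEGLAB
structure are not preserved across a read/write cycle.
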