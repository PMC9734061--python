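# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `tcsleep`, and what the synthetic-data tests do
and do not establish about real recordings.

## Conventions

- **Time**: all event times are seconds from recording start (float).
  Zeitgeber time is stored once, on the recording (`t0_zt`, hours after
  lights-on). Intervals are half-open `[start_s, end_s)`.
- **Vigilance states**: `{Wake, NREM, REM, Artifact}` scored in 1-s
  epochs. Artifact epochs break episode runs and are excluded from
  percent-time denominators (a flag includes them).
- **Phase**: for every band-limited signal the instantaneous phase is
  taken from the analytic signal after a zero-phase 4th-order
  Butterworth band-pass, with the convention **trough = 0°, peak =
  180°** (a +180° offset on the analytic-signal angle). A spindle
  locked to the slow-wave peak therefore has preferred phase 180°.
  The convention holds identically in the generator and every analysis
  function, which is verified by round-trip tests.
- **Units**: signals in µV; rates in /s, /min or /h as named.

## Synthetic polysomnography

The generator produces recordings with *known* ground truth so that
every analysis stage is testable by parameter recovery. It is a
phenomenological signal model, not a biophysical one.

**Vigilance states.** A semi-Markov chain with exponential episode
durations: Wake → NREM, NREM → REM with probability `rem_entry_prob`
(default 0.25, else back to Wake), REM → Wake. Mean episode durations
default to 100 s (Wake), 120 s (NREM), 60 s (REM) — typical of mouse
sleep, where NREM episodes last one to a few minutes. `fragmentation`
divides all means, so a fragmented condition has proportionally more,
shorter episodes while the time spent in each state is preserved — the
signature of fragmented rodent sleep. Durations are discretized to 1-s
epochs (each episode keeps at least one epoch).

**Signals** (default 200 Hz; real acquisitions are far faster, but all
analysis bands live below 20 Hz and every rate is configurable). Each
EEG/LFP channel carries independent 1/f^α Gaussian background noise
(α = 1, RMS 20 µV) plus *shared* oscillatory content — the slow
oscillation, spindles and theta model network-wide events, which is
what makes cross-region coupling recoverable:

- **NREM**: a slow oscillation `−(A/2)·cos(2πf t)` (f = 1 Hz, A =
  150 µV peak-to-trough) gated by the NREM sample mask, plus spindle
  events: 12 Hz sinusoids under a Hann envelope, duration uniform on
  0.5–1.5 s, envelope-peak peak-to-trough amplitude 100 µV (the classic
  "~100 µV, > 400 ms" rodent spindle), at 8 events per NREM minute
  (Poisson count). A fraction `couple_prob` (default 0.7) of envelope
  peaks is pinned to slow-oscillation phase `couple_phase_deg`
  (default 180°, the slow-wave peak); the rest land uniformly. Events
  are kept ≥ 0.25 s apart and wholly inside NREM episodes.
- **REM**: 7 Hz theta at 60 µV peak-to-trough.
- **EMG**: broadband noise, 40 µV RMS in Wake, 8 µV in sleep.

**Spike trains.** Per state, tonic firing plus bursts. Tonic spikes are
a dead-time-corrected Poisson process: inter-spike intervals are the
refractory period (set to the intra-burst ISI) plus an exponential
whose rate is inflated so the *output* rate equals the nominal
`tonic_rate_hz` (defaults 8/5/10 Hz in Wake/NREM/REM). Bursts
(20/min in NREM, rare elsewhere — the thalamic T-type pattern) contain
2–6 spikes at exactly 5 ms ISI and are guaranteed ≥ 100 ms of preceding
silence; tonic spikes falling inside a burst's protected window
(preceding silence, burst span, one trailing ISI) are removed, and the
dead time is enforced globally. Consequently the returned burst list is
*exact* ground truth under the generating criteria — the burst detector
must recover it perfectly, and does.

**Determinism.** One integer seed expands into fixed sub-streams
(hypnogram; events; one per channel; one per unit) via
`numpy.random.SeedSequence([seed, tag])`, so identical parameters give
bit-identical outputs and each product is independently reproducible.

**What passing tests do not show.** Real NREM slow waves are aperiodic
and asymmetric, spindles have variable intra-event frequency, episode
durations are not exponential, and artifacts are absent here. Recovery
results on this generator validate the *implementations* (and their
calibration under the stated SNR), not detector performance on real
data.

## Spectral analysis

Welch PSD with 8-s Hann-tapered windows at 75 % overlap and density
scaling; frequency resolution 0.125 Hz. State-restricted estimates
average modified periodograms over every window lying fully inside a
run of masked epochs (segmentation restarts at each run), so an
all-true mask reproduces the plain Welch estimate exactly.
Normalization divides by the trapezoidal total power over the full
computed range, interpreting "total power" as per-recording (whether
the reference analyses normalized per state or per recording is not
determinable; the mask argument lets callers do either). Band powers
are trapezoidal integrals with interpolated edges, so adjacent bands
add exactly. δ2 defaults to 2.75–3.5 Hz; the 2.5–3.5 Hz variant that
also circulates is provided as `DELTA2_BAND_WIDE`. The Hann taper is
used throughout (some MATLAB pipelines default to Hamming; the
difference is negligible for band integrals and the taper is
configurable at the call sites that matter). The SWA time course
computes a fully normalized PSD per time bin restricted to that bin's
NREM epochs, flags empty bins as missing (never interpolates), and
scales by the first non-missing bin or the mean.

## Spindle detection

Energy is the magnitude-squared CWT averaged over 13 center frequencies
spanning 10–16 Hz (complex Morlet `cmor1.5-1.0` by default; frequency
B-spline `fbsp2-1.0-1.5` passes the same suite), smoothed with a 0.1-s
moving average and divided by its NREM mean. Candidates are
contiguous stretches above `mean + 1 SD` (over NREM) containing at
least one sample above `mean + 2.5 SD` (hysteresis). Because both
thresholds are relative, detection times are invariant to signal scale.

**Boundary refinement.** A waxing-waning event extends beyond its
suprathreshold core (for a Hann envelope the core covers only ~55 % of
the support), so each edge walks outward downhill on the smoothed
energy to the nearest local minimum, stopping at the noise floor (the
NREM median energy) so boundaries never wander through background
stretches. On simulated data this brings measured durations within
±0.06 s of the injected mean while leaving recall/precision at 1.0;
without it durations are systematically ~40 % short.

Candidates closer than 0.1 s merge; events outside 0.4–2.0 s are
discarded (the > 400 ms floor is the classic rodent criterion; the 2 s
cap excludes fused delta-band contamination); events with < 50 % NREM
overlap are dropped and those between 50 and 100 % are flagged as
transition events. Peak amplitude is the peak-to-trough excursion of
the 10–16 Hz zero-phase-filtered signal within the event; peak
frequency is the wavelet center with maximal event energy.

## Coupling

**Slow-wave–spindle cross-correlation.** Slow-wave peaks are local
maxima of the 0.5–4 Hz signal inside NREM above the 75th percentile of
NREM peak heights (percentile configurable). The spindle envelope is
excised over ±2·max_lag around each peak and averaged; the result is
Pearson-correlated, lag by lag, against the peak-triggered slow-wave
template (±max_lag), keeping full overlap at every lag. The peak lag
is therefore the delay by which the spindle envelope follows the slow
wave; constructed delays of −0.5…+0.5 s are recovered to the sample.
At least 10 usable peaks are required.

**Modulation index.** Amplitudes are averaged within 18 phase bins and
normalized to a distribution P; MI = KL(P‖uniform)/log 18, the
normalized entropy deficit (0 for uniform, 1 for a single-bin
concentration; empty bins contribute 0·log 0 = 0). The preferred phase
is the amplitude-weighted circular mean. The comodulogram scans phase
centers (bandwidth ±0.4 Hz, floored at 0.05 Hz) against amplitude
centers (±2 Hz) and refuses colliding or super-Nyquist bands.

**Surrogate null.** Circular time-shifts of the amplitude series
(≥ 10 s, preserving autocorrelation — shuffling would not), 200
surrogates, p = (1 + #{MI_surr ≥ MI})/(1 + n). On independent noise the
p-values are uniform (KS test over 500 runs passes at α = 0.01), so MI
significance claims are calibrated.

**Cross-region coupling** samples region A's slow-oscillation phase at
region B's detected spindle envelope peaks and reports the circular
histogram, circular mean and resultant length.

## Unit activity

The spike-band filter is exactly the published acquisition design —
4th-order elliptic band-pass, 0.1 dB passband ripple, 40 dB stopband
attenuation, 600–4000 Hz — applied zero-phase (two passes double the
design ripple/attenuation in dB; the design response is what the
contract tests probe). Spike sorting is out of scope; analyses consume
spike-time tables.

Burst criteria default to the standard thalamic T-type definition
(intra-burst ISI ≤ 10 ms, ≥ 2 spikes, ≥ 100 ms preceding silence), all
three configurable and echoed in outputs. Detection is a single
left-to-right scan; interval comparisons carry a 1 ns tolerance so
spike times one float-ulp off a criterion boundary classify by their
nominal value. The scan is provably equivalent to maximal-ISI-chain
enumeration, and the suite checks exact agreement with an independent
brute-force oracle on 1000 random trains. Transition PETHs require
≥ 20 s flanking runs on both sides (mirroring the stable-episode
threshold); per-bin rate is total spikes/(n_transitions × bin width).

## Numerical and design choices

- Episode absorption (`interruption_s`) defaults to 0 — off — because
  the consolidation rule is only defined for latencies (stable run
  ≥ 20 s); absorption absorbs only runs flanked by the same state and
  never Artifact.
- `min_dur_s = 0` disables the episode-duration filter; a nonzero value
  below one epoch is rejected as contradictory.
- Latency uses the remaining duration of a run already in progress at
  the reference time, and returns `None` (never 0) when no stable run
  exists. REM latency uses the same 20-s rule as NREM.
- Analysis windows are user-supplied; episodes count toward the window
  containing their start.
- Degenerate inputs raise typed errors (`ParameterError`,
  `InsufficientDataError`, `InsufficientEventsError`, `FormatError`)
  rather than returning sentinel numbers; undefined means are `None`.
- EDF export is 16-bit with per-channel symmetric physical ranges and
  1-s records (quantization step ≈ 2·max|x|/65535); the float32 binary
  + JSON sidecar format is lossless for round-trip-exact workflows.
  EDF files are read back through `mne`.
- JSON outputs are written with sorted keys and fixed float repr; the
  end-to-end pipeline is byte-deterministic for a fixed parameter set,
  enforced by test.

## Problem sizes

The test suite exercises the detector-recovery conditions at ten
30-minute recordings and the surrogate calibration at 500 runs of 60-s
series; `scripts/acceptance.py` uses five 30-minute recordings, 200
calibration runs, 300 oracle trains and a 4-h architecture simulation —
sizes at which every sampling-error bound in the tests has comfortable
margin on a single CPU.

## Known limitations

- The generator's slow oscillation is a gated pure sinusoid; detectors
  tuned here may need re-thresholding on real, aperiodic slow waves.
- Spindle "amplitude" is peak-to-trough of the band-filtered trace;
  other conventions (envelope maximum, RMS) differ by fixed factors on
  the synthetic signals but not necessarily on real data.
- The comodulogram uses fixed bandwidths, not variable-Q filters; very
  low phase frequencies (< 0.25 Hz) inherit the 0.05 Hz band floor.
- Artifact handling is limited to the Artifact label: no automatic
  artifact detection is attempted.
- Group-level inference (ANOVA and friends) is deliberately out of
  scope; outputs are per-recording quantities for downstream
  statistics.
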