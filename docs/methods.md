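# Methods

This note documents the models and procedures the package implements, the
parameters that matter, and the choices made where the design was open.

## Behavioural state model

The wheel-speed trace is partitioned into three states. Candidate movement
runs are maximal runs of samples above the flicker threshold (0.25 cm/s).
Within a run, sub-runs above the locomotion threshold (2 cm/s) whose
trapezoidal distance integral reaches the minimum distance (2 cm) are
locomotion; the rest of the run is flickering; everything else is
immobility. Flickering epochs are flagged `excluded` and never contribute to
activity statistics.

Open choices: "instantaneous speed" is the provided sample (an optional
median filter exists but is off by default); runs separated by gaps are not
merged unless `min_epoch_gap_s > 0`; the 2-cm minimum applies per epoch.
Raising the locomotion speed threshold can only shrink total locomotion time
(tested as an invariant).

## ΔF/F and state peak statistics

F₀ is the mean over the three non-overlapping 1-s windows of lowest mean
fluorescence, selected greedily (ties resolved toward the earlier window);
%ΔF/F = (F − F₀)/F₀ × 100 pointwise, hence invariant under any
multiplicative rescaling of the raw signal. The noise SD used by the
transient detector is the SD of the raw signal inside the F₀ windows scaled
to ΔF/F units; transients are local maxima above 3× that SD separated by at
least 315 ms (the taller peak wins). Each transient's *peak signal* is the
mean ΔF/F over the 315-ms window centred on the peak (truncated and counted
at trace edges); peak signals are averaged within each behavioural period
and the period averages are averaged per state, giving the average peak
transient per state. With two imaging sessions the per-state values are
averaged again (S1, S2 → AVG).

## Otsu classification

The classification feature is the per-cell immobility/locomotion ratio of
the AVG peak statistics — scale-free across cells; a difference mode is
available. The threshold is scanned over the internal edges of a 256-bin
histogram spanning the feature range, maximizing the between-class variance
σ_B² computed on the actual sample; ties break toward the lower threshold;
η = σ_B²/σ_T². The identity σ_B² + σ_W² = σ_T² holds at the chosen
threshold to machine precision, and the binned scan agrees with an
exhaustive sorted-midpoint scan to 10⁻³ in η (both tested). All-identical
features raise a "no separability" error rather than returning a degenerate
threshold.

The scan operates on the raw ratio scale. On strongly skewed populations
Otsu's variance criterion can place the threshold inside the upper group's
lower tail rather than in the between-group gap; cells lying there are
assigned to the lower class even when the groups do not overlap. This is a
property of the criterion itself, not of the implementation.

## LFP events

Filtering uses 4th-order Butterworth band-passes applied forward–backward
(zero phase), so event times are not biased by filter delay; linearity and
passband gain are tested. Ripple detection works on the envelope —
rectified band-passed signal smoothed with a 10-ms moving average — against
background statistics over immobility samples: an event must reach
`threshold_sd` (default 5) SDs above the background mean at its peak, and
its extent runs where the envelope stays above a lower boundary level
(default 1 SD). The dual threshold is what makes event *durations*
meaningful: a Gaussian-envelope burst exceeds the 5-SD level only briefly
near its crest, so a single-threshold extent would systematically
under-measure duration. Events closer than 50 ms are merged, events shorter
than 50 ms are dropped, each event's spectral peak (zero-padded
periodogram) must fall inside 125–250 Hz, and the background is re-estimated
once with the initial detections excluded (further iterations change
results by < 1% on synthetic data).

Theta-run epochs are anchored to locomotion onsets (one epoch per
locomotion bout); theta power is the band-passed variance over the epoch and
epochs not exceeding the median immobility power are flagged. Because a
single epoch limits Welch resolution to ~1/duration, the pooled estimator
(`theta_peak_over_epochs`) concatenates all locomotion segments before the
Welch periodogram: discontinuities add broadband leakage but do not move a
narrowband peak.

Event-triggered averages interpolate the ΔF/F trace linearly at
event-relative lag times, so imaging and LFP clocks need not share sample
edges; events without a full window are dropped with a warning. Before/after
means over 500-ms windows (before onset, after offset) support the
ripple-modulation comparison. Group comparisons use the two-sided
Mann–Whitney test (exact enumeration when both samples are ≤ 25 without
ties).

## Intrinsic properties

Spikes are detected where dV/dt first exceeds 20 mV/ms (the standard
criterion; configurable) before each voltage peak; that crossing is the
spike threshold point. AP features follow the usual definitions: amplitude
threshold→peak, latency pulse-onset→threshold, half-width at half amplitude
with sub-sample interpolation, fast AHP threshold→trough within 10 ms of the
peak. When several sweeps in the +40…+60 pA range qualify, the lowest
current is used; no qualifying AP returns an explicit sentinel, never zeros.
Sag is V_steady − V_peak on the hyperpolarizing sweep whose steady state
(mean of the final 100 ms of the pulse) lies within ±3 mV of −100 mV, with
linear interpolation between bracketing sweeps otherwise.

## Synaptic analysis

Failure calling combines two criteria: the response-window mean (15 ms from
the expected latency) must exceed the baseline mean by 2 baseline SDs, and
the onset latency must lie within ±1 ms of the connection's median latency —
the constant-latency property is what separates small unitary events from
noise. Onsets are measured on a 1-ms-smoothed sweep at a 3-SD (of the
smoothed noise) level; smoothing suppresses false early crossings that would
otherwise scatter the latency estimates. Baseline SD is a robust (MAD)
estimate, and sweeps whose smoothed baseline strays beyond 4 SD are flagged
as containing spontaneous events and excluded.

Potency is the baseline-to-peak amplitude of the success-average trace
(lightly smoothed, 0.5 ms); onset = 10%-of-peak crossing; rise = 20→80%
crossing interval; decay τ from a monoexponential least-squares fit over the
90%→30% falling segment — starting just below the peak avoids contamination
by the rising exponential. PPR is measured on the all-sweep average
(failures included), second response against the extrapolated decay of the
first. During trains, the preceding response's decay is fitted on the
average trace and extrapolated under the next pulse; the corrected
amplitudes recover planted per-pulse amplitudes within 3% at 10/50/100 Hz
(tested against analytic superposition). Connection ratios carry Wilson
95% intervals.

## Electrical coupling

CC = ΔV₂/ΔV₁ with ΔV the mean over the last 200 ms of the step minus the
pre-step baseline; pairs are "coupled" at CC ≥ 0.01. The spikelet
decomposition takes the spike-triggered average of the follower cell over
[−10, +100] ms: positive component = max in 0–10 ms, negative = min in
5–100 ms, both minus the pre-event baseline (windows match the fast-spike /
slow-AHP timescales and are configurable). Spike synchrony uses spike start
times detected on 125-Hz high-pass filtered traces, a 5-ms correlogram bin,
and a chance normalization r₁r₂·bin·T for the central bin.

## Synthetic generators

The generators define the study conditions the analysis is validated under.

*Sessions.* Bout durations are log-normal (medians 6 s locomotion, 8 s
immobility, log-SD 0.4); flickering bouts (0.3–0.9 s, 0.3–1.8 cm/s) are
inserted at 30% of immobility→locomotion transitions. Locomotion speed is
generated by a latent Gaussian AR(1) process (200-ms correlation time)
mapped through the normal CDF and a piecewise log-linear quantile function
anchored at (Q1, median, Q3) = (5, 8.8, 30) cm/s: the marginal distribution
of locomotion samples matches those quantiles *exactly* regardless of the
smoothing, which a post-hoc moving average would not (it biases the median
of a right-skewed distribution). The LFP is white + 1/f noise (default SD
0.05 mV, half pink) carrying a 7.1-Hz theta sinusoid gated by a smoothed
locomotion mask and Gaussian-envelope ripple bursts (144.5-Hz carrier,
duration = 4 envelope-σ, default 70 ms) at Poisson times inside immobility
with ≥ 100 ms separation; burst amplitude is calibrated as
`ripple_snr_sd` × the SD of the band-passed noise floor, so detector SNR is
interpretable. Ca²⁺ traces are inhomogeneous-Poisson spike trains
(state-dependent rates; theta-off default 0.4 Hz immobility / 0.05 Hz
locomotion) convolved with a difference-of-exponentials GCaMP6f kernel
(rise 50 ms, decay 400 ms — conventional values, configurable; peak
normalized on the sampled grid so one spike contributes exactly
`unit_amplitude_dff`), plus Gaussian ΔF/F noise, re-expressed as raw
fluorescence around `baseline_f`. The default ripple rate (0.1 events/s of
immobility) yields on the order of 15 events per 5-min session. All
randomness flows from one session seed through named substreams
(behavior/lfp/ca/ephys), so identical configurations are bit-reproducible
and stages can be regenerated independently.

*In vitro.* uIPSC sweeps: each presynaptic AP releases with probability
`p_release` (default 0.4); successes add a difference-of-exponentials
current (rise 1 ms, decay 10 ms) of amplitude 16.3 pA × (1 + 0.15·N(0,1))
at a fixed 2-ms latency, in 2.5-pA Gaussian noise — the potency/noise regime
the failure-calling rules are designed for. The coupled pair is two passive
isopotential compartments (200 MΩ, τ_m 20 ms) joined by a 1.62-GΩ junction,
integrated by forward Euler at 10 kHz (the step must be < τ_m/5 or the
generator refuses); its steady-state division matches the closed form
R₂/(R_j+R₂) within 1%, and AP templates — 1-ms triangular spike (+80 mV)
with an exponential AHP (−8 mV, τ 50 ms) — are imposed on the driver cell's
voltage. Current-step families use a phenomenological sag: hyperpolarizing
responses are I·R[(1−e^{−t/τ}) − a(1−e^{−t/τ_sag})] (a = 0.15,
τ_sag = 150 ms), which has an analytic peak/plateau used as the test oracle;
suprathreshold steps clip at threshold and emit template APs.

What the generators do **not** emulate: real imaging artefacts (motion,
neuropil contamination, bleaching), non-sinusoidal theta waveform and
phase–amplitude structure, ripple-associated sharp waves, spike-history
dependence (bursting, adaptation) in the Ca²⁺ forward model, multivesicular
or history-dependent release, and active dendritic conductances in the pair
model. Passing tests therefore demonstrate correctness of the analysis
rules under the stated statistical structure, not robustness to every
pathology of real recordings.

## Problem sizes and determinism

Validation runs use desk-scale data: 2–6-min sessions, LFP at 2 kHz in most
tests (10 kHz where the full rate matters), 100-sweep uIPSC sets, and
50–100 random repetitions for population-level quantities. The acceptance
script derives all sub-seeds from one command-line seed via
`SeedSequence`, and re-running any stage with the same configuration and
seed reproduces its output bit-for-bit.

## Known limitations

- Ripple duration is envelope-threshold-defined; at SNRs well below the
  default 8 SD the boundary threshold clips tails and durations bias short.
- The "semi-automatic" event curation of interactive software is replaced by
  the deterministic envelope rule; borderline events may differ.
- Otsu on strongly skewed one-dimensional features can mislabel cells lying
  in the heavy tail between the groups (see above).
- The two-cell circuit is passive; spikelet shapes for cells with active
  subthreshold conductances will differ from the RC prediction.
- Cells with no transients in one behavioural state are excluded from
  classification (with a warning) rather than imputed.
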