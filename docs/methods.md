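# Methods

This note documents the models and procedures implemented in `cinphot`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Signal model and preprocessing

The acquisition model is a single femtowatt detector sampled at 10 kHz while
excitation LEDs alternate in 10 ms frames (4 ms on, 6 ms off): three channels
(565 nm sensor, 470 nm sensor, 405 nm isosbestic) for dual-sensor recordings,
two (565/405) when the blue line drives an opsin instead. Demultiplexing
averages the detector samples within each frame's on-window after discarding
the first 1 ms (`settle_ms`, LED/detector settling; exposed as a parameter),
timestamps the frame at the on-window center, and drops any trailing partial
cycle. Windows are half-open `[start, start + on_len)`.

Isosbestic correction fits the control onto each signal channel by ordinary
least squares over the whole session and takes
`dF/F = (signal − fitted)/fitted`. Two deliberate properties follow: the
result is invariant to affine rescaling of the control, and slow
photobleaching is absorbed because both channels bleach together — a known
simplification (no separate detrending is applied). The denominator is the
fitted control, not a running baseline, keeping the operation a pure
function of the two traces.

One implementation detail matters more than it looks: TDM channels are never
sampled at the same instant — on the three-channel schedule the isosbestic
frame trails the first signal frame by 20 ms. Fitting the channels without
accounting for this skew leaves a residual equal to the shared artifact's
time derivative times the skew (measured at ~0.007 dF/F std under the default
motion process with detector noise disabled), which systematically inflates
window statistics. The correction therefore interpolates the control onto
the signal channel's frame times before fitting.

## Event-aligned statistics

Alignment snaps events to the nearest frame of the trace's own grid — no
resampling — because the frame rate (33–50 Hz) is coarse relative to the
0.5–1 s analysis windows and interpolation would manufacture smoothness that
the downstream statistics could then exploit. Windows are half-open
`[−pre, +post)`; the event sample is the first post-event sample.

The ramp statistic is the max–min slope: the slope of the line connecting
the maximum and minimum of the signal in the 0.5 s window ending at approach
completion, first occurrence on ties, zero for a constant segment. The peak
statistic is the plain maximum within 1 s after the event (no
rectification). Both are unit-agnostic, so smoothed firing-rate traces
(Gaussian kernel, default SD 100 ms on a 100 Hz grid, reflected boundaries
so the rate integrates to the spike count) run through identical machinery.

The shuffle test compares the session-mean statistic over real events with
the 2.5th–97.5th percentile interval of the same mean recomputed at
pseudo-event times drawn uniformly from the session (margins of one window
at each end; 1000 shuffles; seeded). The null matches the number of real
events because the comparison is between session-level means; a per-event
null is exposed as an option. Pseudo-times are drawn without exclusion zones
around real events — the random-time null is deliberately assumption-free —
and significance is two-sided at 95%, with the direction of the observed
statistic reported separately so downward ramps remain distinguishable.
No multiple-comparison correction is applied across recordings; calls are
per-recording by design.

## Stimulation analysis

Evoked amplitudes are baseline-subtracted peaks (baseline: mean over 1 s
pre-train; window: 2 s after a single pulse, train duration + 2 s for
trains — measurement windows are not externally specified and are exposed as
parameters). The paired-pulse analysis scales the single-pulse template to
the measured first-pulse amplitude before subtracting it, so slow
session-level amplitude drift does not bias A₂. The summation analysis
shifts the single-pulse response by k/frequency; shifts are exact integer
sample offsets whenever the trace rate is commensurate with the pulse
frequency (true on the 10 kHz detector grid for 4/8/16 Hz) and linear
interpolation otherwise — frame-rate traces cannot satisfy exact
superposition because the pulse period is not an integer number of frames.

Repeated-measures ANOVA is computed directly from the closed-form
sum-of-squares decomposition (each effect tested against its own
effect-by-subject term). The direct implementation returns F = 0, p = 1 for
zero-variance tables where off-the-shelf routines return NaN; it is verified
in the tests against both a brute-force oracle and statsmodels' AnovaRM.
p-values come from the F distribution; no permutation variant is offered
here, mirroring classical reporting for these designs.

## Behavioral hazard analysis

Trial-initiation latencies are analyzed as a discrete-time hazard at 250 ms
bins: h_i = events_i / at-risk_i, censored trials leaving the risk set
without counting as events; the curve truncates with a notice if the risk
set empties. Curves pool trials across subjects by default (a
per-subject-then-average variant is exposed). The long-latency CDF uses
uncensored latencies > 1 s, normalized to the retained set. Per-bin
condition comparisons use a within-subject label-permutation test
(assumption-free, matching the repeated-measures design); bin-wise tests are
uncorrected, matching per-bin significance marks on hazard/CDF panels, and
this is deliberate. Completed-trial counts feed the same repeated-measures
ANOVA with Holm-corrected paired contrasts against vehicle (only
vehicle-vs-drug contrasts are of interest, so Holm rather than Tukey).

## Synthetic-session generator

The generator emulates, per channel,
`F(t) = baseline · exp(−t/bleach_tau) · (1 + dF/F_true(t) + motion(t))`,
multiplexed into one detector stream with additive Gaussian detector noise.
Motion is a low-pass (2 Hz, 2nd-order Butterworth) Gaussian process injected
multiplicatively and identically into signal and isosbestic channels — the
correction is only testable if a shared artifact exists. dF/F_true carries a
difference-of-exponentials transient (rise 50 ms, decay 500 ms, unit peak —
resembling published DA-sensor kinetics without matching any particular
recording) at each reward click, and a linear ramp ending exactly at each
food-port entry, relaxing back with the transient decay constant.

Defaults, chosen once as realistic recording conditions: session 600 s;
bleach tau 3600 s (gentle within-session bleaching); motion SD 5% of
baseline; detector noise SD 1% of baseline per 10 kHz sample (≈0.2% per
frame after on-window averaging); transient amplitude 0.02 dF/F; ramp
0.2 dF/F/s over 1 s; isosbestic baseline 0.7× the signal baseline (405 nm
excitation is dimmer). Clicks arrive at uniform 15–30 s gaps; collection
latencies are lognormal(μ=0.7, σ=0.6) s clipped to [0.1, 8] s so that both
sub-second and >2 s collections occur — needed to dissociate the click
response from the approach ramp. Neither the collection-latency nor the
initiation-latency distribution is externally constrained; these are
stand-ins.

Stimulation sessions add a phenomenological depression state s: each pulse's
amplitude is scaled by s (and by pulse width relative to 4 ms), after which
s ← s·(1 − depression_factor) and relaxes toward 1 with
`depression_recovery_tau`. `depression_factor = 0` yields an exactly linear,
shift-invariant generator — the oracle for the summation analysis. No
biophysical receptor-desensitization model is implied.

Spike trains are inhomogeneous-Poisson by thinning (base rate 10 Hz;
optional linear rate ramp before approach events). Initiation latencies are
sampled by discrete-time hazard at 250 ms bins (baseline hazard 0.15/bin,
mean latency ≈1.7 s; per-condition bin-wise multipliers; observation capped
at 10 s with censoring). An operant-session generator produces full
light-on/center-in/go-cue/choice event logs with 35–45-trial reward blocks
(10/50/90%), 500–1500 ms holds and hold-failure timeouts, with a known
trial plan; choices are random — no learning model is implied.

A single master seed is split into named substreams (events, motion, noise,
spikes, latency), so outputs are bit-reproducible and adding one noise
component never perturbs the others. Every generator returns its latent
truth (dF/F, rate function, hazard) so recovery tests never re-derive truth
from noisy output.

## Validation studies and their limits

`cinphot.studies` packages the replicate designs used for validation, and
`scripts/acceptance.py` re-runs the two headline ones:

* **Null calibration** — 200 sessions of 420 s (≈18 click trials each; this
  replicate design keeps a full study in the minutes range on one core)
  with ramp slope and transient amplitude set to zero but noise, motion and
  bleaching at defaults. The shuffle interval should contain the observed
  mean slope in ≈95% of sessions; both event-locked components are removed
  because the click transient's decaying tail would otherwise leak into
  short-latency pre-approach windows and turn a calibration check into a
  confound-sensitivity check.
* **Linear summation** — with depression and noise off, observed/predicted
  peak ratios at 4/8/16 Hz equal 1 to 1e-6, evaluated on the detector-grid
  evoked response where the pulse shifts are exact.

Further studies cover ramp-slope recovery across a 0.1–1.0 dF/F/s grid
(the max–min statistic carries a small positive noise bias, largest in
relative terms at the smallest slopes), hazard flatness and multiplier
recovery, per-bin false-flag calibration, and motion attenuation.

What passing does not show: the generator's motion is stationary and purely
multiplicative, bleaching is a single exponential shared exactly between
channels, transients are identical across events, and both sensor channels
carry the same truth signal. Real recordings violate all of these to some
degree — hemodynamic artifacts, wavelength crosstalk, sensor nonlinearity
and within-session kinetics changes are out of scope — so the benchmark
validates the statistical machinery, not sensor physics. Stimulation power
and wavelength metadata are carried but never enter any computation.
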