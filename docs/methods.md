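# Methods

## The analysis problem

Extracellular recordings from dorsal striatum in a hemiparkinsonian mouse
design carry three kinds of evidence: single-unit spiking (30 kHz wideband),
the local field potential (2 kHz, 0.5–250 Hz), and optogenetic stimulation
events (473 nm, 10 Hz trains of 20 ms pulses) that identify unit subtype.
The pipeline turns these into (i) sorted, quality-controlled units with
waveform metrics, (ii) putative D1-/D2-MSN labels, (iii) beta-band (12–30
Hz) LFP power, and (iv) group-level decisions for the four experimental
groups C, CE, PD, PE, alongside the behavioral indices (cylinder, pole,
apomorphine rotation).

No public recordings accompany this design, so the package includes a
generator that produces recordings with *known* ground truth under the same
statistical assumptions the analysis makes.  Every quantitative claim in
the test suite is made against that ground truth.

## Synthetic recordings

**Spike trains.** Each unit fires as a homogeneous Poisson process thinned
to a piecewise-constant rate and pruned to an absolute refractory dead time
(default 2 ms).  The dead time trims the realised rate by a factor of about
`1/(1 + rate·refractory)` (≈1% at typical MSN rates); tests that check rate
recovery use tolerances far wider than this bias.  During each light pulse
the rate becomes `base_rate · (1 + m)` starting at the opto latency after
pulse onset, where `m` is the ground-truth modulation (+ for driven D2
units, − for suppressed D1 units).

**Evoked spikes.** Rate modulation alone cannot reproduce the defining
feature of a directly ChR2-driven unit — a reliable spike within a few ms
of pulse onset.  A +20–50% rate increase on a 2–8 Hz unit leaves the
overwhelming majority of 20 ms pulses without any spike, so a first-spike
latency (which requires ≥ 25% of pulses to respond within 10 ms) would be
undefined.  Positively modulated units therefore also emit one evoked spike
per pulse at the opto latency with configurable probability (default 1.0,
optional jitter).  The two channels are separable by configuration: tests
of the *rate-modulation estimator* switch the evoked channel off, because an
evoked spike per 20 ms pulse contributes ~50 Hz of in-pulse rate and would
dominate the 20% modulation scale; tests of *latency and classification*
switch it on.  This mirrors the physiology: tagging identifies D2 units by
the evoked response, while the modulation sign separates driven from
suppressed populations.

**Waveforms.** Templates are sums of three Gaussians (small pre-peak, deep
trough, post-peak) with lobe widths well below the inter-lobe intervals, so
the ground-truth peak–trough and peak–peak durations equal the construction
parameters to under one sample at 30 kHz.  The template is renormalised so
the trough depth equals the `amplitude` parameter exactly; SNR is defined
as trough depth over the noise SD.  Noise is i.i.d. Gaussian — no line
noise, drift or electrode coupling — so the SNR of a rendered session is
exact by construction.

**LFP.** A 1/f^a background (spectral shaping of white noise, normalised to
`broadband_sd`) plus an independent band-limited Gaussian process (2nd-order
Butterworth around the beta centre, normalised to SD = `beta_amplitude`).
Band power in excess of background therefore scales with amplitude²; a
group contrast is injected purely through `beta_amplitude`.

**Group firing rates.** Per-unit D2-MSN baseline rates are drawn from gamma
distributions matched to the group means and SDs of the design
(C: 1.72 ± 0.52 Hz, PD: 6.40 ± 2.34 Hz, PE: 4.28 ± 1.28 Hz).  No group
statistic is printed for exercised controls, and exercise alone does not
change baseline MSN firing, so CE uses the C parameters.

**Determinism.** One master seed; each component (per-unit train, noise,
LFP, per-subject cohort) uses a child seed derived by hashing
`"{master}:{name}"`.  Identical configuration ⇒ bit-identical session.

## Spike sorting

Detection thresholds at `k·σ̂` (default k = 3) on the 300–6000 Hz zero-phase
filtered trace, with `σ̂ = MAD/0.6745` so the estimate is insensitive to the
spikes themselves; troughs closer than 1 ms merge.  For band-limited
Gaussian noise the expected rate of −3σ level crossings is
`f_eff·exp(−9/2)` ≈ tens per second at 30 kHz, so raw 3σ detection
necessarily admits noise events.  The pipeline handles this where a
practitioner does: snippets are clustered (PCA scores, Gaussian mixtures,
BIC over k = 1..8, seeded), and clusters are then gated by unit-level
quality — mean-waveform SNR ≥ 3 (the inclusion rule), a valid trough-first
biphasic shape, and the MSN criteria.  Noise events concentrate in a
cluster whose mean waveform is the noise autocorrelation around a trough:
narrow (~150 µs to rebound) and shallow, so the width gate removes it.  On
pure noise, accepted-MSN false positives are below 1 per second; on
two-template sessions at SNR 5–6, recall and precision exceed 0.95 with
adjusted label agreement above 0.9.

The ISI Poisson check fits an exponential to ISIs beyond the dead time and
computes a KS statistic; because the rate is estimated from the same data,
the naive KS p-value is conservative, so the null distribution is obtained
by parametric bootstrap (200 seeded replicates — the fitted-parameter
analogue of the Lilliefors correction).  Measured pass rate on true Poisson
trains is ≈ 1 − α.  Units with fewer than 50 spikes return an indeterminate
result, which does not veto the MSN gate (only an explicit failure does).

MSN criteria (rate ≤ 10 Hz, peak–trough ≥ 300 µs) are configuration
defaults standing in for laboratory-specific thresholds; they are exposed on
every entry point.

## Optogenetic tagging

Baseline rate is measured over the 60 s (configurable) before the first
stimulation epoch; in-pulse rate over the union of pulse-on windows, so
unequal durations are handled by working on rates, not counts.  Latency is
the median first-spike delay over responsive pulses (10 ms search window,
undefined when < 25% of pulses respond).  Classification: activated D2 iff
latency ≤ 5 ms and modulation ≥ +0.20; inhibited D1 iff modulation ≤ −0.20
(no latency requirement — a suppressed unit emits no evoked spike);
otherwise unresponsive.  Boundary values count as meeting the criterion,
with an absolute 1e-9 slack so rates landing exactly on the boundary are
not lost to floating-point rounding.  Population percentages use the full
classified-MSN count as denominator and round half-away-from-zero to one
decimal.

## LFP spectra

Welch's estimator, 2 s Hann segments, 50% overlap, one-sided density in
dB re 1 (unit)²/Hz; the beta summary is the mean dB over bins with
12 ≤ f ≤ 30 Hz inclusive.  Absolute dB levels depend on the amplifier
scale, so only differences and orderings between groups are interpreted.
The 0.5–250 Hz conditioning cascades separate high- and low-pass sections:
a joint band-pass with a 0.5 Hz edge at 2 kHz is numerically
ill-conditioned, and the sub-Hz pole rings for seconds, so the forward–
backward pass uses padding of `3·fs/lo_hz` samples.

## Group statistics

The design is a balanced split-plot: training × lesion between subjects
(the four groups), one repeated factor within subjects.  `rm_anova`
computes the classic sums-of-squares decomposition — between-subject
effects tested against subjects-within-groups, within-subject effects
against the subject × time residual.  It agrees exactly (F, df, p) with an
independent mixed-model implementation on designs both can express.  With
more than two repeated levels, Mauchly's test on the pooled within-cell
covariance decides whether the Greenhouse–Geisser-corrected p replaces the
uncorrected one.  Unbalanced or incomplete designs raise instead of
silently reweighting.

The decision procedure is fixed at α = 0.05: if **any** interaction term
(training:lesion, time:training, time:lesion, three-way) is significant,
simple effects of each between factor at each level of the other are tested
against the pooled subject error; otherwise the main effects are
interpreted.  With four interaction gates the null probability of the
main-effects branch is 0.95⁴ ≈ 81%, and the terminal tests hold the nominal
5% size (orthogonal contrasts in a balanced design keep the branch
selection nearly independent of the terminal statistics).  LSD pairwise
comparisons are computed unconditionally but every row carries an
`omnibus_significant` flag so unprotected use is visible.  Pre/post-light
contrasts use the paired t test, with exact handling of zero-variance
differences (identical vectors ⇒ p = 1).

## Problem sizes and what the tests show

Test and acceptance workloads use desk-scale sessions: 60 s two-template
sorting sessions, 150–900 s tagging protocols, cohorts of 20 units per
group, 100–500 replicate null simulations.  These sizes put Monte-Carlo
error well inside each asserted tolerance.  Passing tests demonstrate
correctness of the algorithms under the generator's assumptions (Poisson
spiking, Gaussian noise, stationary rates, single channel); they do not
certify performance on real tissue, where bursting, drift, overlapping
spikes and non-Gaussian noise violate those assumptions.  Multi-channel
geometry is metadata only; no volume conduction is simulated.

## Known limitations

- The sorter has no overlap decomposition; coincident spikes closer than
  the dead time merge into one detection.
- The ISI bootstrap (200 replicates) bounds the attainable p-value
  resolution at ~0.005.
- The split-plot ANOVA requires balance; real cohorts with dropout need a
  mixed-effects model, which is out of scope.
- `classify_msn` thresholds and the tagging windows are defaults, not
  measured constants; they are exposed in `PipelineConfig`.
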