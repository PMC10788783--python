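# Methods

`drybench` re-implements, as a tested and reusable pipeline, the benchmarking
methodology used to compare dry high-density EEG electrode arrays against
gelled Ag/AgCl reference electrodes, together with a synthetic
spatio-temporal EEG generator that encodes the signal structure those
analyses rest on. This note describes the models, the defaults and their
rationale, the numerical choices, and what the synthetic conditions do and
do not establish about real recordings.

## The synthetic EEG model

Real scalp EEG has no ground truth, which is why electrode benchmarking
compares sensors against each other. The generator turns that logic around:
it produces multichannel recordings from a known statistical model so every
analysis stage can be validated against stated ground truth.

**Spatially correlated band fields.** Each frequency band is an independent
band-limited Gaussian random field over the scalp patch. Pairwise
correlation between two scalp points at distance *d* follows a Gaussian
kernel K(d) = exp(−(d/λ)²). The correlation length λ shrinks with band
frequency — low-frequency scalp topographies are spatially smoother than
high-frequency ones — which is the mechanism behind the benchmark's two
headline spatial effects (high-frequency coherence between closely spaced
dry contacts; low-frequency advantage of large gelled contacts). The
Gaussian form is a modelling choice: it is smooth, positive semi-definite
and has a single parameter; nothing in the reference methodology prescribes
a functional form. Band synthesis is exact in the frequency domain
(brick-wall masked white noise, analytically normalised to the configured
RMS) and the spatial structure is imposed by a Cholesky factor of the
channel covariance, with 1e-10 diagonal jitter.

**Contact-disc integration.** An electrode does not sample the field at a
point: each channel is the average of the field over a fixed 37-point
hexagonal stencil spanning its contact disc (rings of 6k points at radii
kR/3, k = 0..3). The channel covariance is therefore the stencil-pair
average of K, computed in closed form rather than by simulating a dense
field — mathematically identical in distribution, and orders of magnitude
cheaper. Large 10 mm gelled cups self-average (spatially low-pass) the
field; 3 mm dry pillars barely do. `point_contacts=True` bypasses the
stencil so that pairwise correlation is exactly K(d), which the recovery
tests rely on.

**Alpha bursting.** The alpha band is multiplied by a shared two-state
Markov on/off envelope (exponential dwell times, default 0.5 Hz transition
rates, gain 3, smoothed by a 100 ms moving average). Because the envelope is
common to all channels, bursts raise alpha power and inter-channel alpha
coherence jointly — the empirically observed co-occurrence the benchmark
discusses. A two-state process is the simplest mechanism with this
property.

**Event-related template.** A stereotyped cue-locked waveform — a positive
Gaussian bump at 200 ms (σ = 30 ms, +4 µV) and a negative one at 400 ms
(σ = 50 ms, −3 µV) — is added identically on every channel at each scheduled
vigilance-task probe. The identical-template choice reflects that the
arrays span only ~2 cm, across which event-related potentials are nearly
uniform. Widths are Gaussian standard deviations.

**Trial schedule.** Probes follow a fixation delay drawn uniformly from
2–11 s plus a fixed 0.5 s per-trial overhead (response and turnaround).
With a 600 s block this yields 85 trials on average, matching the task
design the pipeline is meant to ingest. No cue is placed closer to a
recording edge than the cued-epoch window (−200..1000 ms) requires.

**Sensor noise and impedance coupling.** Per-channel white noise has
variance floor² + κ·Z, with Z the channel's area-normalised impedance in
kΩ·cm² and κ = 0.25 µV²/(kΩ·cm²); an independent per-channel 1/f stream
(RMS 1.5 µV, exponent 1, flattened below 0.5 Hz) represents drift and
electronics pink noise. Impedances are log-normal per electrode type with
medians 1.107 (gelled) and 3.948 (dry) kΩ·cm²; the log-dispersions (0.6488
and 1.0835) are calibrated so the model's quartile spread reproduces the
reported interquartile ranges (1.000 and 6.298 kΩ·cm²) at those medians.
Higher-impedance dry channels are therefore noisier, as in practice.

**Default band parameters.** Source RMS follows a 1/f trend scaled to give
~7–10 µV broadband channels: Delta 5.0, Theta 2.5, Alpha 2.0, Beta 1.0 µV;
correlation lengths λ = 60, 45, 35, 20 mm for Delta/Theta/Alpha/Beta.
Sampling rate 2 kHz, block length 600 s. All of these are config fields.

**What the generator does not model.** No biophysical head (conductivity
layers, dipole sources), no eye-blink or EMG artifacts, no hair/contact
mechanics beyond noise levels, no non-stationarity other than alpha
bursting. Passing tests therefore demonstrate that the *analysis machinery*
recovers known structure under realistic spectra, spatial correlation,
noise and impedance conditions — not that any electrode performs well on
real scalps.

## Preprocessing

Filtering uses a Hamming windowed-sinc FIR band-pass (order 3.3·fs per Hz
of transition bandwidth, rounded to even). The −6 dB cutoffs sit half a
transition bandwidth outside the pass-band edges: 0.5 and 35.5 Hz for the
1–35 Hz broadband filter with its 1 Hz transition. The symmetric odd-length
kernel is applied in a single pass with reflection padding, so filtering is
exactly zero-phase (a forward–backward pass would square the magnitude
response and move the −6 dB points). Because DC lies exactly at the
stop-band edge of the 1 Hz-transition high-pass side, the raw design leaves
about −46 dB of DC leakage; the kernel mean is subtracted to null DC
exactly, perturbing the pass-band response by under 0.02 dB. Narrowband
variants: Delta 1–4, Theta 5–7, Alpha 8–12, Beta 13–30 Hz (config-
overridable; some published figure captions use Theta 4–8 / Alpha 8–13, and
either convention can be configured).

Channel rejection applies only to dry channels — the gelled references are
the comparison anchors, and the criterion itself is correlation-based. The
reference methodology used an interactive channel-cleaning tool with visual
inspection; here the visual step is replaced by a deterministic criterion: a
channel is flagged when, in more than 50% of 5 s windows, its correlation
with the pointwise median of its 4 nearest retained dry neighbours falls
below 0.8, iterated to a fixed point. With fewer than 3 eligible channels
the criterion is undefined and rejection is skipped with a warning.

Artifact rejection is robust-amplitude based (not artifact subspace
reconstruction, which the benchmarking rationale explicitly avoids to keep
signals comparable): each channel is z-scored by median/MAD, and any 1 s
window where a retained channel exceeds |z| = 20 is masked. Channel
statuses and the sample mask are computed once on broadband data and
propagated verbatim to every band-filtered copy, keeping all versions
sample-synchronised.

Regular epochs are all possible non-overlapping 2 s windows, tiled greedily
left to right and restarting after each masked region (handling of
discontinuities is not prescribed by the reference methodology; greedy
restart is the simplest deterministic rule). Cued epochs are −200..1000 ms
around each probe, baseline-corrected by the per-epoch, per-channel mean
over −200..0 ms; epochs touching an edge or a masked sample are skipped and
counted.

## Electrode roles and pairs

AG is the lowest-impedance retained gelled electrode, AG2 the second;
MX-Near/MX-Far are the retained dry channels nearest/farthest from AG;
MX-Neighbor is the dry channel nearest MX-Near; MX-Q1..Q4 are the retained
dry channels nearest the four corners of the dry-grid bounding box (Q1 top
right, counter-clockwise). If a role's natural channel was rejected, the
nearest retained dry channel substitutes. All ties break by label sort
order, making assignment deterministic and permutation-invariant. The six
canonical similarity pairs are AG:AG2 (only when a second gelled channel
exists), AG:MX-Near, AG:MX-Far, MX-Near:MX-Neighbor, MX-Q1:MX-Q3 and
MX-Q2:MX-Q4; event-related analyses add the combined corner comparison
(both corner pairs share one distance). Geometry can force roles to
coincide (MX-Near may be a corner); coincident roles are kept, and
aggregates can be read either raw or deduplicated from the tidy tables.

## Metrics

Timeseries similarity is Spearman rank correlation on the concatenated
retained (unepoched) samples of each band-filtered pair — correlation
ignores temporal ordering, so mask-induced discontinuities are harmless.
Constant inputs yield a missing value, never zero. RMS amplitude is
computed per 2 s epoch and averaged.

Spectral estimates use Welch's method with 1 s Hamming windows (1 Hz
resolution), 50% overlap, constant detrending per segment, over 2–35 Hz.
Power is reported as 10·log₁₀(µV²/Hz); the dB reference is a fixed
convention of this package. Per-epoch dB spectra are averaged across
epochs, then across participants ("grand"), with across-participant
variances carried alongside.

Magnitude-squared coherence supports two aggregation modes. `"epoch"`
(default for reporting) forms MSC within each 2 s epoch (3 segments) and
averages across epochs — this mirrors the within-epoch-then-average recipe,
but a 3-segment coherence estimate carries an O(1) positive bias that no
amount of epoch averaging removes (independent channels plateau near 0.35).
`"pooled"` averages auto- and cross-spectra across all epochs before
forming the ratio; it is consistent, converging to true coherence as epochs
accumulate, and is the mode used wherever ground-truth recovery is asserted
(for a common source s with per-bin source/noise PSD ratio r, pooled MSC →
r²/(1+r)²; for point contacts it converges to K(d)²). Both modes are
invariant to per-channel linear rescaling and symmetric in channel order.
Epochs are weighted equally in all averages.

Split-half stability computes a spectral metric separately on the first and
second halves of the epoch sequence and correlates the two across frequency
bins (Spearman); fewer than 4 epochs yields a missing value.

## ERP and the permutation decomposition

ERPs are arithmetic means of cued epochs per time point; component
detection is an extremum search (maximum in 150–250 ms, minimum in
350–450 ms; a flat ERP degenerates to the window start with amplitude 0).
ERP similarity is Spearman correlation over the full epoch window.

The permutation analysis separates event-locked average similarity from
instantaneous shared activity: epoch i of one channel is matched with epoch
π(i) of the other for B random permutations (default 1000). Pearson
correlation is computed over the concatenation of matched epochs — one
correlation per permutation, matching how permuted similarity is summarised
as a single mean ± SD. Coherence pools cross- and auto-spectra across
matched pairs before forming the ratio; cued epochs (1.2 s) hold only a
single 1 s Welch segment, so a within-epoch coherence would be identically
1 and pooling is the standard multi-trial estimator. Cross-channel
permutations are uniform; self-pair permutations (AG:AG, MX:MX) are
derangements, so a fixed point never injects a trivially perfect match into
the null. For epochs sharing a deterministic template s with independent
noise of variance σ², the expected permuted Pearson r is
var(s)/(var(s)+σ²), which the tests verify at r = 0.5. Everything is
deterministic under the seed.

## Impedance statistics

Area-normalised impedance is raw kΩ × π(d/20)² with the contact diameter d
in mm. Outlier screening uses Tukey 1.5×IQR fences per electrode type
(interpreting "standard outlier detection"; under a normal distribution
this flags ≈0.7%; under the heavy-tailed dry log-normal it trims ~8% of
the upper tail, which biases the post-rejection median low — calibration
quantities are therefore reported from the raw model). The dry-vs-gelled
contrast is a two-sided Mann–Whitney test with average ranks for ties:
exact null distribution when n₁·n₂ ≤ 400 and tie-free, otherwise normal
approximation with tie correction. Quantiles use linear interpolation
between order statistics so medians and IQRs are bit-reproducible. At the
study's sample sizes (187 dry vs 9 gelled) and IQR-matched dispersions, the
measured power of this contrast is ≈0.95 at α = 0.01 and ≈0.7 at α = 0.001
— the nine-strong gelled group caps the achievable rank separation, so
claims of near-certain rejection at α = 0.001 do not hold under these
dispersions.

## Problem sizes and numerical choices

Recovery tests run at reduced sampling rates (200 Hz) and long durations
(600–1200 s) where precision matters, and at the full 2 kHz default
elsewhere; the band-ordering checks use the default 600 s / 2 kHz
conditions over 10–20 seeds. EDF output is 16-bit with a ±1000 µV default
physical range (quantisation ≤ 0.031 µV); the true sample count is stored
in the recording-id header field so round-trips are exact despite
whole-second record padding. All randomness flows from a single integer
seed; per-stage seeds are derived from the global seed, the stage name and
the participant index, and identical config + seed reproduces every table
byte for byte.

## Known limitations

The generator's spatial kernel is stationary and isotropic; real scalp
topographies are neither. Band fields are mutually independent, so
cross-frequency structure (beyond the shared alpha envelope) is absent.
The ERP template is spatially uniform, making inter-channel ERP
correlations optimistic relative to real gradients. The epoch-mode MSC
bias means absolute epoch-mode coherence levels should be compared only
within a fixed epoch/segment configuration. None of the preprocessing
defaults were tuned to real recordings; they are starting points exposed in
the config.
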