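# Methods

This note documents the models, conventions, numerical choices and known
limits of the `eegmst` pipeline in enough detail to reproduce or audit any
number it outputs.

## Data model and interchange format

A recording is a stack of equal-length epochs, `(n_epochs, n_channels,
n_samples)` in microvolts at sampling rate `fs`. The reference geometry is
64 scalp channels at 1024 Hz with thirty 4-s epochs per subject ×
condition (baseline, task), but nothing in the code depends on those
numbers. The interchange format is plain ASCII: a `# channels:` header,
`# epoch k` separators, rows = samples, tab-separated columns = channels,
six decimal digits (exact round trip at that precision). EDF/BDF ingestion
is delegated to `mne` when installed; the ASCII path is the tested
contract. Epoch selection from longer recordings takes the *first* n
consecutive epochs — deterministic, in place of manual artifact screening,
which is out of scope (synthetic data is artifact-free; real data should
be cleaned upstream).

## Filtering

Band-pass filters are windowed-sinc FIRs (Hamming) applied forward and
backward (`filtfilt`), hence zero-phase — a requirement, since a group
delay would shift instantaneous phases. The transition width is half of
min(low edge, bandwidth), floored at 0.5 Hz; the Hamming design rule
(numtaps ≈ 3.3·fs/Δf) then yields ≥ 50 dB stopband per pass, comfortably
more than 20 dB one octave outside the band. The tap count is capped at
roughly a third of the epoch length so the forward–backward padding fits
inside one epoch; in practice the cap binds only for the delta band at
short epochs, where sub-hertz transition bands are unattainable anyway.
Band edges are half-open `[lo, hi)` everywhere (filters and FFT bins), so
a bin at 8 Hz belongs to alpha, never to both theta and alpha.

## Spectral power

Per epoch and channel, a one-sided FFT power spectrum scaled so that the
sum over all bins equals the time-domain mean square (Parseval; enforced
by a 1e−6 relative-error test). Band power is the bin sum over `[lo, hi)`
(bin summation rather than trapezoidal integration; the difference is a
single boundary-bin effect at 0.25 Hz resolution). Relative power divides
by the power in the configurable total range, default 0.5–30 Hz — the
union of the four analysis bands, which makes the four fractions sum to
exactly 1. Fractions are averaged over epochs, then channels.

## Phase Lag Index

Instantaneous phase is the angle of the Hilbert analytic signal of the
band-filtered epoch. PLI = |mean over samples of sign(sin Δϕ)| with
sign(0) → 0, so two identical channels give exactly 0. No edge samples are
trimmed by default (the epoch ends contribute a few distorted phase
samples; at 4096 samples their influence is ≤ 0.1% and trimming is
exposed as an option rather than silently applied). PLI is always computed
within an epoch and then averaged — never on concatenated epochs. The
finite-sample floor of the estimator is E|mean of T signs| ≈ √(2/(πT))
for independent signs; for narrowband signals the effective number of
independent sign samples is set by the band's autocorrelation time, so the
observed chance level (e.g. ≈ 0.18 for theta over a 4-s epoch) sits well
above the white-phase value. Chance levels in tests are therefore
estimated by Monte-Carlo with independent channels through the identical
analysis path, not from the iid-sign formula.

## Minimum spanning tree

Kruskal's algorithm (hand-rolled union-find) on link distances 1 − PLI;
ties are broken lexicographically by (i, j) after the distance sort, so
equal-weight inputs still produce a deterministic tree; an optional
1e−12-scale seeded jitter enforces the strict-uniqueness assumption
instead. Metrics follow the standard tree conventions: betweenness
centrality is pair-normalized by 2/((N−1)(N−2)) so leaves score 0 and a
star hub 1; tree hierarchy uses the leaf *number*, T_H = L/(2·m·BC_max),
which places the star at exactly 0.5 (the leaf-*fraction* variant would
not); degree correlation is the Pearson correlation over symmetrized link
endpoint degree pairs, reported as undefined when every link joins the
same unordered degree pair (a star), where orientation-doubling would
otherwise manufacture an artifactual −1. Undefined R values are excluded
from epoch averages with the contributing count reported. Degree,
diameter and eccentricity are reported raw (hops) and normalized by m.
Per subject × condition × band, metrics are computed per epoch and
averaged arithmetically — never from an epoch-averaged matrix, whose tree
is a different object.

## Statistics

The mixed ANOVA is computed from explicit sums of squares rather than a
generic fitter so that the partial η² denominators are unambiguous: the
between-subjects error for the group effect, the subject × condition
error for condition and interaction. The within stratum uses the weighted
(group-size) orthogonal split of within-group condition effects, which
coincides with the textbook decomposition for balanced groups and matches
`pingouin.mixed_anova` on unbalanced ones (cross-checked in tests).
Greenhouse–Geisser ε is computed from the double-centered pooled
within-group covariance and applied to within-factor p-values when the
factor has more than two levels; at two levels sphericity is trivial and
ε = 1. BH-FDR goes through `statsmodels.multipletests` with the
brute-force step-up definition as the test oracle. The default FDR family
is all measures of one band (PLI, relative power and nine MST metrics),
at q = 0.10 with a stricter 0.05 also flagged; delta is computed but
excluded from the statistical family by default. Stepwise regression is
classical forward entry by smallest partial-F p < 0.05 with backward
removal at p > 0.10, iterated to a fixed point; selection stops once the
residual sum of squares is numerically zero, since partial-F tests on
~1e−16 residuals otherwise admit spurious predictors. Two-sided tests
throughout; no small-sample corrections beyond standard degrees of
freedom.

## Synthetic data generator

Per band b, channel i carries

    x_i(t) = Σ_b A_b [ √c_b · Re(S_b(t) e^{iδ_i}) + √(1−c_b) · n_{b,i}(t) ] + pink noise,

where S_b is a shared narrowband analytic signal (brick-wall-filtered
Gaussian noise, unit RMS), δ_i is a constant channel offset drawn
uniformly from ±[0.2π, 0.8π] — bounded away from 0 and π because PLI is
blind to 0/π lags by construction — and n_{b,i} is independent narrowband
noise in the same band. The coupling knob c_b interpolates between
exactly independent channels (c = 0) and perfect nonzero-lag locking
(c = 1); the mixture form was chosen over an explicit circular phase-noise
term because it makes the c = 0 endpoint *exactly* independent, which is
what the chance-level validation compares against. Volume conduction is
the zero-lag mixing x ← (1−v)x + v·x̄ (default v = 0.2); it raises
inter-channel amplitude covariance but not PLI. Pink noise is white noise
shaped by 1/√f in the FFT domain (default amplitude 2 µV RMS against band
amplitudes delta 4, theta 3, alpha 6, beta 2 µV — an alpha-dominant
resting spectrum). Default couplings (delta 0.3, theta 0.45, alpha 0.5,
beta 0.35) give mean PLI values of realistic magnitude.

Studies add multiplicative log-normal amplitude jitter (sd 0.10) and
additive coupling jitter per subject (sd 0.04, shared across conditions)
plus per condition (sd 0.02); these values were calibrated once so that a
20% coupling reduction in one group × condition is detectable at ≥ 80%
power with 31/24 subjects, the regime the statistics layer is meant for.
Group × condition × band effects multiply the coupling knob. All
randomness descends from one seed: `SeedSequence(seed)` spawns one child
per subject, which drives that subject's parameters and both recordings,
so any subject is reproducible in isolation.

What the generator does *not* emulate: biophysical head geometry and
realistic leadfields, non-stationarity within epochs, artifacts (blinks,
EMG), heterogeneous per-channel noise, or cross-band phase coupling.
Passing tests therefore certify the pipeline's correctness and
calibration on data satisfying the model's assumptions, not robustness to
real-world EEG pathology.

## Problem sizes in the validation suite

Full-pipeline statistical checks run at reduced scale chosen as the
smallest sizes that leave the tested property intact: type-I calibration
uses 2,000 null studies of 4+4 subjects, 16 channels, two 4-s epochs at
64 Hz (the size of an F-test does not depend on n; the empirical rates
sit at 4.4–5.5%); effect recovery uses 200 studies at the full 31/24
group sizes with 16 channels, four epochs, 64 Hz. Brute-force MST
validation enumerates all labeled trees via Prüfer sequences up to N = 6
and checks structural invariants on 1,000 random matrices up to N = 23.

## Known limitations

* The mixed ANOVA assumes complete within-subject data; incomplete
  subjects are dropped (with a warning), not imputed.
* The stepwise procedure inherits the classical caveats of data-driven
  selection (inflated R², unstable predictor sets at small n); it is
  provided because it is part of the analysis repertoire, not as a
  recommendation.
* Degree correlation is undefined on degenerate (single-link-type) trees
  and excluded from averages there; heavily star-like empirical trees can
  reduce the effective n of R comparisons.
* The delta band at 4-s epochs has only ~14 spectral bins and a filter
  constrained by the epoch length; its estimates are reported but
  excluded from inference by default.
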