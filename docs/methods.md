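# Methods

This note documents the models, numerical choices and known limitations of
`restband`. It describes what the code computes; every number quoted here is
produced by the package's own tests or scripts.

## Spectral estimation

Per subject and eye condition, the multichannel recording is cut into
contiguous, non-overlapping 1 s epochs (trailing partial epoch dropped).
Epochs whose peak-to-peak amplitude exceeds 150 μV on any channel are
rejected — a deterministic stand-in for interactive artifact screening,
adequate because the synthetic data contain no blink/cardiac artifacts.
ICA-based correction and channel interpolation are out of scope.

Each epoch is tapered and Fourier transformed with zero-padding ×2, giving
a 0.5 Hz grid from 1 s epochs; the periodogram is normalized by the taper
energy (units μV²/Hz). Densities are averaged over epochs, then over
channels, and restricted to the 2–47 Hz analysis range (91 bins).

Numerical choices:

* **Taper.** Default is a full Hann window. A 10%-edge cosine-ramp
  (Tukey α = 0.2) convention is available via `taper_fraction=0.2`, but it
  leaks ≈ 8% of a sinusoid's power outside a ±1 Hz neighborhood, which
  breaks the amplitude-consistency contract (a unit sinusoid must
  integrate to ≈ A²/2 within 5%); the full Hann keeps leakage ≈ 2%.
* **0.5 Hz from 1 s epochs.** Zero-padding interpolates the spectrum onto
  the half-Hz grid. Direct 2 s segmentation (`epoch_len=2.0,
  pad_factor=1`) is supported as the alternative reading.
* **Filtering.** A 1 Hz high-pass (Butterworth order 2, forward–backward)
  and 50 Hz notch are available for real recordings and bypassed by
  default for synthetic data.
* Band bin membership is half-open, `f_low ≤ f < f_high`, keeping adjacent
  anchored bands disjoint; band power sums a(f)·0.5 Hz over member bins.

## Alpha anchoring and the 30 variables

The individual alpha peak is the highest strict local maximum of a(f) in
7–13 Hz. Its prominence is the ratio of its density to a log-log linear
aperiodic fit over 2–47 Hz (excluding 6–14 Hz); `clear_peak` requires
prominence ≥ 1.25. Peakless spectra are reported as such, never with a
fabricated frequency, and subjects lacking a clear peak in *either*
condition are excluded (band anchoring is undefined for them). The 1.25
threshold and the 7–13 Hz search window are configuration, not claims about
the original screening procedure, which was not quantified.

Bands: alpha [peak−3, peak+2], theta [peak−6, peak−3] (lower edge clamped
at 2 Hz with a warning when the peak is below 8 Hz), beta 14–28, gamma
30–47, total 2–47 Hz; re-anchored per condition. Per band and condition the
pipeline computes absolute and relative power, alpha peak frequency/power,
theta/beta center of gravity (Σ a·f / Σ a over band bins) and the density
at the bin nearest the center of gravity (ties toward the lower
frequency — interpolation would also be defensible; nearest-bin is fixed
here). 15 parameters × 2 conditions = 30 features named
`{band}_{param}_{condition}`.

## Group statistics

Independent comparisons use the pooled-variance Student t (the published
df = n1+n2−2 rules out Welch), d_s = Δmean / pooled SD; paired comparisons
use the t on differences, d_z = mean/SD of differences. Identical paired
samples return t = 0 by convention; a non-zero constant difference (zero
variance) is an error. Two-sided p values; no multiple-comparison
correction anywhere, matching the source design. Conversion helpers operate
on printed statistics: d_s = t·√((n1+n2)/(n1·n2)), d_z = t/√n,
η²p = F·df1/(F·df1+df2).

The 2×2 mixed ANOVA is computed from the exact sum/difference
decomposition: subject means carry the between-group test, condition
differences carry the condition and interaction tests, each F equal to the
squared t of its stratum. With unequal groups the condition main effect
tests the *unweighted* mean of the two groups' condition effects (the
SPSS Type-III convention; pingouin weights by group size instead, and the
test suite checks both facts). η²p = SS_effect/(SS_effect+SS_error) within
the stratum.

## PCA, parallel analysis, regression

The 30 features mix Hz, μV² and fractions, so the PCA diagonalizes the
correlation matrix of z-scored features (unrotated); eigenvalues sum to 30,
scores are scaled to unit variance, and component signs follow the
largest-|loading|-positive convention. Horn's parallel analysis draws 900
same-shape standard-normal matrices, takes the 95th percentile of each
eigenvalue rank, and retains components from the top while
`observed − (percentile − 1) > 1`. The sequential (prefix) rule is used
deliberately: counting non-consecutive exceedances deeper in the spectrum
would retain ≥ 1 spurious component on pure noise in roughly a third of
seeds, while the prefix rule keeps that at the nominal ~5%.

Memory scores are modeled by OLS with intercept, age group (centered ±0.5
contrast, so component main effects are cross-group averages), the retained
components' scores, and all age × component interactions. Backward AIC
simplification repeatedly removes the single term whose removal lowers AIC
the most, never violating marginality (an interaction blocks its parents),
until no removal lowers AIC; the AIC sequence is non-increasing by
construction. Simplified and full models are compared by the incremental F
test F = ((RSS_r − RSS_f)/Δdf)/(RSS_f/df_f). Per-group component slopes
re-parameterize the *fitted* model with the group of interest as reference
level (identical column space, so the fit is unchanged) and use that
model's residual df. Published standardized coefficients are treated as
direction/significance anchors only, since the original score scaling is
unknown.

## Synthetic cohort generator

The generator is the package's test bed; its defaults are the study
conditions, not tuning knobs.

**EEG.** Target density per subject/condition:
`offset·f^(−χ) / (1 + (1 Hz/f)⁴) + Σ_b A_b·exp(−(f−c_b)²/2s_b²) + 2σ²/fs`
— an aperiodic 1/f^χ background with an amplifier-style 1 Hz high-pass
rolloff (without it, infra-slow 1/f content leaks through 1 s epochs and
inflates the 2–7 Hz estimates), Gaussian bumps per band, and a white
sensor-noise floor. Defaults: IAPF ~ N(10.38, 1²) Hz young and
N(9.56, 1²) Hz older (means as reported; the within-group SD was not
reported and 1 Hz is a configurable, conventional choice), eyes-open peak
0.2 Hz below eyes-closed; theta bump at IAPF − 4.5 Hz; alpha bump 6 (young)
vs 4 (older) μV²/Hz eyes-closed, ×0.45 eyes-open; theta 1.6 vs 1.0
(×0.8 open); beta 0.5 both (open ratio 0.85 young / 1.1 older); gamma 0.10
vs 0.12 (open ratio 1.1 / 1.4); offset 25 vs 18 μV²/Hz at 1 Hz, exponent
N(1.35, 0.12²). Only the IAPF means are anchored to reported values; the
other magnitudes encode reported effect *directions* at realistic
resting-EEG levels. Three of 27 older profiles (configurable fraction) are
generated with a zero alpha bump to emulate the peakless exclusions.
Time series are realized by random-phase spectral shaping; channels share
one oscillatory realization and receive independent backgrounds. A fast
path (`simulate_spectrum`) instead draws the epoch-averaged spectrum
directly, scaling each bin by Gamma(m, 1/m) averaging noise (m = epoch
count); both paths agree on band powers within sampling error and the fast
path powers the large simulation studies.

**Latent coupling.** A standard-normal factor z scales the theta/alpha/beta
bumps and the offset by exp(0.45·z), so the first principal component
tracks broadband oscillatory power (matching the reported composition of
the first component). The same z enters the memory model in the older
group only.

**Behavior.** Each recall choice succeeds with probability
p = σ(base − coupling·z + 0.4·e), e ~ N(0,1); a failure visits a random
non-goal pad, a success an unfound goal; trials end at the third goal (or
a 12-visit cap). Goal triples are drawn pairwise non-adjacent on a 3×6
grid (the real pad layout is not published; shared-edge adjacency on a
regular grid is the minimal faithful structure). Expected scores have the
closed forms E[CBE] = E[p+p²+p³], E[NET] = 10·E[p³]; no single p matches
both published means exactly, so the base logits (1.7096 young, 0.1848
older) balance the two deviations (each ≤ 0.09). The older-only coupling
1.3 was set by simulation so the age × component-1 interaction on NET is
detected (negative, p < .05) in ≥ 80% of cohorts at n = 21/24 — a planted
effect deliberately stronger than the marginal published one, sized for
reliable recovery; a side effect is somewhat larger older-group score SDs
than reported. Calibration used a dedicated seed block disjoint from the
evaluation seeds.

## What the synthetic data do and do not show

The generator reproduces the spectral shape, group/condition effect
structure, exclusion mechanism, score distributions and one latent
coupling. It does not simulate artifacts, volume conduction, channel
covariance beyond one shared oscillation, non-stationarity, or any
topography (8 generic channels by default). Passing tests therefore
validate the *analysis chain* — estimators, anchoring, statistics, model
selection — not claims about real recordings; analyses of the deposited
data must go through the real-data ingestion path.

## Problem sizes and determinism

Simulation studies run at: 50 subjects for alpha-peak recovery; 100 seeds ×
900 iterations for the two parallel-analysis calibrations; 200 cohorts each
for the coupling-detection and null-rate estimates; 500 subjects/group for
behavioral calibration — sizes chosen so each rate's Monte-Carlo error is
a few percent. All randomness flows from explicit seeds
(`numpy.random.default_rng`); identical configs give bit-identical cohorts,
trial logs and output tables (manifest hashes are compared in the tests).

## Known limitations

* The behavior model couples CBE and NET through one success probability,
  so the planted effect appears in both scores; the original data show it
  clearly only for NET.
* OLS on NET (a bounded count) is used exactly because the source analyses
  did; the null rejection rate of the interaction test measured over 600
  synthetic cohorts is ≈ 4.8%, so the approximation is adequate at this n.
* The aperiodic fit under the alpha-peak prominence rule is a plain
  log-log linear regression, not a full periodic/aperiodic decomposition.
* EDF/BDF writing supports the subset needed here: fixed 1 s records, one
  physical range per channel, integer sampling rates.
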