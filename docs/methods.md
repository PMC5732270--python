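# Methods

## The problem

Single neurons along the auditory pathway respond more strongly to a rare
(deviant, DEV) tone than to a repeated (standard, STD) tone in an oddball
sequence.  That difference — the *neuronal mismatch* — can arise from two
mechanisms: stimulus-specific adaptation (SSA; the standard's response is
suppressed by repetition) or genuine deviance detection (the deviant's
response is enhanced because it violates a prediction).  Control sequences
in which the same tone is equally rare but violates no regularity — the
*cascade* (all 10 tones in strict frequency order) and the
*many-standards* (all 10 tones in balanced random order) — separate the
two: with CTR the control response,

    iMM = DEV_n − STD_n,   iRS = CTR_n − STD_n,   iPE = DEV_n − CTR_n,

where `x_n = x / sqrt(DEV² + STD² + CTR²)` (Euclidean normalization), so
that `iMM = iRS + iPE` exactly, every normalized response lies in [0, 1],
and every index in [−1, 1].  A positive iPE is the signature of prediction
error; iRS quantifies repetition suppression.  This package implements the
full chain from sequence design to station-level statistics, plus a
synthetic generator that produces ground-truth data under either
mechanism so every stage can be validated without recordings.

## Stimulus design

Tone grids hold 10 frequencies geometrically spaced (0.5 octave default),
centered on a neuron's characteristic frequency.  All sequences are 400
tones at a constant rate (4 Hz subcortical, 3 Hz cortical; the SOA is
carried as metadata only, since every analysis operates on onset-aligned
windows).  Oddballs have 10% deviants (40 of 400), a 10-standard lead-in,
and at least 3 standards before every deviant.  Deviant placement samples
the gap lengths between deviants through the stars-and-bars bijection
(each of the 40 gaps gets its mandatory 3 standards, the remaining 230
standards are distributed as a uniformly random composition), which makes
the placement exactly uniform over admissible configurations without
rejection sampling.  The many-standards shuffle is Fisher-Yates followed
by local swap repair of adjacent duplicates (reshuffle on the rare stall);
exact uniformity over no-repeat arrangements is not claimed.  The cascade
is deterministic; the wrap from the last grid tone back to the first at
each cycle boundary is accepted as-is.  Deviants may occupy the final
position; no trailing-standard constraint is imposed.

## Response quantification

Per-trial spike times aligned to tone onset over [−75, 250] ms are
histogrammed in 1-ms bins, averaged over trials, and smoothed with a 6-ms
Gaussian kernel into a spike-density function (Hz).  The kernel is
truncated at the window edges without renormalization, so up to ~2% of the
mass of a spike within 3 SDs of an edge leaks out; the mass-conservation
test tolerates this.  The baseline is the mean rate over the 75 ms before
onset of the same raster.  The **baseline-corrected spike count (BCSC)**
is the area of the SDF above baseline over 0–180 ms, positive patches
only, so the measure is non-negative and targets excitatory responses
(inhibitory responses are out of scope).

For the oddball standard, only the last standard before each deviant is
analyzed (n = 40 trials, matching the deviant count and its adaptation
state).  When a tone is standard in both oddball directions the two STD
measures are averaged; when only one direction exists the single measure
is passed through with a provenance flag.

**Significance.** 1,000 null peri-stimulus histograms are simulated from
constant-rate Poisson spiking and pushed through the identical
baseline → SDF → positive-area chain (each null re-estimates its own
baseline); p = (g + 1)/(N + 1) with g the number of null BCSCs ≥ the
observed one.  The null rate is the *neuron's* spontaneous rate pooled
over the pre-onset windows of all its rasters (≈ 150 s of data), not the
40-trial per-condition estimate: the statistic itself is essentially
exact (empirical type-I error 0.051 at α = 0.05 with the true rate), but
plugging in the noisy 40-trial estimate inflates the type-I error to
≈ 0.09, while the pooled estimate keeps it at ≈ 0.06.  The per-histogram
baseline still performs the BCSC subtraction.  Points with no significant
excitatory response in any of DEV/STD/CTR (all p > 0.05; the boundary
p = 0.05 keeps the point) are excluded.

Frequency-response areas are summarized by the characteristic frequency
(significant response at the lowest intensity; largest response breaks
ties) and Q30 = CF / bandwidth of the contiguous significant band
containing CF at threshold + 30 dB.  A fragmented significant region at
that level flags the neuron untuned (the CF/BW30 convention is standard
but one of several).

## Synthetic generator

Each neuron has Gaussian spectral tuning (peak rate at CF, width in
octaves), a Gaussian temporal response kernel (latency 20 ms, SD 10 ms
default), and spontaneous Poisson firing (5 Hz default).  Adaptation is a
per-channel multiplicative state starting at 1: a presentation of tone
*j* drives channel *i* with spectral weight `w_ij = exp(−Δoct²/(2·bw²))`
and relaxes the state toward `adapt_floor` by `exp(−w_ij/τ)`.  This is
the standard narrow-channel SSA model; it has closed-form expectations on
any sequence, which the oracle tests exploit.  Deviant tones (and only
they — cascade and many-standards tones never qualify) are multiplied by
`1 + pe_gain`.  Spikes are Poisson counts per 1-ms bin (exact at the
analysis resolution), placed uniformly within their bin.

Scenario defaults (chosen once as plausible for the pathway; they are the
study conditions, not tuning knobs):

* `ssa_only` — `pe_gain = 0` everywhere; adaptation deepens along
  IC_L → AC_NL (τ 40→8 presentations, floor 0.55→0.20) with narrow
  cross-frequency spread (0.35 octave), so the deviant inherits
  adaptation from the nearby standard and the expected iPE is ≤ 0.
* `predictive_coding` — adaptation held common across stations
  (τ = 15, floor = 0.35) and `pe_gain` strictly increasing
  (0.10, 0.30, 0.55, 0.85, 1.20, 1.60 along the six stations).  Holding
  adaptation fixed isolates the deviance gain as the only station-graded
  effect, so the recovered iPE ordering is attributable to it.

Synthetic LFPs are sums of Gaussian deflections (defaults: N1 at 42 ms,
P2 at 95 ms, N2 at 165 ms) with per-condition amplitude scalings, plus
Gaussian noise smoothed with a 5-ms kernel to mimic the 3–50 Hz band;
sampling rate 1 kHz.  What the generator does *not* emulate: bursting and
refractory structure, rate nonstationarity, correlated noise across
trials, top-down state changes, and real LFP 1/f spectra — so passing
recovery tests demonstrates correctness of the analysis chain, not that
real recordings would behave this way.

## Population statistics

Station-level comparisons of the three matched conditions use the
Friedman test with Fisher's-LSD pairwise comparisons on rank sums
(SE = sqrt(n·k·(k+1)/6), two-sided normal p, deliberately uncorrected).
The prediction-error index is modeled two ways with dummy-coded OLS
(type-II ANOVA): `iPE ~ hierarchy × nucleus` (reference L, IC) and
`iPE ~ direction × SPL` (SPL in Bels = dB/10; reference descending, so
the "ascending" terms carry the direction effect).  A robust variant
(IRLS with Tukey bisquare weights) is exposed for outlier-heavy tables.
Multiple testing uses Benjamini-Hochberg at FDR = 0.1.  Minimum sample
sizes target 0.8 power for a two-sided one-sample t-test on the index at
effect max(0.05, |mean|) and the sample SD (solved via statsmodels, with
a noncentral-t scan as fallback; n is floored at 2).

## LFP analysis

The prediction-error potential is PE-LFP = mean LFP(DEV) − mean LFP(CTR),
tested at every time point with a paired two-tailed t-test across
recording sites (each site trace is a 40-trial average, hence
approximately normal).  The pointwise correction is configurable —
BH-FDR at q = 0.1 (default) or Bonferroni over the tested grid — because
both conventions are in use for this analysis and they answer slightly
different questions; maximal runs of the corrected mask are reported as
significant intervals.  The time-resolved index recomputes the BCSC in 12
consecutive 20-ms windows tiling [−50, 190] ms (same pre-onset baseline
for every window), renormalizes the triplet per window, and tests each
window's index against zero (signed-rank, BH-FDR over the 12 windows).
With the full [0, 180] ms window this reproduces the headline index to
1e-9 by construction (same code path).

## Spike quality

SNR is the peak-to-trough of the mean waveform over the pooled SD of the
residual samples (waveform minus mean) — the pooling choice reproduces
"amplitude relative to background noise".  ISI violations are the
pooled fraction of intervals under 4 ms.  The Mahalanobis profile
measures each waveform's distance to the set mean under the set
covariance (ridge 1e-6 × trace/32 — scaled to the data when the
covariance degenerates — whenever n ≤ 32 or the covariance is
near-singular); a single Gaussian cluster has median squared distance
≈ χ²₃₂ median ≈ 31.3, a mixture inflates it, and tighter-than-Gaussian
waveforms sit below (left skew).

## Numerical and design choices

* 1-ms bins everywhere; BCSC windows select bins by their centers, so the
  [0, 180] ms window integrates exactly 180 bins.
* Degenerate cases are flagged, not zeroed: all-zero triplets (undefined
  normalization), dev + std = 0 (undefined SSA index), zero-variance
  samples (degenerate power), < 2 spikes (undefined ISI fraction).  Such
  points are excluded from medians; they cannot pass the inclusion filter
  anyway.
* The cascade is the default control for headline outputs; many-standards
  is computed in parallel.  The STD direction-average precedes inclusion
  filtering.
* Pipeline runs are fully reproducible: every stochastic stage draws its
  seed from the master seed via `SeedSequence`, and the manifest records
  the spawned seeds and stage counts.

## Validation problem sizes

The validation suite uses sizes chosen to make each check statistically
decisive at desk scale: 10,000 random triplets for the decomposition
identity; 2,000 spontaneous-only neurons for Monte-Carlo calibration
(fraction flagged at α = 0.05 stays below 0.07); 20 replicates of
50 neurons/station for scenario discrimination (configured-gain rank
recovered with Spearman ρ = 1); 100 replicates of 1,500 points for
linear-model recovery (all six coefficients within 3 SE); 40 LFP sites
for difference-wave recovery and 1,000 noise-only replicates for its
false-positive rate; 300,000 intervals and 20,000 waveforms for the QC
formulas.  `scripts/acceptance.py` repeats the same checks (10 scenario
replicates) and writes the measured numbers to JSON.

## Known limitations

* The Monte-Carlo p-value is exchangeable only up to the plug-in
  spontaneous rate; with very short recordings (few trials to pool) it
  inherits the 40-trial inflation described above.
* Q30 is undefined for maps whose significant region is fragmented, and
  the nearest available intensity level stands in for threshold + 30 dB.
* Fisher's LSD on Friedman rank sums uses the large-sample normal
  approximation; at very small n the pairwise p-values are approximate.
* The generator's adaptation recursion is one standard choice among
  several (e.g. divisive or synaptic-depression models); conclusions
  about mechanism separation hold within this model family.
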