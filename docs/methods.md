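# Methods

This note records the statistical model, the signal-processing choices,
the synthetic-data design, and the numerical decisions behind
`speechnet`, in enough detail to reproduce or audit any stage.

## 1. Network model and estimation

Each speaker contributes one row of node variables: five acoustic
parameters (local jitter in percent, mean F0 in Hz, the F1/F2 ratio,
intensity in dB, speech rate in syllables/s) and optionally the ordinal
anxiety rating (0–3). The model treats the observed variables as monotone
transforms of a latent Gaussian vector, so dependence is summarized by the
Spearman correlation matrix (average ranks for ties; this is also the
reason an ordinal rating can enter the network directly). Rows with any
missing node value are dropped listwise — the EBIC's `n` term requires a
single consistent sample size. A non-positive-definite rank-correlation
matrix is repaired by clipping eigenvalues at 1e-6 and renormalizing to
unit diagonal; the repair is flagged.

The sparse precision matrix solves the graphical-lasso program with the
**diagonal unpenalized** (the psychometric-network convention; it also
makes the p = 2 solution an exact soft-threshold of the off-diagonal
correlation, which the tests exploit as a closed form). The solver is
ADMM: the proximal step for the log-det term is an eigendecomposition, the
L1 step a soft-threshold, with residual-balancing adaptation of the
penalty parameter so that eigenvalue-clipped (near-singular) inputs still
converge. Stopping is at normalized primal and dual residuals below 1e-7
(1e-8 for single fits), with a hard failure — reporting the duality gap
tr(SK) + λ‖K‖₁,off − p — if the iteration budget is exhausted. Kernels
are numba-compiled because the permutation and bootstrap procedures below
re-run the full path tens of thousands of times.

Model selection: λ is chosen on a 100-point log-spaced path from λ_max
(the largest absolute off-diagonal correlation, the smallest λ giving an
empty graph) down to 0.01·λ_max, minimizing
EBIC_γ = −2ℓ(K) + E log n + 4γE log p with
ℓ(K) = (n/2)(log det K − tr(SK)) and E the number of nonzero off-diagonal
pairs. γ defaults to 0.5 (sparsity-favoring). The additive Gaussian
constant −(np/2)log 2π is omitted: it is constant along the path and
cannot change the argmin; any external likelihood comparison must add it
back. EBIC ties resolve to the sparser (larger-λ) model. Edge weights are
the partial correlations of the selected precision matrix, with the
penalized (shrunken) estimates reported directly — no relaxed refit — as
is standard for this estimator.

Centrality is one-step expected influence (signed row sum), appropriate
when negative edges exist. Redundancy screening before estimation flags
node pairs with zero-order |ρ| ≥ 0.50 whose correlation profiles with the
remaining nodes differ significantly for fewer than 25% of those nodes;
the dependent-correlation test is Steiger's (1980) z with the
mean-correlation plug-in (the `hittner2003` back-transformed variant is
available). Samples below n = 10 are reported "untestable" rather than
silently passed. Layout for figures is Fruchterman–Reingold on |w| with a
fixed seed.

## 2. Stability and group comparison

*Edge accuracy.* Nonparametric bootstrap (default B = 1000): rows
resampled with replacement, the entire Spearman → glasso → EBIC chain
re-estimated per replicate, percentile 2.5/97.5 CIs per edge. Percentile
(not BCa) intervals are used deliberately — they match the convention of
the stability machinery this module mirrors and keep the test oracle
simple. Difference tests for edge pairs and EI pairs call a difference
significant when its bootstrap CI excludes zero; no multiplicity
correction is applied anywhere, matching the exploratory design.

*Centrality stability.* Case-dropping bootstrap over drop proportions
0.05–0.75 (step 0.05): at each drop, B subsamples without replacement are
re-estimated and their EI vector correlated (Pearson over the p nodes)
with the full-sample EI. The CS coefficient is the largest drop whose 5th
percentile correlation is still ≥ 0.7 (0 if none). Degenerate
correlations (zero-variance EI, failed fits) are scored below threshold —
a conservative choice. Reported quality flags: > 0.5 stable, 0.25–0.5
moderate, < 0.25 unstable. Drops leaving fewer than 3p rows are excluded
with a warning.

*Comparison.* The two-group test permutes group labels (sizes preserved)
with full re-estimation per permutation. Statistics: global expected
influence S = |Σw_A − Σw_B| over unique edges (so each group's node-EI
total is exactly twice its sum), the maximum absolute edge difference M,
per-edge |Δw|, and per-node |ΔEI|. p-values use the add-one estimator
(1 + #{perm ≥ obs})/(1 + P), bounded below by 1/(P+1). The compared
networks exclude the anxiety rating by default (it defines the groups);
passing `columns` explicitly includes it. A replicate or permutation whose
estimation fails is dropped and counted; more than 5% failures aborts.

All resampling draws from `numpy.random.default_rng(seed)`; a fixed seed
reproduces every CI bound and p-value bit-for-bit. The pipeline derives
one child seed per stage from a root `SeedSequence`.

## 3. Feature extraction

Signals are trimmed of leading/trailing silence (10 ms RMS windows,
threshold 0.05 of the maximum window RMS, configurable; all-silent input
is an error), pre-emphasized (y_t = x_t − 0.97x_{t−1}) and framed with a
512-sample Hamming window at 50% hop. Intensity is computed on the raw
(non-pre-emphasized, un-windowed) frame samples: pre-emphasis is a tilt
filter that would attenuate a low-formant vowel by tens of dB and turn
"intensity" into a spectral-tilt measure. The dB reference is full scale
plus a +91 dB calibration offset (absolute SPL is unrecoverable from a
file; the offset places conversational speech near 67 dB and cancels in
every correlation).

*Voicing* requires frame RMS above half the 0.3-quantile of frame RMS (a
silence gate) **and** a corrected normalized autocorrelation peak ≥ 0.45
in the F0 band. The frame autocorrelation is divided by the analysis
window's own autocorrelation (Boersma's correction); without it the peak
at the true period is attenuated relative to harmonic sub-lags whenever
the window holds only a few periods.

*F0* (default band 75–400 Hz): per voiced frame, candidate lags are local
maxima of the corrected autocorrelation whose uncorrected value clears a
floor of 0.15 (guarding against noise amplified by the correction at long
lags), scored with a small octave cost (0.02 per octave) that breaks the
exact tie between the true period and its integer multiples; the winning
peak is parabolically interpolated. Frame values more than 20–25% from
the track median are discarded as octave glitches before averaging.

*Jitter* is Praat-convention local jitter,
jitter = [ (1/(N−1)) Σ|T_i − T_{i−1}| ] / [ (1/N) ΣT_i ], reported in
percent by default, computed on cycle-level periods, not frame-level F0:
epochs are marked on the magnitude of the whole-signal 12th-order LPC
residual by sequential tracking (march forward/backward one expected
period at a time, taking the local maximum within ±0.25T — greedy global
peak-picking can alternate between primary and secondary excitation peaks
and fabricate jitter), then each consecutive pair of marks is refined to
sub-sample precision by maximizing the normalized cross-correlation of
adjacent cycle-length windows **of the residual** (the raw waveform's
resonator ringing biases alignment at high F0). Corrected periods outside
(0.75, 1.25)× the mean period (gaps, octave errors) are discarded.
Synthesis round trips put the remaining error below ~0.05 percentage
points across jitter 0–2%.

*Formants*: 12th-order autocorrelation-method LPC (Levinson recursion via
`scipy.linalg.solve_toeplitz`), with the signal decimated to 11.025 kHz
first — twelve poles model ~6 resonances, the right density for an
~11 kHz band, and the stated order would over-fit at 44.1 kHz. Candidate
resonances are polynomial roots with positive imaginary part, frequency
from the root angle and bandwidth −(sr/π)ln|root|, filtered to
90 Hz ≤ f ≤ Nyquist − 50 Hz and bandwidth ≤ 400 Hz; F1/F2 are the two
lowest survivors, averaged over voiced frames (frames with fewer than two
candidates are ignored). The formant path applies **no pre-emphasis** by
default: the synthetic source spectrum is flat, and pre-emphasizing it
biases F1 upward by 5–15%; for natural glottal sources (−12 dB/oct tilt)
the config exposes `formant_pre_emphasis` ≈ 0.97. Because LPC roots are
pulled toward strong harmonics when the analysis window resolves them,
the frame-averaged estimates are then refined by analysis-by-synthesis
against the harmonic envelope: harmonic amplitudes are read off an
averaged ~3-period-window spectrum, the other formants' two-pole
log-magnitudes (cascade filters add in log domain) are subtracted, and a
single resonator (center, bandwidth, gain) is least-squares fitted to the
residual amplitudes near each candidate, with amplitude-proportional
weights and the center constrained to ±0.8·F0 of the LPC value. The
refinement needs the F0 estimate and is skipped without one.

*Speech rate* divides a syllable count by the full (untrimmed) task
duration by default (`rate_denominator="speech"` switches to the trimmed
duration). The count comes from a synthesis annotation when available,
otherwise from a transcript by an orthographic heuristic: maximal vowel
runs (aeiouy) per word, minimum one per word.

Missing sub-features propagate as NaN with a recorded warning, never as
silent zeros; rows with any missing feature are excluded from network
estimation (listwise), consistent with the valid-participant convention
upstream.

## 4. Synthetic data

*Planted networks.* `build_precision` places minus the target partial
correlations on the off-diagonal of an identity matrix; when that matrix
is positive definite (true for every default topology, which are all
diagonally dominant) the implied partials equal the targets **exactly**.
Infeasible target sets fail loudly, naming the edge set — diagonal
inflation would only meet the targets by silently shrinking them.
Feature tables are multivariate normal draws from the implied correlation
matrix, affinely rescaled column-wise to the requested marginal
means/SDs; rank-based estimation downstream is invariant to this. The
ordinal anxiety rating is the latent anxiety node cut at the quantiles of
the requested rating probabilities, so a planted anxiety–jitter partial
correlation survives into the Spearman analysis; groups whose rating
range excludes some categories draw the rating with zero mass there (a
warning, by design, not an error).

Default study conditions: group sizes 119 (low) / 197 (high); group
marginals from the reference study's descriptive table; total-sample
topology anxiety–jitter −0.17, jitter–F0 −0.39, rate–intensity 0.28,
intensity–F1/F2 0.26, F1/F2–F0 0.24; high-anxiety speech network 0.28 /
0.33 / 0.20 / −0.39 with the intensity–F1/F2 edge present; low-anxiety
network 0.28 / 0.30 / −0.39 with it absent. The low-group F1/F2–F0
weight (0.30) is fixed by the published expected-influence arithmetic
(global EI 0.19 and F1/F2 EI 0.30) rather than printed directly. Rating
probabilities [0.30, 0.70, 0, 0] (low) and [0, 0, 0.49, 0.51] (high)
reproduce the published within-group rating means and SDs and, mixed at
119/316, the total mean 1.83 ± 1.01.

*Vowel synthesis* is source–filter: a glottal impulse train with periods
T_i = (1/F0)(1 + ε_i), ε_i i.i.d. N(0, σ²) with σ = (jitter%/100)·√π/2 —
for i.i.d. Gaussian perturbations E|T_i − T_{i−1}|/E[T] = 2σ/√π, so the
expected local jitter equals the requested value, giving extraction
tests a closed-form target. Pulses are band-limited windowed-sinc
impulses at exact fractional-sample positions (every cycle has an
identical waveform shape, so zero requested jitter yields exactly equal
realized periods). The vocal tract is a cascade of two-pole resonators
(default 500/1500/2500 Hz); aspiration noise is white noise through the
**same** cascade at `noise_db` (default −40 dB) relative to the voiced
signal, so the spectral envelope is continuously excited, as in breathy
natural speech. Syllable gating multiplies by a raised-cosine envelope at
`syllable_rate` events/s (70% duty cycle; 0 = continuous voicing), and
the realized periods, epochs and syllable count are returned as ground
truth. The intensity target is defined operationally: the signal is
scaled so the extractor's own statistic (mean un-windowed frame RMS of
the trimmed signal in dB re full scale + offset) equals `rms_db` — truth
and measurement share one definition, which is what a 0.5 dB round-trip
tolerance requires.

What the generator does **not** emulate: phonemes, articulation dynamics,
F0 declination, shimmer, room reverberation, channel/microphone effects,
or inter-speaker covariance between acoustics beyond the planted graph.
Passing round-trip tests therefore demonstrate correctness of the
estimators under the stated signal model, not field performance on
conversational recordings.

## 5. Problem sizes in the test suite

The acceptance-style experiments run at the study's own scale where the
claim depends on it (group sizes 119/197, total 316; 50 seeds for
recovery) and at reduced resampling depth where only calibration is being
checked: permutation tests use P = 200 with 100 (null) and 50 (power)
meta-repeats, bootstrap reproducibility uses B = 100, the pure-noise CS
check 10 repeats at B = 50, and the near-deterministic CS check n = 5000
at B = 20. The λ path is shortened to 50 points inside the permutation
meta-experiments; at p = 5–6 the EBIC argmin is insensitive to path
resolution well beyond that. Full-fidelity settings (B = P = 1000) are
one flag away in the CLI (`--paper-settings`).

## 6. Known limitations

- Formant recovery degrades where the task is ill-posed: close vowels
  with F1 below ~1.5·F0 at high pitch (e.g. /i/ at F0 = 220 Hz)
  under-sample the F1 resonance with their harmonic comb; errors above 5%
  are expected there for any envelope-based estimator. The round-trip
  guarantees cover mid-open vowels (F1 400–750 Hz) at F0 110–210 Hz.
- The cascaded vocal-tract filter's spectral peaks sit within ~1.5% of
  the requested centers (neighboring resonator skirts shift them); only
  an isolated resonator peaks exactly at its center frequency.
- The NCT's global statistic compares signed edge-weight sums; two
  networks with equal sums but different topologies are invisible to it
  (the per-edge tests are the sensitive instrument there).
- Spearman-based glasso treats the 4-level rating as a monotone latent
  proxy; a polychoric-correlation front end would be more efficient for
  very coarse ordinal data but is deliberately out of scope.
- EBIC-glasso weights are shrunken; planted weights are recovered in
  sign and support far more reliably than in magnitude at n ≈ 100–300.
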