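# Methods

`depnet` reimplements, end to end, a resting-state EEG analysis that asks
whether four symptom subtypes of depression — depressed mood, anhedonia,
cognitive depression, somatic depression — carry distinct alpha- and
beta-band connectivity signatures.  Because the participant data behind
such studies are rarely deposited, the package pairs every analysis stage
with a synthetic-data generator whose ground truth is known, so the whole
chain is testable and its statistical behaviour can be characterised
honestly.  This note documents the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic results do and do
not say about real data.

## 1. Questionnaire model and scoring

The Zung Self-Rating Depression Scale (SDS) has 20 items rated 1–4 for
symptom frequency; the ten positively worded items are reverse-keyed
(`5 − raw`), giving a total in [20, 80] with 40 the conventional cutoff for
clinically significant depression.  Subtypes are scored as the *mean* of
their scored items (mood: items 1, 3, 14, 15, 17, 19; anhedonia: 5, 6, 18,
20; cognitive: 11, 12, 16; somatic: 4, 7, 8, 9, 10, 13) so that differing
item counts are not a confound.  The reverse-keyed set
{2, 5, 6, 11, 12, 14, 16, 17, 18, 20} is the standard instrument
convention; it is config-overridable because scale translations sometimes
deviate.  Records with missing or out-of-range responses are excluded with
a warning — no imputation, since any imputation model would dominate the
subtype means of a 3–6 item scale.

Groups are formed **per subtype**: the cutoff is the cohort mean of that
subtype score, computed on the cohort *after* EEG-based exclusion (the
descriptive statistics such splits are compared against are post-exclusion
numbers), and a participant at exactly the cutoff is labelled depressed,
mirroring the "40 or above" convention of the full scale.  Sex enters the
Spearman demographic screen coded 0/1 in order of appearance; with two
levels, Spearman's rho is invariant to which level is 0.

## 2. Cohort generator

Subtype severities follow a one-general-factor model:
`severity_s = λ·G + σ_s·ε_s` with a shared standard-normal G, loading
λ = 0.9 and specific σ_s = 0.45 for all four subtypes.  Item responses are
generated graded-response style: `severity + σ_item·ε_item` (σ_item = 0.6)
thresholded at (−0.15, 0.95, 1.9) into levels 1–4; positively worded items
are emitted inverted, on the raw questionnaire scale.  These four numbers
were calibrated once so that a cohort of 100 reproduces what community
samples show: subtype mean scores ≈ 1.7–1.8, SDS total ≈ 35 ± 11, Cronbach
alpha ≈ 0.94, and pairwise inter-subtype correlations ≈ 0.61–0.74 (inside
the 0.55–0.90 acceptance band; empirical reports put them at roughly
0.63–0.83).  Ground-truth labels per subtype split the *latent* severity at
its cohort mean; the SDS-estimated splits agree with the latent ones at
≈ 85–90%, which is the realistic measurement attenuation the pipeline then
has to live with.

## 3. Head model and forward problem

The head is three concentric spheres — brain, skull, scalp at radii 87, 92,
100 mm with conductivities 0.33, 0.0042, 0.33 S/m — with fixed radially
oriented dipole sources.  A spherical model was chosen over a template BEM
deliberately: it has an exact per-harmonic solution, so the inverse
solver's zero-localisation-error property can be tested against ground
truth with no meshing error, and the leadfield is an explicit input
everywhere downstream, so a realistic leadfield can be substituted without
touching any other stage.  For each spherical-harmonic degree n the
potential in shell i is `A_i r^n + B_i r^−(n+1)` times a Legendre
polynomial; the five coefficients per degree follow from potential and
radial-current continuity at the two interfaces plus zero current at the
scalp.  Radii are normalised by the scalp radius before solving so the
`r^±n` terms stay bounded; the series is truncated at degree 120, where the
eccentricity factor `(b/R)^(n−1)` is below ~1e-10 for all sources used.
With equal conductivities the solver reproduces the homogeneous-sphere
closed form to machine precision (this is a test).

Electrode directions for the 24-site 10-10 montage (FP1 … O2) come from
MNE's packaged standard montage, centred on the montage's best-fit sphere
and projected to the scalp radius.  Source and ROI positions are given in
MNI-style millimetres and shifted by a fixed head-centre offset
(0, −15, 10) mm into the sphere frame.  The source grid holds the 18 ROI
centres plus (by default) 30 rejection-sampled interior nodes at least
12 mm apart — a deliberately sparse stand-in for a cortical grid that keeps
the inverse honest (sources outnumber channels) at desk-scale cost.

## 4. EEG generator

Each of the 18 ROI sources is a sum of three unit-variance components
assembled in the frequency domain with random phases: a 1/f background
(exponent 1), a Gaussian alpha bump (10 ± 1.5 Hz) and a beta bump
(15 ± 2 Hz), with relative amplitudes 0.8 / 1.0 / 0.6 and per-component
lognormal amplitude jitter (σ = 0.3) for between-participant variability.
Lagged coupling on a designated edge replaces part of the receiver's own
band component with a delayed copy of the sender's:

    receiver_band ← sqrt(1 − w²)·receiver_band + w·delay(sender_band, lag)

with lag 25 ms (a quarter cycle at 10 Hz) and mixing weight
`w = strength·(1 + group_contrast)` for depressed-group members,
`w = strength` otherwise (defaults 0.4 and 0.5, i.e. w = 0.6 vs 0.4).  The
mixing is variance-preserving on purpose: the group contrast then lives in
the *lagged dependence* alone, not in band power, so a detected difference
is a connectivity difference.  A strictly positive lag is enforced —
zero-lag mixing carries no lagged connectivity by construction, and a test
hook exists precisely to demonstrate that.

Scalp EEG is `gain · sources` plus 2 µV white sensor noise, scaled so the
median channel standard deviation is ≈ 6.5 µV — chosen so that clean-epoch
peaks sit safely inside the ±50 µV rejection threshold, which is what "most
participants had >90% usable epochs" implies about the real recordings.
Artifacts are Poisson-placed: 400 ms frontal-weighted blink deflections
(200 µV, 0.7/min), single-channel step "electrode pops" (100 µV, 0.1/min)
and 25 Hz muscle bursts (60 µV, 0.2/min).  At these rates a typical
participant keeps ≈ 94% of epochs and exclusions under the 75% rule are
rare, matching the reference protocol's single exclusion out of ~100.

What the generator does *not* emulate: cortical folding and orientation
dispersion, conductivity anisotropy, heavy-tailed artifact morphologies,
non-stationary alpha reactivity, or any dependence of EEG on severity
other than through the designated coupling edges.  Passing tests therefore
show that the *pipeline* recovers what it is pointed at under a fair
forward model — not that real depression subtypes behave this way.

## 5. Preprocessing

Filtering is exact zero-phase frequency-sampling: the rFFT of each channel
is multiplied by a designed magnitude response and inverted.  The chain is
a 1 Hz high-pass with a 2 Hz transition, a 30 Hz low-pass with an 8 Hz
transition, a 50 Hz notch (1.5 Hz transitions) with harmonics, and a 50 Hz
band-stop of 10 Hz width (5 Hz transitions) with harmonics.  Each
transition is a raised cosine with **full attenuation at the printed cutoff**
and the transition extending beyond it; the centred-transition alternative
was rejected because it leaves only ~17 dB at 0.5 Hz for the high-pass,
violating the ≥ 20 dB stop-band behaviour the chain is specified to have.
Filters are applied before epoching on the full record, so edge effects
(~1 s) are negligible over 3 min.

Epochs are back-to-back 4 s segments (45 from 3 min; the trailing
remainder is discarded).  Rejection demeans each epoch per channel (the
whole epoch is the baseline) and drops it if any sample on any channel
exceeds ±50 µV; participants with fewer than 75% artifact-free epochs are
excluded.  Spectra use a Tukey taper with 10% cosine fraction (a "Hann
window with 10% width"; a full Hann is available by flag), normalised so
bin powers sum to the mean-square amplitude — an in-band sinusoid of
amplitude A contributes A²/2 regardless of taper.  Band power sums the
0.25 Hz bins whose centres lie inside the printed edges: alpha
8.00–12.75 Hz (20 bins; 12.9 is not a bin centre at 4 s epochs), beta
13.00–18.00 Hz (21 bins).

## 6. Inverse solution and ROI series

The source estimate is the exact low-resolution tomography family's
weighted minimum-norm solution for fixed orientations: with
average-referenced gain K and diagonal weights W, iterate

    M = pinv(K W⁻¹ Kᵀ + α H),    w_j ← sqrt(k_jᵀ M k_j)

(H is the average-reference centering operator) to a fixed point (max
relative weight change < 1e-6, cap 200 iterations, explicit failure
otherwise), then apply `T = W⁻¹ Kᵀ M`.  α is trace-normalised Tikhonov,
`α = reg·tr(K W⁻¹ Kᵀ)/n_ch`, default reg = 0.05; at reg → 0 (bare
pseudoinverse) the operator localises every noiseless point source on the
grid exactly, which the acceptance suite verifies for all 50 nodes of the
test grid.  Average-referencing of data and gain is the common EEG inverse
convention; the pseudoinverse handles the rank deficiency it introduces.

ROI time series are the arithmetic mean of member grid nodes (nodes within
10 mm of the ROI centre; a first-principal-component alternative is
available).  A ROI with no member node is a hard error naming the ROI.
With 24 channels and 48+ sources the inverse necessarily leaks activity
between ROIs; leakage is instantaneous and therefore does not *create*
lagged connectivity, but it attenuates true coupling and spreads real
group differences onto neighbouring edges — see §8.

## 7. Connectivity and group comparison

Per participant and band, epoch-averaged cross-spectra S(f) (same Tukey
taper, epoch mean of X·conj(Y), taper-power normalised) yield the lagged
linear connectivity per bin,

    LLC(f) = Im(S_xy)² / (S_xx S_yy − Re(S_xy)²) ∈ [0, 1],

averaged over in-band bins.  Three per-bin regimes are distinguished: the
regular ratio; a collapsed denominator with perfect instantaneous
coherence (identical series), where the lagged share is 0 by definition;
and no power at all, where the value is undefined (NaN) and excluded, with
pairs that have no usable bin propagated as missing downstream.  Averaging
LLC per bin and then over bins (rather than pooling spectra over bins
first) is the default; the alternative is a flag.  The diagonal is set to
0 for clean matrix I/O.

Groups are compared per subtype, band and edge with pooled-variance
Student t tests (Welch behind a flag); Cohen's d uses the pooled n−1
standard deviation, signed depressed − non-depressed.  Edges with
|d| ≥ 0.2 are flagged ("at least 0.2" is inclusive).  The printed d = 0.2
⇔ t = 2.0 correspondence found in this literature is a one-sample-formula
convention (d = t/√N) inconsistent with the two-sample pooled formula at
n = 50/50 (where d = 0.2 ⇔ t = 1.0); the package implements the standard
two-sample d and treats the flagging threshold as a d criterion, with t
and p reported as adjuncts.  An edge flagged under two or more subtypes in
the same band is removed everywhere (exclusivity; direction is not part of
the identity).  Counts per subtype × band × direction, signed 18 × 18
indicator matrices and DMN/ECN/SAL network aggregates are emitted
together, with a conservation test tying counts to matrix non-zeros.
Family-wise corrected p values use max-|t| label permutation with the
add-one convention (default 5000 permutations in production runs); they
are reported alongside the effect-size screen, not used as the screen.

## 8. Statistical behaviour of the screen — what to expect

Two properties of this design are worth stating plainly, because the
synthetic experiments in `analysis/` exhibit both.

**The d ≥ 0.2 screen is permissive by construction.**  Under a true null
with n = 50/50, the sampling SD of d̂ is ≈ √(4/N) = 0.2, so each edge is
flagged with probability P(|d̂| ≥ 0.2) ≈ 0.32.  Of 153 edges per subtype
and band, ~49 are flagged by chance alone.  The null-calibration analysis
measures exactly this, and the max-statistic permutation correction is
what restores family-wise control (≈ 5% of null cohorts reach corrected
p ≤ 0.05).

**The exclusivity filter has a hard statistical ceiling.**  An edge
planted for one subtype survives only if *none* of the other three
subtypes flags it.  Even if the planted effect leaked nowhere (other
subtypes exactly null and their splits independent), each survives with
probability at most P(|d̂| < 0.2)³ ≈ 0.68³ ≈ 0.32; perfectly co-dependent
splits raise the bound only to ≈ 0.68.  In practice the subtype severities
are correlated (r ≈ 0.6–0.85), so the planted contrast *does* leak into
the other subtypes' comparisons at roughly half its size, and source
leakage spreads it across neighbouring edges besides — driving exclusive
recovery toward zero even while the d ≥ 0.2 screen itself recovers
essentially all planted edges with the correct direction.  The pipeline
reports recovery both before and after exclusivity for this reason.  The
corollary for interpreting real analyses of this design is that
subtype-exclusive edge sets of size ~5–20 per cell are exactly what
correlated subtype scores produce under weak or absent true contrasts,
and exclusive sets should be read as a descriptive partition, not as
evidence of subtype-specific circuits.

## 9. Numerical and reproducibility notes

- All generators are pure functions of (spec, seed); pipeline randomness
  flows from one run seed through documented seed-sequence spawns (child 0
  cohort, child 1 grid, children 2+i participant EEG).
- Per-participant EEG is processed in single precision (µV-scale signals;
  LLC agrees with double precision to ~1e-9) to keep a 100-participant,
  3-minute, 1 kHz run around half a minute on one core.
- Degenerate inputs are explicit errors, not silent NaN: non-positive
  coupling lags, non-increasing ordinal thresholds, sources outside the
  brain shell, empty ROI membership, degenerate group labels, zero
  total-score variance in Cronbach's alpha.
- Ties at group cutoffs go to the depressed side; identical cohorts
  therefore label everyone depressed rather than crashing.
- The default problem sizes in the analyses (100 participants, 45 epochs,
  50-node grids, 10-seed recovery batteries, 100-cohort null studies) are
  the package's chosen desk-scale study conditions; they match the
  reference protocol's cohort and recording arithmetic.

## 10. Known limitations

- EDF export is not provided (no EDF writer among the dependencies);
  recordings are written as `.npy` matrices with JSON headers, and EDF
  *reading* is available through MNE where needed.
- The spherical head model and radial fixed orientations understate the
  leakage structure of a realistic BEM; absolute LLC levels in synthetic
  runs should not be compared with values from template-head software.
- The exclusivity analysis treats the four subtypes symmetrically;
  hierarchical or partial-exclusivity schemes (e.g. requiring a d margin
  over other subtypes rather than a hard threshold) are out of scope.
- Confidence intervals for d are intentionally not produced at n = 100.
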