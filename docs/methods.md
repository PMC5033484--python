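# Methods

This note documents the models, algorithms, parameter defaults and
numerical conventions implemented in `erpstates`, and what the synthetic
data do and do not establish about real recordings.

## Conventions

Time is in milliseconds, voltages in microvolts, sample indices 0-based.
All windows are half-open `[start, end)`: a [-100, 500) ms epoch at
1 kHz has exactly 600 samples. Every stochastic step takes an explicit
integer seed; per-subject and per-block streams are derived by seeding
`numpy` generators with `(seed, subject/block, salt)` tuples, so any
output is a pure function of `(config, seed)`.

## The oddball design and its simulator

One block presents `n_standards` standard images in runs of 3, 4 or 5,
each run followed by exactly one deviant (so deviants are never
adjacent), with equal numbers of non-target and target deviants. The run
lengths form the most balanced feasible multiset: counts `c_l` solve
`sum c_l = n_deviants`, `sum l*c_l = n_standards`, minimizing the spread
between counts. For the full design (640 standards, 160 deviants) this
gives 53/54/53 runs of 3/4/5 — exactly equal counts are arithmetically
impossible there, and this choice reproduces the printed totals
deterministically. The four (category x colour) stimulus cells rotate
through the standard role across the four blocks; the non-target is the
standard's category in the other colour, the target the other category
in the other colour.

Continuous EEG is built as

```
V(ch, t) = sum_components  a_c * s_subj * m_c(condition) * u_c(ch) * g((t - onset - L_c)/w_c)
         + noise + blink propagation
```

- `u_c`: zero-mean, unit-GFP scalp map built from Gaussian blobs on the
  montage geometry — P1 positive at OZ/POZ, N1 negative at P7/P8/PO7/PO8.
  Zero channel mean makes every planted map average-reference-consistent
  by construction. In the study-emulating recipe the P1 map differs by
  category (the face map is slightly broader/more lateral), because the
  source category effect was topographic: a pure amplitude scaling is
  invisible to GFP-normalized configuration tests like the TANOVA. The
  dissociation recipe disables the variant so its planted effects are
  amplitude-only.
- `g`: Gaussian time course, width (sd) 10 ms. The width was chosen so
  the two components, 48 ms apart at their default latencies, remain
  temporally separable while the waveform stays band-limited enough for a
  30 Hz filter; real P1/N1 deflections are somewhat broader, which is one
  of the idealizations listed below.
- `L_c`: subject-level latency, Normal(116.5, 1.5) ms for P1 and
  Normal(164.5, 3) ms for N1, matching the reported per-condition peak
  ranges (114–119 and 159–170 ms).
- `a_c`: base GFP amplitude, 3 µV (P1) and 4 µV (N1).
- `s_subj = exp(N(0, 0.12))`: a log-normal between-subject scale.
- `m_c(condition)`: the planted effect structure. The study-emulating
  default multiplies P1 by 1.3 for faces (all roles), P1 by 1.15 for
  blue non-target deviants, and N1 by 1.4 for targets. A *dissociation*
  recipe keeps only the P1 category and N1 target multipliers — the pure
  two-effect condition used by the dissociation property test.
- Noise: temporally white Gaussian, sd 4 µV per channel, mixed spatially
  by the Cholesky factor of a unit-diagonal squared-exponential kernel
  over electrode distances (length scale = 0.5 head radii). Single-trial
  SNR is therefore low and averaging is required, as in real ERP work.
- Blinks: Poisson events (10/min) with a 150 µV, 40 ms-sd Gaussian
  course on the EOG channel, propagated to each scalp channel by a fixed
  front-to-back coefficient gradient (0.40 frontal to 0.02 occipital,
  quadratic in the anterior coordinate). A fixed per-subject coefficient
  vector makes the regression correction exactly identifiable.
- Behaviour: per-trial accuracy is Bernoulli (standard 0.97, non-target
  0.937, target 0.683) and RT is a shifted log-normal matched to the
  reported means/sds (non-target 270.8 ± 39.6 ms, target 442.9 ± 38.6 ms),
  with a ±8 ms category twist that reverses between roles and a 1%
  anticipation rate producing sub-100 ms responses for the RT floor
  filter to catch.

Electrode positions come from the idealized 10-05 template (through
MNE); CB1/CB2 — Quik-Cap names for the inferior occipital row — sit at
the I1/I2 template positions.

## Preprocessing

- **Filter**: the "30 Hz, 48 dB/octave, zero phase shift" specification
  is realized as an 8th-order Butterworth applied forward–backward
  (`sosfiltfilt`): 48 dB/octave nominal single-pass slope, squared
  magnitude response, zero group delay, unit DC gain. The realization is
  recorded in the recording's provenance metadata. The on-line
  0.01–200 Hz acquisition filter is not re-implemented: the simulation
  is already band-limited and drift-free.
- **Ocular correction**: blink peaks are detected on the EOG at a 3.5-z
  threshold with 400 ms minimum separation; per-channel propagation
  coefficients are ordinary least squares of scalp on EOG over ±200 ms
  blink segments after per-segment mean removal; the whole recording is
  corrected as `scalp − b·EOG`. No blinks → identity; flat EOG → warning
  and identity.
- **Epochs**: [-100, 500) ms, baseline mean over [-100, 0) subtracted
  per trial and channel. Trials too close to a recording edge are
  dropped with reason `edge`.
- **Rejection**: epochs with any baseline-corrected scalp sample
  exceeding ±75 µV are marked `amplitude`. The screen runs *after*
  ocular correction (the order is configurable; the source procedure
  does not state it).
- **Averaging**: correct trials only, per (role, category, colour) cell;
  individual averages are re-referenced to the common scalp average
  before grand averaging, making every downstream map zero-mean.

## Component statistics

Peaks are marked on the electrode-ROI mean waveform (P1: O1 OZ O2
PO3 POZ PO4; N1: CB1 CB2 P7 P8 PO5 PO6 PO7 PO8) as the *first* local
extremum of the component's polarity inside a configurable search window
(P1 80–160 ms, N170 130–210 ms — windows that enclose the reported
latency ranges with margin). Exact ties resolve to the earliest latency;
a window with no qualifying extremum yields a flagged missing-peak
result, never a window edge. Mean amplitudes are per-electrode means
over 40 ms centred on each *condition's* grand-average peak, removing
latency confounds from amplitude comparisons.

`rm_anova` implements the classical fully-crossed within-subject ANOVA
for any number of factors on a balanced table via the tensor-centering
decomposition: each effect's SS comes from centering the cell-mean
tensor along the effect's axes; its error term is the effect-by-subject
interaction. Greenhouse–Geisser epsilon is computed from the covariance
of orthonormal contrast scores (Kronecker products of per-factor
contrast bases); single-df effects have epsilon 1 by construction.
Partial eta squared is SS_effect / (SS_effect + SS_error) and satisfies
`(F·df1)/(F·df1 + df2)` identically. No pre-installed package covers
this (five within factors with epsilon and effect sizes), so it is
implemented here and cross-checked in the tests against pingouin on 1–2
factor designs and against explicit paired-t sums-of-squares oracles.
Post-hoc comparisons default to paired t-tests with Holm correction.

## Topographic statistics

GFP is the spatial RMS of an average-referenced map. DISS is the RMS
difference of the two GFP-normalized maps and satisfies
`DISS² = 2(1 − r)` with `r` the spatial Pearson correlation. The TANOVA
compares, at each timepoint, the DISS of the two condition group-mean
maps (GFP-normalized by default — the test is then configuration-only;
a documented switch disables normalization) against a null built by
swapping each subject's condition labels. With `2^n ≤ n_perm` all
relabelings are enumerated and p is the exact null fraction ≥ observed;
otherwise `n_perm` random relabelings give `p = (count + 1)/(n_perm + 1)`
(add-one smoothing, minimum attainable p = 1/(n_perm+1)). Significant
windows are maximal runs of `p < alpha` lasting at least `min_duration`
(default 10 ms — the temporal criterion behind the reported windows is
not stated in the source, so it is configurable and always reported).

A literal per-timepoint calibration check would leave ~5% of timepoints
outside their own 200-simulation binomial band even under perfect
calibration, so the calibration test pools the rejection rate over all
(simulation × timepoint) pairs and compares it against the binomial band
at n = 200 — conservative, since timepoints are independent in the null
generator.

## Microstates

Segmentation uses AAHC (atomize-and-agglomerate hierarchical
clustering): every training map starts as its own cluster; the cluster
contributing least to the global explained variance is dissolved and its
members reassigned to the best-correlated survivors; templates are
re-estimated after each step. Polarity-sensitive mode (the ERP
convention, default) assigns by signed spatial correlation and uses the
renormalized member mean as template; polarity-invariant mode uses
absolute correlation and the first principal orientation. Training
defaults to every timepoint of the concatenated deviant grand averages
over 0–500 ms; a `gfp_peaks_only` switch restricts training to local GFP
maxima. Model order is chosen by the modified predictive residual
variance `sigma² · ((N_ch−1)/(N_ch−1−K))²`, undefined for K ≥ N_ch−1;
`select_k` takes the argmin over the searched range (default 2–8 — the
source reports two P1-range and two N1-range maps but not the total K
searched, so the range is configurable and recorded in the model
metadata).

Back-fitting labels each timepoint of an ERP with the best-correlated
template (ties to the lowest index, zero-GFP timepoints unassigned) and
reports, per map: explained variance (GFP-weighted squared correlation
over assigned timepoints, normalized by total squared GFP), mean GFP of
assigned timepoints, and coverage. An optional minimum segment duration
(off by default) absorbs label runs shorter than the threshold into
their temporal neighbours. Maps are named (P1a, P1b, N1a, …) by
their median assigned latency relative to the component windows
(P1: 85–140 ms, N1: 140–215 ms by default).

### Window-level condition statistics

Per component window the pipeline reports three per-subject
x -condition statistics, each feeding the Map/Deviant/Category
repeated-measures ANOVAs:

1. **Summed explained variance** of the back-fit within the window.
   Being a *fraction* of total variance, it is sensitive to amplitude
   changes elsewhere in the epoch.
2. **Noise-corrected GFP power**: mean squared GFP over the window minus
   the mean squared GFP over the prestimulus baseline. Residual
   averaging noise adds the same power floor to both, so the difference
   removes the bias that otherwise inflates conditions retaining fewer
   correct trials (rare targets).
3. **Template strength**: the window's dominant map (largest
   GFP²-weighted coverage on the pooled grand-average back-fit) is
   quantified at every window timepoint by its least-squares coefficient
   against a two-template basis (the window's own dominant map plus the
   neighbouring window's), averaged over the window. This statistic is
   linear in the data — averaging noise stays zero-mean regardless of
   trial counts — and the joint fit partials out temporally overlapping
   or filter-ringing activity belonging to the neighbouring component.
   It is the statistic used for the dissociation verdict, precisely
   because the quadratic alternatives (1) and (2) proved biased under
   unequal trial counts and steep-filter ringing in simulation
   decompositions.

## Problem sizes

The full study design (19 subjects, 64 channels at 1 kHz, 4 × 800
trials) is supported but deliberately not the default: the package's
default configuration runs the same four-block structure at 128 + 16 +
16 trials per block, 32 channels (retaining every analysis electrode)
at 250 Hz. The test suite and the dissociation property use this
reduced scale (10–19 subjects), the TANOVA calibration uses 10 subjects
× 16 channels × 100 timepoints × 500 permutations × 200 simulations,
and parameter-recovery checks use 20–50 seeds — sizes chosen so the
statistical properties are well-estimated while a complete run of the
suite stays cheap.

## What the synthetic data do not establish

The generator plants separable, fixed-topography components with
Gaussian time courses, stationary spatially-smooth white noise, and a
deterministic blink gradient. Real ERP data have broader, overlapping
components with latency jitter across trials, 1/f and alpha-band noise,
non-stationary artifacts, and electrode-position error. Passing tests
therefore demonstrate the *correctness and calibration of the
algorithms* under the stated model — not that the pipeline would
reproduce the source study's specific F values or window boundaries on
re-recorded data. The real-data quantities were never deposited, and no
attempt is made to reproduce them figure-for-figure.

## Known limitations

- `rm_anova` requires complete, balanced designs; unbalanced data are
  rejected, not reweighted.
- The Greenhouse–Geisser correction is the only sphericity adjustment
  (no Huynh–Feldt).
- The AAHC implementation is O(T²) in training maps; segmenting long
  continuous recordings (resting-state microstates) is out of scope.
- Blink correction assumes a single ocular source measured by one EOG
  channel; no ICA fallback is provided.
- EDF/BrainVision import is limited to epoched exports via the HDF5/TSV
  container; raw-vendor-format readers are not bundled.
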