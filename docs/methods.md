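# Methods

This note documents the models, estimators, and numerical choices behind
`seizstate`, and what the synthetic-cohort experiments do and do not show.

## Connectivity features

Seizure iEEG (channels × samples) is re-referenced to a common average
(subtracting the instantaneous cross-channel mean), then cut into half-open
windows `[t, t + 10 s)` anchored at electrographic onset, stepping by 1 s
(10 s window, 9 s overlap); a trailing partial window is dropped, so a
seizure of length `L` yields `floor((L − 10)/1) + 1` windows and seizures
shorter than 10 s are excluded. Within each window, magnitude-squared
coherence between every channel pair is estimated with Welch's method — 2 s
Hann segments, 50% overlap, constant detrend — giving at least 9 averaged
segments per window, which bounds the well-known upward bias of coherence on
few segments (≈ 1/K for K segments under independence). Coherence values are
averaged over FFT bins with `f_lo ≤ f < f_hi` (half-open, so boundary bins
are never double-counted) in six bands: delta 1–4, theta 4–8, alpha 8–13,
beta 13–30, gamma 30–80, high gamma 80–150 Hz. Bands above Nyquist are
dropped with a warning. No line-noise notch is applied by default (an
optional flag exists); coherence is scale-invariant, so amplifier gain does
not matter. The per-seizure tensors are flattened (band-major, pair-minor)
and concatenated across seizures into one `feature_dim × total_windows`
non-negative matrix per patient.

The implementation computes all pairs at once from a single set of segment
FFTs; it is verified in the tests against `scipy.signal.coherence` bin for
bin.

## Network states

The patient's window matrix is factorized as `X ≈ W H` with Frobenius NMF
(multiplicative updates, random uniform initialisation, iteration cap 500,
relative tolerance 1e-6, seeded). Columns of `W` are rescaled to unit L2
norm with the scale absorbed into `H`, making basis patterns comparable
across fits. NMF does not produce orthogonal states: patterns may overlap,
and the synthetic generator reproduces this by drawing sparse non-negative
bases with pairwise cosine similarity capped at 0.9.

**Rank selection.** NMF is non-deterministic under random restarts, and the
number of states is chosen as the largest rank whose basis reproduces across
restarts. For each candidate rank we run `n_repeats` independently seeded
fits; for every pair of fits, the two `W` matrices are matched column-wise
by Hungarian assignment on the cosine-similarity matrix, and the pair's
similarity is the mean matched cosine. Instability(rank) = 1 − mean pair
similarity. The selected rank is the largest with instability ≤ τ = 0.01,
falling back to the argmin if no rank qualifies. τ and the repeat count are
configurable; the full instability curve is always returned and stored in
the run manifest. This operationalises "the same set of states across
restarts" as a concrete, reproducible statistic.

**Labels and features.** Each window is hard-labelled with the argmax state
of its `H` column (ties to the lowest index; all-zero columns are flagged
unassigned and excluded). Occurrence is a per-seizure boolean per state;
states present in every seizure carry no occurrence variability and are
excluded from occurrence tests but retained for duration tests. Duration is
the total window count a seizure spends in a state, summed over visits;
zero durations are excluded so duration effects are not occurrence effects
in disguise. Factorization is strictly per patient — states are not
comparable across patients and the pipeline never pools them.

## Spike-rate cycles

The hourly spike-rate series is decomposed with CEEMDAN. The EMD core sifts
each mode with cubic-spline envelopes through the local extrema (two extrema
mirrored at each boundary), stopping a sift when the mean-envelope energy
falls below 1% of the signal energy (cap 30 siftings) and stopping the
decomposition when the residual has fewer than three extrema. CEEMDAN adds,
at stage k, the k-th EMD mode of each of 100 white-noise realisations
(scaled to 0.2 × the running residual's SD), extracts one mode from each
perturbed residual, and averages; the noise ensemble is seeded, and the
modes plus final residual reconstruct the input exactly by construction.
NaN gaps of ≤ 2 samples are linearly interpolated; longer gaps are
interpolated for the decomposition but masked for all downstream phase use.

**Cycle selection.** A mode becomes a "spike-rate cycle" if it carries at
least 5% of the total IMF variance and its average period is between 0.8 d
(the analysis targets circadian and slower rhythms; faster modes are
broadband noise by construction here) and one sixth of the record length
(slower modes complete too few cycles to interpret). Adjacent kept modes
whose periods differ by under 25% are summed before re-estimating the
period, since EMD can split one physiological rhythm across neighbours. The
average period is twice the mean interval between successive zero crossings
(sub-sample crossings by linear interpolation), robust to the amplitude and
frequency non-stationarity EMD modes are designed to carry. Cycles with
average period in [0.8, 1.2] d are circadian, all others multidien. All
thresholds are configurable and logged.

**Phases.** Instantaneous phase is the analytic-signal (Hilbert) angle of
the demeaned cycle: 0 at the peak, ±π at the trough, (−π, 0) on the rising
limb. Each seizure takes the phase at the sample nearest its onset. A
(seizure, cycle) phase is invalid — and excluded from all statistics — if
the onset falls in a masked gap, within half an average period of either
record edge (Hilbert edge distortion), or where the cycle's analytic
envelope is below 10% of its median (phase is meaningless when the
oscillation has collapsed).

## Association statistics

Four tests per patient, one FDR family across everything:

- **Occurrence × time.** Wilcoxon rank-sum (tie-corrected normal
  approximation, two-sided — effects in either direction are findings)
  comparing times since implantation of seizures with vs. without the
  state, reported as AUC = U/(n₁n₂) = P(T_with > T_without) + ½P(=).
- **Duration × time.** Spearman correlation (midranks, t approximation) of
  non-zero durations against seizure times; at least 5 durations required,
  constant durations flagged and excluded from the family.
- **Occurrence × cycle phase.** Phase-locking value
  `R e^{−iψ} = (1/S) Σ e^{−iφ_s}` of the S seizures containing the state.
  Null: draw S seizures without replacement from all analysed seizures and
  recompute R, 10 000 times. Because the null pool keeps the full empirical
  phase distribution of seizure timing, any timing phase preference —
  seizures themselves are usually phase-locked to their cycles — is present
  in every draw and therefore controlled. Effect size ΔR = R_obs − R(all
  seizures).
- **Duration × cycle phase.** Rank circular-linear correlation: durations
  are mapped to rank-uniform circular scores `u = 2π·rank/n`, and
  `D = (r_c² + r_s² − 2 r_c r_s r_cs)/(1 − r_cs²)` with `r_c = corr(u, cos
  φ)`, `r_s = corr(u, sin φ)`, `r_cs = corr(cos φ, sin φ)`, clipped to
  [0, 1]. D is invariant to monotone transforms of duration. Null: shuffle
  durations against fixed phases, 10 000 times. Since significance is
  purely permutation-based, the exact normalisation of D does not affect
  calibration.

Permutation p-values use the add-one rule `p = (#{T_perm ≥ T_obs} + 1) /
(n_perm + 1)` — never exactly zero, valid at any permutation count, and
within 1e-4 of the plain proportion at 10 000 permutations. The ≥
comparison carries a 1e-12 float guard so exact ties (e.g. S equal to the
pool size) count as ties. Both nulls are computed vectorised (a single
argsort-based draw matrix and one matrix product), which is what makes the
1000-cohort calibration experiments cheap. Each test draws from its own
seeded generator stream.

Benjamini–Hochberg step-up at α = 0.05 is applied to the single family of
all (occurrence + duration) × (time + each cycle) tests across all
patients; tests whose preconditions failed are excluded from the family and
logged rather than assigned p = 1 (a fake p = 1 would still dilute the
step-up thresholds for every other test).

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
seizure electrophysiology:

- **Spike rate** (hourly): baseline 100 spikes/h plus a circadian cosine
  (period 1.0 d) and one or more multidien cosines (default 10.6 d),
  amplitude 30 each, with per-oscillation period jitter (±10% uniform by
  default) so cycles are non-stationary in frequency, plus Gaussian noise
  (SD 10), clipped at zero. Ground-truth instantaneous phase of every cycle
  is retained. Optional slow amplitude modulation is available but off by
  default.
- **Seizure timing**: uniform proposals thinned by a von Mises weight
  (default κ = 2) on a designated cycle's phase — seizures themselves are
  phase-locked, which is precisely the confound the PLV permutation null
  must absorb.
- **Composition**: each state enters a seizure independently with base
  probability 0.45; a modulated state's probability is
  `clip(p₀ + a·exp(κ cos(φ − ψ₀))/exp(κ), 0, 1)`. Empty compositions are
  redrawn (conditioning on ≥ 1 state), which preserves each state's
  phase-dependent inclusion law; force-including a uniformly chosen state
  would inject phase-independent occurrences and distort low-base-rate
  modulated states. Included states appear in random order as one run each.
- **Durations**: log-normal (μ = ln 15 windows, σ = 0.5) — strictly
  positive and right-skewed; planted duration modulation adds
  `(effect/2)·sin(φ)` (phase) or a linear-in-time term (drift) on the log
  scale, so `effect` is the peak-to-trough log-duration difference.
- **Window features**: `W[:, state] × scale + truncated Gaussian noise`
  (SD 0.05), with ground-truth sequences exact — the generator emits the
  connectivity features the factorization consumes rather than raw signals,
  keeping ground truth exact where the statistics live. A raw-signal mode
  (state-dependent mixing of band-limited sources) exists solely to
  exercise the connectivity stage end to end.

One seed determines everything; independent named streams per operation
keep stages independently re-runnable.

**What passing recovery tests do not show**: real spike-rate cycles have
amplitude collapse, missing data and non-sinusoidal shape beyond the
jittered-cosine model; real connectivity noise is structured, not i.i.d.
truncated Gaussian; and real state libraries are not guaranteed to be as
separable as the cosine-capped synthetic bases. The experiments validate
the estimators and their calibration under the assumed structure, not
performance on any specific clinical recording.

## Validation experiments and problem sizes

`scripts/acceptance.py` (and the cohort-scale tests) run, at sizes chosen to
keep a desk-scale run in minutes on one CPU:

- **Calibration**: 1000 cohorts (300 seizures, timing κ = 2, no planted
  modulation), 1000 permutations per test; both permutation tests must
  reject at ≈ 5%.
- **Occurrence recovery**: 200 cohorts with a planted von Mises occurrence
  modulation (κ = 2, ψ₀ = π/2, ~60 modulated-state seizures of 300);
  seizure timing is locked at the same phase (the paper-style scenario
  where the state's preference sits inside the seizures' own preferred
  phase range), so ψ₀ is identifiable from the subset resultant.
- **Duration recovery**: 200 cohorts, 0.5 log-unit peak-to-trough planted
  coupling at n = 200, plus 1000 null draws checking D < 0.05 under
  independence.
- **Cycle recovery**: 90-day hourly record with 1.0 d + 10.6 d cycles, full
  CEEMDAN (ensemble 100), phase recovery scored against ground truth at 60
  onset times.
- **State recovery**: 20 cohort seeds per k_true ∈ {4, 6} (60 seizures,
  5 channels, noise SD 0.05), stability selection over ranks 2–8 with 10
  repeats per rank, label accuracy after Hungarian matching.
- **End-to-end demonstration**: one 300-seizure cohort with pronounced
  planted modulations (occurrence κ = 3, duration 0.8 log-units, timing
  κ = 1) through the full simulate → states → cycles → associate path with
  10 000 permutations. The stronger-than-criterion effects are deliberate:
  a single-cohort demonstration through EMD-estimated phases should not sit
  at the detection boundary, and the moderate-timing/strong-modulation
  regime is the one where the planted preferred phase dominates the
  observable resultant.

## Known limitations

- The stability-NMF criterion is one concrete operationalisation of
  rank-reproducibility; other instability metrics (e.g. consensus
  clustering of H) are not implemented.
- CEEMDAN parameters (ensemble 100, noise 0.2) follow common practice;
  mode-splitting of a single rhythm across two IMFs can survive the 25%
  merge rule on short records.
- Gap handling interpolates before decomposition; long gaps bias the IMFs
  near their edges even though phases there are masked.
- The pipeline tests association, not causation, and per-patient states are
  not comparable across patients by design.
- Seizures enter as EDF files (via `mne`, if installed), numeric channel ×
  sample matrices (`.npy`/text), or precomputed window features in the
  cohort container; artifact rejection and channel pruning are out of
  scope and assumed done upstream.
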