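# Methods

## Behavioral generative model

The simulator implements the independent horse-race account of stopping.
Go finishing times are ex-Gaussian, `G = μ + σZ + τE` with `Z ~ 𝒩(0,1)` and
`E ~ Exp(1)`; defaults μ = 450 ms, σ = 60 ms, τ = 200 ms give a mean go RT
of 650 ms with realistic right skew. On STOP trials the stop process starts
at the SSD and finishes at `SSD + s`, `s ~ 𝒩(SSRT, σ_s)` truncated at zero
(defaults SSRT = 190 ms, σ_s = 25 ms); the faster process wins. With
probability `p_trigger_failure` (default 0.02) the stop process never
starts and the go response always escapes. GO_FAST and GO_CERTAIN trials
shift the go finishing time by −85 ms and +58 ms respectively, so the
preparation-cost and oddball contrasts come out near the high tens of ms.
These defaults were chosen once to land the simulated OFF condition near
typical patient values (go RT ≈ 650 ms, PC ≈ 84 ms, OE ≈ 58 ms, tracked
SSD ≈ 430 ms) and are not tuned per experiment.

Trial mix per 100-trial block: GO 52.6%, STOP 15.8%, GO_FAST 15.8%,
GO_CERTAIN 15.8%. Counts are allocated by the deterministic
largest-remainder rule, which coincides with plain rounding whenever
rounding fills the block exactly and otherwise assigns the leftover trials
to the largest fractional remainders — the mix above at 100 trials would
otherwise be unrealizable (plain rounding yields 101). The block order is a
seeded permutation with STOP trials inserted into distinct gaps between
non-stop trials, so two STOP trials are never adjacent (avoids SSD
carryover artifacts; common SST practice).

The staircase moves the SSD up 50 ms after a successful inhibition and down
50 ms after a failure, clipped to [50, 900] ms, starting at 300 ms; each
later block restarts from the mean SSD of the last four stop trials of the
previous block. A one-up/one-down rule converges on the 50% point of the
psychometric function regardless of the race parameters, which is the basis
of the tracking checks.

Go-family responses slower than 1200 ms are recorded as omissions and enter
the task-error rate. The error mechanism is deliberately minimal (no
wrong-hand responses, no lapses); at the default parameters omissions stay
under 4%, so their handling in the SSRT estimator (exclusion from the
finishing-time distribution, no max-RT replacement) is immaterial at the
tolerances tested.

Cohorts jitter `go_mu` and `ssrt_true` per subject with a lognormal of 10%
coefficient of variation (mean-preserving). The ON condition subtracts
`rt_shift` from `go_mu` and adds `ssrt_shift` to `ssrt_true`; the default
injected effects (50 ms speeding, 53 ms SSRT lengthening) mirror the
direction and size of stimulation effects in this population.

## SSRT estimation

The integration method: sort the go RTs, take the `⌈p·n⌉`-th order
statistic at `p = P(respond | stop signal)` observed in the session, and
subtract the session's mean SSD. The per-session observed signal-respond
fraction is used rather than the nominal 50% because short sessions sit off
the tracking target. Known behavior, measured here across replicate
simulated sessions of ~47 stop trials: a small negative bias (≈ −9 to
−13 ms at SSRT 150–250 ms), driven by SSD variability under the staircase
combined with the skewed go distribution, partly offset by the positive
small-sample bias of the ceiling order statistic and by trigger failures
inflating `p`. The estimator warns on non-positive estimates and returns
them unchanged. Degenerate sessions (all stop trials responded or all
inhibited) leave the SSRT field missing rather than fabricating a value.

## EEG synthesis and what it does not emulate

Epochs span (−200, +500) ms around the alignment cue at 250 Hz, endpoints
inclusive (176 samples). Components are Gaussian bumps in time
(`half_width` is the half width at half maximum) times a fixed spatial
topography — a Gaussian in 3-D electrode distance on the standard 10-05
montage, centred at FCz (N100), F4 (N200), CPz (P300) and C3 (go-locked
motor component, right-hand responses). The 96-channel label set is the
10-10 core padded with 10-5 positions and always contains F4. Stop epochs
contain the go-locked motor component shifted to `latency − SSD` (the
overlapping go process), the stop-locked N100, and N200/P300 at full
amplitude on successful stops or scaled by 0.6 on unsuccessful ones —
consistent with the inhibition process having lost the race. Condition
effects are per-component amplitude factors and latency shifts; the default
ON condition scales N200 by 0.88 and P300 by 0.82 and delays P300 by 17 ms.

Noise is white Gaussian per channel and sample. Real patient EEG adds 1/f
background, DBS and ocular artifacts, bad channels and trial-to-trial
latency jitter, none of which are modeled (artifact removal by ICA and
visual rejection is out of scope). Passing recovery tests therefore show
the *analysis chain* is correct and unbiased under its own assumptions, not
that it would survive raw clinical recordings. The noiseless stop-locked
part of every epoch is stored alongside the data as the ground truth that
recovery tests compare against.

## ERP analysis

Preprocessing is a 4th-order zero-phase Butterworth band-pass (sensor data:
1–45 Hz at the acquisition rate, then polyphase resampling to 250 Hz, then
a 30 Hz low-pass before averaging). Averages are common-average referenced
and baseline-corrected per channel over (−150, −50) ms; referencing first
makes the channel mean exactly zero at every sample and baseline
subtraction preserves that.

The Go-process correction removes go-locked activity from stop epochs under
race-model logic. Unsuccessful stops subtract the mean of go epochs with
RT within ±50 ms of the trial's own response (the go processes that
actually escaped); successful stops subtract the mean of go epochs with
RT > SSD + SSRT (the ones that would have escaped). Subtrahends are shifted
by the trial's SSD, rounded to the nearest sample, into stop-cue time, with
zero padding outside the go window. A stop trial with no matching go trials
falls back to the grand go average and logs a warning. The ±50 ms matching
tolerance and nearest-sample shifting are implementation choices; the
correction is linear in the data, which the suite asserts.

GFP is implemented exactly as the sum over electrodes of absolute
deviations from the scalp-wide mean — not the conventional RMS. Amplitudes
in that convention scale with channel count and carry μV-summed units; they
are compared within-montage only. Peak detection takes the largest strict
local extremum of the requested polarity inside the component window
(plateaus resolve to their first sample, ties to the earliest latency); a
window with no interior extremum returns the window-edge maximum flagged
`at_edge`.

## Group statistics

Paired two-sided t-tests (t with n−1 df) and Wilcoxon signed-rank tests
(exact null for n ≤ 25 without zero differences, normal approximation
otherwise), uncorrected for multiple comparisons. Zero-variance differences
flag the t statistic undefined instead of producing a p-value.

## Connectivity model space and RFX-BMS

The model space has six regions — bilateral IFG {±54, 12, 18}, bilateral
DLPFC {±37, 27, 39}, medial preSMA/dACC {0, −6, 56}, and the basal ganglia
collapsed into one hidden source — and exactly 14 connections: IFG↔DLPFC
forward/backward within each hemisphere (4), DLPFC→preSMA/dACC feedback
(2), bidirectional lateral pairs preSMA↔BG (2) and IFG↔BG per hemisphere
(4), and interhemispheric lateral edges IFG–IFG and DLPFC–DLPFC (2).
Lateral edges are used wherever no hierarchical direction is asserted, in
particular around the hidden BG node. This 14-edge list is one canonical
reconstruction consistent with the constraints above; it is pinned in
`src/sstdbs/data/model_space.yaml` and by tests. Nine modulation models
cross the cortical partner whose BG edges may change between conditions
(IFG, preSMA/dACC, both) with the direction (afferent to BG, efferent from
BG, both); families group by cortical partner. Intrinsic connections are
never modulated.

RFX-BMS fits the variational Dirichlet posterior over population model
frequencies: responsibilities `g_nk ∝ exp(lnE_nk + ψ(α_k) − ψ(Σα))`,
`α = α₀ + Σ_n g_nk`, iterated until `max|Δα| < 1e-6` (cap 500 iterations,
non-convergence flagged). The prior is uniform `α₀ = 1` per model; family
analysis rescales it to `1/|family|` per model so families are a priori
equiprobable — both standard conventions, chosen here rather than imposed
by data. Exceedance probabilities are Monte-Carlo (default 1e6 Dirichlet
draws, seeded, chunked; argmax ties split uniformly); the two-model case
reduces to a Beta tail probability and serves as a closed-form oracle in
tests, never as the implementation. BMA weights each subject's models
within the chosen family by the softmax of its log-evidences (uniform
within-family prior), averages connection log-strengths with those weights,
and summarizes the group as the exponential of the across-subject mean;
ON/OFF differences per connection are tested with the paired t-test.

Because per-subject evidences from biophysical model fitting are not
computable here (the neural-mass forward model and its variational fitting
are out of scope), `simulate_evidences` provides a synthetic stand-in: the
generating model earns a fixed log-evidence advantage (`effect_nats`) over
a zero baseline plus Gaussian noise, with optional population
heterogeneity. `simulate_connection_params` likewise generates per-model
log connection strengths in which a condition effect (e.g. scaling
BG→R_IFG by 0.7 under ON) is expressed only by models whose modulation mask
contains that connection.

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen to keep Monte-Carlo error well
inside the asserted bands: 12 sessions × 300 trials for staircase tracking,
60 replicate sessions per SSRT level for estimator bias, 12-subject cohorts
at 1 μV noise for the ERP effect-direction check, 108 replicates for
9-model recovery, and 1000 null cohorts (one 100-trial block per session)
for t-test calibration. Cohorts whose degenerate stop counts leave the SSRT
inestimable are skipped in the calibration count, which is
direction-symmetric under the null. All randomness flows from explicit
seeds; the pipeline derives per-stage seeds by hashing (master seed, stage
name), so outputs are reproducible bit-for-bit and adding a stage never
perturbs earlier draws.

## Known limitations

- The behavioral generator has no post-stop slowing, fatigue, or RT
  autocorrelation; the staircase analysis is blind to such dynamics.
- The EEG model is additive and stationary with fixed component latencies
  per condition; latency jitter would bias peak amplitudes of averages
  downward in real data.
- GFP-as-absolute-sum makes amplitudes montage-dependent.
- The BMS layer consumes log-evidences; it cannot detect misspecification
  of the forward model that produced them.
- The evidence and parameter generators are deliberately simple (additive
  Gaussian); they probe the inference machinery, not DCM estimation.
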