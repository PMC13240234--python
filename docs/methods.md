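# Methods

## Data model and preprocessing

A relocation is (group, timestamp, position). Positions arriving as WGS84
lon/lat are projected to UTM (default zone 49N, covering western Hainan)
with an in-package transverse-Mercator implementation (4th-order Krüger
flattening series; series error within a zone is far below GPS noise, and
the test suite cross-checks it against an independently derived
Snyder/USGS-series oracle to < 0.5 m and round-trips to < 1 mm). The zone
is fixed per study region rather than inferred per fix, to avoid seams.

Cleaning drops exact duplicate timestamps (first record kept) and fixes
whose displacement from the previously retained fix exceeds a speed cap of
1000 m per 15-min interval, scaled linearly with the actual gap. The cap is
a conservative biological bound for brachiating gibbons and is
configuration-exposed, since published analyses rarely state their outlier
rule.

Segmentation splits each group's series at gaps > 45 min (i.e., more than
two missed 15-min fixes; configurable) and keeps runs with at least 4 fixes
spanning at least 60 min — the standard field validity rule for this
sampling design. Step lengths are Euclidean distances; headings are
`atan2(Δy, Δx)`; turning angles are wrapped into (−π, π], with the −π tie
sent to +π. A zero-length step leaves its heading undefined, so both
adjacent turning angles are recorded as missing; in likelihoods, steps are
censored below ε = 0.1 m so power-law and log densities stay finite.

## Likelihood conventions

The observation unit is the step. Turning angles are missing at each
segment start and wherever a zero-length step occurs; missing angles are
omitted from **every** model's likelihood, and the i.i.d. models include
the circular-uniform constant per available angle, so all four models score
exactly the same observation set and AICc differences reflect model
structure only. Segments are independent in the likelihood.

- **BW**: exponential steps (closed-form MLE rate = 1/mean).
- **TLW**: truncated-Pareto steps with empirical support a = smallest,
  b = largest retained step (recorded with the fit, not counted in k); the
  exponent is profiled on (1, 20] with ties resolved to the smaller value.
- **CCRWo**: 2-state HMM; exponential steps per phase, circular-uniform
  angles in the intensive phase, von Mises (mean 0) in the extensive phase.
  The initial distribution is the stationary vector of the transition
  matrix (a segment starts at an arbitrary time), so k = 5: two rates, one
  concentration, two free transition entries.
- **CCRWp**: 2-phase HSMM; Weibull steps and wrapped-Cauchy angles per
  phase, dwell = 1 + Poisson(λ) per phase (the shift guarantees each
  behavioral phase emits at least one step; an unshifted law would allow
  zero-length phases). k = 8.

The HSMM is computed as a dwell-expanded HMM: each phase is unrolled into M
sub-states tracking elapsed dwell, with discrete hazards governing exits
and strict two-phase alternation at phase ends. The expansion is sparse, so
a forward step costs O(M). M is the 0.999 dwell quantile (floor 30) when
evaluating a given parameter set; during optimization a fixed M = 160 is
used so the objective cannot jump when the quantile crosses an integer, and
the reported log-likelihood is recomputed at the exact truncation. For
segments shorter than M the recursion is exact, which is how it is tested
(brute-force path enumeration to 1e−10).

**Segment starts sit mid-dwell.** A trajectory segment is an arbitrary cut
of a continuous movement process, not the start of a fresh behavioral
phase. The HSMM therefore initializes each segment at the stationary
equilibrium over (phase, elapsed dwell age): phase probability proportional
to mean dwell, age following the discrete residual-life law
P(age = j) = P(D ≥ j+1)/E[D]. This matters in practice: with a
long, tightly concentrated intensive dwell (mean ≈ 100 steps), a
fresh-dwell start makes within-segment switching nearly impossible on
hour-to-day-scale segments and biases the extensive-phase proportion
upward severalfold; the equilibrium start removes that bias. The synthetic
generator draws its first dwell from the same law, and the geometric-dwell
special case still reduces exactly to the matched HMM.

Label switching is resolved by convention: the extensive phase is the
larger-mean-step phase, enforced after fitting and at reporting time.

## Fitting and model selection

CCRW likelihoods are multimodal, so fitting uses a moment-based start (step
median split for scales, angular mean resultant length for concentration)
plus a fixed 8-point Latin grid over log/logit-transformed parameters,
seeded and reproducible. All starts get a short L-BFGS-B exploration; the
two most promising are polished to convergence (gradient tolerance 1e−6).
Bounds keep concentrations in [0, 1−1e−6] and dwell λ in [1e−6, 120] (mean
dwell up to ~30 h of observation time); boundary-pinned optima are flagged
in the convergence record. Log-densities are floored at −745 to avoid −∞
propagation.

AICc uses n = total steps across segments (angles are not double-counted);
each fit carries its exact k so the ledger is explicit. Near-ties
(ΔAICc < 1e−6) resolve to the smaller k. Profile-likelihood confidence
intervals bisect each side of the profile to the χ²₁(level)/2 drop,
re-optimizing nuisance parameters; a side that reaches the feasible
boundary first is reported open (NaN).

## Diagnostics

Pseudo-residuals are one-step-ahead probability-integral transforms. For
the i.i.d. models they are marginal CDFs. For the CCRWs, step residuals use
the forward predictive phase probabilities P(S\_t | past); angle residuals
additionally condition on the concurrent step length (the emission
factorizes as step × angle density), so both streams are exactly uniform
under the fitted model despite serial dependence. The G-test bins residuals
into 20 equal-width bins (df = 19, no parameter-count correction — the
generic form; both are configurable). The overall PR-p pools step and angle
residuals into one G-test by default; Fisher's combination is available,
since published tables rarely state the combination rule.

## Synthetic campaigns

The generator emulates the field protocol: one continuous latent walk per
group stepping on a 15-min lattice around the clock, observed only on the
first `days_per_month` days of each month within 06:00–18:00, with
independent per-fix dropout. Overnight and between-day gaps therefore arise
naturally and are segmented away by the validity rule, exactly as in real
data. Groups may carry per-dietary-period parameters (fruit-eating
April–September vs mixed October–March); at a month-boundary switch the
phase and dwell restart from the new regime's equilibrium. Named presets
(HG, LG, FP, MP) are two-phase regimes built from reported field-scale
summaries (pI, sI, sE, rE) — generator settings, not truth claims — with
the remaining free quantities chosen once as: Weibull shapes 1.1
(intensive) and 1.5 (extensive), intensive-phase angular concentration
ρ\_I = 0.1 (weakly directed within-patch movement), mean extensive dwell 3
steps (45 min of between-patch travel); the intensive dwell mean then
follows from pI.

What the generator does **not** emulate: GPS positional noise, habitat or
canopy covariates, attraction to known feeding trees or sleeping sites,
home-range boundedness, and behavioral observation (scan sampling). Passing
recovery tests therefore show the estimator is correct under the assumed
switching-walk process at field-like sample sizes — not that real gibbon
data satisfy those assumptions.

## Verification design and problem sizes

Exactness checks compare both forward algorithms against brute-force path
enumeration on segments of T ≤ 6 (100 randomized parameter sets).
Statistical checks are sized to run on one CPU in minutes, chosen as the
smallest sizes at which the targeted effects are unambiguous: parameter
recovery uses n = 5000 steps (median over five replicates, because the
single-realization MLE of the extensive-phase proportion has sampling SD
≈ 0.035 under these settings); model-selection recovery uses 20 datasets of
n = 1000 (five per generating model); diagnostic calibration and power use
40 replicates of n = 2000; the seasonal contrast uses a 6-month, 10
day/month campaign.

## Known limitations

- Two phases only; no covariate-dependent switching.
- Profile CIs for the 8-parameter HSMM are computed on demand and are slow;
  they are off by default in the pipeline configuration.
- The truncated-Pareto support convention (empirical min/max) makes its
  likelihood mildly sensitive to the single smallest/largest step.
- The equilibrium segment-start assumption is right for segments created by
  observation gaps; if segmentation instead followed behaviorally defined
  events (e.g., leaving a sleeping site), a fresh-dwell start could be more
  appropriate.
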