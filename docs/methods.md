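# Methods

## The natural-history model

`screenmsm` models the progression of breast cancer in a screened population
as a continuous-time Markov chain over four latent states:

1. free of breast cancer;
2. progressive preclinical screen-detectable phase (PCDP) — asymptomatic
   disease a mammogram can find, which will surface clinically;
3. clinical phase (CP) — symptomatic disease, assumed always to reach the
   cancer register;
4. non-progressive PCDP — screen-detectable disease that would never surface
   clinically.  Detecting it is, by definition, overdiagnosis.

Allowed transitions are 1→2 (onset, rate λ12), 2→3 (clinical surfacing, rate
λ23) and 1→4 (non-progressive onset, rate λ14); states 3 and 4 absorb.  The
non-progressive onset rate is tied to the progressive one through a single
dimensionless ratio r = λ14(t)/λ12(t), shared across ages.  Rates are
piecewise constant on the left-closed age intervals [40,50), [50,60), [60,∞):
the chain is non-homogeneous in age, and the disease process is anchored in
state 1 at the initiation age t0 = 40 (risk before 40 is taken as zero).
The mean sojourn time (MST) in the progressive PCDP is 1/λ23 per age
interval.

Because the chain is acyclic, the within-interval transition matrix has a
closed form (with a = λ12(1+r)):

    P11 = e^{-a·dt}                 P14 = (r·λ12/a)(1 - e^{-a·dt})
    P12 = λ12 (e^{-a·dt} - e^{-λ23·dt}) / (λ23 - a)        P22 = e^{-λ23·dt}

with the analytic limit P12 = λ12·dt·e^{-a·dt} applied inside a band
|λ23 - a| < 1e-8 to avoid catastrophic cancellation at the removable
singularity.  Multi-interval probabilities compose the piece solutions at the
age cut-points; the tests verify equivalence with a matrix-exponential oracle
to 1e-10 and with a direct ODE integration of the forward Kolmogorov system
to 1e-8, including near-degenerate λ23 ≈ a.

## Observation model and likelihood

Screens observe the latent state imperfectly: a woman in the PCDP (state 2 or
4) is detected at an attended screen with sensitivity S and missed with
probability 1-S; a woman free of cancer is never recorded as a case (false
positives are resolved at assessment, and benign recalls collapse to negative
findings in the likelihood); clinical surfacing is always registered, with an
exactly observed age.  A missed case is assumed to be detected with certainty
at the woman's next *attended* screen, unless a progressive case surfaces
clinically first (the standard false-negative carry-forward simplification;
exact modelling of repeated independent misses is deliberately out of scope).

The per-woman likelihood is a forward recursion over a three-component belief
anchored at the last attended screen: mass still in state 1, and progressive/
non-progressive mass missed at that screen.  Negative findings route newly
entered PCDP mass through (1-S) and annihilate carried missed mass (which
must have resolved); a screen detection contributes S on newly entered mass
plus the carried mass; a clinical diagnosis contributes the density
λ23(u)·P12(prev,u) + λ23(u)·P22(prev,u) (for this chain, exactly
d/du P13(prev,u) from the state-1 component); censoring contributes the
probability of no clinical event with latent whereabouts marginalised.
Non-participation is non-informative: invitations without attendance add no
factor, and never-attenders contribute pure clinical-incidence terms —
clinically surfacing cases (interval and non-participant cancers) are what
identify λ23 and, through them, S.

Per-woman likelihoods are computed in linear space (they are bounded well
away from underflow for realistic histories — a woman contributes at most a
few dozen bounded factors) and summed as logs across the cohort; the
recursion is vectorised across women, which is what makes a 50,000-woman
likelihood evaluation take ~0.1 s.

**Left truncation.** A screening register only contains women not clinically
diagnosed before their first invitation.  The likelihood is *unconditional*
by default (plain state-1 anchoring at 40), with an optional flag that
divides each contribution by 1 − P13(40, entry age).  On register-style
synthetic data the unconditional fit is measurably distorted — the optimiser
recoups the log-likelihood the truncation mismatch leaves on the table by
driving λ23 on [40,50) and r toward zero — so every fitting driver in this
repository passes `condition_on_entry=True`.  The flag exists separately from
the default because the two choices answer different questions (fit the
stated anchoring assumption vs. fit the sampling design), and the default
preserves the plain anchoring.

## Estimation

Free parameters of the non-homogeneous model: λ12 on [50,60) and [60,∞), λ23
on all three intervals, r, and S (seven).  λ12 on [40,50) is not identifiable
from screening histories that begin at 50 and must be supplied externally
(from pre-screening registry incidence); the package default is 0.0015 per
woman-year, logged as a synthetic default whenever used.  The homogeneous
comparator estimates a single λ12 and λ23 over all ages plus r and S (four).

Optimisation runs on transformed scales (log for rates and r, logit for S):
BFGS with central-difference gradients (step 1e-6) followed by a Nelder–Mead
polish.  Stationarity and curvature are checked at the optimum (KKT): the
gradient sup-norm must fall below 1e-5·max(1, |−2logL|) — relative, because
finite-difference noise scales with the objective, which is ~1e5 at cohort
size — and the finite-difference Hessian (step 1e-4) must have eigenvalues
above −1e-6 relative to its norm.  The inverse Hessian on the transformed
scale provides the covariance; standard errors and Wald intervals are mapped
to the natural scale by the delta method, with lower bounds truncated at zero
for nonnegative parameters (which reproduces the conventional reporting style
for r when its interval crosses zero) and the sensitivity interval clipped to
[0,1].  The homogeneous/non-homogeneous comparison is a likelihood-ratio test
with 7 − 4 = 3 degrees of freedom.

r is weakly identified at realistic values (a few non-progressive cases per
thousand detections): at 50,000 women the estimate frequently sits on the
zero boundary, where the transformed coordinate runs to −∞ and carries no
curvature.  Boundary parameters (natural value below 1e-8) are therefore
profiled out of the Hessian: the covariance is computed over the interior
coordinates, boundary rows are zero (a point mass at the boundary, which
understates that parameter's uncertainty and is flagged), and their standard
errors are reported as missing.  If even the interior Hessian is not
positive definite the covariance is withheld entirely and the pipeline
reports overdiagnosis point estimates without a CI rather than fabricating
one.

## Overdiagnosis

The probability that a screen detection at age t_k is non-progressive is
(A1+A2)/((A1+B1)+(A2+B2)) with

    A1 = P11(t_{k-2}, t_{k-1}) · P14(t_{k-1}, t_k) · S     (entered 4, detected)
    B1 = P11(t_{k-2}, t_{k-1}) · P12(t_{k-1}, t_k) · S     (entered 2, detected)
    A2 = P14(t_{k-2}, t_{k-1}) · (1 − S)                   (in 4, missed once)
    B2 = P12(t_{k-2}, t_{k-1}) · P22(t_{k-1}, t_k) · (1 − S)

(state 4 persists with probability one, so A2 carries no extra factor).  At a
woman's first (prevalent) screen no missed-carryover exists and S cancels:
P14(t0,t1)/(P14(t0,t1)+P12(t0,t1)) anchored at t0 — the first-round formula is
not published, and this is the minimal model-consistent reconstruction; for a
second screen t_{k-2} is likewise replaced by t0.  Expected non-progressive
counts evaluate the round-appropriate formula at each detected woman's own
attended-screen ages (irregular gaps respected) and sum by round class;
fractions divide by screen-detected counts.  95% CIs redraw the transformed
parameter vector 1000 times from MVN(MLE, covariance) — drawing on the
log/logit scale guarantees valid parameters, where natural-scale drawing
would need rejection — and take 2.5/97.5 percentiles of the recomputed
fractions.

The package's central end-to-end oracle: on model-faithful simulated cohorts
the formula's per-round expected counts match the simulator's latent
ground-truth labels within Monte-Carlo error, both at the reference r
(0.00182) and at an elevated r = 0.05 where the counts carry real
information.

## Synthetic cohorts

The generator emulates an organized biennial program: first invitation at age
50 (uniformly jittered ±1 year to avoid grid artifacts; can be disabled),
invitations every 2 years through 69, per-invitation independent attendance
with probability 0.727, benign recalls with probability 0.02 per attended
screen of a cancer-free woman, censoring two years after the last invitation.
Latent paths draw state-1 exit by inversion of the piecewise-exponential
hazard λ12(t)(1+r), destination non-progressive with probability r/(1+r),
and progressive sojourn from the piecewise hazard λ23(t).  The default truth
parameters are the published non-homogeneous estimates for this program
(λ12 = 276 and 381 per 1e5 woman-years for 50–59 and 60–69; λ23 = 0.385,
0.464, 0.284; r = 0.00182; S = 0.88).  Women whose progressive cancer
surfaces before first invitation are excluded, as a register would; they
appear in the ground-truth sidecar flagged `excluded`.

`model_faithful` mode reproduces the carry-forward assumption exactly
(missed ⇒ detected at next attended screen); `natural` mode makes every
screen an independent Bernoulli(S).  Fitting the carry-forward likelihood to
natural-mode data (common random numbers) shifts the sensitivity estimate
only slightly — consistent with the expectation that the simplification
slightly overstates sensitivity — and the suite bounds that shift at five
percentage points.

What the generator does *not* emulate: calendar-time effects (program
roll-out, film-to-digital sensitivity drift, hormone-replacement-therapy
periods), opportunistic screening outside the program, death as a competing
state, per-woman participation frailty, and in-situ disease.  Passing tests
therefore demonstrate internal consistency of model, estimator and formulas
under the stated design — not robustness of the estimates to these real-data
features.

## Fit diagnostics

Observed vs expected cumulative incidence among ever-attenders, by age band
(50–59 and 60+), on one-year age bins.  The observed curve is annual detected
cases (screen plus clinical) over at-risk person-years (first invitation to
diagnosis, last invitation + 2, or end of study).  The expected curve walks
each woman's actual schedule at the fitted parameters: detection probability
at each attended screen and clinical-surfacing mass per year-bin, conditioned
on her previous negative findings.  Accrual starts at the first attended
screen with the belief conditioned on no clinical surfacing by then: an
ever-attender cannot have an earlier clinical diagnosis (it would have ended
her screening before she ever attended), and ignoring that selection
inflates the expected curve below age 60 by a few percent.  Follow-up of clinically detected cases extends to the next
supposed examination time (two years after the latest scheduled invitation)
so expected mass is not truncated at the diagnosis.  Both curves share the
observed person-year denominators.  On model-faithful data expected tracks
observed within Monte-Carlo error; with non-homogeneous truth the
age-constant comparator overshoots below 60 and undershoots above — the
qualitative signature that motivates the non-homogeneous model.

## Problem sizes and numerical defaults

Chosen as the package's study design for a single-CPU desk run:

- parameter recovery: 50,000 women (the likelihood fit takes ~1 minute);
- formula-vs-truth overdiagnosis oracle: 120,000 women at the reference r,
  60,000 at r = 0.05;
- outcome-frequency validation of the likelihood: 150,000 women;
- LRT null calibration: 30 replicates of 1,200 women (Kolmogorov–Smirnov
  against chi-square(3) at the 1% level);
- Wald coverage: 25 replicates of 2,500 women, asserting coverage ≥ 0.8 for
  S and λ12(50–59) (binomial noise around 0.95 at that replicate count);
- overdiagnosis CI: 1000 parameter draws (default).

Tolerances for stochastic checks are three Monte-Carlo standard errors (or
three times the measured seed-to-seed spread for the recovery checks); exact
algebraic identities are asserted at machine-level precision against
independent oracles (matrix exponential, ODE integration, quadrature,
brute-force recounts).
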