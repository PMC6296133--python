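# screenmsm

Natural-history modelling of breast cancer from individual mammography-
screening histories, and quantification of overdiagnosis.

Organized screening programs invite whole populations, so there is no
contemporary unscreened control group from which to measure overdiagnosis —
the detection of cancers that would never have surfaced clinically.  This
package takes the modelling route instead: a hidden Markov model with four
latent states — free of breast cancer (1), progressive preclinical
screen-detectable phase (2), clinical phase (3), and *non-progressive*
preclinical phase (4) — is fitted by maximum likelihood to individual
screening histories (invitations, attendance, screen outcomes, clinical
diagnoses, censoring).  Transition intensities are piecewise constant on the
age intervals [40,50), [50,60), [60,∞), with the non-progressive onset rate
tied to the progressive one by a ratio r = λ14(t)/λ12(t) and an imperfect
test with sensitivity S (misclassification matrix with
Pr(screen-positive | cancer-free) = 0).  From the fitted model, the expected
number of screen-detected non-progressive cancers — the overdiagnosed cases —
is computed per screening round, with simulation-based confidence intervals.

The intended users are biostatisticians and screening epidemiologists who
want a tested, reproducible implementation of this estimator, together with
a synthetic-cohort generator that reproduces the statistical structure the
estimator assumes (and a "natural" variant that deliberately breaks one
assumption, to measure its cost).

The key quantities:

- **λ12(t)** — onset rate of progressive preclinical disease (per woman-year);
- **MST = 1/λ23(t)** — mean sojourn time in the preclinical phase (years);
- **r = λ14/λ12** — relative rate of non-progressive onset (dimensionless);
- **S** — mammography sensitivity;
- **overdiagnosis fraction** — expected non-progressive detections divided by
  screen-detected cases, per round class (prevalent / subsequent / overall).

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
register (a 20,000-woman cohort at the published non-homogeneous estimates):

```bash
python analysis/01_simulate_cohort.py      # writes scratch/cohort.csv
python analysis/02_describe_program.py     # Tables: participation, recall, IC ratio
python analysis/03_fit_models.py           # ML fits + likelihood-ratio test
python analysis/04_estimate_overdiagnosis.py
python analysis/05_check_fit.py            # observed vs expected incidence curves
```

With the default seed (2026) the run prints, abridged:

```
simulated 20000 women (seed 2026, model_faithful mode)
  entered cohort: 19782 (excluded pre-entry clinical: 218)
  clinical: 521 / no_cancer: 18632 / screen_detected: 629

invitations 193100, screens 140792 (participation 72.9%),
recalls 3407 (recall rate 2.42%)

nonhomogeneous model: -2logL = 15806.7 (converged=True, KKT ok=True)
homogeneous model:    -2logL = 15884.2
LRT homogeneous vs non-homogeneous: chi2 = 77.4, df = 3, p = 1.1e-16

band 50-59: final cumulative gap (expected - observed)
            non-homogeneous +4, homogeneous +430 per 1e5
band 60+:   non-homogeneous -26, homogeneous -633 per 1e5
```

Reading the output: participation and recall reproduce the program design
(72.7% / ~2.4%); the likelihood-ratio test firmly rejects age-constant rates;
and the fitted non-homogeneous model tracks the observed cumulative
incidence within a few cases per 100,000 in both age bands, while the
age-constant comparator overshoots below 60 and undershoots above — the
signature that motivates the non-homogeneous model.  One honest caveat at
this demonstration scale: with only ~600 screen-detected cases, the ratio r
(non-progressive share of onsets) is weakly identified — the likelihood is
nearly flat along a ridge trading r against sensitivity and sojourn rates,
and its estimate can land far from the generating value (here r̂ = 0.17
against a generating 0.00182, inflating step `04`'s overdiagnosis estimate
accordingly).  Identifying r is precisely why register-scale data (hundreds
of thousands of women) are needed; the 50,000-woman recovery tests in the
suite pin down the well-identified parameters (S and the 50s onset rate),
and even then r regularly sits on its zero boundary.

All functionality is importable directly:

```python
from screenmsm import (SimulationConfig, simulate_cohort, fit_mle,
                       expected_npbc, AgePartition)

cohort, truth = simulate_cohort(SimulationConfig(n_women=20_000, seed=1))
fit = fit_mle(cohort, AgePartition(), "nonhomogeneous", condition_on_entry=True)
print(fit.params.S, expected_npbc(cohort, fit).fraction)
```

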