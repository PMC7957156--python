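# trialpath

Continuous-time multi-state Markov modelling of drug-development
trajectories, built for the question: **does biomarker-guided patient
selection change a cancer drug's chances of surviving clinical
testing?**

Oncology drug development has a notoriously high attrition rate —
roughly nine of ten drugs entering Phase I never reach approval. A
natural way to quantify how covariates such as biomarker use shift that
risk is to treat a drug's development program as a stochastic process
moving through five states:

```
Phase I (1) ──► Phase II (2) ──► Phase III (3) ──► Approved (4)
    │                │                 │
    └────────────────┴────────────────►└──────────► Failed (5)
```

with Approved and Failed absorbing. The process is a continuous-time
Markov chain with intensity matrix Q; the off-diagonal entries q_rs are
the transition intensities (per year), rows sum to zero, and covariates
act multiplicatively (proportional intensities):

    q_rs(z) = q⁰_rs · exp(β_rs′ z)

exp(β) is the intensity ratio — reported as a **hazard ratio** for
advancing a phase (or reaching approval) with the covariate versus
without. Transition probabilities over an interval t are P(t) =
expm(Qt); the cohort likelihood is a product of per-interval terms that
accommodates right state censoring of programs still in testing, and
models with and without the covariate are compared by likelihood-ratio
tests. `trialpath` implements the whole chain: deterministic
classification of raw trial records into state histories, the panel
likelihood and its maximum-likelihood fitter, hazard ratios with Wald
intervals, LRTs, per-indication / pooled / biomarker-subtype analyses,
and a synthetic cohort generator with known ground truth so every stage
is testable without access to a curated trial dataset.

Intended users: biostatisticians and meta-researchers analysing
drug-development risk from registry-derived trial tables (e.g.
ClinicalTrials.gov curations covering breast, colorectal, melanoma and
NSCLC programs), and anyone needing a tested panel-data multi-state
engine with exact-transition-time and sparse-panel observation schemes.

## Worked example

Simulate a cohort of 745 drugs in which biomarker-selected drugs carry
a five-fold intensity ratio on every progression transition, then fit
and compare the two Markov models:

```python
from trialpath import pipeline, synth

cfg = synth.SimulationConfig(n_drugs=745, seed=42)
panel, truth = synth.simulate_cohort(cfg)
report = pipeline.run_pooled_analysis(panel)

point, lo, hi = report.overall_hr
print(f"sample sizes:   {report.sample_sizes}")
print(f"LRT: chi2 = {report.lrt.statistic:.1f}, df = {report.lrt.df}, "
      f"p = {report.lrt.p_value:.2e}")
print(f"overall biomarker HR: {point:.2f}  (95% CI {lo:.2f}, {hi:.2f})")
```

prints

```
sample sizes:   {'PhaseI': 745, 'PhaseII': 522, 'PhaseIII': 340}
LRT: chi2 = 572.1, df = 3, p = 1.12e-123
overall biomarker HR: 4.57  (95% CI 4.01, 5.21)
```

The LRT says the biomarker covariate dramatically improves the fit of
the phase-progression model; the overall hazard ratio of 4.57 (interval
covering the generating value 5) is the estimated multiplicative
benefit of biomarker use on the intensities of advancing Phase I→II,
II→III and III→Approved, from a single beta shared across those
transitions. `report.per_phase_hazards` holds the fitted per-year
intensity of each progression transition at both covariate levels with
95% intervals — the hazard-by-phase summary:

```
PhaseI->PhaseII        without: 0.382/yr   with biomarker: 1.634/yr
PhaseII->PhaseIII      without: 0.247/yr   with biomarker: 1.260/yr
PhaseIII->Approved     without: 0.210/yr   with biomarker: 0.979/yr
```

On real data the same pipeline starts from a trial table CSV:

```bash
trialpath classify --data trials.csv --reference-date 2017-01-02 --out panel.csv
trialpath analyze  --data panel.csv --indication all --out report.json
trialpath figures  --report report.json --out figs/
```

`trialpath simulate` and `trialpath recover` expose the generator and
the parameter-recovery / LRT-calibration experiments from the shell.

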