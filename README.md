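# g4rloop

Quantitative analysis of how G-quadruplex/R-loop structures tune
transcription.

When a potential G-quadruplex-forming sequence (PQS) sits on the
non-template strand downstream of a promoter, two R-loop species form in
succession during in vitro transcription: first an R-loop whose displaced
strand folds into an **intramolecular DNA G4** (the *IG4 R-loop*, which
traps polymerase and suppresses RNA output), then an R-loop containing an
**intermolecular DNA:RNA hybrid G4** (the *HG4 R-loop*, which enhances
transcription).  The HG4/IG4 balance — set by the PQS loop lengths — is the
index of transcriptional activity.

`g4rloop` is for researchers quantifying these dynamics from EMSA gels and
single-molecule FRET movies.  It provides:

- **PQS sequences** (`g4rloop.pqs`): constructs from linker-length codes
  ("111" → `GGGTGGGTGGGTGGG`, "123" → `GGGTGGGTTGGGTTTGGG`) and their
  features — loop lengths, loop variance, GC density, IG4 competence
  (≥ 4 G-runs).
- **Gel quantification** (`g4rloop.gel`): Cy5 band fractions per lane, SYBR
  Green II-normalized RNA, OLS transcription rates, HG4/IG4 ratios,
  replicate statistics and Welch t-tests.
- **Kinetics** (`g4rloop.kinetics`): the mass-action scheme

      DNA  ⇌(k1, k1r)  IG4  →(k2)  HG4        (+ optional reverse k2r)

  solved in closed form, fitted by seeded multi-start least squares
  (statsmodels-style `KineticModel` → `KineticFitResults` with
  `summary()`, standard errors and `plot()`), compared by AIC, and the IG4
  equilibrium constant Keq = k1/k1r.
- **smFRET** (`g4rloop.smfret`): E = I_A/(I_D+I_A), donor-only exclusion by
  alternating-excitation response, donor-leakage correction, normalized
  histograms, multi-peak Gaussian fits, threshold state assignment
  (low = duplex, mid = HG4 R-loop, high = IG4 R-loop) and dwell times.
- **Correlation ledger** (`g4rloop.correlates`): pairwise Pearson
  correlations of RNA production with IG4/HG4 levels, the HG4/IG4 ratio,
  loop features and fitted rates, plus RNase-H-resistance stability proxies.
- **Synthetic data** (`g4rloop.synth`): seeded generators for gel lane
  tables (kinetic model + lognormal band noise), smFRET traces
  (continuous-time Markov chain with camera binning, shot noise,
  photobleaching, donor leakage, donor-only molecules) and
  loop-length-coupled multi-construct cohorts — each with a ground-truth
  record, so every pipeline stage is testable without raw data.
- **Pipeline & CLI** (`g4rloop.pipeline`, `g4rloop` command): end-to-end
  runs with YAML config, explicit seeds and provenance reports.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

Simulate a three-replicate gel time course for the tight-loop construct
"111" (true rates k1 = 0.3, k1r = 0.05, k2 = 0.02 min⁻¹, 5% band noise),
quantify it, and fit the kinetic scheme jointly over replicates:

```python
import pandas as pd
import g4rloop as g
from g4rloop.synth import GelGeneratorConfig, generate_gel_timecourse
from g4rloop.io import write_lane_table, read_lane_table

config = GelGeneratorConfig(
    params=g.KineticParams(k1=0.3, k1r=0.05, k2=0.02),
    construct_code="111", seed=1,
)
lanes, truth = generate_gel_timecourse(config)
write_lane_table(lanes, "lanes_111.csv")

quant = g.quantify_table(read_lane_table("lanes_111.csv"))
replicates = g.replicate_timecourses(quant, construct="111")
result = g.KineticModel(replicates).fit(n_starts=10, seed=0)
print(result.summary())
```

```
Kinetic model fit: DNA <-> IG4 -> HG4
  construct: 111
  n_obs: 72 (3 species x 8 times x 3 replicates)
  converged: True   multi-start: 10 (seed 0)
  rss: 0.00637155   AIC: -665.9457

   param     estimate      std err
      k1     0.294866     0.002982
     k1r      0.04677     0.001434
      k2    0.0191536     0.000202

  Keq = k1/k1r = 6.305
```

The fitted rates recover the generating values within a few percent: IG4
R-loops form fast (k1 ≈ 0.29 min⁻¹), revert slowly (k1r ≈ 0.05 min⁻¹,
Keq ≈ 6 — a stable IG4), and convert slowly to HG4 (k2 ≈ 0.02 min⁻¹).
Comparing the irreversible scheme against the reversible alternative:

```python
comparison = g.compare_models(replicates, n_starts=10, seed=0)
print(comparison.summary())
```

```
AIC irreversible: -665.9457
AIC reversible:   -663.9457
delta AIC (rev - irr): 2.0000
preferred: irreversible_hg4
```

The extra back-conversion rate buys no fit improvement (Δ AIC equals the
parameter penalty), so the irreversible scheme is preferred — as expected,
since the data were generated without HG4 back-conversion.

On a 12-construct synthetic cohort whose kinetics are coupled to loop
length, the correlation ledger reproduces the qualitative structure of the
system:

```python
from g4rloop.synth import generate_cohort, DEFAULT_COHORT_CODES
from g4rloop.correlates import correlation_ledger

summaries, truth = generate_cohort(DEFAULT_COHORT_CODES, seed=0)
print(correlation_ledger(summaries).summary())
```

```
Correlates of rna_production (signed r, descending):
       hg4_ig4_ratio  r = +0.980
                  k2  r = +0.971
       loop_variance  r = +0.916
           hg4_level  r = +0.914
    loop_length_mean  r = +0.908
                  k1  r = +0.334
                 keq  r = -0.823
           ig4_level  r = -0.933
```

The HG4/IG4 ratio is the strongest positive correlate of RNA production
(followed by the conversion rate k2), and the IG4 level is the strongest
negative correlate — high stable IG4 suppresses transcription, while
conversion to HG4 enhances it.

The same steps are available from the shell:

```bash
g4rloop synth gel --seed 1 --out lanes.csv
g4rloop kinetics fit timecourse.csv --model both --starts 20 --seed 0
g4rloop synth cohort --seed 0 --out summary.csv
g4rloop correlates ledger summary.csv
g4rloop run --config run.yaml        # full pipeline; --show-defaults prints the config
```

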