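# Methods

## The system being modelled

During in vitro transcription of a potential G-quadruplex-forming sequence
(PQS) placed on the non-template strand downstream of a T7 promoter, two
R-loop species appear in succession on EMSA gels.  The first carries an
intramolecular DNA G4 folded from the displaced non-template strand (the
*IG4 R-loop*); the second carries an intermolecular DNA:RNA hybrid G4 whose
tetrads draw G-runs from both the non-template DNA and the transcript (the
*HG4 R-loop*).  The two species pull transcription in opposite directions —
IG4 R-loops trap polymerase and suppress RNA output, HG4 R-loops enhance it —
so the HG4/IG4 balance, tuned by the PQS loop lengths, sets transcriptional
activity.  This package implements the quantitative layer of that analysis:
sequence features, gel arithmetic, the kinetic scheme, smFRET histogram
analysis, the cross-construct correlation ledger, and a synthetic-data
generator that stands in for raw gels and movies.

## PQS constructs

Constructs are uniform G-runs (GGG by default) joined by thymidine linkers
and named by the string of linker lengths ("111" = GGG T GGG T GGG T GGG).
Derived features: loop lengths, mean loop length, loop-length variance,
GC density, G-run count, and IG4 competence (>= 4 G-runs, i.e. a code of
>= 3 digits).  **Loop variance uses the population formula** (divide by n);
the sample (n-1) form is available via `loop_variance(design, sample=True)`.
The choice is a convention — with two to three loops per construct the two
differ by a constant factor and never change a correlation sign.  Parsing
rejects non-thymidine linkers explicitly (adenine-substituted linkers are a
different construct family, out of scope here) rather than silently
accepting them.

## Kinetic model

Species fractions follow linear mass action over D (duplex), I (IG4
R-loop), H (HG4 R-loop):

    dD/dt = -k1 D + k1r I
    dI/dt =  k1 D - (k1r + k2) I + k2r H
    dH/dt =  k2 I - k2r H

with k2r = 0 in the primary (irreversible-HG4) scheme and k2r >= 0 in the
reversible alternative.  Times are minutes, rates min^-1.  The initial
condition is (1, 0, 0) — pure duplex before NTP addition; pre-folded-G4
experiments may pass `initial=(1-f, f, 0)`.

**Solution.**  The system is linear, so `solve_timecourse` diagonalises the
rate matrix and evaluates `V exp(Λt) V⁻¹ x₀` directly.  When the smallest
eigenvalue gap falls below 1e-10 (relative) or the eigenvector matrix is
ill-conditioned, the solver falls back to an LSODA initial-value integration
(rtol 1e-10, atol 1e-12) instead of using limiting forms.  The two paths are
cross-checked against each other and against a `scipy.linalg.expm` oracle in
the test suite (max-abs agreement well below 1e-6 over random rate sets in
[1e-3, 10] min^-1).

**Fitting.**  `KineticModel(data).fit()` minimises the unweighted sum of
squared residuals jointly over all three species with
`scipy.optimize.least_squares` (trf, rates bounded to [0, 100] min^-1).
Multi-start: one fixed anchor at 0.1 min^-1 for every rate plus log-uniform
draws in [1e-3, 10] (default 20 starts, seeded); the best converged start
wins and `converged` reports honestly whether any start converged.  Standard
errors come from the Gauss–Newton covariance rss/(n-p) (JᵀJ)⁻¹ and should be
read as local approximations — k1r is weakly identified on the standard
8-point grid and its uncertainty is routinely large.

Residual weighting is uniform across species because the gel data give no
error model per band; per-species weights are exposed on the constructor.
Time points later than 30 min are excluded by default (`max_time=30`):
beyond that the reaction has exhausted rNTPs and the plateau no longer
reflects the modelled kinetics.

**Replicates.**  `KineticModel` accepts either one time course or a list of
replicate time courses fitted jointly (one shared parameter set, residuals
stacked).  Joint fitting is the recommended mode for model comparison: the
within-replicate scatter then calibrates the likelihood scale that AIC
needs.  Fitting a replicate *mean* curve is supported (and is what the
parameter-recovery analyses use), but with eight smooth points and no error
scale AIC becomes anti-conservative and over-selects the larger model.

**Model comparison.**  Both schemes are fitted and compared by
AIC = n ln(rss/n) + 2p (the least-squares Gaussian form; n counts scalar
residuals, p free rates).  The reversible fit additionally starts from the
irreversible optimum with k2r = 0, which guarantees the nested-model
inequality rss(reversible) <= rss(irreversible) up to solver tolerance.
The rss entering the AIC is floored at a per-residual resolution of 1e-9 —
far below any gel quantification noise — so numerically exact fits compare
by parameter count rather than by log-of-zero noise.  Two caveats are worth
stating: AIC's ±2 penalty is an asymptotic criterion and with only eight
time points per species its type-I rate is materially above the nominal
level; and the generator's multiplicative band noise is heteroscedastic
while the loss is unweighted, which inflates apparent improvements from the
extra parameter.  Model preferences from single datasets should therefore
be read as indicative; across simulated ensembles in the well-identified
regime (k2 ~ 0.1 min^-1) the true irreversible scheme is preferred in
roughly 90% of datasets.

**Equilibrium constant.**  Keq = k1/k1r indexes IG4 R-loop stability.  With
k1r = 0 it is reported as +inf with a warning, never an exception.

## Gel quantification

Per lane: species fractions are each Cy5 band over the lane's total Cy5
signal (they sum to 1 by construction and are invariant to lane-wide
rescaling); the normalized RNA level is the *summed* RNA band intensity over
the combined SYBR Green II signal of the DNA, IG4 and HG4 bands of the same
lane.  RNA bands are identified upstream (SYBR-positive/Cy5-negative — a
labelling step on the image, not implemented here) and smeared RNA bands are
summed before they enter the lane table.  The transcription rate is the OLS
slope of normalized RNA versus time (minutes).  The HG4/IG4 ratio is
undefined when the IG4 fraction is zero and propagates as missing (NaN),
never as infinity.  Replicate aggregation reports mean ± sample SD (n-1);
group comparisons use two-tailed t-tests, **Welch's unequal-variance form by
default** with the pooled-variance variant as an option — the unequal-variance
form is the safer default when replicate variances differ across constructs.

## smFRET analysis

Framewise efficiency is E = I_A/(I_D + I_A); frames with no signal in either
channel are missing, not zero.  Molecules are imaged under alternating
excitation (10 green FRET frames, a dark frame, 10 red direct-acceptor
frames, a dark frame; 100-ms frames).  A molecule is called donor-only when
its red-excitation acceptor response stays below the pooled dark-frame level
plus 3 SD; the per-molecule statistic is the 0.9 quantile of red-frame
acceptor intensity, which tolerates photobleaching partway through the
movie.  Excluded molecules are returned, not dropped: their apparent
efficiency estimates the donor leakage coefficient l = E_d/(1 - E_d), and
the correction acceptor' = max(0, acceptor - l·donor) is then applied to the
retained molecules (l = 0 is the identity; the clamp prevents negative
intensities).

Histograms take the first 21 green frames of each molecule, bins of width
0.02 spanning [-0.1, 1.1] (the paper-scale histogram uses >4000 molecules;
the bin width is a package default, configurable), density-normalized to
integrate to 1.  Peaks are fitted by least squares with a sum of Gaussians
on the binned density (1-4 components, multi-start, seeded), component SDs
floored at 0.01 to prevent delta collapse; a warm start from the (k-1)-fit
makes rss non-increasing in component count.  Least squares on the binned
density (rather than maximum likelihood on raw E values) matches how
multi-peak fits are done on published histograms; an ML route can be added
on top of the same components.

State assignment thresholds the green-frame efficiency into low/mid/high —
in this system duplex DNA, the HG4 R-loop (plus the short-lived bare
R-loop), and the IG4 R-loop respectively.  Default thresholds are the
midpoints between fitted mixture means.  Ties at a boundary go to the lower
state.  Dwell times are contiguous-run lengths times the frame interval,
counted within the green-frame series (the interleaved red/dark blocks are
short relative to state dwells).  An optional 3-frame median filter
suppresses single-frame shot-noise excursions; it is off by default because
the acquisition pipeline being emulated describes no trace smoothing.

## Synthetic-data generator

The generator produces data with the statistical structure the analysis
assumes; it is scaffolding for validation, not a mechanistic claim.

*Gel time courses.*  Fractions from the kinetic model on the 8-point grid
(0, 0.5, 3, 5, 10, 15, 20, 30 min), converted to band intensities with a
random per-lane scale and multiplicative lognormal noise per band (unit
mean; default CV 5%, matching replicate scatter of quantified gels; 3
replicates).  Cumulative RNA integrates an instantaneous rate
r(t) = max(0, r0 + α·H(t) - β·I(t)) — HG4 enhances, IG4 suppresses.  The
clamp is applied to the *rate*, so RNA(t) is non-decreasing (clamping the
cumulative signal instead would let RNA fall, which the assay cannot show).
The linear form encodes only the established signs; defaults r0 = 0.005,
α = β = 0.03 per minute give 30-min RNA levels spanning roughly 0.01-0.12
normalized units across the default cohort — low output for tight-loop
constructs whose IG4 dominates, higher output as HG4 takes over.

*smFRET traces.*  Each molecule runs a continuous-time Markov chain over
FRET states (defaults: low 0.3, mid 0.5, high 0.75, SD 0.05 — the three
regimes of this system, loosely anchored to the reported peak positions;
a low<->mid<->high chain at 0.5 s^-1 per step, uniform stationary
occupancy).  Per green frame the efficiency is drawn from the occupied
state's Gaussian; donor/acceptor intensities partition a total intensity
(default 1000/frame) by that efficiency, with Gaussian shot-like noise
(variance equal to the mean), camera background 20 ± 5 per channel, donor
leakage l (default 0.05) added to the acceptor channel, and joint
single-exponential photobleaching (default 0.01 s^-1) silencing both dyes —
no blinking, no gamma factor, no direct acceptor excitation under green
light.  Donor-only molecules emit full donor signal, leakage-only acceptor
signal under green light and no response to red light.  Red frames drive
the acceptor directly; dark frames record background.

*Cohorts.*  Rate constants follow monotone maps of mean loop length L:
Keq(L) = 10·exp(-0.8·(L-1)) (tighter loops, more stable IG4) and
k2(L) = 0.015·exp(0.5·(L-1)) (longer loops convert to HG4 faster), with
k1 = 0.35 min^-1 common and 10% lognormal construct-to-construct jitter.
RNase-H resistance of the IG4 R-loop is the saturating map keq/(keq + 2).
Only the monotone *directions* are established findings; the functional
forms and constants are package choices made once so that the generated
cohort expresses the qualitative structure the analysis is meant to
recover.  Each generator returns a ground-truth record (rates, occupancies,
donor-only flags, bleach times) sufficient to score recovery without
re-deriving anything.

What the generator does **not** emulate: gel background and band overlap,
imaging-chain nonlinearity, RNA secondary-structure smearing, acceptor
blinking and spectral crosstalk beyond donor leakage, and any sequence
thermodynamics behind the rate maps.  Passing recovery tests therefore
demonstrate that the estimators are consistent and correctly implemented
under the assumed noise structure — not that real gels or movies satisfy
that structure.

## Correlation ledger

Pairwise Pearson correlations (Spearman available) over construct summaries:
RNA production (default: normalized RNA at the 30-min point; the rate slope
is selectable), IG4 and HG4 levels at the summary point, HG4/IG4 ratio,
mean loop length, loop variance, fitted k1, k2 and Keq.  Missing values
(undefined ratios, failed fits) are excluded pairwise; correlations with
fewer than 3 complete pairs or zero variance are reported missing with a
warning.  The ledger is descriptive — no multiple-testing correction — and
the ranking of RNA correlates is by signed r.  The RNase-H stability proxy
reports r(IG4 remaining after digestion, Keq) and r(remaining/total IG4,
mean loop length).

## Pipeline and reproducibility

`g4rloop run --config run.yaml` executes stages (cohort generation,
quantification, rate regression, kinetics, correlation, smFRET) in
dependency order.  Every stochastic stage takes an explicit seed; identical
configs reproduce byte-identical outputs, and each run writes a report with
the config hash, seeds, per-stage outputs and captured warnings.  A failed
stage is recorded with its error and downstream stages are skipped, never
half-run.

## Problem sizes used in validation

The shipped test suite and the acceptance script size their simulations as:
100 random rate sets for solver/oracle agreement; 100 noisy datasets (8-point
grid, 5% noise, 3 replicates) for rate recovery and 100+10 for model
selection; 1000 molecules for the smFRET recovery battery; 12 constructs for
the cohort ledger.  These sizes give comfortable margins on every tolerance
while keeping a full run around a minute on one core.

## Known limitations

- k1r (and hence Keq) is the weakly identified rate on the standard grid;
  treat fitted Keq rankings, not magnitudes, as meaningful.
- AIC at eight time points is anti-conservative (see Model comparison).
- The closed-form/numeric switch is automatic but the numeric path is ~100x
  slower; pathological rate sets (all rates equal and large) always take it.
- The smFRET state caller is a threshold method; fast exchange between
  adjacent states broadens dwell-time estimates and a hidden-Markov
  idealization is deliberately out of scope.
- Band detection, image background subtraction and TIRF spot extraction are
  upstream of this package: it consumes intensity tables and traces.
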