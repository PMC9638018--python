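# Methods

`immetab` implements the quantitative analysis chain used to study how
extracellular succinate suppresses T cell effector function: stable-isotope
tracing read-outs, extracellular-flux bioenergetics, cytokine quantitation,
and an IFN-γ response signature score on tumor RNA-seq counts. This note
records the models, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Natural-abundance correction of mass isotopomer distributions

GC-MS measures a metabolite fragment's isotopologue envelope at unit-mass
resolution: ion counts at mass shifts m+0 … m+K. The measured envelope is the
tracer-derived labeling convolved with the natural isotope pattern of every
atom in the derivatized fragment. For a fragment with elemental formula F and
n tracer-accessible carbon positions, the forward model is a
(K+1) × (n+1) matrix **M** whose column *j* is the natural isotope
distribution of the residual formula (F minus *j* carbons fixed heavy),
shifted up by *j*. Per-element shift distributions are exact multinomial
convolutions of single-atom distributions (no polynomial approximations);
the full, untruncated column always sums to 1.

The corrected MID solves **M**·x ≈ counts by non-negative least squares
(`scipy.optimize.nnls`) followed by renormalization to Σx = 1. NNLS is used
because negative isotopologue fractions are unphysical; plain inversion of a
square **M** is available implicitly through the oracle tests but is not the
default. All-zero spectra and rank-deficient matrices are rejected rather
than silently returning garbage.

Defaults and their rationale:

* **Fragment formulas** — the measured fragment depends on derivatization
  chemistry and instrument method. The shipped table holds the standard
  [M−57]⁺ (tert-butyl loss) ions of TBDMS-derivatized metabolites, e.g.
  succinate C12H25O4Si2 (m/z 289) with a 4-carbon tracer backbone; every
  entry is user-overridable via a formula TSV.
* **Natural abundances** — standard representative values (¹³C 0.0107,
  ²⁹Si 0.04685, ³⁰Si 0.03092, …), overridable via an abundance TSV. Silicon
  from the derivatization groups dominates the correction for TBDMS ions.
* **Correction scope** — full-formula correction is the default; a
  carbon-only mode is provided for comparison with legacy schemes.
* **Spectrum window** — K defaults to n (the window typically acquired);
  longer windows are supported and improve conditioning.
* **Tracer purity** is taken as 1.0 (no purity correction is applied).

Summary statistics: fractional enrichment Σᵢ i·Mᵢ / n; relative abundance =
total ion count / internal-standard ion count (D6-glutaric acid in the
motivating experiments); labeled abundance is reported both per-isotopologue
(Mᵢ × relative abundance, i ≥ 1) and as the labeled sum, since either
convention is used in practice.

## Extracellular-flux bioenergetics

Metrics follow the standard stress-test arithmetic on per-well OCR/ECAR
traces with annotated injections:

* ATP-coupled OCR = mean(last 3 OCR cycles before oligomycin) −
  mean(first 3 cycles after). The 3-cycle window matches one measurement
  phase and is configurable.
* Basal glycolysis = mean(first 3 ECAR cycles after glucose) −
  mean(last 3 before). Traces acquired with a perturbation-only protocol
  (no glucose injection) raise an explicit error instead of guessing a
  surrogate, and `summarize_wells` reports NaN for that metric.
* ATP production rates re-derive the published rate equations with every
  constant exposed in `AtpRateConstants`: mito ATP = coupled OCR × 2 O/O₂ ×
  P/O (default 2.75); glycolytic proton efflux = basal ECAR × `ecar_to_per`
  − 0.61 × (basal OCR − post-rotenone/antimycin OCR); glyco ATP = proton
  efflux × 1 ATP/H⁺. `ecar_to_per` defaults to 1.0, i.e. glycolytic rates
  are reported in ECAR-equivalent units until a medium buffer factor is
  configured; absolute pmol ATP/min for the glycolytic branch therefore
  requires that one instrument-specific constant. total = mito + glyco by
  construction, exactly.

Wells are analyzed independently; averaging replicate wells per condition is
a deliberate, separate step so that well-level variance remains visible.

## Signature scoring on RNA-seq counts

Counts are normalized with median-of-ratios size factors (the DESeq2
definition, re-implemented explicitly): the reference for each gene is its
geometric mean across samples, and a sample's factor is the median ratio to
that reference over genes with nonzero counts in every sample (a
positive-geometric-mean variant is available behind `strict=False`). Log2
normalized values are log2(count/s + pseudocount) with pseudocount 1 by
default — IFNG-class transcripts are often undetectable, so zeros are
expected, and a pseudocount ≥ 1 also guarantees non-negative log2 values so
the geometric mean below is defined.

The signature score for a sample is the geometric mean over signature genes
of its log2 normalized values, per the literal reading of the source
convention; the alternative reading (arithmetic mean of log2 values, i.e.
the log of the geometric mean of normalized counts) is available with
`geometric_mean_of_logs=False`. Genes missing from the matrix are a hard
error unless `allow_missing` is set. The 45-gene IFN-γ response list used in
the motivating study is supplementary material not redistributed here; the
signature is a required input file, and tests use the synthetic generator's
own labelled signature genes.

Group comparisons use the two-sided rank-sum (Mann-Whitney/Wilcoxon) test —
exact for small untied samples, normal approximation with tie correction
otherwise — or Welch's t.

**A note on rescaling invariance.** Multiplying every count of one of *n*
samples by k is *not* perfectly absorbed by median-of-ratios factors: the
geometric-mean reference itself shifts, so every normalized count in the
matrix changes by the common factor k^(1/n) (the scaled sample's factor
rises by k^(1−1/n), all others fall by k^(1/n); the product of factors is
invariant). The property tests assert this exact algebraic form to 1e-9.
For the 45-sample cohort the residual common shift is k^(1/45) — under 2%
even for an 8-fold library-size change — and cancels entirely from
between-group contrasts.

## Cytokine quantitation

Standard curves are four-parameter logistic, OD = d + (a−d)/(1+(x/c)^b),
fit by least squares with quantile-derived initial guesses and fixed-seed
jittered restarts on non-convergence; (a, b, c, d) and (d, −b, c, a) define
the same curve, so fits are canonicalized to b > 0 with a the
zero-concentration response. 4PL rather than 5PL: immunoassay calibration
rarely supports an asymmetry parameter, and none of the motivating data
suggested one. Unknowns are interpolated with the analytic inverse, defined
only strictly between the asymptotes; out-of-range ODs are an error, not an
extrapolation.

Concentrations are corrected to a common reference live-cell input:
corrected = raw × reference / (input cells × viability). This is the minimal
proportional reading of "corrected for cell count using known input cell
number and measured viability"; the reference defaults to 2×10⁵ cells (the
typical supernatant-harvest input), and a per-10⁶-cells column is emitted
alongside since either reporting convention appears in practice.

## Synthetic-data generators

The generators define the conditions under which the pipeline is validated;
all are deterministic for a fixed scenario and seed and emit sidecar truth
tables.

* **Tracer** — spectrum = scale × (**M**·true MID) with multiplicative
  log-normal noise (mean 1, CV as configured; default 1%), truncated at 0.
  The default scenario is a C4 succinate fragment with true MID
  (0.15, 0.03, 0.04, 0.08, 0.70) — a pool dominated by the fully labeled
  m+4 species, as when cells are grown on fully ¹³C-labeled succinate.
* **Flux** — phase means plus additive Gaussian noise, 3 cycles per phase,
  combined protocol (basal → glucose → oligomycin → uncoupler →
  rotenone/antimycin) so both OCR and ECAR metrics are defined. Default
  means (OCR 100→105→40→160→15 pmol/min; ECAR 15→60→80→70→40 mpH/min) are
  typical activated-T-cell magnitudes.
* **Counts** — negative binomial with var = μ + αμ² (α = 0.1, a typical
  bulk RNA-seq dispersion), gene means log-normal (log2 mean 6, sd 2),
  two groups of 18 and 27 samples, and the 45 signature genes shifted by
  2^(log2_effect) (default −1, i.e. 2-fold down) in group 1.
* **ELISA** — 4PL plus additive Gaussian OD noise; an 8-point 2-fold
  dilution series of standards from 2000 pg/mL plus unknown wells carrying
  cell counts and viabilities.

Replicate-level noise magnitudes are conventions, not published values; they
are parameters, not constants. What the generators do **not** emulate —
chromatographic artifacts and detector saturation, instrument drift within a
flux run, batch effects, GC content/length biases or outlier genes in
RNA-seq, plate edge effects — bounds what passing tests show: they validate
the *estimators* (correct inversion, exact arithmetic, calibrated tests)
under each platform's canonical noise model, not robustness to every
real-world artifact.

## Numerical choices and degenerate inputs

* NNLS + renormalization after correction; MIDs are asserted non-negative
  and unit-sum to 1e-9 after every correction.
* Exhaustive enumeration over atom isotope states (feasible to ~8 atoms) is
  the oracle for the convolution code, with agreement required to 1e-12.
* Exact rank-sum enumeration (n ≤ 8, no ties) vs normal approximation is
  delegated to `scipy.stats.mannwhitneyu`'s automatic policy.
* Degenerate paired t tests (all differences identical) are an error, not a
  p-value; Bonferroni adjustment is min(1, m·p) over the comparisons within
  one analysis.
* Pipeline outputs use a fixed float format (`%.10g`), carry a header with
  the tool version and config checksum, and are byte-reproducible for a
  fixed config and seed.

## Problem sizes used in validation

Oracle equivalence uses 50 random formulas of ≤ 8 atoms; noisy-MID recovery
uses 1000 spectra at 1% CV; the flux sampling-variance check uses 10⁴
replicate traces against the closed form sd = σ√(2/3) for a difference of
two 3-means; cohort validation uses 200 simulations (effect sign) and 1000
(null calibration) of the 18-vs-27 design; the bundled end-to-end fixture
uses 100 genes and 2 wells so golden files stay small and diffable.
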