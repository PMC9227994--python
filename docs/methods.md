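# Methods

This note documents the quantitative procedures permkit implements, the
mechanistic model behind its synthetic-data generator, the defaults and why
they were chosen, and what the test suite does and does not demonstrate
about real assay data.

## 1. Quantification

### Calibration

Detector response is modelled as linear in concentration, `y = a·x + b`,
fitted by unweighted OLS (1/x and 1/x² weighting are available but off by
default, since plain linear regression is the norm for HPLC-PDA assays over
a ≤ 40-fold range).  The LLOQ is defined as the lowest non-blank standard
(protocol default 0.025 µg/mL).  When blank injections are supplied, the
LLOD is the smallest concentration whose predicted response reaches five
times the mean blank response, solved from the fitted line and floored at
zero; the mean (rather than, say, mean + 3σ) is the simplest unbiased
reading of the 5×-blank rule, and the statistic is the only free choice
there.  If the implied LLOD exceeds the LLOQ the curve is still returned,
with a warning flag — that situation indicates a noisy blank, not an
unusable assay.

Back-calculation inverts the line; results below the LLOQ are returned as
explicit `Censored` markers rather than numbers.  The accuracy gate follows
bioanalytical-validation convention: per-level relative error of
back-calculated vs nominal concentration must be within ±15 %, relaxed to
±20 % at the LLOQ.

### Assay QC

* MTT viability: `100·(A_sample − A_blank)/(A_control − A_blank)`; affine
  shifts of all three absorbances cancel.  Values above 100 % are reported
  as computed.
* Stability: percent remaining `100·C_after/C_before` per storage/incubation
  condition.
* TEER: `(R_measured − R_background)·A` in Ω·cm², pass at ≥ 400 Ω·cm².
  (Some sources typeset the background correction as a ratio; the
  subtraction form is the physically meaningful one — the cell-free insert
  resistance is in series — and is what is implemented.)

## 2. Transport analysis

### Aliquot-corrected cumulative amount

With receiver volume V and aliquot S withdrawn and replaced at each sampling
time, the concentration measured at the n-th timepoint no longer accounts
for mass carried away earlier.  The cumulative transported amount is

    Q_n = C_n·V + Σ_{i=1..n−1} C_i·S.

Censored concentrations contribute zero to the sum, and every Q from the
first censored point onward is flagged as a lower bound.

### Flux and Papp

dQ/dt is the OLS slope of the quantifiable (t, Q) points.  The origin (0, 0)
is *not* forced by default: compound loading and the cell-compartment
transient produce a lag, and a forced-origin fit is biased whenever a lag
exists.  (`include_origin` and a `window` restriction are exposed in the
config.)  Then

    Papp = (dQ/dt in µg/s) / (C₀ [µg/cm³] · A [cm²])   →  cm/s.

Per-well fits come first; replicates are aggregated afterwards as mean ± SD.
Pooling concentrations across wells before fitting would understate the
between-well variance and is deliberately not done.

A sink flag (`sink_ok`) is set when the final receiver concentration stays
below 10 % of C₀ — the conventional criterion; violation is a warning, not
an error, because the standard protocol (400 µL apical donor) genuinely
violates sink conditions for fast permeants and the fitted slope is then a
protocol-conditioned effective Papp, as it is in the wet lab.

### Censoring policy

Sub-LLOQ measurements never enter flux regressions.  A run with fewer than
two quantifiable receiver points yields Papp = not available ("N.A."), which
is reported as *non-absorbed*, distinct from zero: the datum is an upper
bound, not a measurement of nothing.

### Efflux ratio and statistics

ER = Papp(B→A)/Papp(A→B), computed from the replicate means of each
direction; classification (passive < 2 ≤ efflux-suspected) uses the
unrounded ratio, reporting rounds to one decimal.  Between-group comparisons
(direction within an arm, dose within a family) use the equal-variance
Student t-test by default (Welch optional); matched before/after
deconjugation wells use the paired t-test, with fold change defined as the
ratio of means.  Stars encode p < 0.05/0.01/0.001.

### Deconjugation dilution correction

Enzyme treatment mixes sample and β-glucuronidase/sulfatase solution 1:20,
diluting the analyte by 20/21.  Whether published workflows correct for this
is typically unstated, so the correction (×21/20 on deconjugated
concentrations) is applied by default and exposed as a config switch, making
both interpretations reproducible.

### Basolateral recovery

Primary definition: `100·Q_final / (C₀·V_donor)` with the receiver-side
cumulative amount in the numerator.  A companion mass-balance variant,
`100·(donor residual + Q_final)/(C₀·V_donor)`, is computed when the donor
residual is supplied; the two bracket the ambiguity in how "recovery" is
defined across labs.

## 3. The simulator

### Model

One insert is a three-compartment mass balance: donor chamber, cell
monolayer (a single well-mixed aqueous compartment), receiver chamber.

* Parent crosses each membrane by passive diffusion,
  `J = P_m·A·(C_upstream − C_cell)`, with the per-membrane permeability set
  to **2×Papp** so that two equal barriers in series give the nominal
  monolayer Papp exactly in the sink regime.
* Intracellular conjugation is saturable Michaelis–Menten:
  `r = Vmax·C_cell/(Km_app + C_cell)` (µg/min), the minimal kinetic form
  that produces dose-disproportionate totals.
* The conjugate is membrane-impermeant and leaves by carrier-like one-way
  export: permeability `P_exp` across the basolateral membrane and
  `P_exp·asym` across the apical membrane, with `asym < 1` encoding the
  basolateral preference typical of glucuronide/sulfate efflux
  transporters.  This makes the *total*-drug efflux ratio fall below 1
  after deconjugation while the parent remains direction-symmetric.

Integration is fixed-step classical RK4 (default dt = 0.5 s): a fixed step
keeps runs bit-reproducible, and RK4's accuracy makes the step-halving
convergence criterion (< 0.1 % change in any concentration) pass with
orders of magnitude to spare.  A step too large for the fastest
cell-compartment rate shows up as a negative mass and raises a step-size
error rather than silently producing garbage.

The withdraw-and-replace sampling protocol is applied exactly: at each
sampling time the receiver concentration is recorded, the aliquot's
per-species mass is appended to a ledger, and resident receiver masses are
scaled by (V − S)/V.  Compartments plus ledger always sum to the initial
dose; this mass ledger is the oracle against which the analysis-side Q
reconstruction is verified to machine precision.

The measurement layer adds mean-preserving multiplicative lognormal noise
(σ² = ln(1 + CV²)) and then censors below the LLOQ.  Noise is applied per
replicate to a shared deterministic kinetic trajectory — replicate wells in
a real study differ biologically too, but a measurement-only error model is
the simplest one consistent with reporting mean ± SD of three wells.

### Default parameters

| parameter | default | rationale |
| --- | --- | --- |
| insert area | 1.12 cm² | 12 mm transwell format |
| chamber volumes | 0.4 / 1.2 mL (apical/basolateral) | protocol |
| aliquots | 0.2 / 0.6 mL, replaced | protocol |
| sampling times | 30, 60, 90, 120 min | protocol |
| doses | extract 250/500 µg/mL (13.07 mg analyte per g → 3.2675/6.535 µg/mL) and pure 3.267/6.808 µg/mL | study design |
| replicates | 3 | study design |
| Papp (parent) | 5×10⁻⁶ cm/s | low-permeability paracellular compound |
| conj Vmax | 0.009 µg/min | captures ≳ 95 % of parent flux at these doses |
| conj Km | 0.25 µg/mL | saturation onsets inside the studied dose range |
| conjugate export P | 60×10⁻⁶ cm/s | export faster than formation (non-limiting) |
| export asymmetry | 0.1 (apical/basolateral) | basolateral-preferring conjugate efflux |
| extract matrix | ×3 on parent permeability, ×2 on apparent Km | see below |
| cell volume | 2.24×10⁻⁴ mL | sets lag timescale only (~10 s) |
| noise CV | 5 % | keeps 3-well SDs at realistic bench magnitudes |
| LLOQ | 0.025 µg/mL | assay quantification limit |

The kinetic defaults were fixed once, by solving the steady-state flux
balance for the regime pattern the study design requires, and then frozen:

1. **pure-compound arms**: receiver parent below the LLOQ at every timepoint
   in both directions and at both doses (near-complete first-pass
   conjugation), while total drug is quantifiable after deconjugation;
2. **extract arms**: receiver parent quantifiable, with a pre-deconjugation
   ER near 1 (passive, symmetric);
3. **saturation**: total-drug Papp strictly lower at the doubled extract
   dose;
4. after/before-deconjugation fold ≫ 1 and post-deconjugation ER < 1.

### The extract-matrix effect needs two knobs

A permeability-only matrix enhancement cannot produce pattern (1) and (2)
simultaneously here, because the pure doses (3.267–6.808 µg/mL) and the
extract-equivalent doses (3.2675–6.535 µg/mL) overlap almost exactly: any
intracellular-concentration regime reachable by the extract arms is nearly
reachable by the high pure dose, so whatever lets extract parent escape
conjugation also leaks pure parent above the LLOQ.  The generator therefore
models the matrix as (a) a ×3 enhancement of parent membrane permeability
(paracellular loosening by co-extracted compounds) **and** (b) a ×2
increase of the apparent conjugation Km — competitive inhibition by
co-extracted polyphenols that are themselves phase-II substrates.  Both are
plausible mechanisms for a complex plant matrix; jointly they separate the
regimes cleanly.  This is a modelling choice about what the synthetic data
should look like, not a claim about the biology of any particular extract.

### What the simulator does *not* emulate

* **Reported Papp magnitudes.**  Published post-deconjugation values of
  ~20–46×10⁻⁶ cm/s are mutually inconsistent with a 400 µL donor over
  2 h (they imply transporting more than the donor contains), so the
  generator targets the qualitative regime pattern — censoring structure,
  orderings, fold directions — at self-consistent magnitudes, not the
  printed numbers.
* Biological replicate variability (passage effects, monolayer-to-monolayer
  TEER differences): only measurement noise is modelled.
* Paracellular vs transcellular route resolution, pH gradients, unstirred
  water layers, transporter inhibition.

Consequently, passing tests demonstrate that the *analysis* is correct under
the stated mass-balance and noise assumptions — they do not validate any
biological claim about a real extract.

## 4. Numerical choices and degenerate inputs

* OLS slope r² is defined as 1 for an exactly constant Q series (nothing
  left to explain); fewer than two usable points → not evaluable.
* Noise can drive a near-zero fitted slope slightly negative; Papp is
  floored at 0 in that case.
* Paired tests with exactly zero-variance differences are reported as not
  evaluable rather than p = NaN.
* Config files are validated strictly: unknown keys are errors, geometry
  invariants (aliquot ≤ volume, positive dimensions) are enforced at load.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; study generation spawns per-replicate
  substreams from it, and identical seeds give byte-identical CSV output.

## 5. Problem sizes used in the checks

The property checks run at deliberately modest sizes chosen to probe the
estimators well: 100 random parameter draws for the ledger-equivalence
property; a four-point Papp grid (1, 5, 10, 50 ×10⁻⁶ cm/s) with 50 noise
seeds × 3 replicate fits per level for parameter recovery; and the default
4-dose × 2-direction × 2-arm × 3-replicate study for end-to-end round
trips.  Sink-regime recovery checks use enlarged chambers (40/120 mL) so
that donor depletion stays below ~1 % even at the fastest permeability —
that is what "sink regime" means operationally — and the passive-symmetry
check uses equal chamber volumes, since with unequal donors the two
directions deplete at different rates and their protocol-conditioned Papp
estimates legitimately differ.
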