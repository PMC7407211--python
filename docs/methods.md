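# Methods

## The measurement problem

Bile acids (BAs) and lysophospholipids (LPLs) circulate in plasma across
roughly five orders of magnitude and carry most of their structural
information in isomerism: hydroxylation position on the cholanoic core,
conjugation (glycine, taurine, sulfate, glucuronide), acyl chain length
and unsaturation, and the sn-1/sn-2 attachment position of the single
acyl chain of an LPL. A single negative-mode LC-HRMS run acquired as
all-ion fragmentation (AIF) — one MS1 scan over *m/z* 370–700 followed by
one fragment-level scan with no precursor isolation — can profile both
families at once, but every inference (identity, isomer, concentration)
must then be reconstructed computationally from accurate mass,
chromatographic co-elution and peak areas. That reconstruction is what
this package implements, together with the bioanalytical validation
calculus used to decide whether the numbers it produces can be trusted.

## Ion mass arithmetic

All masses are monoisotopic sums over IUPAC atomic masses (≥ 6 decimals;
deuterium is a first-class pseudo-element so labelled internal standards
parse like any other formula). Anion *m/z* includes the electron mass
(5.49 × 10⁻⁴ Da):

* [M−H]⁻ : M − m(H) + m(e)
* [M+CH₃COO]⁻ : M + m(CH₃COO) + m(e) — used for the choline lipids
  (LPC, O-LPC), which do not deprotonate efficiently; all other classes
  are detected deprotonated.
* intact anions (diagnostic fragments): m(composition) + m(e)

The electron-inclusive convention is not cosmetic: the class-diagnostic
fragment masses in the shipped registry (glycinate 74.0248, the three
taurine fragments 79.9574 / 106.9808 / 124.0074, bisulfate 96.9601,
glucuronide 193.0354) agree with instrument-reported values only when the
electron is counted. The M+1 isotopologue is modelled as a single ¹³C
substitution (Δ = 1.0033548 Da) with abundance 1.07 % per carbon; finer
isotope structure is out of scope.

The registry also records a neutral SO₃ loss for sulfated species. Its
mass is stored as computed from the composition (79.9568 Da); a slightly
different figure (79.9597) sometimes circulates in print and is kept as a
comment in the resource file, not used in computation.

## Chromatographic reconstruction

An extracted-ion chromatogram (XIC) is the per-scan sum of centroid
intensities inside a ±5 ppm window (the instrument-grade mass tolerance
used throughout; configurable). Scans with no in-window centroid
contribute zero — this matters for the noise estimate below.

Peak detection, replacing the proprietary vendor integrator:

1. smooth with a 5-point moving mean (maxima search only; integration is
   always on the raw trace);
2. take strict local maxima as candidates; extend bounds to the
   flanking valleys or to baseline return (2 % of the candidate's own
   apex — a *local* criterion, so a small analyte peak next to a 50×
   internal-standard peak on a shared fragment channel keeps its bounds);
3. split overlapping neighbours at the valley between apices;
4. estimate baseline noise as 1.4826 × MAD of the trace outside clearly
   dominant candidates (two-pass: a preliminary spread marks dominant
   regions, ordinary noise maxima stay in the baseline so the estimate is
   not biased low). Centroided baselines are sparse, so when the MAD
   collapses to zero the plain standard deviation is used; a truly flat
   baseline yields noise 0 and the S/N is flagged infinite;
5. keep candidates with S/N ≥ 3 (aligned with the detection-limit rule)
   **and** a contiguous half-height run of ≥ 4 scans. The second filter
   encodes the physics: at 0.5 s per MS level a σ = 0.04 min peak spans
   ≈ 5.6 scans at half height, while sparse noise centroids form 1–2-scan
   spikes. Without a shape criterion, S/N alone passes noise maxima on
   blank channels.

Areas are trapezoidal on the raw trace; S/N is height over the robust
baseline spread. Two peaks co-elute when their apices are within 0.1 min
and their RT intervals overlap — the only precursor/fragment link
available in AIF data.

## Identification

Identity is confirmed by three criteria: (1) an MS1 XIC peak at the
analyte mass; (2) at least one class-diagnostic fragment XIC peak (AIF
level) co-eluting with it; (3) apex RT within 0.1 min of the reference
standard's RT. Unconjugated bile acids fragment poorly in negative mode
and define no diagnostic fragments; for them criterion 2 is vacuously
satisfied and identification rests on mass + RT. Compounds whose RT is
predicted rather than measured on a standard are confirmable on criteria
1–2 alone, flagged `rt_source="predicted"`.

Untargeted screening enumerates candidate space: C24 cholanoic cores with
1–3 hydroxyls × conjugation sets of size ≤ 2 for bile acids (33
candidates); chain lengths C12–C22 × 0–6 double bonds × six LPL classes.
Every MS1 peak matching a candidate mass becomes a hit scored by the
fraction of expected fragment channels co-eluting; fragment-free matches
are reported as mass-only rather than suppressed, because in AIF data a
mass-only hit at low abundance is informative (fragments fall below
detection before precursors do).

sn-isomer assignment: when one LPL's XIC shows exactly two peaks with an
apex offset of 0.15–0.5 min and minor/major area ratio ≤ 0.35, the
earlier peak is labelled sn-2 and the later sn-1. The elution order of
the positional isomers is stored as a configuration option
(`sn2_first`, default true) rather than hard-coded, and a consistency
flag records whether the minor peak actually eluted first; polyunsaturated
species can show a third peak, which stays unlabelled. RT prediction for
species without standards is a per-class least-squares plane
rt = a + b·C + c·db (equivalent-carbon-number behaviour on a
reversed-phase gradient), quoted ± 0.3 min.

## Quantification and validation

Calibration fits area ratio (analyte/internal standard) against nominal
concentration by weighted least squares with weights 1/x, the standard
choice when calibration spans three orders of magnitude and relative —
not absolute — error should be uniform. The fit uses per-level mean
ratios; back-calculated deviations are evaluated per replicate. R² is
computed on the same weighted fit (1 − SSE_w/SST_w with the 1/x weights);
whether to weight R² is genuinely underdetermined by convention, so the
definition is fixed here for reproducibility. Acceptance follows the
usual bioanalytical rules: R² > 0.995 over ≥ 6 levels, |deviation| ≤ 15 %
(≤ 20 % at the LLOQ).

* LOD: lowest level at S/N ≥ 3.
* LOQ: lowest level *inside the calibrated range* with triplicate CV ≤ 20 %.
* Recovery: 100 × (pre-extraction spike area) / mean(post-extraction spike areas).
* Matrix effect: 100 × slope(matrix calibration) / slope(solvent calibration).
* Trueness: 100 × mean(measured)/nominal per QC level.
* Repeatability: pooled within-day CV from a days × replicates design.
* Intermediate precision: √(s²_within + s²_between)/grand mean, with the
  between-day component from a one-way ANOVA decomposition by day
  (negative estimates truncated at zero). The estimator behind
  "intermediate precision" is rarely stated in validation reports; this
  one is declared so the numbers are reproducible.

Species without calibration standards (most LPLs) get single-point
estimates analyte_area / IS_area × IS concentration against a
class-matched internal standard, documented as estimates (response
factor 1 assumed), never as validated quantification.

QC spike levels default to 0.02 / 0.20 / 2.00 µM; a variant triple with
0.002 µM at the bottom is accepted input as well.

## Cohort QC and statistics

Feature tables (samples × lipids, µM, three timepoints CID1/CID2/CID3)
are filtered per feature: discard when > 10 % of values are missing or
> 10 % of the non-missing values fall outside wide Tukey fences
[Q1 − k·IQR, Q3 + k·IQR] with k = 4 (quartiles by linear interpolation,
type 7; missing values are excluded and never flagged; constant features
flag nothing by the strict-inequality rule). Per-sample weight-loss
response features are log2(CID2/CID1) with missing/zero propagating to
missing — never imputed to zero, because a non-detected lipid is not a
zero-concentration lipid.

Two-sample comparisons from summary statistics use the Welch t-test by
default (Satterthwaite df), with the pooled-variance variant available;
group-balance tests on counts use the two-sided Fisher exact test (sum of
hypergeometric tables no more probable than the observed). Downstream
multivariate modelling (imputation by chained equations, sPLS-DA, mixed
models) belongs to dedicated tools; the module exports exactly the
matrices those tools consume — baseline levels, log2 fold-changes,
covariates, and a seeded 75/25 group-stratified split.

## What the synthetic generator emulates — and what it does not

`synthgen` produces runs with: one MS1 + one AIF scan per 1-s cycle
(0.5 s per level; instrument cycle time is not published, injection times
suggest this order); Gaussian elution (σ = 0.04 min, ~5.6 s FWHM,
typical of a sub-2-µm column at 450 µL/min); M+1 satellites; fragment
channels sharing the precursor's elution profile scaled by a yield
(default 0.2 of precursor intensity); sn-isomer pairs (default 9 % sn-2
share, 0.3 min earlier); uniform ±2 ppm mass jitter; and noise as a
sporadic baseline term (a half-normal draw of scale `noise_floor`
appearing in a channel on `noise_density` = 10 % of scans — centroided
baselines are sparse, not continuous) plus a proportional intensity term
(1–3 %). Response factors default to 10⁵ area counts·min per µM with the
internal standard matched to the analyte class, so single-point IS
estimates are exact in expectation. Centroids below 1 count are not
recorded, as on a real instrument. The `LOD_NOISE_FLOOR` constant
(1000 counts) is the one calibrated quantity: chosen once so a 0.003 µM
analyte sits about an order of magnitude above baseline, making the
detection limit land near the bottom of the calibrated range by design.

Not emulated: peak tailing/fronting, retention drift between runs,
chimeric-fragment interference between co-eluting compounds beyond
channel sharing, ion-suppression transients, or detector saturation.
Passing tests therefore demonstrate that the *algorithms* recover what
the acquisition model contains — they do not certify performance on real
plasma, where the validation experiments the package computes
(recovery, matrix effect, precision) exist precisely to measure those
unmodelled effects.

The cohort generator draws log-normal concentrations (median spread ~1
log unit across features, σ = 0.3 within), plants responder effects at
baseline that attenuate over follow-up, and injects missingness/outlier
violations in deterministic counts so the QC filter's truth is exact.

## Problem sizes

Tests and the acceptance script trim runs to the RT window that contains
the simulated analytes (typically 5–12 min of gradient at full scan rate)
and use 3 analytes + their internal standards for calibration series,
the full 26-compound panel for selectivity, 8 × 3 calibration designs,
5-replicate CV studies, and 100-subject × 116-feature cohorts — the
same designs at their natural sizes, shortened only in gradient dead
time.

## Known limitations

* AIF co-elution is necessary, not sufficient, for a precursor–fragment
  link; isomers sharing mass and RT cannot be distinguished without
  standards, and the screens report them as separate hits per peak.
* The vendor integrator is not reproduced bit-for-bit; equivalence with
  its areas is not claimed.
* The sn-2/sn-1 elution-order convention is configurable because the
  published evidence is not fully self-consistent; the default follows
  the standard-injection result (2-isomer first).
* Fisher's exact test and the t distribution come from scipy; the
  enumeration and closed-form oracles used to verify them live in the
  test suite.
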