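# Methods

## Scope and data model

The package processes direct-infusion FTICR-MS peak lists — per
(sample, analytical mode) tables of accurate mass and signal-to-noise
(S/N) intensity — into a *metabolite array* (unique neutral masses ×
samples) and runs time-course group statistics and accurate-mass
annotation on it. There is no chromatographic dimension: alignment is
purely in mass, and identification rests on mass accuracy plus
composition calculus.

Six analytical modes are modelled, combining ion source, polarity and
extract phase (codes 1101/1102 aqueous ±, 1201/1202 organic-1 ±,
1203/1204 organic-2 ±). Only polarity enters the computation (it fixes
the adduct sign); the source labels (ESI for aqueous/organic-1, APCI
for organic-2) are a naming convention, since with six of the eight
source × phase combinations run, the mapping is not uniquely determined
by the mode codes alone.

## Mass calculus

Atomic monoisotopic masses are IUPAC values to ≥ 8 decimals, shipped as
a versioned TSV so golden-value tests are bit-stable. Neutral masses
carry no electron-mass correction; the adduct step uses the proton mass
1.007276 Da directly, and the conversion m/z ↔ neutral assumes singly
charged [M+H]⁺ / [M−H]⁻ ions. The residue table stores amino-acid
residue formulas (amino acid minus water); a peptide of *n* residues is
the residue sum plus one H₂O, with N-acetyl (+C₂H₂O) and C-amide
(−O+N+H) terminal modifications available. Leu, Ile and Nle share one
composition class: accurate mass cannot distinguish them, nor determine
residue order, so compositions are treated as multisets throughout.

## Synthetic-data generator

The generator defines the study conditions the pipeline is validated
under; its defaults emulate a 12-week time-course with groups
control/week4/week8/week12 and realized replicate counts 2/3/2/3.

* **Metabolites**: rejection-sampled even-electron CHNOPS formulas with
  element-ratio bounds (H/C 0.3–3.0, N/C ≤ 1.3, O/C ≤ 1.2, P/C ≤ 0.3,
  S/C ≤ 0.8, integer RDBE in [0, 25]) and neutral mass in 100–1500 Da,
  so that enumeration tests face realistic decoys. Planted masses are
  kept ≥ 20 ppm apart (truth rows stay unambiguous) and ≥ 20 ppm away
  from every internal-standard m/z including the ¹³C positions — spiked
  calibrants are chosen to be interference-free in practice, and a
  calibrant overlapped by an analyte would corrupt the anchor match.
* **Intensity**: baseline log2 S/N ~ Uniform(2, 10) (the range seen in
  published reference tables); replicate noise is Gaussian on log2 S/N
  with sd 0.2, the simplest multiplicative model consistent with a
  10–15 % replicate CV (lognormal CV = sqrt(exp((0.2·ln2)²) − 1) ≈ 14 %).
* **Trend clusters**: group-mean offsets in units of the effect size δ —
  cluster 1: −δ at weeks 4/8/12; cluster 2: −δ at week 12; cluster 3:
  +δ at week 8 and −δ at week 12; cluster 4: +δ at week 12. Fractions
  of the panel are assigned per cluster; the remainder are nulls
  (effect 0). δ defaults to 1.5 log2 units, the scale of the published
  fold-change plots.
* **Mass axis**: per-run linear miscalibration (slope 1 + N(0, 2×10⁻⁶),
  intercept N(0, 0.2 mDa)) plus multiplicative N(0, 0.3 ppm) jitter per
  peak. ¹³C partners sit +1.0033548 Da above the parent with the exact
  expected abundance ratio n_C·0.0107/0.9893 (isotope-ratio noise is not
  modelled); partners below the S/N = 1 floor are not emitted.
* **Detection**: each metabolite appears in one or two
  polarity-compatible modes; the emulated study gives no per-metabolite
  mode model, so the assignment is random but seed-deterministic.
* **Replicate injections**: a pooled-extract emitter produces *n*
  replicate runs per mode (default 6) for QC.

What the generator does **not** emulate: peak shape/resolution, ion
suppression and matrix effects, correlated (compound-class) intensity
structure, multiply charged species, adducts beyond ±H, and isotope
fine structure. Passing tests therefore demonstrate correctness of the
computational pipeline under the stated statistical model, not
robustness to those instrument effects.

## Calibration

Standards are matched to peaks one-to-one, nearest in ppm first, ties
toward higher S/N, inside a 10 ppm window (the window must exceed the
miscalibration it corrects; with intercept-type errors of ~2 ppm at
m/z 110 a 5 ppm window would drop the low-mass anchor). Fewer than two
matches is an error. The correction regresses theoretical on observed
mass — so it applies directly to observed peaks — by linear least
squares with inverse-variance weights 1/m². The weights matter: FTICR
mass error is multiplicative, and an unweighted fit in Da lets the
high-mass standards dominate, leaving ppm-scale residuals at the
low-mass end (with 8 standards over 100–1000 and 0.3 ppm jitter, the
110 Da residual exceeds 1 ppm in ~14 % of runs unweighted, < 1 %
weighted). Post-fit residuals above 1 ppm raise a flag. Peaks outside
100–1000 m/z are corrected by the same line (extrapolation, logged).

## Alignment

Isotope pairing scans parents in ascending mass; a peak is flagged as a
¹³C partner when it lies at +1.0033548 Da within 2 ppm and its intensity
ratio matches n_C·0.0107/0.9893 within ±50 % (relative) for an integer
1 ≤ n_C ≤ mass/12. Flagged peaks are retained but never become rows.

Across samples, masses are clustered by single linkage in one
dimension (split where the gap exceeds the 2 ppm link threshold) rather
than fixed binning, avoiding bin-boundary artifacts; clusters spanning
more than 3× the threshold log a split warning. The representative mass
is the S/N-weighted mean; each sample contributes at most one peak per
row (nearest to the representative, ties toward higher S/N). Mode
tables are merged the same way; rows equal within tolerance across
modes collapse into one row with joint mode provenance (a flag
preserves the separate-count convention instead). Missing cells are
filled with S/N = 1, i.e. log2 = 0 — the floor-at-noise choice for S/N
data, where absence means "below noise", not "unknown". The 2 ppm
default leaves headroom over the < 1 ppm calibration guarantee.

## Statistics

All tests run on log2 S/N. The across-group test is a one-way ANOVA
(four groups); pairwise comparisons are independent two-sample Student
t-tests with pooled variance — the groups are different animals, so no
pairing exists; a paired variant would require a within-animal design.
Constant rows yield NaN p-values. P-values are reported raw (the
workflow's thresholds are 0.05 and 0.01); Benjamini–Hochberg adjustment
is available behind a flag but off by default. PCA treats samples as
observations of mass variables, column-centered, via SVD; variance
fractions sum to 1 by construction. HCA clusters masses by
1 − Pearson r and samples by Euclidean distance with average (UPGMA)
linkage — the distance metrics are fixed by the emulated workflow, the
linkage is this package's choice. Constant rows get the maximum
correlation distance (2.0) with a warning.

Trend profiles are control-normalized log2 fold changes at weeks
4/8/12 with significance flags a (vs control), b (vs week 4), c (vs
week 8) at α = 0.05. Classification is rule-based with a fold-change
threshold τ = 0.5 log2 units (the published description gives only
significance letters, so τ is a package choice: half the smallest
planted effect considered interesting): cluster 1 requires FC < −τ
with flag a at all three weeks; cluster 2 requires |FC| ≤ τ at weeks
4/8 and FC < −τ with a, b, c at week 12; cluster 3 requires FC > +τ
with a, b at week 8 and FC < −τ with a, c at week 12; cluster 4 mirrors
cluster 2 upward. Anything else is unclassified.

QC mirrors the replicate design: the CV of each internal standard's
S/N across a mode's replicate injections (averaged per mode; the
acceptance bound is a mean CV < 20 %, typically ~13 % under default
noise) and the pairwise R² between replicate log2 profiles after
aligning the replicates into one table (bound > 0.95).

## Annotation

Formula enumeration walks the bounded CHNOPS lattice (S, P, N, O, C
loops with running-mass pruning; H solved directly from the residual
mass), with mass-scaled default bounds (C ≤ m/12, H ≤ m/1.0078,
N ≤ m/14, O ≤ m/16, P ≤ 3, S ≤ 3). Filters: nitrogen rule (nominal-mass
parity equals N parity for even-electron neutrals), RDBE in [−0.5, 40]
computed with valences C4/H1/N3/O2/P3/S2 (P trivalent by convention;
the −0.5 floor admits protonation edge cases), and the element-ratio
limits above; carbon-free candidates are restricted to ≤ 5 heavy atoms
(small inorganics such as H₂O — ratio heuristics are meaningless
without carbon). Ranking is by |ppm| with ties toward lower RDBE;
contextual evidence (mode, extract, clustering) is surfaced as columns,
never folded into an opaque score. The de novo peptide search runs a
depth-first traversal over residue-class multisets of length 4–8 with
running-mass bounds. Library matching reports every (mass, compound)
pair inside the window; an empty hit table is itself a result (e.g.
oxysterol candidates that match nothing).

## Determinism and problem sizes

Every stochastic step takes a seed or Generator; the pipeline spawns
per-stage substreams from one root seed, and identical config + seed
reproduce byte-identical artifacts (hashes recorded in the run
manifest). Validation problem sizes were chosen to hold Monte-Carlo
error well below the decision margins: 200 runs for the calibration
residual contract, 100 seeds × 200-metabolite panels for the
multivariate-structure checks, 1000 null rows for type-I error, and
50–100 seeds for the QC summaries.

## Known limitations

Single charge and ±H adducts only (multiply charged peptides are noted
but not deconvolved); no isotope fine structure or averaged masses; no
retention/mobility dimension; enumeration beyond ~1500 Da becomes
slow and, more importantly, chemically underdetermined — candidate
lists grow too dense for mass-only identification, which is the method's
intrinsic boundary, not an implementation one.
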