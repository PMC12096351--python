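# Methods

## Problem setting

The package measures how faithfully a predicted electron-ionization (EI)
mass spectrum reproduces an experimental one, for libraries of
monosubstituted α-amino acids measured by GC-EI-MS, either free or
derivatized with MTBSTFA (which replaces active hydrogens on O, N and S
with tert-butyldimethylsilyl, TBDMS, groups). Spectra are centroided
integer-m/z stick spectra; predictions from neural-network predictors are
integer-mass by construction, and accurate-mass data are binned to the same
grid before comparison.

## Spectral representation

A spectrum is an ordered map m/z → intensity with non-negative finite
intensities and at least one positive peak. Fractional m/z values are
rounded **half-up** (59.5 → 60); peaks that collide after rounding merge by
intensity sum, which conserves total intensity exactly. Two spectra are
compared after zero-padding both onto the grid m/z = 0 … N−1 with
N = (larger maximum m/z) + 1. The grid deliberately starts at 0 even
though GC-EI instruments typically acquire from m/z 50: the zero region
contributes only zeros to dot products but *does* enter the RMSE
denominator (below).

Before RMSE, SCA and WCS, both spectra are normalized so the base peak
equals 100. Relative-intensity (0–100) spectra are the convention in EI
library work and make the RMSE scale well-defined; SEN instead renormalizes
each spectrum internally to a probability distribution, so it is
insensitive to the choice.

## The four accuracy measures

* **Padded RMSE** = √( (1/N) Σᵢ (Pᵢ−Oᵢ)² ) over all N padded positions.
  Note the quirk this definition inherits: N grows with the heaviest
  fragment of either spectrum, so heavier molecules dilute the same
  absolute peak disagreements over more grid positions. This is kept as
  defined rather than "fixed" — it is the reason derivatized (heavier)
  molecules can differ significantly from free ones on RMSE while being
  indistinguishable on the angular metrics, a behaviour the group
  comparison is designed to expose.
* **Spectral contrast angle (SCA)**: the angle between the two intensity
  vectors, in degrees. Computed as 2·arcsin(‖u−v‖/2) on unit vectors u, v —
  algebraically the arccos of the normalized dot product, but exactly 0 for
  identical inputs and accurate for small angles where arccos loses
  precision. Nonnegative intensities bound it in [0°, 90°].
* **Weighted cosine similarity (WCS)**: cosine similarity after the
  elementwise transform wᵢ = (m/z)^α · I^β. The α = 1, β = 0.5 defaults are
  the weighting convention used to train neural EI predictors; since
  published descriptions of this metric vary (e.g. the Stein–Scott
  weighting uses different exponents), both exponents are parameters of
  `MetricParams` and are recorded in every report manifest.
* **Spectral entropy similarity (SEN)**:
  1 − (2H(m) − H(p) − H(q))/ln 4, with H the Shannon entropy (natural
  log), p and q the two spectra as probability distributions and
  m = (p+q)/2 — a Jensen–Shannon divergence scaled into [0, 1]. The
  originating method's low-entropy re-weighting (intensities raised to
  0.25 + 0.25·H for spectra with H < 3, then renormalized) is implemented
  behind `sen_apply_li_weighting` and **off by default**, since evaluation
  practice varies on whether it is applied.

Identity behaviour is exact by construction: evaluate_pair(S, S) returns
(0, 0°, 1, 1) to machine precision, and two single-peak spectra at the same
m/z score as identical regardless of absolute intensity.

## Curation rules

The Type Ia monosubstituted α-amino-acid gate is one SMARTS-based
predicate: a tetrahedral carbon carrying (i) a primary amine — nitrogen
with two hydrogens, acyclic, not an amide (this excludes proline-like
secondary amines, N-methyl amino acids, sarcosine, betaines and peptide
bonds), (ii) a carboxylic acid, and (iii) at most one non-hydrogen side
chain; the molecule must contain exactly one such core. Glycine (side
chain = H) is accepted as the degenerate member. Derivatized molecules are
classified on the parent scaffold: TBDMS groups are stripped (restoring
O–H/N–H) before matching, so free and derivatized forms classify
identically. The definition is isolated in one predicate
(`classify_type1a`) so it can be amended if a different taxonomy is wanted.

Deduplication matches on the first (skeleton) block of the InChIKey,
ignoring stereochemistry, because EI fragmentation cannot distinguish
enantiomers; matching full keys would fail to deduplicate D/L pairs.
logP is Crippen's atom-contribution estimate; absolute values differ from
proprietary predictors, so only correlations against it are meaningful.

## Statistics

Library summaries are unweighted arithmetic means over pairs. Correlations
with molecular weight and logP are squared Pearson coefficients (simple
linear R²). The derivatized-vs-free comparison is a two-sided Welch
t-test (unequal variances, Welch–Satterthwaite df): group sizes and
variances genuinely differ between the two sets, and the choice is
conservative when they do not. Raw p-values are reported with the number
of tests recorded in the manifest; no multiplicity correction is applied.

Threshold classification: SCA < 26° is "adequate" for library search,
WCS > 0.7 "similar" (strict comparisons), and SEN ≥ 0.75 "similar"
(inclusive, following the "0.75 or greater" convention for this metric).
The exact comparators are part of `ThresholdConfig` and serialized with
every report. Degenerate inputs: constant metric columns (e.g. in an
undistorted control library) make R² and the t statistic undefined; these
combinations are reported as NaN with an explanatory note rather than
aborting the run, while the low-level functions raise.

## Synthetic data: what it emulates and what it does not

The generator exists because the real inputs — a proprietary reference
library and the output of a trained neural predictor — cannot be shipped.
It emulates the *structure* of the evaluation, not fragmentation chemistry:

* **Molecules** are drawn from a pool of 22 real Type Ia amino-acid SMILES
  (proteinogenic members plus norleucine, norvaline, homoserine and
  2-aminobutyric acid), with 30% of draws replaced by linear
  2-aminoalkanoic-acid homologs (chain length 1–12) to spread molecular
  weight; a configured fraction (default 0.5) receive bis-TBDMS
  derivatization on the α-amine and carboxyl via RDKit reactions. The
  resulting free+derivatized MW range is ≈75–500 Da.
* **Observed spectra** have 5–60 peaks at integer m/z drawn without
  replacement from [50, round(MW)+1], always including a molecular-ion
  peak at round(MW); intensities are log-normal (many small peaks, few
  large — the qualitative shape of EI spectra), base peak scaled to 100.
* **Predicted spectra** are distorted copies of the observed ones. The
  distortion model has four components — per-peak dropout (p = 0.35),
  ±1 Da mass shifts (p = 0.15, stressing integer-binning collisions),
  multiplicative log-normal intensity jitter (σ = 0.4), and Poisson
  spurious-peak insertion (rate 6) — each scaled linearly by a single
  `level` ∈ [0, 1]. Level 0 returns an exact copy; the base peak is never
  dropped so a spectrum always survives. These component magnitudes were
  chosen once so that mid-level distortion produces mean accuracy values
  in the range reported for real predicted-vs-experimental amino-acid
  comparisons (mean RMSE of order 10 on the 0–100 scale, mean SCA tens of
  degrees, WCS/SEN ≈ 0.6–0.95), and are config-exposed.

Reproducibility: each molecule consumes an independent
counter-based substream ([root seed, molecule index]) of the root seed, so
libraries are bit-identical across runs and robust to partial generation.

What passing tests on this generator shows: the metrics, curation and
statistics behave correctly on inputs with the right formats, scales and
degradation structure, and the pipeline discriminates distortion levels
monotonically. What it does not show: anything about real fragmentation
physics — isotope patterns, rearrangements, retention behaviour and
predictor-specific error structure are all absent, so library-level
accuracy numbers from synthetic runs are not comparable to evaluations on
measured spectra.

## Problem sizes and numerical choices

Tests and the acceptance script use 100–200 molecules per library, 200
pairs per distortion level, 100 power replicates and 1,000 null replicates
for the Welch calibration (n = 50/group) — sizes at which the Monte-Carlo
standard error of a rejection rate is ≤ 0.02 and the whole suite runs in
about a minute. Cosines are clamped to [−1, 1] (WCS additionally to
[0, 1]) to absorb floating-point overshoot; SEN is clipped to [0, 1].
MSP files store intensities with `repr` (shortest round-trip float), so
the parser/writer round trip is exact.

## Known limitations

* The Type Ia definition is a reconstruction isolated in one predicate;
  other taxonomies (Type Ib/II) are out of scope.
* The WCS exponent convention and SEN weighting of any particular external
  evaluation may differ from the defaults; both are parameters, and
  reports record what was used.
* Padded RMSE's dependence on N is inherited by design (see above) —
  comparisons of RMSE across molecules of different mass conflate
  disagreement with spectral extent.
* The synthetic distortion model is stationary across m/z; real prediction
  error is not.
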