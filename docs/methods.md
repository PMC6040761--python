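# Methods

## Scope and data model

The package evaluates how preanalytical handling of blood (collection tube
additives, delays before/after centrifugation, storage temperature and
duration, and hemolysis) perturbs the measured serum/plasma N-glycome. The
unit of analysis is a *glycome profile*: relative intensities of a fixed
panel of glycan compositions, normalized to sum 1. Two instrument views are
modeled: MALDI-TOF-MS of permethylated, sodiated glycans (46 compositions,
sialylation retained) and CE-LIF of desialylated APTS-labeled glycans
(23 co-migration bins, the sialic-acid dimension collapsed).

All internal math uses fractions; CSV interfaces are in percent with four
significant digits.

## Glycan mass calculus

Compositions are counted in Hex (H), HexNAc (N), deoxyhexose (F) and NeuAc
(S), with the N-glycan core constraint N ≥ 2, H ≥ 3 enforced at parse time.
Elemental formulas are assembled from dehydrated residue formulas plus one
water; permethylation adds CH₂ per derivatizable site, where

sites = 5·H + 5·N + 4·F + 7·S − 2·(residues − 1),

i.e. free-residue hydroxyl/N-H counts (NeuAc includes the carboxyl methyl
ester, hence 7) minus two sites per glycosidic bond. Monoisotopic masses use
CODATA atomic masses; charged adducts subtract the electron mass — the
[M+Na]⁺ of the permethylated disialylated biantennary composition evaluates
to 2792.38 Da, matching published tables. Building-block residue increments
are kept as configuration constants but validated against the
elemental-formula oracle in the test suite, so a hand-copied mass can never
drift silently.

Composition decomposition of an observed m/z enumerates the bounded grid
H ≤ 12, N ≤ 8, F ≤ 5, S ≤ 5 (covering the panel with margin) and returns
all compositions within half the 0.49 m/z calculation window; the window is
interpreted as a *full* width throughout the package.

## MALDI extraction chain

1. **Recalibration.** Nine glycan peaks of known composition spanning
   1836–4413 m/z anchor a linear observed→theoretical fit. Because the +1
   isotopologue outgrows the monoisotopic peak above roughly 2.4 kDa, each
   calibrant is searched at its *predicted tallest* isotopologue; apexes are
   refined by log-parabolic interpolation (exact for Gaussian peaks), and
   matches whose fit residual exceeds 0.2 Da are rejected iteratively.
   Fewer than three surviving calibrants is a hard error.
2. **Baseline.** Rolling minimum over ±5 Da followed by a rolling mean of
   the same width, clipped at zero. This stand-in for the instrument
   software's unnamed baseline detector is isolated behind one function;
   it is exact for flat offsets and idempotent on isolated peaks narrower
   than the window.
3. **Integration.** For each analyte the first k = 3 isotopologue windows
   (±0.245 m/z around mono + j·1.00336) are summed, counting each point
   once. Isotopologue abundances come from per-element binomial
   distributions convolved over the permethylated elemental formula.
   Points claimed by two analytes' windows are integrated jointly and split
   in proportion to predicted envelope abundance times a preliminary
   exclusive-point area estimate, conserving total signal (the default
   panel has no such collisions, but the rule makes panel edits safe).
4. **Normalization.** Areas are clipped at zero and divided by their sum;
   an all-zero extraction raises rather than returning a degenerate
   profile. Points below 990 m/z (acquisition ion suppression) never
   contribute.

## CE-LIF chain

Traces (uniform time axis, 0–20 min) are aligned on the highest peak of
each trace, smoothed with a Savitzky–Golay filter (11 points, cubic),
baseline-subtracted with the same rolling min/mean scheme, and integrated
by prominence-based peak detection with boundaries at the minima between
adjacent apexes. Peaks are assigned to bins by apex offset from the
internal-standard (APTS-maltose) apex; the internal standard is
auto-identified as the large peak that, used as the time reference, places
the most peaks inside bin windows. One peak per bin (largest area wins,
conflicts logged); relative areas are renormalized over assigned bins.

The generic detection default (prominence 0.5 % of the trace maximum) is
deliberately overridden in the pipeline configuration (2·10⁻⁴): the 23-bin
panel spans a ~10⁻³ dynamic range relative to the tallest peak, so a 0.5 %
cutoff would drop the small bins by construction. Spurious noise peaks are
harmless — they land outside bin windows or lose bin conflicts.

## Statistics

* Replicate means (3 MS / 2 CE) per (donor, condition), renormalized.
* Per-analyte Friedman test over the 15 complete-design conditions with the
  10 donors as blocks (average ranks, tie correction; implemented via
  scipy and cross-checked against a brute-force rank oracle in tests).
  Analytes pass the gate at p < .05; the all-ties degenerate case reports
  statistic 0, p 1.
* Post-hoc paired Wilcoxon signed-rank of each altered condition versus the
  matrix reference, SPSS conventions: zero differences dropped, average
  ranks for ties, Z = (T − n(n+1)/4)/√(n(n+1)(2n+1)/24) with **no**
  continuity correction and two-sided normal p. This convention is what
  reproduces Z = −2.803/−2.701/−2.599 for T = 0/1/2 at n = 10. Exact
  enumeration of the 2¹⁰ sign patterns shows the approximation deviates
  from the exact two-sided p by < 0.004 in the decision-relevant tail
  (approximate p ≤ .05) and by up to ~0.05 near the distribution center,
  where no decision depends on it. Thresholds: .05/9 → .0056 (serum,
  9 comparisons), .05/5 → .01 (plasma, 5 comparisons, one of which — the
  shaking-hemolysis arm — has only 5 donor pairs and is reported but cannot
  reach |Z| = 2.803).
* Shapiro–Wilk p values are reported to justify the nonparametric path;
  they never branch the analysis. Constant input reports NaN.
* Hemolysis correlations are Pearson r between free hemoglobin (mg/dl) and
  analyte/GLYCOV values, two-sided t-distribution p, with Evans strength
  labels on |r| in 0.2-wide bins, boundary values assigned upward
  (|r| = .80 is "very strong").
* Medians/IQR use linear percentile interpolation for cross-implementation
  determinism.

## Synthetic study generator

The generator emulates the study design exactly: two collection sets of
five donors; conditions 1–15 for everyone, condition 16 (overnight-shaking
hemolysis) only for the second set; serum reference = clot-activator tube F,
plasma reference = citrate tube H; tubes F and K feed multiple conditions;
3 MS and 2 CE preparations per cell — 465 MS and 310 CE preparations, 60 of
the MS preparations from reference tubes.

* **Donor glycomes**: lognormal perturbation (σ = 0.15) of the panel's
  reference medians, renormalized. The reference median fixture reproduces
  the published trait marginals (complex ≈ 93 %, oligomannose ≈ 6 %,
  hybrid ≈ 0.7 %, diantennary ≈ 72–75 %) but the per-analyte split is
  synthetic, constrained rather than measured, and replaceable by a
  laboratory panel CSV.
* **Condition effects**: multiplicative per-analyte vectors, default 1.0
  (the non-hemolysis conditions are simulated as null, because the study
  design reports directions/significance rather than fold changes).
* **Hemolysis**: free hemoglobin is drawn lognormally (hypotonic median
  100 mg/dl, shaking median 500 mg/dl, σ = 0.4 — visible-to-gross in vitro
  hemolysis); profiles respond as intensity·exp(slope·Hb) with slopes
  +2·10⁻³ per mg/dl for asialylated analytes (oligomannose included),
  −5·10⁻⁴ for monosialylated and −1·10⁻³ for multiply sialylated analytes,
  then renormalization. These defaults make the hemolysis-responsive
  analytes detectable at n = 10 under the default technical noise, and make
  GLYCOV strictly decreasing in hemoglobin by construction (denominator up,
  numerator down).
* **Technical noise**: multiplicative lognormal, CV 5 % per replicate for
  both modalities (intensities are positive and compositional).
* **MALDI signals**: Gaussian isotopologue peaks (σ = 0.05 Da) on a
  990–5000 Da axis at 0.05 Da steps, areas proportional to relative
  intensity × envelope abundance (10⁶ total counts), linear calibration
  drift (slope SD 5·10⁻⁵, intercept SD 0.03 Da), decaying-exponential
  baseline (2·10⁴ counts at 990 Da, τ = 1000 Da) and additive Gaussian
  detector noise (SD 200 counts), clipped at zero.
* **CE signals**: the profile is projected to the desialylated bin panel
  (drop S, merge; co-migration merges are fixture data), Gaussian peaks
  (σ = 0.04 min) at bin centers relative to the internal standard, a global
  migration shift (SD 0.1 min), slow linear baseline drift and detector
  noise.

One master seed determines everything (donor glycomes, hemoglobin,
replicate noise, per-sample signal seeds), so a rerun is byte-identical.
Ground truth (pre-noise profiles, hemoglobin, drift parameters, bin areas)
is emitted alongside every dataset.

**What the generator does not emulate** — and hence what passing round-trip
tests do *not* show about real data: mass-dependent TOF resolution and
detector saturation, matrix cluster ions and chemical background, real
co-migration drift and electroosmotic instability in CE, inter-batch
permethylation efficiency, and any analyte identity beyond composition
(linkage isomers are invisible to both the model and the real MS
measurement). Round-trip accuracy statements (< 0.5 percentage points per
analyte for MS at default noise, < 2 percentage points absolute for CE)
certify the processing chain against the generator's signal model, not
instrument physics.

## Problem sizes and numerical choices

Round-trip and mechanism analyses run at desk scale by restricting the
simulated design rather than changing any parameter: the MALDI round trip
uses the 10-donor reference conditions (60 spectra), the CE round trip 10
traces, calibration recovery 100 seeded drifts, null calibration 2000
Friedman/Wilcoxon replicates, and the hemolysis mechanism 200 seeded
shaking-arm studies. The full 465 + 310 preparation study runs end-to-end
in about a minute and is exercised by the pipeline tests.

Degenerate inputs are explicit errors, never silent: empty peak lists,
non-monotone axes, flat traces (no alignment maximum), missing replicate
cells, zero GLYCOV denominators, zero-variance correlations, and
sub-minimum calibrant matches. Ties are resolved deterministically
(average ranks in statistics; largest-area-wins in bin conflicts;
stable panel order everywhere).

## Known limitations

* The 46-analyte panel, its reference medians and the 23-bin CE map are
  synthetic fixtures constrained by published marginals (class counts,
  trait means, calibrant and GLYCOV membership, named analytes); both are
  replaceable by laboratory CSVs of the same layout, and the supplementary
  importer (`import_supplementary`) maps a complete-measurements
  spreadsheet onto the same schema so the statistics battery can run on
  real data.
* Antenna counts ignore bisecting GlcNAc (indistinguishable from an antenna
  by composition); hybrid classification of monosialylated N3H5-type
  compositions follows the composition rule.
* Recalibration is linear; nine well-spread calibrants over 1000–5000 Da
  make a line adequate, but strongly nonlinear miscalibration is out of
  scope.
* The Friedman battery runs on the complete conditions 1–15; the
  second-set-only condition 16 enters only post-hoc comparisons and
  correlations (n = 5).
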