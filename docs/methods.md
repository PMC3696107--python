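# Methods

## Scope and data model

The pipeline operates on five plain tabular inputs: sample metadata (WHO
grade, 4-year recurrence), 1D ¹H spectra (or a precomputed metabolite-level
table), per-nucleus FISH signal counts, a log2 expression matrix
(probesets × samples, RMA-style normalization assumed upstream), and an
RT-PCR Ct table. Everything is TSV: UTF-8, tab-delimited, header row,
decimal points, no quoting. Numeric TSVs are written with `%.17g` and read
with round-trip float parsing so that a written cohort reanalyzes to
bit-identical results.

## Metabolite quantification

Resonances are modeled as Lorentzians — the natural NMR lineshape —
L(x) = (A/π)·σ/((x−c)² + σ²) with full-line area A, center c (ppm) and
half-width at half-maximum σ. `fit_peak` performs a least-squares fit of k
components plus a constant baseline inside a fixed chemical-shift window
(lmfit/Levenberg–Marquardt; centers bounded to the window, areas bounded
non-negative). Initial centers default to the k highest well-separated
points in the window.

Fit quality is an L1 residual fraction, Σ|obs − fit| / Σ|obs| over the
window; a fit is accepted only below 0.10. The residual metric itself is a
package choice (the QC threshold is fixed at 10%); L1 was chosen over L2
for robustness to single-point outliers. Non-convergence yields a rejected
result (residual = ∞) rather than an exception.

Relative levels are accepted area / total spectral area (numerical integral
of |intensity| over the full recorded axis), in arbitrary units. Solvent
exclusion windows are configurable and off by default. Rejected fits leave
the metabolite flagged missing; missing markers later count as
not-in-range, which is conservative toward benignA.

The default marker library uses literature-standard shifts: lactate doublet
1.320/1.345 ppm, fatty-acid methyl band 0.88/0.92 ppm, choline 3.21 ppm,
taurine 3.25/3.42 ppm, all with σ = 8·10⁻⁴ ppm (≈1 Hz FWHM at 600 MHz).
The fatty-acid methylene band near 1.3 ppm is deliberately omitted: it
would overlap the lactate window, and the quantifier requires pairwise
disjoint windows so that every resonance is attributed to one metabolite.
Only window separation, not exact shift values, matters for the analysis.

## FISH deletion calling

Each nucleus is scored from its (test, control) signal pair: deleted when
the test probe shows fewer signals than the control, or at most one signal
against a present control (ratios 0/1, 0/2, 1/2, 1/3, …); normal otherwise
(the balanced 2/2 pattern and any test-excess pattern — gains are outside
the deletion rules); 0/0 is uninformative and leaves the denominator.
"Imbalance" patterns such as 1/3 are not distinguished from deletions
downstream; both map to status `deletion`.

A sample/probe is called deleted when the deleted fraction strictly exceeds
the cutoff (so exactly 20% at the default 0.20 cutoff is normal — the rule
is "> cutoff"). At least 50 informative nuclei are required; 100–200 are
conventional and anything outside that range warns. Region tags are
bookkeeping only: calls on pooled counts equal calls on region-tagged
counts.

Two cutoff policies exist, both configurable: the fixed 0.20 default, and
control-derived cutoffs median + 3·SD over per-control deleted fractions
from non-neoplastic tissue (used whenever controls are supplied; n−1 SD,
floored at 0). The pipeline logs which policy produced each cutoff.

## Classification rule

Grade II → atypical, unconditionally. For grade I:

1. **Chromosomal arm**: abnormal beyond chromosome 22, i.e. the union of
   FISH deletions and karyotype alteration labels minus {22} is non-empty.
   Isolated −22 — the canonical meningioma alteration — does not count.
2. **Metabolic arm**: ≥ 3 of the 4 markers within the two-sided inclusive
   band mean ± 2·SD of the atypical reference. The reference is the
   per-marker sample mean and n−1 SD over the supplied atypical profiles
   (≥ 2 usable samples per marker; profiles missing a marker are excluded
   from that marker's statistics only). Fixed external reference values can
   be supplied instead via `AtypicalReference`.

benignB iff arm 1 **or** arm 2 (inclusive or — samples without karyotypes
must still be classifiable by metabolites alone); otherwise benignA. A
grade I sample with neither evidence stream is an error, not a silent
label. The 2-SD band is inclusive at both ends; "markers required" (3) and
the SD multiplier (2) are parameters of `classify_sample` and
`PipelineConfig`.

## Differential expression

Per probe, a two-sided pooled-variance Student's t-test on log2 values
(each group n ≥ 2). Zero-pooled-variance probes use the documented
degenerate convention p = 1 if the means are equal, else 0. The same
pooled t (and convention) is used for metabolite group comparisons.

Fold change is computed from group means on the log2 scale and
back-transformed: r = 2^(mean_ref − mean_cmp), reported as r when r ≥ 1
and −1/r otherwise. Positive values mean higher in the reference group
(benignA in the study contrast).

Benjamini–Hochberg step-up q-values are computed over the **full** probe
set before any thresholding: q(i) = min over j ≥ i of p(j)·m/j along the
sorted p-values, capped at 1; tied p-values share the q of their last
sorted occurrence. The combined filter keeps a probe iff |FC| ≥ 2 AND
p < 0.005 (strict) AND q ≤ 0.005 (inclusive), mirroring the wording of the
original criteria ("2 or higher", "p<0.005", "maximum FDR 0.005"). Output
is sorted by signed fold change, descending.

Published tables print p and q rounded to 4 decimals, so re-checking a
printed record against the strict p-filter uses compatibility at printed
precision (`consistent_with_filter`): a printed p of 0.0050 is consistent
with an unrounded value that passed p < 0.005. Matrix-level filtering is
always strict.

Sample clustering uses 1 − Pearson correlation and average linkage — the
prevailing microarray convention; merge order ties resolve to the lower
sample index (scipy's deterministic behavior). A zero-variance sample has
undefined correlations; they are set to 0 (distance 1) with a warning.

## Outcome statistics

**Fisher test.** Two-sided exact p = sum of hypergeometric probabilities of
all tables with the observed margins that are at most as probable as the
observed table. This is the definition that reproduces the study's printed
recurrence p of 0.014 from counts 0/9 vs 6/11 (verified by enumeration in
the tests). A zero margin admits one table → p = 1. Reported p-values are
rounded to 3 decimals in outputs; full precision is kept internally.

The study also prints a −1p frequency comparison (5/32 vs 7/10) with
p = 0.023; enumeration of those counts under the standard two-sided
definition gives ≈0.0024, so that printed value is not reproducible from
its printed counts and is not used as a check here.

**ΔΔCt.** ΔCt = Ct_target − Ct_reference within each sample;
ΔΔCt = ΔCt − mean ΔCt of the control group; relative expression =
2^(−ΔΔCt), assuming 100% amplification efficiency (one cycle = twofold).
No efficiency correction is modeled. Samples missing the reference
measurement are excluded with a warning.

**Mann–Whitney.** For total n ≤ 20 the two-sided p comes from the full
permutation distribution of the rank-sum statistic with mid-ranks under
ties: the fraction of the C(n, n_x) group assignments whose rank sum
deviates from its null mean at least as much as observed. Beyond 20 the
tie-corrected normal approximation (scipy) is used; the study's validation
groups are n = 4, always exact. Discreteness makes the exact test
conservative at α = 0.05 (checked empirically in the tests).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the biology or physics behind it. Defaults are the study conditions:
20 benignA / 20 benignB / 14 atypical samples; recurrence probabilities
0.0 / 0.545 / 0.9 (0.545 = 6/11; the atypical figure is configurable since
the study's atypical denominators are reported inconsistently — the 2×2
counts actually tested were 0/9 vs 6/11); 1,000 probes with 50 planted
effects of |log2 FC| = 2 (alternating sign, shared by benignB and
atypical) on N(7,1) baselines with N(0, 0.25²) residual noise; Ct =
30 − log2(expression) + N(0, 0.15²) for four planted genes in 4 samples
per group, with a noise-free reference gene fixed at Ct 20.

Metabolite truth levels are group-wise Gaussians (benignB means equal
atypical means, benignA means at 40–50% of them, SD = 15% of the mean,
clipped at 0). Spectra are sums of the marker Lorentzians plus six
constant non-marker background resonances (total area 50 a.u., placed
outside all marker windows) emulating the metabolites common to all tissue
— without them, normalizing to total area would cancel the group structure
entirely. Spectral noise defaults to SD 0.4 intensity units against peak
heights of ~200–2000 (high SNR, as for 600 MHz tissue acquisitions), so
marker signals pass QC as they did in the study; raising it exercises the
QC-rejection path. FISH nuclei are Bernoulli-abnormal at per-group,
per-probe fractions (benignA: only −22 elevated; benignB/atypical: −1p and
−14 too), with abnormal nuclei drawing a random deleted ratio pattern and
3% of normal nuclei rendered uninformative (0/0). Non-neoplastic control
fractions are drawn per probe with centers calibrated so median + 3·SD
lands inside the cutoff ranges reported for these probes (14–22%).

Every draw flows from a single `numpy.random.Generator` seeded by
`SimConfig.seed`: identical configs give byte-identical cohorts, pipelines
and outputs.

Not emulated: raw CEL images or array normalization, FISH microscopy,
karyotype band strings, acquisition physics (temperature, spinning,
water suppression), probe-to-gene mapping, within-group correlation
structure, batch effects, or any dependence between metabolite levels,
chromosomal state and expression beyond the shared group labels. Passing
tests therefore demonstrate that the statistical machinery recovers known
planted structure under the study's nominal conditions — not performance
on real tissue data.

## Numerical choices and problem sizes

- Degenerate t-tests: p = 1 (equal means) / 0 (unequal) at zero pooled
  variance.
- Strict vs inclusive boundaries are fixed and tested explicitly: FISH
  call strictly > cutoff; DE p strictly < 0.005; FC and FDR inclusive;
  2-SD marker band inclusive at both ends.
- Group reductions are computed on contiguous arrays so results are
  bitwise identical whether a matrix arrives from memory or from disk.
- Test and acceptance runs use cohorts of 54 samples × 1,000 probes, 200
  null simulations for the false-discovery check, 100 replicates for the
  SNR-50 fitting check and 2,000 for the Mann–Whitney type-I-error check —
  sizes chosen so the planted-recovery and calibration bounds are sharp
  while the whole suite stays fast.

## Limitations

- The published table's FDR column derives from the full ~54,675-probe
  array and cannot be recomputed from its 59 printed rows; the fixture
  treats p, q and FC as given data. The original software's exact test
  variant is unrecorded, so results on the deposited array data
  (ArrayExpress E-MEXP-3586, never required by this package) are expected
  to be close but not identical.
- The benignA-vs-atypical published table (163 records) is distributed
  only as a journal supplement; the same loader parses it when a copy is
  placed at `data/supplementary_benignA_vs_atypical.tsv`.
- Gains/polysomies are not called; karyotype evidence enters as an opaque
  label set, not parsed ISCN strings.
- No survival modeling: recurrence is the study's binary 4-year endpoint.
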