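# Methods

## The model

Biodiesel quality is predicted here entirely from FAME composition, using
the empirical regressions listed in the README. These are literature
correlations, not thermodynamic models: each maps weight-percent composition
linearly (or, for CN, hyperbolically in SV) onto a measured fuel index. Their
assumptions and consequences:

* **Percents are used as printed.** Profiles whose totals fall short of
  100 % (unidentified peaks) are *not* renormalized. SV and IV are linear in
  the composition, so renormalizing would scale them by 100/TFA and break
  agreement with reference values computed on unnormalized tables. Callers
  who want normalized profiles can construct them explicitly with
  `normalize_peak_areas`.
* **Unrounded intermediates.** CFPP is computed from the unrounded LCSF, OS
  from the unrounded DU, CN from unrounded SV/IV. Rounding exists only at
  report time (`round_to`). This matters at the margins — e.g. a culture
  with LCSF 5.205 has CFPP −0.124 °C, which rounds to the printed −0.12 but
  would come out −0.11 if LCSF were rounded first.
* **Molar-mass convention.** The M in SV/IV is the methyl-ester mass
  (formula C(n+1)H(2(n+1)−2d)O₂), computed from atomic masses C 12.011,
  H 1.008, O 15.999. The free-acid convention is selectable
  (`convention="free_acid"`) for sensitivity analysis; it raises SV by ~5 %
  and does not reproduce the reference values. Residual disagreement with
  reference SV/IV under the ester convention is below 0.3 %.
* **Two pour-point readings.** Some sources print the PP regression with a
  "C18" symbol. Implemented on the palmitic percent (default), which
  reproduces every self-consistent reference PP cell; the stearic reading
  (`on_palmitic=False`) reproduces none but is kept selectable.
* **LCSF as a sum.** The long-chain saturation factor is the sum of its
  five weighted terms over the *saturated* C16–C24 percents (some printings
  omit the plus signs between terms).
* **FP terms.** The C18:1/C18:2/C18:3 flash-point terms sum across omega
  isomers; the C22 term is read as behenic acid (C22:0).

## Reported class totals vs re-summed composition

Transcribed literature tables can be internally inconsistent: printed class
sum rows (Σ MUFA etc.) sometimes disagree with the per-acid cells above
them, and downstream printed values follow the sums. `FAProfile` therefore
carries the printed totals as `reported_totals` alongside the composition;
`class_totals()` always recomputes, and `predict_all(...,
use_reported_totals=True)` is the faithful-reproduction mode for such
tables. For clean data the two paths are identical.

In the bundled reference dataset this matters for two cultures (Mn-4,
Mn-6), whose printed DU/OS only follow from the printed sums, and the
garbled Co-1 and Mn-2 columns are flagged `low_confidence` with a
transcription note. The fixture test requires every unflagged column to
re-sum to its printed totals within ±0.05.

## The audit

`audit_table` checks each printed property cell against the governing
equation applied to its *authoritative upstream inputs*: base properties
(SV, IV, LCSF, CP, PP, FP) against recomputation from the composition, DU
against the printed class sums, and chained properties against the printed
value of their own upstream column (CN from printed SV/IV, CFPP from printed
LCSF, OS from printed DU). This separates "the table is inconsistent with
its own inputs" from "an upstream cell was already wrong", and avoids
cascading one divergence into many. Flagging tolerances — SV/IV 0.5 %
relative; CN 0.5; DU/LCSF/CFPP/CP/PP 0.25; OS 0.05; FP 1.0 absolute — are
sized to absorb two-decimal transcription rounding across the affine maps
while catching genuine inconsistencies, which in the reference table are an
order of magnitude larger than the tolerance in every flagged case.

## REEC

The REEC baseline P_L is, per compound, the minimum over *treated* cultures
with a reported value; the control is scored but never sets the baseline.
The score is invariant under a common rescaling of either compound's yields,
so mg/g CDW and % DW inputs are interchangeable (mixing units within one
dataset is the caller's error to avoid). Because published yield tables may
report one compound only in a figure, `EnergyYields` permits a missing
value: such treatments are excluded from the baseline minima and receive an
undefined score rather than a fabricated one. Ranking is descending by
score, ties broken by lipid term then label; undefined scores sort last.

## Correlations

Plain Pearson r per (class, property) pair, two-sided t-test stars at
p < 0.05, no multiple-testing correction (one exploratory 3×10 matrix).
Zero-variance vectors yield an undefined (NaN, masked) cell, never 0.
Two modes exist because printed property tables may be internally
inconsistent: reproduce-figure mode correlates against the printed columns,
pipeline mode against the engine's recomputed ones. On the bundled data the
printed-mode r(SFA, OS) is 0.700; pipeline-mode values differ most where
the printed column disagrees with its own inputs (e.g. the control DU/OS
pair).

## Synthetic data

The generator emulates the statistical shape of heavy-metal-stress FAME
tables: per sample, class proportions (SFA, MUFA, PUFA) are drawn from a
Dirichlet centred on `class_mix` with concentration `class_concentration`;
an optional per-treatment additive shift is applied and clipped back to the
simplex; each class share is split over its panel acids by a second
Dirichlet whose weights favour the dominant species (palmitic, oleic,
linoleic); the result is scaled to a total drawn uniformly from
`tfa_range`; and percents below `nd_threshold` are zeroed to mimic
"not detected" cells.

Defaults are calibrated to the reference panel: `class_mix = (0.59, 0.37,
0.04)` (the mean class shares of the 11 cultures), `class_concentration =
60` (giving the observed few-point spread), `tfa_range = (72, 100)` (the
printed total range), `nd_threshold = 0.05 %`. Yields are gamma draws with
configured mean and coefficient of variation (CV 0.05 by default at the
reference means); zero CV returns the mean exactly, which is how the
generate→REEC chain is checked end-to-end against the reference score.

Determinism: one integer seed; sample *i* uses substream `(0, i)` and yield
row *j* substream `(1, j)` of `numpy.random.SeedSequence(seed)`, so growing
`n_samples` never reshuffles earlier samples.

What the generator does **not** emulate: mechanistic metal-stress
physiology (effects are phenomenological class-proportion shifts),
between-acid correlations beyond class structure, measurement error on
individual peaks, or replicate structure. Passing tests on synthetic data
therefore demonstrate the pipeline's correctness and invariances, not
biological realism of any particular treatment effect.

## Numerical and degenerate-input choices

* Empty profile: SV = IV = 0, DU = 0, cold-flow indices at their
  intercepts; CN raises (division by SV). `normalize_peak_areas` rejects
  all-zero areas.
* Profile totals may exceed 100 by at most 0.5 (printed-table rounding);
  more is a validation error.
* Standards: comparators are inclusive (boundary values pass); seasonal
  limits require an explicit season, and winter is at least as strict as
  summer in every encoded standard. Limits live in a versioned YAML
  resource; properties a standard does not regulate are absent from its
  map and graded "not-specified".
* Correlation needs ≥ 3 paired samples; fewer is an error, not a NaN.

## Problem sizes

The reference dataset is 11 cultures × 29 panel acids; the property-based
checks run on 1,000 synthetic profiles and the calibration checks on 200 —
sizes chosen so the whole suite and the analysis scripts complete in
seconds while the law-of-large-numbers assertions (±3 points on class
shares at n = 200) remain comfortably stable across seeds.

## Known limitations

* The regressions are calibrated for vegetable-oil-range FAMEs; profiles
  dominated by very short (C4–C10) or very long (C28+) chains extrapolate
  outside the calibration data, and CN via 5448/SV degrades for SV far from
  the typical 140–210 range.
* Viscosity and density — part of full standard parameter sets — have no
  composition regression here and are not graded.
* Several printed reference cells (CN and FP columns especially) are not
  reproducible from their own inputs under any reading of the equations;
  the package documents these via the audit rather than fitting to them.
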