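# Methods

This note documents the models, parameter choices and numerical conventions
behind `ncx`, and what the synthetic benchmark does and does not establish.

## Scope and data model

The pipeline starts from *identified* MS1 peptide features — one row per
(protein accession, peptide sequence, charge) with theoretical and observed
m/z, retention time (minutes) and peak volume (PV, integrated MS1
intensity) — plus per-run metadata: bait antibody, sample class
(`target_ap`, `tuc_control`, `ko_control`) and solubilisation detergent
(`CL-47` mild, `CL-91` intermediate stringency). Spectral search,
feature detection and charge deconvolution are upstream and out of scope.
Feature tables are a documented bespoke TSV (the in-house formats these
pipelines consume have no published schema); protein sequences are FASTA.

Protein grouping is by exact accession. Collapsing subset/homologous
proteins onto a predominant group member is not implemented; inputs are
assumed pre-grouped.

## Mass arithmetic and digestion

Monoisotopic masses (via `pyteomics.mass`) are used for all ppm-scale m/z
arithmetic; average masses for gel-scale reporting (protein and oligomer
masses in kDa), where the isotope envelope is unresolved. The tryptic rule
is "cleave after K/R, not before P" — the convention matching common search
engines; the Keil WK/MR exceptions are deliberately not applied. Default
digest parameters: ≤1 missed cleavage (mirroring the upstream search
setting) and a 700–3500 Da window as the MS1-observable range. The
*MS-accessible peptide count* (the abundance-norm denominator) is the
number of distinct in-window tryptic peptides at those settings; this is a
declared stand-in for the unpublished upstream definition and is
configurable through `DigestParams`.

## m/z recalibration

Per run, the offset is the median of (observed − theoretical)/theoretical
× 1e6 over peptides matched within a wide 50 ppm window (≥20 matches
required); observed m/z is divided by (1 + offset·1e−6). The median makes
the estimate robust to a minority of mismatches; with ≥1000 features the
residual offset is ≪0.1 ppm.

## Retention-time alignment

Reference times are the median peptide elution times over all aligned
runs (each run votes once per (peptide, charge), via its within-run
median). Each run is warped onto the reference by LOESS (tricube weights)
with span 0.3 and 2 robustifying iterations — the method is named by the
upstream workflow, the hyperparameters are this package's defaults — and
the fitted curve is passed through isotonic regression so the warp is
non-decreasing: elution order must never be inverted by alignment.
Prediction interpolates linearly between anchors and extends with unit
slope outside them. "Dynamically calculated" reference times are realised
as 2 alternation rounds of {reference → per-run warp → apply}; per-run
residual MAD is reported per round and is non-increasing on simulated
data. Warping a run needs ≥30 anchors (configurable); fewer is an error
naming the run rather than a silent skip.

## PV assignment

A feature is assigned to a library peptide iff |ΔRT| ≤ 1 min and
|Δppm| ≤ 3 ppm (the upstream window is quoted as 2–3 ppm; 3 is the default
and both windows are configurable). Each feature goes to at most one
peptide; ambiguity is broken by smaller |Δppm|, then smaller |ΔRT|, then
lexicographic (peptide, charge) order — a deterministic rule chosen because
the upstream description is silent. PVs of features mapping to the same
(peptide, charge) are summed, so total assigned PV never exceeds total
feature PV.

## Quantification and ratios

Per (protein, run): total PV over *specific* peptides (those mapping to a
single protein in the library); proteins with <2 distinct specific peptides
are excluded. `abundance_norm = total_pv / n_accessible` (flagged undefined
when the denominator is 0). AP-versus-control comparisons use the median
abundance norm over target pull-downs against the **maximum** over all
control runs — the worst-case control is the stringent choice; the upstream
description states the comparison but not the aggregation. A protein absent
from every control keeps a distinguishable `control_detected = False` flag
and is compared against a pseudo-floor of half the smallest positive
control abundance norm, avoiding infinite ratios.

## Interactor calling

Specificity per pull-down: abundance ratio ≥ `specificity_fold` (default
10), or never detected in any control. The published record of this
procedure color-codes specificity without printing a numeric threshold;
10 is this package's declared default and separates planted truth from
background cleanly on the benchmark. Consistency: ≥2 distinct antibodies
among the specificity-passing pull-downs of one detergent. Relative
abundance classes use lower-inclusive bounds, with "=" closed at 3.3;
ratios above 3.3 map to "=" with a warning since no class is defined above
the reference. The bait is reported with ratio 1 and class "=" but excluded
from the high-confidence partner set. Raising either threshold can only
shrink the called set (tested property).

## BN-gel complexome profiling

Slice 1 is the gel top (largest mass); profiles are smoothed by a centered
5-slice sliding average whose window truncates at the edges (length
preserved, no padding artifacts). Calibration fits the 4-parameter logistic
`log10(M) = d + (a − d)/(1 + exp((s − s0)/b))` through ≥4 markers spanning
≥1 decade by least squares (`scipy.optimize.curve_fit`, bounded, p0 from
the marker range); monotonicity of the fitted curve is verified and
`fit_residual_mad` reports the sigma-consistent robust residual scale
(1.4826 × MAD, log10 units). "Sigmoidal" is realised as the 4-parameter
logistic; the exact upstream parameterisation is unpublished. Peak reports
take the argmax slice (ties → smaller slice = larger mass, with a
multi-peak flag), convert it through the calibration, and bound the mass
range by the outermost slices at ≥50% of the peak — the half-maximum rule
is a declared choice; published mass ranges of this kind do not state their
bound rule. All-zero profiles yield a flagged no-peak report.

## Synthetic benchmark

`simulate_apms_study` emulates the study design the pipeline targets:

- 5 target antibodies × 2 detergents, 5 TUC antibodies × 2 detergents, and
  KO pull-downs per target antibody (30 runs);
- 1 bait + 5 planted partners (bait-relative ratios 1, 0.1, 0.1, 0.1,
  0.01, spanning the `=`/`<`/`<<` classes) among 500 background proteins;
- background abundances log-uniform over 4 decades below the bait
  (matching the quantification dynamic range of the emulated instrument
  workflow); partners absent from every control by default
  (`enrichment_fold = inf`; finite values place them at
  target/enrichment_fold);
- partner levels attenuated 10× under CL-91 (weaker complexes survive only
  the milder detergent);
- per-run monotone RT drift: PCHIP through 6 knots with bounded random
  perturbation (amplitude ≤2 min) and a minimum-slope repair — smooth and
  strictly increasing, which is all LOESS alignment assumes;
- constant per-run m/z offset uniform in ±10 ppm plus 0.5 ppm per-feature
  noise; log-normal PV noise (σ = 0.5 natural log); 15% feature dropout and
  a PV detection floor of 1e3 (so a 5-decade study censors its bottom
  half-decade, giving the dynamic-range check a physical limit);
- peptides are real tryptic products of generated sequences (unique
  6–17-mer blocks ending in K/R), so ppm arithmetic acts on physically
  sensible m/z values at charges 2–3.

`simulate_complexome` plants Gaussian peaks (192 slices) at the positions
implied by each complex's mass through a known logistic, with 7 markers at
140–3000 kDa, multiplicative PV noise (σ = 0.05) and a 0.02 log10-mass
migration jitter applied to every complex — the irreducible gel
irregularity that calibration must average over.

What the generators do **not** emulate: correlated contaminant structure
(CRAPome-style frequent flyers), abundance-dependent ionisation bias,
chromatographic peak shapes, charge-envelope overlap, shared peptides
between homologues, or real TUC off-target binding (controls carry
background binders only — recorded as an assumption). Passing the benchmark
therefore demonstrates that the decision procedure and numerical stages are
implemented correctly and are recoverable under realistic noise, not that
the thresholds are optimal for any particular real dataset.

## Benchmark problem sizes

The default study (30 runs × ~3000 features) runs the full pipeline in
~15 s on one CPU; the test suite completes in well under a minute except
for the end-to-end acceptance checks (~1 min total). These sizes were
chosen as the smallest at which the planted effects are comfortably
recoverable at the stated tolerances.

## Known limitations

- Exact-accession grouping only; no parsimony/homology collapse.
- No cross-run normalisation beyond the abundance norm (no iBAQ/LFQ-style
  scaling), no match-between-runs FDR model.
- The calibration's `valid_slice_range` is the marker span; outside it the
  logistic extrapolates with a warning.
- The tetramer reference-mass check depends on the canonical mouse TRPM7
  sequence (UniProtKB Q923J1), which must be fetched or supplied locally;
  the package bundles no third-party sequence data.
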