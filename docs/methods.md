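# Methods

## The measurement model

A cytosine site carries f⁵C on a fraction `f` of the transcript
molecules that span it. Pic-borane reduces a carried f⁵C to
dihydrouracil (DHU) with per-molecule probability ε (the conversion
efficiency); DHU is read through by reverse transcriptase and called T.
Unconverted cytosines are miscalled T with probability e₀ (the
background C-to-T error of the library: RT misincorporation, sequencing
error surviving quality filters, trace chemistry side products). Reads
are conditionally independent given the site, so the T count at a site
with filtered coverage n is

    n_T ~ Binomial(n, p),   p = f·ε + (1 − f·ε)·e₀ = ε(1 − e₀)·f + e₀.

This is exactly linear in `f`, with slope a = ε(1 − e₀) and intercept
b = e₀ — the justification for the straight-line calibration and for
the binomial machinery everywhere downstream. Real libraries depart
from this ideal in ways the model deliberately omits (see
*Limitations*).

### Reduction-cascade masses (`chem_mass`)

The cascade is represented as signed elemental deltas on two mass
scales:

| step | elemental change | avg Δ (Da) | mono Δ (Da) |
|---|---|---|---|
| 3,4-reduction | +H₂ | +2.016 | +2.0157 |
| deformylation | −CHO +H = −CO | −28.010 | −27.9949 |
| deamination | −NH₂ +OH | +0.984 | +0.9840 |
| net (f⁵C → DHU) | | −25.010 | −24.9952 |

Average atomic masses H 1.008, C 12.011, N 14.007, O 15.999;
monoisotopic values to 7 decimals. Operations act on a supplied
starting mass rather than computing oligo masses de novo, since the
probe's sequence identity is irrelevant to the deltas. Printed-peak
comparison rounds half away from zero to the nearest Dalton, matching
how MALDI peak labels are reported. Observed m/z values are treated as
neutral average masses; no adduct or charge-state correction is
applied. Peak assignment is deterministic and refuses symmetric ties
(two candidates within tolerance raise rather than picking one).

The low-temperature condition returns {f⁵C, DHf⁵C, DHC} — the stalled
cascade with its deformylated-but-not-deaminated minor intermediate —
and the high-temperature condition returns {DHU} only. Relative peak
intensities are not modeled.

## Synthetic libraries (`simulate`)

The generator emulates, per transcript: uniform random fragmentation
breakpoints with truncated-normal fragment lengths (mean 40 nt, SD 8,
minimum 15 — an alkaline-fragmentation-like size profile; the chemistry
itself leaves f⁵C intact and is not modeled); per-molecule Bernoulli
modification and conversion as above; an optional uniform sequencing
error that flips any base to one of the other three; and optional 1–2 nt
indels with proper CIGARs, used to exercise alignment-walking code.
Reads are single-end, emitted both as FASTQ (molecule orientation) and
as a "perfect" SAM with true coordinates, so the downstream modules are
testable without an aligner. Transcripts annotated on the `−` strand
generate reverse-flagged alignments whose conversion evidence appears
as G-to-A in reference space.

Defaults are the package's study conditions: conversion efficiency
ε = 0.9 (the calibration slope implied by the assay's high observed
mutation rates at fully modified sites), background e₀ = 0.002
(surrounding-base mutation in this chemistry is minimal), sequencing
error 0 unless enabled. The spike-in design is the NN(f⁵C)NN wildcard
motif (256 contexts, each embedded in fixed 10-nt flanks as its own
short transcript) plus a five-point fraction series at
{0, 0.25, 0.5, 0.75, 1}; the series values follow the standard
evenly-spaced design since the assay's own oligo fractions are not
published. Three modes: `pic_borane` (the assay), `untreated_input`
(ε forced to 0; the SNP/editing control), and `malononitrile` (adduct
chemistry whose dominant product is an RT stop: each adducted site
truncates the cDNA with probability τ, giving single-site read-through
rate 1 − f·τ; adducts that are read through are miscalled T). With
multiple stop sites per fragment the per-site read-through summary
counts a read as spanning if it survives truncation at that site, which
slightly overstates spanning when another site truncates first — the
single-site case, which is what the summary is designed for, is exact.

All randomness flows from one `numpy` PCG64 generator keyed by the
config seed, with draws in deterministic transcript/read order, so a
config is byte-reproducible. `simulate_site_counts` exposes the
counts-level marginal of the same model (binomial draws of n_T per
site) for statistical checks where individual reads are not needed;
read-level/counts-level agreement is itself under test.

## Pileup counting (`pileup`)

SAM records are parsed with pysam; counting is done in-package because
the per-strand, per-reference-base bookkeeping is the quantity under
study. A site lives on the strand where the reference base is C: `+`
sites count forward alignments (T = mutation evidence, C = reference,
anything else = other), `−` sites count reverse-flagged alignments
(A/G in forward alignment space). The protocol is assumed
strand-preserving, so cross-strand alignments never contribute.
Filters: mapping quality ≥ 10, base quality ≥ 20 by default (the
assay's own thresholds are not published; these are ordinary
short-read values and are exposed as parameters). Read Ns and deleted
positions contribute to no counter, so n_T + n_C + n_other = coverage
holds exactly. Coordinates are 0-based half-open internally; TSVs also
carry a 1-based column. Perfect single-M alignments take a vectorized
path; anything with indels/clips walks aligned pairs base by base —
both paths are checked against an independent naive recount.

## Calibration (`calibrate`)

The spike-in points (f, m, n) are fitted by weighted least squares with
weights n/(m̂(1−m̂)), m̂ clamped to [0.5/n, 1−0.5/n] so zero-mutation
points keep finite weight. Because these weights are *known* binomial
variances, parameter standard errors and the slope–intercept covariance
are reported at fixed scale 1 (known-variance GLS) rather than
rescaled by the residual variance — with a five-point series the
residual estimate has 3 degrees of freedom and would make the SEs
themselves unusably noisy. Sampling noise around a clean background can
push the fitted line marginally outside the physical region, so the
intercept is floored at 0 and the slope capped at 1 − b; predictions
then stay in [0,1] over f ∈ [0,1].

Inversion is f̂ = (m − b)/a, clamped to [0,1] with an explicit flag
(never silently), and strictly increasing in m on the unclamped range.
Uncertainty: a Wilson score interval on the rate at 95% (default) is
propagated through the inverse line; the delta-method SE additionally
folds in Var(b̂), Var(â) and their covariance. A curvature fallback is
deliberately not fitted — the relation is linear under the model above,
and the observed calibration is described as nearly linear; residual
diagnostics (R², residual SD) are reported so a user can judge.

Context dependence: per-context rates over the full 4ᴺ design, the
pooled grand mean, between-context SD and CV, and a z-flag for contexts
deviating from the grand mean by more than 5 binomial SEs (null
contexts across a 256-member family stay below ~3.5; a genuinely
aberrant context, e.g. half efficiency, sits tens of SEs out).

## Site calling (`callsites`)

Background e₀ is pooled n_T over pooled coverage across non-candidate
cytosines with coverage ≥ 10 (at least 100 such sites required).
Candidates need coverage ≥ 20 and rate ≥ 0.05 — permissive enough that
sites at the low stoichiometries seen in polyadenylated RNA (≤ 10%)
remain callable at adequate depth. Each candidate gets a one-sided
exact binomial tail P(X ≥ n_T | n, e₀); adjustment across candidates is
Benjamini–Hochberg at α = 0.05 (an FDR framing suits a
transcriptome-wide scan with hundreds of tests; Holm–Šídák is reserved
for the replicate-level contrasts in `diffmod`). Ties in the discrete
p-values receive equal q, so calling is invariant to input row order.
An untreated input library vetoes sites whose unconverted C-to-T rate
strictly exceeds 0.01 (genomic SNPs, native C-to-U editing); sites the
input does not cover at depth ≥ 10 are flagged `input_uncovered` but
retained with a warning. Output carries every input site with flag
columns, plus BED6+ export of the called set (score = 1000·f̂).

## Differential modification (`diffmod`)

Replicate-level rates (or fractions, by flag) are compared per site
with a two-sample t-test and Holm–Šídák step-down adjustment over all
sites tested in the run; labels follow the ns/*/**/*** convention at
0.05/0.01/0.001. The default variant is Student's pooled-variance test:
with two technical replicates per condition — the design this assay
actually uses — Welch's Satterthwaite degrees of freedom collapse
toward 1 whenever the two sample variances differ by chance, inflating
the critical t from ~9.9 to ~63.7 at the 1% level and destroying power
for effects the assay clearly resolves (a 42% → 29% fraction drop at
coverage 5,000 is detected at adjusted p < 0.01 in ~95% of simulations
with the pooled test versus ~50% with Welch). Welch remains available
via `variant="welch"` for designs with more replicates. Zero-variance
degenerate cases follow a documented convention (equal means p = 1,
unequal p = 0), and every result from ≤ 2 replicates per group carries
a low-replicate warning flag. Tests default to the mutation-rate scale
(the directly observed quantity); testing deduced fractions instead is
a flag.

## Problem sizes used in the checks

The statistical test-suite checks run at the model's study conditions:
spike-in series and fraction-grid recovery at 50,000 reads/site over 40
seeds; caller error control on 10,000-site null scenes and
5-true-site scenes (coverage 1,000) over 40 seeds; knockdown power at
coverage 5,000, two replicates, 40 seeds; pileup/oracle equivalence on
100 simulated alignments of up to 1,000 reads with mixed strands and
indels. Counts-level draws are used where only per-site statistics
matter; read-level checks (law of large numbers at 10,000 reads × 50
seeds, byte-level reproducibility, SAM/FASTQ consistency) cover the
read path itself.

## Limitations

- The model omits ligation bias, PCR duplication, quality
  miscalibration, paired-end structure, and context-specific conversion
  efficiency (the assay demonstrates context independence; the
  simulator takes it as given).
- Conversion efficiency and background error are free parameters, not
  asserted constants; published mutation-rate/fraction pairs imply
  ε near 0.9 but the assay's fitted calibration parameters are not
  public, so absolute fraction estimates from real data inherit the
  user's spike-in fit.
- Carboxylcytosine would in principle produce the same signature; it is
  not modeled (none has been detected in RNA).
- The caller assumes a single pooled background; locally elevated error
  (e.g. near splice junctions in real alignments) is not modeled.
- `build_pileup` consumes alignments as given; it performs no
  realignment or duplicate marking.
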