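# f5cseq

Quantitative, base-resolution mapping of 5-formylcytosine (f⁵C) in RNA
from chemical-conversion sequencing data.

f⁵C occurs naturally in RNA — most prominently at C34 of human
mitochondrial tRNA-Met and cytosolic tRNA-Leu, where it is installed by
NSUN3 (m⁵C) and ALKBH1 (oxidation to f⁵C) — and at lower stoichiometry
across mRNA and chromatin-associated RNA. Treating RNA with 2-picoline
borane (pic-borane) reduces f⁵C through a three-step cascade
(3,4-reduction → deformylation → deamination) to dihydrouracil (DHU),
which reverse transcriptase reads through and calls as T. A modified
site therefore appears as a C-to-T mismatch signal whose rate is, to a
good approximation, linear in the modification fraction:

```
m = f·ε + (1 − f·ε)·e₀  ≈  a·f + b
```

where `f` is the fraction of molecules modified at the site, `ε` the
chemical conversion efficiency (absorbed into the slope `a`), and `e₀`
the background C-to-T error (the intercept `b`). Spike-in oligos with
known `f` pin down `(a, b)`, so an observed mutation rate `m` at any
transcriptomic cytosine inverts into an absolute stoichiometry estimate
`f̂ = (m − b)/a`.

The package is aimed at epitranscriptomics groups running (or
simulating) this class of mutation-signature assay. It provides:

- **`f5cseq.chem_mass`** — elemental mass deltas of the reduction
  cascade and MALDI-TOF peak prediction/assignment for the reaction
  intermediates (f⁵C → DHf⁵C → DHC → DHU).
- **`f5cseq.simulate`** — a generative read simulator for
  pic-borane-converted libraries (per-molecule Bernoulli modification,
  conversion, background error, alkaline-fragmentation-style breakpoints,
  optional RT-stop chemistry and untreated input mode), emitting FASTQ,
  a perfect-alignment SAM and a ground-truth table.
- **`f5cseq.pileup`** — strand-aware per-cytosine mismatch counting
  (C-to-T on `+` sites, G-to-A on reverse-strand alignments for `−`
  sites) with base/mapping-quality filters.
- **`f5cseq.calibrate`** — weighted least-squares spike-in calibration,
  rate→fraction inversion with Wilson confidence intervals, and a
  sequence-context dependence report over the NN(f⁵C)NN spike-in set.
- **`f5cseq.callsites`** — transcriptome-wide site calling: pooled
  background estimation, one-sided exact binomial tests,
  Benjamini–Hochberg adjustment, untreated-input SNP/editing filtering,
  BED export.
- **`f5cseq.diffmod`** — replicate-level condition contrasts
  (e.g. shControl vs shALKBH1) with t-tests and Holm–Šídák step-down
  adjustment.

## Worked example

Predict the MALDI peaks of a 1,555 Da f⁵C 5-mer probe fully reduced at
70 °C:

```sh
$ f5cseq mass --start-mass 1555 --condition high
label   mass_avg        mass_mono
DHU     1529.990        1530.0048
```

The sole product is DHU at 1,530 Da (nearest integer): the cascade's
net elemental change is +H₂ − CO − NH₂ + OH = −25.01 Da. At 25 °C
(`--condition low`) the reaction stalls and the intermediates DHf⁵C
(1,557) and DHC (1,529) appear instead.

Simulate a small converted library (5 random transcripts plus the
256-context and five-fraction spike-in sets), pile it up, calibrate and
call sites:

```sh
$ f5cseq simulate --seed 3 --n-transcripts 5 --reads-per-transcript 300 --out sim
$ f5cseq pileup --sam sim/sim.sam --ref sim/ref.fasta --out pileup.tsv
1809 sites -> pileup.tsv
$ f5cseq calibrate --points points.tsv --out cal.json
slope=0.8895 intercept=0.0034 R2=0.9997 -> cal.json
$ f5cseq call --pileup pileup.tsv --calibration cal.json --out calls.tsv --bed calls.bed
265 sites called of 1809
```

(`points.tsv` joins the spike-in truth fractions to their observed
pileup rates; see `docs/methods.md`.) The fitted slope 0.8895 recovers
the simulation's effective conversion efficiency
ε(1 − e₀) = 0.9 × 0.998 ≈ 0.898, and the 265 calls are the 256 context
spike-ins, the non-zero fraction-series oligos and the five simulated
transcript sites — each annotated with `f̂`, its Wilson CI, and
binomial p/q values. A knockdown-style contrast between two conditions'
replicate tables runs with `f5cseq diff`.

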