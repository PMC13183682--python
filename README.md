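# exondef

Kinetic modeling of coupled alternative-exon (AE) and intron-retention (IR)
decisions through stepwise exon definition.

## The problem

In a three-exon splicing unit, two decisions are made at once: whether the
middle (alternative) exon is included or skipped, quantified as
PSI = 100% × f_incl / (f_incl + f_skip), and whether the introns are removed
at all, quantified as the splicing efficiency f_incl + f_skip (its complement
is the total IR frequency). Mutagenesis screens of minigene reporters and
transcriptome-wide splicing tables both show that these decisions are
coordinated: splicing efficiency drops when PSI is intermediate, i.e. IR
products accumulate exactly where the AE decision is balanced.

`exondef` implements the modeling framework that explains this coupling.
A pre-mRNA is synthesized at rate *s*; the spliceosome defines each exon
reversibly (rates k1/k4, k2/k5, k3/k6); splicing catalysis (k_spli) removes
an intron only when both flanking exons are defined; unspliced species exit
the nucleus at k_ret and become IR isoforms; the five terminal isoforms
(inclusion, skipping, fullIR, 1IR, 2IR) degrade with isoform-specific rates.
In the **one-step model** AE definition is a single reversible step (k2).
In the **two-step model** it takes two consecutive steps (k2a, then k2b)
through a catalytically inactive intermediate — a kinetic-proofreading stage
whose export as fullIR couples IR to the AE decision. Both networks are
affine-linear, so steady states come from a direct linear solve; an exact
Gillespie simulation of the same reaction list gives per-cell isoform
distributions.

Around this core the package provides, each as its own module:

- `toy` — closed-form n-step AE recognition models (step *i* at rate
  α^(i−1)·k2); effective Hill coefficient h = log 81 / log(k2,90/k2,10),
  switching fold, and minimal efficiency: the switching/efficiency trade-off.
- `error_model` — the replicate scaling law
  std = mean/(mean + (1−mean)α) − mean + b0, fitted per isoform and used as
  the χ² weight.
- `fitting` — joint χ² fits of either model to WT + M single-mutant isoform
  tables, one multiplicative fold-change per mutation on its assigned
  exon-definition rate (Latin-hypercube multistart, sparse Jacobian).
- `rbp` — the 15 (2⁴−1) RBP regulatory-mode variants k_x,KD = ε^flag·k_x,
  fitted to knockdown data and ranked by cross-validated prediction error.
- `core_model` — the reduced transcriptome model
  efficiency = δ² / (1 + √(PSI(1−PSI)/λ)), with λ = K2b/K2a the ratio of the
  two AE definition steps and δ the constitutive-exon recognition
  probability; joint normal/cancer fits report the λ fold change.
- `lsv` — filtering, classification (short junction = inclusion, long =
  skipping, IR flag), PSI binning and the intermediate-vs-extreme efficiency
  contrast for MAJIQlopedia-style LSV tables, plus dPSI/dSE coordination for
  binary-event knockdown panels (SE = 100 − PIR).
- `synth` — seeded generators for all of the above input formats with known
  ground truth.

## Worked example

Dose-response summaries of the n-step toy models at the reference parameters
(k_spl = 1, k_ret = 0.2, α = 1/30):

```bash
$ exondef toy --steps 1,2,3,7
n_steps  hill      switching_fold  min_efficiency
1        1.000     81.00           0.8333
2        1.597     15.66           0.4355
3        2.148     7.74            0.1041
7        3.569     3.43            0.0000
```

One AE recognition step gives a Michaelis–Menten PSI response (h = 1, an
81-fold change in k2 to switch PSI from 10% to 90%) and an efficiency that
cannot drop below k_spl/(k_spl+k_ret) = 0.833. Adding steps sharpens the
switch (h → 1.6, 2.1, … 3.6) but opens an efficiency dip at intermediate
PSI — with seven steps splicing essentially stalls there. Two steps balance
the trade-off, which is why the two-step model also fits minigene data best.

The full two-step model at the package's reference parameters (slow second
AE step, k2b/k2a = 0.05):

```bash
$ exondef simulate --variant two_step --params params.json
isoform    frequency
inclusion  0.4050
skipping   0.3486
fullIR     0.2212
1IR        0.0114
2IR        0.0137
```

i.e. PSI ≈ 54% and efficiency ≈ 0.75 — the WT sits in the efficiency dip,
and sweeping the AE recognition fold-change
(`exondef.psi_efficiency_curve`) traces the characteristic U-shaped
efficiency–PSI locus with boundary efficiency ≈ 0.88.

The same analysis end-to-end from synthetic transcriptome tables:

```bash
$ exondef synth lsv --seed 1 --n 300 --out-prefix demo
$ exondef lsv-analyze --table demo_lsv.tsv --min-reads 10 --boot 300 --seed 7 --out-prefix demo
599/600 LSVs kept; difference = -0.1719 (p = 0.003322)
```

— the median efficiency at intermediate PSI (40–60%) is 17 percentage
points below the extreme-PSI bins, significant at 95% by the calibrated
one-sided permutation test.

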