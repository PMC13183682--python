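# Methods

## Kinetic models

Both exon-definition models are open, first-order reaction networks: constant
synthesis *s* of the fully unspliced species, reversible exon
definition/dissociation, irreversible splicing catalysis, first-order nuclear
export of unspliced species, and first-order degradation of the five terminal
isoforms (fullIR degrades at kdr1 + kdr2). The ODE system is therefore
affine-linear, dx/dt = A·x + b, with a unique, strictly positive steady state
whenever every terminal isoform that receives flux also degrades. The steady
state is computed by a direct linear solve of A·x = −b (exact to rounding);
numerical integration is retained only as a test oracle, and the residual of
the solve is checked against 1e−10·s. Isoform *frequencies* are steady-state
abundance fractions among the five terminal isoforms, not production-flux
fractions: sequencing measures abundances, and the two differ exactly by the
isoform lifetimes, which are free parameters of the fit.

The partially spliced intermediates follow the mechanism, not any particular
notation: after intron 1 is removed (P11_0, P11_1) the pending transition is
definition/dissociation of exon 3 (k3/k6), and symmetrically exon 1 (k1/k4)
after intron 2 is removed. This is the unique assignment under which every
loss term reappears as a gain elsewhere (mass conservation), and it satisfies
the exon-1↔3 exchange symmetry (k1↔k3, k4↔k6, kdr1↔kdr2 maps 1IR↔2IR).

Units are seconds throughout. Fixed values: all dissociation rates 0.01/s and
s = 0.001/s; free parameters are k1, k3, the AE rates (k2, or k2a and k2b),
kspli, kret and the four degradation rates — 9 shared parameters for the
one-step model, 10 for the two-step model.

**Equivalence limit.** With k2b → ∞ the two-step AE intermediate is
transient, but it also funnels dissociation flux forward: the limit is the
one-step model with an effective AE dissociation rate k5a·k5b/k2b → 0, not
with the fixed 0.01/s. The property test uses this mapping (agreement ~1e−10).

**Stochastic simulation.** The same reaction list drives an exact SSA
(Gillespie), vectorized across cells; concentrations are converted to
molecule counts with an explicit scale factor, by default chosen so the
deterministic steady state holds ~1000 molecules. Cells start empty and are
propagated for several relaxation times (−1/max Re eig(A)); unimodality of
the per-cell PSI distribution is summarized by counting local maxima of the
histogram that hold at least 5% of cells. A gradual (unimodal) shift from
skipping to inclusion is the expected regime for this linear network, whose
stationary law is product-form Poisson.

## Toy models

The n-step chain has recognition rate α^(i−1)·k2 for step i; skipping and
inclusion are produced at kspl from the first and last species, retention at
kret from every species. Closed-form steady states give
PSI(k2) = a·k2ⁿ / (a·k2ⁿ + (kspl+kret)·∏_{i=1..n−1}(αⁱk2 + kret)) with
a = α^{n(n−1)/2}, consistent with the explicit two- and three-step
expressions. k2,10 and k2,90 are found by bisection on log k2 (relative
tolerance 1e−8, bracket auto-expanded geometrically); the Hill coefficient is
log 81 / log(k2,90/k2,10). Minimal efficiency over the full k2 range combines
a 200-point geometric grid with a local refinement around the grid minimum;
both k2 → 0 and k2 → ∞ give kspl/(kspl+kret). Reference parameters kspl = 1,
kret = 0.2, α = 1/30. The random-sampling study draws kspl, kret, α
log-normally (sd of the natural log 0.5, default 2000 samples) around these
values; k2 is swept, not sampled. For the seven-step model the package
computes h ≈ 3.57; both 3.6 and 3.8 circulate as printed values and no
attempt is made to force either.

**Relation to the full network.** The toy model produces inclusion in one
lumped catalysis step, while the full network removes the two introns
sequentially through export-able intermediates. The two agree exactly in the
slow-export limit kret ≪ kspl (intermediates pass with probability ~1); at
the reference kret/kspl = 0.2 the toy model is its own, deliberately simpler
object.

## Error model

Replicate standard deviation of an isoform frequency follows
std = mean/(mean + (1−mean)·α) − mean + b0, a bell-shaped curve for α < 1
that equals b0 at both boundaries. Per isoform, (mean, std) pairs across
minigenes are fitted by unweighted nonlinear least squares (the fitting
procedure is not otherwise specified; weighting is a documented alternative).
Sample standard deviations from n replicates underestimate σ by the c4(n)
factor (0.886 for n = 3), so stds are divided by c4 before fitting —
without this, α is biased up ~25%. Minigenes with fewer than two finite
replicates are excluded with a warning. As a χ² weight the predicted std is
floored at 1e−4. Symmetry diagnostics compute the skewness of pooled
(replicate − mean) deviations; |skewness| < 0.5 is called symmetric.

## Model fitting

Mutations map to the definition rate of their residing (exonic) or nearest
(intronic) exon; intronic positions within 40 nt of either AE splice site map
to the AE, and midpoint ties in the remaining intron interior break toward
the AE (logged). Each mutation contributes one multiplicative fold-change on
its assigned rate; in the two-step model an AE mutation scales k2a and k2b by
the same factor, so their ratio is a shared property of the transcript. The
WT fold-change is pinned to 1, which fixes the fold/rate scaling degeneracy.

The objective is the standard χ² over all records and isoforms with σ from
the fitted error model evaluated at the data means. Ingested frequency rows
must sum to 1 within 0.02 and are renormalized exactly. All parameters are
optimized in log10 space (shared rates bounded to [−5, 2], folds to [−4, 4])
with `scipy.optimize.least_squares` (TRF); the Jacobian sparsity pattern —
each mutant's five residuals depend only on the shared parameters and its own
fold — and batched steady-state solves (one stacked `np.linalg.solve` per
evaluation) make the joint fit of 10 + 405 parameters take seconds.
Multistart uses Latin-hypercube samples of the shared log-rates plus one
physiologically plausible centre start. A fast `profile` mode (shared
parameters fitted to WT only, then 1-D fold fits) exists for tests; it is an
approximation, not the estimator.

**χ² calibration.** With single-draw noise at the model σ, the refit χ² is
expected near the data count n; the test band is
[n − p − 3√(2n), n + 3√(2n)] because the p fitted parameters absorb roughly
p units and the necessary renormalization of noisy frequencies to the
simplex removes part of the injected variance.

## RBP mode selection

The 15 non-empty subsets of (k1, k2a, k2b, k3) are enumerated in ascending
binary order; a knockdown multiplies every flagged rate by a common ε
(log-bounded to [1e−3, 1e3]), fitted one-dimensionally to the five KD WT
frequencies with all other parameters frozen at the control fit. Variants
whose ε does not move the outputs are flagged non-identifiable.
Cross-validation predicts every KD mutant with the control fold-changes and
no refitting. Ranking is by prediction RMSE first and fit RMSE second
(cross-validation spirit); χ²-based ranks are reported alongside, with
critical values at 95%: df = 4 (five frequencies minus one parameter) for
the fit score and df = number of predicted points for the prediction score.

## Reduced transcriptome model

Assuming fast spliceosome binding equilibria, recognition probabilities
α = K1/(1+K1), γ = K3/(1+K3), β1, β2 for the sequential AE steps define 12
equilibrium states whose frequencies multiply out and sum to 1. With
K2b = λ·K2a and αγ = δ², efficiency(PSI) = δ²/(1 + √(PSI(1−PSI)/λ)) — as
printed, exactly symmetric with its minimum at PSI = 0.5 and depth
δ²/(1 + 0.5/√λ); statements about the *position* of the minimum moving
therefore refer to λ changing the curve's shape, not to asymmetry.
Condition pairs are fitted jointly (four free parameters, independent
(λ, δ) per condition) by unweighted least squares of the curve at bin-centre
PSI against per-bin median efficiency, in log space (λ ∈ [1e−4, 1e4],
δ ∈ (0, 1]), from three deterministic starts; a count-weighted option
exists. The headline output is the λ ratio cancer/normal: below 1 means an
amplified interior efficiency drop (slower late or faster early AE step).

## LSV analysis

Filters, in order, with per-filter drop counts: (1) exactly three events
with at least one IR; (2) distance between the two non-IR junctions
> 300 nt — by default the absolute difference of junction span lengths,
with the 3′-end distance as a configurable alternative, since the source
tables' exact coordinate arithmetic is unstated; (3) sum of the two lowest
event frequencies ≥ 1%; (4) total junction reads ≥ cutoff when counts are
present. The filters are independent predicates, so survivor sets are
identical in any order and nested in the read cutoff. Classification: of
the two non-IR events the shorter junction span is inclusion, the longer
skipping; ties and double-IR records are flagged and excluded. PSI bins are
half-open [lo, hi) with the last bin closed at 100; empty bins are missing,
not zero.

The intermediate-vs-extreme contrast (median efficiency at PSI 40–60% minus
the combined 0–10% and 90–100% bins) is estimated by bootstrap resampling
within groups (95% percentile CI). Significance is a one-sided permutation
test (group labels shuffled, same replicate count), which is exactly
calibrated; a Wilcoxon signed-rank statistic across the bootstrap replicates
is reported as `wilcoxon_p` for reference only, because replicates of a
single dataset are mutually dependent and that test overstates significance
(~90% false-positive rate on shuffled nulls in our checks). For binary-event
panels, dPSI and dSE = −dPIR are taken against the control condition, and
the fraction of |dSE| > 5% observations is reported per dPSI bin; events
with PSI sd > 10% across conditions and non-zero IR in > 100 conditions are
flagged for individual profiling.

## Synthetic data

The generators are the package's study conditions, fully determined by their
seed. The ground-truth two-step parameters (k1 = 0.05, k3 = 0.04, k2a = 0.1,
k2b = 0.005, kspli = 0.2, kret = 0.003, lifetimes ~10–17 min) place the WT
at PSI ≈ 54% inside an efficiency dip of ~0.75 against boundary ~0.88, the
regime the two-step mechanism is about. Mutant panels default to 405
mutations allocated 68% to the AE (274 of 405 in the motivating screens),
with log-normal fold-changes (sd of ln = 1) so mutant PSIs span the full
range. Replicate noise is Gaussian per isoform with the error-model std
(defaults α = 0.9, b0 = 0.005, i.e. replicate sds of a few percent),
clipped at 0 and renormalized to the simplex — the marginal error model does
not define a joint distribution on the simplex, so clip-and-renormalize is
the documented choice, and rows where it reorders well-separated isoforms
are logged.

LSV tables draw log10(K2a·√λ) uniformly on (−1, 1), i.e. PSI from ~1% to
~99% — the range that three-event AE–IR LSVs surviving the lowest-two-events
filter actually occupy; wider tails would only populate the saturated ends
of the PSI axis where binned medians carry no information about λ. Junction
read counts are negative-binomial around a median depth of ~50 with
multinomial allocation across the three events; coordinates are schema-valid
but synthetic (no gene models), and a configurable contamination fraction
violates the 300-nt rule. Binary-event panels draw per-event λ from
10^U(−1,−0.3) so efficiency dips are moderate and the dSE-exceedance
profile shows its hump at intermediate dPSI instead of saturating.

What the generators do *not* emulate: read-coverage-dependent error,
NMD-coupled degradation, gene-expression structure, correlated mutations,
or real junction-coordinate arithmetic. Passing recovery tests therefore
demonstrates the estimators' correctness and calibration under the stated
noise models, not performance on real sequencing artifacts.

## Problem sizes used in tests

The test suite runs the discrimination study at 50 mutants with 20
multistarts, the mode-selection study at 30 mutants × 105 replicates, the
SSA ensemble at 150–200 cells and ~1000 molecules, the ODE-oracle check at
50 random parameter sets, and the LSV pipeline at 2000 events; the
full-scale 405-mutant joint fit is exercised once for fold-change recovery.
These sizes were chosen so the whole suite completes in a few minutes while
every statistical check retains comfortable power.

## Known limitations

- The joint fit reports a best-effort result when no start formally
  converges (flagged); identifiability beyond the documented degeneracies
  (WT fold pinning, k2b/k2a ratio shared across mutants) is not analyzed.
- The ε of a regulatory-mode variant is a single shared fold across flagged
  steps; per-step ε values are deliberately excluded (non-identifiable from
  five WT frequencies).
- The core-model fit inherits the binning protocol's deterministic bias:
  with bin-centre abscissae the λ ratio of a 10× reduction is recovered at
  ~0.12–0.13 rather than 0.10 under realistic read depths.
- `profile` fitting mode trades accuracy for speed and should not be used
  for inference.
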