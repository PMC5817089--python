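# Methods

This note documents the statistical machinery in `dualmeth`, the defaults
it ships with, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where more than one reasonable
option existed.

## Data model

A study consists of two assay arms over the same probe set: a bisulfite
(BS) arm whose beta values are the composite 5mC + 5hmC fraction, and a
TET-assisted bisulfite (TAB) arm reporting 5hmC alone.  Because 5hmC is a
component of the composite signal, the TAB expectation never exceeds the BS
expectation at a probe.  Each arm carries a probes × samples beta matrix in
[0, 1] with missing entries, a matched detection-p matrix, and a sample
sheet (species ∈ {human, monkey}, assay ∈ {BS, TAB}, beadchip batch,
replicate group).  Probe annotation follows the HM450 manifest conventions:
1-based coordinates, semicolon-delimited paired gene / region-group lists
(TSS1500, TSS200, 5'UTR, 1st exon, body, 3'UTR; no gene = intergenic), and
a CpG-island relation (island, N/S shore, N/S shelf, open sea).  All
exported intervals (BED, flank windows) are 0-based half-open.

## Preprocessing

Entries with detection p **strictly greater than** 0.01 are set missing
(an entry exactly at the threshold is kept).  Technical replicate pairs
are averaged per probe over their non-missing members, so a pair with one
missing member keeps the available value; an all-missing pair stays
missing.  A probe is then retained iff at most one (collapsed) sample is
missing.  No between-array normalisation is applied.  Hierarchical sample
clustering uses Euclidean distance with average linkage by default
(configurable) on probes with complete data, which keeps the distances
deterministic.

## Confounder-adjusted differential testing

Per probe the OLS model `beta ~ intercept + species + beadchip + F₁…F_k`
is fit and the species coefficient tested two-sided against t(n − rank).
The raw species effect reported alongside is Δβ = mean(human) −
mean(monkey) (available-case means; positive = higher in humans), and
z = sign(Δβ)·Φ⁻¹(1 − p/2).

The latent-factor scores `F_j` are the leading left singular vectors of the
*nuisance-only* residual matrix (intercept + beadchip projected out,
species kept in).  Keeping species in the residual is essential: the
component of a confounder that is correlated with species is precisely the
part that biases the species test, and projecting species out first
discards it.  The price is that concentrated true species signal could
itself define a factor; to prevent that, the 5% of probes with the largest
unadjusted species |t| are excluded before the SVD (`signal_trim`).  A
dense confounder loses almost nothing from a 5% trim, whereas strong
sparse signal is removed nearly entirely.

The factor count is chosen by Horn's parallel analysis on the full-design
residuals (species projected out there, so real signal is never counted):
observed eigenvalues are compared rank-by-rank against the 95th percentile
of eigenvalues from column-permuted matrices, stopping at the first
failure.  Two numerical details matter.  Spectra are computed on
row-standardised residuals (correlation scale), because design-projection
leverage makes raw residual row variances unequal even under pure noise;
and each permuted matrix is re-projected and re-standardised so observed
and null spectra share the same rank deficiency.  Without both, the null
is misaligned and pure noise yields spurious factors.  Permutations are
seeded (default 1000) for determinism.

Calibration is summarised by the genomic inflation factor
λ = median(Φ⁻¹(1 − p/2)²) / 0.4549364 (the χ²₁ median); λ ≈ 1 means
calibrated tests.  Testing operates on raw beta values by default; an
M-value switch (`use_m_values`) is provided.  On strongly confounded data
the beta-scale analysis retains a little residual inflation that the
M-value analysis does not (the inverse-logit compresses a linear
confounder nonlinearly near the boundaries); with a confounder of SD ≳ 0.4
logit units, single-factor adjustment can leave λ ≈ 1.1–1.15 on betas
while the same data adjust to λ ≈ 1.0 on M-values.  This is a documented
limitation of testing on the beta scale, not of the factor machinery.

## HMM-LIS multiple testing

Probes are ordered by (chromosome, position); entries whose p-value is
missing or exactly 0 or 1 are discarded and z-scores recomputed if absent.
The ordered z sequence is modelled as a homogeneous two-state hidden
Markov chain with states null/non-null, emission densities

* null: Gaussian with mean and SD estimated from the data (empirical
  null), and
* non-null: a nonparametric kernel density.

EM alternates scaled forward–backward posteriors with closed-form M-steps:
the transition matrix from expected transition counts, the null mean/SD by
posterior-weighted MLE, and the alternative density as a posterior-weighted
Gaussian KDE with Silverman's bandwidth on the weighted effective sample
size, evaluated on a fixed 512-point grid with linear interpolation
(binned at 2048 bins for speed).  Chains restart at the stationary
distribution of the transition matrix at each chromosome boundary by
default (`restart_per_chromosome=False` pools everything into one chain).
Initialisation is deterministic — null N(0,1), transition
[[0.95, 0.05], [0.05, 0.95]], symmetric two-bump alternative at ±3 — so
repeated fits are bit-identical.  EM stops when the log-likelihood
improves by less than ε = 0.01 or after 100 iterations (both
configurable); the likelihood trace is exposed and non-decreasing.

One identifiability device is essential for honest error control.  The
semiparametric null/alternative split is not identifiable where the null
dominates: the likelihood is nearly flat in moving probability mass
between π₀f₀ and π₁f₁ under the null peak, and an unconstrained weighted
KDE converges to a fixed point with spurious alternative mass there.  The
result is measurable anti-conservativeness (realized mean false-discovery
proportion ≈ 0.052 at a nominal 0.05, versus ≈ 0.049 with oracle
parameters, on the default simulation).  The `zero_window` constraint pins
the alternative density to zero within one null SD of the null mean —
the standard "zero assumption" of empirical-null theory — after which the
fitted procedure matches oracle calibration (≈ 0.047 at 0.05, ≈ 0.009 at
0.01 over 50 replicate chains).  Set `zero_window=0` to disable.

The local index of significance of observation i is its posterior null
probability given the whole chromosome chain, LIS_i = P(state_i = null |
z₁…z_n).  Sorting LIS ascending, the adjusted LIS at rank k is the running
mean of the k smallest LIS values; an observation is called significant
iff its aLIS < α (default 0.01).  Since the running mean is the
procedure's own estimate of the expected false-discovery fraction among
the calls, thresholding it controls the marginal FDR under dependence,
and the chain structure gives it strictly more power than rank-based
rules (Benjamini–Hochberg) when signal is serially correlated.

Exactness of the forward–backward recursions is verified against
exhaustive 2ⁿ path enumeration on chains up to length 12 (absolute error
below 1e-10).

## Dual-assay attribution

For each locus, Δβ is computed separately from the BS matrix
(Δ composite) and the TAB matrix (Δ 5hmC).  Loci significant in both arms
are classed DhML unconditionally — a 5hmC difference moves the composite
signal too, so dual significance indicates a hydroxymethylation
difference — with a quadrant label from the sign pair (human_human,
monkey_monkey, human_monkey, monkey_human).  BS-only loci are DML,
TAB-only loci DhML.  The "similar abundances" concordance statistic is the
fraction of dual loci whose two deltas agree in sign and differ by at most
0.1 (the band is a package choice; no principled value exists).  Direction
splits use the sign of the relevant delta; a significant locus with delta
exactly 0 is warned about and assigned no direction.

## Permutation enrichment and overlap tests

For a set of significant loci, each distinct region-group of a locus
contributes one label occurrence (an intergenic locus contributes
"intergenic"); island relations are single-valued.  The observed per-label
count ("actual number") is compared against counts from drawing the same
number of loci uniformly without replacement from a universe — all tested
loci, or an alternate frame such as the other assay's significant set —
and re-expanding labels ("permuted number").  Defaults are 100,000
permutations for region structures and 10,000 for island relations.
P-values use the add-one rule p = (1 + #extreme)/(n_perm + 1) with weak
(≥ / ≤) tie handling; a `legacy_p` flag divides the raw exceedance count
by n_perm (allowing p = 0) and `strict_tie` counts strict inequalities.
Sampling is vectorised by random-key partial sorting in memory-bounded
chunks and is reproducible from the seed.  Monte-Carlo tails are verified
against exact hypergeometric enumeration on small universes.

Gene-set overlap uses Pearson's chi-square with Yates continuity
correction on the 2×2 membership table within a stated universe:
χ² = N(max(|ad − bc| − N/2, 0))² / ((a+b)(c+d)(a+c)(b+d)), 1 df.  The
correction is clamped at zero (the convention that makes a balanced table
give χ² = 0, p = 1 exactly).  A zero margin raises an error.

## Flank-window export

Motif-discovery inputs are built as ±250 bp windows around each called
locus (501 bp total; the window is centred on the cytosine).  Loci on the
same chromosome closer than 500 bp are clustered into one window spanning
min − 250 to max + 250.  A gap of up to 2×flank is merged as well, so
merged windows are guaranteed pairwise non-overlapping (at the default
parameters a 500 bp gap would otherwise overlap by one base).  Sequences
are emitted on the forward strand; downstream motif scanners handle both
strands.

## Synthetic-data generator

The generator emulates the structure of a two-species dual-assay array
study; its defaults are the study conditions used throughout the tests.
Per probe, a baseline composite level is drawn on the logit scale from its
annotation (islands ≈ −2.2, shores ≈ −0.6, shelves ≈ +0.7, open sea
≈ +1.3, with region-group adjustments such as TSS200 ≈ −1.4 and body
≈ +0.4, plus N(0, 0.3) probe noise), reproducing the canonical abundance
ladder island < shore < shelf < open sea and the depletion at promoters.
A hydroxymethyl fraction ρ ~ U(0.1, 0.5) splits the composite into 5mC and
5hmC components, so TAB ≤ BS in expectation by construction.

Differential states follow a two-state Markov chain along each chromosome
(default transition [[0.99, 0.01], [0.25, 0.75]], stationary differential
fraction ≈ 3.8%, chosen to match the few-percent call rates typical of
cross-species comparisons; an i.i.d.-state mode tests robustness to the
chain assumption).  A differential probe receives a species shift on the
logit of its driving component only — 5mC with probability
1 − `frac_hmc_driven`, 5hmC otherwise — with magnitude
Gamma(4, effect/4) (mean = `effect_size`, default 2.0 logit units) and
random sign.  Latent confounders load on probes (N(0, `confounder_sd`))
with per-biological-sample scores; `confounder_species_cor` correlates the
first factor with species for planted-confounder experiments.  Beadchip
offsets are per (probe, chip) N(0, `batch_sd`); replicate pairs share a
chip so the averaged sample keeps a well-defined batch.  Sample noise is
N(0, `noise_sd` = 0.4) on the logit scale, then inverse-logit transformed.
Detection-p failures are placed uniformly at rate 0.005.  Everything is
reproducible from a single seed.

Deliberately **not** emulated: probe cross-hybridisation, SNPs under
probes, cell-type composition, chromosome-specific effects, and any raw
intensity-level artefacts — so passing tests demonstrate correctness of
the statistical machinery on well-specified data, not robustness to every
failure mode of real arrays.  The sample sizes (3/7 BS, 6/11 TAB) are
deliberately small; power figures from the simulations reflect that
regime.

### Scenario used for the confounder-calibration checks

One latent factor with loading SD 0.2, correlation 0.85 with species, zero
true effects, TAB-arm design: unadjusted λ falls in ≈ 1.4–4.6 across
probe seeds, factor-adjusted λ in ≈ 0.95–1.1.  Because a single λ estimate
has SD ≈ 0.04 at 10,000 probes, the calibration test averages adjusted λ
over three replicate datasets.

## Problem sizes

The test suite runs FDR calibration over 200 replicate chains of 20,000
probes, parameter recovery at 50,000, and the end-to-end dual-assay runs
at 8,000–20,000 probes with the full 44-array design; the whole suite
completes in a couple of minutes on one core.  The acceptance script uses
a 20,000-probe study and 50 calibration chains.

## Known limitations

* Beta-scale testing under very strong confounding retains mild residual
  inflation (see above); use M-values when confounders dominate.
* The signal-trim device assumes differential signal is sparse (≲ 5% of
  probes); with genuinely dense signal the factor scores may absorb some
  of it and the test becomes conservative.
* The empirical-null HMM assumes a unimodal Gaussian null; heavy-tailed
  test statistics would need a different null family.
* The aLIS rule controls the *marginal* FDR; per-dataset FDP fluctuates
  around the nominal level (SD ≈ 0.004 at 20,000 probes in the default
  simulation).
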