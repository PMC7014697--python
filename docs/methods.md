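# Methods

## Model and transformation

The scan tests genetic units in the linear mixed model

    y = 1·mu + X·beta + a + eps,   a ~ N(0, K·sigma_a^2),  eps ~ N(0, I·sigma_e^2),

with one phenotype record per inbred line (the polygenic incidence matrix is
the identity). Re-parameterizing the covariance with the polygenic
heritability h2 = sigma_a^2/(sigma_a^2 + sigma_e^2) gives
Var(y|beta) = (h2/(1−h2)·K + I)·sigma_e^2. After one spectral decomposition
K = U S Uᵀ, the rotation ỹ = Uᵀy, X̃ = Uᵀ[1 X] yields an independent
weighted linear model with diagonal weights w_i = h2/(1−h2)·S_i + 1.
Estimates come from the standard weighted least-squares normal equations,
β̂ = (X̃ᵀW⁻¹X̃)⁻¹X̃ᵀW⁻¹ỹ, solved by whitening (divide by √w_i) and QR-based
least squares; σ̂_e² uses the (n−1) divisor for reporting, and the profile
objective is n·log σ̂_e² + Σ log w_i (additive constants dropped, so only
−2 log L *differences* are meaningful across implementations).

A unit of any width is tested with the nested-model F statistic on weighted
residual sums of squares at a common h2:

    F = ((RSS0 − RSS1)/df_beta) / (RSS1/df_eps),   df_eps = n − df_beta − 1,

referred to F(df_beta, df_eps). Computing F from RSS ratios keeps the stated
F reference distribution exact regardless of the σ² divisor convention, and
a weighted RSS0 (rather than a raw sum of squares around the mean) is the
form under which the statistic actually is F-distributed under the model. A
large-sample chi-square alternative (df_beta·F ~ χ²(df_beta)) is available
behind a flag. If RSS1 = 0 (perfect fit) the test returns a p = 0 sentinel
with a warning; scan-level diagnostics exclude such sentinels.

## Heritability optimization

The profile of −2 log L over h2 is one-dimensional and smooth. The null
(intercept-only) model — the *genomic heritability* — is profiled over
(0, 1) with a 21-point seed grid plus bounded Brent refinement (tolerance
1e-4 on h2); the grid guards against flat or multi-welled profiles, and the
whole fit happens once per trait.

Per-unit optimization searches *downward* from the genomic estimate: a
tested unit can only take variance away from the polygenic term, so its
optimal h2 lies at or below the genomic value. The search interval is
(0, h2_genomic + 0.05]: the 0.05 headroom band exists because null units
optimize essentially *at* h2_genomic, which would otherwise sit exactly on
the search boundary; if the optimum still lands on the extended bound the
interval grows in 0.05 steps (logged) up to 1. Each per-unit search uses a
3-point seed grid plus Brent (same 1e-4 tolerance), ~12 likelihood
evaluations per unit — this economy is what keeps the two-pass scan inside
its cost contract (below). The intercept-only model is refit at the unit's
optimal h2 before the F test so both fits share one covariance.

## Scan modes and cost

* **exact** — per-unit h2 optimization for every unit.
* **emmax** — every unit tested at the fixed genomic heritability; one
  weighted regression per unit, with the intercept-only fit shared across
  the whole scan.
* **two_pass** (default) — an EMMAX screening pass over all units, then
  exact re-testing of units with screening p ≤ screen_alpha (default 0.05);
  the exact result replaces the screening result for re-tested units.

Every weighted least-squares solve is counted; the scan reports
i = (total solves)/(number of units), the empirical number of genome-wide
regression-scan equivalents. With the default 5% screen on a null panel,
i ≈ 1.6, inside the designed 1 < i ≤ 2 band; screen_alpha = 1 reproduces
exact mode bit-for-bit and screen_alpha = 0 reproduces EMMAX.

## Kinship

The realized relationship matrix is the VanRaden-style cross-product of
column-centred 0/1 genotypes, K = M Mᵀ / Σ_j p_j(1−p_j) (haploid-equivalent
scaling for inbred coding, putting diag(K) ≈ 1); monomorphic markers are
skipped. Any positive rescaling of K is absorbed by h2 — the mapping
h2/(1−h2) → c·h2/(1−h2) leaves every weight, hence every test statistic,
unchanged — so the scaling convention affects only the interpretation of the
h2 estimate. This absorption is verified by test rather than resolved by
convention. Eigenvalues in (−1e-10, 0) are clipped to zero; anything more
negative is treated as upstream corruption and rejected.

By default a single global K (all markers, tested unit included) serves the
whole scan, so one decomposition suffices. At genome scale any single unit
contributes a vanishing share of K and this choice is innocuous; on small
simulated panels (a few thousand markers) a tested marker's LD block can
reach percent-level weight in K and the polygenic term then absorbs part of
the unit's own signal (proximal contamination). `compute_rrm` therefore
accepts `exclude_chroms` for building leave-one-chromosome-out kinships when
that regime matters; the power simulations below use a background-chromosome
kinship for exactly this reason.

## Haplotype blocks

A marker pair shows recombination evidence iff all four two-locus gamete
classes reach frequency ≥ cutoff (default 1%; classes below the cutoff are
treated as unobserved, tolerating genotyping error and recurrent mutation).
In fully inbred lines each line is an observed haplotype, so gamete classes
are counted directly over samples. Blocks are grown greedily left-to-right
within a chromosome, and a candidate marker joins only if it passes the test
against **every** marker already in the block (all-pairs criterion —
adjacent-only chaining would let recombinant pairs hide inside long blocks).
Single-marker runs are recorded as unblocked.

Within a block, distinct row patterns are haplotype alleles; patterns with
frequency < 0.02 are pooled into one `<block>_rare` allele when at least two
of them exist. A lone sub-threshold pattern keeps its own identity (there is
nothing to pool it with, and it is informationally identical to a named
allele); if *every* pattern is rare, the most frequent one stays named so a
block always retains ≥ 2 alleles. Alleles sort by descending frequency
(ties: lexicographic pattern, pooled class last), and block designs drop the
last allele in that order. Block spans are inclusive 1-based bp; the BED
export converts to 0-based half-open.

## Synthetic data

The generator emulates the structure the model assumes, not a demographic
history. Genotypes: geometric block lengths (mean 8 SNPs, matching a
landscape where most blocks hold < 10 SNPs), a founder pool of 4 haplotypes
per block with Dirichlet(1.2) founder frequencies (yielding mostly 3–6
observed alleles per block and a supply of rare patterns), per-marker founder
allele frequencies uniform on [0.1, 0.5], and copying fidelity 0.98 (each
copied bit is replaced by a fresh frequency draw with probability 0.02).
Lines draw founders independently across blocks, which is what makes the
kinship informative. Phenotypes follow the generative mixed model exactly:
polygenic effects drawn with covariance K (via its eigendecomposition), SNP
or block QTL effects scaled to stated fractions of a unit total variance,
Gaussian residuals for the remainder. All randomness flows from one seed
through fixed (seed, stream) split points, so every dataset is reproducible
bit-for-bit.

What the simulator does *not* emulate: recombination maps and distance-based
LD decay, population stratification beyond founder sharing, genotyping error,
allele-frequency spectra from real demographies, and linked selection.
Passing tests therefore demonstrate the statistical machinery is correct
under the model's own assumptions, not that any particular real panel meets
those assumptions.

## Verification design

* Closed-form/desk checks: Bonferroni thresholds and coverage arithmetic at
  the published maize panel's unit counts.
* Dual-route numerics: weighted fits against dense GLS on the original
  scale (1e-8); the unified F against a classical two-model F on the
  whitened variables computed through an independent regression library;
  identity-kinship scans against ordinary-regression F tests (1e-10); the
  FGT partitioner against a brute-force all-pairs oracle on exhaustive small
  matrices.
* Operating characteristics: type-I error at the 5% level within the exact
  binomial 99% CI and genomic-control λ in [0.9, 1.1] under polygenic-null
  simulation (n = 300; 2,000 tests per unit width df ∈ {1, 3, 6}, spread
  over 40 phenotype draws so the tests are near-independent and the binomial
  CI applies); genomic-heritability recovery at n = 400 over 100 replicates
  (interior values by a 99% Monte-Carlo CI on the mean; h2 = 0 by the
  median, since the ML estimate is boundary-censored there and no ML
  estimator has mean zero at a boundary truth); planted-QTL power (a
  10%-variance QTL at n = 500 detected above the Bonferroni threshold in
  ≥ 90% of 100 two-pass scans, with the background-chromosome kinship
  described above).

Problem sizes throughout (hundreds of lines, 10²–10³ markers per panel) are
chosen so the full suite exercises every code path at desk scale; the
statistics being checked — calibration, recovery, cost factors — are
scale-free or are computed at the published counts where the quantity itself
is arithmetic.

## Known limitations

Single-trait, intercept-only fixed effects (pre-adjust covariates upstream);
ML rather than REML variance estimation (small downward bias in σ̂_a² at
small n, immaterial to the F tests); no imputation or phasing (heterozygous
or missing calls are rejected at input); Bonferroni-only multiple-testing
control; dense eigendecomposition (O(n³) once per dataset) — panels of tens
of thousands of lines would need low-rank or randomized variants that are
out of scope here.
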