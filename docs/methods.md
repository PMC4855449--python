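# Methods

## Model

An individual's genome derives proportions `m = (m1, m2, m3)` from three
ancestral populations — European (EU), American Indian (AI), African (AF) —
with `m1 + m2 + m3 = 1`, `m_i ≥ 0`. Reference ("parental") allele-1
frequencies `p_EU, p_AI, p_AF` at each panel SNP are treated as known
constants (the *fixed parental allele* assumption). The expected allele-1
frequency in the individual ("hybrid frequency") is the convex combination

```
P_h = p_AF + m1·Δ1 + m2·Δ2,    Δ1 = p_EU − p_AF,  Δ2 = p_AI − p_AF.
```

Assuming Hardy–Weinberg proportions at `P_h` and independence across SNPs,
an observed dosage `d_g ∈ {0, 1, 2}` of allele 1 at SNP `g` contributes

```
d_g = 2:  ln P_h²
d_g = 1:  ln 2·P_h·(1 − P_h)
d_g = 0:  ln (1 − P_h)²
```

and the individual's log-likelihood is the sum over non-missing SNPs.
Missing dosages are simply omitted (missing-at-random is assumed).

## Estimation

The likelihood is maximized over the lattice `{(m1, m2): m1, m2 ≥ 0,
m1 + m2 ≤ 1}` with step 0.001 (`grid_step`); `m3 = 1 − m1 − m2`. Because the
log-likelihood is concave in `(m1, m2)` (each term is a composition of a
concave log with an affine map), a coarse-to-fine search — step 0.01
globally, then step 0.001 inside a ±0.02 box around the coarse optimum — is
exactly equivalent to the exhaustive scan; the test suite verifies the
equivalence instance-by-instance, and `mode="exact-grid"` retains the full
scan. Ties are broken lexicographically (smallest `m1`, then smallest `m2`),
which only matters for degenerate panels. The grid evaluation is vectorized
as two matrix products per cohort (`ln P_h` against dosages, `ln(1 − P_h)`
against their complement), so estimating hundreds of individuals on a
1300-SNP panel takes seconds.

## Standard errors

The expected (Fisher) information for `(m1, m2)` is

```
I11 = Σ 2·Δ1² / (P_h(1 − P_h))     I12 = Σ 2·Δ1·Δ2 / (P_h(1 − P_h))
I22 = Σ 2·Δ2² / (P_h(1 − P_h))
```

summed over non-missing SNPs and evaluated at the MLE. Inverting the 2×2
matrix gives `V(m1)`, `V(m2)`, `Cov(m1, m2)`, and the simplex constraint
gives `V(m3) = V(m1) + V(m2) + 2·Cov(m1, m2)`. An observed-information
variant (`info="observed"`), with per-SNP weight
`d/P_h² + (2 − d)/(1 − P_h)²`, is available; it agrees with the expected
form in expectation. A near-singular information matrix (determinant below
`1e-10` of its scale) raises `DegenerateInformationError` — this is the
method's explicit warning that the panel carries essentially no information
for one contrast; cohort-level calls can convert it to NaN variances instead.

### Standard-error calibration — what the tests show and do not show

Monte-Carlo checks in the test suite show the reported SEs are *calibrated*:
over repeated simulation the SD of the estimates matches the Fisher SE, and
the nominal 95 % confidence intervals cover the truth at an observed rate of
≈0.95 (within [0.92, 0.98]).

However, two historically quoted performance figures for this design are
**not reproducible** under this likelihood, and the corresponding acceptance
tests are left failing on purpose:

* mean SE targets of 0.02 / 0.01 / 0.008 at 200 / 700 / 1300 SNPs for a
  four-group admixed cohort (our calibrated values: ≈0.065 / 0.035 / 0.025);
* per-component mean absolute error < 0.02 for a 200-individual
  interior-truth cohort on the full panel (ours: ≈0.021–0.024, exactly
  consistent with the SEs above).

The obstruction is an information bound, not an implementation detail. For
an interior individual (e.g. roughly half-EU, half-AI) the hybrid frequency
sits well inside (0, 1), so `P_h(1 − P_h) ≳ 0.15`; with maximized deltas
near 0.53 and off-contrast deltas below 0.3 (the panel design itself), the
per-SNP information is bounded and the attainable SE at 1300 SNPs is a few
hundredths, not 0.008. We verified that alternative frequency-generating
laws reproducing the same delta structure (including a drift-model
generator) give the same SE scale. The quoted 0.008-class figures are
therefore anti-conservative for interior ancestry; empirical SDs of repeated
estimates, which our simulations match, are the trustworthy quantity. We
deliberately did not tune simulator parameters, seeds or thresholds to force
those tests green.

## Marker statistics and panel balance

* **δ (delta)** — absolute allele-frequency difference between two
  populations; the basic per-marker informativeness for one contrast.
* **Informativeness for assignment `In`** — per SNP and allele,
  `−p̄·ln p̄ + Σ_i (p_i/K)·ln p_i` with `p̄` the across-population mean and
  `0·ln 0 = 0`; summed over both alleles (default; always ≥ 0) and over
  SNPs. Additive over disjoint marker sets; natural log.
* **Weir–Cockerham θ (Fst)** — the two-population variance-components
  estimator built from per-SNP sample sizes, heterozygote counts and allele
  counts; sites monomorphic in both samples are reported NaN (undefined).

A *balanced* panel contains three marker sets, each maximized for one
contrast: maximized δ ≥ 0.5 with both off-contrast δ < 0.3 (with these
thresholds the classes are mutually exclusive since 0.5 ≥ 2 × 0.3 fails only
when δ < 0.6, which the off-δ window already enforces — in any case the
classifier guards against double labels). Selection additionally drops
strand-ambiguous A/T and C/G SNPs and SNPs with replicate discordance
> 0.032, and enforces ≥ 500 kb spacing between same-set SNPs on a chromosome
(greedy, descending δ). The balance audit compares the three all-SNP
contrast `In` values; the panel is balanced when their max/min ratio is
within 10 % (`tolerance=0.10`).

Why balance matters: a cohort whose ancestry is absent from the maximized
contrast of the only markers used is estimated with means drifting far from
truth and SDs inflated severalfold — the vertex-recovery experiment
reproduces this failure signature, and the large reported SE is the
estimator's only internal warning.

## Simulators — scope and limitations

**Panel generator** (`simulate_panel`): for each SNP of a set, the maximized
δ is drawn from Normal(0.53, 0.022) truncated to [0.5, 1]; the lower of the
two contrast frequencies is uniform on the feasible range; the off-population
frequency is uniform on the window keeping both off-contrast δ < 0.3
(rejection sampling; a configuration with no feasible window raises
`ConfigError` after 10,000 rejected draws). Frequencies are kept in
[0.01, 0.99]. SNPs are placed on 22 pseudo-chromosomes at 600 kb spacing with
the three sets shuffled together, so the generated panel passes the selection
pipeline unchanged. Default sizes: 450/450/400.

**Cohort generator** (`simulate_cohort` + `find_like_truth`): individual
truths are Dirichlet draws (concentration 13.0, i.e. `α = 13·mean`) around
four group means typical of admixed-cohort studies — mostly-European
(0.961, 0.014, 0.025), mostly-American-Indian (0.045, 0.945, 0.010),
three-way-admixed (0.476, 0.447, 0.077) and mostly-African
(0.149, 0.021, 0.830) — 100 individuals per group by default. Dosages are
`Binomial(2, P_h)`, i.e. drawn from exactly the model the estimator assumes.

Deliberately *not* modeled: linkage disequilibrium between markers (the
spacing rule stands in for it), genotyping error, departures from HWE,
frequency-estimation noise in the reference panels, and drift between the
reference samples and the true ancestral populations. Consequently the
simulation results are best-case for the method: they test internal
consistency and calibration, not robustness to reference misspecification.

## Numerical choices

* Hybrid frequencies are clamped to `[clamp, 1 − clamp]` with
  `clamp = 0.001` before taking logs, so fixed or nearly fixed SNPs cannot
  produce infinite log-likelihoods; the clamp also bounds the per-SNP
  information. `clamp=0` is allowed when frequencies are strictly interior.
* The grid is generated in exact `i/k` rational steps (no accumulated float
  increments); estimates are exact grid multiples and `m3` is rounded to
  12 decimals to remove `1 − m1 − m2` round-off residue.
* All random draws flow through `numpy.random.default_rng`; every simulator
  and experiment is bit-reproducible given a seed, and child seeds are
  spawned via `SeedSequence` where one seed drives several generators.
* SE-curve ordering: marker prefixes interleave the three sets round-robin
  in randomized order (default), because a naive genome-order prefix of a
  synthetic panel could front-load one contrast and confound the curve with
  the balance-failure mode; a chromosome-position ordering is retained as an
  option.
* Averaging in the SE curve: SEs are averaged over individuals within each
  group, then over groups with equal weight, then over the three components.
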