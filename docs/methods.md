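# Methods

## Model and estimation

The analysis model is a repeated-records animal model
`y = Xb + Zu + Wp + e` with `u ~ N(0, K σu²)`, `p ~ N(0, I σc²)`,
`e ~ N(0, I σe²)`.  Each record belongs to exactly one animal, so Z and W
are single-entry incidence rows; W spans only animals with records.  Fixed
effects are year contemporary group, fleece color, sex-by-physiological
status (male / female-empty / female-lactating) and age in days as a
linear + quadratic covariate.  Age is standardized before squaring and the
squared term standardized again; this removes the near-collinearity between
age and age² that otherwise destabilizes the normal equations, and the
recorded transform makes solutions back-transformable.  Categorical factors
are reference-level constrained (first sorted level dropped); degenerate
columns (single-level factors, constant age) are dropped with a warning,
and any remaining rank deficiency is an error naming the aliased columns —
estimable functions are unaffected by the choice of constraint, which the
tests verify via invariance of predictions to shifts of y.

Henderson's mixed-model equations are solved by sparse LU factorization
(problem sizes here are ≲ 10⁴ equations; an iterative solver would buy
nothing), and every solve checks the normal-equations residual against
1e-8·‖RHS‖∞.

### Relationship matrices

* `tabular_A` builds dense A by the recursive tabular method and serves as
  the oracle for everything else; it is intended for ≲ 3,000 animals.
* Inbreeding coefficients use the Meuwissen–Luo L·D decomposition and match
  the tabular diagonal to 1e-12 on random pedigrees.
* `a_inverse` applies Henderson's rules *with* inbreeding.  Inbreeding is
  always included: in deep pedigrees ignoring it changes H⁻¹ materially,
  and with it A⁻¹·A reproduces the identity to 1e-8.
* `a22` extracts the genotyped block by solving A⁻¹ against unit vectors
  (sparse LU), avoiding the full dense A; the genotyped set here is a few
  hundred animals, so its dense inversion is cheap and no indirect
  (Colleau-type) algorithm is needed.
* `vanraden_G` uses observed-frequency centring (base-population
  frequencies are unobservable in data of this design), which makes G's
  rows sum to zero — a property the tests assert.
* `blend_G` forms G* = w·G + (1−w)·A22 with w = 0.95.  No further
  compatibility tuning of G to the A22 scale is applied by default: the
  blend is the only adjustment the method description prescribes, though
  the weight is configurable.  A reciprocal condition number below 1e-12
  in G* or A22 raises an error suggesting blending/QC review.
* `h_inverse` adds the genotyped-block correction G*⁻¹ − A22⁻¹ to A⁻¹.
  With no genotyped animals it returns A⁻¹ itself, so ssGBLUP degenerates
  to BLUP bit-for-bit — this identity anchors several tests.

### SNP quality control

Markers with call rate ≤ 95% are removed first; minor allele frequency is
then computed on the survivors' non-missing calls and markers with
MAF ≤ 0.05 are removed.  Both thresholds are deliberately *inclusive* (the
boundary value is removed), matching the stated filter wording even though
strict inequality is the more common convention; both bounds are
configurable.  MAF is computed from allele counts rather than as
`min(p, 1−p)`: with p = 19/20 the float expression `1−p` exceeds 0.05 by
one rounding step and a boundary-MAF marker would dodge the inclusive
threshold.  The filter order is recorded in the QC report so removal
tallies are auditable.  Missing dosages are mean-imputed to 2pⱼ before
centring.  No per-animal call-rate, Hardy–Weinberg or Mendelian checks are
applied.

### EM-REML

Variance components are estimated by EM-REML rather than an
average-information algorithm: EM is simple, respects the parameter space,
and its monotone REML log-likelihood provides a strong internal
correctness check (asserted in every test run).  The updates are

    σu² ← (ûᵀK⁻¹û + σe²·tr(K⁻¹C_uu)) / q
    σc² ← (p̂ᵀp̂  + σe²·tr(C_pp))     / q_p
    σe² ← êᵀy / (n − rank X)

with C the inverse of the λ-form coefficient matrix.  Because the
permanent-environment block of the coefficient matrix is diagonal, those
equations are absorbed analytically and only the (fixed + animal) system is
factored densely per iteration; the needed inverse blocks (C_uu on the
sparsity pattern of K⁻¹, the diagonal sums behind tr(C_pp)) and
log-determinants are recovered exactly through the absorption.  A unit test
checks every absorbed quantity against a brute-force inverse of the full
coefficient matrix.

Plain EM crawls near the optimum (hundreds of iterations for tight
tolerances), so each cycle attempts a squared-extrapolation (SQUAREM-type)
step across two EM updates.  The accelerated candidate is evaluated and
accepted only if the REML log-likelihood did not decrease; otherwise the
plain EM step is taken.  The recorded likelihood trace is therefore
monotone by construction, and the accelerated and plain recursions agree on
the fixed point (tested).  Defaults: relative-change tolerance 1e-8,
iteration cap 500 (counted in factorizations); hitting the cap returns a
`converged=False` flag, never silently.  Negative numerical updates are
clamped to 1e-10 with a warning.  If no animal has repeated records, σc²
is unidentifiable and fixed at zero with a warning; with no random animal
term at all the estimator reduces to the OLS residual mean square.

### Validation protocol

Deregressed phenotypes ď are computed **once on the full data**: OLS on the
fixed-effects-only model, per-record residuals averaged within animal.
Held-out animals therefore keep a "true" value — the only reading under
which a holdout can be scored.  Each cross-validation replicate removes all
records of a random sample of genotyped animals (default 100), solves both
methods on identical training data, and scores each by the Pearson
correlation of predictions with ď over the holdout.  The method contrast
uses a paired two-sided t-test across replicates — pairing is the natural
choice because both methods share each replicate's holdout — and the
percent increase is computed from unrounded replicate means (ratios of
independently rounded means will not reproduce it exactly).  Per-replicate
seeds derive from the master seed via `SeedSequence(master, spawn_key=(r,))`
so changing the replicate count never shifts earlier replicates.
Truncation selection takes the top `ceiling(fraction × n)` animals per
method with ties broken by internal animal ID.  Variance components are
re-estimated per replicate by default; a config switch instead holds
supplied components fixed across replicates, which is how the long
replicated runs in the acceptance suite are configured.

The forward check removes the last recording period's records for a listed
animal set (default: every animal recorded in the last year — the calendar
is data-driven, not hard-coded), refits both methods and correlates their
predictions with the animals' full-data ď, reporting the genotyped fraction
of the evaluated set alongside.

## Synthetic data

The generator emulates a fiber-recording breeding scheme: a multi-
generation natural-mating pedigree (each generation mates a sampled sire
set of `prop_sires` × dams to all dams), unlinked biallelic SNPs gene-
dropped from founder frequencies `U(0.10, 0.50)` (random allele labelled
reference), and repeated records with the full fixed-effect structure.
A fraction of parent links (default 10%) is reset to unknown, mimicking
incomplete recording; unknown-parent gametes draw from founder
frequencies, which is exactly the base-population assumption the A-matrix
rules make.

True breeding values are **marker-determined**: a QTL subset of the SNPs
(default 200 of 2,000) carries i.i.d. normal effects, rescaled so the
founder variance of u equals σu².  This matters: were u sampled from the
pedigree, genomic relationships would carry no information beyond A and the
BLUP-vs-ssGBLUP contrast would have no mechanism.  Loci are unlinked — the
evaluations use no linkage information, so LD beyond cosegregation is
unnecessary for the tested contrasts.

Defaults are a desk-scale emulation of the motivating study design
(~3,000 pedigree animals over 5 generations from 500 founders, ~400
genotyped drawn from the youngest two generations, 2,000 SNPs, ~2 records
per animal via 1 + Poisson(1)), roughly quarter scale with the genotyped
fraction preserved.  The FD / SD / PM trait presets fix the variance triple
((2.824, 1.289, 4.332), (0.354, 0.144, 0.431), (27.416, 39.509, 106.316)
trait-units²), the trait mean and the number of year levels (19, 19, 4).
Record-count and age distributions are pragmatic choices (first record
around the second year of life, one record per subsequent year); fixed-
effect coefficients are drawn with spreads proportional to the phenotypic
SD (year 0.25·σP, color and status 0.15·σP, age 0.10·σP), and a
`fixed_effect_scale` switch zeroes them for calibration tests.  Years track
generations so the "last year" is populated by the youngest animals, which
gives the forward check its temporal meaning.

What the simulator does **not** reproduce: selection (matings are random),
genotype-by-environment interaction, maternal/litter effects, linkage and
LD structure, genotyping error, and age-trait trends beyond the smooth
covariate.  Passing tests therefore demonstrate correctness of the
machinery and the direction of the genomic gain under the stated
generating model — not the magnitude of any gain in real fiber data.

## Problem sizes and numerical choices in the test/acceptance runs

* Matrix oracle suite: 50 random pedigrees of ≤ 200 animals; tolerances
  1e-8 (A⁻¹·A), 1e-12 (inbreeding), 1e-10 (A22), 1e-6 (H⁻¹ vs dense
  partitioned oracle).
* Variance-component recovery: 10 simulated pedigrees of ~2,000 animals
  with ~2 records each at the FD-like triple; EM run to relative tolerance
  1e-7 (cap 150 factorizations) — past that point the components move by
  far less than the 15% recovery band being tested, so tighter tolerances
  only add runtime.
* Cross-validation direction: the default desk-scale scenario, 10
  replicates of a 100-animal holdout with components held at their true
  simulation values (the documented fixed-components mode), one-sided
  paired test at α = 0.05.
* The acceptance script's synthetic stage uses the same desk scale, with
  EM-REML run once per kernel on the full data and held fixed across its
  10 CV replicates.

## Known limitations

* Dense `tabular_A` and the dense per-iteration factorization in EM-REML
  cap practical pedigree sizes at a few thousand animals; production-scale
  evaluations would need supernodal sparse Cholesky with selected
  inversion.
* No unknown-parent groups or metafounders: all unknown parents are one
  base population.
* Single-trait only; the three fiber traits are analyzed independently.
* No τ/ω scaling or APY approximation in H⁻¹; the genotyped set is assumed
  small enough for dense G* and A22 inversion.
* The EM-REML σe² update uses the êᵀy/(n − rank X) form, which assumes the
  residual covariance is I·σe² (no weights, no heterogeneous residual
  classes).
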