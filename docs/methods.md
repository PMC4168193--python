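# Methods

## Model

Colony performance is modelled as `P_c = Ā_w^W + A_d^Q + E_c`: the mean
worker-effect breeding value of the colony's worker group, the queen-
effect breeding value of its queen, and an independent residual (one
colony per queen, so queen- and worker-borne environmental effects merge
into a single residual with variance σ²_E). Worker and queen effects are
two correlated traits with additive variances σ²_AW, σ²_AQ and genetic
correlation r_G; the mixed-model equations carry `A⁻¹` times the
elements of `σ²_e G⁻¹` in the genetic blocks, with solution order
(fixed | worker effects | queen effects).

Three entity types populate the pedigree. A *queen* is an individual. A
*sire* is the group of `S` drone-producing queens (DPQs) whose drones
collectively mate one or more queens; it enters the pedigree as one
record whose "breeding value" is the group mean. A *worker group* is the
colony's worker cohort, treated as an n → ∞ family mean. Every record
has at most one dam (a queen) and one sire; all offspring entities of one
(dam, sire) mating — the dam's worker group plus her progeny queens and
sires — are full sibs and form one *mating block*.

## Sampling covariance structure

Mendelian-sampling terms are independent *between* matings but correlated
*within* them, for two reasons: sibs may descend from the same drone
(clonal sperm; probability p₁), and the realised contributions of the S
DPQs vary around 1/S (probability p₂ of sharing a DPQ). Hence

- queens: `var(δ) = (1−F_d)/4 + (1−F_s)/4 + (S−1)(1+F_s−a_ss)/(4S)`
- sires: `var(δ̄) = var(δ)/S + (S−1)/S · cov(δ_FS)`
- worker groups: `var(δ̄) = cov(δ_FS)`
- all within-block off-diagonals: `cov(δ_FS) = p₁(1−F_s)/4 + (p₂−1/S)(1+F_s−a_ss)/4`

(units of σ²_A throughout; F_s and a_ss are the inbreeding and mutual
relatedness of the mating sire's DPQs). D is assembled block-wise and
inverted block-wise (blocks are tiny — 1 + #progeny queens + #progeny
sires); a block whose smallest eigenvalue is ≤ 1e−10 raises, since that
signals inconsistent biology parameters rather than round-off.

Contribution models for (p₁, p₂):

| model | p₁ | p₂ | use |
|---|---|---|---|
| `POISSON` | 1/T + 1/D | 1/D + 1/S | Poisson family sizes (default) |
| `BER` | 1/D | (S+D−1)/(DS) | equal drone shares; the Beebreed partition |
| `EMPIRICAL` | D·σ²_cD + 1/D | S·σ²_cS + 1/S | measured contribution variances |

T (total offspring per queen) defaults to 10⁶: the 1/T term is retained
but numerically negligible. The Poisson p₂ form is an approximation that
breaks down at S = 1 (it exceeds 1); the exact limits are reached through
the `EMPIRICAL` model with zero variances, which the degeneracy tests
use.

## Forward recursion and the tabular A

F, a_sd, a_ss and the D blocks are interleaved in one pass in pedigree
order: for each mating its a_sd is read off the dense A built so far,
offspring inbreeding is a_sd/2, and a newly formed sire's DPQ relatedness
follows the stepwise recursion
`a_ss' = (1+F_d)/4 + p₁/2 + (p₂−p₁)(1+F_s)/4 + (1−p₂)a_ss/4 + a_sd/2`.
Base sires take a_ss = 0. The dense A is capped at 20 000 records
(~3.2 GB); A⁻¹ itself never needs it — it is assembled sparsely as
`(I−M)' D⁻¹ (I−M)`.

One subtlety is not visible in the row formula usually quoted for
tabular methods. The new record's row is `A_ij = ½A_dam,j + ½A_sire,j +
cov(δ_i, a_j)`, and `cov(δ_i, a_j)` is cov(δ_FS) not only for same-block
sibs j but also half that for a sib's previously recorded offspring, a
quarter for grand-offspring, and so on: the sampling covariance
propagates down descendants of full sibs recorded *before* the new
record. The implementation runs this propagation only when an earlier
block member already has offspring; in chronological pedigrees (the
simulator's, and typical field data) the case never arises and the plain
block rule is exact. The gene-dropping oracle in the test suite confirms
the propagated values on pedigrees constructed to trigger it, and with
the propagation the assembled A⁻¹ inverts the tabular A to ~1e−13 on
arbitrary record orders.

Unknown parents are handled by completing the variance so that any
non-inbred record with unknown or base parents has var(A_i) = σ²_A: a
parentless queen gets D_ii = 1, a dam-only queen 1 − (1+F_d)/4, a
sire-only queen 1 − var(Ā_s)/4, a parentless sire 1/S, and a one-parent
sire var(Ā_new) minus the known parent's quarter-variance, with the
missing parent entering the a_ss recursion as base. These choices force
A_ii = 1 + F and keep D blocks positive definite.

## The approximate (BER) evaluation

The comparison method replaces the two distinct paternal worker
relationships (within vs. between colonies) by one value whose square
root q weights the sire link: rows of M carry (½, q), D is assumed
diagonal with `D_ii = 1 + (½−q)a_ds − (1+F_d)/4 − q²(1+F_s)`, and sires
and worker groups are treated as single individuals (their group-mean
variance reduction is ignored — the method's defining approximation, kept
faithfully). q derives from the fixed point a_FS of the a_ss recursion
under the BER probabilities with inbreeding ignored: for S=8, D=12,
a_FS = 123/307 ≈ 0.400650 and q ≈ 0.367112. The historical year-mean
correction term on the sire path is *not* applied, matching how the
method is evaluated here (within-year regressions are unaffected by it);
the selection criterion replaces the ½ on the mate's EBV by q, i.e. a
candidate queen scores ½·(own EBV total) + q·(mate EBV total). An
alternative convention would score candidates by their colony EBV under
the approximate matrix, exactly as the exact method does; the two rank
candidates similarly but weight own-colony data differently, and the
replacement-by-q convention is used here consistently for both selection
decisions and accuracy summaries.

## Simulator

The scheme: years 1–3 seed NSY = 5 base sires each; years 2–3 seed
NQY = 75 base queens as 25 full-sib groups of NQ = 3. Queens born in year
y are mated at birth to the sires born in year y−1 (each sire serves
NFQ = 5 full-sib groups, a whole group to the same sire, allocation
random); each mated queen heads one colony whose record (worker TBV +
queen TBV + N(0, σ²_E)) is made at queen age 2. From year 4, among the
tested two-year-olds the top NSY by criterion each breed one sire and the
top NSY·NFQ each breed one full-sib group (random choices when selection
is off; ties broken by record order). Every queen born through year 20
gets a colony record, i.e. the final data set includes the year-20
cohort's colony tests.

True breeding values follow the same decomposition the exact estimator
assumes: parent mean + a *shared* bivariate-normal sampling component
(variance cov(δ_FS), identical for all offspring entities of a mating)
+ an *individual* component (variance var(δ) − cov(δ_FS); absent for
worker groups). Sampling variances are taken from the forward recursion
with the equal-contribution (BER) probabilities, so generator and BB
estimator share one covariance structure exactly. Base full-sib groups
descend from *recorded* base matings — a parentless base dam mated to a
base sire with a_ss = 0, heading no colony — so the relatedness of base
sibs is visible to the estimators too and BLUP consistency is exact from
the first cohort on.

Defaults (σ²_AW = 1, σ²_AQ = 0.5, σ²_E = 2, r_G = −0.5, S = 8, D = 12,
NSY = 5, NFQ = 5, NQ = 3, 20 years) describe a small, realistic test
programme with a moderately heritable colony trait and the typical
negative worker-queen correlation.

Diagnostics:

- *slopes*: within-replicate regression of TBV on EBV per category
  (queens / sires / colonies) and effect, among records born in the
  focal year, averaged over replicates (SE = SD/√reps); slope 1 ⇔
  unbiased BLUP.
- *criterion-goal correlation*: per replicate over the mated queens born
  in the focal year, between the selection criterion (worker-group EBV
  total for the exact method; ½ own + q mate for the approximation, both
  from the final all-data MME) and the breeding-goal TBV of one simulated
  virgin daughter per mating, which reuses the mating's shared sampling
  pair so the goal correlates with the colony exactly as a real daughter
  would.
- *cumulative response*: mean worker+queen TBV total of the queens born
  each year.

## Numerical choices

- MME solved by SuperLU sparse factorization (`scipy.sparse.linalg.spsolve`),
  CG fallback at rtol 1e−10; a data-free system returns zero EBVs rather
  than a singular solve.
- Regression slopes use centred sums (no mixed-ddof covariance/variance).
- Replicated experiments: 300 no-selection replicates for the slope and
  correlation checks, 200 per estimator for the selection comparison with
  common random numbers (identical per-replicate seed streams, so the
  response difference between estimators is measured on shared base
  populations). These sizes put the Monte-Carlo SE of every reported
  quantity at or below half its validation tolerance while keeping a full
  validation run in the tens of minutes on one core.
- All randomness flows from `numpy` SeedSequences spawned from a single
  integer seed; a replicate is bit-reproducible from (config, index).

## Known limitations

- One colony per queen; no drone-level pedigree records; no
  individual-DPQ pedigrees with unequal contributions.
- No REML/Bayesian variance-component estimation; the genetic parameters
  are inputs.
- The dense tabular A bounds exact-method pedigrees to ~20 000 records;
  an inbreeding algorithm that avoids the dense A (the usual
  Meuwissen–Luo-style shortcut does not carry over because D has
  off-diagonals) is not provided.
- The simulator emulates the reference breeding design only: non-
  overlapping selection cycles, a single trait, the mean as the only
  fixed effect. Passing tests demonstrate correctness of the estimators
  under the generator's assumptions (shared drone/DPQ contribution
  model, normal effects), not robustness to real-data features such as
  unknown mating stations, variable group sizes or non-normal residuals.
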