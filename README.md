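# beeblup

Breeding-value estimation for honey bees: exact relationship matrices,
BLUP of correlated worker and queen effects, and a breeding-scheme
simulator.

## The problem

Genetic evaluation in *Apis mellifera* cannot use the standard animal
model directly. A colony record is produced jointly by the ~10&#8201;000
workers (the *worker effect*) and by the queen (the *queen effect*), the
queen is mated once — to roughly a dozen drones descending from a group
of *S* drone-producing queens ("the sire") — and a drone is effectively a
flying gamete producing clonal sperm. Because two workers of one colony
may carry an identical paternal gamete, Mendelian-sampling terms of
full-sibs are *correlated*: the sampling covariance matrix **D** in
Henderson's decomposition

```
a = M a + d,    A = (I − M)⁻¹ D (I − M)'⁻¹,    A⁻¹ = (I − M)' D⁻¹ (I − M)
```

is not diagonal but block diagonal, one block per (queen × sire) mating.
With *p₁* the probability that two full-sibs descend from the same drone
and *p₂* that they descend from the same drone-producing queen,

```
cov(δ_FS) = p₁ (1 − F_s)/4 + (p₂ − 1/S)(1 + F_s − a_ss)/4     (per σ²_A)
```

where *F_s* is the inbreeding of the sire's member queens and *a_ss*
their relatedness. Worker groups (the n → ∞ family mean) get exactly this
value as their diagonal; queens and sires get their own sampling
variances; all within-block off-diagonals equal cov(δ_FS). Inbreeding
(*F = a_sd/2*) and *a_ss* are obtained recursively in one forward pass
over the pedigree.

The package implements

* **pedigree_core** — the queen / pseudo-sire / worker-group data model,
  validation, topological ordering, mating-block detection, CSV I/O;
* **relmatrix** — the exact ("BB") construction of M, block-diagonal D,
  D⁻¹, A and A⁻¹ under Poisson, equal-contribution (BER) or empirical
  drone/DPQ contribution models;
* **ber_method** — the approximate evaluation used by the German
  Beebreed programme (path coefficient *q* on the sire link, diagonal D),
  reconstructed for comparison;
* **blup** — the two-effect mixed-model equations (worker + queen effect
  with genetic correlation r_G) and selection criteria;
* **simulator** — a stochastic breeding scheme (per year: 5 sires, 25
  full-sib groups of 3 queens; colonies tested at queen age two; optional
  truncation selection) used to validate both estimators.

## Worked example

```python
import numpy as np
from beeblup import (MatingBiology, ContributionModel, Pedigree,
                     IndividualRecord, Category, validate_and_order,
                     build_A_and_tables)

R, C = IndividualRecord, Category
ped = validate_and_order(Pedigree([
    R("dam",   C.QUEEN),
    R("sire",  C.SIRE, group_size=8),
    R("queen", C.QUEEN, "dam", "sire"),
    R("queen2", C.QUEEN, "dam", "sire"),
    R("workers", C.WORKER_GROUP, "dam", "sire"),
]))
bio = MatingBiology(S=8, D=12, model=ContributionModel.POISSON)
t = build_A_and_tables(ped, bio)
print(np.round(t.A, 4))
```

prints

```
[[1.     0.     0.5    0.5    0.5   ]
 [0.     0.125  0.0625 0.0625 0.0625]
 [0.5    0.0625 1.     0.3229 0.3229]
 [0.5    0.0625 0.3229 1.     0.3229]
 [0.5    0.0625 0.3229 0.3229 0.3229]]
```

Read: a base sire of 8 unrelated drone-producing queens has
var(Ā_s) = 1/8 (row 2); two full-sib queens are related 0.3229 — more
than the classical 0.25 + 1/32 because sibs can share a drone father —
and the worker group's "diagonal" 0.3229 is the variance of the family
mean, far below 1, which is exactly what the approximate method ignores
when it treats the group as a single individual.

The same matrices from the shell:

```
beeblup amatrix --pedigree ped.csv --biology poisson -S 8 -D 12 --out out/bb
beeblup blup --pedigree ped.csv --phenotypes phen.csv --method bb \
        --params params.yaml --out ebv.csv
beeblup simulate --config sim.yaml --out results/
```

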