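# crossanno

Correcting cross-annotation in read-count functional profiles of
metagenomes.

## The problem

A metagenomic sample is functionally profiled by aligning its sequencing
reads against a protein-family database (such as the Clusters of
Orthologous Groups, COG) and assigning each read to the family of its
best-scoring alignment. With short next-generation reads (~100 bases)
this best-hit assignment is error-prone in both directions: a family's
tally includes reads that truly originate from other families, and reads
that truly belong to it end up counted elsewhere. This two-sided error is
called **cross-annotation**, and it can distort family abundances by
orders of magnitude — a family with 5 071 true reads can show a best-hit
tally of 18.

## The model

Let a read be aligned to one of *N* observed families *a₁…a_N* and
originate from one of *M* estimated truly-existing families *c₁…c_M*
(the last being a reserved `EXTRA` family for coding sequences outside
the catalogue and non-coding sequence). With

- *α_ij* = P(A = aᵢ | T = c_j), the confusion probability of a read from
  *c_j* being aligned to *aᵢ* (each column of α on the simplex), and
- *β_j* = P(T = c_j), the origin proportions,

the observed counts *y₁…y_N* follow a multinomial with cell
probabilities Σ_j α_ij β_j, and the observed-data log-likelihood is

    ℓ(α, β | y) = Σᵢ yᵢ log( Σⱼ α_ij β_j ).

The true origin of each read is latent, so (α, β) are estimated by EM:

- **E step** Φ_ij = yᵢ · α_ij β_j / Σ_s α_is β_s — the expected number of
  reads aligned to *aᵢ* that originate from *c_j*;
- **M step** α_ij ← Φ_ij / Ψ_j and β_j ← Ψ_j / Σᵢ yᵢ, with Ψ_j = Σᵢ Φ_ij;

iterating until every parameter changes by less than 10⁻⁶. The corrected
count for family *c_j* is ŷ_j = [ (Σᵢ yᵢ) · β̂_j ], rounding half away
from zero.

Because the decomposition is over-parameterized, EM is started from
**learned initial values**: from a labeled sample (reads of known
origin), α⁰ copies the empirical per-origin alignment frequencies α^L
and β⁰ is assembled from the empirical origin-given-alignment
frequencies γ^L weighted by the new sample's counts, with leftover
probability mass split evenly over families the labeled sample never saw.

Inputs are standard BLAST tabular alignments filtered at bit score > 66
(best hit wins), with families lacking any RPS-BLAST support at bit
score > 61 flagged as artificial and excluded from the existing set.

## Worked example

Simulate a small sample with known truth, then correct it:

```sh
crossanno simulate --seed 11 --out-dir fixtures \
    --n-existing 6 --n-aligned 9 --total-reads 50000 --learning-reads 50000
crossanno correct --counts fixtures/counts.tsv \
    --rps-counts fixtures/rps_counts.tsv \
    --learning fixtures/learning.tsv \
    --truth fixtures/truth.tsv --out-dir run
```

The run logs one line per EM iteration and the accuracy of the corrected
profile against the simulated truth:

```
INFO crossanno.em: EM iteration 2: loglik=-91975.41156 max-param-change=1.11e-16
INFO crossanno: accuracy: RRMSE=0.05938 AVGRE=0.0414 MAXRE=0.1238 DTV=0.003497
INFO crossanno: converged in 2 iterations
```

and `run/profile.tsv` holds the corrected profile — the estimated origin
proportion β̂_j and corrected read count ŷ_j per existing family,
including the `EXTRA` catch-all:

```
family_id	beta_hat	count_hat
COG0001	0.5981258551635358	29906
COG0002	0.114347789555068	5717
COG0003	0.0020466186136966435	102
COG0004	0.012976351836834295	649
COG0005	0.02373902743543139	1187
EXTRA	0.24876435739543384	12438
```

COG0003's raw best-hit tally was 9 665 reads of 50 000 — almost all of
them cross-annotated from other families — while its corrected count is
102 (its true simulated proportion is ~0.002). The total-variation
distance between the corrected and true proportions over the real
families is 0.0035.

The same functions are available as a library:

```python
from crossanno import (estimate_learning_distributions, initialize_alpha,
                       initialize_beta, fit_plsa, corrected_profile)
```

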