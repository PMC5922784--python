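# Methods

## Model and estimation

Observed data are the best-hit read counts y = (y₁…y_N) over the N
aligned families of one sample. The model assumes each read originates
from exactly one of M existing families (the last being the `EXTRA`
catch-all) with probability β_j, is aligned independently of all other
reads, and lands on aligned family aᵢ with probability α_ij conditional
on its origin. The counts are therefore multinomial with cell
probabilities (αβ)ᵢ and log-likelihood ℓ(α, β | y) = Σᵢ yᵢ log Σⱼ α_ij β_j.

EM treats the per-read origin as latent. The E step needs only the
aggregated responsibilities Φ_ij = yᵢ α_ij β_j / Σ_s α_is β_s (per-read
posteriors are identical within an aligned family, so individual reads
are never materialized); the M step is closed-form column normalization,
α_ij ← Φ_ij/Ψ_j, β_j ← Ψ_j/Σᵢyᵢ. Each iteration cannot decrease ℓ; the
trace is recorded and checked in the tests with 1e-9 slack for float
noise.

**Convergence** is declared when the maximum absolute change over *all*
parameters (every α entry and every β entry) is below `tol` (default
1e-6), with an iteration cap (`max_iter`, default 1000) and a `converged`
flag — parameter change, not likelihood change, because the stopping rule
is stated for the estimates themselves.

**Identifiability.** With N observations and N·M + M free parameters the
maximum of ℓ is far from unique: from an uninformative start EM reaches a
perfect-fit stationary point whose (α, β) split is essentially arbitrary.
The method's answer is the learned initialization below; the fitted β̂ is
meaningful insofar as the initial α⁰ is close to the sample's true
confusion structure. `fit_plsa(update_alpha=False)` is provided to fit β
alone under a known/fixed α; ℓ is then concave in β and the global
maximizer is found regardless of the start.

## Learned initialization

From a labeled joint count matrix (origin × aligned):

* α^L_ij — row-normalized: the fraction of reads from origin c_j aligned
  to aᵢ; origins with zero reads are dropped.
* γ^L_ji — column-normalized: the fraction of reads aligned to aᵢ that
  originate from c_j; aligned families with zero reads are dropped.

For a new sample, α⁰ copies α^L where origin and aligned family were both
seen; aligned families private to the new sample split the leftover
column mass 1 − Σ_shared α^L evenly; origins the labeled sample never saw
(often `EXTRA`) get uniform 1/N columns. β⁰_j = Σ_shared γ^L_ji yᵢ / Σ yᵢ
for known origins; new-only origins split the leftover mass evenly.

Every initialized column/vector is floored at ε = 1e-12 and renormalized:
EM's multiplicative updates keep exact zeros at zero forever, and the
floor removes those absorbing states at a cost far below sampling noise.
When the labeled sample had aligned families the new sample lacks, a
copied column can sum to less than 1 with no new-only families to absorb
the remainder; the renormalization handles this combination too.

The transfer rests on two assumptions — per-origin alignment frequencies
and per-aligned-family origin frequencies are similar across samples —
which are surfaced in the CLI help but not enforced; violating them
degrades the initialization, not the machinery.

## Input filtering

Alignments are 12-column BLAST tabular; bit score must be strictly
greater than the cutoff (default 66, appropriate for ~100-base reads
against COG), and the best hit is the maximum bit score with ties broken
by lowest e-value then lexicographically smallest subject id, making the
assignment independent of input order. An e-value filter mode
(`--filter-mode evalue`) reproduces the conventional 1e-3/1e-5 baselines
for comparison runs. A family is flagged *artificial* when it has zero
read count in an RPS-BLAST run filtered at bit score > 61; artificial
families stay in the aligned list (their reads remain observed data) but
are excluded from the existing families. The reserved id `EXTRA` may not
occur as a real family id — the pipeline refuses rather than renaming.

## Accuracy measures

RRMSE, AVGRE, MAXRE (relative errors against the true β) and DTV (half
the L1 distance) are all computed over the M−1 real families, excluding
`EXTRA`, whose "proportion" aggregates unclassified sequence rather than
a family abundance. The estimated β̂ entries are used as fitted, not
renormalized after dropping `EXTRA`. True proportions must be positive
for the relative measures to exist; zeros are an error, not a silent
skip. RRMSE includes the square root, per its name.

The cross-annotation summary turns per-family (true, assigned, correct)
read tallies into `misassigned_in = assigned − correct` and
`misassigned_out = true − correct`, with a totals row.

## Synthetic data

`sample_truth` draws a ground-truth model: each real family has a "self"
aligned family carrying Beta-distributed mass with mean 1 − `cross_rate`
(sharpness 10·`concentration`), the rest spread by a Dirichlet(
`concentration`) over the other aligned families; the `EXTRA` column is a
broad Dirichlet over all N; β is Dirichlet over the M origins.
`simulate_counts` draws one multinomial from the joint law {α_ij β_j};
labeled draws return the full origin × aligned table, unlabeled draws
its aligned marginal, and both coincide under the same seed.

Defaults are M = 10 existing (incl. `EXTRA`), N = 15 aligned, 10⁵ reads,
`cross_rate` 0.3 (real best-hit data show roughly a quarter to a third of
a family's reads crossing to other families), `concentration` 1.0. What
the generator does *not* emulate: sequencing-error profiles, read-length
and CDS-conservation biases in the counts, or correlated confusion
between homologous families — so passing recovery tests demonstrates the
estimator works when the model holds, not that real BLAST output obeys
the model.

`label_read_truth` applies the truth-labeling rule for simulated reads
placed on a reference: identity strictly greater than 95% and an overlap
of at least 60 bases (0-based half-open intervals) with a family's coding
sequence; among several qualifying families the largest overlap wins and
an exact tie is an error flagged for review rather than an arbitrary
pick.

## Numerical and design choices

* Likelihood in log space; no products over reads.
* M-step columns with Ψ_j = 0 (an origin explaining no reads) keep their
  previous α column — the update is 0/0 otherwise — and receive a
  vanishing β mass before renormalization; when no column is dead, β is
  exactly Ψ/Σy with no renormalization so closed-form cases are bit-exact.
* Corrected counts round half away from zero and are *not* forced to sum
  to Σy (they can differ by up to M/2).
* Cutoffs are strict (>) for both the BLAST (66) and RPS-BLAST (61)
  filters; "similarity score" is read as the BLAST bit score.
* With no learning sample the pipeline falls back (with a warning) to
  uniform α⁰ columns and β⁰ proportional to each existing family's own
  aligned count, `EXTRA` taking the artificial families' mass — a
  documented convenience, with no claim to the learned init's accuracy.
* The fitted α̂ is exposed on the result object but the profile output
  uses β̂ only.

## Problem sizes

The test suite and the acceptance script run synthetic instances at
M = 10, N = 15 with 10⁵-read samples for recovery checks (seconds on one
CPU) and dozens of small random instances (N ≤ 12) for the invariant
sweeps; these sizes put multinomial sampling error well below the
acceptance margins while keeping the whole suite under a couple of
minutes.

## Limitations

* Real confusion structure varies with read length, database version and
  alignment parameters; learned initial values transfer only between
  samples processed identically.
* Abundance estimates for families absent from the learning sample rest
  on uniform initial columns and are correspondingly weaker.
* Read-count biases from CDS length and conservation are not modeled.
* The EM fit returns one local maximum; no restarts are attempted since
  the learned initialization is the intended remedy.
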