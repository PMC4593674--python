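# Methods

## The model

omegascan tests for episodic positive selection on a designated branch of a
phylogeny using a branch-site codon mixture model on in-frame coding
alignments.

The substitution process on each branch is a Goldman–Yang continuous-time
Markov chain over the 61 sense codons of the universal code.  The
instantaneous rate from codon *i* to *j* is zero unless the codons differ at
exactly one nucleotide, and otherwise

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

where `kappa` is the transition/transversion rate ratio, `omega = dN/dS` the
nonsynonymous/synonymous rate ratio, and `pi` the equilibrium codon
frequencies.  Frequencies follow the F3×4 convention: position-specific
nucleotide frequencies pooled over taxa (missing codons excluded),
multiplied per codon and renormalised over the sense codons.  F3×4 is the
conventional default for this model family; it is a design choice here (the
alternative F61/F1×4 estimators are out of scope) and `pi` can be supplied
directly wherever it is consumed.

The branch-site mixture (model A) assigns each codon column independently to
one of four classes.  With `omega0 in (0,1)`, `omega1 = 1` fixed, and
`omega2 >= 1` operating only on the flagged "foreground" branch:

| class | proportion                       | background | foreground |
|-------|----------------------------------|------------|------------|
| 0     | p0                               | omega0     | omega0     |
| 1     | p1                               | 1          | 1          |
| 2a    | (1−p0−p1)·p0/(p0+p1)             | omega0     | omega2     |
| 2b    | (1−p0−p1)·p1/(p0+p1)             | 1          | omega2     |

The null model fixes `omega2 = 1`; the alternative estimates it.  The test
statistic `2(lnL_alt − lnL_null)` is referred to the upper tail of
chi-square with 1 d.f.  Because the null pins `omega2` at the boundary of
the alternative's parameter space, the chi-square(1) reference is
conservative; the simpler reference is used deliberately (rather than the
50:50 mixture of a point mass at 0 and chi-square(1)) and the type-I
calibration check asserts conservativeness, not exactness.

### Likelihood evaluation

Per-gene likelihoods use Felsenstein pruning over collapsed site patterns.
Missing codons (gaps, ambiguity codes, masked stops) contribute all-ones
partial vectors, i.e. they are marginalised.  Transition probabilities come
from the eigendecomposition of the pi-symmetrised rate matrix
`B = D^{1/2} Q D^{-1/2}` (D = diag(pi)), which is exact for reversible Q and
much faster than repeated dense exponentials; a dense `expm` fallback exists
and the two paths are cross-checked in the tests.  Partial likelihood
vectors are renormalised every third level of the tree (and at the root)
with the log-scale accumulated, so deep trees cannot underflow.  Equilibrium
frequencies are floored at 1e-8 and renormalised inside the spectral path so
that codons assigned zero F3×4 weight cannot break the decomposition.

Rate-matrix scaling: each gene uses a single scaling constant — the
class-weighted average substitution rate of the *background* class omegas —
so branch lengths are expected substitutions per codon averaged over site
classes on a background branch.  The simulator uses the identical
convention, which keeps generating and fitted parameters on one scale.

### Fitting

Free parameters are optimised by L-BFGS-B on transformed coordinates: log
kappa, logit omega0, log(omega2 − 1), and a 2-parameter softmax for
(p0, p1, 1−p0−p1).  The alternative fit uses 3 starts (one fixed default,
the rest drawn from a seeded dispersion); the null reuses the alternative's
optimum as one of its starts.  Convergence tolerance is ~1e-7 on lnL
(relative ftol 1e-10).  If the alternative still lands below the null, it is
refitted from the null's optimum, and as a last resort the null optimum
itself — a feasible alternative point with omega2 = 1 — is adopted, so the
models nest exactly and the LRT statistic is never negative by construction
(residual noise is clamped at 0).

Branch lengths are estimated once per gene under a single-omega (M0) fit and
then fixed for both branch-site fits — the standard practice for
genome-scale screens, and the default here (`branch_length_mode="m0"`;
`"fixed"` uses the input tree's lengths as-is).  In a rooted tree the two
root-adjacent edges are only jointly identifiable under a reversible model;
the optimiser settles anywhere on that ridge, which does not affect the
likelihood.

### BEB site posteriors

Site posteriors for the positively selected classes use Bayes Empirical
Bayes: a discrete uniform prior grid with 10 midpoints per dimension over
omega0 in (0,1), omega2 in (1,11), and the (p0, p1) simplex via the map
p0 = u, p1 = v(1−u) over unit-square midpoints (near-uniform coverage of the
triangle; the mild density distortion is a documented simplification).
kappa, branch lengths and the rate-scaling constant are held at their ML
estimates.  Grid points are weighted by their marginal data likelihoods and
the per-column class posteriors averaged under those weights; each column's
four posteriors sum to one.  A column is a positively selected site (PSS)
when the class 2a+2b posterior strictly exceeds 0.50.

### Filtering and multiple testing

Tightly clustered PSS calls are the classic footprint of local alignment
error rather than selection.  For each gene the scan computes `D_med`, the
median of successive differences of sorted PSS positions (adjacent codons
give an interval of 1); a gene is excluded when `D_med` is defined and
≤ 10 codons (the boundary itself excluded).  Genes with fewer than two PSSs
cannot show clustering and are always kept.  Benjamini–Hochberg step-up
q-values are then computed per focal branch across the genes that were
tested on that branch and survived the filter — filtering precedes
correction.  The final call requires raw p < 0.05, surviving the filter,
and q < 0.10, which makes the summary cascade
(tested ≥ p<.05 ≥ filtered p<.05 ≥ q<.10) monotone by construction.
Genes lacking the taxa that define a focal clade are skipped for that branch
and logged, so branches can have different tested-gene denominators.

### GC3 diagnostics

Per-taxon GC3 is the fraction of non-missing codons whose third base is G or
C; a row with no usable codons is *undefined* (NaN), never 0 — fragmentary
rows must not masquerade as AT-rich.  deltaGC3 for a focal branch is the
mean GC3 of the foreground tips minus the mean over the remaining tips (an
ancestral-reconstruction-based definition would be an alternative; the
tip-mean version is the documented substitute).  The Pearson correlation of
LRT p-values with deltaGC3 across genes flags compositional confounding of
the selection signal.

## The synthetic-data generator

The generator is the package's stand-in for transcriptome-derived inputs and
defines the study conditions under which the pipeline is validated.

- **Codon alignments** are evolved forward under the branch-site model
  itself: per column a class is drawn i.i.d. from (p0, p1, p2a, p2b), the
  root codon from pi, and states propagate along each branch with the class-
  and branch-appropriate omega.  Defaults: kappa 2, omega0 0.2, p0 0.5,
  p1 0.3 (so ~20% of sites fall in the selected classes), selected genes
  omega2 = 8, null genes omega2 = 1.
- **The default study tree** has 6 taxa with mammal-like branch lengths
  (total ≈ 1.9 expected substitutions per codon).  The foreground is an
  internal branch of length 0.30 above a cherry — a long-branch regime in
  which an episodic burst leaves a detectable substitution excess.  Short
  foreground branches (≲0.15) put the same omega2 in an intrinsically
  weak-signal regime where much of the simulated data carries no detectable
  excess at all.
- **Missing data** is injected as whole-taxon dropout or contiguous codon
  blocks (block-structured, mimicking fragmentary transcript assemblies,
  not i.i.d. missingness).
- **Interaction networks** come from a planted-partition model: proteins
  assigned round-robin to clusters, within-cluster edges at high probability
  and high combined scores (700–999), between-cluster edges rare and
  low-scoring (150–499); each cluster's members share planted GO terms, plus
  diffuse background terms so enrichment has competition.

What the generator does **not** emulate: among-site autocorrelation of
classes (columns are i.i.d., per the model's own assumption — artifact-like
clustered signal can be planted explicitly via `site_classes`), indel
processes and alignment error itself, orthologue mis-assignment,
composition heterogeneity across lineages, and rate variation beyond the
four classes.  Passing tests therefore demonstrate correctness of the
machinery under the model, not robustness to real-data violations of it.

## Problem sizes and numerical choices

Validation studies are scaled to run on one CPU: type-I error uses 100 null
genes (6 taxa, L = 200 codons), power uses 50 genes with omega2 = 8, the
full-scan cascade check uses a 12-gene mixture at L = 120, and likelihood
correctness is checked against exhaustive internal-state enumeration on 200
random 3–4 taxon instances (61^2–61^3 terms per column).  Empirical
rejection rates at these sizes carry binomial noise of a few percent, which
the asserted bounds accommodate.

One stationarity check deserves a note: comparing empirical tip codon
frequencies with pi on a tree of total branch length 50 at L = 5000 has a
Monte-Carlo noise floor of ~0.013 total-variation distance — even fully
independent draws at that sample size average ~0.009, and phylogenetic
correlation between tips (bounded by the fixed total tree length, whatever
the tip count) pushes it higher.  The check is implemented faithfully and
its observed value (~0.014) reflects that floor, not a simulator bias; the
bias itself is bounded by the identity of the generator's transition
matrices with the likelihood's, which the oracle tests verify.

Other numerical details: site patterns are collapsed before likelihood
evaluation (oracle-checked against uncollapsed enumeration); identical
columns therefore share all computation.  P(t=0) is returned as the exact
identity so that zero-length branches make conflicting columns exactly
impossible (log-likelihood −inf) rather than astronomically unlikely.
Degenerate proportions (p0+p1 → 0 or 1) are handled through the softmax
parameterisation, which cannot reach them exactly.  Hub ranking and
component ordering in the network stage break ties lexicographically so all
outputs are deterministic.

## Known limitations

- The chi-square(1) reference is conservative (see above); power figures are
  therefore slightly pessimistic relative to a mixture reference.
- BEB here follows the published grid convention but holds the rate-scaling
  constant at the MLE rather than recomputing it per grid point; the effect
  is a second-order perturbation of the prior grid, shared by all classes.
- The scan treats the input tree as rooted as written and does not infer
  trees; per-gene trees are pruned from the fixed species tree, not
  re-estimated.
- GO enrichment implements the classic one-sided Fisher test only; the
  elim/weight decorrelation family and true-path propagation beyond a
  user-supplied closure are out of scope.
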