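# Methods

This note documents the models and procedures implemented in `scn2a_pheno`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data tests do and do not establish about real cohorts.

## Ontology model

The phenotype vocabulary is a rooted directed acyclic graph of terms linked
by `is_a` edges (the HPO is a DAG, not a tree: terms may have several
parents).  Only `id`, `name`, `alt_id`, `is_a` and `is_obsolete` are
interpreted when parsing OBO files; `part_of`, logical definitions and OWL
semantics are out of scope.  Structural violations are hard errors: a cycle
is reported with one offending path, a dangling `is_a` target by id.
Annotations given under alternate (merged) ids are silently canonicalized
with a logged count.  Obsolete terms stay resolvable but are excluded from
closure queries, and may not have children.

Closures include the query term itself.  This is the standard Resnik
convention and is load-bearing: a term that subsumes another must be its own
candidate most-informative common ancestor (MICA).  The root and other
universally-carried terms participate in propagation — they simply acquire
frequency 1, hence information content IC = −log₂ f = 0 bits, and contribute
nothing downstream.  MICA ties are broken by lexicographically smallest term
id so results are deterministic; the IC value is unaffected by the
tie-break.  MICA queries demand a complete propagated frequency table and
fail loudly on missing terms rather than imputing a frequency.

Non-phenotype branches of a real ontology (inheritance, clinical modifiers)
can be excluded by restricting to a subtree (`parse_obo(..., restrict_to=)`);
the default leaves the graph unrestricted because synthetic and fixture
ontologies have no such branches.

## Harmonization

Positive annotations propagate upward: the harmonized positive set is the
ancestor closure of the base set.  Negative (explicitly absent) annotations
propagate downward — absence of a general phenotype implies absence of every
specialization — and are then compressed by **apex-only pruning**: a negative
term is kept iff none of its parents is negative.  Pruning is lossless by
construction; `propagate → prune → re-propagate` is the identity on the full
negative set, and the test suite verifies this round trip on random DAGs.

Positive assertions dominate negatives.  During downward propagation, any
term that is itself positive, or has a positive descendant, is silently
excluded from the negative region.  A base negative term *identically*
present in the supplied positive set is instead a hard conflict error naming
the individual and term.  With an ancestor-closed positive set this flags
negatives asserted at an ancestor of a positive (one cannot lack "seizures"
in general while having infantile spasms) as curation contradictions, which
is the desired strictness for pipeline input; calling the primitive with the
raw base positives gives the softer branch-blocking behaviour.  Absence of a
term is never inferred: a term not asserted is "not recorded", not "absent".

An optional `max_depth` bounds downward propagation for very deep
ontologies; the default is unlimited, since pruning already controls the
stored set size.

The effect of propagation on term frequencies is quantified per base term by
a two-sided Fisher exact test of base versus propagated counts (each against
the cohort remainder), BH-corrected at FDR 10%.  The test statistic treats
the two counts as independent samples, which is conservative for the
purpose of flagging strongly shifted terms.

## Association testing

Each phenotype column (propagated positive terms plus `NP:`-prefixed pruned
negatives) is tested against a genotype grouping with the two-sided Fisher
exact test.  Odds ratios are conditional maximum-likelihood estimates with
exact 95% confidence intervals (a zero cell yields 0 or +∞ with one finite
bound), alongside the sample cross-product ratio for transparency.  One BH
correction runs per named analysis: the variant-class analysis over its
terms, and the location analysis pooled over the whole location × term
family.  Location groups are each channel domain, each segment class pooled
across domains, and the derived S5–S6 pore-loop flag, always restricted to
missense carriers (truncating variants have no meaningful protein position).
Whether positives and negatives should be corrected jointly is genuinely
open; the implementation pools them within each analysis, and the tables
carry polarity so either view can be recomputed.

## Channel topology

The topology is a data table of 1-based inclusive feature intervals (domain,
region, segment), not code.  The bundled Na_V_1.2 table is a **synthetic,
approximate** reconstruction of the canonical 4×6-segment sodium-channel
architecture, consistent with published location labels of well-known
recurrent variants but not with curated UniProt boundaries; the file header
says so, and boundary-sensitive conclusions require substituting a curated
table.  The pore-loop flag is derived, not stored: any position strictly
between a domain's S5 end and S6 start is pore-loop territory.

## Phenotypic similarity

Term-pair similarity is the IC of the MICA under propagated cohort
frequencies.  Individual-pair similarity is the best-match-average:
s(A→B) = Σ_{a∈A} max_{b∈B} IC(MICA(a, b)), symmetrized as the arithmetic
mean of the two directions.  The mean (rather than the raw symmetric sum)
keeps self-similarity on a scale comparable across set sizes; the sum is
available as a configuration option and is exactly twice the mean.  Only
positive propagated terms enter the score — negative assertions carry
different semantics and are excluded.

Group homogeneity is tested by permutation: the observed statistic is the
median of all C(n,2) within-group pairwise similarities; the null draws n
individuals uniformly *without replacement from the entire cohort, the
group's own members included*, N times (default 100,000), and
p = (1 + #{null ≥ observed}) / (N + 1), which can never reach zero and is
floored at 1/(N+1).  Because the group is part of the sampling frame, small
groups in small cohorts can be redrawn exactly, producing ties — the add-one
formula handles this correctly, and the test suite checks the formula
against the exposed null draws.  Individuals with empty term sets score 0,
are dropped from group memberships with a warning, and remain in the null
frame.  Medians over pairwise scores were chosen over per-individual best
scores as the reading of "median similarity of n individuals"; the
alternative is a one-line change in `CohortSimilarity.group_test`.

All null draws index into a precomputed cohort similarity matrix, so a suite
of permutation tests costs one matrix build plus cheap resampling.

Phenograms — per-term frequency in a subgroup versus the cohort remainder
with *uncorrected* two-sided Fisher p-values and a p < 0.05 highlight — are
descriptive companions to the permutation test, not an association analysis.

## Logistic PCA and variant-function prediction

The binary phenotype matrix (propagated positive terms carried by at least
`min_count = 2` individuals; negatives excluded by default, switchable) is
factorized by logistic PCA: each observation is represented by the
saturated natural parameter θ̃ = m(2x − 1) and the model minimizes the
Bernoulli deviance of Θ = 1μ′ + (Θ̃ − 1μ′)UU′ over an orthonormal p × k
loading matrix U and offsets μ.  The fit is majorization–minimization with
the standard quadratic bound (curvature ¼): working responses
Z = Θ + 4(X − σ(Θ)), U from the top-k eigenvectors of B′Z_c + Z_c′B − B′B,
then the μ fixed point.  Each iteration provably does not increase the
deviance; convergence is declared at relative deviance change below 1e-6,
and hitting `max_iter` flags the model rather than raising.  Initialization
is the deterministic SVD of the centred natural parameters, so fits are
reproducible without randomness.

The scale m bounds fitted log-odds at ±m.  Default m = 4 (log-odds ≈ 98%
probability); 5-fold cross-validated held-out deviance over {2, 4, 6, 8, 10}
is available (`select_m`) but disabled by default for speed and
determinism.  Deviance explained is reported against the column-mean null
model.  Because the majorizer's eigenvalue order need not match deviance
contribution, fitted components are re-ordered by the deviance each explains
alone, then cumulative deviance over leading components is reported; on all
tested data this sequence is non-decreasing and bounded by 1.  Sign
indeterminacy is fixed by orienting each component so its score correlates
positively with the presence of its top-loading term.

Components are scored against external binary labels with rank-statistic AUC
(tie-corrected), the Youden-optimal cutoff (ties resolved toward higher
sensitivity), precision–recall and F1 at that cutoff, and an empirical PPV
curve swept in both directions.  For GoF/LoF prediction the best-AUC
component is re-oriented so higher scores mean GoF on the labeled subset
(truncating variants are LoF by mechanism; missense labels come from the
electrophysiology evidence table; mixed-effect variants stay unclassified
and are excluded).  Each individual's PPV is read off the labeled empirical
curve at their score, clamped at the most extreme labeled score, so an
individual beyond the labeled range inherits the terminal value.

## Synthetic data: what it emulates, and what it does not

`generate_ontology` builds random rooted DAGs, acyclic by construction
(parents are drawn from strictly shallower levels; a second parent appears
with probability `extra_parent_p`).  `generate_cohort` mirrors the
statistical structure of a literature-curated channelopathy cohort:

* 341 missense / 68 protein-truncating / 4 other carriers (configurable);
* a median of 6 base terms per individual, drawn depth-biased; the
  background budget discounts each individual's expected planted additions
  so the median stays on target;
* planted class effects: designated leaf terms carried with class-dependent
  probability tuned to a target odds ratio (default 8) over a baseline
  frequency (default 0.12);
* a pore-loop location effect (default odds ratio 5) among missense
  carriers, with ~12% of singleton missense variants placed in pore-loop
  intervals;
* recurrent-variant groups (defaults 18/14/5 members) sharing homogeneous
  term cores at 0.85–0.9 penetrance;
* a latent GoF/LoF factor expressed through two disjoint 6-term marker sets
  carried at 0.60 (matching latent class) versus 0.08, with 17 GoF and 30
  missense LoF variants labeled (truncating variants add to the LoF side);
* negative assertions only for individuals whose positive closure does not
  contradict them, mirroring the curation rule that absence must be
  documented.

The truth record documents every planted term, group and label, enabling
analytic expectations (e.g. planted-term class frequencies) to be checked
within binomial tolerance.  The generator does **not** emulate realistic HPO
co-occurrence beyond the configured structure, annotation depth differences
between publication eras, ascertainment bias, or correlated negative
assertions.  Passing tests therefore demonstrate that the pipeline recovers
structure of the planted kinds at realistic sizes and controls error rates
under its null — not that any particular real-cohort estimate is correct.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at desk scale, as the
package's own choice of problem sizes: random-DAG oracles at ≤ 50 nodes
(100 cases), similarity oracles over 100 set pairs, null-uniformity over a
150-individual cohort with 500 random groups at N = 2,000 permutations,
association recovery over 100 replicates of the 68-vs-341 design and 200
null replicates, and N = 20,000 permutations in the acceptance study
(production default 100,000).  The pipeline derives per-stage random streams
from one seed (`SeedSequence.spawn`), so changing the permutation count
never perturbs the PCA, and identical configuration plus inputs give
bitwise-identical outputs and manifest checksums.

Degenerate inputs are handled explicitly: empty term sets score 0 similarity
with a warning and are excluded from group tests; constant phenotype columns
are dropped before PCA with a notice; zero-member locations are skipped with
a log line; empty groups, single-class labels, non-binary matrices, and
malformed CURIEs are errors.

## Known limitations

* The bundled channel topology is approximate (see above).
* Fisher tests are unadjusted for covariates; the design deliberately uses
  only exact tests.
* Logistic PCA deviance explained depends on m; values are comparable only
  at fixed m.  With very strong signal the m-capped projection bounds the
  explainable fraction (≈ 0.41–0.55 for the strong rank-1 simulation at
  m = 4) below what an uncapped model would report.
* Alternative term-set similarity kernels (beyond Resnik best-match-average)
  are an extension point: the term-pair matrix in `SimilarityEngine` is the
  single place a different kernel would plug in.
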