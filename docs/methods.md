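# Methods

This note documents the models, conventions and numerical choices behind
`otupick`: what the clustering engine actually computes, what the
synthetic benchmark does and does not emulate, and where the design was
genuinely open.

## Percent identity and alignment

The engine's single primitive is the percent identity between a read and a
candidate centroid. Greedy clustering tools do not agree on a definition,
so ours is declared explicitly and used consistently by the engine, the
workflows and the independent test oracles:

* alignment is semi-global: gaps before the first and after the last
  aligned column are free on both sequences;
* the alignment optimum maximises `matches − gaps` (match +1, mismatch 0,
  gap −1, linear gap cost), which prefers a substitution over an
  insertion/deletion pair and never selects an empty overlap when any
  positive-scoring one exists;
* identity = matched columns / alignment columns, terminal gap columns
  excluded; `N` participates in alignment but never counts as a match
  (conservative identity);
* tie-breaks are deterministic (first-best end cell scanning the last DP
  row then column; diagonal > up > left in traceback), and the two
  sequences are put in a canonical order before alignment so that
  identity is exactly symmetric in its arguments.

The kernel is a numba-compiled dynamic program; the test suite re-derives
it with an independently structured numpy prefix-scan implementation and
checks exact agreement on random and adversarial pairs.

## Candidate ranking and the heuristic knobs

Candidate centroids for a query are ranked by the number of distinct
shared `wordlength`-mers, descending, ties broken by centroid insertion
order. `max_accepts` / `max_rejects` stop the scan after that many
accepted / rejected alignments; `stepwords` caps the query scan at
`stepwords × wordlength` positions. The *slow* preset is
20/500/20/12 and *fast* is 1/8/8/8; fast is the package default since the
downstream ecological statistics are insensitive to the difference, while
slow remains appropriate when minting reference collections.

With `max_accepts` and `max_rejects` at least the number of targets the
engine is *exhaustive*: the step cap is lifted and targets sharing no
words are appended to the candidate list in insertion order, so the
result provably equals an all-pairs best-hit search (asserted against a
brute-force oracle). Heuristic degradation is one-sided by construction:
a read may be failed or found an extra OTU, but an accepted assignment is
always a genuine identity ≥ *s*.

Closed-reference assignment depends only on a read's sequence, so the
implementation resolves each distinct sequence once and is invariant to
how reads are partitioned across workers; de novo clustering is serial by
definition (later reads must see earlier OTUs).

## Workflow conventions

* Subsample size: `round_half_up(|failures| × n)`, floored at 1 whenever
  failures exist and `n > 0`, so the new-reference tier is never
  vacuously empty. Failures are subsampled globally (not per worker).
* New OTU naming: `New.ReferenceOTU<i>` and `New.CleanUpReferenceOTU<i>`,
  `i` counting from 0 in founding order. One `ClusteringParams` governs
  every stage of a run.
* The singleton filter keeps OTUs with **total count ≥ c** (default
  c = 2, i.e., "observed at least twice"); this is the reading under
  which c = 2 removes exactly the singletons.
* The contaminant pre-filter (a closed-reference screen at a permissive
  identity, legacy 0.60) is **off by default**; discarding contaminants
  after picking is the recommended practice, and the screen is expensive.
* Both the full and the min-count-filtered tables are always produced;
  the evaluation harness consumes the filtered table, mirroring standard
  downstream practice.
* `iterative_update_reference` appends a run's new-tier centroids to the
  reference under their OTU ids, so later runs assign matching reads to
  the same identifiers through their closed-reference tier.

## Diversity metrics

Faith's PD and weighted/unweighted UniFrac are computed by a single
post-order traversal of a rooted tree whose tips are OTU ids. Missing
branch lengths are treated as 0, and the root edge participates like any
other. Weighted UniFrac defaults to the unnormalised form
`Σ_e l_e |p_A(e) − p_B(e)|`; the normalised variant divides by
`Σ_e l_e (p_A(e) + p_B(e))`. An OTU present in a table but absent from
the tree is a hard error — silently dropping it would corrupt
between-run comparisons. The implementations are cross-checked against
scikit-bio's on random trees and count vectors.

## Concordance statistics

Two runs are compared on the samples surviving rarefaction to a common
depth (at least 3 required): Pearson *r* of per-sample observed OTUs and
Faith's PD; a one-tailed (greater) Mantel test on each UniFrac matrix
with add-one permutation p-values, `p = (1 + #{r_perm ≥ r_obs}) /
(1 + permutations)` (ties count against us; p is never 0); and Pearson
*r* of taxa profiles paired by (sample, taxon) over the union of taxa
with absent taxa as 0 — the only pairing that is well defined when
methods yield different taxa sets. Both tables are rarefied with the same
derived seed by default, so a run compared with itself reports exactly
r = 1; explicit `rarefaction_seeds` expose pure rarefaction noise.
A statistic whose input has zero variance is reported as undefined
(`None`) rather than propagating NaN. Taxonomic ranks are 1-indexed from
kingdom; lineages are semicolon-delimited with `k__`-style prefixes
tolerated but not required, and OTUs without a lineage (e.g., `New.*`
OTUs) pool into `Unassigned`.

## The synthetic benchmark

The generator emulates the three roles reads play in open-reference
picking on real surveys — reads matching the reference, reads from real
but unreferenced lineages, and non-marker contaminants — with planted
ground truth for every read.

* **Lineages.** Centroids evolve from a random ancestor along a random
  bifurcating topology under independent-site (Jukes–Cantor-like)
  substitution; terminal branches carry an expected substitution fraction
  of `divergence/2` (default divergence 0.20) and internal branches half
  that, so even sister lineages differ by about the planted divergence.
  All pairwise centroid identities are verified (and must fall below both
  `1 − divergence/2` and *s*); reads mutate from their centroid at 0.005
  per base (read-to-read divergence ≈ 1%, well inside the 3% threshold).
  The separation of scales — 20% between lineages, 1% within — is what
  makes the planted partition recoverable at *s* = 0.97.
* **Abundances.** 12 samples in 3 groups; each group draws a lognormal
  abundance profile (σ = 2.0 in log space) and each sample perturbs it
  (σ = 0.6). The group structure mimics the strong community gradients
  (soil pH, body sites) of the datasets such evaluations are run on and
  gives the benchmark real alpha- and beta-diversity signal; lognormal
  spreads of σ ≈ 1.5–2.5 are typical of microbial abundance
  distributions.
* **Contaminants.** 2% of each sample's reads (count exact) are exact
  copies of 40 fixed uniform-random source sequences, each verified below
  60% identity to every reference centroid. On the true tree they form a
  single basal clade: a long shared stem (0.5) with short terminal
  branches (0.1), as contamination from one foreign genome. (Hanging each
  source independently from the root on a long branch would let 2% of
  reads dominate presence/absence metrics and drown rarefaction
  comparisons in noise that no real survey exhibits.)
* **Tree coverage.** Diversity metrics need every table OTU as a tip, so
  newly minted centroids are grafted as siblings of their true lineage's
  tip with a small fixed branch (0.01): the tip becomes an unnamed
  internal node with the original lineage and the new OTUs as children,
  which keeps PD monotone under grafting.

What the generator does **not** emulate: indels and platform-specific
error profiles (substitution-only by design, keeping identity arithmetic
analytic), PCR chimeras, length variation, paired-end artefacts, and
taxonomic assignment of novel OTUs. Passing tests therefore demonstrate
the correctness and internal consistency of the workflows and statistics
under controlled conditions, not robustness to every artefact of real
sequencing data.

## Problem sizes and determinism

The standard benchmark is 24,000 reads of length 150 against 60 reference
centroids — small enough that even the exhaustive-settings
limit-equivalence run (subsample fraction 1.0 vs classic) completes in
about a minute on one CPU, while still exercising every stage with
realistic multiplicity. The Mantel null calibration uses 1,000 trials of
n = 10 samples at 200 permutations. All randomness flows from explicit
seeds (`SimConfig.seed`, `WorkflowParams.seed`, per-call seeds for
rarefaction and permutation tests); fixed seeds give byte-identical
benchmark files and OTU results, independent of the worker count.

## Known limitations

* Greedy clustering is order-dependent; with read error near the
  threshold an unlucky founder read can split a lineage into several
  OTUs. This is inherent to the algorithm family (it is why the
  concordance harness exists) and is visible in the clean-up tier counts.
* No reverse-complement matching (amplicons are assumed same-strand) and
  no chimera detection (expected to happen after OTU picking).
* The prefix-based sample inference assumes QIIME-style
  `<sample>_<serial>` read ids; an explicit mapping overrides it.
* OTU tables are dense in memory; the package targets desk-scale
  evaluations, not billion-read surveys.
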