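# Methods

This note documents the models, conventions and numerical choices behind
`haplopars`, and what the synthetic study conditions do and do not show
about real barcode datasets.

## Sequence curation

Records are trimmed to an analysis window delimited by exact 5'/3' anchor
motifs located on a reference sequence (both motifs included; 1-based
inclusive coordinates in logs).  Records whose length matches the reference
are treated as pre-aligned and sliced at the reference coordinates; other
records are anchored by exact motif search on their own sequence.  No fuzzy
motif matching and no multiple-sequence alignment is performed — inputs are
expected to be pre-aligned, and the anchor search is a convenience fallback.
A record covering only part of the window is padded with `N`: the missing
flank then counts against the minimum-length filter (default 610 unambiguous
bases) rather than being mistaken for an alignment gap.

Quality filters remove, in order of precedence, records with (a) any gap
character in-window, (b) an in-frame stop codon, (c) fewer than the minimum
number of unambiguous bases.  Translation uses the invertebrate
mitochondrial code (NCBI table 5) by default.  The window's first base is
generally *not* the first codon position — the default `frame=auto` picks
the reading frame with zero stops on the reference and errors if none
qualifies (if several qualify, the smallest is used with a warning).  The
screen applies one fixed frame to all records rather than a per-record best
frame; a per-record frame would mask genuine frameshifts.  Ambiguity codes
(N, R, Y, …) pass QC — only gaps, stops and length are removal criteria —
and are handled at distance time.

Identical sequences collapse into unique haplotypes carrying a record
count, a country multiset and the lexicographically smallest accession as
representative.  Output order (descending count, then code) and code
assignment are deterministic, so repeated runs are byte-identical.

## Distances

Step counts and K2P distances exclude ambiguous sites pairwise: a site
contributes only when both sequences carry A/C/G/T there, and
`sites_compared` shrinks accordingly.  This matches the common
pairwise-deletion default of distance software and keeps step counts and
K2P consistent with each other.  The K2P closed form
`d = -½ ln[(1−2P−Q)√(1−2Q)]` is evaluated per pair; a domain violation
(saturation) raises an error naming the pair — distances are never silently
truncated, and negative or infinite values are never emitted.  Distances are
stored as proportions and rendered as percentages only in reports.
Within-network summaries are reported as absent for singleton networks.

## Probability of parsimony and the connection limit

Statistical parsimony connects haplotypes only while the probability that
their observed differences contain no homoplasy (no superimposed, parallel
or back substitutions) is at least the confidence level (default 0.95).
The probability model, derived from the method's classical assumptions
(independent sites, equal rates, no recombination, at most two mutational
events per site between two closely related haplotypes):

* per site, the number of events on the path between the two haplotypes is
  0, 1 or 2 with probabilities `(1−q)²`, `2q(1−q)`, `q²`;
* with four nucleotide states a single event is always visible, while a
  second event at the same site restores the original base with probability
  1/3 (hidden homoplasy) and yields a visible but two-step difference with
  probability 2/3;
* the connection of a pair differing at `j` of `L` sites is parsimonious
  exactly when every differing site carried one event and every identical
  site none;
* the nuisance rate `q` is integrated out under a uniform prior, giving the
  posterior probability of parsimony as a ratio of two integrals that
  reduce to finite Beta-function sums.

The implementation evaluates those sums exactly in log space (`betaln` +
`logsumexp`); the test suite re-derives the same quantity by adaptive
quadrature of the defining integrals — an independent numerical route — and
pins P(11, 657) = 0.9476758048 as a regression fixture.  P(0) = 1 by
convention.  The resulting limits behave as required: P is non-increasing
in `j`; `j_max` is non-decreasing in `L` and non-increasing in the
confidence; at 657 bp, `j_max` is 10 at 95% and 12 at 93%, so pairs around
13 steps apart disconnect at 95% and (to within a step) join when the
criterion is relaxed — the qualitative behaviour reported for divergent
haplotypes in this data regime.  Because the historical implementations of
this criterion never published their exact arithmetic, small (±1 step)
differences from other software's limits are possible; network building
therefore also accepts a user-fixed `--max-steps`, which decouples the
graph construction from the probability model entirely.

## Network construction

Haplotype pairs are processed in increasing step distance up to `j_max`.
The component structure is exactly single-linkage clustering at threshold
`j_max` on the step-distance matrix (verified against a brute-force oracle
on hundreds of random instances).  Within a level of equal distance,
component membership is snapshotted at the level start: the first join
between two components is an `observed-step` connection, every further
equal-length join between the same two components is kept and flagged
`ambiguous-loop` rather than pruned — the analysis presents the set of
plausible solutions and leaves tie-breaking to the reader.  Multi-step
joins are realized as chains of inferred intermediate nodes ("missing
intermediates"), one substitution per edge, applying the differing sites in
ascending position order.  That ordering is an arbitrary deterministic
convention; component structure and path lengths are invariant to it.
Inferred sequences are shared within a component, so two chains passing
through the same intermediate sequence reuse one node, and every inferred
node has degree ≥ 2.  Gap characters cannot reach this stage (QC removes
them), so no gap-as-fifth-state handling exists.  Networks are numbered by
descending observed size with ties broken by smallest member code — a
deterministic replacement for figure-driven numbering; the node table
provides the mapping.

The hub of a network is the observed haplotype of maximum degree (ties by
record count, then code).  Hub statistics count observed haplotypes at
unit-graph distances 1 and 2.

## Species delimitation and congruence

Haplotypes are assigned to the reference consensus of minimum K2P
divergence when that minimum is at or below the threshold (default 0.035,
the divergence break used for this complex), else flagged `NEW_SPECIES`.
The threshold metric is K2P, not raw p-distance, for consistency with how
the break was derived.  Ties go to the alphabetically first species with a
logged warning.  Reference consensuses are an input file; when none are
supplied, a reference-free fallback delimits by single-linkage clustering
at the same K2P threshold and reports are labeled accordingly.  The
congruence report classifies each species from how its haplotypes spread
over networks: `single_network`; `network_plus_singletons` (at most one
multi-haplotype network, the rest unconnected singletons); `split` (two or
more multi-haplotype networks).

## AMOVA and ΦST

Two-level AMOVA follows the standard variance-component scheme from squared
pairwise distances (sums of squares within/among groups, expected mean
squares with the unequal-sample-size coefficient n₀).  The distance
entering the sums of squares is the pairwise number of differing sites by
default — the common default of the population-genetics software this
replaces — with K2P available by flag.  Duplicate records are expanded as
individuals via the haplotype counts (`records` mode), because ΦST and
AMOVA are frequency-sensitive; a `unique` mode (one copy per haplotype) is
exposed for comparison since either convention is defensible for database
data.  A negative among-group component is clamped to zero with a warning,
with the raw value retained.  Significance: random reallocation of
individuals among groups, p = (hits + 1)/(permutations + 1), seeded and
bit-reproducible (the per-pair generators derive from the seed and the pair
indices).  For small two-group problems an exact mode enumerates every
assignment and reports the exact tail fraction; the test suite checks it
against independent enumeration.  Default 1000 permutations; the seed is
mandatory in pipeline configs and recorded in every output.

## Synthetic study conditions

The generator emulates the structure of a real invasive species-complex
barcode dataset: `n_species` clusters whose hub sequences lie at least
`between_min_steps` apart (default 40 steps ≈ 6% — beyond both the 95%
connection limit of 10 steps and the 3.5% threshold); within-cluster
radiation in star, chain or mixed topology with pairwise distances capped
by `within_max_steps` (default 8); record counts skewed so the hub carries
`count_skew` (default 0.8) of its species' records — the regime where one
to three haplotypes carry >80% of database records; and country labels
drawn from species-specific home pools and a shared invaded pool with an
`invaded_fraction` (default 0.6) splitting hub records across both ranges,
producing home-only, invaded-only and shared haplotypes.  Defaults are
desk-scale (5 species × 8 haplotypes × 120 records) so the full pipeline
runs in seconds.  Every substitution consumes a globally unique site, so
planted step distances are exact by construction; substitutions respect a
2:1 transition:transversion ratio (so K2P exercises both P and Q terms) and
never introduce frame-1 stop codons; there are no indels and no
recombination, matching the parsimony model's assumptions and the post-QC
data regime.

What passing tests on this generator show: the pipeline's machinery —
collapsing, distances, connection limit, component structure, delimitation,
variance partitioning, range accounting — is correct under the model's own
assumptions.  What they do not show: behaviour under recombination,
indels/alignment error, rate heterogeneity across sites, base-composition
bias, or intermediate divergence levels near the connection limit where
real complexes are genuinely ambiguous.  The AMOVA among-network percentage
on the synthetic conditions (≈99.9%) exceeds values typical of real
complexes (~92%) because planted clusters have no internal deep structure;
it is reported as computed, not calibrated to any published value.

## Degenerate inputs and numerical conventions

Empty inputs error early; single-haplotype tables yield one singleton
network and skip distance matrices; identical haplotypes at the network
stage are a collapse-stage violation and raise; saturated K2P pairs raise
with the pair named; pairs of groups with no within-group degrees of
freedom are skipped in the ΦST matrix with a warning.  All orderings
(haplotype codes, network numbering, report rows) are deterministic, and
every stochastic step takes an explicit seed, so identical configurations
produce byte-identical outputs.

## Known limitations

* The parsimony-probability arithmetic is this package's own transcription
  of the classical model; other implementations may differ by about one
  step in `j_max` at a given length.  The fixed `--max-steps` override
  exists precisely so analyses can be pinned to an externally chosen limit.
* Reference-based delimitation requires externally supplied consensus
  sequences; the clustering fallback is self-contained but is not the
  published rule set.
* Only two-level AMOVA (among/within one grouping) is implemented; no
  hierarchical three-level designs, and no haplotype-frequency-only FST.
* The home/invaded split is configuration, not inference: the shipped
  country lists for the two global whitefly invaders are editable data, and
  unmatched countries are excluded from fractions with a logged warning.
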