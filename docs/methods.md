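# Methods

## The voting model

`helixvote` aligns a query protein family to template families one helix at
a time, treating the alignment of each helix as a discrete estimation
problem over integer offsets rather than as a continuous alignment problem.
The assumptions are:

- Each family is a set of homologous sequences ("profile") sharing a common
  helix architecture, given either internally aligned (gaps allowed,
  windows in alignment-column coordinates — the default) or as plain
  sequence sets with per-sequence window spans.
- A helix is a fixed-length, ungapped window. Insertions and deletions
  inside a helix are assumed negligible over the window length (globin
  helices are structurally conserved even when sequence identity is not),
  so the only free parameter per helix is an integer offset.
- Cross-family pairs are conditionally independent witnesses of the true
  offset. Individually they are unreliable in the twilight zone; voting
  aggregates them.

For a template family *T*, query family *Q* and helix *h* with windows of
common length *L*:

- **Score.** `score(a, b) = Σᵢ M[aᵢ, bᵢ]` over the *L* window positions,
  with `M` a standard substitution matrix (BLOSUM62 default, any Biopython
  matrix by name). A position read past either end of a sequence scores
  `out_of_range_score` (default: the matrix minimum, −4 for BLOSUM62) so
  that extreme shifts cannot win by sliding off the sequence; a gap
  character scores `gap_score` (default 0, i.e. uninformative); an
  out-of-range marker takes precedence over a gap.
- **Votes.** For each ordered pair, the query window is read at every shift
  *s* ∈ [−25, +25]; the argmax shift receives one vote, split 1/*k* over
  *k* exact ties (BLOSUM entries are integers, so ties are exact). The
  direction is then reversed (template windows slid, query fixed) and the
  resulting vector re-indexed by negation onto the same axis. Sign
  convention, used everywhere: **positive offset = the query helix sits
  that many residues to the right of the template's window register**.
- **Mean and scaling.** The per-offset mean of the two direction vectors is
  scaled to [0, 1] by its maximum (an all-zero vector stays zero). Vote
  means are *displayed* rounded half-down to integers; full precision is
  kept internally.
- **Consensus.** Across templates, the scaled profiles are multiplied
  entrywise. The winner is the argmax, ties broken toward smaller |offset|
  and then the negative offset (biased to the null of "no shift").
  Templates whose profile is all-zero (degenerate windows) are dropped from
  the product with a warning rather than annihilating it. The
  `dominance_ratio` (winner product / runner-up product, ∞ when the
  runner-up is 0) quantifies how decisive the consensus is.

Helices C and D are short and variable and are excluded from voting; the
renderer requires explicit manual offsets for them.

## Direction asymmetry

Sliding the query against a fixed template window and sliding the template
against a fixed query window evaluate the same relative alignment over
stretches of sequence that differ by |offset| boundary columns, in addition
to differing in which sequence's ends get truncated. The two direction
vectors therefore agree exactly only when every pair's best offset is
unambiguous (margin larger than the worst-case boundary perturbation); in
the twilight zone they differ slightly, which is precisely why both
directions are computed and averaged. The test suite pins the symmetric
regime (padded windows, closely related families) where the two vectors
coincide exactly, and treats the twilight-zone asymmetry as expected
behaviour.

## Cross-family contracts

Voting requires the two families' windows for a helix to have equal length;
a mismatch raises a configuration error rather than being silently
truncated. Offsets outside the configured range are errors at planting
time but not at extraction time (out-of-range is a value, not an error, so
every offset compares windows of identical length).

## Synthetic families

The generator emulates the statistical regime of remote homology, not its
evolutionary mechanism:

- Every record is an independently substituted copy of one ancestral seed
  sequence. Substitutions are per-position Bernoulli draws, replacing the
  residue uniformly among the other 19.
- `target_identity` is the desired **mean pairwise identity among
  records** — the quantity the twilight zone is defined by. The
  substitution rate *m* is calibrated by solving
  `(1−m)² + m²/19 = target`, so a target of 0.25 yields families whose
  all-vs-all identity is ~25% (the naive choice *m* = 1 − target would
  yield ~9%). The minimum reachable pairwise identity under this model is
  5% (*m* = 0.95); lower targets clamp there.
- Offsets are planted by physically moving helix-window content inside each
  record (vacated positions refilled uniformly at random; records padded at
  the right when needed), so the planted shift is ground truth for the vote
  argmax under the sign convention above. Multiple helices are planted
  simultaneously; overlapping shifted windows are rejected.
- Column plants set exact (column, residue) counts: one random permutation
  per column assigns disjoint record sets to each planted residue, and the
  remaining records are resampled away from all planted residues, so a
  50-sequence family planted with 41 Tyr reports a Tyr fraction of exactly
  0.82.
- One integer seed drives everything; per-record substreams are keyed by
  record index, so output is byte-identical across runs and independent of
  evaluation order.

What the generator does **not** model: phylogenetic correlation between
records (a star tree is assumed), indels, compositional bias, and
helix-specific conservation patterns. Passing tests on these families shows
the estimator recovers planted registers under controlled identity and
independence; it does not show robustness to correlated sampling or to
length variation inside helices, which real families have.

## Study-condition defaults

The default synthetic study uses an ancestral chain of 140 residues
carrying six voted helices of 12–15 residues (A 8–20, B 26–40, E 48–61,
F 67–79, G 85–99, H 105–116) — window lengths matching typical globin
helix annotations (the query helix A span used for the real protein is 13
residues) — with 20 sequences per family at 25% pairwise identity, planted
shifts in −6..+6, and the full −25..+25 vote range. Recovery experiments
use 50–100 seeded replicates; at these sizes a full six-helix, five-template
study runs in seconds on one core because scoring is vectorized over
(pair × offset × position) with an integer-coded lookup table.

## Numerical choices

- Vote fractions are IEEE doubles; conservation (each direction sums to the
  pair count) holds to ~1e−9 after 1/3-type tie splits. The brute-force
  test oracle uses exact rationals.
- Tie-breaking is fully deterministic everywhere (fractional splitting in
  voting; smallest |offset| then negative in consensus), and no stage of
  voting or rendering uses randomness, so identical inputs give
  byte-identical outputs.
- Percent identity counts out-of-range and gap positions as mismatches and
  divides by the full window length, keeping values comparable across
  offsets.
- Degenerate inputs: all-zero vote vectors normalize to zero; an all-gap
  column reports an empty residue map with gap fraction 1; empty families,
  duplicate ids, non-residue characters and sub-length-4 windows are
  rejected at construction with named-field errors.

## Limitations

- Ungapped window scoring cannot represent insertions within a helix; a
  register that drifts mid-helix will blur the vote peak rather than split
  it cleanly.
- The consensus product assumes templates err independently; templates that
  share a bias (e.g. close paralogues) multiply their bias rather than
  cancelling it.
- Window spans are user input (taken from structures by inspection); the
  package does not detect helices.
- No significance model is attached to vote counts or dominance ratios;
  they are descriptive statistics, not p-values.
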