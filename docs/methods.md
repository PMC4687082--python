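# Methods

This note documents the models, conventions and numerical choices behind
`hgtclust`, and what the synthetic-data experiments do and do not show.

## Gain/loss parsimony and candidate calling

Each gene family's phyletic pattern (0/1 over the tips of a rooted tree) is
explained by ancestral presence states minimizing total event cost: a
0→1 transition on a branch (gain) costs `P_g`, 1→0 (loss) costs `P_l`,
no change costs 0.  The minimum is computed by the standard two-state
Sankoff dynamic programme (post-order cost tables, linear in tree size);
multifurcations are handled naturally because the child terms just sum.

Conventions where the method leaves freedom:

* **Root states are free.**  Neither presence nor absence at the root is
  charged, so an anciently present family costs nothing.  This reflects the
  ancestral-genome framing: the analysis asks about events *within* the
  observed clade.
* **DELTRAN resolution.**  Among equally parsimonious reconstructions, state
  changes are delayed toward the tips.  Operationally: a pre-order pass
  assigns each node the state minimizing its own table cost plus the
  transition from its already-fixed parent, breaking ties in favour of the
  parent's state; at the root, ties between the two states resolve to
  *absent*, so presence is explained by tipward gains.  On a four-tip tree
  with one present tip and `P_g/P_l = 2`, the gain-on-tip scenario ties a
  root-presence-plus-two-losses scenario; these conventions select the
  terminal gain.  Other DELTRAN implementations may break such ties
  differently — the choice is convention-dependent and only affects exact
  ties.
* **Unrooted trees are rejected** rather than auto-rooted: with asymmetric
  penalties the root position changes the inferred events.

A gene is an HGT candidate if its family's reconstruction places a gain on
the terminal branch of that genome.  Families flagged as singletons (no
ortholog anywhere in the dataset — likely annotation artifacts) are never
candidates; singleton status is an explicit flag, not inferred from the
pattern, because a family present in a single genome of the matrix can
still have orthology support.  Genes on plasmid replicons, and genes marked
unexamined in the gene orders, are likewise excluded.  Raising `P_g/P_l`
from 1 to 2 re-explains marginal gains as loss series, so the candidate set
shrinks monotonically in practice (tested on simulations).

## Spatial statistic

`Count_G` counts genes that are candidates and have at least one further
candidate among their next `w` right-hand neighbours along the replicon
(`w = 3` by default: at most two intervening genes, within the length of
most *E. coli* operons).  The window is one-sided by construction; counting
is reversal-invariant because every right-window pair is a left-window pair
of the reversed sequence.

The null expectation for `c` of `n` positions occupied uniformly without
replacement is derived by conditioning on the distance `d` to the nearest
right-hand candidate:

    E = sum_{d=1..w} (n-d) * (c/n) * prod_{j=1..d-1} (n-c-j+1)/(n-j) * (c-1)/(n-d)

For `w = 3` this expands to the familiar three-term expression in
`(n-1)...(n-3)`.  Degenerate inputs: the sum truncates at `d = n-1` when
`n <= w`; `c <= 1` returns 0; the product is cut at zero when no
non-candidate remains to intervene.  The formula is exact — the test suite
checks it against exhaustive placement enumeration for every `n <= 12`,
`c <= n`, `w in {1,2,3}` at 1e-12 relative tolerance.

**Topology.**  The default is linear, matching the position counts `(n-d)`
of the expectation; a circular mode (window wraps, position count `n`) is
available since bacterial chromosomes are circular.  The difference is
O(w/n) and negligible at genome scale.

**Gap conventions.**  Singletons and other unexamined genes cannot be
candidates but occupy positions, creating gaps between examined genes.
`gap_mode="conservative"` (default) computes expectation and permutation
null as if the examined genes were contiguous — gaps depress the observed
count but not the expectation, so CC and p are biased against finding
clustering.  `gap_mode="exact"` scatters permuted candidates over the true
examined positions and uses the simulation mean of the null counts as the
expectation; it is the statistically faithful variant.  With no unexamined
genes the two coincide.

**Aggregation and permutation.**  Observed and expected counts are summed
over the genomes in the candidate set's universe (each genome contributes
its own `n_g`, `c_g`); permutations redistribute exactly `c_g` candidates
within each genome, and p = (r+1)/(R+1) with `r` the number of permutation
totals at least the observed total (one-sided enrichment; no
multiple-testing correction across candidate sets).  Per-genome RNG
substreams are derived from (seed, CRC32(genome id)), so results are
invariant to genome ordering.  If the expectation is 0 with a positive
observation, CC is reported as +inf with a warning; 0/0 is NaN.

## Metabolic statistic

The coupling network is an undirected simple graph over a node universe of
`n` genes with `L1` fully coupled pairs, consumed as input with topology
fixed.  Expected coupled pairs among `n2` uniformly chosen candidates is
`p1 * n2(n2-1)/2` with `p1 = L1/(n(n-1)/2)` — exact, not approximate
(verified by rational-arithmetic enumeration over all candidate subsets of
small networks).  Candidates outside the universe are dropped from `n2`
(logged), since the null only redistributes HGT status within the network.
Permutations redraw `n2` nodes uniformly from the universe.

## Synthetic data

Three generators provide ground truth; defaults mirror the empirical regime
the statistics were designed for (~21 tips, ~2,000 genes per genome with
~5% recent transfers and ~15% singletons, ~2,977 root-born families, a
4,242-gene network with 701 coupled pairs).  All randomness flows from one
seed through named substreams.

* `simulate_genome_blocks`: plants exactly `c` candidate genes in
  non-overlapping blocks (lengths from a user distribution; rejection
  sampling with a fit check, final block clipped to conserve `c`) on a
  linear gene order, and marks a fraction of non-candidates unexamined.
* `simulate_family_evolution`: families born at the root are lost per
  branch with probability `loss_rate`; each terminal branch gains
  `terminal_gain_count` new families (internal-branch gains optional, to
  exercise the terminal-only filter); gained families are laid out
  contiguously in blocks in the recipient's gene order.  The event log is
  complete: replaying it along root-to-tip paths reproduces the matrix
  exactly (tested).
* `simulate_coupling_network`: `L1` distinct random pairs; for enriched
  candidate sets, whole coupled cliques are placed inside the candidate
  set.  The network can be grafted onto existing gene identifiers to mimic
  a network tied to one reference strain.

What the generator does **not** emulate: real gene-order conservation decay
with phylogenetic distance, insertion hotspots, compositional (sequence)
signals of transfer, gene rearrangements after transfer, and loss of
previously gained families.  Passing tests therefore demonstrate
correctness of the statistics and the inference machinery under the stated
null and block-transfer mechanisms, not robustness to every feature of real
genomes.

## Calibration and power experiments (`hgtclust.validation`)

* **Spatial null calibration** lays out the study regime — 10 genomes of
  2,000 genes with 96 uniformly placed candidates each — and checks that
  the mean CC is 1 and that p-values are honest.  The multi-genome layout
  matters: the permutation p-value of a *discrete* count is conservative
  through ties, and with a single small genome (expected count ~10) the
  p <= 0.05 rate drops visibly below the nominal level.  Summing over ten
  genomes puts the expected count near 130, where tie mass is negligible
  and the test is nearly exact — which is also the regime the statistic is
  actually used in.
* **Metabolic null calibration** draws uniform candidate sets in networks
  sized so the expected pair count exceeds 1 (n=300, L1=600, n2=40), where
  the ratio CC is informative.
* **Power**: candidates planted in blocks of 3-4 at ~5% of the genome
  across 10 genomes of 2,000 genes are detected (p <= 0.01 and CC > 1.5)
  in essentially every run; permutation depth R=199 suffices since the
  observed counts sit far outside the null.
* **Recovery**: with `loss_rate <= 0.05` and terminal-only gains on a
  10-tip tree, the ratio-1 caller recovers all planted gains — a single-tip
  presence pattern has a unique minimum-cost explanation on trees with
  three or more tips.

Problem sizes (replicate counts, permutation depths) are chosen so the full
battery runs in a few minutes on one CPU; they are stated in each function
signature and reported alongside every number the acceptance script writes.

## Known limitations

* The spatial expectation assumes exchangeable candidate positions; it does
  not model length, orientation or strand structure of operons.
* DELTRAN tie-breaking is convention-dependent (see above); reconstructions
  are unique only up to those ties, though the minimum cost itself is not.
* The benchmark mode compares false-discovery tendencies via clustering
  strength; it is silent about sensitivity, which is why candidate-set
  sizes are always reported next to the scores.
* The one-sided permutation p-value cannot fall below 1/(R+1); very small
  p-values require correspondingly deep permutation runs.
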