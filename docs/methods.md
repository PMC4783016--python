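# Methods

## Model and procedure

`otunet` clusters 16S rRNA amplicon reads into OTUs by a two-pass
seed-based network procedure over dereplicated sequences.

**Dereplication.** Reads are collapsed by exact full-length string identity
(no prefix matching). Each representative carries its abundance and member
read ids; duplicates rejoin their representative's OTU at the end, so the
partition is always over the original reads. Abundance is not discarded in
between: a representative with abundance *a* behaves as if it had *a* − 1
implicit distance-zero neighbors when seeds are chosen.

**k-mer coding and distance.** Unambiguous k-mers are mapped to integer
codes in first-encounter order (a dynamically grown dictionary), and each
sequence becomes a sorted code/count vector. The distance is

    d_kmer(x, y) = 1 − Σ_w min(c_x(w), c_y(w)) / (min(|x|, |y|) − k + 1)

clamped to [0, 1]. Words containing non-ACGT characters are skipped on both
the code and count side; the denominator is unaffected, which makes
ambiguity codes strictly distance-increasing. The coding is a pure change
of representation: a string-path implementation of the same formula is kept
in the package and the two are held to exact agreement in tests. `k = 6` by
default — the usual word size for 16S prefilters, short enough that
sub-percent divergence leaves most words shared, long enough to be
discriminative — and configurable, as is the distance function itself
(isolated in one place so an alternative normalization can be swapped in).

**Alignment.** Needleman–Wunsch with linear gap costs (match +1, mismatch
−1, gap −2 per base) and free terminal gaps: amplicon reads differ in
length, and end-gap-free semantics is what makes "3% dissimilarity" behave
sensibly for partially overlapping reads. Dissimilarity is
1 − identical/counted over the optimal alignment, where terminal-gap
columns are excluded (configurable), interior gap columns count as
differences, and a column is identical only if both characters are equal
and unambiguous — N against anything, including N–N, is a difference.
Traceback ties break diagonal > up > left and equally scoring end cells
resolve toward the matrix corner, so aligned strings are deterministic.
Because distinct optimal alignments can have different counted-column
totals, the *distance* convenience wrapper orders its two arguments
canonically before aligning; this is what makes d(x, y) = d(y, x) exact.
Note the dissimilarity is not a metric (no triangle inequality is claimed),
and for essentially unrelated sequences the end-gap-free optimum can be a
short overlap, giving small distances over few counted columns — see
"Limitations".

**Calibration.** Users specify an NW threshold *t*; the prefilter needs a
k-mer threshold. A seeded random sample (default 1000) of unique sequences
is scored with both distances over all its pairs, and the k-mer threshold
is the 0.99 quantile (default) of k-mer distances among pairs with NW ≤ *t*.
Quantile 1.0 guarantees no false prefilter rejection on the sampled set;
0.99 trims outliers at the cost of a small miss risk, repaired downstream
by refinement (a strain split across initial clusters re-merges when its
seeds align within *t*). If fewer than 50 pairs qualify, a least-squares
line of k-mer on NW distance over all sampled pairs is evaluated at *t*;
if that is degenerate (zero NW spread or a non-positive prediction) the
run stops and asks for an explicit threshold rather than mis-calibrating.

**Scheduling.** The n(n−1)/2 pair space is linearized column by column
(index(i,j) = j(j−1)/2 + i), cut into fixed chunks of 2000 pairs (the
default granularity, configurable), and executed on a local thread pool.
Per-task results merge into the global edge store as each task completes,
and only pairs at or below threshold are kept (sparse edges, never a dense
matrix). The guaranteed contract — enforced by tests — is that the sorted
edge set, and hence everything downstream, is identical for every worker
count and granularity. Multi-host distribution, backup partitions, and
task failover are out of scope; the deterministic-merge contract is what a
distributed backend would have to preserve.

**Peeling and refinement.** The seed is the active node maximizing
abundance-weighted degree (active-neighbor abundance plus own abundance
minus one; ties to the smallest index); its cluster is itself plus its
active neighbors, all removed from the network; repeat until only isolated
nodes remain (singletons, kept as size-1 clusters). Refinement computes NW
distances among all seeds and singletons through the same scheduler,
builds the refined network at threshold *t*, and peels it with degrees
recomputed after every removal. A final cluster is the refined seed, its
active refined neighbors, and every not-yet-assigned initial-network
neighbor of any of those; assignment is greedy and exclusive, so
earlier-formed clusters win contested nodes and the result is a partition.
Every member of a final OTU is therefore the seed, within *t* of the seed,
or one initial-network edge away from such a node — a property checked
post hoc by `verify_membership_structure`. Weighted degree in refinement
uses candidate abundances only, not initial-cluster sizes; the switch
point is `refine()` if a size-weighted variant is ever wanted.

## Evaluation

Accuracy against strain labels is pair-counting: TP/FP/TN/FN as defined
above, computed from a per-(OTU, strain) contingency table with
C(n, 2) binomials — algebraically identical to enumerating all pairs, and
tested against an O(m²) enumeration oracle. The combined score is F_β with
β = 2 by default (recall-weighted); β is exposed, and β = 1 gives the
plain harmonic mean. Note that merging OTUs can only raise recall and
splitting can only lower it, but pair-counting *precision is not monotone
under arbitrary splits* (splitting {a₁, a₂, b} into {a₁, b} + {a₂} drops
precision from 1/3 to 0), so only the true monotonicities are asserted.

## Synthetic communities

The generator emulates an even-concentration mock community: `n_strains`
center sequences, `reads_per_strain` reads each, every read labeled.
Centers are homologous variants of one random ancestral template, each
substituted at the divergence-floor rate (default 0.10), so center pairs
sit near twice the floor (~15–20% dissimilarity) — comfortably apart at a
3% threshold yet alignable end to end, as real 16S amplicons from
different taxa are. Fully independent random centers would *not* emulate
this: under end-gap-free alignment two unrelated strings often admit a
short spurious high-identity overlap, which contaminates calibration with
artificial "close" pairs; homology is the realistic and the correct
regime. A repair loop re-derives the closest pair's closer member until
all pairwise NW dissimilarities clear the floor (bounded retries, then an
error suggesting longer centers or fewer strains).

Reads are centers plus i.i.d. substitutions (default 0.005 per base,
uniform over the three alternatives) and single-base indels (default
0.0005 per base, insertion or deletion equally likely). Expected
read-to-center dissimilarity is, to first order, the sum of the two rates
(0.0055 by default; each substitution is one mismatching column, each
indel one gap column), and the generator is tested to land within three
standard errors of it. A duplicate quota of round(fraction × total reads)
(default 25%, matching the ~20–37% duplicate content typical of real
pyrosequencing datasets) is spread evenly across strains; each duplicated
slot is a byte-identical copy of a randomly chosen earlier read of the
same strain. Everything derives from one seeded generator, so a spec plus
seed identifies the community exactly.

What passing tests on these communities shows — and does not. The
generator produces well-separated, even, fully homologous strains with
ideal labels. Perfect precision/recall on it demonstrates the machinery
(calibration, prefilter, peeling, refinement, rehydration) is correct and
self-consistent; it does not certify accuracy on real communities, where
strain divergences straddle the threshold, abundances are skewed,
chimeras and platform-specific errors (e.g., 454 homopolymer noise) exist,
and "truth" is itself inferred. Those effects are deliberately out of
scope of the generator.

## Numerical choices and degenerate inputs

- DP scores are float64; traceback and end-cell selection compare with a
  1e-9 tolerance. With the default integer-valued scores, arithmetic is
  exact and the tolerance is never load-bearing.
- If an alignment has zero counted columns (possible only for unrelated
  sequences under free ends, e.g. homopolymers of different bases), its
  distance is defined as 1.
- Quantiles use numpy's default linear interpolation; quantile 1.0 is the
  maximum. A calibrated threshold is capped at 1.0.
- A dataset with a single unique sequence skips calibration (threshold 0;
  there are no pairs) and yields one OTU.
- Sampling for calibration is `default_rng(seed)` without replacement,
  with sampled indices sorted so the pair table order is canonical.
- OTU naming is `OTU_0001`… by decreasing size, ties by seed read id;
  all outputs are UTF-8 with LF endings.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run communities of roughly
60–500 reads with 250–450 bp centers and calibration samples of 30–80
sequences. These sizes were chosen so the full battery exercises every
code path (including multi-worker and multi-granularity runs) in a few
minutes on one core; the algorithms themselves carry no size assumptions
beyond the O(n²) pair space.

## Known limitations

- The end-gap-free dissimilarity is anti-conservative for unrelated
  sequence pairs (short-overlap artifact above). In its intended domain —
  reads from one amplified region — pairs are homologous and the issue
  does not arise, but feeding the clusterer a mixture of unrelated loci
  can produce spuriously low distances. `count_terminal_gaps_in_distance`
  and `terminal_gaps_free` are exposed for stricter policies.
- Gap costs are linear only; no affine gaps, banding, or SIMD. Alignment
  cost is O(|x||y|) per pair, so refinement assumes the candidate set
  (seeds + singletons) is much smaller than the read count.
- The parallel backend is a single-host thread pool. CPU-bound speedup is
  limited by the interpreter; the pool exists to honor and continuously
  test the worker/granularity-invariance contract that any heavier
  backend must keep.
- Calibration assumes the sampled pairs are representative; heavily
  length-stratified inputs may want a manual `--kmer-threshold`.
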