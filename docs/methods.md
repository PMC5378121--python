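# Methods

This note records the models, conventions, numerical choices and known
limitations behind `synterate`, in the order the pipeline uses them.

## Orthologs and signed permutations

Orthologs between two genomes are reciprocal best hits from 12-column
tabular hit files. "Best" is the highest bitscore, with ties broken by
higher percent identity and then by lexicographically smaller partner
id, so the pairing is deterministic. Hits are first filtered to
percent identity ≥ 40 (inclusive) and protein length difference
`|l_q − l_s| / max(l_q, l_s)` ≤ 0.2 (inclusive); the max-normalized
denominator is our choice, as is reading the identity rule as a
threshold on alignment identity. Because our hit-table writer emits
full-length alignment coordinates, the reader recovers protein lengths
from the `qend`/`send` columns.

An ortholog map plus the two genomes' gene ranks and strands induces a
signed permutation: genes numbered 1..n along genome A (A's strand
taken as +), listed in genome B's order, negated on strand
disagreement. Multi-replicon genomes should be reduced to their
largest replicon before mapping; the pipeline treats every replicon it
is given as a single circular (by default) element.

## Gene order conservation

GOC counts label pairs (i, i+1) — plus the wrap-around pair for
circular replicons — that are adjacent in the permutation in either
order and either orientation, divided by n (the shared-ortholog
count, for linear replicons too, so a linear identity scores
(n−1)/n). Orientation-insensitivity matches the "contiguous in both
genomes" reading; a strand-sensitive variant sits behind
`strand_sensitive=True`. Whether the chromosome is treated as circular
is exposed per map; circular is the default, since bacterial
chromosomes are circular and the wrap adjacency is real.

Subsampled GOC uses the *induced* order of the subsample (ranks
relabelled 0..m−1 preserving relative order) — the only reading under
which GOC depends on subsample size, which is precisely the effect the
fixed-size estimators neutralize. Note a structural consequence used
by the tests: for a permutation consisting of a few long conserved
blocks, the number of broken adjacencies in any subsample equals the
number of block boundaries, so subsample GOC is deterministic; only
heavily rearranged pairs show resampling spread.

## Inversion distance

Exact reversal distance follows breakpoint-graph theory: frame the
permutation with 0 and n+1, double each element, count alternating
cycles `c`, find connected components of the gray-edge interleaving
graph, classify components whose cycles contain no oriented gray edge
(endpoint positions of equal parity) as unoriented, count hurdles `h`
(unoriented components that are minimal under span containment, or
that contain all other unoriented components) and set the fortress
flag `f` when every hurdle of an odd count is a super-hurdle. Then
`d = (n+1) − c + h + f`. Circular permutations are canonicalized by
flipping (if needed) and rotating so gene 1 leads with positive sign,
then dropping it — reversal distance on a circle of n genes equals the
linear distance of the remaining n−1.

Correctness is enforced by two independent searches in the test suite:
plain breadth-first search (exhaustive over all signed permutations to
n = 5, every hurdle case included) and an optimal A* search over
reversal moves using only the cycle lower bound (500 random n = 8
instances). Component analysis is vectorized (crossing matrix +
sparse connected components); the common no-unoriented-cycle case
short-circuits, so a 250-element distance costs well under a
millisecond.

## Resampled estimators

`resampled_estimate` draws `n_resamples` (default 100) uniform
subsamples of `min(subsample_size, n)` pairs without replacement and
computes GOC and the reversal distance *on the same subsample*,
reporting means and SDs, plus the distance normalized by the effective
subsample size. When the map is smaller than the subsample size every
resample is the full map and the SDs collapse to zero.

## 16S divergence

Pairwise distances maximize the two-sequence likelihood under HKY85
with empirical base frequencies and jointly estimated κ by default
(fixed values accepted). Transition matrices come from the
matrix exponential of the rate matrix normalized to one expected
substitution per site; branch length is optimized on a log scale
(bounded Brent for fixed κ, Nelder–Mead jointly). With κ = 1 and
equal frequencies the estimate reduces to the Jukes–Cantor closed form
−(3/4)·ln(1 − 4p̂/3), which the tests check to 1e−6. Saturated pairs
are capped at 5 substitutions/site with a warning. Alignment columns
with more than 50% gaps are dropped first — a deliberate one-parameter
surrogate for block-based trimming, since dataset assembly is out of
scope. Gamma rate heterogeneity is omitted. Square PHYLIP distance
matrices are read and written for interoperability.

## The decay model

`GOC(x) = f_i + (1 − f_i)·pˣ` with `f_i ∈ [0, 1)` (saturation floor)
and `p ∈ (0, 1]` (per-unit-divergence retention). The headline fit
minimizes the sum of squared residuals by Nelder–Mead on
logit-transformed parameters, multi-started from the grid
`f_i₀ ∈ {≈0, min(goc)/2, min(goc)} × p₀ ∈ {1e−4, 1e−2}` (six starts);
a pure-boundary data set (all GOC = 1) drives `p` to the upper
boundary with zero SSE. Category fits come in two modes: independent
(six parameters) and fixed-`f_i` (the pooled fit's floor pinned, one
free `p` per category — the four-parameter scheme that makes category
rates directly comparable).

Bootstrap confidence intervals are bias-corrected and accelerated:
points (genome pairs — the objects being fit; resampling species is
the noted alternative) are resampled with replacement, the model refit
per resample, `z₀` taken from the fraction of bootstrap estimates
below the point estimate and the acceleration from jackknife skewness.
Refits exploit that the model is linear in `f_i` at fixed `p`: the
optimal floor has a closed form (clipped to [0, 1)), leaving a 1-D
search on log p done by golden section, vectorized across all
resamples at once. This is the same objective as the headline
optimizer (the tests verify agreement) and keeps the 10,000-resample
default cheap. Degenerate (zero-spread) bootstrap distributions
return the point interval.

Genome-stability indices are per-species means of observed − predicted
GOC over the species' pairs; against a data set's own fit they average
to ≈ 0 by construction for complete designs. Group inference uses the
two-sample Fisher–Pitman permutation test (statistic = group-A sum),
exact by full enumeration when `C(n, n_A)` ≤ 2×10⁶ and Monte Carlo
with 10⁵ draws (observed assignment included, so p ≥ 1/(B+1))
otherwise. The primary R-vs-N inference is on per-species stability
indices, which controls for the non-independence of pairwise points;
the point-level residual-category test (R-R + R-N vs N-N) is also
reported. Tukey–Kramer HSD (statsmodels' studentized-range
implementation, unequal group sizes supported) serves the multi-group
stability comparisons.

## Genomic indicators of selection

All five indicators resolve the replication geometry via oriC and the
antipodal terminus. Leading-strand fraction: within each replichore
the leading strand is the majority-gene strand (genes assigned by
midpoint; ties contribute half), so the statistic is ≥ 0.5 by
construction and is skipped (with the genome excluded) when oriC is
unknown. ΔGC skew splits the published strand into the two arcs,
computes (G−C)/(G+C) per arc, labels the G-richer arc leading, and
returns leading − lagging — sign-invariant to rotating the sequence
start; an alternative convention that reverse-complements the lagging
arc is behind a flag. rRNA–origin distance uses gene midpoints and
minimal circular arcs. A gene is "single" iff both circular
neighbours are on the opposite strand. Group contrasts are one-tailed
Welch t-tests in the direction of relaxed selection in the resistant
group (lower leading-strand fraction, fewer rRNA genes, larger
rRNA–origin distance, lower ΔGC skew, larger single-gene ratio), with
Bonferroni flags over the five indicators; constant-valued groups are
reported as p = 0.5 when equal rather than NaN.

## Repeats and MUMs

Maximal exact repeat pairs (direct and inverted) are found by seeding
on length-`min_length` k-mers and extending each seed pair to its
unique maximal pair (left/right extensions are independent, so greedy
order is immaterial); duplicates merge on the extended coordinates.
Direct pairs may self-overlap (tandems); inverted copies are kept
disjoint. The significance length used for the P-threshold mode is
the Karlin–Ost-style expected-count criterion over unordered position
pairs, E[count] = (1−E)/2·n²·E^l with E = 2(gc/2)² + 2((1−gc)/2)²,
crossed below the requested p. That constant was validated against
simulated random genomes (the longest-repeat 0.999 quantile at
n = 10⁵); at bacterial genome sizes and GC contents it lands at
26–28 bp, on the scale of the minimal efficient processing segment for
recombinational repair. Repeat genome coverage is the merged union of
both copies of every pair, as a percentage.

MUMs follow the classical `-mum` semantics: maximal matches of at
least `min_length` whose substring occurs exactly once in the forward
reference and exactly once in the query counting both strands jointly;
reverse-strand matches report query starts in forward coordinates.
Both scanners are verified against quadratic brute-force oracles.

## The simulator

`evolve_gene_orders` grows a clade on a star or ultrametric Yule tree
scaled to the requested root-to-tip depth (divergence units are
expected 16S substitutions per site, so a tip pair's divergence is its
path length). Along each branch, inversions arrive as
Poisson(rate × length) — the resistant-tip rate applies only on
terminal branches of R species, the simplest scheme producing the
R-R > R-N > N-N rate ordering — and each gene is lost independently
with probability 1 − exp(−loss_rate × length) (loss applied before the
branch's inversions; no gain or transfer). How rearrangement events
split between the two lineages of a pair is this branch-wise scheme —
a modelling choice, not an observed quantity. Inversion endpoints are
uniform over cuttable adjacencies; a configurable fraction of
ancestral adjacencies is protected (never cut), which produces the
saturation floor `f_i` downstream, and a configurable probability
makes an inversion origin-symmetric (endpoints mirrored about oriC to
the nearest allowed slot — gene orders are kept in origin frame, list
position 0 = oriC). True pairwise divergences are emitted directly so
gene-order analyses carry no 16S estimation error unless the 16S
simulator is explicitly used. Everything is deterministic under the
config seed.

Hit tables give every true ortholog reciprocal hits with identity
100·exp(−decay·x) plus Gaussian noise and hash-derived matched protein
lengths; spurious paralog hits (lower identity and score) are injected
at a configurable rate. Nucleotide genomes have position-dependent
G/C probabilities `gc/2·(1 ± skew_amp)` switching sign at oriC and its
antipode (so the recovered ΔGC skew is ≈ 2·skew_amp), exact planted
repeats placed without overlap, and rRNA annotations. 16S pairs are
one stationary draw evolved for time x under HKY (valid by
reversibility); no indels are simulated, so pairs are born aligned.

What the simulator does *not* emulate — operon structure, horizontal
transfer, replichore-biased gene orientation, realistic repeat
families, rate variation across the 16S molecule — bounds what passing
tests demonstrate: the pipeline's statistical machinery is calibrated
and its algorithms exact, but conclusions about real genomes still
depend on the biological adequacy of the decay model itself.

## Study scales used by the checks

The self-checks run at deliberately desk-sized conditions: the
concordance clade uses 12 species × 1000 genes at Yule depth 0.1 with
inversion rate 2200 per unit divergence (chosen analytically so
GOC₂₅₀ spans roughly 0.1–0.9 across pairs) and gene loss 0.3; the
power study uses 8 R + 12 N species × 300 genes with rate_R = 3·rate_N
over 100 replicates; bootstrap coverage uses 300 replicates of 105
points (a 15-species clade's pair count) with GOC noise σ = 0.03 and
B = 1000; repeat-significance calibration uses 100 random 100-kb
genomes. These sizes are the package's chosen reference conditions
for its own validation.

## Known limitations

- Only inversion distances are implemented; translocations and
  transpositions are out of scope (single-replicon analyses).
- The permutation test's exact mode is capped by enumeration size;
  beyond the cap the Monte Carlo p-value has resolution 1/(B+1).
- The repeat scanner's seed-and-extend is exact but quadratic in
  the copy number of a repeat family; genomes dominated by huge
  tandem arrays would be slow.
- `f_i` and `p` trade off near saturation: very fast clades push `p`
  to the boundary and inflate `f_i`; the fixed-`f_i` category mode
  exists precisely to keep category comparisons meaningful there.
- BCa intervals assume the resampled objects (pairs) are
  exchangeable; pair non-independence within a clade is only
  addressed at the test level (species-level permutation), not in the
  intervals.
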