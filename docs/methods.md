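# Methods

This note documents the models, conventions and numerical choices behind
`stemevol`, in the order the pipeline applies them, together with the design
decisions that were genuinely open and the limitations a user should know.

## Alphabet and alignment conventions

Rows are RNA over `{A,C,G,U}` plus two distinct non-base symbols: `-` (the
base is absent — evidence of absence) and `~` (the region was not sequenced
— absence of evidence). The two are never merged: `-` participates in
reconstruction and counting as a fifth character state, while any `~` in a
stem's region removes that species from presence/absence calls and marks
the stem-length cell *unknown*. `T` is silently normalized to `U` and `.`
to `-` on input; lowercase letters (used in curated alignments to flag
mutated, non-pairing bases) are uppercased but kept as per-sequence column
metadata. IUPAC ambiguity codes are accepted and carried through; each
counting step skips columns it cannot interpret rather than guessing.
Column indices are 0-based half-open internally and 1-based in every file
and error message.

## Stem grammar

The consensus structure line uses independent bracket classes `()`, `[]`,
`{}`, `<>` and letter pairs (`A`…`a`), each matched with its own stack, so
pseudoknotted helices can be written with letters while nested helices use
brackets (WUSS-compatible). Matched pairs are chained into stems while
nesting is direct and contiguous: a gap on one strand only (a bulge) keeps
the stem together; at least one unpaired column on *both* strands (an
internal loop), or an intervening paired column from another helix, starts
a new stem. This granularity matches how curated databases name stems.
Pseudoknot flags come from the exact arc-crossing test
(`i<k<j<l`) applied to every pair of stems, verified in the tests against a
brute-force scan.

**Realized stem length** counts the stem's column pairs that form a
canonical pair — Watson–Crick plus the G·U wobble — in a given row. The
wobble is included because comparative RNA analysis treats G·U as
structure-preserving; all other juxtapositions count as "unable to pair".
Bulge columns are excluded by default; `count_bulges=True` adds
stem-internal bulge columns holding a base, for compatibility with
annotation tools that quote stem lengths "including the bulges". A pair
containing an ambiguity code is skipped entirely (neither paired nor
broken).

**Variability categories** bin each stem by the fraction of species whose
known length equals the modal length: conserved (>70%), intermediate
(>40%), variable (otherwise). Modal ties break toward the larger length,
i.e. conservatively toward "stem present".

## Ancestral reconstruction

*Continuous lengths* use unweighted squared-change parsimony: internal
values minimize Σ(parent−child)² over branches. The optimum satisfies
"every internal node equals the mean of its neighbors", a sparse linear
system solved exactly with `numpy.linalg.solve`; this is deterministic,
handles polytomies, and ignores branch lengths (the unweighted form).
Species with unknown cells are pruned from the tree first.

*Sequences and presence* use unit-cost Sankoff dynamic programming per
column, which generalizes Fitch counting to polytomies (the tests verify
the binary-tree equivalence and, on small trees, equality with exhaustive
enumeration over all internal labelings). The state space is
`{A,C,G,U,-}`: treating the gap as a fifth, substitutable state is what
lets an ancestor be reconstructed as having *no sequence* in a region,
which the event classifier depends on; `gaps_as_missing=True` switches to
the lenient convention. `~` and IUPAC codes constrain a leaf to the
compatible state set at zero cost. After an up pass, a down pass over
conditional costs yields, per node, the full set of states occurring in at
least one globally minimal labeling; non-singleton sets are written `?` and
the sets themselves are preserved in the JSON output. Nothing is ever
sampled, so reconstructions are deterministic.

## Variable-stem detection and event classification

The original analyses selected variable stems and clades by expert
inspection; `stemevol` uses an algorithmic surrogate. A change on one
branch makes the subtree below it internally uniform yet different from its
sisters, so a clade is reported for a stem when one of its branches carries
a single length and another branch a different length — *provided that pair
of lengths has not already been explained by a reported descendant clade*.
Without the proviso the same contrast would be echoed at every ancestor up
to the root; with it, each event region yields one record, while genuinely
new contrasts (fresh length pairs) still surface at higher nodes. The root
is reported as a fallback when an unexplained contrast survives to the top
without a uniform branch to witness it.

Classification reads the reconstructed ancestor of the clade over the
stem's paired columns. With g = gap fraction of the ancestral region and
θ_gap = 0.9 (configurable; "no sequence present" while tolerating a couple
of residual columns):

- g ≥ θ_gap and some descendant realizes the stem → **whole-stem
  insertion** (direction: gain);
- g < θ_gap, ancestral realized length > 0, and some descendant's region is
  (near-)all-gap → **whole-stem deletion** (loss);
- otherwise → **pairing change by substitutions/indels**, with direction
  from the median descendant length vs the ancestral length.

Parsimony cannot always polarize the clade node itself: losses on most
branches cost exactly as much as ancestral absence plus gains, leaving the
region `?`. When more than half of the stem's ancestral columns are
unresolved, the classifier climbs to the nearest ancestor whose region is
resolved — the common node at which sequence presence can actually be read —
and uses that; if nothing resolves (an innovation at the root bifurcation),
it falls back to the majority presence state over all sequenced rows. The
event evidence records which route was taken, along with the gap fractions
and lengths needed to re-derive the call. Species with `~` in the region
are excluded; a clade whose members are all unsequenced raises a no-call
error rather than guessing. Partial stem shortening falls in the
substitution/indel class, giving the two-way split that the family-level
frequency table and the chi-square test (Pearson, r×2 counts, df = r−1, no
continuity correction) operate on.

## Substitution matrices

Counting unit: one tally per (sequence pair, column) for single nucleotides
and per (sequence pair, column pair) for base-pair duplets, over the
columns of variable stems only. Extant/extant mode compares every unordered
pair of sequences within each variable clade (not only sister pairs) and
stores counts fold-symmetric in the lower triangle; ancestral/extant mode
compares the clade-node reconstruction against each member and stores
directional counts (ancestor row → extant column). No-change (diagonal)
cells are tallied. Skipped: columns with `~` or ambiguity codes, ancestral
`?` columns (making the ancestral matrices conservative), and all-gap
duplets. A compensatory double change such as G:C → A:U therefore counts
once, as a duplet change.

The log-odds transform is `A = log2(f_obs / f_exp)` in bits with observed
frequencies normalized by the total event count and expected frequencies
from the matrix's own marginals. For fold-symmetric counts the marginal of
state *i* is `f_ii + ½·(off-diagonal mass involving i)` and off-diagonal
expectations use both orderings (`2 f_i f_j`); directional matrices use row
and column marginals as-is. Zero-observation cells are reported `NA`, never
−∞; an optional pseudocount (default 0) can fill them. The transform is
scale-invariant and vanishes identically on independence-structured counts,
both verified exhaustively in the tests.

## Profile statistics

PCA is performed on the covariance of the centered stem-length matrix —
deliberately *not* autoscaled, because all variables share one unit (base
pairs) and long variable stems should contribute proportionally more
variance. An autoscaled variant is available (`scale=True`). Rows with
unknown cells are dropped for PCA; partial sequences (any `~` in the row)
are excluded by default. K-means instead imputes unknown cells with the
stem's modal length so every species is assigned; the best of `restarts`
seeded runs (by within-cluster sum of squares) is kept, and a WCSS-vs-k
side table (k = 2..8) supports choosing k without automating the choice.
The biplot payload is drawing-neutral: 2-D scores with cluster classes,
per-stem loading vectors, and outliers defined as species whose score
distance from the centroid exceeds 2.5× the root-mean-square distance.

## The simulator

The generator emulates the processes the inference is built to detect, on a
hairpin-series root molecule (default: 4 stems of 4–8 bp with 3–6 nt loops
and linkers, all pairs canonical; an optional 3-bp helix pairing the first
hairpin loop with the following linker plants a pseudoknot). Along each
branch, event counts are Poisson with rate × branch length:

| process | default rate / unit branch | note |
|---|---|---|
| whole-stem insertion | 0.05 | new hairpin, fresh alignment columns |
| whole-stem deletion | 0.05 | stem block gapped in the lineage |
| pair substitution | 0.5 | compensated with probability 0.5 |
| in-stem single-base indel | 0.2 | breaks/restores one pairing partner |
| loop substitution | 0.5 | neutral background |

On a unit-branch 12-leaf tree (~22 branches) this yields a couple of
whole-stem events against an order of magnitude more pairing changes —
whole-stem gain/loss as the rarer class, the regime reported for real
structured-RNA families. At most one whole-stem event touches a stem per
branch, keeping the truth log uniquely interpretable. Insertions open new
columns at element boundaries, gap-filled in all other lineages, so the
emitted alignment is a true multiple alignment and no aligner confounds the
evaluation. An optional `~`-mask censors terminal regions of some leaves to
exercise the unknown-region logic. Identical seeds give byte-identical
output.

What the simulator does **not** model: site-rate heterogeneity, GTR-style
base composition, loop indels, stem slippage/extension, or alignment error.
Passing the recovery tests therefore shows the inference is correct for the
modeled event classes on correct alignments, not that it is robust to
curation noise in real data.

## Problem sizes and verification

The test suite and the acceptance script size their computations to run in
seconds on one CPU while remaining conclusive: 200 random trees (≤6 leaves,
polytomies included) for the exhaustive-enumeration parsimony oracle, 50
random ≤10-leaf trees against a BFGS optimizer for squared-change parsimony
(agreement < 1e-6 relative), 50 randomized count matrices for the log-odds
identities, 20 default-rate 12-leaf simulated families for pooled
whole-stem recall / class precision / ancestral accuracy (all ≥ 0.9), and
single-process control batches whose inferred class split is exactly
100%/0%. Larger trees or families change none of the algorithms, only the
runtime.

## Known limitations

- Parsimony polarity: a loss spanning the majority of the tree is
  indistinguishable from an ancestral absence with gains, and root-level
  innovations cannot be polarized at all; the majority fallback then
  decides, and will be wrong half the time in truly symmetric cases.
- One record per (stem, clade): several same-class events of one stem
  inside one clade collapse into a single record, so event *counts* are a
  lower bound; the class split is unaffected.
- The ancestral/extant matrices inherit parsimony's bias toward common
  residues and are conservative for rare changes.
- Squared-change parsimony ignores branch lengths by design; a weighted
  variant would require trusting the reference tree's rates.
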