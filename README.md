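# stemevol

Evolutionary analysis of RNA secondary-structure stems: how do the double
helical regions of structured RNAs (tmRNA, RNase P RNA, telomerase RNA, ...)
change along a phylogeny?

Functional RNAs conserve their base-paired architecture through compensatory
mutations (covariation), yet across related species individual stems still
vary in length, appear, and disappear. `stemevol` takes a curated structural
alignment — gapped sequences over `{A,C,G,U,-,~}` plus one consensus
structure line — and an independently built rooted reference tree, and asks,
for every stem, *what kind of mutation produced the variation*: the gain or
loss of the whole stem as a sequence block, or point substitutions and
single-base indels that create or disrupt base pairs.

## What it computes

- **Stem annotation.** The consensus structure (brackets plus `Aa`-style
  letter pairs, or Stockholm `#=GC SS_cons`) is parsed into stems, loops and
  pseudoknots; two stems are a pseudoknot when their arcs cross
  (`i < k < j < l` for pairs `(i,j)`, `(k,l)`). Per sequence, the *realized*
  length of a stem is the number of its column pairs forming a canonical
  pair (Watson–Crick + G·U wobble). Stems are binned as conserved /
  intermediate / variable when the modal length covers 71–100%, 41–70%, or
  1–40% of the species.
- **Ancestral reconstruction.** Continuous stem lengths are mapped onto the
  tree by unweighted squared-change parsimony (internal nodes solve the
  linear system "each node is the mean of its neighbors", which handles
  polytomies exactly); sequences and stem presence are reconstructed by
  unit-cost Sankoff parsimony over `{A,C,G,U,-}` with the gap as a fifth
  state, so "no sequence at this ancestor" is a reconstructable outcome.
  Positions whose minimal-cost state set is not unique are written `?`.
- **Event classification.** Each variable (stem, clade) is classified by
  the reconstructed ancestor of the clade: region absent ancestrally
  (gap fraction ≥ θ_gap = 0.9) with descendants realizing the stem →
  *whole-stem insertion*; region present ancestrally with descendants
  losing it → *whole-stem deletion*; otherwise a *pairing change* by
  substitutions/indels. Family-level class frequencies are compared with a
  Pearson chi-square.
- **Substitution matrices.** Within variable stems, single-nucleotide and
  base-pair (duplet) changes are counted for extant/extant and
  ancestral/extant comparisons and turned into gap-aware log-odds scores,
  `A_ij = log2(f_ij / (f_i f_j))` in bits, with marginals taken from the
  count matrix itself (undefined cells stay `NA`).
- **Profile statistics.** Species are clustered by stem-length profile
  (k-means) and projected by covariance PCA; the biplot payload reports the
  top-loading stems per component and outlier species.
- **Simulation.** A generative model evolves a hairpin-series RNA along a
  tree with whole-stem indels, compensatory/non-compensatory pair
  substitutions, in-stem single-base indels and loop substitutions, logging
  the complete truth (alignment, ancestors, events) for end-to-end
  validation of everything above.

## Worked example

Simulate a 12-leaf family and run the full pipeline:

```sh
stemevol simulate --seed 7 -o sim
# -> 12 leaves, 104 columns, 25 events
stemevol run-all sim/alignment.txt sim/tree.nwk -o out
```

`out/` then contains the stem-length table, ancestral sequences (FASTA),
the event log, four substitution matrices with log-odds transforms,
PCA/cluster tables and a manifest. For this seed the event log reads:

```
A pairing_change_substitution_indel loss clade 4
A pairing_change_substitution_indel loss clade 20
A pairing_change_substitution_indel gain clade 22
B pairing_change_substitution_indel loss clade 3
C pairing_change_substitution_indel loss clade 3
C whole_stem_deletion loss clade 21
D whole_stem_insertion gain clade 9
E whole_stem_insertion gain clade 4
F pairing_change_substitution_indel loss clade 9
```

i.e. of the 9 stem/clade changes, 3 are whole-stem events and 6 are pairing
changes — whole-stem gain/loss is the rarer mode. The PCA variance table
shows which stems dominate the length variation:

```
component  variance_share top_stem
      PC1        0.462404        C
      PC2        0.337842        E
      PC3        0.145083        D
```

(stem C, which suffered the whole-stem deletion, carries the largest share).
The same analyses run on real structural alignments in the `bracket`
dialect (aligned FASTA + one `#structure` line) or Stockholm files with an
`SS_cons` line; `~` marks non-sequenced regions and is excluded from all
presence/absence calls.

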