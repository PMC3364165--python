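# Methods

This note documents the models, parameters and numerical choices behind
`barcode_audit`, and what the synthetic-data tests do and do not establish
about real libraries.

## Coordinate frame, anchoring and QC

All analyses operate on the fixed 658-site Folmer fragment of COI. No
multiple sequence alignment is performed: the barcode region is treated as
indel-free, full-length reads are anchored at site 1, and short amplicons
are assumed to be 5′ fragments (the common 325-bp mini-barcode) unless an
explicit start offset is supplied. This is appropriate for barcode
libraries, where length variants are screened out during QC; it is *not*
appropriate for markers with real indel variation.

QC translates each sequence under the invertebrate mitochondrial code
(NCBI table 5) in the reading-frame offset (0, 1 or 2) that minimises
in-frame stop codons, ties going to the smallest offset. Decisions are
ordered: `too_short` (default minimum 300 sites, matching a library whose
shortest retained records are ~314 bp), then `indel` (any internal gap
character — with a gap the frame itself is untrustworthy, so gap screening
precedes stop screening), then `stop_codon`, else `pass`. Frame choice is
invariant to 3′ truncation by whole codons.

## K2P distances with pairwise deletion

For a pair of anchored sequences, comparable sites are those where both
carry a concrete A/C/G/T; IUPAC ambiguity codes, N and gaps are excluded
(standard pairwise-deletion semantics). With transition proportion P and
transversion proportion Q over the n comparable sites,

d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q).

A pair is **undefined** when n < `min_overlap` (default 100 — genuine
barcode pairs share at least the 325-site 5′ window, so 100 is a generous
floor) or when a logarithm argument is non-positive (saturation).
Undefined distances propagate as NaN: they are excluded from species
summaries with a logged warning, raise an error inside single-linkage
clustering and NJ (where silently dropping a pair would change the
result), and print as `NA`/`–` in exports. Distances are stored as
proportions; reports print percent with one decimal (two where finer
precision is conventional).

## Clustering, trees, monophyly

**Single-linkage clusters** at cutoff c connect specimens through chains of
pairs with d < c (strict), so distinct clusters are separated by ≥ c.
Clusters are labelled by their smallest member id; the partition is
deterministic.

**Neighbor joining** follows Saitou–Nei with the Studier–Keppler criterion
Q(i,j) = (n−2)·d(i,j) − R(i) − R(j). Exact ties — which occur in
degenerate matrices such as equidistant taxa — are broken by the
lexicographically smallest sorted pair of node labels, where an internal
node carries the smallest specimen id beneath it. This makes tree
construction bit-reproducible and invariant to input order. Branch lengths
use the standard NJ formulas and negative lengths are retained (they are
cosmetic here: monophyly uses topology only). NJ is exact on additive
matrices; the test suite verifies path-length recovery to 1e−10 on random
additive matrices and cross-checks topology against scikit-bio's
independent implementation.

**Midpoint rooting** places the root halfway along the longest
leaf-to-leaf path, ties again broken lexicographically; an all-zero tree
is rooted on the edge adjacent to the first leaf. Rooting matters only for
the paraphyly/polyphyly distinction; an outgroup can be used instead by
rooting externally and passing the rooted tree to the classifier.

**Monophyly**: species s with leaf set L is *monophyletic* if some clade
equals L; otherwise, with I the non-conspecific leaves under MRCA(L), it is
*paraphyletic* if I itself forms one clade and *polyphyletic* otherwise;
single-specimen species are *singleton*. This is one defensible
formalisation of calls usually made by eye on published NJ trees, not a
claim about any author's procedure.

## Audit thresholds

| parameter | default | meaning |
|---|---|---|
| `t_deep` | 0.022 | MXID above this trips `deep_divergence` — the 2.2% level repeatedly found to delimit insect species |
| `t_split` | 0.050 | single-linkage cutoff for deep haplotype clusters; ≥ 2 clusters trips `multi_cluster` (cryptic-complex candidate) |
| `t_assign` | 0.020 | name-propagation radius: a query inherits a name only from expert references within < 2% |
| `mnid_scope` | genus | where MNID's nearest non-conspecific may come from (genus/family/all). MNID can only shrink as scope widens |

All flag comparisons are strict (`>`): an MXID of exactly 2.2% is not
flagged. The deep-divergence and multi-cluster screens answer different
questions: `deep_divergence` is a sensitive screen (any species whose
extremes exceed the species-delimitation level), while `multi_cluster`
demands discrete clusters separated by > 5% and is the operational
definition of a cryptic complex used throughout.

**Discordance screening** flags a specimen when its nearest neighbor lies
within `t_assign` under a *different* name while its nearest conspecific
(if any) lies beyond `t_split`. The full audit (`run_audit`) applies this
screen first and by default sets flagged specimens aside before computing
summaries, mirroring the curation workflow in which flagged vouchers are
re-examined: a single mislabelled barcode otherwise corrupts the MXID,
MNID and cluster count of two species at once. Pass
`exclude_discordant=False` to audit the library exactly as labelled.

**Name assignment** computes distances from the query to every
expert-identified reference. If references of exactly one species fall
within `t_assign`, that name is propagated; several species → `ambiguous`;
none → `unassigned`, the entry point for provisional naming. Note that
with intraspecific divergences of the same order as `t_assign`, a fraction
of genuine conspecifics necessarily lands in `unassigned`; the rule is
conservative by design and never guesses.

**Diagnostic nucleotides**: (position, state) is diagnostic for species s
within a comparison set iff every member of s with data at the position
shows the state and no member of another species in the set does. Sites
with fewer than `min_coverage` (default 1) covered members of s are
skipped. Positions are 1-based frame coordinates.

## The synthetic library generator

The generator emulates the statistical structure of a curated
multi-species barcode library, not its genealogy. Sequences evolve under a
per-site continuous-time K2P process with transition/transversion rate
ratio `kappa` (default 3.0), rates normalised so a branch of depth t
accumulates t expected substitutions per site. Ancestors are drawn
codon-wise from the 62 non-stop codons of translation table 5, and every
evolve step redraws children containing an in-frame stop, so emitted
sequences always pass translation QC.

Genealogy is a star radiation at each level. Branch depths are set so that
each configured value is the **expected pairwise K2P distance** of its
comparison class:

| comparison | expected d | default |
|---|---|---|
| conspecific, same cluster | `intra_depth` | 0.02 |
| cryptic clusters, same species | `split_depth` | 0.08 |
| congeneric species | `inter_depth` | 0.12 |
| same family, different genus | `between_genus_depth` | 0.25 |

i.e. specimens sit at depth `intra_depth/2` below their (cluster) ancestor
and a level at expected distance D adds `(D − intra_depth)/2` per branch.
Defaults are calibrated to the divergence levels reported for North
American mayfly barcodes (≈2% mean intraspecific, ≈12% mean minimum
interspecific, ~20% of species containing 2–3 clusters >5% apart, a 2.2%
screen, 325-bp mini-barcodes). `floor(cryptic_fraction · n_species)`
species are built from 2–3 clusters (members dealt round-robin, so
clusters are never singletons); a `fragment_fraction` of sequences is
truncated to the 5′ `fragment_length`; Ns are sprinkled at
`ambiguity_rate`; `misid_count` specimens (default 5) are relabelled to a
random congener in the metadata with the sequence untouched, and recorded
in the truth object. A `provisional_fraction` of species carries
provisional-style labels so report counts exercise that path. One seeded
generator drives every draw; a given seed reproduces output byte for byte
(three seeds are pinned as fixtures under `tests/data/fixtures/`).

What the generator does **not** emulate: coalescent variance and gene-tree
topology within species, rate variation among sites and lineages,
selection, base-composition bias, sequencing error beyond uniform Ns, and
the heavy-tailed sampling of real libraries. Passing the end-to-end tests
therefore shows that the audit recovers truth when divergences follow the
configured structure; it does not show robustness to realities such as
introgression or very recent speciation, which genuinely blur the barcode
gap (and do so in real mayfly data, e.g. minimum interspecific distances
down to 0.3%).

Because distances near the thresholds are stochastic, borderline events are
expected at the configured depths: occasionally a misidentified specimen's
nearest true conspecific falls just outside the 2% radius, or two cryptic
clusters land under 5% apart. The exact-recovery tests are therefore
asserted for pinned seeds, as reproducible instances of the typical case.

## Problem sizes and numerics

The shipped test and acceptance configurations use 20 species × 10
specimens (200 × 658 sites) for end-to-end recovery, 5–8 taxa × 100
replicates for NJ exactness (1e−10), 50 small libraries for diagnostic
soundness/completeness against a brute-force site scan, and 200 random
labeled trees (≤ 32 leaves) for the monophyly classifier against clade
enumeration — sizes at which every check runs in seconds while keeping the
statistics meaningful. Distance matrices are computed in row blocks to
bound memory; closed-form agreement of the distance implementation is
asserted to 1e−12. Floating-point summation-order ties in NJ's Q matrix
are handled by normalising candidate pairs before the lexicographic
tie-break, so results are independent of traversal order.
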