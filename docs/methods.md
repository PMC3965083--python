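# Methods

## The model

A protein is represented by its multi-domain architecture (MDA): the
ordered, non-overlapping sequence of domain-family assignments along the
chain.  Domain families live in a three-level structural hierarchy:
functional families (FunFams) nest inside homologous superfamilies
(shared ancestry), which nest inside folds (shared topology without
demonstrable homology — the CATH T level).  Families from resources
without a structural hierarchy (Pfam-A/B) are carried as *unintegrated*
singletons: they are their own family at every level and can only ever
match an identical identifier.

Two analyses are built on this representation: reconstruction of the
MDA from raw, overlapping domain hits, and global alignment of two MDAs
to quantify architectural similarity.

## Overlap resolution

Domain hits are first filtered by an E-value acceptability threshold
(default 1e-3, inclusive; the threshold is a tunable because acceptable
significance depends on the HMM library in use).  Among the acceptable
hits of one protein, the resolver selects the subset of pairwise
non-overlapping intervals that maximises the number of residues covered.
This is the weighted-interval-scheduling problem with weight = interval
length; we solve it exactly with a chain dynamic programme over hits
sorted by end position (O(n²), exact for any input; hit sets per protein
are small).  Equal-coverage ties are broken deterministically by
(1) fewer domains, (2) smaller summed E-value rank, (3) resource
priority (cath > funfam > superfamily > pfam_a > pfam_b), then
(4) lexicographic family id — favouring parsimonious, confident
architectures and making the output independent of input order.  The
first four DP criteria are additive and therefore exact under the chain
recursion; the lexicographic criterion is a last-resort tie-break only.

`overlap_tolerance` (default 0 residues) optionally allows two selected
hits to share a few residues, which are then trimmed from the
lower-priority hit; the default is zero because resolved assignments are
defined to be non-overlapping.  An alternative weighting —
coverage × score rather than coverage alone — would bias selection
toward significant hits at equal coverage; we keep pure
coverage-maximisation and use significance only in tie-breaks, since
coverage is the quantity the composite MDA is defined to maximise.

## MDA alignment

Global Needleman–Wunsch over domain tokens.  The substitution function
falls through the hierarchy, scoring an aligned pair at the deepest
relationship it has:

* identical FunFam: s_funfam (default 1.0);
* different FunFams of one superfamily that has a FunFam tree:
  s_superfamily + (s_tree_max − s_superfamily) · sim, with
  sim = depth(LCA)/max(depth(a), depth(b)) counted in edges from the
  root on the unweighted topology (identical leaves give 1; an LCA at
  the root gives 0, collapsing to the bare superfamily score).  Branch
  lengths, if present in the Newick input, are ignored: the trees are
  cluster dendrograms and their heights are not calibrated across
  superfamilies;
* same superfamily (no tree, or non-FunFam tokens): s_superfamily
  (default 0.6);
* same fold: s_fold (default 0.3);
* otherwise the mismatch score −1.0.

Gaps cost −0.01 per gapped domain, linear rather than affine, since the
method defines a single per-gap score.  The mismatch and gap constants
are fixed by the method; the positive scores are not published, so the
defaults 1.0 / 0.9 / 0.6 / 0.3 were chosen to give a strict ordering
with meaningful separation between levels, and all four are
configurable subject to s_fold ≤ s_superfamily ≤ s_tree_max ≤ s_funfam.
Note that with the default penalties a mismatch column (−1.0) is never
optimal against deleting and inserting the two domains (−0.02); the
mismatch entry still defines the substitution function and is exposed
directly.

Traceback ties are broken match > gap-in-B > gap-in-A, so the reported
alignment (not just its score) is deterministic.  The normalised score
divides the raw score by the *larger* of the two self-alignment scores
(|X| · s_funfam); normalising by the maximum rather than the minimum
penalises length differences and keeps the score ≤ 1, with equality
exactly for identical all-FunFam architectures.  Two empty MDAs
normalise to 1 by convention (they are identical).

## Genome-level analyses

*All-vs-all* matrices deduplicate proteins by identical family strings
before aligning, since token ranges do not enter the score.
*Distinctive MDAs* are proteins whose best normalised score against all
comparison genomes falls below a threshold (default 0.5 — the midpoint
of the normalised scale; no canonical cut-off exists and it is exposed
as a flag).  An empty comparison set yields −inf sentinels: everything
is trivially distinctive.  *Unique compositions* compare
order-insensitive family multisets, deliberately blind to domain order
and to residue ranges.

*Enrichment* tests, per family, a 2×2 table of foreground vs pooled
background with the two-sided Fisher's exact test (scipy), corrected by
Benjamini–Hochberg across families (statsmodels).  The default counting
unit is proteins-containing-the-family (presence/absence), robust to
tandem repeats; a domain-count mode is provided for gene/domain-count
style comparisons.  Families absent from both sides are never tested.

*MDA-length distributions* count domains per protein, after collapsing
each gene to its longest transcript when a gene→transcript map is
present (length ties break to the lexicographically smallest protein id
for determinism).  *Taxonomic grouping* partitions genomes by the name
at a requested rank of their lineage, with an "unclassified" bin for
genomes lacking the rank; live taxonomy lookups are out of scope and
lineages are supplied as files.

## Synthetic data

The generator emulates the *structure* of real domain-assignment data,
not its sequence-level biology.  `simulate_hierarchy` builds a fully
connected three-level hierarchy (defaults: 3 folds × 2 superfamilies ×
4 FunFams) with a random balanced FunFam tree per superfamily.
`simulate_genome` draws each protein's MDA length from a categorical
distribution (defaults 1:0.35, 2:0.30, 3:0.20, 4:0.10, 5:0.05 —
reflecting the dominance of short architectures in real proteomes),
lays domains of 40–300 residues separated by linkers of 0–50 residues,
and assigns FunFams uniformly.  Protein length is the last domain end
plus a random terminal linker.

Decoy hits (a configurable fraction of all hits; `hit_noise` 0.5 means
one decoy per true hit) are strictly nested inside a randomly chosen
true hit, carry a different family, and draw their E-values from a range
(1e-8–1e-4) disjoint from and worse than the true range (1e-50–1e-10)
yet below the acceptability threshold — so decoys survive filtering and
must be rejected by the coverage optimisation itself.  Strict nesting
makes recovery provable: any subset containing a decoy excludes its
(longer) host and covers strictly fewer residues, so the planted hit set
is the unique coverage optimum.  Real decoys are messier — they can
bridge domain boundaries, tie on coverage, or beat true hits — so
pipeline-recovery tests demonstrate correctness of the optimisation, not
robustness of domain assignment on real genomes.  True hits are pure
FunFam assignments by default; optional fractions of bare-superfamily
and Pfam assignments exercise the mixed-resource path (a protein with a
bare-superfamily domain self-aligns below 1 by design, since a
superfamily match is weaker evidence than a FunFam match).

`mutate_mda` applies single architecture edits (delete, adjacent swap,
substitution within a superfamily, substitution across folds) while
keeping range slots, for constructing controlled test scenarios.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive (HMMER convention); E-value
  thresholds are inclusive (≤).
* Discontinuous domains are not modelled as units: each contiguous
  segment is its own token, since MDA strings are linear.
* Traceback float comparisons are exact by construction: each DP cell
  stores the max of the three candidate expressions, so equality against
  the stored value identifies an achieving move bitwise.
* Empty inputs: empty hit lists resolve to empty MDAs; empty genomes
  give empty matrices and histograms; an empty gene (no transcript with
  an MDA) is skipped with a warning.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`.

## Problem sizes in the test suite

The oracle suites run 500 random MDA pairs of length ≤ 4 against full
alignment-path enumeration, 200 random hit sets of ≤ 12 hits against
enumeration of all 2ⁿ subsets, the Fisher route against exact
integer-weight hypergeometric enumeration on all 2×2 tables with both
row margins ≤ 30 (≈ 246 000 tables), and pipeline recovery on a
200-protein genome at hit-noise 0.5.  These sizes make the exhaustive
oracles cheap while covering every code path; the algorithms themselves
are exact at any size.

## Known limitations

* The positive substitution scores and the tree-similarity metric are
  implementation choices (only their ordering is fixed); rankings are
  stable under monotone re-scoring but absolute normalised values are
  not comparable across parameterisations.
* Alignment is global only; local (Smith–Waterman) architecture matching
  and residue-level alignment are out of scope.
* The resolver maximises coverage, not assignment probability; it does
  not rescore hits.
* Taxonomic grouping requires caller-supplied lineages.
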