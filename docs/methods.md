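# Methods

## Problem and model

The package reconstructs the early evolution of a gene family — developed for
and shipped with data on the TNF superfamily in ten vertebrates (three
agnathans, two chondrichthyans, three actinopterygians, *Latimeria* and
*Homo*) — from three printed inputs: a rooted species tree annotated with
whole-genome duplications (the two ancestral vertebrate WGDs, WGD1/WGD2, on
the stem above the vertebrate ancestor, and the teleost-specific TS_WGD on
the *Danio*+*Takifugu* stem), a species × orthology-group gene-count census,
and an origin-constraint table stating, per group, whether it arose in a WGD
(as an ohnolog of a named pre-WGD progenitor lineage) or by a tandem
duplication of a named parent group on a named branch.

Presence/absence evolves under **Dollo parsimony**: each group arises exactly
once and can only be lost afterwards. Unconstrained groups originate at the
most recent common ancestor of their carrier species; constrained groups
originate where the constraint dictates, which can force losses plain Dollo
would avoid (e.g. a WGD2 ohnolog absent from all agnathans implies a loss on
the agnathan stem). Losses are placed at the roots of maximal carrier-free
subtrees, which is the loss-minimal placement for a fixed origin; species in
the tree but absent from the census are missing data and never induce a
loss.

Copy number within the presence region evolves under **Wagner parsimony**:
integer states, cost |Δ| per branch, one copy entering at the origin. The
programme is an exact Sankoff dynamic programme over states 1..S with
S = observed maximum + 4 (headroom for WGD doublings), capped at 32. Ties are
broken toward the smallest ancestral count, so duplications are called as
late (and as conservatively) as possible. A copy gain on a TS_WGD branch is
labelled `wgd_retention` when the group predates that branch; all other
gains are `tandem_duplication`; partial decreases are `copy_loss` and
decreases to zero are presence-level `loss`.

Derived summaries: the **progenitor count** is the number of distinct
pre-WGD lineages (WGD-originated groups contribute their progenitor label;
tandem groups inherit their transitively-resolved parent's; unconstrained
root-originating groups count as their own). The **post-WGD gene count**
counts groups whose origin is at or before WGD2; a tandem on the WGD-bearing
stem itself is taken to postdate the WGDs of that stem (on the packaged data
this excludes the two stem tandems and yields 13 of the 15
vertebrate-ancestor groups). The **conservation summary** partitions groups
into present-in-all-species, shared across the agnathan/gnathostome divide
but not universal, and lineage-restricted sets; it is computed directly from
the census, so a group recorded in a single agnathan counts as shared even
where a coarser reading might exclude it.

## Orthology classification

Gene-tree leaves are grouped by four ordered rules (module `orthogroup`).
Branches with bootstrap support below `min_support` (default 95%, the usual
significance convention for ultrafast-bootstrap values; missing supports
count as 0) are uninformative. A supported clade containing reference-species
genes defines one group unless a supported *internal* branch separates those
reference genes "species-consistently": at most one reference gene on each
side, and every non-reference species' leaves wholly on one side. This
operationalises the co-ortholog situation in which several species' genes
are equally related to two reference genes — no supported branch sorts the
species to one side or the other — and such reference genes merge into a
slash-named group (TNFSF1 + TNFSF2 → "TNFSF1/2"). A bare leaf is not a
partition, otherwise any reference pair would be trivially separable.
Supported multi-species clades without reference genes become novel groups
auto-named "GRP-" plus their lexicographically smallest accession. Leaves
outside any qualifying clade are rescued into a group when they carry
same-position or same-chromosome synteny evidence with a member of exactly
one group; equal-strength evidence toward two groups yields UNASSIGNED with
a conflict flag rather than an arbitrary choice. There is no tentative
("question-mark") assignment tier: a sequence is either rescued by the
stated rules or left unassigned.

Raising `min_support` cannot create supported clades, and on realistically
structured trees (strong within-group support, weak between-group support)
the number of groups is non-increasing in the threshold; the property test
asserts this on simulator output. It is not a theorem for adversarial
support values: a merged clade whose support falls below the threshold can
split into per-reference singleton groups.

## Synteny evidence

Neighbourhoods are defined on gene order (ranks), with base-pair windows —
200 kb per side, expanding to at most 1 Mb on a side with no gene — only
bounding their extent on sparse scaffolds. Two genes in different species
are *same_position* when an immediately adjacent gene of one has an ortholog
immediately adjacent to the other; tandem copies of the focal gene's own
family are stepped over when determining adjacency, because they are not
independent markers. Failing that, *same_chromosome* applies when any
neighbour's ortholog lies on the partner gene's scaffold; an empty or
unavailable neighbourhood is *undetermined*, never *none*.

The chance that an unrelated gene occupies a flanking slot is modelled as
`neighbor_slots / genome_gene_count`. The default of 4 slots (two immediate
flankers per side) in a 20,000-gene genome gives 1/5,000; both numbers are
configurable. Evidence across comparator species is combined per (group,
species) by taking the best class and multiplying collision probabilities
under an independence assumption, with corroboration declared below
`alpha = 1e-3`. Strand is recorded but ignored: the adjacency argument is
orientation-agnostic.

## Synthetic data generator

`synthgen` mirrors the generative structure the analysis assumes:
single-origin families, WGD-correlated gains, lineage losses and locally
conserved neighbourhoods. Defaults are chosen to emulate the study system:
`n_progenitors = 3`; `wgd_retention_prob = 0.9` (nearly all ancestral-WGD
ohnologs persisted in gnathostomes); `loss_rate = 0.1` and
`tandem_rate = 0.05` per copy per unit branch length (losses outnumber
tandem gains, but both are common on the multi-unit branches of the packaged
tree); `rearrangement_rate = 0.1`; `support_noise = 5` percent;
`genome_gene_count = 20,000`. WGD events fire at the top of their branch;
each retained ancestral-WGD duplicate founds a new group, whereas TS_WGD
duplicates stay in-group as extra copies — matching how teleost ohnologs are
tallied inside their parent orthology group in the census. Losses are
per-copy Poisson thinning (survival `exp(-loss_rate * t)`); first-generation
tandem offspring do not themselves duplicate within the same branch.

Tracks place each group at a random ancestral slot among background genes
whose order (and scaffold boundaries, cut in ancestral coordinates) is
conserved across species, with tandem copies adjacent to their parent;
rearrangement relocates `Poisson(rate × root-to-leaf length × genome size)`
random genes. Gene trees are a star of per-group clades with supports
100 − |N(0, support_noise)|; within-group topology is not modelled, which is
sufficient for (and matched to) the classification rules, but means the
generator cannot produce the misleading *between*-group attractions seen in
real trees. Matrices, tracks and gene trees from one run are mutually
consistent by construction.

What passing recovery tests show, therefore, is that the inference is exact
on data satisfying its own assumptions and degrades monotonically as those
assumptions are relaxed (loss rate, rearrangement rate, support noise) — not
that it is robust to alignment error, assembly fragmentation, or convergent
sequence evolution, none of which are modelled.

## Numerical and degenerate-case choices

- Wagner ties break toward the smallest state (then the earliest branch,
  implicitly, by assigning top-down); the DP is exact, verified against
  exhaustive enumeration.
- A tandem constraint on a WGD-bearing branch is ordered after that branch's
  WGDs; WGD1 precedes WGD2 on a shared branch by validation.
- Blank census cells are zeros; the "Other" column is carried for totals but
  excluded from all group-level inference.
- Coordinates are 0-based half-open; overlapping genes are ordered by start
  then end.
- An all-zero matrix yields an empty history; a constraint whose branch is
  not ancestral to every carrier raises an infeasibility error (CLI exit 3).
- Simulation problem sizes in the tests (30–120 background genes, the
  packaged ten-species tree, 100 replicates for exact-recovery and 15–25 per
  grid point for trend checks) were chosen as the smallest sizes at which
  the checked statistics are stable.

## Known limitations

- Event labels on a branch that carries both a TS_WGD retention and a tandem
  duplication are not separately identifiable from leaf counts; exactness of
  event recovery is therefore checked under a no-tandem configuration.
- Dollo cannot distinguish independent losses in two sister lineages from a
  single earlier loss plus regain; by axiom it reports the former.
- The combined synteny probability multiplies per-species comparisons as if
  independent, which overstates evidence when comparator species are closely
  related.
- The classifier has no tentative tier and no model of rate heterogeneity;
  fast-evolving members are recovered only through synteny rescue.
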