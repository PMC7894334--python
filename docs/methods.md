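# Methods

This note documents the models, rules and constants behind each stage, the
choices made where the underlying analysis left the design open, and what
the synthetic-data tests do and do not demonstrate about real data.

## Trees and supports

Newick input is parsed with dendropy; internally trees are a small mutable
rooted node structure so rerooting and the clade algorithms control their
own invariants. Bootstrap supports are integer percents in [0, 100] stored
on internal nodes but semantically attached to edges (bipartitions):
rerooting on an outgroup edge moves each support with its bipartition, and
the new root edge carries the support of the split it represents on both
children. Fractional supports (≤ 1, written with a decimal point) are
multiplied by 100 on ingest; the convention is selectable
(`support_scale="percent"|"fraction"|"auto"`). Polytomies are retained —
nothing resolves topology the input does not assert — and clade
enumeration treats each polytomy child as a separate candidate.
Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at the boundary.

## Lineage delineation

A candidate anchor is a clade that passes the support threshold
(`support_min = 60`) and satisfies criterion 1 (clade content contains D
and intersects {A, B}) or criterion 2 (its sister satisfies criterion 1).
A single leaf can qualify only through criterion 2; leaves and the whole
ingroup are exempt from the support test (a one-taxon clade is trivially
supported). Delineation then descends from the ingroup root: a clade
*divides* when at least two disjoint candidates lie strictly below it; a
single maximal candidate is followed downward, because any division of its
subtree also divides the parent. Minimal (indivisible) candidates become
lineage anchors; outgroup-clade leaves form one extra lineage numbered
last.

Two points are genuinely under-determined by the published rule and are
explicit, logged configuration here:

- **Unassigned leaves.** Divisions need not partition the leaf set
  exactly; ingroup leaves under no qualifying clade are absorbed
  (`unassigned_policy="nearest-anchor"`): first by the nearest ancestral
  anchor, otherwise by the lineage sharing the deepest common ancestor,
  ties broken toward the lineage with the lexicographically smallest
  member id (invariant to child order, which keeps the partition stable
  under input permutation).
- **Support-absent nodes** fail the support test by default
  (`support_absent="fail"`); a tree with no supports at all is rejected
  unless the policy is `"pass"`.

Raising `support_min` can only coarsen the partition (fewer, larger
lineages); this monotonicity and the completeness/disjointness of the
partition are property-tested, and the whole rule is tested against an
independent leaf-set-based exhaustive implementation on hundreds of random
trees.

## Reconciliation and gain/loss accounting

LCA reconciliation is standard: each gene node maps to the species-tree
LCA of its descendants' species; a node is a duplication iff it maps to
the same species node as one of its children. Copy numbers are counted
per lineage on the subtree induced by the lineage's members (absorbed
leaves included), so one lineage's mapping is never distorted by another's
genes.

The number of copies of a lineage surviving to a species-tree node S is
the number of gene-tree edges crossing S's crown: an edge (u, v) counts
when v maps inside S's subtree — excluding duplications mapping exactly to
S, which happen on the branch above the crown — and u maps above the crown
(or v is the lineage root, whose stem descends from the family's origin).
This is the Dollo-minimal, survival-evidenced count: copies that left no
sampled descendants are invisible, which is why simulated losses can only
be undercounted (verified as a property).

Gains from one ancestral copy are reported two ways, since a duplication
on the branch between the ingroup crown and two clade crowns (e.g. above
the A+B split) predates both: the **per-clade** tally (headline) sums
`copies_at(ingroup crown) − 1` plus `max(0, copies_at(clade crown) −
copies_at(ingroup crown))` per lineage and clade; the **pooled** tally
counts each duplication node once. Losses are (lineage, clade) absences;
species-level losses below clade crowns are not in the headline number.
On loss-free simulations with perfect supports, lineage count, both gain
tallies and the per-clade breakdown equal the generator's event log
exactly on every seed tested (100 families in the validation suite).

## Synteny

Anchors admitted at `e_value_max = 1e-10` are chained per chromosome pair
by the DP recurrence `score(i) = match_score + max_j(score(j) +
gap_penalty·gap(i, j))` over predecessors with both rank deltas in
[1, max_gaps + 1], `gap = (Δrank_a − 1) + (Δrank_b − 1)`; both
orientations are searched, blocks under `match_size` anchors are
discarded, and after each best-first extraction anchors within
`overlap_window` ranks of a block anchor (either genome) are suppressed
before re-chaining. The DP equals exhaustive chain enumeration on all
anchor sets ≤ 8 (500 seeded layouts). The E-value gate applies to anchor
admission; no block-level significance statistic is recomputed, as those
formulas vary by tool version while anchor gating is deterministic.

Tandem arrays are transitive homology groups on one chromosome whose
consecutive members lie within `max_intervening = 5` ranks (the published
analysis names no bound; 5 mirrors common collinearity-tool defaults and
is a flag). Both the array count and the implied duplication-event count
`Σ(size − 1)` are reported; the latter is the headline.

An interspecific pair is **syntenic** when both genes are anchors of one
shared block, or (span membership, on by default) lie within
`window = 5` ranks of one of its anchors *with consistent displacements*
(|Δa − sign·Δb| ≤ 2 under the block's orientation). Plain
anywhere-in-the-span membership was rejected: in dense families it labels
any copy that transposed into a collinear segment as syntenic with
everything in that segment. The stricter anchors-only count is always
reported alongside. Classification is symmetric in genome order.

## Sequence statistics

Column trimming keeps exactly the columns whose non-gap fraction is ≥ the
threshold (default 0.3), with an index map back to original coordinates;
threshold 0 is the identity and thresholds > 1 empty the alignment.
Similarity is percent identity over mutually ungapped columns — the only
parameter-free reading of "similarity" — undefined (None) when no such
column exists. Medians use the mean-of-central-pair convention for even n.

Ka/Ks is Nei–Gojobori (1986): per-codon synonymous site fractions
(mutations creating stops counted as nonsynonymous), pathway-averaged
difference counts for multi-hit codons (pathways through stops dropped
unless all are), Jukes–Cantor correction `d = −(3/4)·ln(1 − 4p/3)` with
p ≥ 3/4 flagged saturated and Ks = 0 flagging the ratio undefined. The
pathway counts are tested against an independent recursive enumeration,
and whole estimates against a second published implementation (agreement
to ~1e-5 except rare multi-stop-pathway codons, tolerance 0.01). NG86 was
chosen as the simplest standard estimator; analyses sensitive to the
estimator should expect ±0.05 around the reported medians.

## Synthetic families

The generator emulates the study regime: an eight-species,
four-clade species tree of unit depth (three clade-A species, two B, two
D, one F outgroup), one ancestral copy at the root, and a Gillespie
birth–death process with defaults `dup_rate = 3.6` and `loss_rate = 0.4`
per copy per unit time — chosen once so per-species family sizes span
roughly a handful to ~100, as in the emulated family. Duplicates are
placed in tandem (insert at parent rank + 1, shifting subsequent ranks)
with `p_tandem = 0.35`, else at a uniform random chromosome position,
which creates the tandem-adjacency and dispersed-placement signals the
synteny stage detects. Genomes carry 3 × 80 background genes whose
cross-species orthologs are the collinearity anchors; segmental
rearrangements (`rearrangement_rate = 4` per genome per unit time,
segments of 8–40 genes) break collinearity into local blocks as real
rearrangements do. Families extinct outside the outgroup are resampled
(with the count logged), matching the survivorship conditioning implicit
in studying an extant family; the expectation test that checks the pure
birth mean e^λ disables this conditioning.

CDS evolution attempts point mutations at `substitution_rate = 0.55` per
site per unit time, rejects stops, accepts synonymous changes always and
nonsynonymous ones with probability ω (`omega = 0.7`, the purifying
regime of the emulated family); this yields cross-clade conserved-region
identities around 40–70% and within-clade Ka/Ks medians near 0.65–0.75.
Supports are 100 with probability `q_support = 0.9`, else uniform on
[30, 100). Every tree- or genome-shaping random choice is written to the
event log, and `replay_events` reconstructs the exact gene tree and gene
orders from the log alone (round-trip tested); the same seed yields
byte-identical outputs.

**What the simulations do not show.** Founder counts under the defaults
are single digits, not the tens of lineages of the emulated family — the
defaults are a scaled-down regime, and study-scale behaviour is asserted
only where the published inputs themselves are available. Sequences
evolve without indels (so simulated "alignments" are trivially gap-free
and trimming removes nothing), there is no whole-genome
duplication/triplication, no rate heterogeneity across sites or lineages,
and bootstrap supports are drawn from a toy model rather than estimated
from sequences. Synteny classification is validated against the
generator's ancestral-locus truth: exact on planted deterministic
scenarios, ≥ 85–95% agreement on full random simulations — the residual
disagreement comes from genomic context genuinely merged by rearrangement
and segments shorter than `match_size`, which no context-based detector
can resolve and which real analyses share.

## Problem sizes

The validation suite runs entirely on synthetic data at desk scale:
200 random trees (≤ 24 leaves) for the delineation oracle, trees ≤ 50
leaves for the reconciliation brute force, 500 anchor layouts ≤ 8 for the
chaining oracle, 100 loss-free families for parameter recovery, and 200
neutral 300-codon pairs for estimator calibration. `scripts/acceptance.py`
uses one default-conditions family (hundreds of genes) plus 50 recovery
families and 100 neutral pairs. The study-scale reproduction (727
homologs, 25 lineages, the published tandem/synteny/Ka-Ks tallies) runs
only when the journal's supplementary datasets are placed under
`data/study/`.
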