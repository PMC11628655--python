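# Methods

## Coordinate model

All intervals are 0-based, half-open, on the reference assembly; GFF3 input
is converted at the boundary.  Orientation is +1/−1 internally.  A
*karyotype* is an ordered dict of chromosomes, each an ordered list of
signed reference fragments; the simulator's root ancestor is its own
reference, while analysis-side karyotypes (built from syntenic fragments)
are anchored on the extant reference genome.  Elementary operators
(inversion, fission, fusion) are pure functions that split fragments as
needed and re-coalesce contiguous same-sign fragments afterwards, so
inverse operations restore the original representation exactly.

## Syntenic fragments and breakpoint regions

`merge_blocks` merges reference-consecutive blocks when they share target
chromosome and orientation, the target order continues in the direction the
orientation implies, and both the reference gap and the target gap are at
most the resolution (default 300 kb; 150 kb is the same code path).  Merged
fragments shorter than the resolution are discarded.  Merging is idempotent.

`call_ebrs` emits one candidate EBR per pair of reference-adjacent SFs
whose target adjacency is broken — different target chromosome, orientation
change, or a target-order discontinuity beyond the resolution (one
threshold governs both merging and breakage).  The EBR interval is the raw
inter-SF gap; zero-width EBRs (abutting SFs) are legal and keep their
shared coordinate as midpoint.  Size classes: ≤ 50 kb *well_defined*
(boundary inclusive), ≤ 300 kb *not_defined* (inclusive), larger breaks are
*gap_discarded* and excluded from downstream statistics.  Breaks at
reference chromosome ends are undetectable with a single reference and are
never emitted; consequently fission breakpoints only become visible where a
later fusion placed the fissioned content inside another chromosome.

## Rearrangement typing

`compare_karyotypes` first splits both karyotypes to the common refinement
of their fragment boundaries and verifies identical reference content
(with `restrict=True` both are first cut to their shared coverage, which
gapped real maps require).  Interchromosomal events come from the bipartite
content map: an A-chromosome with content on *k* B-chromosomes contributes
*k−1* fissions, and symmetrically for fusions.  Intrachromosomal events
come from a run decomposition of each B chromosome: maximal segments with
the same A chromosome, consecutive A order and uniform relative
orientation.  Runs are grouped into same-A-chromosome stretches, each read
in its own canonical direction (majority order of run ranges), so a fusion
operand assembled in flipped orientation is not mistaken for a disturbance.
A counter-oriented run flanked by good (order-contiguous) boundaries, at
least one of them an anchored same-chromosome flank, is one inversion.
Whole-chromosome orientation is gauge freedom: a reversed block with no
same-chromosome flank (an entire chromosome, a fission product, a wholly
flipped fusion operand) is not an event, which also makes fusion-with-flip
count as exactly one fusion.  Consecutive runs touching order-violating
boundaries form one *complex* event per maximal disturbed region, reported
with a lower bound of ceil(bad boundaries / 2) simple events; no exact
inversion-distance (Hannenhalli–Pevzner) computation is attempted, by
design — the target regime makes events directly readable, and the lower
bound documents what a disturbed region minimally implies.

Branch assignment compares consecutive nodes of the lineage series
(oldest first), attributing each comparison's events to that branch.
Rates are count/duration (events/My), with interchromosomal = fissions +
fusions, reported to two decimals.

### EBR dating and typing

The adjacency flanked by an EBR exists in the reference and in every node
younger than the event that created it; older nodes lack it.  For each
ancestor we test whether the reference stretch across the EBR (probing
0/1/10/100 kb outward when a flanking base falls in that genome's own
alignment gap) is contiguous — possibly wholly reversed — in that node's
karyotype.  A nested broken pattern (an oldest-first prefix) dates the EBR
to the branch below the youngest broken node; the terminal branch gives
*reference-specific*.  Non-nested patterns indicate breakpoint reuse and
are assigned to the most recent breaking branch with confidence
`reuse_flagged`.  EBR type comes from the events whose induced breakpoints
fall inside the (slack-widened, when jittered) interval: any fusion or
fission match wins (*interchromosomal*), otherwise inversion; an EBR
matched only by a complex event counts as inversion-type, since complex
events here arise from overlapping intrachromosomal changes.

### Fragment histories

Each SF accumulates the event types whose affected reference intervals it
overlaps: none → collinear; {inversion} → inversion; {fission} →
fission_collinear; {fission, fusion} → fission_fused; {fission, inversion}
→ fission_inverted; anything else non-empty → complex.  Fission events
carry the full content of the chromosome that split; fusions the full
content of the fused product; inversions the flipped block.  Fractions are
SF bases per label over assembly size and sum to the SF coverage fraction.

## Simulator

`simulate_ancestor` draws chromosome lengths from a Dirichlet partition
(concentration 5, minimum length 1% of the mean).  `simulate_lineage`
takes exact per-branch counts or per-My rates (counts ~ Poisson(rate ×
duration)) and applies the branch's events in random order.  Inversion
lengths are log-normal — median 10 Mb, σ(log) = 1, truncated to
[1 Mb, chromosome − 2·resolution]; the distribution is a configurable
choice, not an empirical fit.  The default lineage is five nested
ancestors over a reference leaf at ages 50/34/30/27/24/0 My; ages and
branch counts are fully configurable.

Under `no_reuse=True` the simulator enforces an identifiability regime:
breakpoints stay ≥ resolution from every prior breakpoint (across the whole
lineage) and from chromosome ends; inversion regions are disjoint from all
prior event regions; and each chromosome takes part in at most one fission
or fusion per branch (operands of a fusion may not derive from a same-branch
fission, and vice versa).  The last rule exists because chained
interchromosomal events on one branch net out differently in a pairwise
parent/child comparison than in the event-time log, making exact per-type
recovery impossible; with the rule, the recovered (type, branch) multiset
equals the truth log exactly on zero-jitter maps, which the test suite
verifies over many seeds.

`emit_synteny` re-expresses every genome in the reference leaf's frame via
the common refinement of fragment boundaries.  Each true breakpoint can be
widened into an alignment-style gap of total width ~ Uniform[0, 2·jitter]
split between the flanking blocks (truth EBR intervals record the result),
and long blocks can be Poisson-split into collinear sub-blocks separated by
sub-resolution gaps to exercise merging.  Annotation generation places
non-overlapping genes (log-normal lengths, median 30 kb) and per-family TEs
with sampling density multiplied by a fold factor inside supplied intervals
(fold 0 = exclusion, 1 = uniform); per-window GC is Normal(0.42, 0.05)
truncated to [0, 1] with an optional additive shift at supplied loci.
Expression matrices give housekeeping genes TPM ~ LogNormal(log 50, 0.2) in
every tissue and tissue-specific genes LogNormal(log 100, 0.3) in one
random tissue over a LogNormal(0, 0.5) background; at nine tissues these
two populations separate almost completely at the Gini 0.4 threshold,
which is what makes the recovery benchmark meaningful.

What the simulator does *not* emulate: sequence-level alignment error,
segmental duplication and translocation (absent from the event menu),
lineage-specific gene family turnover, or assembly fragmentation beyond
the block-splitting knob.  Passing recovery tests therefore demonstrate
the correctness of the calling logic under clean-to-moderately-jittered
maps, not robustness to every artefact of real alignments.

## Statistics

The permutation null re-places each region uniformly at random
(chromosome ∝ length, lengths preserved, regions non-overlapping;
vectorized rejection sampling with a sequential fallback for crowded
genomes).  Statistics: count of regions overlapping any feature, or total
overlapping bases — the base statistic is nearly tie-free and is the one
used for calibration checks; the count statistic is conservative under
heavy ties, as expected for a discrete statistic with the add-one rule
p = (b+1)/(n_perm+1) (never zero).  The alternative defaults to the
direction of the observed deviation, matching the signed-z/one-p reporting
convention of genomic association tools; z = (obs − mean)/sd with sd = 0
flagged degenerate (p = 1, z undefined).  No multiple-testing correction
is applied across TE families or chromosomes; outputs say so.  The
per-chromosome density test scatters EBR midpoints multinomially ∝
chromosome length and reports densities in EBRs/Mbp to three decimals.

GC windows tile chromosomes (default 10 kb, trailing partial window
dropped); N bases count in the denominator, windows over 50% N are flagged
missing and excluded from the high-GC set.  High-GC = fraction ≥ 0.60
(inclusive).  An alternative data-driven threshold (mean + 2 × the 95% CI
half-width of the window mean) is implemented but not the default: at
genome-scale window counts the CI half-width is tiny, so the rule lands
near the mean (~0.42) rather than near 0.60, and the explicit fixed
threshold is the reproducible choice.

Composite profiles average feature bases per 10-kb window at offsets
−30…+30 around anchor midpoints (offset 0 centred on the midpoint);
anchors contribute only windows fully inside their chromosome; the CI is a
per-offset t-interval across anchors and a genome-wide expected density
line is included.

Housekeeping calls use strict inequalities for expression (> 10 TPM in
> 90% of tissues, so 10.0 TPM or 8/9 tissues fail) and an inclusive Gini
threshold (≤ 0.4), computed on raw TPM over the shared-tissue columns with
the unbiased n/(n−1) correction by default (a flag disables it).  Ortholog
groups are labelled mammalian-ancestral (housekeeping in all species),
clade-ancestral (exactly the clade set), species-specific (focal species
only), shared_other (any other non-empty combination — kept explicit
rather than forced into the named classes), or non-housekeeping.
Gene-compartment co-location uses ≥ 1 bp intersection, the weakest
documented rule; boundary-spanning genes count in the EBR compartment with
a warning.  Zero-width EBRs are widened to 1 bp for overlap statistics so
they can carry signal.

## Numerical and degenerate-input choices

Gini is computed by the sorted-rank identity (equivalent to the double
sum, O(n log n)), clipped to [0, 1]; all-zero vectors are undefined and
raise (callers degrade them to non-housekeeping with a warning).
Empirical p-values use the add-one rule; permutation sd uses ddof = 1.
Single-chromosome density tests are degenerate by construction (sd = 0 →
p = 1).  Unsorted block input, overlapping SFs, negative widths, empty
EBR/anchor sets, zero/negative branch lengths and out-of-bounds intervals
raise with specific messages rather than propagating silently.

## Problem sizes

The validation scenarios run at full chromosome scale (2.4–2.5 Gb, 24–30
chromosomes) because all algorithms operate on fragment lists, not bases —
a full recovery run takes well under a second.  Statistical property
checks (type-I calibration at 500 replicate datasets, planted-enrichment
power at 100 replicates, profile CI coverage) use 20-Mb toy genomes with
120–200 permutations per test, sizes chosen so the whole suite stays
interactive while the binomial acceptance bands retain their meaning.

## Known limitations

Target chromosomes are assumed anchored consistently with the reference up
to whole-chromosome flips; partially gauge-inconsistent assemblies can
push true inversions into the complex class.  Complex regions report a
lower bound, not a parsimony-optimal event series.  Translocations and
duplications are out of scope.  EBR dating assumes the lineage series is
nested; heavily reused breakpoints are only flagged, not resolved.
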