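# Methods

This note records the models, conventions and design choices behind
`mutscape`, in the order the pipeline runs.

## Coordinates and gene models

All internal coordinates are 0-based half-open; BED exports keep that
convention, while conflict/stats CSV exports are 1-based inclusive (the
spreadsheet convention of the alignment-viewer exports this pipeline
mirrors).  A `GeneModel` is a strict alternating tiling of exons and introns
that begins and ends with an exon; UTR exons and UTR introns carry flags but
are counted with exons and introns respectively in every statistic.

## Synthetic data generator

The generator defines the study conditions for every downstream test; its
defaults are fixed once and are not tuned per test.

* **Gene architecture.**  Exon and intron lengths are uniform over
  configurable ranges (defaults 80–200 bp exons, 60–400 bp introns, 5 exons
  in the CLI).  The first intron's length is
  `first_intron_scale × mean(intron range) × max(n_introns − 1, 1)`, so a
  single knob reproduces genes whose leading (often 5'UTR) intron dominates
  the total intron length — the situation that motivates the dual
  full/partial accounting mode.
* **Substitutions** are drawn once per site with region-specific rates
  (defaults 0.01 exonic, 0.03 intronic — a 3× intronic excess of the kind
  the structural analysis is meant to detect, at densities where multiple
  hits are negligible).  The replacement base is a transition with
  probability κ/(κ+2) (default κ = 2), else one of the two transversions
  with equal probability; this gives the TN93 estimator a real
  transition/transversion structure to recover.
* **Indels are restricted to introns** (initiation probability per intron
  site, geometric lengths, deletions truncated at the intron's end,
  insertions attached to the left).  This keeps the variant→reference
  coordinate map monotone over exons, so the true multiple alignment of any
  set of variants can be reconstructed exactly from the maps — the oracle
  used by the conflict-recovery tests.  Exonic indels are a possible
  extension but would make truth alignments ambiguous.
* **Ground truth** lists every substituted site, every deleted site and
  every insertion's left-attachment coordinate, tagged exon/intron.
* **Contig tilings.**  `overlap_fraction` is the total fraction of the
  sequence at coverage 2, split evenly across junctions; junction positions
  are jittered within bounds that preserve the 1–2× coverage invariant, and
  infeasible geometries raise instead of silently degrading.
* **Ct tables** default to 3 groups × 3 biological replicates (BR) × 3
  technical replicates.  The target gene's Ct is
  `base − log2_effect(group) + BR offset + technical noise`
  (σ_tech = σ_BR = 0.3 cycles by default — the order of replicate scatter
  seen in routine qPCR); the reference gene gets technical noise only.  The
  BR offset therefore models biological replicate-level variation of the
  target transcript and deliberately does **not** cancel in ΔCt; the
  housekeeping gene is assumed stable by construction.  Injected outliers
  (count, magnitude in cycles) are recorded in the returned truth.

What the generator does *not* emulate: amplification-efficiency deviations
from 2, sequencing/assembly error in contigs, alignment-heuristic artifacts
(the true alignment is used), selection or non-uniform mutation processes
within a region.  Tests passing on these fixtures therefore validate the
pipeline's arithmetic and rules, not the biological fidelity of any
particular dataset.

## Consensus from 1–2× tilings

Coverage-1 positions copy the sole contig; agreeing coverage-2 positions
copy the shared base; disagreeing positions where exactly one base matches
the reference retain the reference base (flagged `ref_retained`);
disagreements with no reference match take the left-most contig's base and
are flagged `unresolved`.  The two flagged kinds replace a manual curation
step with a deterministic, auditable rule; the reference-retention rule, by
construction, suppresses true variants that only one of two overlapping
contigs carries — the tests quantify exactly this loss.  Coverage 0 is an
error (gap), coverage > 2 is rejected rather than majority-voted because
the supported tilings never exceed 2×.

## Column classification and conflict marking

A column is **exonic** if any transcript row has a residue, **intronic** if
all transcript rows are gapped but a gene row is not, ambiguous only when
fully gapped (possible in sub-alignments).  A column is **conflictual** when
its non-gap coverage is ≤ 2, or when at coverage ≥ 3 at least two residues
differ or a gene row is gapped against another gene row's residue
(gap-vs-gap is not a difference; transcript gaps encode intron boundaries
and never count).  Conflictual columns project onto a designated anchor
gene row; anchor-gap columns attach to the nearest preceding anchor
coordinate (left attachment, clamped to 0 at the alignment's start), and
duplicate coordinates collapse to one entry, keeping the left-most
contributing column's region.  Left attachment means a multi-column
insertion contributes a single anchor coordinate, whereas a multi-column
deletion in a *non-anchor* row contributes one coordinate per deleted base;
both choices are deliberate and frozen, since reasonable alternatives exist.

`count_by_region` re-checks each entry's region against the gene model's
intervals (authoritative at exon/intron boundaries) and supports an
interval-exclusion mode for dual accounting of genes with one dominant
intron.

## MAT and the contingency test

MAT = (intronic share of conflictual coordinates) / (intron length
fraction), reported unrounded by the library; presentation layers round to
3 decimals.  The expected distribution for the Fisher test is per-base-pair
uniformity within region, giving the 2×2 table of conflictual vs
non-conflictual positions by region.  The two-sided p uses the
point-probability method (sum all hypergeometric tables with the observed
margins whose probability is at most the observed one, with a 1e−7 relative
guard against floating-point ties at the boundary); the test suite checks
it against exact integer enumeration over every table with margins ≤ 30.
Degenerate tables (an empty margin) return p = 1.

When percentages or MAT are recomputed from *printed* tallies whose intron
fraction is itself rounded to 2 decimals, the recomputed MAT can differ
from a published 3-decimal value by one unit in the last digit; the
acceptance tests compare at that printed precision.

## TN93 and neighbor joining

The closed form uses the observed proportions of the two transition classes
and of transversions, with base frequencies averaged over both sequences at
the comparable sites (pairwise deletion: both bases in {A,C,G,T}).  A
non-positive logarithm argument means the pair is saturated for this model;
the distance is reported as NaN and flagged rather than capped, and
saturated matrices are refused by the tree builder.  Degenerate frequency
classes (e.g. no purines) make the corresponding term vanish, since its
transition proportion is then necessarily zero.  The implementation is
cross-checked in the tests against an independent reference implementation
(R `ape::dist.dna`, model `"TN93"`).

Neighbor joining is delegated to scikit-bio behind the module surface;
negative branch lengths (an NJ artifact on noisy matrices) are clamped to
zero.  For three taxa NJ returns the unique additive solution.  NJ on a
distance matrix is a surrogate for maximum-likelihood inference under the
same model: adequate for which-pair-is-closest claims, not for reproducing
ML branch lengths.

## qPCR analysis

ΔCt values are always formed within a biological replicate (all pairs of
target × reference technical replicates, target-major order), and
expression values 2^−ΔCt are pooled per group — 27 values for a 3 BR × 3
tech design — feeding both the fold change and the Mann–Whitney test.
Pooling (rather than averaging per BR first) is the package's chosen
aggregation; both the choice and its consequences are documented here
because the alternative is equally defensible.  In cumulative mode,
expression values from several experiments are concatenated per group after
the per-experiment, per-BR ΔCt step — BRs of different experiments are
never mixed within a ΔCt computation.

Repair runs in two passes with a shared threshold z (default 3): first,
single-Ct outliers are omitted when they deviate from their BR's median by
more than z × the scaled MAD (1.4826 × MAD; with 3 technical replicates a
zero MAD makes any nonzero deviation an outlier); second, a BR is eccentric
when its mean Ct deviates from the mean of its companion BRs' means by more
than z × the standard deviation of those means, and its technical
replicates are then all replaced by the BR's own (post-omission) mean.
Outliers must be handled *before* eccentricity: a single wild Ct shifts its
BR mean by a third of its deviation and would otherwise be "repaired" by
replacing the whole BR with a contaminated mean instead of being dropped.
Both thresholds are exposed in the API and CLI; repair is off by default
(the analysis functions take the data as given unless asked).

The Mann–Whitney p is exact (distribution enumeration) for combined sample
sizes ≤ 12 without ties, otherwise the normal approximation with tie and
continuity corrections — small-sample fidelity with tie robustness.

### Statistical caveats

The pooled U test treats the 27 expression values per group as independent;
they are not (3 independent BRs, and the 9 all-pairs ΔCt within a BR share
technical replicates).  Simulation at the default noise (σ_tech = σ_BR =
0.3) puts the empirical type-I error of the nominal 0.05 test near 0.4, and
near 0.3 even with no BR-level variation — the pooled design's p-values are
optimistic by construction, a direct consequence of pseudoreplication.  The
log2 fold-change estimate is unaffected (unbiased within Monte-Carlo error
in the same simulations, since replicate noise enters target and pooling
symmetrically).  Users who need calibrated p-values should aggregate to one
expression value per BR before testing, at the cost of n = 3 per group; the
pooled mode is retained as the package's primary behaviour because it is
the established practice this pipeline models, and the corresponding
calibration test in the acceptance suite is expected to fail until that
design changes.

## Problem sizes in the test suite

The suite favours many small, deterministic fixtures: conflict-recovery
sweeps use 200 random genes ≤ 200 bp; rate-recovery tests use one ~14 kb
gene × 20 seeded replicates (assertions within 3 standard errors of the
closed-form expectation); distance calibration uses a 50 kb single-exon
gene × 20 replicates; expression recovery uses 100 seeded simulations of
the default 3×3×3 design.  These sizes keep the full suite around ten
seconds while leaving the Monte-Carlo assertions with comfortable margins.

## Known limitations

* Exonic indels and coverage > 2 tilings are out of scope (see above).
* The conflict rules assume transcripts consistent with their own genome's
  gene sequence; transcript-vs-gene discrepancies within one population
  would be marked as conflicts.
* TN93 assumes stationary base composition; strongly non-stationary pairs
  will saturate or bias the estimate.
* Fold changes assume amplification efficiency 2 for both genes (the Livak
  premise); no efficiency correction is implemented.
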