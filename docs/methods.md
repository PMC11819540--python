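# Methods

## The library model

A library template is a string over `{A, C, G, T, N}`; maximal `N` runs are
the random blocks. The production design is a 74-character single-stranded
DNA template with sixteen random nucleotides in a symmetric 2:3:3 block
layout, eight on each side of a central KasI site (`CCATCGGCGCC`). The
descriptive text around this design quotes "73 nt", but the printed sequence
is the operational object, so the parser treats the 74-character string as
authoritative and reports the length in the validation output for the reader
to judge.

The module split coordinate is not part of the published design; any cut
inside the central fixed run preserves the 8+8 partition of random
positions. We cut at the midpoint of the unique restriction-site occurrence
(`site_start + ⌊site_len/2⌋`), which is deterministic and symmetric; an
explicit `split_point` override is accepted.

Fills (the concatenated random-position bases of one module) are indexed
lexicographically with `A < C < G < T`, i.e. base-4 integers. All count
vectors, enumeration order and tie-breaks use this one ordering.

Template validation computes GC content over the concatenated *fixed*
positions only (the random positions have no defined GC), compares it to the
40–60% design band, and runs a self-hybridization screen: the template with
every `N → A` (adenine pairs with neither fixed G/C-rich anchors readily nor
itself, making it a conservative non-pairing proxy) is folded with the
default engine, and base pairs whose partners are both fixed positions
outside the restriction site are reported. The screen is informational —
a maximum-pairing fold will find *some* pairs in almost any 74-mer, so
pass/fail rests only on parseability, site uniqueness and GC.

## Sequence-space arithmetic

`sequence_space_stats(n, pool, synthesized)` returns the exact space
`4**n` (Python integers, no floating-point overflow at n = 40), the mean
copies per possible sequence for a physical pool, and the fraction of the
space a synthesis covers. These are the quantities that motivate the closed
design: 4¹⁶ ≈ 4.29 × 10⁹ with ~1000 copies per sequence at a 4.29 × 10¹²
pool, versus 4⁴⁰ ≈ 1.2 × 10²⁴ sampled at ~8.3 × 10⁻¹⁰ by a 10¹⁵ synthesis.

## Folding engine

The default engine maximizes base-pair count by Nussinov-style interval
dynamic programming under three constraints: no pseudoknots, hairpin loops
of at least `min_loop = 3` unpaired bases, and helices of at least
`min_helix = 2` contiguous stacked pairs (no isolated pairs, mirroring the
"avoid lonely pairs" convention of thermodynamic folders). Allowed pairs are
Watson–Crick plus G–T wobble; the wobble is a configurable default since DNA
folding conventions differ. The recursion considers, for each interval
start, either leaving the base unpaired or opening a helix of `h ≥
min_helix` pairs to a partner `k`, with the interior interval scored
recursively; a helix whose interior contains no room for pairs must enclose
at least `min_loop` unpaired bases. Co-optimal structures are resolved
deterministically (pair the 5'-most base if possible, prefer the outermost
partner, then the longest helix), so outputs are reproducible byte for
byte.

This is a combinatorial engine, not a thermodynamic one: it reproduces the
qualitative design arguments (contiguous complements like `GGGCCC` cannot
fold; spacing them as `GGGAAACCC` yields a hairpin) and is exact in pair
count — the test suite checks equality against exhaustive enumeration of
all valid pair sets for short sequences. Minimum-free-energy folding at a
given temperature and salt is delegated to a pluggable engine interface
(`rnafold_engine` shells out to ViennaRNA's `RNAfold` when the binary is
present); every analysis function accepts any `seq -> DotBracket` callable.

## Structure annotation and diversity

Unpaired positions are classified by the loop their innermost enclosing
pair closes: no enclosed branch → hairpin (H); one branch with unpaired
bases on one side only → bulge (B); one branch, both sides → internal loop
(I); two or more branches → multiloop (M); not enclosed at all → external /
dangling end (E). Paired positions are stems (S). This is the standard
six-class loop decomposition of nested secondary structures; pseudoknots
and finer segment taxonomies are out of scope.

Ensemble summaries are an element × position relative-abundance matrix
(columns sum to 1), the per-position Shannon diversity
`H_j = −Σ_e p_ej log₂ p_ej` in bits (0 for a degenerate column, log₂6 ≈
2.585 at the uniform maximum — base 2 chosen as the conventional unit), and
per-element motif statistics (mean number of maximal same-label runs per
sequence and mean run length).

Sequence sampling is uniform over the joint fill space with uniqueness
enforced (index permutation for spaces up to 2²², rejection sampling above)
and fully determined by the seed.

## Module counting

Reads are matched against a module's fixed positions at their expected
offsets with no indel tolerance and a default budget of one mismatch across
the fixed anchors; both the read and its reverse complement are tried
(forward preferred). Matching reads contribute the bases at their random
offsets as a fill; reads failing length, anchor, or containing an ambiguous
base in the fill are tallied in a rejection ledger, never silently dropped,
so `accepted + rejected` always equals the input record count. Reads
shorter or longer than the module amplicon are rejected rather than
partially matched, avoiding ambiguous offset inference; primer tails from
library preparation can be handled upstream (trimming) or by supplying a
template whose fixed context includes them. Internally, extraction is
vectorized over read chunks (byte matrices and integer base codes), which
keeps counting at 10⁶–10⁷ reads per sample within seconds.

Frequencies are `counts / total accepted reads` per module, a probability
vector over the 4^w module space.

## Outer-product reconstruction and screening statistics

The joint frequency surface `f(a, b) = f_A[a] · f_B[b]` is represented by an
accessor that exposes one module-A row at a time; the 4¹⁶-cell surface is
never materialized (a dense convenience path exists for spaces ≤ 4⁸, used
only by tests and small analyses). Replicate statistics (mean and sample
standard deviation, `ddof = 1` as the conventional estimator over triplicate
designs; configurable) stream the same way. With a single replicate the
standard deviation is 0 by convention and flagged.

The z statistic divides the mean-frequency difference between conditions by
the average of their standard deviations, floored at `eps`. A handful of
replicates easily produces near-zero standard deviations by chance, which
would inflate z without bound; the default floor is one count at the median
sample depth (`1 / median total reads`), i.e. differences are never scored
against a precision finer than the sequencing resolution. Fold values floor
the denominator at `pseudo = 0.5 / median total reads` (half a count) so a
sequence absent from a counter selection yields a large finite fold rather
than infinity; both floors are parameters.

Top-k selection is exact, not approximate: per row, the k best entries
under the full ordering (z descending, then target mean frequency
descending, then lexicographic sequence index ascending) are selected; a
global pruned buffer of at most 4k keys then yields exactly the k best
cells of the full space with O(k + row) memory. Tests verify equality with
a brute-force sort of the materialized space.

The counter-target screen retains a candidate only if its fold against
every thresholded counter condition meets that threshold — the in-silico
analogue of immune tolerance over a closed, re-usable sequence set.
Thresholds are configuration: published screens combine several filters
whose exact cutoffs are not specified, so the package exposes them
per-counter rather than hard-coding any.

**Known artifact, kept visible.** Because only module marginals are
observed, enriching one sequence raises the reconstructed frequency of
every sequence sharing either of its modules, and with several enriched
sequences the cross terms (module A of one binder with module B of another)
are *indistinguishable* from true joint enrichment — the reconstructed
surface is rank one. The tests assert this behavior rather than masking
it, and the recovery metrics are designed around it (see below).

## The selection simulator

The simulator is the package's ground truth generator, emulating the
triplicate single-round design:

- **Pool**: each replicate's full-sequence abundance vector is an
  independent symmetric Dirichlet draw. The concentration parameter is the
  expected copies per sequence in the physical pool (default 1000, the
  redundancy the closed design targets), giving ~3% replicate-to-replicate
  coefficient of variation — independent draws per replicate mimic
  independently prepared selections rather than resampling one pool.
- **Selection**: each planted binder's abundance is multiplied by its
  enrichment factor, then the vector is renormalized; binders are tied to a
  condition family (the target, or a named counter-target), and no other
  selection mechanism is modeled.
- **Sequencing**: one multinomial draw at the configured depth (default
  5 × 10⁶ reads per sample, the depth at which each 65,536-sequence module
  averages ~76 copies); every drawn molecule contributes one module-A and
  one module-B amplicon (the two module read sets share the draw, as a
  restriction digest implies). Reads receive independent per-base
  substitution errors at a default rate of 10⁻³, typical of short-read
  platforms; indels are not modeled, matching the no-indel extraction
  contract.

The production 8+8 template implies a 4¹⁶ abundance vector that cannot be
materialized, so simulations run at reduced width — the template's surplus
random positions are frozen to `A`, keeping anchors, site and split
identical. The default is 4+4 (65,536 full sequences); all screening code
is width-invariant, so nothing in the analysis path is specific to the
reduced scale. What the simulator does *not* emulate: PCR amplification
bias (the single-round design's motivation, not a mechanism of it), binding
thermodynamics, carry-over between conditions, or read-quality structure.
Passing recovery tests therefore demonstrate the statistical machinery, not
wet-lab performance.

The `TruthManifest` records the planted binders, their realized pre/post
frequencies per replicate, and the *analytic outer-product expectations*:
the expected enriched joint distribution is computed in closed form, its
module marginals taken, and their outer product gives the frequency surface
the pipeline should reconstruct. The expected fold of a binder is the ratio
of these surfaces between conditions — deliberately much smaller than the
raw enrichment factor (a 50× joint enrichment at 4+4 width dilutes to a
~1.4× outer-product fold), because that is what marginal counting can see.
Recovery reports score a screen by each binder's z rank, the fraction
inside a top window, and the relative error of estimated versus analytic
fold.

## Problem sizes used in the checks

End-to-end validation runs at 4+4 module widths, three replicates per
condition, 10⁶ reads per module sample, five target binders at 50× and two
counter binders at 40×: all five target binders land inside the top 100 of
65,536 by z, estimated folds sit within a few percent of the analytic
expectation (checked at 25%), and both counter binders are removed at fold
threshold 1. Streamed statistics are checked for exact agreement with dense
materialized computation over randomized instances at widths 2–4, and the
folding engine for exact pair-count agreement with exhaustive enumeration
over random sequences up to 12 nt. Smaller depths are used in unit tests
purely to keep them quick; the statistics scale with depth, not with any
test-specific tuning.

## Degenerate inputs and edge conventions

- Empty samples: frequency of a zero-read table raises rather than
  returning NaNs.
- `n = 1` replicate: standard deviation 0, flagged; the z denominator then
  sits at the `eps` floor.
- `k` larger than the space: the full ranking is returned.
- Binders with factor < 1, fills outside the module space, or unknown
  counter names in thresholds are configuration errors, raised eagerly.
- Module enumeration above a configurable width cap (default 12) raises,
  guarding against accidental 4¹⁶ enumeration.
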