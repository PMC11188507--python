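# Methods

## Interval model

Coordinates are 0-based, half-open (BED convention); chromosome names are
matched as exact strings, with an optional `chr`-prefix harmonizer for
mixed input dialects. Region sets are kept normalized — sorted, with
overlapping *and abutting* intervals merged — so total length is a count of
distinct bases and is invariant under re-normalization. Abutment merging
makes the multi-way partition minimal: adjacent output pieces with
identical support are coalesced.

The Jaccard index of two empty sets is NaN rather than 0: 0/0 is
undefined, and silently reporting 0 would make "no calls at all" look like
"complete discordance". The same convention propagates to precision
(empty query) and recall (empty truth), so a caller that fails to make any
call of a type shows as undefined, not as zero accuracy.

## Consensus scoring

Typing cutoffs compare total copy number against 2 with a 1e-6 equality
tolerance, because several callers emit fractional copy numbers; exactly-2
segments are LOH when the caller flags them or the minor-allele copy
number is 0. Scores are computed on the disjoint partition, so a call
supports an interval iff it covers at least one base of it; at interval
granularity, support is binary by construction.

The replicate grouping is configurable (`center, replicate, group,
divisor` table). The default layout has 21 replicates in five groups with
divisors (1, 1, 1, 3, 1); the 9-replicate group's divisor of 3 caps every
group's contribution at 3 and the per-caller cumulative score at 15. The
cumulative-to-converted mapping (0–3→0, 4–6→1, 7–9→2, 10–15→3) is extended
to the fractional scores that the 9-replicate group can produce by reading
the integer ranges as the half-open bins [0,3], (3,6], (6,9], (9,15] —
the minimal consistent extension.

Two gaps in the published LOH scale (aggregated scores of exactly 8 and
exactly 3 are not assigned a level) are closed downward: 8 → medium and
3 → neutral, preserving the strict ">8" condition for strong evidence. A
total score of 0 is reported as NONE rather than neutral: the published
scale starts at 1, and all-false support cannot arise from partitioning
but can appear after masking edge cases and in degenerate inputs. Callers
with no calls of the requested type anywhere in the cohort are dropped
from that type's scale with a warning, which is how a caller that never
reports LOH yields the five-caller LOH scale.

## Orthogonal validation and benchmark assembly

"Validated by a technology" is per-base, same-type coverage; all rates in
the validation table are length ratios, which is why a region can be 40%
validated. The ≥2-technology region is the union of pairwise intersections
of the per-technology typed regions. Benchmark retention of medium/weak
intervals applies the ≥2 test per base, splitting intervals at support
boundaries.

Conflict resolution removes a gain (loss) base only when orthogonal
evidence there is exclusively opposite-type; any same-type orthogonal
support retains the base. The published rule is stated for strong-evidence
regions; this implementation applies it uniformly to all retained
intervals, as a deliberate extension (non-strong intervals have already
passed the stricter ≥2-technology filter). Breakpoint trimming then makes
gain and loss disjoint: in an overlap of a gain end and a loss end, the
orthogonally supported end keeps its coordinate; if both or neither end is
supported the overlap is split at its midpoint (symmetric and
conservative; each such decision is logged).

Non-redundant clustering of replicate calls (used for orthogonal
technologies measured in replicate) links same-type calls whose two
breakpoints both lie within 10 kb and whose length ratio exceeds 0.5,
single-linkage; the proximity test is applied to both ends, and each
cluster is represented by the median start, end and copy number. The
representative choice and the both-ends reading are this package's own
(the source procedure says only "merged", "within 10 kbp position").

The median copy number attached to each benchmark interval is the median
total copy number over all same-type cohort calls overlapping the
interval.

## Ploidy and re-centering

Overall ploidy is the length-weighted mean total copy number over called
segments (denominator: total called length); it is invariant under
splitting segments. The re-centering shift log2(2/Π) is exact; rounding to
two decimals happens only at presentation.

## Synthetic data

The generator emulates the study conditions at the segment level: a
three-chromosome 60 Mb genome (30/20/10 Mb) with a 2 Mb exclusion mask
standing in for gap regions, segment lengths ~ 200 kb + exponential with
1.5 Mb mean, and type fractions gain 0.45 / LOH 0.20 / loss 0.05 /
neutral 0.30 with gain copy numbers on {3..6}; the expected length-weighted
ploidy is ≈2.82, emulating a hyper-diploid (≈2.85) tumor genome. The truth
draw is redrawn from derived substreams until realized ploidy is within
±0.3 of the target, so the landscape honors the design for any seed. A
paper-scale genome is not used in tests; the compact genome keeps the full
126-call-set pipeline under a few seconds.

Caller noise has four channels, chosen to mirror the failure modes
multi-caller studies observe: per-type sensitivity (default 0.95),
false segments as a Poisson process (default 1 per 100 Mb per replicate,
exponential lengths), rounded-Gaussian breakpoint jitter (default SD 5 kb,
clamped to chromosome bounds, degenerate segments dropped), a minimum
detectable length (50 kb), and whole-replicate ploidy mis-centering
(probability 0 by default; when triggered, all copy numbers shift by an
integer and the genome is re-typed, which converts neutral territory to
gain en masse — the "caller reports ploidy 5" pathology). Orthogonal
technologies use the same channels minus false calls and mis-centering,
with higher sensitivity (0.98), smaller jitter (2 kb) and a coarser size
floor (100–150 kb). All of these defaults are this package's own
characterization; the source study does not quantify its callers' noise.

Randomness uses one root seed with per-stream seeds derived by SHA-256
hashing of (root, caller, center, replicate), so adding a caller or
technology never perturbs existing streams and every artifact is
byte-reproducible.

What the simulation does *not* model: read-level effects (coverage,
mappability, GC), tumor purity titration, correlated errors between
callers sharing a segmentation strategy, sub-clonal copy states, and
fractional copy numbers. Passing the recovery tests therefore shows the
consensus/validation machinery is correct and robust to the modeled noise
channels, not that any particular real caller combination achieves those
accuracies.

## Degenerate inputs and numerical choices

Malformed intervals (start ≥ end) are rejected naming the offending
record; unknown segment-table dialects are rejected listing the registered
ones. Copy-number comparisons use absolute tolerance 1e-6. Benchmark VCF
output converts half-open [s, e) to 1-based POS = s+1 with inclusive
END = e and symbolic alleles `<DUP>`/`<DEL>`/`<LOH>`; the package's reader
(via pysam) round-trips it losslessly. Scored-interval tables, masks and
annotations are plain TSV/BED so every stage can be regenerated from the
previous stage's files.

## Known limitations

- The evaluation offers only length-based metrics; call-count-based
  precision/recall is deliberately not offered because the region-based
  definition is the unambiguous one.
- Midpoint splitting of doubly-supported (or unsupported) gain/loss
  breakpoint overlaps is a tie-break the source procedure leaves
  unspecified; alternatives (e.g. confidence-weighted splits) would change
  few bases but are not implemented.
- The LOH confidence scale is the published five-caller one; the gain/loss
  scale is never applied to LOH totals even though the two coincide
  nowhere except at 0.
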