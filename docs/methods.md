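# Methods

## Signal model and normalization

The unit of evidence is an aligned fragment: a 0-based half-open interval on
a named chromosome, either the insert of a properly paired read pair or a
single-end read extended from its 5′ end to a fixed length (250 bp default)
in the strand direction. Fragments are retained by length — 120–500 bp for
CUT&RUN-style data, 120–1000 bp for CUT&Tag — with both bounds inclusive;
exact-coordinate duplicates can be dropped (first kept), which is idempotent.

Coverage lives on fixed 100-bp bins (the last bin of a chromosome may be
partial). A fragment increments every bin it overlaps by ≥ 1 bp; a
midpoint-assignment mode exists behind a flag but is not the default, because
overlap counting matches coverage semantics for broad domains. Two
normalization factors are supported, both pure rescalings by an arbitrary
constant: spike-in, `N = 10,000 / n_spike_fragments` (comparable across
samples even under global occupancy shifts, since the exogenous chromatin is
constant per cell); and depth, `N = 2.8e9 / n_mapped` (order of the mappable
mammalian genome in bp). The normalized per-fragment increment is applied as
one float multiply over integer bin counts, so bins no fragment touches are
exactly zero and c-fold fragment replication cancels exactly against a
c-fold spike-in count — the scale-invariance property holds to machine
precision, not merely 1e-9.

Replicates are combined by summation of already-normalized tracks (percentile
cutoffs downstream are scale-free, so sum vs mean only rescales). Smoothing
is a running mean spanning ±1,000 bp around each bin; at chromosome ends the
window truncates and divides by the number of included bins, avoiding
artificial decay (an interior impulse spreads to v/21 over 21 bins; at bin 0
it becomes v/11 over the 11 existing bins). Double smoothing is refused to
keep provenance honest.

## Domain calling

The domain cutoff is the smallest observed bin value strictly greater than
the values of F% of all genome-wide bins — nearest-rank, zeros included, each
bin counted once. F defaults to 95; noisy/broad datasets (the SU-DIPG-IV
regime) use 75. A constant track has no qualifying value and raises a
degenerate-distribution error rather than returning an arbitrary cutoff.

Runs of bins ≥ cutoff are linked. Two runs merge when the gap between them is
at most 750 bp (≤ 7 full bins, inclusive) *and* every gap bin holds at least
0.75 × cutoff — the per-bin reading of the jump condition, not a gap mean.
Merging is transitive; domains never span chromosomes; the reported mean
signal averages all included bins, bridged gaps included. Domains are
reported on the bin grid with no sub-bin refinement.

Putative domains are filtered by IgG enrichment:
`log2((mean + ε) / (mean_IgG + ε)) > 2` with a symmetric pseudocount
ε = 0.01 normalized units (keeps zero-IgG regions finite without reordering
ratios). Because the percentile cutoff by construction marks 5% of the genome
regardless of signal quality, the IgG filter is what removes
background-fluctuation calls; on flat (enrichment-free) synthetic data at
shallow IgG depth a few percent of background calls still pass by chance,
which is the expected behavior of the published procedure, not a defect.

An independent utility coalesces externally annotated chromatin-state
segments (e.g., SEGWAY "FacultativeHet") whose ends lie within 500 bp,
transitively, for size-distribution comparisons.

## Unique segments, clustering, classification

Condition-wise domain sets are first `reduce`d (overlapping/bookended
intervals merged), then `disjoin`ed: the atomic intervals induced by the
union of all boundary coordinates. Every output segment is wholly inside or
outside each input domain; their union is bp-identical to the union of
inputs. Both operations are small sweep-line routines validated against
per-bp label-vector oracles, exactly, over thousands of random inputs.

Per-segment features are `log2(mean + ε)` per condition (ε = 0.01),
row-standardized so k-means tracks trajectory shape and magnitude jointly
(raw and unstandardized modes exist behind flags). k-means uses 50 restarts
at a fixed seed; rows are presented to the optimizer in lexicographic order
and labels assigned by nearest final center, which makes the labeling
invariant to input segment order. Clusters are renumbered 1…k by ascending
mean (last − first) log2 change, so cluster 1 is always the strongest loss
and cluster k the strongest gain. With only two conditions, row
standardization collapses features to three distinct points; trajectory
clustering is designed for ≥ 3 time points and k ≤ 3 in the two-condition
case.

Boundary-change classification of treated vs reference: a segment covered by
both is **same** (bp-identity on the bin grid — a one-bin shift already
counts as change); reference-only segments are **shrinking**, including
reference domains that disappeared entirely (full retraction); treated-only
segments are **spreading** when their treated domain still overlaps some
reference domain, otherwise **new**. A domain may contribute both shrinking
and spreading segments (one boundary in, one out); no single domain-level
label is forced. When classification is applied to segments from a
multi-condition disjoin, segments present only in intermediate conditions lie
outside both compared sets; callers choose an error (default) or skipping
(pipeline, with the skipped count logged).

Summaries: per-cluster bp and % bp by category (percentages sum to 100 per
non-empty cluster; empty clusters report zeros and a flag); % of segments per
cluster containing ≥ 1 bp of a feature interval (CpG islands, bivalent
promoters); bp-weighted overlap with a reference domain set; and
center-anchored signal matrices (per-domain rows of bin values around the
domain midpoint, NaN beyond chromosome ends) whose log2-ratio variant zeroes
all positions outside the anchoring domain.

## Bimodal partitioning

Per-segment log2 ratios are binned into 60 equal-width density bins and the
explicit two-component form `A0·exp(−((x−A1)/A2)²) + A3·exp(−((x−A4)/A5)²)`
is fitted by bounded nonlinear least squares to the (bin center, density)
pairs — a histogram-curve fit, deliberately not an EM likelihood fit, to
match the interactive-plotting workflow the formula comes from. `A2`/`A5`
are widths in the `exp(−((x−m)/w)²)` sense (σ = w/√2); component areas
A0·A2, A3·A5 are the mixing weights of the matching sampler used for
testing. Initialization takes the two strongest KDE peaks (25th/75th
percentiles when unimodal), widths at half the peak separation, amplitudes
at peak densities, plus 10 deterministic jittered restarts; lowest residual
sum of squares wins and components are ordered A1 ≤ A4. Non-convergence of
all restarts raises an error carrying the best parameters seen.

Group boundaries: `cut_low = A1 − A2` (one width below the left mean) and
`cut_high` = the x between the means where the two fitted component curves
are equal (closed-form quadratic; midpoint fallback when no crossing lies
between the means). Labels: CL1 below `cut_low` (loss), CL2 between
(limited gain), CL3 at/above `cut_high` (strong gain). Both cuts are
configurable conventions: the three-group idea is canonical, the exact cut
placement is this package's documented choice.

## Statistics

Overlap enrichment between two clusterings uses the hypergeometric
distribution on a shared segment universe. Because independent experiments
segment the genome differently, the universe is built by intersecting the
two segmentations: each atomic intersection piece is one sampling unit
inheriting both parents' cluster labels (a bp-weighted variant is a flag).
For each cluster pair both tails are computed — P(X ≥ k) for enrichment,
P(X ≤ k) for depletion — the smaller is reported with its direction, and
Benjamini–Hochberg correction runs over all pairs × both directions.
BH adjustment itself (statsmodels step-up) preserves input order, never
exceeds 1, and is a fixed point on plateau outputs; it is *not* idempotent
on arbitrary adjusted vectors, which is a property of the procedure, not of
this implementation.

Rank-sum comparisons use exact mid-rank enumeration over all group
assignments for combined n ≤ 20 (correct under ties; two-sided p =
2·min(tails) capped at 1) and the tie-corrected, continuity-corrected normal
approximation otherwise. Null calibration at n = 20 + 20 sits at a 4.8–5.5%
rejection rate at α = 0.05 over 10,000 simulations.

Gene-level summaries consume a precomputed differential-expression table
(chrom, start, end, gene_id, log2fc, padj — produced upstream by standard
RNA-seq tooling, out of scope here); significant genes (|log2FC| > 1,
FDR < 0.05) join every cluster whose segments they overlap by ≥ 1 bp
(multi-membership allowed and counted), and clusters are compared pairwise by
rank-sum with BH adjustment. Groups with a single observation are summarized
but not tested.

## Synthetic data: what it emulates, and what it does not

The generator plants non-overlapping truth domains on a toy genome, each with
per-condition intervals and a scenario — same, shrinking, spreading, new, or
lost — then samples fragments per condition. Target fragment *midpoints*
follow a density model: enrichment_fold inside the condition's present
domains, 1 outside (an optional background_rate mixes in a uniform
genome-wide component; default 0 so the closed-form expectations are exact).
Midpoint placement keeps edge expectations sharp: the expected in-domain
fraction is `fold·p / (fold·p + (1 − p))` for domain bp fraction p. Fragment
lengths are truncated normal (mean 180 bp, sd 40, clipped to [50, 600] bp),
spanning the retention windows so length filters exercise both branches.
Spike-in fragments are uniform over a dedicated genome with `spike_`-prefixed
chromosome names; IgG fragments are uniform over the target genome. One root
seed feeds per-stream derived seeds (truth/target/spike/IgG × condition), so
adding or resizing one stream never perturbs another, and all outputs are
byte-reproducible.

Not emulated: sequence content, mappability gaps, copy-number variation,
fragment-length dependence on chromatin state, PCR-duplicate family
structure, or chromatin-state correlations between IgG and target. Passing
the planted-recovery checks therefore demonstrates algorithmic correctness
of the pipeline under its own stated model, not robustness to artifacts of
real libraries.

### Reference validation scenarios

Two frozen designs (module `scenarios`) exercise the stated study depth —
three replicates × 100,000 fragments, 8-fold enrichment, F = 95, matched
IgG:

* **Caller boundary recovery** (single condition): twenty 12-kb domains on a
  4.8-Mb chromosome, i.e. ~5% domain coverage, so the 95th-percentile cutoff
  falls mid-way up the ±1-kb smoothing ramp at domain edges. This is the
  operating point the percentile rule presumes (F "set based on background
  signal"): called boundaries land within 1–2 bins of truth and no called
  domain is spurious after IgG filtering.
* **Change-category recovery** (two conditions): 25 domains — 9 spreading
  (4 → 16 kb), 9 new (12 kb), 6 shrinking (16 → 4 kb), 1 same (12 kb) —
  exactly 30/30/20/20% of changed bp by category, on a 12-Mb chromosome.
  Coverage is deliberately sparse (1–3%) so both conditions' cutoffs sit
  symmetrically just above background and their (identical) boundary offsets
  cancel in the between-condition comparison; recovered category fractions
  land within ~5–7 percentage points of the planted mix.

The two regimes differ because the percentile cutoff responds to how much of
the genome is enriched: a condition pair whose domain coverages differ
two-fold (forced by the planted change mix) cannot place both cutoffs at the
edge-resolving mid-ramp point simultaneously. Boundary accuracy is therefore
a single-track property, measured on the first design; comparative category
accuracy is measured on the second. Genome sizes and domain geometries were
fixed from this analysis before the validation suite was frozen.

## Numerical and reproducibility choices

* Coordinates are 0-based half-open everywhere; 1-based dialects convert at
  readers.
* Percentile cutoffs use nearest-rank with an 1e-9 slack against float
  round-off in `F·n/100`.
* The IgG pseudocount (0.01), segment-enrichment pseudocount (0.01) and
  mixture histogram bin count (60) are package defaults, configurable.
* k-means determinism: fixed seed, 50 restarts, lexicographic presentation,
  nearest-center labeling, ties to the lowest center index.
* The pipeline's only randomness is the config seed; reruns are
  byte-identical on all text outputs (no timestamps in provenance).
* Degenerate inputs raise early with named offenders: constant tracks, zero
  spike-in counts, unknown chromosomes/conditions, off-grid segments,
  unclassified segments in summaries.

## Known limitations

* The caller's boundary resolution is one smoothing half-span (±1,000 bp);
  no sub-bin refinement is attempted.
* The percentile cutoff presumes an approximately constant enriched-genome
  fraction; strong global gains shift the cutoff with them, and the same
  caveat the spike-in normalization carries for DNA-content differences
  between arrested and cycling cells applies here.
* Trajectory clustering with only two conditions is degenerate under row
  standardization (three distinct feature points).
* The two-component fit is the only mixture considered; no model selection
  beyond the one-vs-two-component residual comparison in the tests.
* `rank_sum`'s exact path enumerates C(n, n1) assignments and is gated to
  combined n ≤ 20.
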