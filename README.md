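# k27domains

Analysis of broad repressive chromatin domains — H3K27me3 facultative
heterochromatin in particular — from fragment-level chromatin profiling data
(CUT&RUN, CUT&Tag, ChIP-seq). The package is for genomicists who need to ask
not just *where* a broad mark is, but *how its domain boundaries move* between
conditions: cell-cycle perturbations, culture-state switches, oncohistone
knockouts.

## What it computes

1. **Normalized coverage tracks.** Fragments (0-based half-open intervals)
   are length-filtered (120–500 bp CUT&RUN, 120–1000 bp CUT&Tag), optionally
   deduplicated, and counted on fixed 100-bp bins: each fragment adds the
   sample's normalization factor *N* to every bin it overlaps. With an
   exogenous spike-in genome, *N* = 10,000 / (spike-in fragment count); for
   plain depth normalization, *N* = 2.8×10⁹ / (mapped reads). Replicates are
   summed and smoothed with a ±1,000-bp running average.

2. **Broad-domain calling.** The *domain cutoff* is the smallest bin value
   greater than the values of *F*% of all genome-wide bins (nearest-rank,
   *F* = 95 by default). Runs of bins ≥ cutoff are linked, bridging gaps of up
   to 750 bp whose bins all hold ≥ 0.75 × cutoff; putative domains are kept
   when their mean signal exceeds matched IgG ≥ 4-fold (log₂ enrichment > 2).

3. **Unique-segment comparison.** Domain sets from several conditions are
   *disjoined* into atomic non-overlapping segments; per-segment enrichment
   trajectories are k-means-clustered (labels ordered loss → gain), and each
   segment of a treated-vs-reference pair is classified **same** /
   **shrinking** / **spreading** / **new**.

4. **Bimodal log₂-ratio partitioning.** Per-segment log₂ ratios between two
   conditions are histogram-fitted with
   `y = A0·exp(−((x−A1)/A2)²) + A3·exp(−((x−A4)/A5)²)`
   and split into three groups at `cut_low = A1 − A2` and `cut_high` = the
   crossing point of the two fitted components.

5. **Statistics.** Hypergeometric overlap enrichment between independent
   segment clusterings (atomic intersection pieces as sampling units),
   Benjamini–Hochberg correction, exact/asymptotic Wilcoxon rank-sum tests,
   per-cluster gene-expression summaries from a precomputed fold-change table.

A synthetic-data module plants domains with known boundary changes in toy
genomes and samples fragment sets around them, so the whole pipeline is
testable without any sequencing download.

## Worked example

`python examples/01_simulate_and_call_domains.py` plants twenty 12-kb domains
on a 4.8-Mb toy chromosome (three replicates × 100,000 fragments, 8-fold
in-domain enrichment), builds the spike-in-normalized smoothed track, and
calls domains back:

```
planted 20 domains of 12 kb on a 4.8-Mb chromosome
domain cutoff (F=95 genome-wide percentile): 54.67 normalized units
called 20 domains after the >4-fold-over-IgG filter:
  chr1:107900-120000  log2(IgG enrichment)=2.56  boundary error vs truth: 100 bp
  chr1:254800-266800  log2(IgG enrichment)=2.38  boundary error vs truth: 0 bp
  ...
```

All twenty planted domains are recovered with boundaries within one or two
bins of truth — the ±1,000-bp smoothing half-span is the method's intrinsic
boundary resolution. `examples/02_compare_conditions.py` continues to the
two-condition comparison: with 30% spreading / 30% new / 20% shrinking / 20%
same planted by bp, the recovered per-cluster category table is

```
         pct_same  pct_shrinking  pct_spreading  pct_new
cluster
1            40.6           59.4            0.0      0.0
2            18.6            0.0           37.7     43.7
```

cluster 1 (losing segments) carries the shrinking bp, cluster 2 (gaining) the
spreading and new bp, and the genome-wide category fractions land within a
few percentage points of the planted mix. The other examples demonstrate the
mixture fit, the overlap statistics, and the one-command pipeline
(`k27domains run --config run.yaml` from a shell, or `run_domain_diff` from
Python).

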