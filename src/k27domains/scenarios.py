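"""Reference synthetic scenarios: the study conditions for validation runs.

Two frozen designs exercise the pipeline end to end:

* :func:`caller_recovery_scenario` — one condition, 20 planted 12-kb domains
  on a 4.8-Mb toy chromosome, so domain-plus-ramp bins span the 95th
  percentile and the cutoff falls mid-ramp: the regime the percentile caller
  is built for, used to measure boundary-recovery accuracy.
* :func:`change_scenario` — two conditions on a 12-Mb chromosome with 25
  planted domains mixing spreading / new / shrinking / same so that exactly
  30% / 30% / 20% / 20% of changed-domain bp falls in each category; domain
  coverage is sparse (1–3%), the regime where both conditions' cutoffs sit
  symmetrically in the background tail, so boundary offsets cancel between
  conditions and category fractions are recovered faithfully.

Both use the criterion-level sequencing depth: three replicates of 100,000
target fragments each, 8-fold in-domain enrichment, matched IgG, spike-in
normalization, 120–500 bp length retention, F = 95.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .coverage import (
    BinGrid,
    CoverageTrack,
    bin_coverage,
    combine_replicates,
    filter_fragments,
    smooth_running_average,
    spike_in_factor,
)
from .simdata import SimConfig, TruthDomain, make_truth_set, simulate_fragments

__all__ = [
    "caller_recovery_scenario",
    "change_scenario",
    "condition_tracks",
    "truth_category_bp",
]

#: planted scenario mix of the two-condition change design (by domain count;
#: by bp this is exactly 30% spreading, 30% new, 20% shrinking, 20% same)
CHANGE_MIX = {"spreading": 0.36, "new": 0.36, "shrinking": 0.24, "same": 0.04}


def caller_recovery_scenario(seed: int) -> tuple[SimConfig, list[TruthDomain]]:
    """Single-condition design for measuring domain-caller boundary accuracy."""
    config = SimConfig(
        chrom_sizes={"chr1": 4_800_000},
        n_target_fragments=100_000,
        n_spike_fragments=10_000,
        enrichment_fold=8.0,
        seed=seed,
    )
    truth = make_truth_set(config, 20, {"same": 1.0}, same_len=12_000)
    return config, truth


def change_scenario(seed: int) -> tuple[SimConfig, list[TruthDomain]]:
    """Two-condition design with the planted 30/30/20/20 change mix (by bp)."""
    config = SimConfig(
        chrom_sizes={"chr1": 12_000_000},
        n_target_fragments=100_000,
        n_spike_fragments=10_000,
        enrichment_fold=8.0,
        seed=seed,
    )
    truth = make_truth_set(
        config, 25, CHANGE_MIX,
        same_len=12_000, new_len=12_000, core_len=4_000, ext_len=6_000,
    )
    return config, truth


def condition_tracks(
    truth: Sequence[TruthDomain],
    condition: str,
    config: SimConfig,
    n_replicates: int = 3,
    min_len: int = 120,
    max_len: int = 500,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Simulate replicates for one condition → (signal, IgG) smoothed tracks.

    Per replicate: sample fragments, apply the length retention window,
    spike-in normalize, bin at 100 bp; replicates are summed and the combined
    track smoothed ±1,000 bp. IgG replicates go through the same path.
    """
    grid = BinGrid(config.chrom_sizes)
    reps, iggs = [], []
    for rep in range(n_replicates):
        rep_config = SimConfig(
            chrom_sizes=config.chrom_sizes,
            n_target_fragments=config.n_target_fragments,
            n_spike_fragments=config.n_spike_fragments,
            enrichment_fold=config.enrichment_fold,
            background_rate=config.background_rate,
            seed=config.seed + 1009 * (rep + 1),
            n_igg_fragments=config.n_igg_fragments,
            spike_chrom_sizes=config.spike_chrom_sizes,
        )
        target, spike, igg = simulate_fragments(truth, condition, rep_config)
        target = filter_fragments(target, min_len, max_len)
        factor = spike_in_factor(len(spike))
        reps.append(bin_coverage(target, grid, factor, sample=f"{condition}_rep{rep + 1}"))
        iggs.append(bin_coverage(igg, grid, factor, sample=f"{condition}_igg_rep{rep + 1}"))
    signal = smooth_running_average(combine_replicates(reps))
    control = smooth_running_average(combine_replicates(iggs))
    return signal, control


def truth_category_bp(
    truth: Sequence[TruthDomain],
    reference: str = "reference",
    treated: str = "treated",
) -> dict[str, int]:
    """Planted change-category bp totals implied by a truth set.

    Derived directly from the per-condition truth intervals (shared bp →
    same; reference-only → shrinking; treated-only of an overlapping domain →
    spreading; treated-only of a reference-absent domain → new), independent
    of any calling or disjoin code.
    """
    bp = {c: 0 for c in ("same", "shrinking", "spreading", "new")}
    for d in truth:
        r = d.per_condition.get(reference)
        t = d.per_condition.get(treated)
        if r is None and t is None:
            continue
        if r is None:
            bp["new"] += t[1] - t[0]
        elif t is None:
            bp["shrinking"] += r[1] - r[0]
        else:
            inter = max(0, min(r[1], t[1]) - max(r[0], t[0]))
            bp["same"] += inter
            bp["shrinking"] += (r[1] - r[0]) - inter
            bp["spreading"] += (t[1] - t[0]) - inter
    return bp
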