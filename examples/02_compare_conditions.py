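"""Compare domain sets from two conditions: disjoin into unique segments,
cluster enrichment trajectories, and classify boundary changes.

Run:  python examples/02_compare_conditions.py
"""

from k27domains import (
    call_domains,
    category_bp_summary,
    classify_change,
    cluster_segments,
    disjoin,
    segment_enrichment,
)
from k27domains.scenarios import change_scenario, condition_tracks, truth_category_bp

# two-condition scenario with planted spreading/new/shrinking/same changes
# (exactly 30/30/20/20 by bp)
config, truth = change_scenario(seed=7)

tracks, domains = {}, {}
for cond in ("reference", "treated"):
    signal, igg = condition_tracks(truth, cond, config)
    tracks[cond] = signal
    domains[cond], cutoff = call_domains(signal, igg)
    print(f"{cond}: cutoff {cutoff:.2f}, {len(domains[cond])} domains")

segments = disjoin(domains)
segments = segment_enrichment(segments, tracks)
segments = cluster_segments(segments, k=2, seed=7)
segments = classify_change(domains["treated"], domains["reference"], segments)

table = category_bp_summary(segments)
print("\nper-cluster % of bp by change category "
      "(cluster 1 = strongest loss, 2 = strongest gain):")
print(table[[c for c in table.columns if c.startswith("pct_")]].round(1))

planted = truth_category_bp(truth)
total = sum(planted.values())
print("\nplanted mix for comparison:",
      {c: f"{100 * v / total:.0f}%" for c, v in planted.items()})
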