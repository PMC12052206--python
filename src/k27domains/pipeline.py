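"""End-to-end orchestration: fragments → tracks → domains → segments → groups.

A run is described by a declarative :class:`RunConfig` (usually a YAML file):
an ordered sample sheet of conditions with fragment/spike-in/IgG replicate
files, a normalization mode, domain-call parameters, a cluster count and one
seed. ``run_domain_diff`` executes every stage, writes plain-text artifacts
(bedGraph tracks, domain BEDs, segment tables, fit JSON, summary TSVs) plus a
provenance log of every effective parameter, and returns the in-memory
results. Reruns with the same config are byte-identical on text outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import (
    BinGrid,
    CoverageTrack,
    bin_coverage,
    combine_replicates,
    dedup_fragments,
    depth_factor,
    filter_fragments,
    smooth_running_average,
    spike_in_factor,
)
from .domains import Domain, DomainCallParams, call_domains, domains_to_frame
from .io import read_bed_fragments, read_chrom_sizes, write_bedgraph
from .mixture import BimodalFit, fit_bimodal, partition_groups
from .segments import (
    UniqueSegment,
    category_bp_summary,
    classify_change,
    cluster_segments,
    disjoin,
    segment_enrichment,
    segments_to_frame,
)

__all__ = [
    "ConditionInputs",
    "RunConfig",
    "ResultBundle",
    "run_domain_diff",
    "run_report",
    "write_demo_dataset",
]


@dataclass
class ConditionInputs:
    """Replicate-level input files for one condition."""

    fragments: list[str]
    spike: list[str] = field(default_factory=list)
    igg: list[str] = field(default_factory=list)
    igg_spike: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    chrom_sizes: str | Mapping[str, int]
    conditions: dict[str, ConditionInputs]      # insertion order: reference first, treated last
    normalization: str = "spike_in"             # "spike_in" | "depth"
    min_len: int = 120
    max_len: int = 500
    dedup: bool = False
    params: DomainCallParams = field(default_factory=DomainCallParams)
    igg_filtering: bool = True
    k: int = 6
    seed: int = 0
    pseudocount: float = 0.01
    smooth_half_span: int = 1000
    out_dir: str = "k27_run"
    write_bigwig: bool = False

    def validate(self) -> None:
        if self.normalization not in ("spike_in", "depth"):
            raise ValueError("normalization must be 'spike_in' or 'depth'")
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions (reference first, treated last)")
        for name, ci in self.conditions.items():
            if not ci.fragments:
                raise ValueError(f"condition {name!r} has no fragment files")
            if self.normalization == "spike_in" and len(ci.spike) != len(ci.fragments):
                raise ValueError(
                    f"condition {name!r}: spike_in normalization needs one spike-in "
                    f"fragment file per replicate"
                )
            if self.igg_filtering and not ci.igg:
                raise ValueError(
                    f"condition {name!r}: IgG filtering is enabled but no IgG files given"
                )
            if (
                self.igg_filtering
                and self.normalization == "spike_in"
                and len(ci.igg_spike) != len(ci.igg)
            ):
                raise ValueError(
                    f"condition {name!r}: spike_in normalization needs one spike-in "
                    f"file per IgG replicate"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        conditions = {
            name: ConditionInputs(**spec) for name, spec in raw.pop("conditions").items()
        }
        params = DomainCallParams(**raw.pop("params", {}))
        return cls(conditions=conditions, params=params, **raw)


@dataclass
class ResultBundle:
    config: RunConfig
    grid: BinGrid
    tracks: dict[str, CoverageTrack]
    igg_tracks: dict[str, CoverageTrack]
    cutoffs: dict[str, float]
    domains: dict[str, list[Domain]]
    segments: list[UniqueSegment]
    fit: BimodalFit | None
    group_labels: np.ndarray | None
    summary: pd.DataFrame | None
    out_dir: Path
    provenance: dict


def _condition_track(
    config: RunConfig, grid: BinGrid, fragment_files, spike_files, sample: str
) -> CoverageTrack:
    reps = []
    for i, frag_path in enumerate(fragment_files):
        frags = read_bed_fragments(frag_path)
        n_mapped = len(frags)
        if config.dedup:
            frags = dedup_fragments(frags)
        frags = filter_fragments(frags, config.min_len, config.max_len)
        if config.normalization == "spike_in":
            factor = spike_in_factor(len(read_bed_fragments(spike_files[i])))
        else:
            factor = depth_factor(n_mapped)
        reps.append(bin_coverage(frags, grid, factor, sample=f"{sample}_rep{i + 1}"))
    combined = combine_replicates(reps)
    return smooth_running_average(combined, config.smooth_half_span)


def run_domain_diff(config: RunConfig) -> ResultBundle:
    """Run every stage of the domain-difference analysis for one config."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom_sizes = (
        read_chrom_sizes(config.chrom_sizes)
        if isinstance(config.chrom_sizes, (str, Path))
        else dict(config.chrom_sizes)
    )
    grid = BinGrid(chrom_sizes)
    conditions = list(config.conditions)

    tracks: dict[str, CoverageTrack] = {}
    igg_tracks: dict[str, CoverageTrack] = {}
    cutoffs: dict[str, float] = {}
    domains: dict[str, list[Domain]] = {}
    for name, ci in config.conditions.items():
        try:
            tracks[name] = _condition_track(config, grid, ci.fragments, ci.spike, name)
            if config.igg_filtering:
                igg_tracks[name] = _condition_track(
                    config, grid, ci.igg, ci.igg_spike, f"{name}_IgG"
                )
            doms, cutoff = call_domains(
                tracks[name], igg_tracks.get(name), config.params
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'domains' failed for condition {name!r}: {exc}") from exc
        cutoffs[name] = cutoff
        domains[name] = doms
        write_bedgraph(tracks[name], out / f"track_{name}.bedgraph")
        if config.write_bigwig:
            from .io import write_bigwig

            write_bigwig(tracks[name], out / f"track_{name}.bw")
        _write_domains_bed(doms, out / f"domains_{name}.bed")

    segments = disjoin(domains)
    n_skipped = 0
    fit = None
    group_labels = None
    summary = None
    seg_frame = pd.DataFrame()
    if segments:
        segments = segment_enrichment(segments, tracks, config.pseudocount)
        try:
            segments = cluster_segments(segments, config.k, config.seed)
        except ValueError as exc:
            raise RuntimeError(f"stage 'clustering' failed: {exc}") from exc
        classified = classify_change(
            domains[conditions[-1]], domains[conditions[0]], segments, on_outside="skip"
        )
        n_skipped = len(segments) - len(classified)
        segments = classified
        summary = category_bp_summary(segments)
        summary.to_csv(out / "category_summary.tsv", sep="\t")
        values = np.array([s.log2_row[-1] - s.log2_row[0] for s in segments])
        if len(values) >= 100:
            fit = fit_bimodal(values)
            group_labels = partition_groups(values, fit)
            with open(out / "mixture_fit.json", "w") as fh:
                json.dump(
                    {k: (v if np.isfinite(v) else None) for k, v in asdict(fit).items()},
                    fh, indent=2, sort_keys=True,
                )
        seg_frame = segments_to_frame(segments, conditions)
        if group_labels is not None:
            seg_frame["group"] = group_labels
        seg_frame.to_csv(out / "segments.tsv", sep="\t", index=False)
        _write_segments_bed(segments, out / "segments.bed", conditions, group_labels)

    provenance = {
        "version": __version__,
        "normalization": config.normalization,
        "length_window": [config.min_len, config.max_len],
        "dedup": config.dedup,
        "domain_params": asdict(config.params),
        "smooth_half_span": config.smooth_half_span,
        "pseudocount": config.pseudocount,
        "k": config.k,
        "seed": config.seed,
        "cutoffs": cutoffs,
        "conditions": conditions,
        "n_segments": len(segments),
        "n_segments_outside_compared_pair": n_skipped,
        "n_domains": {c: len(domains[c]) for c in conditions},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return ResultBundle(
        config=config, grid=grid, tracks=tracks, igg_tracks=igg_tracks, cutoffs=cutoffs,
        domains=domains, segments=segments, fit=fit, group_labels=group_labels,
        summary=summary, out_dir=out, provenance=provenance,
    )


def _write_domains_bed(domains, path) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(domains, start=1):
            score = 0
            if np.isfinite(d.log2_igg):
                score = int(min(max(round(100 * d.log2_igg), 0), 1000))
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\tdomain_{i}\t{score}\t.\n")


def _write_segments_bed(segments, path, conditions, group_labels) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(segments):
            extras = "\t".join(f"{v:.6g}" for v in s.log2_row)
            group = group_labels[i] if group_labels is not None else "."
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\tseg_{i + 1}\t0\t.\t"
                f"{extras}\t{s.cluster}\t{s.category}\t{group}\n"
            )


def write_demo_dataset(
    root,
    seed: int = 3,
    n_fragments: int = 30_000,
    enrichment_fold: float = 8.0,
    n_replicates: int = 2,
    genome_size: int = 3_000_000,
    n_domains: int = 8,
):
    """Small two-condition synthetic dataset on disk, ready for a RunConfig.

    Plants ``n_domains`` with an equal mix of spreading / new / shrinking /
    same changes and writes per-replicate target, spike-in and IgG fragment
    BEDs plus a chrom.sizes table. Returns (chrom_sizes_path, conditions,
    truth_domains).
    """
    from .io import write_bed_fragments, write_chrom_sizes
    from .simdata import SimConfig, make_truth_set, simulate_fragments

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    base = SimConfig(chrom_sizes={"chr1": genome_size}, n_target_fragments=n_fragments,
                     n_spike_fragments=max(n_fragments // 10, 1000),
                     enrichment_fold=enrichment_fold, seed=seed)
    truth = make_truth_set(
        base, n_domains,
        {"spreading": 0.25, "new": 0.25, "shrinking": 0.25, "same": 0.25},
    )
    conditions = {}
    for cond in ("reference", "treated"):
        ci = ConditionInputs(fragments=[], spike=[], igg=[], igg_spike=[])
        for rep in range(n_replicates):
            rep_cfg = SimConfig(chrom_sizes=base.chrom_sizes,
                                n_target_fragments=n_fragments,
                                n_spike_fragments=base.n_spike_fragments,
                                enrichment_fold=enrichment_fold,
                                seed=seed + 101 * (rep + 1))
            target, spike, igg = simulate_fragments(truth, cond, rep_cfg)
            for name, frame, bucket in (
                ("frags", target, ci.fragments),
                ("spike", spike, ci.spike),
                ("igg", igg, ci.igg),
                ("igg_spike", spike, ci.igg_spike),
            ):
                p = root / f"{cond}_rep{rep}_{name}.bed"
                write_bed_fragments(frame, p)
                bucket.append(str(p))
        conditions[cond] = ci
    sizes_path = root / "chrom.sizes"
    write_chrom_sizes(base.chrom_sizes, sizes_path)
    return str(sizes_path), conditions, truth


def run_report(bundle: ResultBundle, out_dir=None) -> list[Path]:
    """Render heatmap, category bars and mixture-fit figures to static files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir) if out_dir is not None else bundle.out_dir / "report"
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    conditions = list(bundle.tracks)

    if not bundle.segments:
        fig, ax = plt.subplots(figsize=(6, 2))
        ax.text(0.5, 0.5, "no domains called", ha="center", va="center", fontsize=16)
        ax.axis("off")
        p = out / "report.png"
        fig.savefig(p)
        plt.close(fig)
        return [p]

    # cluster heatmap of per-segment log2 trajectories
    order = np.argsort([s.cluster for s in bundle.segments], kind="stable")
    mat = np.vstack([bundle.segments[i].log2_row for i in order])
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(mat, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_xticks(range(len(conditions)), conditions, rotation=45, ha="right")
    ax.set_ylabel("unique segments (by cluster)")
    fig.colorbar(im, ax=ax, label="log2(mean + eps)")
    p = out / "cluster_heatmap.png"
    fig.tight_layout()
    fig.savefig(p)
    plt.close(fig)
    written.append(p)

    # per-cluster category bp percentages
    if bundle.summary is not None:
        pct = bundle.summary[[c for c in bundle.summary.columns if c.startswith("pct_")]]
        fig, ax = plt.subplots(figsize=(6, 4))
        bottom = np.zeros(len(pct))
        for col in pct.columns:
            ax.bar(pct.index.astype(str), pct[col], bottom=bottom, label=col[4:])
            bottom += pct[col].to_numpy()
        ax.set_xlabel("cluster")
        ax.set_ylabel("% bp")
        ax.legend()
        p = out / "category_bars.png"
        fig.tight_layout()
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    if bundle.fit is not None:
        from .mixture import bimodal_model

        values = np.array(
            [s.log2_row[-1] - s.log2_row[0] for s in bundle.segments]
        )
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(values, bins=60, density=True, alpha=0.5, label="segments")
        xs = np.linspace(values.min(), values.max(), 400)
        ax.plot(xs, bimodal_model(xs, *bundle.fit.params), "r-", label="bimodal fit")
        ax.axvline(bundle.fit.cut_low, color="k", ls="--", label="cut_low")
        ax.axvline(bundle.fit.cut_high, color="k", ls=":", label="cut_high")
        ax.set_xlabel("log2 ratio (treated / reference)")
        ax.set_ylabel("density")
        ax.legend()
        p = out / "mixture_fit.png"
        fig.tight_layout()
        fig.savefig(p)
        plt.close(fig)
        written.append(p)
    return written
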