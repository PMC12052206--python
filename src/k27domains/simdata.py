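"""Synthetic fragment data with planted domains and known change scenarios.

The generator builds a toy genome, plants non-overlapping enriched domains
whose boundaries are *same*, *shrinking*, *spreading*, *new* or *lost* between
a reference and a treated condition, and samples fragment sets per condition:

* target fragments — midpoints placed by a density model (density ∝
  ``enrichment_fold`` inside a condition's present domains, 1 outside), with
  an optional ``background_rate`` fraction placed uniformly genome-wide;
* spike-in fragments — uniform over a dedicated exogenous genome whose
  chromosome names are prefixed ``spike_``, so one BED can carry both genomes;
* IgG fragments — uniform over the target genome (flat background control).

Fragment lengths follow a truncated normal (mean 180 bp, sd 40 bp, clipped to
[50, 600] bp), spanning the usual retention windows so length filters exercise
both keep and drop branches. All randomness flows from one root seed through
per-stream derived seeds, so adding a stream never perturbs another.

Every downstream stage of the pipeline can therefore be verified against
closed-form expectations without touching real sequencing data. The
two-component log2-ratio sampler lives in :mod:`k27domains.mixture` and is
re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import DEFAULT_BIN_WIDTH
from .io import _open_text
from .mixture import simulate_log2_mixture  # noqa: F401  (module surface)

__all__ = [
    "SimConfig",
    "TruthDomain",
    "SCENARIOS",
    "make_truth_set",
    "simulate_fragments",
    "simulate_log2_mixture",
    "write_truth_bed",
]

SCENARIOS = ("same", "shrinking", "spreading", "new", "lost")

_STREAM_IDS = {"truth": 1, "target": 2, "spike": 3, "igg": 4, "lengths": 5}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic experiment.

    Chromosome lengths must be multiples of ``bin_width`` so binned
    expectations are exact.
    """

    chrom_sizes: Mapping[str, int]
    n_target_fragments: int = 100_000
    n_spike_fragments: int = 10_000
    fraglen_mean: float = 180.0
    fraglen_sd: float = 40.0
    fraglen_min: int = 50
    fraglen_max: int = 600
    background_rate: float = 0.0
    enrichment_fold: float = 8.0
    seed: int = 0
    n_igg_fragments: int | None = None
    spike_chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"spike_chr1": 1_000_000}
    )
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        for chrom, size in {**dict(self.chrom_sizes), **dict(self.spike_chrom_sizes)}.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
            if size % self.bin_width:
                raise ValueError(
                    f"chromosome {chrom!r} length {size} is not a multiple of the "
                    f"{self.bin_width}-bp bin width"
                )
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must lie in [0, 1]")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.fraglen_mean <= 0 or self.fraglen_sd < 0:
            raise ValueError("fragment length parameters must be positive")
        if not 1 <= self.fraglen_min <= self.fraglen_max:
            raise ValueError("need 1 <= fraglen_min <= fraglen_max")

    @property
    def igg_fragments(self) -> int:
        return self.n_target_fragments if self.n_igg_fragments is None else self.n_igg_fragments


@dataclass
class TruthDomain:
    """A planted domain with per-condition intervals and a change scenario.

    ``start``/``end`` give the union footprint over all conditions;
    ``per_condition`` maps condition name to a (start, end) tuple or ``None``
    when the domain is absent in that condition.
    """

    chrom: str
    start: int
    end: int
    per_condition: dict[str, tuple[int, int] | None]
    scenario: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty truth domain")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for cond, iv in self.per_condition.items():
            if iv is not None and iv[1] <= iv[0]:
                raise ValueError(f"empty interval for condition {cond!r}")

    @property
    def conditions(self) -> list[str]:
        return list(self.per_condition)


def _stream_rng(config: SimConfig, stream: str, condition: str = "") -> np.random.Generator:
    entropy = [config.seed, _STREAM_IDS[stream]] + list(condition.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _scenario_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"scenario fractions sum to {total}, not 1")
    for sc in mix:
        if sc not in SCENARIOS:
            raise ValueError(f"unknown scenario {sc!r}; known: {SCENARIOS}")
    raw = {sc: n * f for sc, f in mix.items()}
    counts = {sc: int(np.floor(v)) for sc, v in raw.items()}
    short = n - sum(counts.values())
    for sc in sorted(mix, key=lambda s: raw[s] - counts[s], reverse=True)[:short]:
        counts[sc] += 1
    return counts


def make_truth_set(
    config: SimConfig,
    n_domains: int,
    scenario_mix: Mapping[str, float],
    conditions: Sequence[str] = ("reference", "treated"),
    same_len: int = 12_000,
    new_len: int = 12_000,
    core_len: int = 4_000,
    ext_len: int = 6_000,
    min_gap: int = 5_000,
) -> list[TruthDomain]:
    """Place ``n_domains`` non-overlapping truth domains on the toy genome.

    Geometry per scenario (first condition = reference, last = treated):
    ``same``/``lost`` occupy ``same_len``; ``new`` occupies ``new_len``;
    ``spreading`` grows from a ``core_len`` reference interval by ``ext_len``
    on each side; ``shrinking`` retracts the mirror-image way. Footprints are
    bin-aligned and separated by at least ``min_gap`` bp so smoothing and gap
    jumping cannot merge neighbours. Deterministic for a given config seed.
    """
    if len(conditions) < 2:
        raise ValueError("need at least a reference and a treated condition")
    rng = _stream_rng(config, "truth")
    counts = _scenario_counts(n_domains, scenario_mix)
    ref, treat = conditions[0], conditions[-1]
    w = config.bin_width

    footprints: list[tuple[str, int]] = []  # (scenario, footprint length)
    for sc in SCENARIOS:
        for _ in range(counts.get(sc, 0)):
            if sc in ("same", "lost"):
                L = same_len
            elif sc == "new":
                L = new_len
            else:
                L = core_len + 2 * ext_len
            if L % w:
                raise ValueError("domain lengths must be multiples of the bin width")
            footprints.append((sc, L))
    order = rng.permutation(len(footprints))
    footprints = [footprints[i] for i in order]

    # allocate domains to chromosomes by length (largest remainder)
    chroms = list(config.chrom_sizes)
    total_len = sum(config.chrom_sizes.values())
    raw_share = {c: len(footprints) * config.chrom_sizes[c] / total_len for c in chroms}
    n_per = {c: int(np.floor(raw_share[c])) for c in chroms}
    for c in sorted(chroms, key=lambda c: raw_share[c] - n_per[c], reverse=True)[
        : len(footprints) - sum(n_per.values())
    ]:
        n_per[c] += 1

    domains: list[TruthDomain] = []
    idx = 0
    for chrom in chroms:
        n_c = n_per[chrom]
        if n_c == 0:
            continue
        chunk = footprints[idx : idx + n_c]
        idx += n_c
        need = sum(L for _, L in chunk) + min_gap * (n_c + 1)
        size = int(config.chrom_sizes[chrom])
        if need > size:
            raise ValueError(
                f"cannot place {n_c} domains on {chrom!r} ({size} bp): "
                f"{need} bp required including {min_gap}-bp gaps"
            )
        free = size - sum(L for _, L in chunk) - min_gap * (n_c + 1)
        extra = np.diff(np.concatenate(([0], np.sort(rng.uniform(0, free, n_c)), [free])))
        pos = min_gap
        for (sc, L), pad in zip(chunk, extra[:-1]):
            start = (pos + int(pad)) // w * w
            end = start + L
            pos = start + L + min_gap
            per: dict[str, tuple[int, int] | None] = {c: None for c in conditions}
            if sc == "same":
                for c in conditions:
                    per[c] = (start, end)
            elif sc == "lost":
                per[ref] = (start, end)
                for c in conditions[1:-1]:
                    per[c] = (start, end)
            elif sc == "new":
                per[treat] = (start, end)
            elif sc == "spreading":
                per[ref] = (start + ext_len, end - ext_len)
                per[treat] = (start, end)
            elif sc == "shrinking":
                per[ref] = (start, end)
                per[treat] = (start + ext_len, end - ext_len)
            # intermediate conditions interpolate between reference and treated
            mids = conditions[1:-1]
            for j, c in enumerate(mids, start=1):
                if sc in ("spreading", "shrinking"):
                    frac = j / (len(mids) + 1)
                    shift = int(round(ext_len * frac / w)) * w
                    if sc == "spreading":
                        per[c] = (start + ext_len - shift, end - ext_len + shift)
                    else:
                        per[c] = (start + shift, end - shift)
                elif sc == "new":
                    per[c] = None
            domains.append(TruthDomain(chrom, start, end, per, sc))
    domains.sort(key=lambda d: (d.chrom, d.start))
    return domains


def _interval_sampler(intervals: list[tuple[str, int, int]]):
    """Uniform-per-bp midpoint sampler over a list of (chrom, start, end)."""
    lens = np.array([e - s for _, s, e in intervals], dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(lens)))

    def sample(rng: np.random.Generator, n: int):
        offs = rng.integers(0, cum[-1], size=n)
        which = np.searchsorted(cum, offs, side="right") - 1
        chrom_idx = which
        local = offs - cum[which]
        return chrom_idx, local

    return sample, cum[-1]


def _make_fragments(
    rng: np.random.Generator,
    intervals: list[tuple[str, int, int]],
    chrom_idx: np.ndarray,
    local: np.ndarray,
    lengths: np.ndarray,
    chrom_sizes: Mapping[str, int],
) -> pd.DataFrame:
    chroms = np.array([iv[0] for iv in intervals])
    starts = np.array([iv[1] for iv in intervals], dtype=np.int64)
    mid = starts[chrom_idx] + local
    frag_start = mid - lengths // 2
    frag_end = frag_start + lengths
    names = chroms[chrom_idx]
    sizes = np.array([chrom_sizes[c] for c in names], dtype=np.int64)
    frag_start = np.maximum(frag_start, 0)
    frag_end = np.minimum(frag_end, sizes)
    frag_end = np.maximum(frag_end, frag_start + 1)
    return pd.DataFrame({"chrom": names, "start": frag_start, "end": frag_end})


def _lengths(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    raw = rng.normal(config.fraglen_mean, config.fraglen_sd, size=n)
    return np.clip(np.round(raw), config.fraglen_min, config.fraglen_max).astype(np.int64)


def simulate_fragments(
    truth: Sequence[TruthDomain],
    condition: str,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample (target, spike-in, IgG) fragment sets for one condition.

    Target midpoints appear inside the condition's present truth intervals at
    ``enrichment_fold`` × the background density in expectation (plus a
    uniform component of weight ``background_rate``); spike-in midpoints are
    uniform over the spike genome; IgG midpoints are uniform over the target
    genome. Deterministic given the config seed, stream and condition.
    """
    if truth:
        known = truth[0].conditions
        if condition not in known:
            raise ValueError(f"unknown condition {condition!r}; known conditions: {known}")
    genome = [(c, 0, int(s)) for c, s in config.chrom_sizes.items()]
    present = [
        (d.chrom, *d.per_condition[condition])
        for d in truth
        if d.per_condition.get(condition) is not None
    ]
    # background = genome minus present domains, per chromosome
    background: list[tuple[str, int, int]] = []
    for chrom, _, size in genome:
        pos = 0
        for _, s, e in sorted((p for p in present if p[0] == chrom), key=lambda p: p[1]):
            if s > pos:
                background.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < size:
            background.append((chrom, pos, size))

    rng = _stream_rng(config, "target", condition)
    n = config.n_target_fragments
    dom_bp = sum(e - s for _, s, e in present)
    bg_bp = sum(e - s for _, s, e in background)

    rows = []
    if n > 0:
        uniform_mask = rng.random(n) < config.background_rate
        n_unif = int(uniform_mask.sum())
        n_model = n - n_unif
        if dom_bp > 0:
            p_dom = (config.enrichment_fold * dom_bp) / (
                config.enrichment_fold * dom_bp + bg_bp
            )
        else:
            p_dom = 0.0
        in_dom = rng.random(n_model) < p_dom
        n_dom = int(in_dom.sum())
        lengths = _lengths(rng, config, n)
        pieces = []
        if n_dom:
            sampler, _ = _interval_sampler(present)
            ci, lo = sampler(rng, n_dom)
            pieces.append(_make_fragments(rng, present, ci, lo, lengths[:n_dom], config.chrom_sizes))
        if n_model - n_dom:
            sampler, _ = _interval_sampler(background)
            ci, lo = sampler(rng, n_model - n_dom)
            pieces.append(
                _make_fragments(rng, background, ci, lo,
                                lengths[n_dom:n_model], config.chrom_sizes)
            )
        if n_unif:
            sampler, _ = _interval_sampler(genome)
            ci, lo = sampler(rng, n_unif)
            pieces.append(
                _make_fragments(rng, genome, ci, lo, lengths[n_model:], config.chrom_sizes)
            )
        target = pd.concat(pieces, ignore_index=True) if pieces else _empty_fragments()
    else:
        target = _empty_fragments()

    spike_genome = [(c, 0, int(s)) for c, s in config.spike_chrom_sizes.items()]
    rng_s = _stream_rng(config, "spike", condition)
    if config.n_spike_fragments > 0:
        sampler, _ = _interval_sampler(spike_genome)
        ci, lo = sampler(rng_s, config.n_spike_fragments)
        spike = _make_fragments(
            rng_s, spike_genome, ci, lo,
            _lengths(rng_s, config, config.n_spike_fragments), config.spike_chrom_sizes
        )
    else:
        spike = _empty_fragments()

    rng_i = _stream_rng(config, "igg", condition)
    n_igg = config.igg_fragments
    if n_igg > 0:
        sampler, _ = _interval_sampler(genome)
        ci, lo = sampler(rng_i, n_igg)
        igg = _make_fragments(rng_i, genome, ci, lo,
                              _lengths(rng_i, config, n_igg), config.chrom_sizes)
    else:
        igg = _empty_fragments()
    return target, spike, igg


def _empty_fragments() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def write_truth_bed(truth: Sequence[TruthDomain], path) -> None:
    """Write a truth set as BED6 with the scenario in the name column."""
    with _open_text(path, "wt") as fh:
        for d in truth:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.scenario}\t0\t.\n")
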