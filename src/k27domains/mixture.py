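"""Two-Gaussian partitioning of per-segment log2 fold-change distributions.

Genome-wide distributions of per-segment log2 ratios between two conditions
are often bimodal: a mode of regions that keep (or lose) signal and a mode of
regions that gain strongly. The density histogram is fitted by nonlinear
least squares with the sum of two Gaussian-shaped curves

    y = A0·exp(−((x−A1)/A2)²) + A3·exp(−((x−A4)/A5)²)

where A0, A3 are amplitudes (density height), A1 ≤ A4 the component means and
A2, A5 the component widths (for a normal density this ``w`` equals σ·√2).
Fitted components define three groups of segments:

* CL1: x < cut_low           (cut_low = A1 − A2, one width below the left mean)
* CL2: cut_low ≤ x < cut_high
* CL3: x ≥ cut_high          (cut_high = the x between the means where the two
  component curves cross; midpoint of the means if they never cross there)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde

from .coverage import CoverageTrack
from .segments import UniqueSegment

__all__ = [
    "BimodalFit",
    "FitError",
    "log2_ratio",
    "bimodal_model",
    "fit_bimodal",
    "partition_groups",
    "simulate_log2_mixture",
    "GROUP_LABELS",
]

GROUP_LABELS = ("CL1", "CL2", "CL3")


class FitError(RuntimeError):
    """Raised when no restart of the bimodal fit converges.

    Carries the best parameter vector and residual sum of squares seen, so a
    caller can still inspect the near-miss.
    """

    def __init__(self, message: str, best_params=None, best_rss=float("inf")):
        super().__init__(message)
        self.best_params = best_params
        self.best_rss = best_rss


@dataclass
class BimodalFit:
    A0: float
    A1: float
    A2: float
    A3: float
    A4: float
    A5: float
    rss: float
    cut_low: float
    cut_high: float

    @property
    def params(self) -> np.ndarray:
        return np.array([self.A0, self.A1, self.A2, self.A3, self.A4, self.A5])


def bimodal_model(x, A0, A1, A2, A3, A4, A5):
    """Sum of two Gaussian-shaped curves (amplitude/mean/width per component)."""
    return A0 * np.exp(-(((x - A1) / A2) ** 2)) + A3 * np.exp(-(((x - A4) / A5) ** 2))


def log2_ratio(
    segments: Sequence[UniqueSegment],
    track_num: CoverageTrack,
    track_den: CoverageTrack,
    pseudocount: float = 0.01,
) -> np.ndarray:
    """Per-segment log2((mean_num + ε) / (mean_den + ε))."""
    if (
        track_num.grid.chroms != track_den.grid.chroms
        or track_num.grid.bin_width != track_den.grid.bin_width
    ):
        raise ValueError("numerator and denominator tracks must share a grid")
    w = track_num.grid.bin_width
    out = np.empty(len(segments))
    for i, s in enumerate(segments):
        b0, b1 = s.start // w, -(-s.end // w)
        m_num = track_num.values[s.chrom][b0:b1].mean()
        m_den = track_den.values[s.chrom][b0:b1].mean()
        out[i] = np.log2((m_num + pseudocount) / (m_den + pseudocount))
    return out


def _initial_guesses(values: np.ndarray) -> tuple[np.ndarray, float]:
    """KDE-peak initialization; percentile fallback when unimodal."""
    grid = np.linspace(values.min(), values.max(), 512)
    dens = gaussian_kde(values)(grid)
    peaks = argrelmax(dens)[0]
    if len(peaks) >= 2:
        top = peaks[np.argsort(dens[peaks])[::-1][:2]]
        m1, m2 = sorted(grid[top])
        h1, h2 = dens[top].min(), dens[top].max()
    else:
        m1, m2 = np.percentile(values, [25, 75])
        h1 = h2 = dens.max()
    sep = max(m2 - m1, 1e-3)
    width = sep / 2
    return np.array([h1, m1, width, h2, m2, width]), sep


def fit_bimodal(values: Sequence[float], n_bins: int = 60, n_restarts: int = 10) -> BimodalFit:
    """Least-squares fit of the two-component model to a density histogram.

    The values are binned into ``n_bins`` equal-width density bins and the
    model fitted to (bin center, density) pairs, starting from KDE-derived
    guesses plus jittered restarts; the lowest-RSS converged solution wins and
    components are ordered so A1 ≤ A4. Deterministic for given data.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise ValueError("need at least 100 values for a stable histogram fit")
    if n_bins < 20:
        raise ValueError("n_bins must be at least 20")
    dens, edges = np.histogram(values, bins=n_bins, density=True)
    x = 0.5 * (edges[:-1] + edges[1:])
    p0, sep = _initial_guesses(values)
    rng = np.random.default_rng(0)  # jitter only; fit is deterministic per data
    span = values.max() - values.min()
    lower = [0.0, values.min() - span, 1e-6, 0.0, values.min() - span, 1e-6]
    upper = [np.inf, values.max() + span, 10 * span + 1, np.inf, values.max() + span, 10 * span + 1]
    best, best_rss = None, np.inf
    for r in range(n_restarts):
        p = p0.copy()
        if r > 0:
            p[[1, 4]] += rng.normal(0, 0.1 * sep, size=2)
            p[[2, 5]] *= rng.uniform(0.5, 1.5, size=2)
            p[[0, 3]] *= rng.uniform(0.5, 1.5, size=2)
        p = np.clip(p, lower, upper)
        try:
            popt, _ = curve_fit(bimodal_model, x, dens, p0=p, bounds=(lower, upper),
                                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(((bimodal_model(x, *popt) - dens) ** 2).sum())
        if rss < best_rss - 1e-15:
            best, best_rss = popt, rss
    if best is None:
        raise FitError("bimodal fit failed to converge in all restarts",
                       best_params=None, best_rss=best_rss)
    A0, A1, A2, A3, A4, A5 = best
    if A1 > A4:
        A0, A1, A2, A3, A4, A5 = A3, A4, A5, A0, A1, A2
    fit = BimodalFit(float(A0), float(A1), float(A2), float(A3), float(A4), float(A5),
                     rss=best_rss, cut_low=float("nan"), cut_high=float("nan"))
    fit.cut_low, fit.cut_high = _cut_points(fit)
    return fit


def _cut_points(fit: BimodalFit) -> tuple[float, float]:
    """cut_low = A1 − A2; cut_high = component crossing between the means."""
    cut_low = fit.A1 - fit.A2
    cut_high = None
    # equal component heights: A0 e^{-((x-A1)/A2)^2} = A3 e^{-((x-A4)/A5)^2}
    # -> quadratic a x^2 + b x + c = 0
    if fit.A0 > 0 and fit.A3 > 0:
        ia2, ib2 = 1.0 / fit.A2 ** 2, 1.0 / fit.A5 ** 2
        a = ia2 - ib2
        b = -2 * (fit.A1 * ia2 - fit.A4 * ib2)
        c = fit.A1 ** 2 * ia2 - fit.A4 ** 2 * ib2 - np.log(fit.A0 / fit.A3)
        if abs(a) < 1e-12:
            if abs(b) > 1e-12:
                root = -c / b
                if fit.A1 < root < fit.A4:
                    cut_high = root
        else:
            disc = b * b - 4 * a * c
            if disc >= 0:
                roots = [(-b + s * np.sqrt(disc)) / (2 * a) for s in (+1, -1)]
                inside = [r for r in roots if fit.A1 < r < fit.A4]
                if inside:
                    cut_high = min(inside, key=lambda r: abs(r - (fit.A1 + fit.A4) / 2))
    if cut_high is None:
        cut_high = 0.5 * (fit.A1 + fit.A4)
    return float(cut_low), float(cut_high)


def partition_groups(values: Sequence[float], fit: BimodalFit) -> np.ndarray:
    """Assign each value to CL1/CL2/CL3 by the fit's cut points."""
    values = np.asarray(values, dtype=float)
    labels = np.full(values.shape, "CL2", dtype=object)
    labels[values < fit.cut_low] = "CL1"
    labels[values >= fit.cut_high] = "CL3"
    return labels


def simulate_log2_mixture(A: Sequence[float], n: int, seed: int) -> np.ndarray:
    """Sample the two-component normal mixture that the fit formula describes.

    Component k has mean A1 (resp. A4) and standard deviation A2/√2 (resp.
    A5/√2), and mixing weight proportional to A0·A2 (resp. A3·A5) — the areas
    under the two curves.
    """
    A0, A1, A2, A3, A4, A5 = map(float, A)
    if A2 <= 0 or A5 <= 0:
        raise ValueError("component widths A2 and A5 must be positive")
    w1, w2 = A0 * A2, A3 * A5
    if w1 < 0 or w2 < 0 or w1 + w2 <= 0:
        raise ValueError("component weights must be non-negative and sum to > 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    pick2 = rng.random(n) < w2 / (w1 + w2)
    out = np.where(
        pick2,
        rng.normal(A4, A5 / np.sqrt(2), size=n),
        rng.normal(A1, A2 / np.sqrt(2), size=n),
    )
    return out
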