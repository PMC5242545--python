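"""Localized instability signal (gamma): monotone smoothing, slope
extraction, trend removal, distance normalization and peak calling.

A breakage hot spot at position ``h`` enriches every window distal to
``h``, so it appears as a step in the micronuclear coverage profile.  The
profile is smoothed under a shape constraint — non-decreasing away from the
centromere, or decreasing-then-increasing when the proximal-retention
(rho) effect is active — which suppresses local wiggles unrelated to the
cumulative gain.  gamma is the per-window slope of that smoothed profile;
the fitted quadratic trend slope (clipped at zero) is subtracted, and the
residual slope is multiplied by the distance to the distal telomere
``(L - x)``.  A step produced by a fixed breakage rate at ``h`` has height
proportional to ``1/(L - h)``, so after this normalization equal breakage
rates give equal peak values regardless of position.

Significance is empirical: the detrended gamma values on designated
low-hotspot null chromosomes estimate the null s.d. (after trimming
extreme values); the per-position cutoff is ``k * sigma_null * (L - x)``,
linear in the telomere distance, with the more conservative (larger) null
chromosome s.d. used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .genome import GenomeLayout, WindowGrid
from .normalize import NormalizedTrack
from .trend import TrendResults

__all__ = [
    "GammaTrack",
    "PeakCall",
    "PeakComparison",
    "NullCutoff",
    "monotone_smooth",
    "compute_gamma",
    "normalize_gamma",
    "null_cutoff",
    "call_peaks",
    "compare_peaks",
    "GammaAnalysis",
    "DEFAULT_TRIM",
    "DEFAULT_K",
]

DEFAULT_TRIM = 1e-7
DEFAULT_K = 3.0
DEFAULT_SMOOTH_HALFWIDTH = 0


def _local_mean(values: np.ndarray, halfwidth: int) -> np.ndarray:
    """Symmetric centered moving average with edge-shrunk (still symmetric)
    windows: index ``i`` averages ``[i-h_i, i+h_i]`` with
    ``h_i = min(halfwidth, i, n-1-i)``.

    Symmetry makes the operator exact on linear sequences, and it preserves
    monotonicity: growing/shrinking the window at the edges only adds or
    removes extreme elements on the correct side.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if halfwidth <= 0 or n < 3:
        return v.copy()
    cs = np.concatenate([[0.0], np.cumsum(v)])
    i = np.arange(n)
    h = np.minimum(np.minimum(i, n - 1 - i), halfwidth)
    return (cs[i + h + 1] - cs[i - h]) / (2 * h + 1)


def smoothing_tolerance(iso: np.ndarray, halfwidth: int) -> float:
    """Upper bound on |smooth - isotonic| for the local-averaging smoother.

    The average over ``[i-h, i+h]`` of a monotone sequence lies between
    ``iso[i-h]`` and ``iso[i+h]``, as does ``iso[i]``, so the deviation is
    at most the isotonic fit's range over the widest window.
    """
    iso = np.asarray(iso, dtype=float)
    n = iso.size
    if halfwidth <= 0 or n < 3:
        return 0.0
    i = np.arange(n)
    h = np.minimum(np.minimum(i, n - 1 - i), halfwidth)
    return float(np.max(np.abs(iso[i + h] - iso[i - h])))


def _fill_nan(values: np.ndarray) -> np.ndarray:
    """Linearly interpolate masked (NaN) windows; edges take nearest value."""
    v = np.asarray(values, dtype=float).copy()
    ok = np.isfinite(v)
    if ok.all():
        return v
    if not ok.any():
        raise ValueError("all windows masked")
    idx = np.arange(v.size)
    v[~ok] = np.interp(idx[~ok], idx[ok], v[ok])
    return v


def monotone_smooth(
    values,
    has_rho: bool = False,
    split_window: int = 1000,
    smooth_halfwidth: int = DEFAULT_SMOOTH_HALFWIDTH,
):
    """Shape-constrained smooth of a per-window coverage profile.

    With ``has_rho`` the split point is the argmin of the running median
    (window ``split_window`` points, shrunk to the data size); a monotone
    non-increasing fit is taken before it and a non-decreasing fit after,
    made continuous at the split.  Without ``has_rho`` a single monotone
    non-decreasing fit is used.

    Each arm is an isotonic regression followed by a symmetric local
    average of half-width ``smooth_halfwidth`` windows, which preserves
    the shape constraint exactly, reproduces linear arms exactly, and
    deviates from the raw isotonic fit by at most
    :func:`smoothing_tolerance`.  ``smooth_halfwidth=0`` gives the pure
    isotonic fit.

    Returns ``(smoothed, split_index_or_None)``.
    """
    v = _fill_nan(values)
    n = v.size
    if n < 10:
        raise ValueError(f"monotone_smooth needs >= 10 windows, got {n}")
    x = np.arange(n, dtype=float)
    if not has_rho:
        fit = IsotonicRegression(increasing=True).fit_transform(x, v)
        return _local_mean(fit, smooth_halfwidth), None
    m = min(split_window, n)
    med = pd.Series(v).rolling(m, center=True, min_periods=max(1, m // 2)).median().to_numpy()
    split = int(np.argmin(med))
    # refine to the raw minimum inside the median window (exact on a clean V)
    lo, hi = max(0, split - m // 2), min(n, split + m // 2 + 1)
    split = lo + int(np.argmin(v[lo:hi]))
    split = max(1, min(n - 2, split))
    left = IsotonicRegression(increasing=False).fit_transform(x[: split + 1], v[: split + 1])
    right = IsotonicRegression(increasing=True).fit_transform(x[split:], v[split:])
    # continuity: lowering an endpoint to the joint minimum preserves both
    # shape constraints (it is the minimum of each arm)
    joint = min(left[-1], right[0])
    left[-1] = joint
    right[0] = joint
    left = _local_mean(left, smooth_halfwidth)
    right = _local_mean(right, smooth_halfwidth)
    out = np.concatenate([left[:-1], right])
    return out, split


def _step_eval(midpoints: np.ndarray, values: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Right-continuous step function through (midpoint, value) pairs."""
    idx = np.searchsorted(midpoints, pos, side="right") - 1
    idx = np.clip(idx, 0, values.size - 1)
    return values[idx]


def compute_gamma(smoothed: np.ndarray, grid: WindowGrid, chrom: str) -> np.ndarray:
    """Per-window slope of the smoothed profile, in density per bp.

    The smoothed per-window values are read as a right-continuous step
    function jumping at window midpoints; gamma for window ``i`` is
    ``(S(end_i) - S(start_i)) / window_size``.  A single step of height
    ``h`` therefore yields ``h / w`` exactly in the window containing the
    jump and 0 elsewhere.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.size != grid.n_windows(chrom):
        raise ValueError("smoothed track does not match the grid")
    mids = grid.midpoints(chrom)
    s_start = _step_eval(mids, smoothed, grid.starts(chrom).astype(float))
    s_end = _step_eval(mids, smoothed, grid.ends(chrom).astype(float))
    return (s_end - s_start) / grid.window_size


def normalize_gamma(
    gamma_raw: np.ndarray,
    trend: TrendResults,
    grid: WindowGrid,
    chrom: str,
    trend_scale: float = 1.0,
):
    """Remove the fitted quadratic trend slope and normalize by telomere distance.

    ``gamma_detrended = gamma_raw - max(0, trend_slope(x) * trend_scale)``
    (the clip keeps the decreasing rho arm from manufacturing
    negative-gamma artifacts) and ``gamma_norm = gamma_detrended * (L -
    x)``.  ``trend_scale`` converts the trend's slope onto the scale the
    gamma track was computed on (1/window_size when gamma was taken on
    per-bp densities of per-window counts).
    """
    L = grid.layout.length(chrom)
    x = grid.midpoints(chrom)
    tslope = np.clip(trend.slope_for_length(x, L) * trend_scale, 0.0, None)
    gd = np.asarray(gamma_raw, dtype=float) - tslope
    gn = gd * (L - x)
    return gd, gn


@dataclass(frozen=True)
class NullCutoff:
    """Empirical-null scale: cutoff(x) = k * sigma_null * (L - x)."""

    sigma_null: float
    k: float = DEFAULT_K
    per_chrom_sigma: dict = field(default_factory=dict)

    def cutoff(self, distance_to_telomere) -> np.ndarray:
        return self.k * self.sigma_null * np.asarray(distance_to_telomere, dtype=float)


def null_cutoff(
    gamma_detrended_by_chrom: dict,
    trim: float = DEFAULT_TRIM,
    k: float = DEFAULT_K,
) -> NullCutoff:
    """Estimate sigma_null from detrended gamma on null chromosomes.

    Per chromosome the s.d. is taken over values with magnitude-trimmed
    extremes removed (values greater than ``trim`` dropped); sigma_null is
    the maximum over null chromosomes — the more conservative choice.
    """
    sigmas = {}
    for c, gd in gamma_detrended_by_chrom.items():
        gd = np.asarray(gd, dtype=float)
        gd = gd[np.isfinite(gd)]
        kept = gd[gd <= trim]
        if kept.size == 0:
            raise ValueError(f"null_cutoff: all gamma values on {c} exceed the trim {trim}")
        sigmas[c] = float(np.std(kept, ddof=1))
    sigma = max(sigmas.values())
    return NullCutoff(sigma_null=sigma, k=k, per_chrom_sigma=sigmas)


@dataclass
class GammaTrack:
    """Gamma profiles for one chromosome on the analysis grid."""

    chrom: str
    grid: WindowGrid
    smoothed: np.ndarray
    gamma_raw: np.ndarray
    gamma_detrended: np.ndarray
    gamma_norm: np.ndarray
    cutoff: np.ndarray
    split: Optional[int] = None


@dataclass(frozen=True)
class PeakCall:
    """A significant gamma peak (half-open interval, apex at the max)."""

    chrom: str
    start: int
    end: int
    apex: int
    gamma_norm: float
    cutoff: float
    significant: bool = True

    def overlaps(self, other: "PeakCall") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def call_peaks(
    gamma_norm: np.ndarray,
    cutoff: np.ndarray,
    grid: WindowGrid,
    chrom: str,
    gap: int = 1,
) -> list:
    """Merge runs of supra-cutoff windows into peaks.

    Runs separated by at most ``gap`` sub-cutoff windows are merged; the
    apex is the leftmost argmax of gamma_norm within the run.
    """
    gn = np.asarray(gamma_norm, dtype=float)
    above = np.where(np.isfinite(gn) & (gn > cutoff))[0]
    if above.size == 0:
        return []
    runs = []
    run_start = prev = above[0]
    for i in above[1:]:
        if i - prev <= gap + 1:
            prev = i
        else:
            runs.append((run_start, prev))
            run_start = prev = i
    runs.append((run_start, prev))
    starts, ends = grid.starts(chrom), grid.ends(chrom)
    mids = grid.midpoints(chrom)
    peaks = []
    for a, b in runs:
        seg = gn[a : b + 1]
        apex_i = a + int(np.argmax(seg))  # argmax is leftmost on ties
        peaks.append(
            PeakCall(
                chrom=chrom,
                start=int(starts[a]),
                end=int(ends[b]),
                apex=int(mids[apex_i]),
                gamma_norm=float(gn[apex_i]),
                cutoff=float(cutoff[apex_i]),
            )
        )
    return peaks


@dataclass
class PeakComparison:
    """Matched peaks between two conditions with per-peak fold changes."""

    common: list  # (peak_a, peak_b, fold_change)
    unique_a: list
    unique_b: list

    @property
    def mean_fold_change(self) -> float:
        if not self.common:
            return float("nan")
        return float(np.mean([fc for _, _, fc in self.common]))


def compare_peaks(peaks_a: Sequence[PeakCall], peaks_b: Sequence[PeakCall], match_dist: int) -> PeakComparison:
    """Match peaks across conditions by interval overlap or apex proximity.

    Fold change for a matched pair is ``gamma_norm_a / gamma_norm_b``.
    Matching is greedy by apex distance; each peak matches at most once.
    """
    candidates = []
    for i, a in enumerate(peaks_a):
        for j, b in enumerate(peaks_b):
            if a.chrom != b.chrom:
                continue
            if a.overlaps(b) or abs(a.apex - b.apex) <= match_dist:
                candidates.append((abs(a.apex - b.apex), i, j))
    candidates.sort()
    used_a, used_b = set(), set()
    common = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = peaks_a[i], peaks_b[j]
        fc = a.gamma_norm / b.gamma_norm if b.gamma_norm > 0 else float("inf")
        common.append((a, b, fc))
    unique_a = [p for i, p in enumerate(peaks_a) if i not in used_a]
    unique_b = [p for j, p in enumerate(peaks_b) if j not in used_b]
    return PeakComparison(common, unique_a, unique_b)


class GammaAnalysis:
    """Run the full gamma stage over a normalized track.

    Converts per-window values to per-bp tag densities (value /
    window_size, so gamma magnitudes and the trim threshold live on the
    density-per-bp scale), smooths every chromosome under its shape
    constraint, extracts gamma, removes the fitted trend slope, estimates
    the empirical-null cutoff on the designated null chromosomes and calls
    significant peaks.
    """

    def __init__(
        self,
        track: NormalizedTrack,
        trend: TrendResults,
        null_chroms: Sequence[str] = ("chr7", "chr11"),
        has_rho: Optional[dict] = None,
        trim: float = DEFAULT_TRIM,
        k: float = DEFAULT_K,
        gap: int = 1,
        split_window: int = 1000,
        smooth_halfwidth: int = DEFAULT_SMOOTH_HALFWIDTH,
        density_scale: bool = True,
        edge_guard: Optional[int] = None,
    ):
        self.track = track
        self.trend = trend
        self.null_chroms = tuple(null_chroms)
        self.trim = trim
        self.k = k
        self.gap = gap
        self.split_window = split_window
        self.smooth_halfwidth = smooth_halfwidth
        # isotonic fits spike at sequence boundaries; gamma is zeroed there
        self.edge_guard = smooth_halfwidth + 2 if edge_guard is None else edge_guard
        self.scale = 1.0 / track.grid.window_size if density_scale else 1.0
        if has_rho is None:
            # auto: rho arm enabled genome-wide when its bootstrap CI sits above 0
            try:
                rho_on = trend.rho_significant()
            except RuntimeError:
                rho_on = False
            has_rho = {c: rho_on for c in track.values}
        self.has_rho = has_rho

    def run(self) -> "GammaResults":
        tracks = {}
        gd_null = {}
        for c in self.track.grid.layout.chrom_names:
            if c not in self.track.values:
                continue
            sm, split = monotone_smooth(
                self.track.values[c] * self.scale,
                has_rho=self.has_rho.get(c, False),
                split_window=self.split_window,
                smooth_halfwidth=self.smooth_halfwidth,
            )
            graw = compute_gamma(sm, self.track.grid, c)
            gd, gn = normalize_gamma(graw, self.trend, self.track.grid, c, trend_scale=self.scale)
            g = self.edge_guard
            if g > 0 and gd.size > 2 * g:
                gd[:g] = gd[-g:] = 0.0
                gn[:g] = gn[-g:] = 0.0
            tracks[c] = (sm, split, graw, gd, gn)
            if c in self.null_chroms:
                gd_null[c] = gd
        if not gd_null:
            raise ValueError("no null chromosomes present in the track")
        nc = null_cutoff(gd_null, trim=self.trim, k=self.k)
        out = {}
        peaks = []
        for c, (sm, split, graw, gd, gn) in tracks.items():
            L = self.track.grid.layout.length(c)
            dist = L - self.track.grid.midpoints(c)
            cut = nc.cutoff(dist)
            out[c] = GammaTrack(c, self.track.grid, sm, graw, gd, gn, cut, split)
            peaks.extend(call_peaks(gn, cut, self.track.grid, c, gap=self.gap))
        return GammaResults(out, peaks, nc)


@dataclass
class GammaResults:
    tracks: dict  # chrom -> GammaTrack
    peaks: list
    null: NullCutoff

    def peaks_to_bed(self, path) -> None:
        """Write peaks as BED6 (score = 1000-capped gamma_norm/cutoff ratio)."""
        with open(path, "w") as fh:
            for i, p in enumerate(self.peaks):
                ratio = p.gamma_norm / p.cutoff if p.cutoff > 0 else 0.0
                score = int(min(1000, round(100 * ratio)))
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i + 1}\t{score}\t+\n")
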