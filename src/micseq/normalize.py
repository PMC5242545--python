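"""GRN-ratio normalization, per-chromosome baseline (alpha) estimation and
depth scaling.

The granulocyte (GRN) fraction carries the same GC, library and strain
biases as the micronuclear (MN) fraction but none of the micronucleation
biology, so dividing MN window counts by GRN window counts cancels any
shared multiplicative window bias.  Windows whose GRN count is zero or
falls outside mean +/- k s.d. of the genome-wide GRN counts are masked.
The ratio is rescaled by the mean GRN count so normalized values stay on
the count scale.

alpha, the per-chromosome baseline representation, is estimated as the
minimum over all runs of ``m`` consecutive unmasked windows of the run
median.  This ignores the quadratic distance trends and is therefore a
documented slight over-estimate.  Samples are then depth-scaled by the
median ratio of reference-to-sample alpha over chromosomes without strong
baseline changes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout, WindowGrid
from .io import CoverageTrack

log = logging.getLogger(__name__)

__all__ = [
    "NormalizedTrack",
    "AlphaEstimate",
    "grn_normalize",
    "estimate_alpha",
    "alphas_for_track",
    "depth_scale",
    "DEFAULT_EXCLUDE_CHROMS",
    "DEFAULT_RUN_LENGTH",
]

# chromosomes with strong baseline shifts in the deficient condition are
# excluded from depth scaling so biology does not masquerade as depth
DEFAULT_EXCLUDE_CHROMS = ("chr6", "chr12", "chr15", "chr16", "chr18", "chr19", "chrX")
DEFAULT_RUN_LENGTH = 1000


@dataclass
class NormalizedTrack:
    """MN counts ratio-normalized by GRN, with a per-window validity mask."""

    grid: WindowGrid
    values: dict  # chrom -> float array; NaN where masked
    mask: dict  # chrom -> bool array, True = valid
    scale_factor: float = 1.0

    def copy(self) -> "NormalizedTrack":
        return NormalizedTrack(
            self.grid,
            {c: v.copy() for c, v in self.values.items()},
            {c: m.copy() for c, m in self.mask.items()},
            self.scale_factor,
        )

    def chrom_values(self, chrom) -> np.ndarray:
        return self.values[chrom]

    def to_tsv(self, path) -> None:
        rows = []
        for c in self.grid.layout.chrom_names:
            if c not in self.values:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": c,
                        "start": self.grid.starts(c),
                        "end": self.grid.ends(c),
                        "value": self.values[c],
                        "mask": self.mask[c].astype(int),
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        with open(path, "w") as fh:
            fh.write(
                f"# micseq normalized w={self.grid.window_size} s={self.grid.step} "
                f"scale_factor={self.scale_factor:.10g}\n"
            )
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, layout: GenomeLayout) -> "NormalizedTrack":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(tok.split("=", 1) for tok in header[1:].split() if "=" in tok)
            df = pd.read_csv(fh, sep="\t")
        grid = WindowGrid(layout, int(meta["w"]), int(meta["s"]))
        values, mask = {}, {}
        for c, g in df.groupby("chrom", sort=False):
            values[c] = g["value"].to_numpy(dtype=float)
            mask[c] = g["mask"].to_numpy(dtype=bool)
        return cls(grid, values, mask, float(meta.get("scale_factor", 1.0)))


@dataclass(frozen=True)
class AlphaEstimate:
    """Per-chromosome baseline: minimum sliding median over m windows."""

    alpha: float
    run_length: int


def grn_normalize(mn: CoverageTrack, grn: CoverageTrack, sd_k: float = 3.0) -> NormalizedTrack:
    """Divide MN window counts by GRN window counts, masking GRN outliers.

    Windows whose GRN count is 0 or lies outside mean +/- ``sd_k`` s.d. of
    the genome-wide GRN counts are masked.  Unmasked values are
    ``mn / grn * mean(grn)``, preserving the MN count scale.  Any window
    bias applied multiplicatively to both fractions cancels exactly.
    """
    if mn.grid != grn.grid:
        raise ValueError("MN and GRN tracks must share a window grid")
    all_grn = np.concatenate([grn.counts[c] for c in grn.grid.layout.chrom_names])
    mu, sd = float(np.mean(all_grn)), float(np.std(all_grn))
    lo, hi = mu - sd_k * sd, mu + sd_k * sd
    values, mask = {}, {}
    n_masked = n_total = 0
    for c in mn.grid.layout.chrom_names:
        g = grn.counts[c]
        m = (g > 0) & (g >= lo) & (g <= hi)
        v = np.full(g.shape, np.nan)
        v[m] = mn.counts[c][m] / g[m] * mu
        values[c], mask[c] = v, m
        n_masked += int((~m).sum())
        n_total += m.size
    if n_masked > 0.5 * n_total:
        warnings.warn(f"grn_normalize: {n_masked}/{n_total} windows masked (>50%)")
    return NormalizedTrack(mn.grid, values, mask, 1.0)


def estimate_alpha(values: np.ndarray, m: int = DEFAULT_RUN_LENGTH) -> AlphaEstimate:
    """Minimum over runs of ``m`` consecutive unmasked windows of the median.

    ``values`` may contain NaN for masked windows; the run is taken over
    consecutive *unmasked* data points.  If fewer than ``m`` unmasked
    windows exist, ``m`` shrinks to that count with a warning.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("estimate_alpha: no unmasked windows")
    if v.size < m:
        warnings.warn(f"estimate_alpha: only {v.size} windows, shrinking run length from {m}")
        m = v.size
    med = pd.Series(v).rolling(m).median().to_numpy()[m - 1 :]
    return AlphaEstimate(alpha=float(np.min(med)), run_length=m)


def alphas_for_track(track: NormalizedTrack, m: int = DEFAULT_RUN_LENGTH) -> dict:
    """Per-chromosome alpha estimates for a normalized track."""
    return {c: estimate_alpha(track.values[c], m).alpha for c in track.values}


def depth_scale(
    samples: list,
    exclude_chroms=DEFAULT_EXCLUDE_CHROMS,
    reference: int = 0,
    m: int = DEFAULT_RUN_LENGTH,
):
    """Scale samples to comparable depth using per-chromosome alpha ratios.

    For each sample the factor is the median over non-excluded chromosomes
    of ``alpha_reference / alpha_sample``; the reference sample gets factor
    exactly 1.  Returns ``(scaled_tracks, factors)``.
    """
    if len(samples) < 2:
        raise ValueError("depth_scale needs at least 2 samples")
    exclude = set(exclude_chroms or ())
    chroms = [c for c in samples[0].grid.layout.chrom_names if c not in exclude and c in samples[0].values]
    if not chroms:
        raise ValueError("depth_scale: all chromosomes excluded")
    alphas = [{c: estimate_alpha(s.values[c], m).alpha for c in chroms} for s in samples]
    ref = alphas[reference]
    scaled, factors = [], []
    for i, s in enumerate(samples):
        if i == reference:
            f = 1.0
        else:
            ratios = [ref[c] / alphas[i][c] for c in chroms if alphas[i][c] > 0]
            if not ratios:
                raise ValueError(f"depth_scale: sample {i} has no positive alphas")
            f = float(np.median(ratios))
        out = s.copy()
        for c in out.values:
            out.values[c] = out.values[c] * f
        out.scale_factor = s.scale_factor * f
        scaled.append(out)
        factors.append(f)
    return scaled, factors
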