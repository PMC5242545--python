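"""Repeat-compartment representation: rDNA and satellite tag ratios.

Reads mapped to an augmented reference carrying the 45S rDNA unit and the
concatenated major (MaSat) and minor (MiSat) satellite consensus contigs
are counted per compartment; enrichment between samples is judged by
regressing rDNA tags on MaSat tags across samples and flagging points
above the 95% prediction band of the baseline cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genome import GenomeLayout
from .io import FragmentRecord, DEFAULT_MIN_MAPQ

__all__ = ["RepeatCounts", "RatioRegression", "count_repeats", "ratio_regression", "DEFAULT_COMPARTMENTS"]

DEFAULT_COMPARTMENTS = ("rDNA45S", "MaSat", "MiSat")


@dataclass
class RepeatCounts:
    """Per-compartment tag counts and the derived ratios for one sample."""

    sample: str
    fraction: str
    counts: dict  # compartment | "genome" -> int

    def ratio(self, num: str, den: str) -> Optional[float]:
        d = self.counts.get(den, 0)
        if d <= 0:
            return None
        return self.counts.get(num, 0) / d

    @property
    def ratios(self) -> dict:
        total = sum(self.counts.values())
        out = {
            "rDNA/MaSat": self.ratio("rDNA45S", "MaSat"),
            "MaSat/MiSat": self.ratio("MaSat", "MiSat"),
        }
        out["rDNA/total"] = self.counts.get("rDNA45S", 0) / total if total > 0 else None
        return out

    def to_row(self) -> dict:
        row = {"sample": self.sample, "fraction": self.fraction}
        row.update(self.counts)
        row.update(self.ratios)
        return row


def count_repeats(
    fragments: Iterable[FragmentRecord],
    layout: GenomeLayout,
    compartments: Sequence[str] = DEFAULT_COMPARTMENTS,
    sample: str = "NA",
    fraction: str = "NA",
    genome_min_mapq: int = DEFAULT_MIN_MAPQ,
    compartment_min_mapq: int = 0,
) -> RepeatCounts:
    """Count retained tags per repeat compartment and the standard genome.

    Compartment assignment is by target contig name.  Repeat arrays are
    near-identical copies, so most repeat reads multi-map and carry low
    mapping quality; compartment contigs therefore use their own MAPQ
    floor (default 0) while genomic counts keep the strict ``> 20`` rule.
    Proper-pair and duplicate filters apply everywhere.
    """
    comp = set(compartments)
    counts = {c: 0 for c in compartments}
    counts["genome"] = 0
    seen_comp = False
    if isinstance(fragments, pd.DataFrame):
        df = fragments
        keep = df["proper_pair"].astype(bool) & ~df["duplicate"].astype(bool)
        df = df.loc[keep]
        chrom = df["chrom"]
        mapq = df["mapq"].to_numpy()
        is_comp = chrom.isin(comp).to_numpy()
        seen_comp = bool(is_comp.any())
        for c in compartments:
            counts[c] = int(((chrom == c).to_numpy() & (mapq >= compartment_min_mapq)).sum())
        in_genome = chrom.isin(set(layout.chrom_names)).to_numpy()
        counts["genome"] = int((in_genome & (mapq > genome_min_mapq)).sum())
    else:
        for frag in fragments:
            if not frag.proper_pair or frag.duplicate:
                continue
            if frag.chrom in comp:
                seen_comp = True
                if frag.mapq >= compartment_min_mapq:
                    counts[frag.chrom] += 1
            elif frag.chrom in layout:
                if frag.mapq > genome_min_mapq:
                    counts["genome"] += 1
    if not seen_comp and all(counts[c] == 0 for c in compartments):
        raise ValueError(
            "no compartment contigs present in the input; map against the "
            f"augmented reference carrying {', '.join(compartments)}"
        )
    return RepeatCounts(sample=sample, fraction=fraction, counts=counts)


@dataclass
class RatioRegression:
    """Least-squares line of rDNA tags on MaSat tags with 95% prediction band."""

    slope: float
    intercept: float
    included: pd.DataFrame  # sample, x, y, band_lo, band_hi, flagged
    excluded: pd.DataFrame
    _fit: object = field(default=None, repr=False)

    @property
    def flagged(self) -> list:
        rows = pd.concat([self.included, self.excluded], ignore_index=True)
        return rows.loc[rows.flagged, "sample"].tolist()

    def band(self, x) -> tuple:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        pred = self._fit.get_prediction(sm.add_constant(x, has_constant="add"))
        fr = pred.summary_frame(alpha=0.05)
        return fr["obs_ci_lower"].to_numpy(), fr["obs_ci_upper"].to_numpy()


def ratio_regression(
    points: pd.DataFrame,
    exclude: Sequence[str] = (),
    alpha: float = 0.05,
) -> RatioRegression:
    """Fit the baseline x-y line and flag enriched samples.

    ``points`` needs columns ``sample``, ``x`` (MaSat tags), ``y`` (rDNA
    tags).  Samples in ``exclude`` are left out of the fit (the suspected
    enriched condition); any point — included or excluded — lying above the
    upper 95% pointwise prediction band is flagged as enriched.
    """
    pts = points.copy()
    excl = pts["sample"].isin(set(exclude))
    inc = pts.loc[~excl]
    if len(inc) < 3:
        raise ValueError("ratio_regression needs >= 3 included points")
    if np.std(inc["x"].to_numpy(dtype=float)) == 0:
        raise ValueError("degenerate x variance in included points")
    X = sm.add_constant(inc["x"].to_numpy(dtype=float))
    fit = sm.OLS(inc["y"].to_numpy(dtype=float), X).fit()
    intercept, slope = fit.params

    def annotate(df):
        if df.empty:
            df = df.copy()
            for col in ("band_lo", "band_hi", "flagged"):
                df[col] = pd.Series(dtype=float if col != "flagged" else bool)
            return df
        Xp = sm.add_constant(df["x"].to_numpy(dtype=float), has_constant="add")
        fr = fit.get_prediction(Xp).summary_frame(alpha=alpha)
        df = df.copy()
        df["band_lo"] = fr["obs_ci_lower"].to_numpy()
        df["band_hi"] = fr["obs_ci_upper"].to_numpy()
        df["flagged"] = df["y"].to_numpy(dtype=float) > df["band_hi"].to_numpy()
        return df

    return RatioRegression(
        slope=float(slope),
        intercept=float(intercept),
        included=annotate(inc.reset_index(drop=True)),
        excluded=annotate(pts.loc[excl].reset_index(drop=True)),
        _fit=fit,
    )
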