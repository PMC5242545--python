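"""End-to-end orchestration: count -> QC -> pool -> normalize -> trend ->
gamma -> peaks -> compare -> repeats.

Replicates of a condition are pooled by summing fragment tables after an
inter-replicate Pearson correlation check (sex chromosomes excluded, since
animals differ in sex); pooled data supports the finer 20 kb / 10 kb grid.
All randomness (the trend bootstrap) derives from the single run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .genome import GenomeLayout, WindowGrid
from .normalize import (
    DEFAULT_EXCLUDE_CHROMS,
    DEFAULT_RUN_LENGTH,
    alphas_for_track,
    depth_scale,
    grn_normalize,
)
from .gamma import DEFAULT_K, DEFAULT_TRIM, GammaAnalysis, compare_peaks
from .trend import DEFAULT_NULL_CHROMS, fit_trend

log = logging.getLogger(__name__)

__all__ = ["Sample", "RunConfig", "run_all", "replicate_correlation", "pool_fragments"]

SEX_CHROMS = ("chrX", "chrY")


@dataclass(frozen=True)
class Sample:
    sample: str
    fraction: str  # MN | GRN | WBC
    condition: str
    path: str  # fragment TSV


@dataclass
class RunConfig:
    samples: list
    layout: GenomeLayout
    window: int = 40_000
    step: int = 20_000
    pooled_window: int = 20_000
    pooled_step: int = 10_000
    control_condition: str = "wt"
    null_chroms: tuple = DEFAULT_NULL_CHROMS
    exclude_chroms: tuple = DEFAULT_EXCLUDE_CHROMS
    alpha_run_length: int = DEFAULT_RUN_LENGTH
    min_mapq: int = 20
    max_insert_quantile: float = 0.999
    trim: float = DEFAULT_TRIM
    k: float = DEFAULT_K
    gap: int = 1
    match_dist: int = 20_000
    boot_reps: int = 1000
    boot_frac: float = 0.5
    qc_floor: float = 0.9
    seed: int = 0

    def __post_init__(self):
        mn_grn = [s for s in self.samples if s.fraction == "GRN" and s.condition == self.control_condition]
        if not mn_grn:
            raise ValueError("run config needs a GRN sample in the control condition")
        for c in self.null_chroms:
            if c not in self.layout:
                raise ValueError(f"null chromosome {c!r} not in layout")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        layout = GenomeLayout.from_chrom_sizes(base / raw["chrom_sizes"])
        samples = [Sample(**s) for s in raw["samples"]]
        for s in samples:
            if not (base / s.path).exists():
                raise FileNotFoundError(f"sample {s.sample}: input {s.path} not found")
        kw = {k: v for k, v in raw.items() if k not in ("chrom_sizes", "samples")}
        for key in ("null_chroms", "exclude_chroms"):
            if key in kw:
                kw[key] = tuple(kw[key])
        samples = [Sample(s.sample, s.fraction, s.condition, str(base / s.path)) for s in samples]
        return cls(samples=samples, layout=layout, **kw)


def replicate_correlation(tracks: Sequence[mio.CoverageTrack], exclude_chroms=SEX_CHROMS) -> pd.DataFrame:
    """Pairwise Pearson r between replicate window counts (sex chroms excluded)."""
    rows = []
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            a, b = tracks[i], tracks[j]
            chroms = [c for c in a.grid.layout.chrom_names if c not in exclude_chroms]
            va = np.concatenate([a.counts[c] for c in chroms])
            vb = np.concatenate([b.counts[c] for c in chroms])
            r = float(np.corrcoef(va, vb)[0, 1]) if va.size > 1 else float("nan")
            rows.append({"i": i, "j": j, "pearson_r": r})
    return pd.DataFrame(rows)


def pool_fragments(frames: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool replicate fragment tables (equivalent to summing window counts)."""
    return pd.concat(list(frames), ignore_index=True)


def _load_filtered(path, layout, min_mapq, quantile):
    df = pd.read_csv(path, sep="\t", comment="#")
    lengths = np.sort((df["end"] - df["start"]).to_numpy())
    if lengths.size == 0:
        raise ValueError(f"{path}: empty fragment table")
    max_insert = int(lengths[max(0, int(np.ceil(quantile * lengths.size)) - 1)])
    return mio.filter_fragments_frame(df, layout, max_insert=max_insert, min_mapq=min_mapq)


def run_all(config: RunConfig, outdir, force: bool = False) -> dict:
    """Execute the full pipeline; returns the report dict (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = config.layout
    grid = WindowGrid(layout, config.window, config.step)
    pooled_grid = WindowGrid(layout, config.pooled_window, config.pooled_step)
    report = {"seed": config.seed, "qc": [], "scale_factors": {}, "trend": {}, "peaks": {}}

    # ---- load, filter, count per sample -----------------------------------
    frags = {}
    tracks = {}
    for s in config.samples:
        fl = _load_filtered(s.path, layout, config.min_mapq, config.max_insert_quantile)
        frags[s.sample] = (s, fl)
        tracks[s.sample] = mio.count_windows(fl, grid, fraction=s.fraction)

    # ---- QC: replicate correlations within condition x fraction ------------
    groups = {}
    for s in config.samples:
        groups.setdefault((s.condition, s.fraction), []).append(s.sample)
    for (cond, frac), ids in groups.items():
        if len(ids) < 2:
            report["qc"].append({"condition": cond, "fraction": frac, "note": "single sample, QC skipped"})
            continue
        qc = replicate_correlation([tracks[i] for i in ids])
        for row in qc.itertuples(index=False):
            r = row.pearson_r
            entry = {
                "condition": cond,
                "fraction": frac,
                "pair": (ids[row.i], ids[row.j]),
                "pearson_r": round(r, 6),
            }
            if r < config.qc_floor:
                entry["warning"] = f"below QC floor {config.qc_floor}"
                if not force:
                    log.warning("QC r=%.3f below floor for %s/%s; pooling anyway (use force to silence)", r, cond, frac)
            report["qc"].append(entry)

    # ---- pool per condition x fraction, recount on the fine grid -----------
    pooled = {}
    for (cond, frac), ids in groups.items():
        merged = pool_fragments([frags[i][1] for i in ids])
        pooled[(cond, frac)] = mio.count_windows(merged, pooled_grid, fraction=frac)

    # ---- normalize each condition's MN against the control GRN -------------
    ref_grn = pooled.get((config.control_condition, "GRN"))
    if ref_grn is None:
        raise RuntimeError("control-condition GRN track missing after pooling")
    conditions = sorted({c for (c, f) in pooled if f == "MN"},
                        key=lambda c: (c != config.control_condition, c))
    norm = {}
    for cond in conditions:
        norm[cond] = grn_normalize(pooled[(cond, "MN")], ref_grn)

    # ---- depth scaling across conditions ------------------------------------
    if len(conditions) > 1:
        scaled, factors = depth_scale(
            [norm[c] for c in conditions],
            exclude_chroms=config.exclude_chroms,
            reference=0,
            m=config.alpha_run_length,
        )
        norm = dict(zip(conditions, scaled))
        report["scale_factors"] = {c: round(f, 6) for c, f in zip(conditions, factors)}
    else:
        report["scale_factors"] = {conditions[0]: 1.0}

    # ---- trend + gamma per condition ----------------------------------------
    results = {}
    for idx, cond in enumerate(conditions):
        t = norm[cond]
        t.to_tsv(outdir / f"norm_{cond}.tsv")
        res = fit_trend(t, null_chroms=config.null_chroms)
        res.bootstrap(frac=config.boot_frac, reps=config.boot_reps, seed=config.seed + idx)
        report["trend"][cond] = res.to_dict()
        ga = GammaAnalysis(
            t, res, null_chroms=config.null_chroms, trim=config.trim, k=config.k, gap=config.gap
        ).run()
        ga.peaks_to_bed(outdir / f"peaks_{cond}.bed")
        results[cond] = ga
        report["peaks"][cond] = {
            "n_peaks": len(ga.peaks),
            "sigma_null": ga.null.sigma_null,
            "alpha": alphas_for_track(t, m=config.alpha_run_length),
        }

    # ---- compare each non-control condition against the control -------------
    report["comparisons"] = {}
    ctrl = conditions[0]
    for cond in conditions[1:]:
        cmp = compare_peaks(results[cond].peaks, results[ctrl].peaks, match_dist=config.match_dist)
        report["comparisons"][f"{cond}_vs_{ctrl}"] = {
            "common": len(cmp.common),
            "unique_condition": len(cmp.unique_a),
            "unique_control": len(cmp.unique_b),
            "mean_fold_change": round(cmp.mean_fold_change, 4) if cmp.common else None,
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
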