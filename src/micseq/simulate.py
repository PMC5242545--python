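"""Forward model of micronuclear fragment coverage with ground truth.

The generator targets the observed functional form of micronuclear
coverage rather than a mechanistic cell model.  Fragment midpoints on each
chromosome follow an inhomogeneous Poisson (or gamma-Poisson) process with
per-bp intensity

    lambda(x) = a_c + B x^2 + R (L - x)^2 + sum_h I_h / (L - h) * 1[x >= h]

where ``a_c`` is the whole-chromosome baseline (micronucleation of intact
chromosomes plus genomic contamination), the ``B x^2`` term arises from
acentric fragments — a break at ``p`` populates everything distal of ``p``,
and break consequence grows linearly toward the distal end — the ``R``
term is the converse proximal-retention effect, and each hot spot ``h``
contributes an expected ``I_h`` fragments spread uniformly over ``[h, L]``
(a coverage step of height ``I_h / (L - h)``).

On a window grid of size ``w`` the implied count-scale trend parameters
are exact:

    alpha_c = a_c w + (B + R) w^3 / 12,   beta = B w,   rho = R w.

A shared multiplicative window bias field (log-normal, piecewise constant
on bias bins) multiplies the expected counts of BOTH the MN and GRN
fractions, emulating GC/strain/library bias; the GRN intensity is uniform
before bias.  Counts are Poisson by default or negative binomial
(gamma-Poisson) to emulate over-dispersion in real libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout, WindowGrid
from .io import FRAGMENT_COLUMNS

__all__ = ["Hotspot", "SimulationConfig", "SimulatedDataset", "simulate_mn", "simulate_repeats", "default_layout"]


def default_layout() -> GenomeLayout:
    """Desk-scale five-chromosome layout; chr7/chr11 serve as trend nulls."""
    return GenomeLayout.from_dict(
        {"chr1": 100_000_000, "chr2": 90_000_000, "chr3": 80_000_000,
         "chr7": 70_000_000, "chr11": 60_000_000}
    )


@dataclass(frozen=True)
class Hotspot:
    chrom: str
    position: int
    intensity: float  # expected fragments contributed by the hot spot


@dataclass
class SimulationConfig:
    """Study conditions for the forward model.

    Intensities are per bp of chromosome: ``alpha0`` ~7.5e-4 gives ~30
    baseline fragments per 40 kb window; the default distal coefficient
    roughly doubles coverage at the far end of a 100 Mb chromosome and the
    proximal coefficient is an order of magnitude weaker, visible only on
    the longest chromosomes — the wild-type phenomenology.
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    alpha0: float | dict = 7.5e-4  # fragments per bp, scalar or per-chromosome
    distal_coeff: float = 1.5e-19  # B, fragments per bp^3
    proximal_coeff: float = 1.5e-20  # R, fragments per bp^3
    hotspots: tuple = ()
    bias_sd: float = 0.2  # log-normal sigma of the shared window bias
    bias_bin: int = 20_000
    grn_per_bp: float = 7.5e-4
    depth_factor: float = 1.0  # multiplies all MN and GRN intensities
    noise: str = "poisson"  # "poisson" | "nb"
    nb_dispersion: float = 0.05
    insert_mean: float = 300.0
    insert_sd: float = 60.0
    seed: int = 0

    def alpha_per_bp(self, chrom) -> float:
        if isinstance(self.alpha0, dict):
            return float(self.alpha0[chrom])
        return float(self.alpha0)

    # -- closed-form expectations -------------------------------------------------

    def expected_bin_counts(self, chrom: str, edges: np.ndarray, fraction: str = "MN") -> np.ndarray:
        """Exact integral of the intensity over [edges[i], edges[i+1])."""
        L = self.layout.length(chrom)
        u, v = edges[:-1].astype(float), edges[1:].astype(float)
        d = self.depth_factor
        if fraction == "GRN":
            return d * self.grn_per_bp * (v - u)
        a = self.alpha_per_bp(chrom)
        B, R = self.distal_coeff, self.proximal_coeff
        mu = a * (v - u) + B * (v**3 - u**3) / 3.0 + R * ((L - u) ** 3 - (L - v) ** 3) / 3.0
        for h in self.hotspots:
            if h.chrom != chrom:
                continue
            ov = np.clip(np.minimum(v, L) - np.maximum(u, h.position), 0.0, None)
            mu = mu + h.intensity / (L - h.position) * ov
        return d * mu

    def true_params(self, grid: WindowGrid) -> dict:
        """Implied count-scale trend parameters on ``grid`` (exact)."""
        w = grid.window_size
        d = self.depth_factor
        B, R = self.distal_coeff, self.proximal_coeff
        alpha = {
            c: d * (self.alpha_per_bp(c) * w + (B + R) * w**3 / 12.0)
            for c in self.layout.chrom_names
        }
        return {"alpha": alpha, "beta": d * B * w, "rho": d * R * w}


@dataclass
class SimulatedDataset:
    """Fragment tables per fraction plus the generating truth."""

    config: SimulationConfig
    mn: pd.DataFrame
    grn: pd.DataFrame
    bias: dict  # chrom -> per-bias-bin multiplier array
    truth_hotspots: tuple

    def true_params(self, grid: WindowGrid) -> dict:
        return self.config.true_params(grid)


def _bin_edges(L: int, bin_size: int) -> np.ndarray:
    edges = np.arange(0, L, bin_size, dtype=np.int64)
    return np.append(edges, L)


def _draw_counts(rng, mu: np.ndarray, noise: str, disp: float) -> np.ndarray:
    if noise == "poisson":
        return rng.poisson(mu)
    if noise == "nb":
        lam = np.where(mu > 0, rng.gamma(1.0 / disp, mu * disp), 0.0)
        return rng.poisson(lam)
    raise ValueError(f"unknown noise model {noise!r}")


def _fragments_for_chrom(rng, chrom, L, counts, edges, insert_mean, insert_sd) -> pd.DataFrame:
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    mids = np.concatenate(
        [
            rng.uniform(edges[i], edges[i + 1], size=int(n))
            for i, n in enumerate(counts)
            if n > 0
        ]
    ).astype(np.int64)
    ins = np.clip(rng.normal(insert_mean, insert_sd, size=total), 100, 1000).astype(np.int64)
    start = np.clip(mids - ins // 2, 0, None)
    end = np.minimum(start + ins, L)
    start = np.minimum(start, end - 1)
    mids = np.clip(mids, start, end - 1)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "left_read_mid": mids,
            "mapq": 60,
            "proper_pair": True,
            "duplicate": False,
        }
    )


def simulate_mn(config: SimulationConfig, seed: Optional[int] = None) -> SimulatedDataset:
    """Draw MN and GRN fragment tables under the configured conditions.

    Deterministic given (config, seed).  The shared bias field is drawn
    once per chromosome and applied to the expected counts of both
    fractions before the count noise.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    bias_fields = {}
    mn_frames, grn_frames = [], []
    for c in config.layout.chrom_names:
        L = config.layout.length(c)
        edges = _bin_edges(L, config.bias_bin)
        nbin = edges.size - 1
        if config.bias_sd > 0:
            bias = np.exp(rng.normal(0.0, config.bias_sd, size=nbin))
        else:
            bias = np.ones(nbin)
        bias_fields[c] = bias
        mu_mn = config.expected_bin_counts(c, edges, "MN") * bias
        mu_grn = config.expected_bin_counts(c, edges, "GRN") * bias
        n_mn = _draw_counts(rng, mu_mn, config.noise, config.nb_dispersion)
        n_grn = _draw_counts(rng, mu_grn, config.noise, config.nb_dispersion)
        mn_frames.append(_fragments_for_chrom(rng, c, L, n_mn, edges, config.insert_mean, config.insert_sd))
        grn_frames.append(_fragments_for_chrom(rng, c, L, n_grn, edges, config.insert_mean, config.insert_sd))
    mn = pd.concat(mn_frames, ignore_index=True)
    grn = pd.concat(grn_frames, ignore_index=True)
    mean_mn = np.mean([b.mean() for b in bias_fields.values()]) if bias_fields else 1.0
    per_win = mn.shape[0] / max(1, sum(len(b) for b in bias_fields.values()))
    if per_win < 1:
        import warnings

        warnings.warn("simulate_mn: expected coverage below 1 fragment per bias bin")
    return SimulatedDataset(config, mn, grn, bias_fields, tuple(config.hotspots))


def simulate_repeats(
    layout: GenomeLayout,
    proportions: dict,
    depth: int,
    enrichment: Optional[dict] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial draw of compartment and genomic fragments.

    ``proportions`` maps compartment name -> baseline mass fraction; the
    remainder is genomic mass spread over the layout chromosomes by
    length.  ``enrichment`` multiplies selected compartment masses before
    renormalization (emulating, e.g., rDNA over-representation in an
    unstable condition).
    """
    mass = {k: float(v) for k, v in proportions.items()}
    if enrichment:
        for k, e in enrichment.items():
            mass[k] = mass.get(k, 0.0) * float(e)
    comp_total = sum(mass.values())
    if comp_total >= 1.0 or any(v < 0 for v in mass.values()):
        raise ValueError("compartment proportions must be nonnegative and sum below 1")
    rng = np.random.default_rng(seed)
    names = list(mass) + ["genome"]
    probs = np.array([mass[k] for k in mass] + [1.0 - comp_total])
    probs = probs / probs.sum()
    counts = rng.multinomial(depth, probs)
    frames = []
    for name, n in zip(names, counts):
        if n == 0:
            continue
        if name == "genome":
            lens = np.array([layout.length(c) for c in layout.chrom_names], dtype=float)
            per_chrom = rng.multinomial(n, lens / lens.sum())
            for c, nc in zip(layout.chrom_names, per_chrom):
                if nc == 0:
                    continue
                mids = rng.integers(0, layout.length(c), size=nc)
                frames.append(_table(c, mids, layout.length(c), mapq=60))
        else:
            # repeat contigs: nominal 100 kb contig, low mapq (multi-mapping)
            mids = rng.integers(0, 100_000, size=n)
            frames.append(_table(name, mids, 100_000, mapq=0))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=FRAGMENT_COLUMNS)


def _table(chrom, mids, L, mapq) -> pd.DataFrame:
    mids = np.asarray(mids, dtype=np.int64)
    start = np.clip(mids - 150, 0, None)
    end = np.minimum(start + 300, L)
    start = np.minimum(start, end - 1)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "left_read_mid": np.clip(mids, start, end - 1),
            "mapq": mapq,
            "proper_pair": True,
            "duplicate": False,
        }
    )
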