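# micseq

Coverage analysis for micronucleus sequencing (Mic-Seq).

Red blood cells expel their nucleus during maturation, but DNA damage in
the erythroid lineage leaves behind micronuclei — mostly acentromeric
chromosome fragments produced by double-strand breaks.  Sequencing the DNA
of the micronuclear fraction of blood therefore gives a genome-wide,
cumulative readout of ongoing chromosome breakage in an animal.  `micseq`
turns aligned Mic-Seq fragments into quantitative instability measures and
breakage hot-spot calls, for researchers studying replication stress,
fragile sites and genome instability in mouse models.

## The model

All mouse chromosomes are telocentric, so genomic position `x` on a
chromosome of length `L` is the distance from the centromere.  Micronuclear
tag density across a chromosome is modelled as

```
E[y(x)] = alpha_c + beta * x^2 + rho * (L - x)^2   (+ local gamma steps)
```

- **alpha_c** — per-chromosome baseline: whole-chromosome micronucleation
  plus contamination with nucleated-cell DNA.  Estimated as the minimum
  sliding median (1000 windows) of the coverage profile.
- **beta** — a break at position `p` sends the acentromeric fragment
  `[p, L]` into a micronucleus, and breaks are more consequential towards
  the distal end; integrating a linear break density gives the quadratic
  rise of coverage with centromere distance.
- **rho** — the converse, weaker rise towards the centromere-proximal end,
  visible mainly on the longest chromosomes.
- **gamma** — localized breakage hot spots appear as *steps* in coverage
  that persist distally.  gamma is the slope of a shape-constrained
  (monotone) fit of the coverage profile; after subtracting the fitted
  beta/rho trend slope and multiplying by the distance to the distal
  telomere `(L - x)`, equal breakage rates give equal peak heights
  regardless of position.  Peaks are significant where the normalized
  gamma exceeds `3 * sigma_null * (L - x)`, with `sigma_null` estimated
  from the designated low-hot-spot null chromosomes (chr7 and chr11, the
  larger of the two s.d. values, extreme values trimmed).

Sequencing/GC/strain bias is removed by ratio-normalizing MN window counts
against the granulocyte (GRN) fraction of a control animal; samples are
depth-scaled by median ratios of their alpha estimates.  A multinomial
counter quantifies 45S rDNA and major/minor satellite (MaSat/MiSat)
representation and flags enriched samples against the 95% prediction band
of the baseline rDNA-vs-MaSat regression.

A forward simulator (`micseq.simulate`) generates fragment tables with
exact ground-truth alpha/beta/rho, hot spots, a shared MN/GRN window bias
field and Poisson or negative-binomial counting noise, so every stage has
parameter-recovery tests without any external data.

## Worked example

```python
from micseq import (GenomeLayout, WindowGrid, SimulationConfig, Hotspot,
                    simulate_mn, count_windows, grn_normalize, fit_trend,
                    GammaAnalysis)

layout = GenomeLayout.from_dict(
    {"chr1": 40_000_000, "chr7": 30_000_000, "chr11": 30_000_000})
cfg = SimulationConfig(layout=layout,
                       hotspots=(Hotspot("chr1", 24_000_000, 15_000),),
                       seed=11)
ds = simulate_mn(cfg)

grid = WindowGrid(layout, 20_000, 10_000)   # pooled-data grid
mn = count_windows(ds.mn, grid, "MN")
grn = count_windows(ds.grn, grid, "GRN")
norm = grn_normalize(mn, grn)

trend = fit_trend(norm, null_chroms=("chr7", "chr11"))
trend.bootstrap(frac=0.5, reps=200, seed=11)
print(trend.summary())

gamma = GammaAnalysis(norm, trend, null_chroms=("chr7", "chr11")).run()
top = max(gamma.peaks, key=lambda p: p.gamma_norm)
print(f"{len(gamma.peaks)} significant peaks; strongest at "
      f"{top.chrom}:{top.apex:,}")
```

prints

```
Chromosome trend model: y = alpha_c + beta*x^2 + rho*(L-x)^2
  null chromosomes : chr7, chr11
  n windows        : 5970
  residual norm    : 577.062

  param           estimate       boot sd                        95% CI
  beta         2.92124e-15     4.767e-16      [2.151e-15, 4.13235e-15]
  rho                    0     3.022e-16              [0, 1.03401e-15]
  alpha[chr7]       16.5037        0.2416            [15.7859, 16.7984]
  alpha[chr11]       16.8372        0.2602            [16.1424, 17.1021]

25 significant peaks; strongest at chr1:24,000,000
```

The fitted beta (2.9e-15 counts/bp², bootstrap CI covering the generating
value 3e-15) is the chromosome-wide distal retention bias; the strongest
peak sits exactly at the injected hot spot.  The remaining peaks are the
calibrated ~0.4% false-positive rate any empirical 3-s.d. cutoff implies.

The same pipeline is scriptable from the shell:

```
micseq simulate --config sim.yaml -o simdir/
micseq count --fragments simdir/fragments_MN.tsv --chrom-sizes simdir/chrom.sizes \
             --window 20000 --step 10000 -o counts_MN.tsv
micseq normalize --mn counts_MN.tsv --grn counts_GRN.tsv --chrom-sizes ... -o norm.tsv
micseq fit-trend --norm norm.tsv --chrom-sizes ... -o trend.json
micseq gamma --norm norm.tsv --trend trend.json --chrom-sizes ... -o gamma/
micseq run --config run.yaml -o out/            # whole pipeline from a sample sheet
```

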