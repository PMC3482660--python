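# absquant

Absolute transcriptome and proteome quantification for cell populations:
convert relative expression measurements into molecules per cell, and
analyze what the absolute numbers reveal.

Most expression assays are relative — read counts, probe intensities,
precursor ion intensities — and compositional effects make them treacherous
to compare across conditions whose total RNA or protein content differs
(e.g. proliferating versus quiescent yeast, where total RNA per cell drops
by ~85% while the proteome merely scales with cell volume).  `absquant`
implements the calibration chain that anchors such data to absolute scales:

- **RNA**: reads-per-kilobase scores, simulated-read mappability
  correction, "DNA over simulated" sequencibility flags, spike-in
  calibration of a molecule counter, and anchor-gene regression calibrating
  all features to copies/cell (`absquant.rna`);
- **protein**: in-silico tryptic digestion, MS-suitable peptide counting
  (700–6000 Da monoisotopic), peptide-count-normalized summed intensities,
  and heavy-peptide anchor regression (`absquant.proteins`);

both through one shared log-log calibration model with bootstrap fold-error
estimation (`absquant.core`):

    log c = a + b * log s        =>        c = exp(a) * s^b

with copies `c` as response and relative score `s` as predictor.  On top of
the calibrated copy numbers:

- **expression zones** (`absquant.zones`): stratification relative to the
  1 copy/cell mark (zone 1 < 0.5, zone 2 0.5–2, zone 3 > 2 copies/cell),
  cumulative abundance shares and power-law rank fits;
- **cell-cycle deconvolution** (`absquant.cellcycle`): closed-form
  basal/peak copy numbers for periodic genes from the asynchronous average
  `Cbas = Ctot / (A·f_peak + 1 − f_peak)`, with a multi-step ramping
  variant, switch-gene classification and peak-length scans;
- **enrichment** (`absquant.enrichment`): sliding-window Fisher exact tests
  along the abundance ranking with Benjamini–Hochberg correction, and exact
  binomial association tests;
- **condition comparison** (`absquant.compare`): capped-rod cell volumes
  `V = πD²(L − D/3)/4`, per-cell versus per-volume retention, fold-change
  censuses, total-RNA-content time-course correction, and protein/mRNA
  amplification analysis.

A seeded generator (`absquant.simulate`) produces synthetic genomes,
ground-truth copy numbers and synthetic measurements (Poisson read counts,
noisy counter runs with spikes, summed MS intensities, cell geometries,
time courses) with the statistical structure the analyses assume, so every
stage is testable by parameter recovery — see `docs/methods.md`.

## Worked example

```python
from absquant.simulate import (SimulationConfig, generate_catalog, generate_truth,
    generate_readcounts, generate_simulated_reads, generate_ncounter)
from absquant import rna
from absquant.core import ExpressionTable, predict_copies
from absquant.zones import zone_summary
from absquant.cellcycle import basal_peak

cfg = SimulationConfig(seed=7)                      # genome-scale synthetic study
catalog = generate_catalog(cfg)
truth = generate_truth(catalog, cfg)

reads = generate_readcounts(truth, catalog, cfg, "proliferating")
factors = rna.mappability_factors(generate_simulated_reads(catalog, cfg))
corrected = rna.apply_correction(reads.rpk(), factors)
anchors, _ = rna.calibrate_spikes(generate_ncounter(truth, cfg, "proliferating"))
model = rna.fit_anchor_model(corrected.reindex(anchors.index).dropna(), anchors)
expr = predict_copies(model, corrected, "proliferating")

mrna = expr.copies[expr.copies.index.str.startswith("mrna_")]
print(f"calibration: slope={model.slope:.3f}, intercept={model.intercept:.3f}, "
      f"n_anchors={model.n_anchors}")
print(f"median mRNA abundance: {mrna.median():.2f} copies/cell")
print(zone_summary(ExpressionTable.from_copies("proliferating", mrna))
      .table[["count", "fraction_percent"]])

cbas, cpeak = basal_peak(ctot=2.4, amplitude=4.0, f_peak=0.1)
print(f"periodic gene at Ctot=2.4, A=4, f_peak=0.1: "
      f"basal {cbas:.2f}, peak {cpeak:.2f} copies/cell")
```

prints

```
calibration: slope=0.977, intercept=-5.009, n_anchors=49
median mRNA abundance: 2.40 copies/cell
           count  fraction_percent
zone
1            394               7.7
2           1819              35.6
3           2897              56.7
no_signal      0               0.0
periodic gene at Ctot=2.4, A=4, f_peak=0.1: basal 1.85, peak 7.38 copies/cell
```

The 49-anchor regression recovers the (unit-slope) relation between
corrected scores and copies/cell from noisy counter measurements; the
calibrated transcriptome has a median of 2.4 mRNA copies/cell with ~8% of
genes tightly repressed below 0.5 copies and ~57% robustly expressed above
2 copies.  The deconvolution shows that a periodic gene averaging 2.4
copies with a 4-fold amplitude and a 10%-of-cycle peak oscillates between
~1.8 and ~7.4 copies/cell — boosted in its peak phase but never leaving
the robust-expression zone.

The same operations are available from the shell:

```sh
absquant simulate --seed 7 --outdir sim/
absquant calibrate-rna --counts sim/reads_proliferating.tsv \
    --simulated sim/simulated_reads.tsv --anchors anchors.tsv --out copies.tsv
absquant zones --expression copies.tsv --out zones.tsv
```

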