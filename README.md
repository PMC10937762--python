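# stingquant

Quantitative analysis of neuron-intrinsic cGAS–STING pathway activation in
ALS/FTD-style imaging and expression data.

In ALS and FTD, the innate-immune adaptor STING is activated inside the
most vulnerable neurons — layer V cortical motor neurons and spinal motor
neurons — where it relocalizes to a perinuclear compartment while its
downstream effectors (p-IRF3, p-NF-κB) appear in the nucleus, often
alongside the DNA-damage marker γH2AX. Demonstrating this quantitatively
requires a per-cell measurement pipeline (who is a neuron, which layer,
how much STING sits next to the nucleus, which cells count as positive)
plus cohort-level statistics, and a pathway-level enrichment readout on
transcriptomic data. `stingquant` implements that pipeline as a tested,
reusable library for anyone doing per-cell immunofluorescence
quantification with layer-resolved positive-cell counting, together with a
from-scratch preranked gene-set enrichment statistic and a synthetic-data
generator that makes the whole chain verifiable by planted-truth recovery.

## What is implemented

- **Imaging I/O** — multi-page 16-bit TIFF + YAML channel-role sidecars;
  max/mean/sum z-projection.
- **Segmentation** — DAPI nuclei (Otsu + distance-transform watershed),
  pan-neuronal masks, nearest-nucleus cytoplasm assignment, layer
  assignment by cortical band geometry or a layer marker (CTIP2/CRYM
  analog).
- **Quantification** — the perinuclear ring (nuclear mask dilated 10
  iterations minus the nucleus), exact area/integrated-intensity/mean per
  compartment, stained area above background, positive-cell calling
  (control mean + k·SD, global Otsu, or fixed), dual-positive and
  layer-resolved counting.
- **Enrichment** — preranked GSEA: weighted running-sum ES, gene-sampling
  permutation null, NES, two-sided empirical p, leading edge, and a
  random-gene-set negative control; a 25-gene STING-pathway panel ships as
  a replaceable synthetic fixture (GMT).
- **Statistics** — unpaired two-tailed Student's t (pooled variance; Welch
  optional), fold change with bootstrap CI over units, ΔΔCt qPCR fold
  changes, significance stars, report bundles.
- **Synthetic cohorts** — fields of disk-and-annulus neurons in layer
  bands with planted per-(group, layer) positive fractions, perinuclear-
  biased STING, coupled nuclear effectors, PSF/Poisson/Gaussian noise, and
  ground-truth tables; named presets plant the study's reported effect
  sizes (five-fold layer-V excess, 36.4% layer-V neuron loss, 18.9%
  perinuclear co-labeling, 4/5/3-fold spinal motor neuron excesses).

The enrichment statistic (ES/NES/empirical p) is written from scratch —
see `docs/methods.md` for the model and its numerical choices.

## Worked example

Recover the planted perinuclear co-labeling fraction end to end
(generate → segment → dilate ring → call → count):

```python
from stingquant.analyses import perinuclear_dual_fraction

result = perinuclear_dual_fraction(seed=33)
print(f"{result['percent_dual']:.1f}% of {result['n_cells']} CTIP2+ neurons "
      f"are perinuclear-STING-positive (planted {result['planted_percent']}%)")
```

prints

```
18.9% of 1859 CTIP2+ neurons are perinuclear-STING-positive (planted 18.9%)
```

i.e. the automated pipeline recovers the planted 18.9% dual-positive
fraction to within the binomial sampling error of a ~1900-cell cohort.
The same pattern works for the other presets, e.g.
`layer_sting_fold_change("fig1b_c9_layerV", seed=11)` returns the
layer-V fold change (planted 5×) with its bootstrap CI and t-test, and the
layer II/III comparison, which stays non-significant.

Enrichment, on a synthetic DE table with a planted pathway shift:

```python
from stingquant import (DePreset, generate_de_table, rank_by_log2fc,
                        analyze_gene_set, random_geneset_control, sting_core_panel)

ranked = rank_by_log2fc(generate_de_table(DePreset(seed=1)))
res = analyze_gene_set(ranked, sting_core_panel(), n_perm=10000, seed=1)
ctl = random_geneset_control(ranked, size=30, n_sets=200, n_perm=1000, seed=1)
print(f"ES={res.es:.3f} NES={res.nes:.2f} p={res.p_emp:.2e}; "
      f"random-set significant fraction={ctl['significant'].mean():.3f}")
```

prints

```
ES=0.972 NES=3.26 p=1.00e-04; random-set significant fraction=0.050
```

— the planted 25-gene panel is strongly enriched (p at the permutation
floor) while random 30-gene sets reach nominal significance at the
expected 5% rate.

There is also a CLI (`stingquant simulate|quantify|enrich|qpcr|report`);
run any subcommand with `--help`.

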