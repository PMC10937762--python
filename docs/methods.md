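# Methods

## What the package measures

`stingquant` quantifies innate-immune activation in single neurons from
multi-channel fluorescence images. The biological readouts are:

- **Perinuclear STING.** STING is an ER-resident adaptor that relocalizes to
  a compact perinuclear compartment when activated. Per cell, the nuclear
  mask (from the DNA dye) is dilated a fixed number of iterations (default
  10, 3×3 structuring element) and the *ring* — dilated mask minus the
  nucleus — is the perinuclear compartment. Area, integrated intensity
  (exact pixel sum), mean, and stained area (pixels above a per-image
  background cut) are recorded there and in the nuclear and cytoplasmic
  compartments.
- **Nuclear effectors.** p-IRF3 / p-NF-κB / γH2AX analogs are measured over
  the nuclear mask; dual positivity (e.g. γH2AX⁺ ∧ STING⁺) is the
  conjunction of per-marker calls.
- **Layer identity.** Cortical layer comes either from horizontal band
  geometry (human-tissue mode) or from a layer-marker channel (CTIP2
  analog, nuclear; CRYM analog, cytoplasmic).
- **Counting statistics.** Cells aggregate to fields, fields average to one
  value per unit (well / mouse / individual), and groups are compared with
  unpaired two-tailed Student's t-tests (pooled variance; Welch optional).
  Fold change is the ratio of group means with a seeded bootstrap CI over
  units. The unit of analysis is always the well/section/mouse, never the
  cell.

A separate track implements preranked gene-set enrichment of a 25-gene
cGAS–STING panel over log2-fold-change-ranked differential-expression
tables, with a random-gene-set negative control.

## Segmentation and cell assembly

Nuclei: Gaussian smooth (σ=2) → Otsu threshold → fill holes →
distance-transform watershed (peak markers ≥5 px apart) → area gate
(40–2500 px). The pipeline is deliberately the minimal standard one and
every parameter is config-exposed. Blank channels return an empty mask.

Neuron mask: Otsu on the smoothed pan-neuronal channel (fixed-quantile
alternative exposed). A cell is a neuron when ≥50% of a thin (2-iteration)
ring around its nucleus overlaps the neuron mask.

Cytoplasm of cell *k*: pixels inside the neuron mask, outside every
nucleus, within 15 µm of nucleus *k*, whose nearest nucleus pixel
(Euclidean distance transform with feature indices) belongs to *k*. For the
convex somata rendered by the generator this equals the geodesic
assignment; exactly equidistant pixels follow the deterministic scan order
of the distance transform. Cytoplasm regions of distinct cells are
disjoint by construction.

## Positivity calling

Three interchangeable policies turn one per-cell measurement (default: the
perinuclear STING mean) into a binary call:

- `control_mean_plus_k_sd` — threshold at mean + k·SD (k default 2) of a
  control-group reference distribution; expected false-positive rate under a
  Gaussian reference is Φ̄(k) ≈ 2.3% at k=2.
- `otsu_global` (default) — Otsu cut on the pooled per-cell measurement
  distribution of the whole cohort. Used as default because the cohort
  pooling gives a clearly bimodal distribution whenever any group carries
  positives, and no explicit control reference is needed.
- `fixed` — user-supplied threshold.

Thresholds are cohort-global so both groups are compared on one scale, and
the threshold used is always returned/logged.

## Enrichment statistic

Given genes ranked by log2FC (descending; ties broken lexicographically),
the running sum steps up by |score|^p / N_R at member genes (p = 1,
N_R = Σ members' |score|^p) and down by 1/(N − N_h) otherwise. ES is the
signed extremum; the running sum ends at exactly 0. The null is fgsea-style
gene sampling: ES of n_perm uniformly drawn sets of the same size (a
shared null per set size). NES divides ES by the mean |ES| of
matching-sign null draws. The empirical p is **two-sided on |ES|**,
p = (1 + #{|null| ≥ |ES|}) / (n_perm + 1): it is floored at 1/(n_perm+1)
and — unlike a one-sided-per-sign count thresholded on both signs, which
doubles the type-I rate — keeps the random-gene-set significance rate at
the nominal α. The bundled 25-gene panel is a synthetic stand-in assembled
from canonical pathway members (sensor, adaptor, trafficking, kinases,
transcription factors, ISG readouts) and can be replaced by any GMT file;
the random control defaults to 30-gene sets.

## Synthetic-data generator

The generator is the benchmark substrate: every downstream stage is tested
by recovery of planted truth.

**Forward model.** Cells are a nuclear disk (radius ~N(7, 0.8²) px) plus a
cytoplasm annulus (width 10 px); no neurites. Per (group, layer, marker) a
planted fraction of cells is positive. A positive cell's STING signal is
split between a perinuclear band (nucleus edge → +8 px) and the distal
cytoplasm according to `perinuclear_bias` (default 0.8). The optical chain
is Gaussian PSF blur (σ=1.2 px) → Poisson shot noise (gain 0.25) →
Gaussian read noise (SD 8) → uint16 quantization, over a background offset
of 100. Placement is dart throwing with a hard non-overlap constraint;
failure after bounded retries raises a placement error rather than
silently truncating. Identical (preset, seed, group, field) reproduces
identical images bit for bit.

**Free parameters.** The source studies report counts and fold changes but
no intensity distributions, so the intensity model (negative/positive
means 30/600 for STING, etc.), noise levels and geometry above are
synthetic defaults chosen to resemble ordinary confocal data:
signal-to-background ≈ 5–6 for positive cells, clearly resolvable but
noisy single-cell distributions. They are declared in `ImagingPreset` and
are not calibrated to any reported image data.

**Named presets** plant the reported effect sizes as study conditions:

| preset | planted contrast | layout |
|---|---|---|
| `fig1b_c9_layerV` | layer-V STING⁺ fraction 0.30 vs 0.06 (5×); II/III 0.04 both | 8 vs 6 sections × 20 fields × ~50 cells |
| `fig1g_sals/_c9/_fals` | ventral-horn STING⁺ 4× / 5× / 3× over 0.08 | 13v6 / 6v6 / 4v3 sections × 20 fields × ~20 cells |
| `fig2b_mouse` | layer-V cell density ×0.636 (36.4% loss) | 5 vs 4 mice × 20 fields |
| `fig2d_mouse_layerV` | 18.9% of layer-V CTIP2⁺ cells STING⁺ | 2 sections × 20 fields (~1900 cells) |
| `fig6_shTDP43` | STING⁺ 0.40 vs 0.08, γH2AX coupled at 0.85 | 6 vs 6 wells × 5 fields |

Problem sizes (fields per section, cells per field, the two-section fig2d
cohort) were chosen once so that the planted-recovery estimators have
sampling error comfortably inside the recovery tolerances; they are the
package's desk-scale stand-ins for tissue-scale data.

**What the generator does not emulate** — and hence what passing recovery
tests do *not* show about real tissue: neurite morphology and touching
somata, autofluorescence and z-dependent aberrations, DAB chromogen
optics, staining batch effects, segmentation failure modes of crowded
tissue, or biological covariance between markers beyond the single
coupling knob. Recovery results certify the measurement logic, not
robustness to histology artifacts.

**DE tables.** Background log2FC ~ N(0, 0.3); target-set genes receive a
+1.0 mean shift (both configurable); adjusted p-values are BH on two-sided
normal z-tests — bookkeeping so the padj < 0.05 convention is exercised,
not a count-model fit.

## Numerical choices

- Dilation uses the 3×3 square (8-connectivity, the ImageJ convention);
  4-connectivity is exposed. Dilation satisfies the semigroup property
  including border clipping.
- The perinuclear region excludes the nucleus by default (STING is
  cytoplasmic/ER); `include_nucleus` preserves the literal
  "within the dilated mask" reading.
- ES is clipped to [−1, 1] to absorb a few ULP of cumulative-sum rounding.
- Integrated intensities are exact float sums; no interpolation anywhere.
- Background cut for stained area: median + 3·1.4826·MAD of the channel.
- All randomness flows from explicit seeds; per-field streams are derived
  with `SeedSequence([seed, crc32(group), field_index])` so fields are
  independent and reproducible in any order.
- qPCR ΔΔCt: ΔCt = Cq_target − Cq_ref (single reference gene by default;
  arithmetic-mean-of-Cq option = geometric mean of expression),
  ΔΔCt = mean ΔCt(treated) − mean ΔCt(vehicle), fold = 2^(−ΔΔCt).
- No multiple-testing correction across comparisons by default (matching
  the source analyses); BH is available where p-values are tabulated.

## Known limitations

- 2D only: z-stacks are max-projected (mean/sum exposed); no 3D ring.
- No colocalization coefficients; dual positivity is flag conjunction.
- The Otsu calling policy assumes the pooled measurement distribution is
  bimodal; cohorts with ~0% positives should use the control-reference
  policy.
- The enrichment module implements the simple gene-sampling null, not
  fgsea's multilevel refinement, so p-values are floored at 1/(n_perm+1).
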