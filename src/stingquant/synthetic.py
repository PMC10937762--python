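"""Synthetic fluorescence-microscopy cohorts and DE tables with planted truth.

The generator emulates confocal fields of cortical or spinal-cord neurons:
cells are rendered as a nuclear disk (DAPI analog) surrounded by a cytoplasm
annulus (pan-neuronal marker analog), arranged in horizontal cortical layer
bands. A configurable fraction of cells per (group, layer) is planted
STING-positive; their STING signal is concentrated in a perinuclear band
(the hallmark of ER-localized, activated STING) with the remainder in the
distal cytoplasm. A nuclear effector channel (p-IRF3 / gH2AX analog) can be
coupled to STING positivity, and a layer-marker channel (CTIP2 analog,
nuclear; or CRYM analog, cytoplasmic) labels cells of a designated layer.
The forward optical model is: ideal signal -> Gaussian PSF blur -> Poisson
shot noise -> Gaussian read noise -> 16-bit quantization.

Every rendered cell has a ground-truth row (position, layer, radius, true
positivity and true mean intensity per marker), so segmentation, positivity
calling and group statistics can all be benchmarked by recovery.

A companion generator emulates differential-expression result tables
(gene, log2FC, padj): background log2FC is Gaussian noise and a designated
gene set receives a planted mean shift, with BH-adjusted two-sided normal
p-values — the substrate for the preranked enrichment analysis.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .enrichment import GeneSet, sting_core_panel
from .errors import ConfigurationError, PlacementError
from .imaging_io import ChannelStack, write_stack

__all__ = [
    "MarkerIntensity",
    "ImagingPreset",
    "DePreset",
    "generate_field",
    "iter_cohort",
    "generate_cohort",
    "generate_de_table",
]

MARKERS = ("sting", "effector", "layer_marker", "neuron_marker", "nucleus_dye")


@dataclass(frozen=True)
class MarkerIntensity:
    """Mean fluorescence (arbitrary units, above background) for one marker."""

    negative_mean: float
    positive_mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.positive_mean > self.negative_mean:
            raise ConfigurationError(
                f"positive_mean must exceed negative_mean "
                f"({self.positive_mean} <= {self.negative_mean})"
            )


DEFAULT_INTENSITY = {
    "nucleus_dye": MarkerIntensity(0.0, 900.0, 60.0),
    "neuron_marker": MarkerIntensity(0.0, 500.0, 50.0),
    "sting": MarkerIntensity(30.0, 600.0, 40.0),
    "effector": MarkerIntensity(20.0, 500.0, 40.0),
    "layer_marker": MarkerIntensity(20.0, 700.0, 50.0),
}


@dataclass(frozen=True)
class ImagingPreset:
    """All knobs of one synthetic imaging condition.

    ``positive_fraction`` maps ``(group, layer, marker)`` to the planted
    fraction of positive cells; missing keys mean 0 (for ``sting`` and
    ``effector``) while the layer marker is implied positive for all cells
    of ``marker_layer``. ``density_factor`` scales the expected cell count
    of a (group, layer), modelling neuron loss. Identical (preset, seed,
    group, field_index) always reproduces identical images.
    """

    name: str = "custom"
    field_shape: tuple[int, int] = (512, 512)
    n_cells_per_field: float = 50.0
    layer_bands: tuple[tuple[str, tuple[float, float]], ...] = (
        ("II/III", (0.05, 0.45)),
        ("V", (0.55, 0.95)),
    )
    positive_fraction: Mapping[tuple[str, str, str], float] = field(
        default_factory=dict
    )
    density_factor: Mapping[tuple[str, str], float] = field(default_factory=dict)
    intensity: Mapping[str, MarkerIntensity] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY)
    )
    nucleus_radius_px: tuple[float, float] = (7.0, 0.8)
    cytoplasm_width_px: float = 10.0
    perinuclear_band_px: float = 8.0
    perinuclear_bias: float = 0.8
    background_offset: float = 100.0
    noise_gaussian_sd: float = 8.0
    poisson_scale: float = 0.25
    psf_sigma_px: float = 1.2
    pixel_size_um: float = 0.325
    marker_layer: str | None = "V"
    layer_marker_localization: str = "nuclear"
    non_neuron_fraction: float = 0.05
    effector_coupling: float | None = None
    poisson_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for key, frac in self.positive_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"positive_fraction{key} = {frac} not in [0,1]")
        if not 0.0 <= self.perinuclear_bias <= 1.0:
            raise ConfigurationError("perinuclear_bias must be in [0,1]")
        if not 0.0 <= self.non_neuron_fraction <= 1.0:
            raise ConfigurationError("non_neuron_fraction must be in [0,1]")
        bands = sorted(self.layer_bands, key=lambda b: b[1][0])
        prev_end = 0.0
        for label, (y0, y1) in bands:
            if not (0.0 <= y0 < y1 <= 1.0):
                raise ConfigurationError(f"band {label!r} interval {y0, y1} invalid")
            if y0 < prev_end:
                raise ConfigurationError(f"layer bands overlap at {label!r}")
            prev_end = y1
        if self.layer_marker_localization not in ("nuclear", "cytoplasmic"):
            raise ConfigurationError("layer_marker_localization: nuclear|cytoplasmic")

    def fraction(self, group: str, layer: str, marker: str) -> float:
        return float(self.positive_fraction.get((group, layer, marker), 0.0))

    def density(self, group: str, layer: str) -> float:
        return float(self.density_factor.get((group, layer), 1.0))

    def with_seed(self, seed: int) -> "ImagingPreset":
        return replace(self, seed=int(seed))


def _field_rng(preset: ImagingPreset, group: str, field_index: int) -> np.random.Generator:
    """Deterministic per-(preset, group, field) stream.

    The preset name enters the key so distinct presets sharing a seed and
    group labels still draw independent fields.
    """
    key = [
        preset.seed,
        zlib.crc32(preset.name.encode()),
        zlib.crc32(group.encode()),
        field_index,
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def _band_pixels(shape: tuple[int, int], interval: tuple[float, float]) -> tuple[int, int]:
    h = shape[0]
    return int(round(interval[0] * h)), int(round(interval[1] * h))


def _place_cells(
    rng: np.random.Generator,
    preset: ImagingPreset,
    group: str,
) -> list[dict]:
    """Dart-throwing placement of non-overlapping cells within layer bands."""
    h, w = preset.field_shape
    band_heights = {lbl: iv[1] - iv[0] for lbl, iv in preset.layer_bands}
    total_height = sum(band_heights.values())
    cells: list[dict] = []
    for label, interval in preset.layer_bands:
        mean_n = (
            preset.n_cells_per_field
            * band_heights[label]
            / total_height
            * preset.density(group, label)
        )
        n = int(rng.poisson(mean_n)) if preset.poisson_counts else int(round(mean_n))
        y_lo, y_hi = _band_pixels(preset.field_shape, interval)
        for _ in range(n):
            r_mu, r_sd = preset.nucleus_radius_px
            radius = float(np.clip(rng.normal(r_mu, r_sd), r_mu - 3 * r_sd, r_mu + 3 * r_sd))
            margin = radius + preset.cytoplasm_width_px + 2.0
            placed = False
            for _try in range(300):
                y = rng.uniform(max(y_lo, margin), min(y_hi, h - margin))
                x = rng.uniform(margin, w - margin)
                ok = True
                for other in cells:
                    min_d = (
                        radius + other["radius"] + 2 * preset.cytoplasm_width_px + 2.0
                    )
                    if (y - other["y"]) ** 2 + (x - other["x"]) ** 2 < min_d**2:
                        ok = False
                        break
                if ok:
                    cells.append({"y": y, "x": x, "radius": radius, "layer": label})
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place cell {len(cells) + 1} in layer {label!r} of a "
                    f"{h}x{w} field; reduce n_cells_per_field or enlarge the field"
                )
    return cells


def _disk_patch(
    shape: tuple[int, int], y: float, x: float, r_outer: float
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Bounding-box slices and squared-distance patch for one cell."""
    h, w = shape
    r = int(np.ceil(r_outer)) + 1
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - y) ** 2 + (xx - x) ** 2
    return (slice(y0, y1), slice(x0, x1)), d2


def generate_field(
    preset: ImagingPreset, group: str, field_index: int = 0
) -> tuple[ChannelStack, pd.DataFrame]:
    """Render one field and its ground-truth table.

    Returns a 2D five-channel stack (uint16) and a DataFrame with one row
    per planted cell: cell_id, centroid, layer, nucleus radius, neuron flag,
    per-marker true positivity and true mean intensity.
    """
    if field_index < 0:
        raise ValueError("field_index must be >= 0")
    rng = _field_rng(preset, group, field_index)
    cells = _place_cells(rng, preset, group)
    shape = preset.field_shape
    canvases = {role: np.zeros(shape, dtype=float) for role in MARKERS}
    rows = []
    for i, cell in enumerate(cells):
        layer = cell["layer"]
        r = cell["radius"]
        r_peri = r + preset.perinuclear_band_px
        r_out = r + preset.cytoplasm_width_px
        sl, d2 = _disk_patch(shape, cell["y"], cell["x"], r_out)
        nucleus = d2 <= r**2
        peri = (d2 > r**2) & (d2 <= r_peri**2)
        distal = (d2 > r_peri**2) & (d2 <= r_out**2)
        cytoplasm = peri | distal

        is_neuron = rng.random() >= preset.non_neuron_fraction
        sting_pos = is_neuron and rng.random() < preset.fraction(group, layer, "sting")
        base_eff = preset.fraction(group, layer, "effector")
        if preset.effector_coupling is not None and sting_pos:
            effector_pos = rng.random() < preset.effector_coupling
        else:
            effector_pos = is_neuron and rng.random() < base_eff
        in_marker_layer = preset.marker_layer is not None and layer == preset.marker_layer
        layer_marker_pos = is_neuron and in_marker_layer

        def level(marker: str, positive: bool) -> float:
            m = preset.intensity[marker]
            mean = m.positive_mean if positive else m.negative_mean
            if mean <= 0:
                return 0.0
            return float(max(rng.normal(mean, m.sd), 0.0))

        dye = level("nucleus_dye", True)
        canvases["nucleus_dye"][sl][nucleus] += dye

        tuj = level("neuron_marker", True) if is_neuron else 0.0
        if tuj:
            canvases["neuron_marker"][sl][cytoplasm] += tuj

        sting_mean = level("sting", sting_pos)
        if sting_mean:
            if sting_pos:
                total = sting_mean * cytoplasm.sum()
                n_peri, n_dist = max(peri.sum(), 1), max(distal.sum(), 1)
                canvases["sting"][sl][peri] += preset.perinuclear_bias * total / n_peri
                canvases["sting"][sl][distal] += (
                    (1.0 - preset.perinuclear_bias) * total / n_dist
                )
            else:
                canvases["sting"][sl][cytoplasm] += sting_mean

        eff_mean = level("effector", effector_pos)
        if eff_mean:
            canvases["effector"][sl][nucleus] += eff_mean

        lm_mean = level("layer_marker", layer_marker_pos)
        if lm_mean:
            target = nucleus if preset.layer_marker_localization == "nuclear" else cytoplasm
            canvases["layer_marker"][sl][target] += lm_mean

        rows.append(
            {
                "cell_id": f"{group}_f{field_index}_c{i}",
                "field_index": field_index,
                "group": group,
                "x": cell["x"],
                "y": cell["y"],
                "layer": layer,
                "nucleus_radius_px": r,
                "is_neuron": is_neuron,
                "sting_pos": sting_pos,
                "effector_pos": effector_pos,
                "layer_marker_pos": layer_marker_pos,
                "sting_true_mean": sting_mean,
                "effector_true_mean": eff_mean,
                "layer_marker_true_mean": lm_mean,
            }
        )

    channels = {}
    for role, img in canvases.items():
        img = img + preset.background_offset
        if preset.psf_sigma_px > 0:
            img = ndi.gaussian_filter(img, preset.psf_sigma_px)
        if preset.poisson_scale > 0:
            img = rng.poisson(img * preset.poisson_scale) / preset.poisson_scale
        if preset.noise_gaussian_sd > 0:
            img = img + rng.normal(0.0, preset.noise_gaussian_sd, size=img.shape)
        channels[role] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    truth_cols = [
        "cell_id", "field_index", "group", "x", "y", "layer", "nucleus_radius_px",
        "is_neuron", "sting_pos", "effector_pos", "layer_marker_pos",
        "sting_true_mean", "effector_true_mean", "layer_marker_true_mean",
    ]
    truth = pd.DataFrame(rows, columns=truth_cols)
    stack = ChannelStack(
        channels=channels,
        pixel_size_um=preset.pixel_size_um,
        acquisition={"preset": preset.name, "group": group, "field_index": field_index},
    )
    return stack, truth


def iter_cohort(
    preset: ImagingPreset,
    group_sizes: Mapping[str, int],
    fields_per_section: int = 20,
) -> Iterator[tuple[str, int, int, ChannelStack, pd.DataFrame]]:
    """Yield (group, section, field, stack, truth) for a whole cohort.

    Sections are independent units (wells / mice / individuals); fields of a
    section use distinct field indices so all fields are independent draws.
    """
    if not group_sizes:
        raise ConfigurationError("group_sizes must be non-empty")
    for group, n_sections in group_sizes.items():
        for section in range(n_sections):
            for f in range(fields_per_section):
                idx = section * fields_per_section + f
                stack, truth = generate_field(preset, group, idx)
                truth = truth.assign(section=section, field_in_section=f)
                yield group, section, f, stack, truth


def generate_cohort(
    preset: ImagingPreset,
    group_sizes: Mapping[str, int],
    out_dir: str | Path,
    fields_per_section: int = 20,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Write a cohort to disk: TIFFs, per-field truth CSVs and a manifest.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set. Deterministic: the manifest records an MD5 per
    image so repeat runs can be verified byte-for-byte.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise ConfigurationError(
            f"output directory {out_dir} is not empty; pass overwrite=True"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for group, section, f, stack, truth in iter_cohort(
        preset, group_sizes, fields_per_section
    ):
        safe_group = group.replace("/", "-")
        stem = f"{safe_group}_s{section:02d}_f{f:02d}"
        tiff_path = out_dir / f"{stem}.tif"
        write_stack(stack, tiff_path)
        truth_path = out_dir / f"{stem}_truth.csv"
        truth.to_csv(truth_path, index=False)
        records.append(
            {
                "group": group,
                "section": section,
                "field": f,
                "image": tiff_path.name,
                "truth": truth_path.name,
                "n_cells": len(truth),
                "md5": hashlib.md5(tiff_path.read_bytes()).hexdigest(),
            }
        )
    manifest = pd.DataFrame(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    import yaml

    meta = {
        "preset": preset.name,
        "seed": preset.seed,
        "layer_bands": [[lbl, list(iv)] for lbl, iv in preset.layer_bands],
        "marker_layer": preset.marker_layer,
        "pixel_size_um": preset.pixel_size_um,
        "fields_per_section": int(fields_per_section),
        "group_sizes": {g: int(n) for g, n in group_sizes.items()},
    }
    (out_dir / "cohort.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return manifest


# ---------------------------------------------------------------------------
# synthetic differential-expression tables


@dataclass(frozen=True)
class DePreset:
    """Planted-enrichment DE table: background noise + shifted target set."""

    n_genes: int = 15000
    target_set: GeneSet | None = None
    planted_shift: float = 1.0
    null_sd: float = 0.3
    seed: int = 0

    def resolved_target(self) -> GeneSet:
        return self.target_set if self.target_set is not None else sting_core_panel()


def _gene_universe(n_genes: int, target: GeneSet) -> list[str]:
    members = sorted(target.members)
    if len(members) > n_genes:
        raise ConfigurationError("target set larger than the gene universe")
    n_bg = n_genes - len(members)
    background = [f"GENE{i:05d}" for i in range(n_bg)]
    return members + background


def generate_de_table(preset: DePreset) -> pd.DataFrame:
    """Emulate a DESeq2-style result table (gene, log2fc, padj, in_target).

    Background log2FC ~ Normal(0, null_sd); target-set genes get an added
    mean shift of ``planted_shift``. Adjusted p-values are BH-corrected
    two-sided normal p-values of log2fc / null_sd — bookkeeping so the
    downstream padj < 0.05 convention is exercised, not a count model fit.
    """
    target = preset.resolved_target()
    genes = _gene_universe(preset.n_genes, target)
    missing = target.members - set(genes)
    if missing:
        raise ConfigurationError(f"target genes missing from universe: {sorted(missing)}")
    rng = np.random.default_rng(preset.seed)
    log2fc = rng.normal(0.0, preset.null_sd, size=len(genes))
    in_target = np.fromiter((g in target.members for g in genes), bool, len(genes))
    log2fc[in_target] += preset.planted_shift
    z = log2fc / preset.null_sd
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"gene": genes, "log2fc": log2fc, "pvalue": pvals, "padj": padj,
         "in_target": in_target}
    )
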