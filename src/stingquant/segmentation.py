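"""Nuclear segmentation, neuron masking and per-cell record assembly.

The nuclear pipeline is the minimal standard one for DAPI-like channels:
Gaussian smooth -> Otsu threshold -> fill holes -> distance-transform
watershed to split touching nuclei -> size filter. Cytoplasm is assigned to
the nearest nucleus within the neuron mask, bounded by a maximum soma
radius; the perinuclear compartment is the 10-iteration dilation ring of
the nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, segmentation as skseg
from skimage.feature import peak_local_max

from .errors import ConfigurationError
from .imaging_io import ChannelStack
from .morphology import perinuclear_ring

__all__ = [
    "LabelMask",
    "CellRecord",
    "segment_nuclei",
    "define_neuron_mask",
    "assemble_cells",
]


@dataclass
class LabelMask:
    """Integer label image (0 = background) with provenance."""

    labels: np.ndarray
    provenance: str = ""

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass
class CellRecord:
    """One segmented cell: geometry, compartment masks and measurements."""

    cell_id: int
    nucleus_label: int
    centroid: tuple[float, float]
    nuclear_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    perinuclear_mask: np.ndarray
    layer_label: str = "unassigned"
    is_neuron: bool = True
    ring_clipped: bool = False
    measurements: dict = field(default_factory=dict)
    positivity: dict = field(default_factory=dict)


def segment_nuclei(
    nucleus_channel: np.ndarray,
    min_area_px: int = 40,
    max_area_px: int = 2500,
    smooth_sigma: float = 2.0,
    min_peak_distance: int = 5,
) -> LabelMask:
    """Segment nuclei from a DAPI-like channel.

    Blank (constant) channels return an empty mask rather than erroring.
    Touching nuclei are split by watershed on the distance transform with
    peak markers at least ``min_peak_distance`` apart; labels are compact
    consecutive integers ordered by scan position.
    """
    img = np.asarray(nucleus_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_nuclei expects a 2D channel")
    smoothed = ndi.gaussian_filter(img, smooth_sigma)
    if np.ptp(smoothed) == 0:
        return LabelMask(np.zeros(img.shape, dtype=np.int32), "nucleus_dye/blank")
    fg = smoothed > filters.threshold_otsu(smoothed)
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return LabelMask(np.zeros(img.shape, dtype=np.int32), "nucleus_dye/empty")
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=min_peak_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = skseg.watershed(-dist, markers, mask=fg)
    # size gate, then renumber consecutively
    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < min_area_px) | (areas > max_area_px))
    labels[np.isin(labels, bad[bad > 0])] = 0
    labels, _, _ = skseg.relabel_sequential(labels)
    return LabelMask(labels.astype(np.int32), "nucleus_dye/otsu+watershed")


def define_neuron_mask(
    neuron_channel: np.ndarray, policy: str = "otsu", quantile: float = 0.9
) -> np.ndarray:
    """Binary mask of neuronal (pan-marker-positive) pixels.

    ``otsu`` thresholds the smoothed channel globally; ``quantile`` uses a
    fixed intensity quantile instead. All-constant channels yield an empty
    mask (nothing above threshold is distinguishable from background).
    """
    img = np.asarray(neuron_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("define_neuron_mask expects a 2D channel")
    if policy not in ("otsu", "quantile"):
        raise ValueError(f"unknown neuron-mask policy {policy!r}")
    if np.ptp(img) == 0:
        return np.ones(img.shape, bool) if img.flat[0] >= 65535 else np.zeros(img.shape, bool)
    smoothed = ndi.gaussian_filter(img, 1.0)
    if policy == "otsu":
        thr = filters.threshold_otsu(smoothed)
    elif policy == "quantile":
        thr = float(np.quantile(smoothed, quantile))
    else:
        raise ValueError(f"unknown neuron-mask policy {policy!r}")
    mask = smoothed > thr
    labeled, _ = ndi.label(mask)
    sizes = np.bincount(labeled.ravel())
    keep = sizes >= 16
    keep[0] = False
    return keep[labeled]


def _nearest_nucleus(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel Euclidean distance to, and label of, the nearest nucleus pixel."""
    dist, (iy, ix) = ndi.distance_transform_edt(labels == 0, return_indices=True)
    return dist, labels[iy, ix]


def assemble_cells(
    nuclei: LabelMask,
    neuron_mask: np.ndarray,
    stack: ChannelStack,
    layer_bands: Sequence[tuple[str, tuple[float, float]]] | None = None,
    max_radius_um: float = 15.0,
    dilation_iterations: int = 10,
    connectivity: int = 8,
    neuron_overlap_min: float = 0.5,
) -> list[CellRecord]:
    """Build per-cell records from nuclei, the neuron mask and the stack.

    Cytoplasm of cell k = pixels inside ``neuron_mask``, outside every
    nucleus, whose nearest nucleus pixel belongs to nucleus k and lies
    within ``max_radius_um``. The perinuclear compartment is the dilation
    ring of the nucleus (other nuclei excluded). A cell is a neuron when at
    least ``neuron_overlap_min`` of a thin ring around its nucleus overlaps
    the neuron mask. Layers come from horizontal band geometry when
    ``layer_bands`` is given; otherwise all cells are 'unassigned' (a
    layer-marker channel can re-assign them downstream).
    """
    labels = nuclei.labels
    if labels.shape != stack.shape:
        raise ConfigurationError("label mask and stack shapes differ")
    neuron_mask = np.asarray(neuron_mask, dtype=bool)
    n = int(labels.max())
    if n == 0:
        return []
    max_radius_px = max_radius_um / stack.pixel_size_um
    dist, nearest = _nearest_nucleus(labels)
    cyto_owner = np.where(
        neuron_mask & (labels == 0) & (dist <= max_radius_px), nearest, 0
    )
    h, w = labels.shape
    props = measure.regionprops(labels)
    records = []
    pad = dilation_iterations + 2
    for prop in props:
        k = prop.label
        # work on an expanded bounding-box patch; dilation cannot escape it
        y0, x0, y1, x1 = prop.bbox
        py0, px0 = max(y0 - pad, 0), max(x0 - pad, 0)
        py1, px1 = min(y1 + pad, h), min(x1 + pad, w)
        win = (slice(py0, py1), slice(px0, px1))
        nuc_patch = labels[win] == k
        ring_patch = perinuclear_ring(nuc_patch, 2, connectivity)
        overlap = neuron_mask[win][ring_patch].mean() if ring_patch.any() else 0.0
        peri_patch = perinuclear_ring(nuc_patch, dilation_iterations, connectivity)
        peri_patch &= labels[win] == 0  # never sample a neighbouring nucleus
        nuc = np.zeros(labels.shape, bool)
        nuc[win] = nuc_patch
        peri = np.zeros(labels.shape, bool)
        peri[win] = peri_patch
        touches_border = y0 == 0 or x0 == 0 or y1 == h or x1 == w
        layer = "unassigned"
        if layer_bands:
            yfrac = prop.centroid[0] / h
            for band_label, (y0, y1) in layer_bands:
                if y0 <= yfrac < y1:
                    layer = band_label
                    break
        records.append(
            CellRecord(
                cell_id=k,
                nucleus_label=k,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                nuclear_mask=nuc,
                cytoplasm_mask=cyto_owner == k,
                perinuclear_mask=peri,
                layer_label=layer,
                is_neuron=bool(overlap >= neuron_overlap_min),
                ring_clipped=bool(touches_border),
            )
        )
    return records
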