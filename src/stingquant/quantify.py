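"""Measurement core: compartment intensities, the perinuclear ring readout,
positive-cell calling and field-level counting.

Per cell and compartment (nuclear / cytoplasmic / perinuclear) we record the
mask area (px and um^2), the integrated intensity (exact pixel sum) and the
mean. "Stained area" is the count of pixels above a per-image background
threshold. Cells are then called positive for a marker by thresholding one
chosen measurement — either relative to a control-group reference
distribution (mean + k*SD), by a global Otsu cut on the pooled per-cell
measurement distribution, or at a fixed value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import filters

from .errors import ConfigurationError
from .imaging_io import ChannelStack
from .morphology import dilate_nuclear_mask  # re-exported public surface
from .segmentation import CellRecord

__all__ = [
    "Measurement",
    "PositivityPolicy",
    "FieldSummary",
    "dilate_nuclear_mask",
    "pixel_background_threshold",
    "measure_compartment",
    "measure_perinuclear",
    "measure_cells",
    "call_positive",
    "count_dual_positive",
    "summarize_field",
    "assign_layer_from_marker",
]

COMPARTMENTS = ("nuclear", "cytoplasmic", "perinuclear")


@dataclass(frozen=True)
class Measurement:
    area_px: int
    area_um2: float
    integrated_intensity: float
    mean_intensity: float
    stained_area_px: int | None = None
    flag_empty: bool = False


@dataclass(frozen=True)
class PositivityPolicy:
    """How a per-cell measurement becomes a positive/negative call.

    method 'control_mean_plus_k_sd' thresholds at mean + k*SD of a control
    reference distribution; 'otsu_global' takes the Otsu cut of the pooled
    per-cell measurements (useful when no explicit control reference
    exists); 'fixed' uses ``value`` directly. ``target_measure`` names the
    (compartment, channel_role, statistic) column that is thresholded.
    """

    method: str = "otsu_global"
    k: float = 2.0
    value: float | None = None
    target_measure: tuple[str, str, str] = ("perinuclear", "sting", "mean")

    def __post_init__(self) -> None:
        if self.method not in ("control_mean_plus_k_sd", "otsu_global", "fixed"):
            raise ConfigurationError(f"unknown positivity method {self.method!r}")
        if self.k <= 0:
            raise ConfigurationError("k must be > 0")
        if self.method == "fixed" and self.value is None:
            raise ConfigurationError("fixed policy requires a value")

    @property
    def column(self) -> str:
        comp, role, stat = self.target_measure
        return f"{comp}_{role}_{stat}"

    def threshold(self, values: np.ndarray, reference: np.ndarray | None = None) -> float:
        if self.method == "fixed":
            return float(self.value)
        if self.method == "control_mean_plus_k_sd":
            if reference is None or len(reference) == 0:
                raise ConfigurationError(
                    "control_mean_plus_k_sd requires a non-empty reference"
                )
            ref = np.asarray(reference, dtype=float)
            return float(ref.mean() + self.k * ref.std(ddof=1))
        values = np.asarray(values, dtype=float)
        if len(values) < 2 or np.ptp(values) == 0:
            return float(values.max()) if len(values) else 0.0
        return float(filters.threshold_otsu(values))


@dataclass
class FieldSummary:
    """Counts for one field: neurons, per-layer marker positives, duals."""

    field_id: str
    group: str
    section: int
    n_neurons: int
    positive_by_layer: dict
    n_dual_positive: int
    n_marker_layer_neurons: int
    fraction_marker_layer_sting_positive: float


def pixel_background_threshold(
    channel: np.ndarray, method: str = "median_mad", k: float = 3.0
) -> float:
    """Per-image background cut for 'stained area' (robust median + k*MAD)."""
    img = np.asarray(channel, dtype=float)
    if method == "median_mad":
        med = float(np.median(img))
        mad = float(np.median(np.abs(img - med)))
        return med + k * 1.4826 * mad
    if method == "otsu":
        return float(filters.threshold_otsu(img))
    raise ConfigurationError(f"unknown background method {method!r}")


def _mask_for(cell: CellRecord, compartment: str) -> np.ndarray:
    if compartment == "nuclear":
        return cell.nuclear_mask
    if compartment == "cytoplasmic":
        return cell.cytoplasm_mask
    if compartment == "perinuclear":
        return cell.perinuclear_mask
    raise ConfigurationError(f"unknown compartment {compartment!r}")


def measure_compartment(
    cell: CellRecord,
    channel: np.ndarray,
    compartment: str,
    pixel_size_um: float = 0.325,
    background_threshold: float | None = None,
) -> Measurement:
    """Exact area / integrated-intensity / mean over one compartment mask.

    Empty masks (e.g. a ring fully clipped at the image border) return a
    zero-area measurement flagged ``flag_empty`` rather than raising.
    """
    mask = _mask_for(cell, compartment)
    vals = np.asarray(channel, dtype=float)[mask]
    area = int(mask.sum())
    if area == 0:
        return Measurement(0, 0.0, 0.0, 0.0, 0 if background_threshold is not None else None, True)
    integrated = float(vals.sum())
    stained = (
        int((vals > background_threshold).sum())
        if background_threshold is not None
        else None
    )
    return Measurement(
        area_px=area,
        area_um2=area * pixel_size_um**2,
        integrated_intensity=integrated,
        mean_intensity=integrated / area,
        stained_area_px=stained,
    )


def measure_perinuclear(
    cell: CellRecord,
    sting_channel: np.ndarray,
    pixel_size_um: float = 0.325,
    background_threshold: float | None = None,
) -> Measurement:
    """Perinuclear-ring STING readout (area, integrated, mean).

    The ring must have been built by nuclear-mask dilation during cell
    assembly; ``background_threshold`` enables the stained-area readout
    (pixels above background within the ring).
    """
    if background_threshold is None:
        background_threshold = pixel_background_threshold(sting_channel)
    return measure_compartment(
        cell, sting_channel, "perinuclear", pixel_size_um, background_threshold
    )


DEFAULT_MEASURES: tuple[tuple[str, str], ...] = (
    ("perinuclear", "sting"),
    ("cytoplasmic", "sting"),
    ("nuclear", "effector"),
    ("nuclear", "layer_marker"),
    ("cytoplasmic", "layer_marker"),
    ("nuclear", "nucleus_dye"),
)


def measure_cells(
    cells: Sequence[CellRecord],
    stack: ChannelStack,
    measures: Iterable[tuple[str, str]] = DEFAULT_MEASURES,
    background_k: float = 3.0,
) -> pd.DataFrame:
    """Tidy per-cell measurement table for one field.

    Columns follow ``{compartment}_{role}_{area_px|area_um2|integrated|mean|
    stained_area}``; measurements are also stored on each CellRecord.
    """
    measures = [(c, r) for c, r in measures if r in stack.channels]
    bg = {
        role: pixel_background_threshold(stack.channels[role], k=background_k)
        for _, role in measures
    }
    rows = []
    for cell in cells:
        row: dict = {
            "cell_id": cell.cell_id,
            "centroid_y": cell.centroid[0],
            "centroid_x": cell.centroid[1],
            "layer": cell.layer_label,
            "is_neuron": cell.is_neuron,
            "ring_clipped": cell.ring_clipped,
        }
        for comp, role in measures:
            m = measure_compartment(
                cell, stack.channels[role], comp, stack.pixel_size_um, bg[role]
            )
            cell.measurements[(comp, role)] = m
            prefix = f"{comp}_{role}"
            row[f"{prefix}_area_px"] = m.area_px
            row[f"{prefix}_area_um2"] = m.area_um2
            row[f"{prefix}_integrated"] = m.integrated_intensity
            row[f"{prefix}_mean"] = m.mean_intensity
            row[f"{prefix}_stained_area"] = m.stained_area_px
        rows.append(row)
    return pd.DataFrame(rows)


def call_positive(
    cell_table: pd.DataFrame,
    policy: PositivityPolicy,
    marker: str | None = None,
    reference: np.ndarray | pd.Series | None = None,
) -> tuple[pd.DataFrame, float]:
    """Flag cells positive for a marker by thresholding one measurement.

    Returns the table with a ``{marker}_positive`` column added and the
    threshold actually used (logged for reproducibility). The call is
    strictly-greater-than, so a fixed threshold of 0 on strictly positive
    measurements flags every cell.
    """
    col = policy.column
    if col not in cell_table.columns:
        raise ConfigurationError(f"measurement column {col!r} missing from cell table")
    marker = marker or policy.target_measure[1]
    values = cell_table[col].to_numpy(dtype=float)
    thr = policy.threshold(values, None if reference is None else np.asarray(reference))
    out = cell_table.copy()
    out[f"{marker}_positive"] = values > thr
    return out, thr


def count_dual_positive(
    cell_table: pd.DataFrame, marker_a: str, marker_b: str
) -> int:
    """Cells positive for both markers (conjunction of the two flags)."""
    a = cell_table[f"{marker_a}_positive"].to_numpy(bool)
    b = cell_table[f"{marker_b}_positive"].to_numpy(bool)
    return int((a & b).sum())


def assign_layer_from_marker(
    cell_table: pd.DataFrame, marker: str = "layer_marker", layer_name: str = "V"
) -> pd.DataFrame:
    """Override band-geometry layers using layer-marker positivity (CTIP2 mode)."""
    flag = f"{marker}_positive"
    if flag not in cell_table.columns:
        raise ConfigurationError(f"{flag!r} not present; call call_positive first")
    out = cell_table.copy()
    out.loc[out[flag], "layer"] = layer_name
    return out


def summarize_field(
    cell_table: pd.DataFrame,
    field_id: str = "",
    group: str = "",
    section: int = 0,
    markers: Sequence[str] = ("sting", "effector", "layer_marker"),
    dual_pair: tuple[str, str] = ("effector", "sting"),
    marker_layer: str = "V",
) -> FieldSummary:
    """Aggregate one field's cells into the counting readouts.

    Only cells flagged ``is_neuron`` enter any count. ``positive_by_layer``
    maps (layer, marker) -> positive-neuron count; the dual count is the
    conjunction of the two ``dual_pair`` flags; the marker-layer STING
    fraction is the within-layer dual readout (CTIP2+ cells that are also
    STING+).
    """
    neurons = cell_table[cell_table["is_neuron"]]
    counts: dict = {}
    for marker in markers:
        flag = f"{marker}_positive"
        if flag not in neurons.columns:
            continue
        for layer, sub in neurons.groupby("layer"):
            counts[(str(layer), marker)] = int(sub[flag].sum())
    dual = 0
    if all(f"{m}_positive" in neurons.columns for m in dual_pair):
        dual = count_dual_positive(neurons, *dual_pair)
    layer_cells = neurons[neurons["layer"] == marker_layer]
    n_marker_layer = len(layer_cells)
    frac = (
        float(layer_cells["sting_positive"].mean())
        if n_marker_layer and "sting_positive" in layer_cells.columns
        else 0.0
    )
    return FieldSummary(
        field_id=field_id,
        group=group,
        section=section,
        n_neurons=int(len(neurons)),
        positive_by_layer=counts,
        n_dual_positive=dual,
        n_marker_layer_neurons=n_marker_layer,
        fraction_marker_layer_sting_positive=frac,
    )
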