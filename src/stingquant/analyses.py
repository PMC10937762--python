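"""Planted-contrast recovery analyses over the named synthetic cohorts.

Each function generates a preset cohort, runs the full measurement pipeline
(segment -> perinuclear ring -> positivity call -> count -> group statistics)
and returns the recovered effect alongside the planted one, so recovery can
be judged end to end rather than stage by stage.
"""

from __future__ import annotations

from .pipeline import (
    QuantConfig,
    call_cohort,
    compare_layer_counts,
    get_preset,
    per_unit_neuron_counts,
    per_unit_positive_counts,
    quantify_preset_cohort,
)
from .quantify import count_dual_positive

__all__ = [
    "layer_sting_fold_change",
    "ctip2_layerV_reduction",
    "perinuclear_dual_fraction",
    "smn_fold_changes",
    "dual_positive_fractions",
]


def _quantified(spec, config: QuantConfig):
    cells = quantify_preset_cohort(spec, config)
    return call_cohort(cells, config)


def layer_sting_fold_change(
    preset_name: str = "fig1b_c9_layerV",
    seed: int = 0,
    config: QuantConfig = QuantConfig(),
) -> dict:
    """Layer-resolved disease/control fold change of STING-positive neurons.

    Returns per-layer fold change of the per-unit mean counts, its bootstrap
    CI and the two-tailed t-test p, plus the planted contrast for reference.
    """
    spec = get_preset(preset_name, seed)
    cells, thresholds = _quantified(spec, config)
    out: dict = {"planted": dict(spec.planted), "thresholds": thresholds, "layers": {}}
    for layer_label, _ in spec.preset.layer_bands:
        units = per_unit_positive_counts(cells, layer_label, "sting")
        comp, ratio, ci = compare_layer_counts(units, spec.disease, spec.control, seed=seed)
        out["layers"][layer_label] = {
            "fold_change": ratio,
            "ci95": ci,
            "p": comp.p_two_tailed,
            "t": comp.t_stat,
            "comparison": comp,
        }
    return out


def ctip2_layerV_reduction(seed: int = 22, config: QuantConfig = QuantConfig()) -> dict:
    """Percent reduction of layer-V marker-positive neuron counts (neuron loss).

    Counts CTIP2-analog-positive layer-V neurons per unit (mouse) and returns
    100 * (1 - mean_disease / mean_control) with the group comparison.
    """
    spec = get_preset("fig2b_mouse", seed)
    cells, _ = _quantified(spec, config)
    units = per_unit_neuron_counts(cells, "V", "layer_marker_positive")
    disease = units.loc[units["group"] == spec.disease, "mean_count"].to_numpy()
    control = units.loc[units["group"] == spec.control, "mean_count"].to_numpy()
    from .stats import student_t_two_tailed

    comp = student_t_two_tailed(disease, control, spec.disease, spec.control)
    reduction = 100.0 * (1.0 - disease.mean() / control.mean())
    return {
        "percent_reduction": float(reduction),
        "planted_percent_reduction": spec.planted["percent_reduction"],
        "n_units": len(units),
        "p": comp.p_two_tailed,
        "comparison": comp,
    }


def perinuclear_dual_fraction(seed: int = 33, config: QuantConfig = QuantConfig()) -> dict:
    """Fraction of marker-positive (CTIP2-analog) neurons with perinuclear STING.

    Disease group only; positivity of both markers is called over the pooled
    cohort and the dual readout is the within-layer STING-positive fraction
    among CTIP2-positive neurons.
    """
    spec = get_preset("fig2d_mouse_layerV", seed)
    cells, thresholds = _quantified(spec, config)
    ctip = cells[cells["is_neuron"] & cells["layer_marker_positive"]]
    frac = float(ctip["sting_positive"].mean())
    return {
        "percent_dual": 100.0 * frac,
        "planted_percent": spec.planted["dual_fraction_percent"],
        "n_cells": int(len(ctip)),
        "thresholds": thresholds,
    }


def smn_fold_changes(seed: int = 0, config: QuantConfig = QuantConfig()) -> dict:
    """Fold changes of STING-positive spinal motor neurons for three cohorts.

    The three ventral-horn cohorts plant four-, five- and three-fold
    disease/control contrasts; each is generated, quantified and compared
    independently.
    """
    out = {}
    for name in ("fig1g_sals", "fig1g_c9", "fig1g_fals"):
        spec = get_preset(name, seed)
        cells, _ = _quantified(spec, config)
        units = per_unit_positive_counts(cells, spec.readout_layer, "sting")
        comp, ratio, ci = compare_layer_counts(units, spec.disease, spec.control, seed=seed)
        out[name] = {
            "fold_change": ratio,
            "planted_ratio": spec.planted["ratio"],
            "ci95": ci,
            "p": comp.p_two_tailed,
        }
    return out


def dual_positive_fractions(seed: int = 0, config: QuantConfig = QuantConfig()) -> dict:
    """Dual effector+STING positive fraction per group (knockdown cohort)."""
    spec = get_preset("fig6_shTDP43", seed)
    cells, _ = _quantified(spec, config)
    out: dict = {"planted": dict(spec.planted), "groups": {}}
    for group, sub in cells[cells["is_neuron"]].groupby("group"):
        dual = count_dual_positive(sub, "effector", "sting")
        out["groups"][group] = {"fraction_dual": dual / len(sub), "n": int(len(sub))}
    return out
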