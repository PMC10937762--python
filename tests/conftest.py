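import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from stingquant import ImagingPreset, generate_field
from stingquant.pipeline import QuantConfig, call_cohort, quantify_cohort
from stingquant.synthetic import iter_cohort


def small_preset(**overrides) -> ImagingPreset:
    """A fast 256x256 single-band preset for unit tests."""
    defaults = dict(
        name="unit_test",
        field_shape=(256, 256),
        n_cells_per_field=10.0,
        layer_bands=(("V", (0.05, 0.95)),),
        positive_fraction={("disease", "V", "sting"): 0.5},
        marker_layer="V",
        non_neuron_fraction=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return ImagingPreset(**defaults)


def match_cells(
    truth: pd.DataFrame, cells: pd.DataFrame, max_dist: float = 5.0
) -> pd.DataFrame:
    """Match detected cells to ground-truth cells by nearest centroid."""
    from scipy.spatial import cKDTree

    tree = cKDTree(truth[["y", "x"]].to_numpy())
    d, idx = tree.query(cells[["centroid_y", "centroid_x"]].to_numpy())
    matched = cells.copy()
    matched["truth_idx"] = np.where(d <= max_dist, idx, -1)
    return matched


@pytest.fixture(scope="session")
def planted_cohort():
    """One ~500-cell planted cohort, quantified and called, with truth.

    Single disease group, 10 fields, ~50 cells each, 18.9% of layer-V
    neurons planted perinuclear-STING-positive; shared across recovery
    tests to keep the suite fast.
    """
    preset = ImagingPreset(
        name="planted_cohort",
        layer_bands=(("V", (0.05, 0.95)),),
        positive_fraction={("disease", "V", "sting"): 0.189},
        marker_layer="V",
        seed=7,
    )
    truths = []
    fields = []
    for group, section, fidx, stack, truth in iter_cohort(preset, {"disease": 1}, 10):
        truths.append(truth)
        fields.append((group, section, fidx, stack, truth))
    cells = quantify_cohort(fields, layer_bands=preset.layer_bands)
    cells, thresholds = call_cohort(cells, QuantConfig())
    truth_all = pd.concat(truths, ignore_index=True)

    # per-field nearest-centroid matching of detections to planted cells
    matched_parts = []
    for fidx, sub in cells.groupby("field"):
        tsub = truth_all[truth_all["field_index"] == fidx].reset_index(drop=True)
        m = match_cells(tsub, sub)
        for col in ("sting_pos", "is_neuron", "layer_marker_pos"):
            m[f"truth_{col}"] = np.where(
                m["truth_idx"] >= 0, tsub[col].to_numpy()[m["truth_idx"].clip(0)], False
            )
        matched_parts.append(m)
    matched = pd.concat(matched_parts, ignore_index=True)
    return {
        "preset": preset,
        "truth": truth_all,
        "cells": matched,
        "thresholds": thresholds,
        "fields": fields,
    }
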