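import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from stingquant import ChannelStack, PositivityPolicy, count_dual_positive, summarize_field
from stingquant.errors import ConfigurationError
from stingquant.morphology import dilate_nuclear_mask
from stingquant.quantify import call_positive, measure_compartment, measure_perinuclear
from stingquant.segmentation import CellRecord


# ---------------------------------------------------------------------------
# independent brute-force oracle for iterative dilation


def brute_force_dilate(mask, iterations, connectivity=8):
    """Flood-style dilation oracle: per-pixel neighbourhood scan per step."""
    mask = mask.astype(bool).copy()
    if connectivity == 8:
        offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    else:
        offsets = [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    for _ in range(iterations):
        out = np.zeros_like(mask)
        for y in range(h):
            for x in range(w):
                for dy, dx in offsets:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and mask[yy, xx]:
                        out[y, x] = True
                        break
        mask = out
    return mask


def single_pixel_mask(size=31):
    m = np.zeros((size, size), bool)
    m[size // 2, size // 2] = True
    return m


@pytest.mark.parametrize(
    "connectivity,expected_area",
    [(8, 441), (4, 2 * 10 * 11 + 1)],  # 21x21 square; L1 ball 2r(r+1)+1
)
def test_ten_iteration_dilation_of_single_pixel(connectivity, expected_area):
    m = single_pixel_mask()
    dilated = dilate_nuclear_mask(m, 10, connectivity)
    assert dilated.sum() == expected_area
    assert (dilated & ~m).sum() == expected_area - 1  # ring area 440 / 220
    np.testing.assert_array_equal(dilated, brute_force_dilate(m, 10, connectivity))


def test_zero_iterations_is_identity_and_negative_rejected():
    rng = np.random.default_rng(0)
    m = rng.random((16, 16)) > 0.7
    np.testing.assert_array_equal(dilate_nuclear_mask(m, 0), m)
    with pytest.raises(ValueError):
        dilate_nuclear_mask(m, -1)


@given(
    seed=st.integers(0, 500),
    a=st.integers(0, 4),
    b=st.integers(0, 4),
    connectivity=st.sampled_from([4, 8]),
)
def test_dilation_semigroup_property(seed, a, b, connectivity):
    """dilate(m, a+b) == dilate(dilate(m, a), b), including border clipping."""
    rng = np.random.default_rng(seed)
    m = rng.random((12, 12)) > 0.85
    lhs = dilate_nuclear_mask(m, a + b, connectivity)
    rhs = dilate_nuclear_mask(dilate_nuclear_mask(m, a, connectivity), b, connectivity)
    np.testing.assert_array_equal(lhs, rhs)


def test_ring_area_is_monotone_in_iterations():
    m = single_pixel_mask(41)
    areas = [(dilate_nuclear_mask(m, i) & ~m).sum() for i in range(12)]
    assert all(b >= a for a, b in zip(areas, areas[1:]))


# ---------------------------------------------------------------------------
# compartment measurements


def make_cell(shape=(32, 32), nuc_r=4, ring_w=3):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (yy - 16) ** 2 + (xx - 16) ** 2
    nuc = d2 <= nuc_r**2
    peri = (d2 > nuc_r**2) & (d2 <= (nuc_r + ring_w) ** 2)
    cyto = (d2 > nuc_r**2) & (d2 <= (nuc_r + 8) ** 2)
    return CellRecord(1, 1, (16.0, 16.0), nuc, cyto, peri)


def test_uniform_ring_measurement():
    cell = make_cell()
    channel = np.zeros((32, 32))
    channel[cell.perinuclear_mask] = 5.0
    m = measure_perinuclear(cell, channel, background_threshold=1.0)
    area = cell.perinuclear_mask.sum()
    assert m.integrated_intensity == pytest.approx(5.0 * area)
    assert m.mean_intensity == pytest.approx(5.0)
    assert m.stained_area_px == area


def test_constant_compartment_integrated_intensity():
    cell = make_cell()
    channel = np.full((32, 32), 7.0)
    m = measure_compartment(cell, channel, "nuclear")
    assert m.integrated_intensity == pytest.approx(7.0 * cell.nuclear_mask.sum())
    assert m.area_um2 == pytest.approx(cell.nuclear_mask.sum() * 0.325**2)


def test_measurement_additivity_over_disjoint_compartments():
    cell = make_cell()
    rng = np.random.default_rng(1)
    channel = rng.random((32, 32)) * 100
    m_nuc = measure_compartment(cell, channel, "nuclear")
    m_cyt = measure_compartment(cell, channel, "cytoplasmic")
    union = cell.nuclear_mask | cell.cytoplasm_mask
    assert m_nuc.integrated_intensity + m_cyt.integrated_intensity == pytest.approx(
        channel[union].sum()
    )


@pytest.mark.parametrize("seed", range(5))
def test_measurement_agrees_with_naive_per_pixel_loop(seed):
    rng = np.random.default_rng(seed)
    channel = rng.random((32, 32)) * 50
    cell = make_cell()
    for comp, mask in [
        ("nuclear", cell.nuclear_mask),
        ("cytoplasmic", cell.cytoplasm_mask),
        ("perinuclear", cell.perinuclear_mask),
    ]:
        m = measure_compartment(cell, channel, comp)
        total = sum(
            channel[y, x] for y in range(32) for x in range(32) if mask[y, x]
        )
        assert m.integrated_intensity == pytest.approx(total, rel=1e-12)
        assert m.mean_intensity == pytest.approx(total / mask.sum(), rel=1e-12)


def test_empty_ring_flags_instead_of_raising():
    cell = make_cell()
    cell.perinuclear_mask = np.zeros((32, 32), bool)
    m = measure_perinuclear(cell, np.ones((32, 32)))
    assert m.flag_empty and m.area_px == 0


def test_perinuclear_bias_one_concentrates_signal_in_ring():
    """A bias-1 positive cell keeps >=90% of its STING signal in the ring."""
    from conftest import small_preset
    from stingquant import generate_field
    from stingquant.segmentation import assemble_cells, define_neuron_mask, segment_nuclei

    preset = small_preset(
        perinuclear_bias=1.0,
        cytoplasm_width_px=14.0,
        positive_fraction={("disease", "V", "sting"): 1.0},
        n_cells_per_field=4.0,
        poisson_counts=False,
        seed=9,
    )
    stack, truth = generate_field(preset, "disease", 0)
    nuclei = segment_nuclei(stack.require("nucleus_dye"))
    neuron_mask = define_neuron_mask(stack.channels["neuron_marker"])
    cells = assemble_cells(nuclei, neuron_mask, stack, max_radius_um=8.0)
    assert len(cells) == len(truth)
    img = stack.channels["sting"].astype(float) - preset.background_offset
    for c in cells:
        whole = c.perinuclear_mask | c.cytoplasm_mask
        assert img[c.perinuclear_mask].sum() / img[whole].sum() >= 0.9


# ---------------------------------------------------------------------------
# positivity calling


def _measurement_table(values):
    return pd.DataFrame({"perinuclear_sting_mean": values, "is_neuron": True, "layer": "V"})


def test_fixed_zero_threshold_flags_all_strictly_positive():
    table = _measurement_table([0.1, 5.0, 2.0])
    out, thr = call_positive(
        table, PositivityPolicy(method="fixed", value=0.0)
    )
    assert thr == 0.0
    assert out["sting_positive"].all()


def test_control_k_sd_false_positive_rate_matches_gaussian_tail():
    """With threshold mean+2sd of a Gaussian reference, FPR ~ P(Z>2) ~ 2.3%."""
    rng = np.random.default_rng(0)
    reference = rng.normal(100, 10, size=20000)
    fresh = rng.normal(100, 10, size=20000)
    out, thr = call_positive(
        _measurement_table(fresh),
        PositivityPolicy(method="control_mean_plus_k_sd", k=2.0),
        reference=reference,
    )
    fpr = out["sting_positive"].mean()
    from scipy.stats import norm

    assert fpr == pytest.approx(norm.sf(2.0), abs=0.005)


def test_control_policy_requires_reference():
    with pytest.raises(ConfigurationError, match="reference"):
        call_positive(
            _measurement_table([1.0]),
            PositivityPolicy(method="control_mean_plus_k_sd"),
        )


def test_positive_counts_decrease_as_k_grows():
    rng = np.random.default_rng(1)
    reference = rng.normal(100, 10, 5000)
    values = _measurement_table(rng.normal(110, 20, 5000))
    counts = []
    for k in (1.0, 2.0, 3.0, 4.0):
        out, _ = call_positive(
            values, PositivityPolicy(method="control_mean_plus_k_sd", k=k), reference=reference
        )
        counts.append(out["sting_positive"].sum())
    assert counts == sorted(counts, reverse=True)


def test_percell_positivity_accuracy_on_planted_cohort(planted_cohort):
    cells = planted_cohort["cells"]
    matched = cells[(cells["truth_idx"] >= 0) & cells["is_neuron"]]
    accuracy = (matched["sting_positive"] == matched["truth_sting_pos"]).mean()
    assert accuracy >= 0.9


# ---------------------------------------------------------------------------
# counting


def test_dual_positive_enumeration():
    table = pd.DataFrame(
        {"a_positive": [True, True, False], "b_positive": [True, False, True]}
    )
    assert count_dual_positive(table, "a", "b") == 1


@given(seed=st.integers(0, 1000))
def test_dual_count_bounded_by_single_counts(seed):
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {"a_positive": rng.random(30) > 0.5, "b_positive": rng.random(30) > 0.5}
    )
    dual = count_dual_positive(table, "a", "b")
    assert dual <= min(table["a_positive"].sum(), table["b_positive"].sum())


def test_knockdown_dual_positive_fraction_recovery():
    """TDP-43 knockdown cohort: the recovered dual gH2AX+/STING+ fraction
    per group falls inside the binomial 95% CI of the planted value."""
    from stingquant.analyses import dual_positive_fractions

    result = dual_positive_fractions(seed=5)
    planted = {
        "shTDP43": result["planted"]["dual_fraction_disease"],
        "shScramble": result["planted"]["dual_fraction_control"],
    }
    for group, res in result["groups"].items():
        p, n = planted[group], res["n"]
        half = 1.96 * np.sqrt(p * (1 - p) / n)
        assert res["fraction_dual"] == pytest.approx(p, abs=half), group


def test_field_summary_counts_are_consistent(planted_cohort):
    cells = planted_cohort["cells"]
    one_field = cells[cells["field"] == 0]
    summary = summarize_field(one_field, field_id="f0", group="disease")
    assert summary.n_neurons == one_field["is_neuron"].sum()
    assert all(v <= summary.n_neurons for v in summary.positive_by_layer.values())
    assert 0.0 <= summary.fraction_marker_layer_sting_positive <= 1.0
    layer_v = one_field[one_field["is_neuron"] & (one_field["layer"] == "V")]
    assert summary.positive_by_layer[("V", "sting")] == layer_v["sting_positive"].sum()
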