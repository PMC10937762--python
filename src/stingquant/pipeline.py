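"""End-to-end wiring: simulate -> segment -> measure -> call -> count -> compare.

Named cohort presets encode the study conditions the synthetic generator
emulates — planted disease/control contrasts in layer-resolved STING
positivity, layer-V neuron density, perinuclear co-labeling and
dual-positivity — and this module runs whole cohorts through segmentation,
the perinuclear-ring readout, positivity calling and group statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .imaging_io import ChannelStack, read_stack, project_z
from .quantify import (
    PositivityPolicy,
    assign_layer_from_marker,
    call_positive,
    measure_cells,
)
from .segmentation import assemble_cells, define_neuron_mask, segment_nuclei
from .stats import GroupComparison, fold_change, student_t_two_tailed
from .synthetic import ImagingPreset, iter_cohort

__all__ = [
    "QuantConfig",
    "RunConfig",
    "CohortSpec",
    "PRESETS",
    "get_preset",
    "quantify_field",
    "quantify_cohort",
    "call_cohort",
    "per_unit_positive_counts",
    "compare_layer_counts",
]


@dataclass(frozen=True)
class QuantConfig:
    """Parameters of the measurement stage (all config-exposed)."""

    dilation_iterations: int = 10
    connectivity: int = 8
    max_radius_um: float = 15.0
    min_nucleus_area_px: int = 40
    max_nucleus_area_px: int = 2500
    projection: str = "max"
    neuron_policy: str = "otsu"
    positivity_method: str = "otsu_global"
    positivity_k: float = 2.0
    background_k: float = 3.0
    layer_from: str = "bands"  # or "marker"


@dataclass
class CohortSpec:
    """A named synthetic cohort: preset + group layout + analysis hints."""

    preset: ImagingPreset
    group_sizes: dict[str, int]
    fields_per_section: int
    disease: str
    control: str
    readout_layer: str
    planted: dict = field(default_factory=dict)


def _smn_preset(name: str, disease_fraction: float, control_fraction: float, seed: int = 0) -> ImagingPreset:
    return ImagingPreset(
        name=name,
        field_shape=(360, 360),
        n_cells_per_field=20.0,
        layer_bands=(("ventral_horn", (0.05, 0.95)),),
        positive_fraction={
            ("disease", "ventral_horn", "sting"): disease_fraction,
            ("control", "ventral_horn", "sting"): control_fraction,
        },
        marker_layer=None,
        seed=seed,
    )


def _build_presets() -> dict[str, CohortSpec]:
    presets: dict[str, CohortSpec] = {}

    # Human motor cortex, repeat-expansion carriers vs controls: the planted
    # contrast is a five-fold excess of layer-V STING-positive neurons with
    # matched low positivity in layer II/III.
    presets["fig1b_c9_layerV"] = CohortSpec(
        preset=ImagingPreset(
            name="fig1b_c9_layerV",
            positive_fraction={
                ("disease", "V", "sting"): 0.30,
                ("control", "V", "sting"): 0.06,
                ("disease", "II/III", "sting"): 0.04,
                ("control", "II/III", "sting"): 0.04,
            },
            marker_layer=None,
        ),
        group_sizes={"disease": 8, "control": 6},
        fields_per_section=20,
        disease="disease",
        control="control",
        readout_layer="V",
        planted={"layerV_ratio": 5.0, "layerII_III_ratio": 1.0},
    )

    # Ventral-horn spinal motor neurons: planted four-, five- and three-fold
    # excesses of STING-positive SMNs over matched controls.
    presets["fig1g_sals"] = CohortSpec(
        preset=_smn_preset("fig1g_sals", 0.32, 0.08),
        group_sizes={"disease": 13, "control": 6},
        fields_per_section=20,
        disease="disease",
        control="control",
        readout_layer="ventral_horn",
        planted={"ratio": 4.0},
    )
    presets["fig1g_c9"] = CohortSpec(
        preset=_smn_preset("fig1g_c9", 0.40, 0.08),
        group_sizes={"disease": 6, "control": 6},
        fields_per_section=20,
        disease="disease",
        control="control",
        readout_layer="ventral_horn",
        planted={"ratio": 5.0},
    )
    presets["fig1g_fals"] = CohortSpec(
        preset=_smn_preset("fig1g_fals", 0.24, 0.08),
        group_sizes={"disease": 4, "control": 3},
        fields_per_section=20,
        disease="disease",
        control="control",
        readout_layer="ventral_horn",
        planted={"ratio": 3.0},
    )

    # Mouse repeat-expansion model: planted 36.4% loss of layer-V
    # CTIP2-positive neurons, superficial layers unchanged.
    presets["fig2b_mouse"] = CohortSpec(
        preset=ImagingPreset(
            name="fig2b_mouse",
            density_factor={("disease", "V"): 1.0 - 0.364},
            positive_fraction={
                ("disease", "V", "sting"): 0.19,
                ("control", "V", "sting"): 0.02,
            },
            marker_layer="V",
        ),
        group_sizes={"disease": 5, "control": 4},
        fields_per_section=20,
        disease="disease",
        control="control",
        readout_layer="V",
        planted={"percent_reduction": 36.4},
    )

    # Mouse layer V close-up: 18.9% of CTIP2-positive neurons carry
    # perinuclear STING in the disease group.
    presets["fig2d_mouse_layerV"] = CohortSpec(
        preset=ImagingPreset(
            name="fig2d_mouse_layerV",
            layer_bands=(("V", (0.05, 0.95)),),
            positive_fraction={
                ("disease", "V", "sting"): 0.189,
                ("control", "V", "sting"): 0.02,
            },
            marker_layer="V",
        ),
        group_sizes={"disease": 2},
        fields_per_section=20,
        disease="disease",
        control="disease",
        readout_layer="V",
        planted={"dual_fraction_percent": 18.9},
    )

    # Induced cortical-like neurons after TDP-43 knockdown: dual DNA-damage
    # (gH2AX) and STING positivity rises against a scramble control.
    presets["fig6_shTDP43"] = CohortSpec(
        preset=ImagingPreset(
            name="fig6_shTDP43",
            field_shape=(360, 360),
            n_cells_per_field=20.0,
            layer_bands=(("culture", (0.05, 0.95)),),
            positive_fraction={
                ("shTDP43", "culture", "sting"): 0.40,
                ("shScramble", "culture", "sting"): 0.08,
            },
            effector_coupling=0.85,
            marker_layer=None,
        ),
        group_sizes={"shTDP43": 6, "shScramble": 6},
        fields_per_section=5,
        disease="shTDP43",
        control="shScramble",
        readout_layer="culture",
        planted={"dual_fraction_disease": 0.40 * 0.85, "dual_fraction_control": 0.08 * 0.85},
    )
    return presets


PRESETS = _build_presets()


def get_preset(name: str, seed: int | None = None) -> CohortSpec:
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    spec = PRESETS[name]
    if seed is not None:
        spec = replace(spec, preset=spec.preset.with_seed(seed))
    return spec


# ---------------------------------------------------------------------------
# quantification


def quantify_field(
    stack: ChannelStack,
    layer_bands=None,
    config: QuantConfig = QuantConfig(),
) -> pd.DataFrame:
    """Segment and measure one field; returns the per-cell table (uncalled)."""
    if stack.is_3d:
        stack = project_z(stack, config.projection)
    nuclei = segment_nuclei(
        stack.require("nucleus_dye"),
        min_area_px=config.min_nucleus_area_px,
        max_area_px=config.max_nucleus_area_px,
    )
    if "neuron_marker" in stack.channels:
        neuron_mask = define_neuron_mask(stack.channels["neuron_marker"], config.neuron_policy)
    else:
        neuron_mask = np.ones(stack.shape, bool)
    cells = assemble_cells(
        nuclei,
        neuron_mask,
        stack,
        layer_bands=layer_bands,
        max_radius_um=config.max_radius_um,
        dilation_iterations=config.dilation_iterations,
        connectivity=config.connectivity,
    )
    return measure_cells(cells, stack, background_k=config.background_k)


def quantify_cohort(
    fields: Iterable[tuple[str, int, int, ChannelStack, pd.DataFrame | None]],
    layer_bands=None,
    config: QuantConfig = QuantConfig(),
) -> pd.DataFrame:
    """Quantify an iterable of (group, section, field, stack, truth) fields."""
    tables = []
    for group, section, fidx, stack, _truth in fields:
        table = quantify_field(stack, layer_bands=layer_bands, config=config)
        table.insert(0, "group", group)
        table.insert(1, "section", section)
        table.insert(2, "field", fidx)
        tables.append(table)
    if not tables:
        raise ConfigurationError("no fields to quantify")
    return pd.concat(tables, ignore_index=True)


def quantify_preset_cohort(
    spec: CohortSpec, config: QuantConfig = QuantConfig()
) -> pd.DataFrame:
    """Generate-and-quantify a whole preset cohort in memory."""
    return quantify_cohort(
        iter_cohort(spec.preset, spec.group_sizes, spec.fields_per_section),
        layer_bands=spec.preset.layer_bands,
        config=config,
    )


def load_cohort_fields(cohort_dir: str | Path):
    """Yield (group, section, field, stack, None) from a cohort directory."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    for row in manifest.itertuples():
        yield row.group, int(row.section), int(row.field), read_stack(
            cohort_dir / row.image
        ), None


def cohort_layer_bands(cohort_dir: str | Path):
    meta = yaml.safe_load((Path(cohort_dir) / "cohort.yaml").read_text())
    return tuple((lbl, tuple(iv)) for lbl, iv in meta["layer_bands"])


DEFAULT_CALL_TARGETS = {
    "sting": ("perinuclear", "sting", "mean"),
    "effector": ("nuclear", "effector", "mean"),
    "layer_marker": ("nuclear", "layer_marker", "mean"),
}


def call_cohort(
    cells: pd.DataFrame,
    config: QuantConfig = QuantConfig(),
    markers: Mapping[str, tuple[str, str, str]] = DEFAULT_CALL_TARGETS,
    control_group: str | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Call positivity for each marker over the pooled cohort cell table.

    Thresholds are cohort-global (one per marker) so groups are compared on
    one scale. With the control-reference method, ``control_group`` supplies
    the reference distribution; the default global-Otsu method needs none.
    """
    thresholds: dict[str, float] = {}
    out = cells
    for marker, target in markers.items():
        col = "_".join(target)
        if col not in out.columns:
            continue
        policy = PositivityPolicy(
            method=config.positivity_method, k=config.positivity_k, target_measure=target
        )
        reference = None
        if policy.method == "control_mean_plus_k_sd":
            if control_group is None:
                raise ConfigurationError("control-based policy needs control_group")
            reference = out.loc[out["group"] == control_group, col]
        out, thr = call_positive(out, policy, marker=marker, reference=reference)
        thresholds[marker] = thr
    return out, thresholds


def per_unit_positive_counts(
    cells: pd.DataFrame, layer: str, marker: str = "sting", neurons_only: bool = True
) -> pd.DataFrame:
    """Mean per-field positive-neuron count, one row per (group, section)."""
    df = cells[cells["is_neuron"]] if neurons_only else cells
    df = df[df["layer"] == layer]
    flag = f"{marker}_positive"
    per_field = (
        df.groupby(["group", "section", "field"])[flag].sum().rename("count").reset_index()
    )
    # fields with zero cells in this layer still count as zero
    return (
        per_field.groupby(["group", "section"])["count"].mean().rename("mean_count").reset_index()
    )


def per_unit_neuron_counts(
    cells: pd.DataFrame, layer: str, marker_flag: str | None = None
) -> pd.DataFrame:
    """Mean per-field neuron count per unit, optionally gated on a marker flag."""
    df = cells[cells["is_neuron"]]
    df = df[df["layer"] == layer]
    if marker_flag is not None:
        df = df[df[marker_flag]]
    per_field = df.groupby(["group", "section", "field"]).size().rename("count").reset_index()
    return (
        per_field.groupby(["group", "section"])["count"].mean().rename("mean_count").reset_index()
    )


def compare_layer_counts(
    units: pd.DataFrame,
    disease: str,
    control: str,
    seed: int = 0,
) -> tuple[GroupComparison, float, tuple[float, float]]:
    """Disease-vs-control comparison of per-unit counts with fold change."""
    x = units.loc[units["group"] == disease, "mean_count"].to_numpy()
    y = units.loc[units["group"] == control, "mean_count"].to_numpy()
    comp = student_t_two_tailed(x, y, label_x=disease, label_y=control)
    ratio, ci = fold_change(x, y, seed=seed)
    comp.fold_change = ratio
    return comp, ratio, ci


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    preset: str = "fig1b_c9_layerV"
    seed: int = 0
    out_dir: str = "results"
    dilation_iterations: int = 10
    connectivity: int = 8
    positivity_method: str = "otsu_global"
    positivity_k: float = 2.0
    projection: str = "max"
    n_perm: int = 1000
    alpha: float = 0.05

    def quant_config(self) -> QuantConfig:
        return QuantConfig(
            dilation_iterations=self.dilation_iterations,
            connectivity=self.connectivity,
            projection=self.projection,
            positivity_method=self.positivity_method,
            positivity_k=self.positivity_k,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


PIPELINE_STAGES = ("simulate", "quantify", "enrich", "report")


def run_pipeline(
    config: RunConfig, stages: tuple[str, ...] = ("simulate", "quantify", "report")
) -> dict[str, Path]:
    """Execute pipeline stages in order, resuming from on-disk intermediates.

    simulate writes the cohort under ``<out_dir>/cohort``; quantify turns it
    into ``cells.csv``; report produces the comparisons TSV/JSON; enrich
    runs the gene-set analysis on a generated DE table. A stage whose output
    already exists is skipped (resume); a stage whose input is missing
    raises a ConfigurationError naming the stage to run first. The run log
    records the config echo and its hash so identical configs can be
    checked for identical outputs.
    """
    unknown = set(stages) - set(PIPELINE_STAGES)
    if unknown:
        raise ConfigurationError(
            f"unknown stage(s) {sorted(unknown)}; valid: {PIPELINE_STAGES}"
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = get_preset(config.preset, config.seed)
    qconfig = config.quant_config()
    artifacts: dict[str, Path] = {}
    cohort_dir = out_dir / "cohort"
    cells_path = out_dir / "cells.csv"

    if "simulate" in stages:
        from .synthetic import generate_cohort

        if not (cohort_dir / "manifest.csv").exists():
            generate_cohort(
                spec.preset, spec.group_sizes, cohort_dir, spec.fields_per_section
            )
        artifacts["simulate"] = cohort_dir

    if "quantify" in stages:
        if not cells_path.exists():
            if not (cohort_dir / "manifest.csv").exists():
                raise ConfigurationError(
                    "no cohort manifest found; run the 'simulate' stage first"
                )
            cells = quantify_cohort(
                load_cohort_fields(cohort_dir),
                layer_bands=cohort_layer_bands(cohort_dir),
                config=qconfig,
            )
            cells, _ = call_cohort(cells, qconfig)
            cells.to_csv(cells_path, index=False)
        artifacts["quantify"] = cells_path

    if "enrich" in stages:
        import json as _json

        from . import enrichment as enr
        from .synthetic import DePreset, generate_de_table

        enrich_path = out_dir / "enrichment.json"
        if not enrich_path.exists():
            ranked = enr.rank_by_log2fc(generate_de_table(DePreset(seed=config.seed)))
            res = enr.analyze_gene_set(
                ranked, enr.sting_core_panel(), n_perm=config.n_perm, seed=config.seed
            )
            enrich_path.write_text(_json.dumps(res.to_dict(), indent=2) + "\n")
        artifacts["enrich"] = enrich_path

    if "report" in stages:
        import pandas as pd

        from .stats import build_report

        if not cells_path.exists():
            raise ConfigurationError(
                "no per-cell table found; run the 'quantify' stage first"
            )
        cells = pd.read_csv(cells_path)
        comparisons = []
        if spec.disease != spec.control:
            units = per_unit_positive_counts(cells, spec.readout_layer, "sting")
            comp, _, _ = compare_layer_counts(
                units, spec.disease, spec.control, seed=config.seed
            )
            comparisons.append(comp)
        build_report(
            comparisons,
            out_dir,
            metadata={"config": asdict(config), "config_hash": config.config_hash()},
            plots=False,
        )
        artifacts["report"] = out_dir / "comparisons.tsv"
    return artifacts
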