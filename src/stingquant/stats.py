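"""Group comparisons, fold changes, ddCt qPCR analysis and report output.

The unit of analysis is the section / well / mouse, never the cell: cells
aggregate to fields and fields average to one value per unit, and groups are
compared with an unpaired two-tailed Student's t-test (pooled variance,
df = n1 + n2 - 2; Welch available behind a flag). Fold change is the ratio
of group means with a seeded bootstrap CI over units. Significance stars
follow the usual convention (* p<0.05, ** p<0.01, *** p<0.001,
**** p<0.0001).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError

__all__ = [
    "GroupComparison",
    "significance_stars",
    "student_t_two_tailed",
    "fold_change",
    "ddct_fold_change",
    "build_report",
]


@dataclass
class GroupComparison:
    label_x: str
    label_y: str
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float
    sem_x: float
    sem_y: float
    t_stat: float
    df: float
    p_two_tailed: float
    stars: str
    fold_change: float | None = None
    zero_variance: bool = False
    welch: bool = False

    def to_row(self) -> dict:
        return asdict(self)


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def student_t_two_tailed(
    x: Sequence[float],
    y: Sequence[float],
    label_x: str = "x",
    label_y: str = "y",
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups of per-unit values.

    Pooled-variance Student's t by default (df = n1+n2-2); ``welch=True``
    switches to the unequal-variance form. Two groups with zero pooled
    variance and equal means return t=0, p=1 with a flag rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError("each group needs at least 2 units")
    zero_var = np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0
    if zero_var and np.mean(x) == np.mean(y):
        t, p, df = 0.0, 1.0, float(len(x) + len(y) - 2)
    else:
        res = sps.ttest_ind(x, y, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        label_x=label_x,
        label_y=label_y,
        n_x=len(x),
        n_y=len(y),
        mean_x=float(np.mean(x)),
        mean_y=float(np.mean(y)),
        sem_x=_sem(x),
        sem_y=_sem(y),
        t_stat=t,
        df=df,
        p_two_tailed=p,
        stars=significance_stars(p),
        zero_variance=zero_var,
        welch=welch,
    )


def fold_change(
    disease: Sequence[float],
    control: Sequence[float],
    n_boot: int = 2000,
    ci: float = 0.95,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Ratio of group means (disease / control) with a bootstrap CI.

    The bootstrap resamples units (sections/wells/mice) within each group.
    A zero control mean is an error; add a pseudo-count upstream if counts
    can be zero.
    """
    disease = np.asarray(disease, dtype=float)
    control = np.asarray(control, dtype=float)
    if control.mean() == 0:
        raise ConfigurationError(
            "control group mean is zero; fold change undefined "
            "(consider a pseudo-count on the counts)"
        )
    ratio = float(disease.mean() / control.mean())
    rng = np.random.default_rng(seed)
    d_idx = rng.integers(0, len(disease), size=(n_boot, len(disease)))
    c_idx = rng.integers(0, len(control), size=(n_boot, len(control)))
    d_means = disease[d_idx].mean(axis=1)
    c_means = control[c_idx].mean(axis=1)
    valid = c_means != 0
    boots = d_means[valid] / c_means[valid]
    lo, hi = np.quantile(boots, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return ratio, (float(lo), float(hi))


def ddct_fold_change(
    records: pd.DataFrame,
    reference_genes: Sequence[str] = ("TBP", "HPRT", "GAPDH"),
    vehicle_label: str = "vehicle",
    combine_references: str = "single",
) -> pd.DataFrame:
    """Relative qPCR quantification by the ddCt method.

    ``records`` needs columns sample, gene, condition, cq. Per sample,
    dCt = Cq_target - Cq_reference, where the reference Cq is the first
    available reference gene (``single``) or the arithmetic mean of all
    available reference Cqs, i.e. the geometric mean on the expression
    scale (``mean``). ddCt = mean dCt(condition) - mean dCt(vehicle);
    fold = 2^(-ddCt); log2FC = -ddCt.
    """
    required = {"sample", "gene", "condition", "cq"}
    if not required <= set(records.columns):
        raise ConfigurationError(f"qPCR table needs columns {sorted(required)}")
    if (records["cq"] <= 0).any():
        raise ConfigurationError("Cq values must be positive")
    if vehicle_label not in set(records["condition"]):
        raise ConfigurationError(f"no {vehicle_label!r} condition present")
    ref_cq = {}
    for sample, sub in records.groupby("sample"):
        refs = sub[sub["gene"].isin(reference_genes)]
        if refs.empty:
            raise ConfigurationError(f"sample {sample!r} has no reference-gene Cq")
        if combine_references == "single":
            for ref in reference_genes:
                hit = refs[refs["gene"] == ref]
                if not hit.empty:
                    ref_cq[sample] = float(hit["cq"].mean())
                    break
        elif combine_references == "mean":
            ref_cq[sample] = float(refs["cq"].mean())
        else:
            raise ConfigurationError("combine_references must be 'single' or 'mean'")
    targets = records[~records["gene"].isin(reference_genes)].copy()
    targets["dct"] = targets["cq"] - targets["sample"].map(ref_cq)
    rows = []
    for gene, sub in targets.groupby("gene"):
        veh = sub[sub["condition"] == vehicle_label]["dct"]
        if veh.empty:
            continue
        for cond, csub in sub.groupby("condition"):
            ddct = float(csub["dct"].mean() - veh.mean())
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "n": len(csub),
                    "ddct": ddct,
                    "fold_change": 2.0 ** (-ddct),
                    "log2fc": -ddct,
                }
            )
    return pd.DataFrame(rows).sort_values(["gene", "condition"]).reset_index(drop=True)


def build_report(
    comparisons: Sequence[GroupComparison],
    out_dir: str | Path,
    metadata: Mapping | None = None,
    plots: bool = True,
) -> pd.DataFrame:
    """Write comparisons as TSV (+JSON metadata, + simple boxplot-style PNGs).

    Output is pure: the TSV bytes depend only on the comparisons and
    metadata passed in.
    """
    if not comparisons:
        raise ConfigurationError("at least one comparison required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame([c.to_row() for c in comparisons])
    table.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
    (out_dir / "run_metadata.json").write_text(
        json.dumps(dict(metadata or {}), indent=2, sort_keys=True) + "\n"
    )
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.2 + 1.2 * len(table), 3.2))
        xs = np.arange(len(table))
        ax.bar(xs - 0.18, table["mean_x"], 0.32, yerr=table["sem_x"], capsize=3, label="group x")
        ax.bar(xs + 0.18, table["mean_y"], 0.32, yerr=table["sem_y"], capsize=3, label="group y")
        ax.set_xticks(xs)
        ax.set_xticklabels(
            [f"{r.label_x}\nvs {r.label_y}\n{r.stars}" for r in comparisons], fontsize=7
        )
        ax.set_ylabel("mean ± s.e.m.")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / "comparisons.png", dpi=120)
        plt.close(fig)
    return table
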